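# Methods

## Model and assumptions

The tumor is a well-mixed, deterministic three-type competitive
Lotka–Volterra system; dose acts instantaneously through carrying capacities
(no pharmacokinetics), there is no mutation, phenotype switching, spatial
structure or demographic noise, and total cell density is the clinical
observable (PSA proxy). Types: T⁺ (needs exogenous testosterone), Tᴾ
(produces testosterone; supplies the T⁺ niche via K_T⁺ = μ(Λ)·x_Tᴾ), T⁻
(androgen-independent, abiraterone-resistant). The patient survives while
the total burden stays at or below the viability cap.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| r | (2.7726, 3.4657, 6.6542)·10⁻³ | 1/time | doubling-time-derived growth rates (ln 2 / days, ×10⁻², for LNCaP 60 h, H295R 48 h, PC-3 25 h) |
| A (α_ij) | rows (1, .7, .8), (.4, 1, .6), (.5, 2, 1) | – | per-capita competition; α₃₂ = 2 enables viable stable equilibria |
| K_T⁻ | 10000 | cells | resistant carrying capacity (dose-independent) |
| K_Tᴾ(Λ) | 10000 − 9900 Λ | cells | drug-sensitive capacity, 10000 → 100 across the dose range |
| μ(Λ) | 1.5 − Λ | – | per-Tᴾ-cell contribution to the T⁺ capacity |
| viability_cap | 9000 | cells | maximal tolerated burden; crossing it is patient death |
| tp_floor | 10⁻⁶ | cells | regularization of K_T⁺ as x_Tᴾ → 0 (below) |

"Cells" are model units; one model time unit ≈ 1 day of scaled kinetics
(100 units ≈ a clinical visit interval of just over 3 months).

### Regularization and integration

K_T⁺ = μ·x_Tᴾ vanishes with the Tᴾ population, leaving the T⁺ logistic
bracket undefined at x_Tᴾ = 0. We set K_T⁺ = μ·max(x_Tᴾ, tp_floor) with
tp_floor = 10⁻⁶ cells: T⁺ then sees an essentially zero capacity and
declines to extinction, which is the intended biology, while the field stays
finite. During Runge–Kutta stages the field is evaluated at the boundary of
the positive cone when a stage state overshoots below zero (the T⁺ die-off
near x_Tᴾ = 0 is violently fast relative to the step).

Trajectories use classical fixed-step RK4 with dt = 1 (10⁴ steps over the
default horizon t_f = 10⁴). Rates are O(10⁻³), so dt = 1 sits deep inside
the stability region, and the fixed grid keeps the forward states, backward
costates and control updates of the optimal-control sweep exactly aligned.
An adaptive `scipy.integrate.solve_ivp` path is available
(`method="adaptive"`) and is used in the tests as a cross-check. Densities
below 10⁻⁹ are snapped to 0 after each step (prevents negative drift and
spurious revival of extinct clones). Breach of the viability cap is checked
at every step, not just at protocol measurement times, so a patient can die
between clinical visits.

## Equilibria and thresholds

For constant dose every equilibrium solves a linear system on its support;
supports containing T⁺ without Tᴾ are impossible (K_T⁺ ∝ x_Tᴾ). Candidates
with negative components or singular support systems are discarded;
components at or below tp_floor are treated as absent (boundary equilibrium
of the reduced support). Stability is classified from the eigenvalues of the
analytic Jacobian of the regularized field: strictly stable below −10⁻¹²,
exact zeros "marginal", never stable. For boundary equilibria the rows of
absent species reduce to invasion growth rates, so invasibility comes out of
the same eigenvalue test.

Closed-form thresholds (defaults in parentheses): the T⁻ monoculture
stabilizes once K_Tᴾ(Λ) ≤ α₂₃ K_T⁻, at Λ = (10000 − 6000)/9900 = 0.40404;
the stable T⁺/Tᴾ branch loses stability when T⁻ can invade it, the root of a
quadratic in Λ (0.48278); the viability window on the stable branch is
[0.28615, ≈0.487], lower endpoint from branch-total = cap in closed form,
upper endpoint from root-bracketing on a Λ-sweep with step 10⁻³ (fine enough
to resolve the narrow three-species window). The default sweep grid step is
10⁻³ for the same reason.

Near the bifurcation the leading eigenvalue vanishes (critical slowing
down), so flow-based verification of stability scales its integration
horizon like 15/|Re λ_max| instead of using a fixed horizon.

## Optimal control

The therapy-design problem minimizes ∫‖x − x*‖² dt over dose paths
Λ(t) ∈ [0, 1], for a stable target equilibrium x*. Costates follow
λ̇ = −∂H/∂x with transversality λ(t_f) = 0, integrated backward with RK4 on
the same dt = 1 grid (states linearly interpolated at stage midpoints,
dose piecewise-constant per step); the Jacobian is analytic, with a central
finite-difference route (h = 10⁻⁴·max(1, xᵢ)) kept as a validation oracle.
The printed form of the adjoint system in the source analysis contains
typographical slips, so the Hamiltonian here is constructed directly from
the implemented dynamics rather than transcribed.

Only the T⁺ and Tᴾ drift terms depend on the dose, through 1/μ(Λ) and
1/K_Tᴾ(Λ), so H(Λ) = c + A/μ(Λ) + B/K_Tᴾ(Λ) has at most one interior
stationary point. The sweep's inner loop minimizes H exactly over
{0, 1, closed-form stationary roots}, vectorized over all 10001 time nodes;
the public `pointwise_dose_minimizer` is the reference dense-grid (1001
points) + golden-section implementation, and the two agree to 10⁻⁹ under
test. Ties (dose-independent Hamiltonian, e.g. at t_f by transversality) are
broken toward the previous control value; the terminal node is carried over
from the last interior node.

The Forward–Backward Sweep alternates forward states, backward costates,
and a relaxed control update Λ ← (1 − w)Λ + w·argmin H. A plain fixed
relaxation (ω = 0.2) limit-cycles on this long, stiff horizon, so the step
is objective-guarded: w starts at ω and is halved until the objective stops
increasing by more than 0.1%. Convergence is declared when the maximum
absolute control change falls below tol = 10⁻³ (10⁻⁶ for degenerate
starts); chattering near the singular arc can leave ensemble members above
tol within max_iter = 500, and such members are flagged unconverged but
still included in ensemble means (sample SD, ddof = 1). The initial control
guess is constant 0, matching the titration shape the optimum takes.
Viability is not enforced during the sweep; breach is diagnosed on the final
trajectory.

## Protocols, cohorts, reporting

Titration moves the dose on the grid {0, 0.1, …, 1} by one step per
measurement (every 100 time units): up above 110% of the target volume,
down below 90%. The grid includes 0 (two protocols start drug-free and the
optimal schedules hold dose 0 for hundreds of time units). Targets are the
incoming baseline volume V_a (fixed at t₀, never re-baselined) or a
preset maximum tolerable volume V_b = 7000. Maximum tolerated dose is
Λ ≡ 1. Adaptive therapy doses at Λ = 1 until the volume halves relative to
baseline, then pauses until it regrows to baseline; its thresholds are
monitored continuously (per integration step) rather than at the 100-unit
cadence — under full dose the sensitive pool collapses within a few time
units, so cadence-level monitoring would always overshoot the 50% trigger,
eradicate the sensitive pool, and make the characteristic volume cycling
(and any adaptive survivorship) impossible.

Virtual cohorts draw initial compositions uniformly on the solid simplex
{x ≥ 0, Σx ≤ 9000} by cube rejection — the simplest law producing a
space-filling scatter of viable tumors; the sampler descriptor is recorded
with every cohort. Because the true clinical distribution is unknown,
cohort-level percentages are sampler-dependent; the robust outputs are the
orderings across protocols (MTD worst with 100% breach; drug-free
up-titration to V_b best) and the geometry of surviving initial conditions
(large volumes, bounded T⁻ share). Kaplan–Meier curves right-censor
patients still viable at t_f = 10⁴; curve estimation is delegated to
lifelines and checked against hand-computed product-limit values. A breach
with more than 80% T⁻ (strict) is classified as competitive release; a
total exactly at the cap does not count as a breach (the constraint is
Σx ≤ 9000).

## Problem sizes

Defaults used by the test suite and the reproduction script: cohorts of
300–500 patients for protocol comparisons and the MTD universality check,
20 initial conditions for the optimal-control ensemble, dose sweeps at step
10⁻³, horizons of 10⁴ (scaled up only for the eigenvalue-slowed stability
verification). These sizes leave every reported ordering and threshold far
from its decision boundary while keeping a full run in minutes on one core.

## Known limitations

Percentage-level cohort outcomes inherit the unspecified initial-composition
law; titration protocols that start at full dose drive x_Tᴾ below the
extinction snap within the first measurement interval, so their survival is
essentially nil here — real tumors (and models with stochastic rescue or
slower kill kinetics) may behave less sharply. The synthetic cohorts have no
observation noise, no patient covariates, and exact volume measurements, so
passing trials say nothing about PSA noise robustness. FBS finds stationary
points, not certified global optima.
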