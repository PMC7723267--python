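"""Equilibria of the tumor model at constant dose, and their stability.

For a fixed abiraterone dose the model is a three-species competitive
Lotka-Volterra system, so every equilibrium is the non-negative solution of a
linear system on some support (subset of types with positive density).  T+
can never be present without TP, because its carrying capacity is
proportional to the TP density.  The supports enumerated are therefore:
the extinct state, the T- and TP monocultures, the T+/TP pair, the TP/T-
pair, and the full interior.

Stability is read off the eigenvalues of the Jacobian of the regularized
vector field; for boundary equilibria the rows of absent species reduce to
their invasion growth rates, so invasibility is handled by the same test.
Sweeping the dose axis reproduces the structure of the stable-branch diagram:
a T+/TP branch at low dose, a narrow three-species window, and the resistant
monoculture at high dose.  Closed-form thresholds (monoculture stabilization
dose, branch bifurcation dose, viability window) are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    DEFAULT_PARAMS,
    EIG_STABILITY_TOL,
    EQUILIBRIUM_RESIDUAL_TOL,
    DomainError,
    ModelParams,
    TumorState,
    jacobian,
    logger,
    vector_field,
)

_SUPPORTS = (
    (),
    ("T-",),
    ("TP",),
    ("T+", "TP"),
    ("TP", "T-"),
    ("T+", "TP", "T-"),
)


@dataclass(frozen=True)
class EquilibriumRecord:
    """One equilibrium at one dose: densities, spectrum, stability, viability."""

    lam: float
    x_star: TumorState
    support: tuple[str, ...]
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool
    viable: bool

    @property
    def total_volume(self) -> float:
        return self.x_star.total_volume

    @property
    def eig_real_max(self) -> float:
        return float(np.max(self.eigenvalues.real))


def candidate_equilibria(lam: float, p: ModelParams = DEFAULT_PARAMS) -> list[TumorState]:
    """All non-negative equilibria of the model at constant dose ``lam``.

    Each support's equilibrium conditions are linear; solutions with a
    negative component (or a singular support system) are discarded.
    Components at or below ``tp_floor`` are snapped to zero, collapsing the
    candidate onto the reduced support.
    """
    if not 0.0 <= lam <= 1.0:
        raise DomainError(f"dose {lam} outside [0, 1]")
    A = np.asarray(p.A)
    ktp = float(p.K_TP_law(lam))
    mu = float(p.mu_law(lam))
    k_tm = p.K_Tminus

    # Equilibrium conditions per species (zero logistic bracket):
    #   T+ : x1 + a12 x2 + a13 x3 = mu x2   <=>  x1 + (a12-mu) x2 + a13 x3 = 0
    #   TP : a21 x1 + x2 + a23 x3 = ktp
    #   T- : a31 x1 + a32 x2 + x3 = k_tm
    M = np.array(
        [
            [1.0, A[0, 1] - mu, A[0, 2]],
            [A[1, 0], 1.0, A[1, 2]],
            [A[2, 0], A[2, 1], 1.0],
        ]
    )
    b = np.array([0.0, ktp, k_tm])
    idx = {"T+": 0, "TP": 1, "T-": 2}

    found: list[TumorState] = []
    seen: set[tuple[float, float, float]] = set()
    for support in _SUPPORTS:
        x = np.zeros(3)
        if support:
            ii = [idx[s] for s in support]
            try:
                sol = np.linalg.solve(M[np.ix_(ii, ii)], b[ii])
            except np.linalg.LinAlgError:
                logger.info("singular support system %s at lam=%g", support, lam)
                continue
            if np.any(sol < 0):
                continue
            x[ii] = sol
        x[x <= p.tp_floor] = 0.0
        key = tuple(np.round(x, 9))
        if key in seen:
            continue
        seen.add(key)
        found.append(TumorState.from_array(x))
    return found


def find_equilibrium(lam: float, support: tuple[str, ...],
                     p: ModelParams = DEFAULT_PARAMS) -> TumorState | None:
    """The candidate equilibrium with the given support, if it exists."""
    idx = {"T+": 0, "TP": 1, "T-": 2}
    want = set(idx[s] for s in support)
    for x in candidate_equilibria(lam, p):
        if {i for i, v in enumerate(x) if v > 0} == want:
            return x
    return None


# Constant-dose levels of the two stabilization targets studied in the
# optimal-control analysis: the T+/TP equilibrium at dose 0.4 and the
# three-species equilibrium inside the narrow polymorphic window.
TARGET_DOSES = {"two-species": 0.4, "three-species": 0.4848}
TARGET_SUPPORTS = {"two-species": ("T+", "TP"), "three-species": ("T+", "TP", "T-")}


def stable_target(kind: str, p: ModelParams = DEFAULT_PARAMS):
    """(x_star, lam) for a named stabilization target ('two-species' etc.)."""
    if kind not in TARGET_DOSES:
        raise DomainError(f"unknown target {kind!r}")
    lam = TARGET_DOSES[kind]
    x_star = find_equilibrium(lam, TARGET_SUPPORTS[kind], p)
    if x_star is None:
        raise DomainError(f"no {kind} equilibrium at dose {lam}")
    return x_star, lam


def equilibrium_residual(x_star, lam: float, p: ModelParams = DEFAULT_PARAMS) -> float:
    return float(np.linalg.norm(vector_field(x_star, lam, p)))


def stability_classify(x_star, lam: float, p: ModelParams = DEFAULT_PARAMS,
                       tol: float = EIG_STABILITY_TOL):
    """Eigenvalues of the Jacobian at an equilibrium and the stability flag.

    Stable iff every eigenvalue's real part is below ``-tol``; a spectrum
    whose largest real part sits within ``tol`` of zero is marginal, not
    stable.
    """
    if equilibrium_residual(x_star, lam, p) >= EQUILIBRIUM_RESIDUAL_TOL:
        raise DomainError("x_star is not an equilibrium (residual too large)")
    eig = np.linalg.eigvals(jacobian(x_star, lam, p))
    re_max = float(np.max(eig.real))
    stable = re_max < -tol
    return eig, stable


def classify_record(x_star, lam: float, p: ModelParams = DEFAULT_PARAMS) -> EquilibriumRecord:
    eig, stable = stability_classify(x_star, lam, p)
    re_max = float(np.max(eig.real))
    x = np.asarray(x_star, dtype=float)
    support = tuple(s for s, v in zip(("T+", "TP", "T-"), x) if v > 0)
    return EquilibriumRecord(
        lam=float(lam),
        x_star=TumorState.from_array(x),
        support=support,
        eigenvalues=eig,
        stable=stable,
        marginal=abs(re_max) <= EIG_STABILITY_TOL,
        viable=float(x.sum()) <= p.viability_cap,
    )


def sweep_equilibria(lam_grid, p: ModelParams = DEFAULT_PARAMS) -> list[EquilibriumRecord]:
    """One record per candidate equilibrium per dose on ``lam_grid``."""
    records: list[EquilibriumRecord] = []
    for lam in np.atleast_1d(np.asarray(lam_grid, dtype=float)):
        for x_star in candidate_equilibria(float(lam), p):
            records.append(classify_record(x_star, float(lam), p))
    return records


def default_dose_grid(step: float = 1e-3) -> np.ndarray:
    """Dose grid fine enough to resolve the narrow three-species window."""
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def records_to_dataframe(records):
    import pandas as pd

    return pd.DataFrame(
        {
            "lam": [r.lam for r in records],
            "support": ["+".join(r.support) if r.support else "extinct" for r in records],
            "x_Tplus": [r.x_star.x_Tplus for r in records],
            "x_TP": [r.x_star.x_TP for r in records],
            "x_Tminus": [r.x_star.x_Tminus for r in records],
            "total": [r.total_volume for r in records],
            "stable": [r.stable for r in records],
            "viable": [r.viable for r in records],
            "eig_real_max": [r.eig_real_max for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Closed-form thresholds along the dose axis
# ---------------------------------------------------------------------------

def _two_species_branch(lam: float, p: ModelParams):
    """(x_T+, x_TP) on the T+/TP equilibrium branch at dose ``lam``."""
    A = np.asarray(p.A)
    mu = float(p.mu_law(lam))
    ktp = float(p.K_TP_law(lam))
    x_tp = ktp / (1.0 + A[1, 0] * (mu - A[0, 1]))
    return (mu - A[0, 1]) * x_tp, x_tp


def analytic_thresholds(p: ModelParams = DEFAULT_PARAMS) -> dict:
    """Closed-form dose thresholds of the stable-branch diagram.

    Returns ``lam_Tminus_mono`` (smallest dose at which the resistant
    monoculture at K_T- is stable, i.e. TP can no longer invade it),
    ``lam_bifurcation`` (dose at which T- can invade the T+/TP branch, where
    the stable branch switches to the three-species equilibrium), and
    ``viability_window`` (dose interval on the stable branch whose
    equilibrium total burden is within the viability cap).  A threshold with
    no root in [0, 1] is reported as ``None``.
    """
    A = np.asarray(p.A)

    # TP invasion of the T- monoculture: r_TP (1 - a23 K_Tminus / K_TP(lam)).
    # Stabilizes once K_TP(lam) <= a23 K_Tminus.
    target = A[1, 2] * p.K_Tminus
    if p.K_TP_law.slope == 0:
        lam_mono = None
    else:
        lam_mono = (target - p.K_TP_law.intercept) / p.K_TP_law.slope
        if not 0.0 <= lam_mono <= 1.0:
            lam_mono = None

    # T- invasion of the two-species branch:
    #   (a31 (mu - a12) + a32) x_TP(lam) = K_Tminus
    def tminus_invasion(lam):
        x1, x2 = _two_species_branch(lam, p)
        return (A[2, 0] * x1 + A[2, 1] * x2) - p.K_Tminus

    lam_bif = _bracketed_root(tminus_invasion)

    # Viability window on the two-species branch: total = (1 + mu - a12) x_TP.
    def branch_total_excess(lam):
        x1, x2 = _two_species_branch(lam, p)
        return (x1 + x2) - p.viability_cap

    lam_lo = _bracketed_root(branch_total_excess)
    window = None
    if lam_lo is not None:
        # Upper endpoint: end of the stable viable branch, located by
        # root-bracketing on a fine sweep (the three-species tail is narrow).
        grid = default_dose_grid(1e-3)
        hi = None
        for rec in sweep_equilibria(grid[grid >= lam_lo - 1e-9], p):
            if rec.stable and rec.viable and "TP" in rec.support:
                hi = rec.lam if hi is None else max(hi, rec.lam)
        if hi is not None:
            window = (float(lam_lo), float(hi))
    return {
        "lam_Tminus_mono": None if lam_mono is None else float(lam_mono),
        "lam_bifurcation": None if lam_bif is None else float(lam_bif),
        "viability_window": window,
    }


def _bracketed_root(f, n_scan: int = 200):
    """First root of ``f`` on [0, 1], located by scan + brentq."""
    lams = np.linspace(0.0, 1.0, n_scan + 1)
    vals = np.array([f(l) for l in lams])
    sign = np.sign(vals)
    for k in range(n_scan):
        if sign[k] == 0:
            return float(lams[k])
        if sign[k] * sign[k + 1] < 0:
            return float(brentq(f, lams[k], lams[k + 1], xtol=1e-14))
    return None
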