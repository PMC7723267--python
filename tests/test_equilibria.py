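import numpy as np
import pytest

from evostab import (
    DomainError,
    analytic_thresholds,
    candidate_equilibria,
    simulate,
    stability_classify,
    sweep_equilibria,
    vector_field,
)
from evostab.equilibria import find_equilibrium, records_to_dataframe


def _contains(cands, target, tol):
    target = np.asarray(target)
    return any(np.max(np.abs(np.asarray(c) - target)) < tol for c in cands)


def test_two_species_equilibrium_at_dose_04(params):
    cands = candidate_equilibria(0.4, params)
    assert _contains(cands, (2082.76, 5206.90, 0.0), 0.01)
    assert _contains(cands, (0.0, 0.0, 10000.0), 1e-9)


def test_interior_equilibrium_inside_polymorphic_window(params):
    # frozen from an exact rational solve of the interior 3x3 linear system
    # at dose 0.4848 (mu = 1.0152, K_TP = 5200.48)
    cands = candidate_equilibria(0.4848, params)
    assert _contains(cands, (961.3996, 4478.2998, 562.7007), 1e-3)


def test_infeasible_supports_are_discarded(params):
    # at dose 0.4 the TP/T- pair solves with a negative TP density
    sup = [tuple(s for s, v in zip(("T+", "TP", "T-"), c) if v > 0)
           for c in candidate_equilibria(0.4, params)]
    assert ("TP", "T-") not in sup
    # T+ never appears without TP (its capacity is proportional to x_TP)
    assert all("TP" in s for s in sup if "T+" in s)


def test_all_candidates_have_tiny_residual(params):
    for lam in np.linspace(0.0, 1.0, 21):
        for x in candidate_equilibria(lam, params):
            assert np.linalg.norm(vector_field(x, lam, params)) < 1e-8


def test_tminus_monoculture_stability_flips_with_dose(params):
    # TP invades the resistant monoculture at low dose (K_TP large), but not
    # once K_TP drops below a23 * K_Tminus
    _, stable = stability_classify((0.0, 0.0, 10000.0), 0.5, params)
    assert stable
    _, stable = stability_classify((0.0, 0.0, 10000.0), 0.3, params)
    assert not stable


def test_two_species_point_is_stable(params, two_species_target):
    x_star, lam = two_species_target
    eig, stable = stability_classify(x_star, lam, params)
    assert stable
    assert np.max(eig.real) < -1e-6


def test_stability_classify_rejects_non_equilibrium(params):
    with pytest.raises(DomainError):
        stability_classify((1000.0, 1000.0, 1000.0), 0.4, params)


def test_sweep_structure_matches_branch_diagram(params):
    # dose 0.4: a single stable viable record, the T+/TP pair
    recs = [r for r in sweep_equilibria([0.4], params) if r.stable]
    viable = [r for r in recs if r.viable]
    assert len(viable) == 1 and viable[0].support == ("T+", "TP")

    # dose 0.6: resistant monoculture at 10000 is stable but not viable
    recs = [r for r in sweep_equilibria([0.6], params) if r.stable]
    mono = [r for r in recs if r.support == ("T-",)]
    assert len(mono) == 1
    assert mono[0].total_volume == pytest.approx(10000.0)
    assert not mono[0].viable

    # dose 0.1: stable two-species branch exceeds the viability cap
    recs = [r for r in sweep_equilibria([0.1], params) if r.stable]
    pair = [r for r in recs if r.support == ("T+", "TP")]
    assert len(pair) == 1
    assert pair[0].total_volume == pytest.approx(11966.4, abs=0.5)
    assert not pair[0].viable


def test_at_most_one_stable_branch_contains_tp(params):
    for lam in np.linspace(0.0, 1.0, 41):
        stable_tp = [r for r in sweep_equilibria([lam], params)
                     if r.stable and "TP" in r.support]
        assert len(stable_tp) <= 1


def test_analytic_thresholds_closed_forms(params):
    th = analytic_thresholds(params)
    assert th["lam_Tminus_mono"] == pytest.approx(4000.0 / 9900.0, abs=1e-12)
    # smaller root of 495 lam^2 - 2476 lam + 1080 = 0
    assert th["lam_bifurcation"] == pytest.approx(0.4827848054753398, abs=1e-9)
    lo, hi = th["viability_window"]
    # lower endpoint: root of 495 lam^2 - 1211 lam + 306 = 0
    assert lo == pytest.approx(0.2861541523103191, abs=1e-9)
    assert 0.486 <= hi <= 0.489


def test_thresholds_agree_with_sweep_flips(params):
    th = analytic_thresholds(params)
    step = 1e-3

    def mono_stable(lam):
        _, s = stability_classify((0.0, 0.0, params.K_Tminus), lam, params)
        return s

    lam = th["lam_Tminus_mono"]
    assert not mono_stable(np.floor(lam / step) * step)
    assert mono_stable(np.ceil(lam / step) * step)

    def pair_stable(lam):
        x = find_equilibrium(lam, ("T+", "TP"), params)
        _, s = stability_classify(x, lam, params)
        return s

    lam = th["lam_bifurcation"]
    assert pair_stable(np.floor(lam / step) * step)
    assert not pair_stable(np.ceil(lam / step) * step)


def test_stable_viable_records_attract_the_flow(params):
    """Classification agrees with long-time integration from a perturbation.

    The integration horizon scales with the slowest eigenvalue: near the
    branch bifurcation the leading rate vanishes (critical slowing down), so
    a fixed horizon cannot see the contraction.
    """
    grid = np.concatenate((np.arange(0.0, 1.0001, 0.04),
                           np.arange(0.483, 0.4876, 1e-3)))
    checked = 0
    for rec in sweep_equilibria(grid, params):
        if not (rec.stable and rec.viable):
            continue
        x_star = np.asarray(rec.x_star)
        pert = x_star * 1.01 + np.where(x_star == 0.0, 0.01, 0.0)
        tf = float(np.ceil(min(8e6, max(5e4, 15.0 / abs(rec.eig_real_max)))))
        traj = simulate(pert, rec.lam, tf=tf, dt=1.0, p=params)
        assert np.linalg.norm(np.asarray(traj.final_state) - x_star) < 0.5, rec
        checked += 1
    assert checked >= 10


def test_sweep_dataframe_schema(params):
    df = records_to_dataframe(sweep_equilibria([0.0, 0.5, 1.0], params))
    assert list(df.columns) == ["lam", "support", "x_Tplus", "x_TP", "x_Tminus",
                                "total", "stable", "viable", "eig_real_max"]
    assert (df.groupby("lam").size() >= 3).all()
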