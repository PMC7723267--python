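"""Survival analysis and end-of-trial summaries for virtual cohorts.

Kaplan-Meier product-limit curves (patients still viable at the horizon are
right-censored there), breach-fraction / breach-time tables, classification
of the tumor composition at breach (competitive release = more than 80% of
resistant T- cells), and characterization of the initial conditions of
surviving patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import DomainError
from .cohort import Cohort, CohortResult
from .protocols import PatientOutcome

TMINUS_RELEASE_THRESHOLD = 0.8   # strict: breach is "competitive release" if T- > 80%


@dataclass
class KMCurve:
    """Product-limit survival estimate on the distinct event-time grid."""

    times: np.ndarray            # distinct event times
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray          # number at risk at each event time
    censoring_times: np.ndarray

    def step_function(self):
        """(t, S) arrays for a right-continuous step plot, starting at (0, 1)."""
        t = np.concatenate(([0.0], self.times))
        s = np.concatenate(([1.0], self.survival))
        return t, s


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    ``events[i]`` is True for an observed breach at ``times[i]`` and False
    for censoring (still viable at the horizon).  Estimation is delegated to
    lifelines; the curve is re-expressed on the distinct event-time grid.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0 or times.shape != events.shape:
        raise DomainError("times/events must be equal-length non-empty arrays")
    if np.any(times <= 0):
        raise DomainError("times must be positive")

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events])
    if event_times.size:
        surv = kmf.survival_function_at_times(event_times).to_numpy()
    else:
        surv = np.empty(0)
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=at_risk,
        censoring_times=np.sort(times[~events]),
    )


def summarize_deaths(result: CohortResult):
    """(fraction breached, mean breach time, sample-SD breach time).

    The fraction is over the whole cohort; mean and SD are over breached
    patients only, reported as ``None`` when nobody breached.
    """
    events = result.km_events
    frac = float(events.mean()) if events.size else 0.0
    bt = result.km_times[events]
    if bt.size == 0:
        return frac, None, None
    sd = float(bt.std(ddof=1)) if bt.size > 1 else 0.0
    return frac, float(bt.mean()), sd


def breach_composition_class(outcome: PatientOutcome):
    """Composition frequencies at breach and the competitive-release flag.

    The flag is True iff the T- frequency strictly exceeds 80% (the "top
    triangle" of the composition simplex).
    """
    freqs = outcome.composition_at_breach   # raises DomainError if not breached
    return freqs, bool(freqs[2] > TMINUS_RELEASE_THRESHOLD)


def surviving_initials_summary(cohort: Cohort, result: CohortResult):
    """(min initial total volume, max initial T- share) among survivors."""
    events = result.km_events
    if events.all():
        return None, None
    x0 = cohort.initial_states[~events]
    volumes = x0.sum(axis=1)
    shares = np.divide(x0[:, 2], volumes, out=np.zeros_like(volumes), where=volumes > 0)
    return float(volumes.min()), float(shares.max())


def table_one(results: list[CohortResult]):
    """Per-protocol breach percentage and breach-time mean (SD)."""
    import pandas as pd

    rows = []
    for res in results:
        frac, mean_t, sd_t = summarize_deaths(res)
        rows.append(
            {
                "protocol": res.spec.label,
                "pct_death": 100.0 * frac,
                "mean_time": mean_t,
                "sd_time": sd_t,
            }
        )
    return pd.DataFrame(rows)


def release_fraction(result: CohortResult) -> float | None:
    """Share of breached patients whose breach shows competitive release."""
    flags = [breach_composition_class(o)[1] for o in result.outcomes if o.breached]
    if not flags:
        return None
    return float(np.mean(flags))


# ---------------------------------------------------------------------------
# Optional plotting (matplotlib; imported lazily)
# ---------------------------------------------------------------------------

def plot_km(results: list[CohortResult], ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for res in results:
        curve = kaplan_meier(res.km_times, res.km_events)
        t, s = curve.step_function()
        ax.step(np.append(t, res.horizon), np.append(s, s[-1]), where="post",
                label=res.spec.label)
    ax.set_xlabel("time (model units)")
    ax.set_ylabel("fraction surviving")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return ax


def plot_sweep(records, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    stable = [r for r in records if r.stable]
    lam = [r.lam for r in stable]
    for i, (name, color) in enumerate(zip(("T+", "TP", "T-"), ("C0", "C1", "C2"))):
        ax.plot(lam, [np.asarray(r.x_star)[i] for r in stable], ".", ms=2,
                color=color, label=name)
    ax.set_xlabel("dose")
    ax.set_ylabel("stable equilibrium density (cells)")
    ax.legend()
    return ax


def plot_mean_control(ensemble, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ensemble.t, ensemble.mean, "k-", lw=1)
    ax.fill_between(ensemble.t, ensemble.mean - ensemble.sd,
                    ensemble.mean + ensemble.sd, alpha=0.3)
    ax.set_xlabel("time (model units)")
    ax.set_ylabel("mean dose")
    ax.set_ylim(-0.05, 1.05)
    return ax
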