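"""Virtual-patient cohorts: seeded initial tumors and protocol trials.

Initial tumor compositions (x_T+, x_TP, x_T-) are drawn uniformly on the
solid simplex {x >= 0, sum(x) <= cap} by rejection from the cube [0, cap]^3,
the simplest law consistent with a space-filling scatter of viable tumors;
the sampler descriptor travels with every cohort for provenance.  A cohort
run applies one protocol independently to every patient and aggregates
breach statistics and the (time, event) arrays that feed the Kaplan-Meier
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import DEFAULT_DT, DEFAULT_PARAMS, DomainError, ModelParams, logger
from .protocols import PatientOutcome, ProtocolSpec, run_protocol

SAMPLER_DESCRIPTOR = "uniform-solid-simplex(cube-rejection)"


@dataclass
class Cohort:
    """Seeded list of viable initial tumor compositions."""

    initial_states: np.ndarray   # (n, 3)
    seed: int
    sampler: str = SAMPLER_DESCRIPTOR

    @property
    def n(self) -> int:
        return self.initial_states.shape[0]

    @property
    def total_volumes(self) -> np.ndarray:
        return self.initial_states.sum(axis=1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.initial_states, columns=["x_Tplus", "x_TP", "x_Tminus"])


@dataclass
class CohortResult:
    """Per-patient outcomes and survival summaries for one protocol."""

    spec: ProtocolSpec
    outcomes: list[PatientOutcome]
    horizon: float
    failures: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.outcomes)

    @property
    def km_times(self) -> np.ndarray:
        """Event/censoring times: breach time, or the horizon if censored."""
        return np.array(
            [o.breach_time if o.breached else self.horizon for o in self.outcomes]
        )

    @property
    def km_events(self) -> np.ndarray:
        return np.array([o.breached for o in self.outcomes], dtype=bool)

    @property
    def fraction_breached(self) -> float:
        return float(self.km_events.mean())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x0_Tplus": [o.initial_state.x_Tplus for o in self.outcomes],
                "x0_TP": [o.initial_state.x_TP for o in self.outcomes],
                "x0_Tminus": [o.initial_state.x_Tminus for o in self.outcomes],
                "breached": self.km_events,
                "time": self.km_times,
                "xf_Tplus": [o.final_state.x_Tplus for o in self.outcomes],
                "xf_TP": [o.final_state.x_TP for o in self.outcomes],
                "xf_Tminus": [o.final_state.x_Tminus for o in self.outcomes],
            }
        )


def sample_cohort(n: int, seed: int, cap: float = DEFAULT_PARAMS.viability_cap,
                  v_min: float = 0.0) -> Cohort:
    """Draw ``n`` initial tumors uniformly on {x >= 0, v_min <= sum(x) <= cap}.

    Cube-rejection sampling; deterministic given ``seed``.
    """
    if n <= 0:
        raise DomainError("cohort size must be positive")
    if not 0.0 <= v_min < cap:
        raise DomainError("need 0 <= v_min < cap")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 3))
    got = 0
    while got < n:
        draw = rng.uniform(0.0, cap, size=(max(2 * (n - got), 64), 3))
        tot = draw.sum(axis=1)
        keep = draw[(tot <= cap) & (tot >= v_min)]
        take = min(n - got, keep.shape[0])
        out[got : got + take] = keep[:take]
        got += take
    descriptor = SAMPLER_DESCRIPTOR + (f"+v_min={v_min:g}" if v_min > 0 else "")
    return Cohort(initial_states=out, seed=int(seed), sampler=descriptor)


def run_cohort(cohort: Cohort, spec: ProtocolSpec, p: ModelParams = DEFAULT_PARAMS,
               dt: float = DEFAULT_DT) -> CohortResult:
    """Run one protocol independently over every cohort member.

    Patients are evaluated in order but independently, so results are
    invariant under cohort permutation; an individual integration failure is
    logged and recorded, not fatal.
    """
    outcomes: list[PatientOutcome] = []
    failures: list[int] = []
    for i, x0 in enumerate(cohort.initial_states):
        try:
            outcomes.append(run_protocol(x0, spec, p, dt))
        except Exception:   # noqa: BLE001 - per-patient isolation is the contract
            logger.exception("patient %d failed under %s", i, spec.label)
            failures.append(i)
    return CohortResult(spec=spec, outcomes=outcomes, horizon=spec.horizon,
                        failures=failures)
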