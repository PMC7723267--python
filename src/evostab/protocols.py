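"""Six clinically feasible abiraterone dosing protocols as closed-loop rules.

All protocols observe only the total tumor volume (the clinical PSA proxy),
measured every 100 model time units, and run to a horizon of 10000:

* **MTD** — maximum tolerated dose, lam = 1 throughout.
* **Adaptive therapy** — full dose until the volume halves relative to
  baseline, then no drug until the volume regrows to baseline, and repeat.
  The on/off thresholds are monitored continuously (at integration-step
  resolution): under full dose the sensitive subpopulations collapse on a
  timescale of a few time units, so threshold checks at the 100-unit cadence
  would always overshoot far past the 50% trigger, eradicate the sensitive
  pool, and make the characteristic volume-cycling of adaptive therapy
  impossible.
* **Dose titration** (four variants) — the dose moves on the grid
  {0, 0.1, ..., 1} by one step per measurement: up when the measured volume
  exceeds 110% of the target, down when it falls below 90%.  The target is
  either the incoming baseline volume Va or a fixed maximum tolerable volume
  Vb (default 7000), and the starting dose is either 0 or 1.

Breach of the viability cap is checked at every integration step, so a
patient can die between measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .model_core import (
    DEFAULT_DT,
    DEFAULT_HORIZON,
    DEFAULT_PARAMS,
    EXTINCTION_SNAP,
    DomainError,
    ModelParams,
    TumorState,
    _as_state_array,
    _kernel_args,
    _rhs,
    integrate_steps,
)

MTD = "mtd"
ADAPTIVE = "adaptive"
TITRATION = "titration"


@dataclass(frozen=True)
class ProtocolSpec:
    """One closed-loop dosing policy on measured total tumor volume."""

    kind: str
    target_volume_mode: str | None = None   # "baseline" (Va) or "fixed" (Vb)
    target_volume_value: float = 7000.0     # Vb, used in "fixed" mode
    initial_dose: float = 1.0
    dose_step: float = 0.1
    band: tuple[float, float] = (0.9, 1.1)
    measurement_interval: float = 100.0
    horizon: float = DEFAULT_HORIZON

    def __post_init__(self):
        if self.kind not in (MTD, ADAPTIVE, TITRATION):
            raise DomainError(f"unknown protocol kind {self.kind!r}")
        if self.kind == TITRATION and self.target_volume_mode not in ("baseline", "fixed"):
            raise DomainError("titration needs target_volume_mode 'baseline' or 'fixed'")
        if not 0.0 <= self.initial_dose <= 1.0:
            raise DomainError("initial dose outside [0, 1]")
        if not self.band[0] < 1.0 < self.band[1]:
            raise DomainError("band must straddle 1")

    @property
    def label(self) -> str:
        if self.kind == MTD:
            return "MTD"
        if self.kind == ADAPTIVE:
            return "Adaptive"
        tgt = "Va" if self.target_volume_mode == "baseline" else "Vb"
        return f"Titration({tgt}, lam0={self.initial_dose:g})"


@dataclass
class PatientOutcome:
    """Per-patient result of one closed-loop protocol run."""

    initial_state: TumorState
    breached: bool
    breach_time: float | None
    final_state: TumorState
    dose_times: np.ndarray
    dose_values: np.ndarray

    @property
    def composition_at_breach(self) -> np.ndarray:
        if not self.breached:
            raise DomainError("patient did not breach the viability constraint")
        x = np.asarray(self.final_state, dtype=float)
        return x / x.sum()


def _snap_to_grid(dose: float, step: float) -> float:
    return round(dose / step) * step


def titration_update(current_dose: float, v_measured: float, v_target: float,
                     step: float = 0.1, band: tuple[float, float] = (0.9, 1.1)) -> float:
    """One titration step: +-``step`` when outside the 90-110% band, clamped."""
    if v_measured < 0 or v_target < 0:
        raise DomainError("volumes must be non-negative")
    dose = current_dose
    if v_measured > band[1] * v_target:
        dose += step
    elif v_measured < band[0] * v_target:
        dose -= step
    return _snap_to_grid(min(1.0, max(0.0, dose)), step)


def adaptive_update(phase: str, v_measured: float, v_baseline: float) -> tuple[str, float]:
    """Adaptive-therapy switch: off below 50% of baseline, on at baseline."""
    if v_baseline <= 0:
        raise DomainError("baseline volume must be positive")
    if phase == "on":
        if v_measured <= 0.5 * v_baseline:
            return "off", 0.0
        return "on", 1.0
    if phase == "off":
        if v_measured >= v_baseline:
            return "on", 1.0
        return "off", 0.0
    raise DomainError(f"unknown phase {phase!r}")


@njit(cache=True)
def _adaptive_path(x0, v0, n_steps, dt,
                   r1, r2, r3, a11, a12, a13, a21, a22, a23, a31, a32, a33,
                   ktp_i, ktp_s, mu_i, mu_s, k_tm, tp_floor, cap, snap):
    """Adaptive on/off cycling with per-step threshold checks."""
    x1, x2, x3 = x0[0], x0[1], x0[2]
    dose_steps = np.empty(n_steps)
    on = True
    breach_idx = -1
    k_end = n_steps
    for k in range(n_steps):
        lam = 1.0 if on else 0.0
        dose_steps[k] = lam
        h = dt
        k1a, k1b, k1c = _rhs(x1, x2, x3, lam, r1, r2, r3, a11, a12, a13,
                             a21, a22, a23, a31, a32, a33,
                             ktp_i, ktp_s, mu_i, mu_s, k_tm, tp_floor)
        k2a, k2b, k2c = _rhs(x1 + 0.5 * h * k1a, x2 + 0.5 * h * k1b, x3 + 0.5 * h * k1c,
                             lam, r1, r2, r3, a11, a12, a13,
                             a21, a22, a23, a31, a32, a33,
                             ktp_i, ktp_s, mu_i, mu_s, k_tm, tp_floor)
        k3a, k3b, k3c = _rhs(x1 + 0.5 * h * k2a, x2 + 0.5 * h * k2b, x3 + 0.5 * h * k2c,
                             lam, r1, r2, r3, a11, a12, a13,
                             a21, a22, a23, a31, a32, a33,
                             ktp_i, ktp_s, mu_i, mu_s, k_tm, tp_floor)
        k4a, k4b, k4c = _rhs(x1 + h * k3a, x2 + h * k3b, x3 + h * k3c,
                             lam, r1, r2, r3, a11, a12, a13,
                             a21, a22, a23, a31, a32, a33,
                             ktp_i, ktp_s, mu_i, mu_s, k_tm, tp_floor)
        x1 = x1 + h / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        x2 = x2 + h / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
        x3 = x3 + h / 6.0 * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
        if x1 < snap:
            x1 = 0.0
        if x2 < snap:
            x2 = 0.0
        if x3 < snap:
            x3 = 0.0
        v = x1 + x2 + x3
        if v > cap:
            breach_idx = k + 1
            k_end = k + 1
            break
        if on and v <= 0.5 * v0:
            on = False
        elif (not on) and v >= v0:
            on = True
    out = np.empty(3)
    out[0], out[1], out[2] = x1, x2, x3
    return out, dose_steps[:k_end], breach_idx


def run_protocol(x0, spec: ProtocolSpec, p: ModelParams = DEFAULT_PARAMS,
                 dt: float = DEFAULT_DT) -> PatientOutcome:
    """Closed-loop simulation of one patient under one protocol.

    Integrates between measurement times under the current dose (breach
    checked at every step), measures the total volume at each measurement
    time, and updates the dose per the protocol rule.
    """
    x = _as_state_array(x0)
    v0 = float(x.sum())
    n_per_seg = int(round(spec.measurement_interval / dt))
    n_segs = int(round(spec.horizon / spec.measurement_interval))

    if spec.kind == ADAPTIVE:
        n_steps = int(round(spec.horizon / dt))
        xf, dose_steps, breach_idx = _adaptive_path(
            np.ascontiguousarray(x), v0, n_steps, dt, *_kernel_args(p),
            float(p.viability_cap), EXTINCTION_SNAP,
        )
        change = np.nonzero(np.diff(dose_steps))[0] + 1
        idx = np.concatenate(([0], change))
        return PatientOutcome(
            initial_state=TumorState.from_array(x0),
            breached=breach_idx >= 0,
            breach_time=None if breach_idx < 0 else float(breach_idx * dt),
            final_state=TumorState.from_array(xf),
            dose_times=idx * dt,
            dose_values=dose_steps[idx],
        )

    dose = 1.0 if spec.kind == MTD else float(spec.initial_dose)
    v_target = None
    if spec.kind == TITRATION:
        v_target = v0 if spec.target_volume_mode == "baseline" else float(spec.target_volume_value)

    dose_times = [0.0]
    dose_values = [dose]
    breach_time = None
    t = 0.0
    for _ in range(n_segs):
        seg_dose = np.full(n_per_seg, dose)
        states, breach_idx = integrate_steps(x, seg_dose, dt, p, stop_on_breach=True)
        x = states[-1]
        if breach_idx >= 0:
            breach_time = t + breach_idx * dt
            break
        t += spec.measurement_interval
        v = float(x.sum())
        if spec.kind == TITRATION:
            new_dose = titration_update(dose, v, v_target, spec.dose_step, spec.band)
        else:
            new_dose = dose
        if new_dose != dose:
            dose = new_dose
            dose_times.append(t)
            dose_values.append(dose)

    return PatientOutcome(
        initial_state=TumorState.from_array(x0),
        breached=breach_time is not None,
        breach_time=breach_time,
        final_state=TumorState.from_array(x),
        dose_times=np.asarray(dose_times),
        dose_values=np.asarray(dose_values),
    )


def protocol_catalog(v_b: float = 7000.0) -> list[ProtocolSpec]:
    """The six policies compared in the virtual trial, in reporting order."""
    return [
        ProtocolSpec(kind=MTD),
        ProtocolSpec(kind=ADAPTIVE),
        ProtocolSpec(kind=TITRATION, target_volume_mode="baseline", initial_dose=1.0),
        ProtocolSpec(kind=TITRATION, target_volume_mode="baseline", initial_dose=0.0),
        ProtocolSpec(kind=TITRATION, target_volume_mode="fixed",
                     target_volume_value=v_b, initial_dose=1.0),
        ProtocolSpec(kind=TITRATION, target_volume_mode="fixed",
                     target_volume_value=v_b, initial_dose=0.0),
    ]
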