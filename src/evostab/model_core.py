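"""Three-type Lotka-Volterra dynamics of mCRPC under abiraterone.

The tumor is modeled as three competing cell types: ``T+`` cells that require
exogenous testosterone, ``TP`` cells that produce testosterone (CYP17a
expressing), and ``T-`` cells that are androgen independent and hence
abiraterone resistant.  Each type grows logistically,

    dx_i/dt = r_i x_i (1 - sum_j alpha_ij x_j / K_i),

and the abiraterone dose ``lam`` in [0, 1] enters through the carrying
capacities: ``K_TP(lam) = 10000 - 9900 lam`` and ``K_T+ = mu(lam) * x_TP``
with symbiosis coefficient ``mu(lam) = 1.5 - lam`` (T+ cells live off the
testosterone public good secreted by TP cells, so their capacity is
proportional to the TP density).  ``K_T-`` is dose independent.  A patient is
considered viable while the total burden stays at or below ``viability_cap``
(default 9000 cells); the first time the total exceeds the cap is recorded as
the breach time ("patient death").

Trajectories are integrated with a fixed-step classical RK4 scheme (default
``dt = 1`` model time unit; rates are O(1e-3) so this is deep inside the
stability region and keeps forward/backward sweeps on identical grids).  An
adaptive scipy integrator is available as an option and as a cross-check.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from numba import njit

logger = logging.getLogger("evostab")

# Numerical policy shared by every module.
EXTINCTION_SNAP = 1e-9   # densities below this are set to 0 after each step
DEFAULT_DT = 1.0         # model time units per RK4 step
DEFAULT_HORIZON = 10000.0
EIG_STABILITY_TOL = 1e-12
EQUILIBRIUM_RESIDUAL_TOL = 1e-8

SPECIES = ("T+", "TP", "T-")


class DomainError(ValueError):
    """Input outside the model's admissible domain."""


class IntegrationError(RuntimeError):
    """Numerical integration failed; carries the failure time."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} (t={t:g})")
        self.t = t


@dataclass(frozen=True)
class AffineLaw:
    """Affine dose-response map ``lam -> intercept + slope * lam``."""

    intercept: float
    slope: float

    def __call__(self, lam):
        return self.intercept + self.slope * np.asarray(lam, dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """Single source of truth for the Lotka-Volterra parameterization.

    Defaults are the abiraterone-era parameterization used throughout the
    analysis: growth rates derived from LNCaP / H295R / PC-3 doubling times
    scaled by 1e-2, the competition matrix with alpha_32 = 2, and a maximal
    tolerated burden of 9000 cells.
    """

    r: tuple[float, float, float] = (2.7726e-3, 3.4657e-3, 6.6542e-3)
    A: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.7, 0.8),
        (0.4, 1.0, 0.6),
        (0.5, 2.0, 1.0),
    )
    K_Tminus: float = 10000.0
    K_TP_law: AffineLaw = AffineLaw(10000.0, -9900.0)
    mu_law: AffineLaw = AffineLaw(1.5, -1.0)
    viability_cap: float = 9000.0
    tp_floor: float = 1e-6

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if r.shape != (3,) or np.any(r <= 0):
            raise DomainError("r must be 3 positive growth rates")
        if A.shape != (3, 3) or np.any(A < 0):
            raise DomainError("A must be a non-negative 3x3 matrix")
        if self.K_Tminus <= 0 or self.tp_floor <= 0:
            raise DomainError("K_Tminus and tp_floor must be positive")
        if self.viability_cap <= 0:
            raise DomainError("viability_cap must be positive")
        for lam in (0.0, 1.0):  # affine => extremes suffice
            if self.K_TP_law(lam) <= 0 or self.mu_law(lam) <= 0:
                raise DomainError("K_TP and mu must stay positive on [0, 1]")
        object.__setattr__(self, "r", tuple(float(v) for v in r))
        object.__setattr__(self, "A", tuple(tuple(float(v) for v in row) for row in A))

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "r": list(self.r),
            "A": [list(row) for row in self.A],
            "K_Tminus": self.K_Tminus,
            "K_TP_law": {"intercept": self.K_TP_law.intercept, "slope": self.K_TP_law.slope},
            "mu_law": {"intercept": self.mu_law.intercept, "slope": self.mu_law.slope},
            "viability_cap": self.viability_cap,
            "tp_floor": self.tp_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        for key in ("K_TP_law", "mu_law"):
            if key in d and isinstance(d[key], dict):
                d[key] = AffineLaw(**d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def with_alpha(self, i: int, j: int, value: float) -> "ModelParams":
        A = [list(row) for row in self.A]
        A[i][j] = value
        return replace(self, A=tuple(tuple(row) for row in A))


DEFAULT_PARAMS = ModelParams()


class TumorState(NamedTuple):
    """Cell densities (cells) of the three types; iterable as (T+, TP, T-)."""

    x_Tplus: float
    x_TP: float
    x_Tminus: float

    @property
    def total_volume(self) -> float:
        return self.x_Tplus + self.x_TP + self.x_Tminus

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "TumorState":
        x = np.asarray(x, dtype=float)
        return cls(float(x[0]), float(x[1]), float(x[2]))


def _as_state_array(state) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (3,):
        raise DomainError("state must have exactly three densities")
    return x


@dataclass(frozen=True)
class DoseSchedule:
    """Piecewise-constant dose path ``t -> lam(t) in [0, 1]``.

    ``values[i]`` applies on ``[times[i], times[i+1])``; the last value holds
    from ``times[-1]`` onward.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if times.shape != values.shape or times.ndim != 1 or times.size == 0:
            raise DomainError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(times) <= 0):
            raise DomainError("breakpoints must be strictly increasing")
        if np.any((values < 0) | (values > 1)):
            raise DomainError("doses must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @classmethod
    def constant(cls, lam: float, t0: float = 0.0) -> "DoseSchedule":
        return cls(np.array([t0]), np.array([float(lam)]))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, None)
        return self.values[idx]

    def step_values(self, t0: float, dt: float, n_steps: int) -> np.ndarray:
        """Dose applied on each integration step, sampled at left endpoints."""
        return np.asarray(self(t0 + dt * np.arange(n_steps)), dtype=float)


@dataclass
class Trajectory:
    """Time grid, states, applied dose, and (optionally) the breach time."""

    t: np.ndarray            # (n,)
    states: np.ndarray       # (n, 3)
    dose: np.ndarray         # (n,) dose applied on the step starting at t[k]
    breach_time: float | None = None

    @property
    def total_volume(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def final_state(self) -> TumorState:
        return TumorState.from_array(self.states[-1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "x_Tplus": self.states[:, 0],
                "x_TP": self.states[:, 1],
                "x_Tminus": self.states[:, 2],
                "dose": self.dose,
                "total_volume": self.total_volume,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dose response and growth-rate derivation
# ---------------------------------------------------------------------------

def dose_response(lam: float, p: ModelParams = DEFAULT_PARAMS) -> tuple[float, float]:
    """Carrying capacity of TP cells and symbiosis coefficient at dose ``lam``."""
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise DomainError(f"dose {lam} outside [0, 1]")
    return float(p.K_TP_law(lam)), float(p.mu_law(lam))


def growth_rate_from_doubling_time(hours: float, scale: float = 1.0) -> float:
    """Per-model-time growth rate from a cell-line doubling time in hours.

    ln(2) / (doubling time in days), optionally rescaled (the in-vivo
    parameterization uses scale = 1e-2 to slow cell-line kinetics down to
    tumor-environment kinetics).
    """
    if hours <= 0 or scale <= 0:
        raise DomainError("doubling time and scale must be positive")
    return math.log(2.0) / (hours / 24.0) * scale


# ---------------------------------------------------------------------------
# Vector field and Jacobian (numpy reference implementations)
# ---------------------------------------------------------------------------

def vector_field(state, lam: float, p: ModelParams = DEFAULT_PARAMS) -> np.ndarray:
    """Instantaneous density rates ``dx/dt`` at ``state`` under dose ``lam``.

    The T+ capacity is regularized as ``mu * max(x_TP, tp_floor)`` so the
    field stays well defined as the TP population vanishes (T+ then sees a
    vanishing capacity and declines to extinction, as the biology dictates).
    """
    x = _as_state_array(state)
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise DomainError(f"dose {lam} outside [0, 1]")
    r = np.asarray(p.r)
    A = np.asarray(p.A)
    ktp, mu = p.K_TP_law(lam), p.mu_law(lam)
    K = np.array([mu * max(x[1], p.tp_floor), ktp, p.K_Tminus])
    return r * x * (1.0 - (A @ x) / K)


def jacobian(state, lam: float, p: ModelParams = DEFAULT_PARAMS) -> np.ndarray:
    """Analytic Jacobian d(dx/dt)/dx of the regularized vector field."""
    x = _as_state_array(state)
    r = np.asarray(p.r)
    A = np.asarray(p.A)
    ktp, mu = float(p.K_TP_law(lam)), float(p.mu_law(lam))
    x2e = max(x[1], p.tp_floor)
    K = np.array([mu * x2e, ktp, p.K_Tminus])
    load = A @ x
    J = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            J[i, j] = -r[i] * x[i] * A[i, j] / K[i]
            if i == j:
                J[i, j] += r[i] * (1.0 - load[i] / K[i])
    if x[1] > p.tp_floor:
        # K_T+ = mu * x_TP contributes d/dx_TP [load_0 / (mu x_TP)]
        J[0, 1] = -r[0] * x[0] * (A[0, 1] * x[1] - load[0]) / (mu * x[1] ** 2)
    return J


# ---------------------------------------------------------------------------
# Fixed-step RK4 integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs(x1, x2, x3, lam, r1, r2, r3,
         a11, a12, a13, a21, a22, a23, a31, a32, a33,
         ktp_i, ktp_s, mu_i, mu_s, k_tm, tp_floor):
    # negative stage states (RK4 overshoot during fast T+ die-off) are
    # evaluated at the boundary of the positive cone
    if x1 < 0.0:
        x1 = 0.0
    if x2 < 0.0:
        x2 = 0.0
    if x3 < 0.0:
        x3 = 0.0
    mu = mu_i + mu_s * lam
    ktp = ktp_i + ktp_s * lam
    x2e = x2 if x2 > tp_floor else tp_floor
    k1 = mu * x2e
    f1 = r1 * x1 * (1.0 - (a11 * x1 + a12 * x2 + a13 * x3) / k1)
    f2 = r2 * x2 * (1.0 - (a21 * x1 + a22 * x2 + a23 * x3) / ktp)
    f3 = r3 * x3 * (1.0 - (a31 * x1 + a32 * x2 + a33 * x3) / k_tm)
    return f1, f2, f3


@njit(cache=True)
def _rk4_path(x0, dose_steps, dt, r1, r2, r3,
              a11, a12, a13, a21, a22, a23, a31, a32, a33,
              ktp_i, ktp_s, mu_i, mu_s, k_tm, tp_floor,
              cap, stop_on_breach, snap):
    """RK4 path under per-step doses; returns states and first breach index."""
    n = dose_steps.shape[0]
    states = np.empty((n + 1, 3))
    states[0, 0], states[0, 1], states[0, 2] = x0[0], x0[1], x0[2]
    breach_idx = -1
    if x0[0] + x0[1] + x0[2] > cap:
        breach_idx = 0
        if stop_on_breach:
            return states[:1], breach_idx
    x1, x2, x3 = x0[0], x0[1], x0[2]
    for k in range(n):
        lam = dose_steps[k]
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
        # extinction snap: kill negative drift and spurious revival
        if x1 < snap:
            x1 = 0.0
        if x2 < snap:
            x2 = 0.0
        if x3 < snap:
            x3 = 0.0
        states[k + 1, 0], states[k + 1, 1], states[k + 1, 2] = x1, x2, x3
        if breach_idx < 0 and x1 + x2 + x3 > cap:
            breach_idx = k + 1
            if stop_on_breach:
                return states[: k + 2], breach_idx
    return states, breach_idx


def _kernel_args(p: ModelParams):
    A = p.A
    return (p.r[0], p.r[1], p.r[2],
            A[0][0], A[0][1], A[0][2], A[1][0], A[1][1], A[1][2],
            A[2][0], A[2][1], A[2][2],
            p.K_TP_law.intercept, p.K_TP_law.slope,
            p.mu_law.intercept, p.mu_law.slope,
            p.K_Tminus, p.tp_floor)


def integrate_steps(x0: np.ndarray, dose_steps: np.ndarray, dt: float,
                    p: ModelParams, stop_on_breach: bool = False):
    """Low-level fixed-step integration; returns (states, breach_idx)."""
    x0 = np.ascontiguousarray(_as_state_array(x0))
    dose_steps = np.ascontiguousarray(dose_steps, dtype=float)
    states, breach_idx = _rk4_path(
        x0, dose_steps, float(dt), *_kernel_args(p),
        float(p.viability_cap), stop_on_breach, EXTINCTION_SNAP,
    )
    return states, int(breach_idx)


def simulate(x0, dose: DoseSchedule | float, t0: float = 0.0,
             tf: float = DEFAULT_HORIZON, dt: float = DEFAULT_DT,
             stop_on_breach: bool = False, p: ModelParams = DEFAULT_PARAMS,
             method: str = "rk4") -> Trajectory:
    """Integrate the tumor dynamics from ``x0`` under a dosing schedule.

    Breach (total burden exceeding ``p.viability_cap``) is checked at every
    integration step; with ``stop_on_breach`` the trajectory is truncated at
    the first breached sample.  ``method='adaptive'`` delegates to
    ``scipy.integrate.solve_ivp`` (RK45) on the same output grid.
    """
    if tf <= t0:
        raise DomainError("tf must exceed t0")
    if dt <= 0:
        raise DomainError("dt must be positive")
    if not isinstance(dose, DoseSchedule):
        dose = DoseSchedule.constant(float(dose), t0)
    n_steps = int(round((tf - t0) / dt))
    if not math.isclose(t0 + n_steps * dt, tf, rel_tol=0, abs_tol=1e-9 * max(1.0, tf)):
        raise DomainError("(tf - t0) must be an integer number of steps dt")
    dose_steps = dose.step_values(t0, dt, n_steps)
    if np.any((dose_steps < 0) | (dose_steps > 1)):
        raise DomainError("dose schedule leaves [0, 1]")

    if method == "adaptive":
        return _simulate_adaptive(x0, dose, dose_steps, t0, dt, n_steps, stop_on_breach, p)
    if method != "rk4":
        raise DomainError(f"unknown method {method!r}")

    states, breach_idx = integrate_steps(x0, dose_steps, dt, p, stop_on_breach)
    n_out = states.shape[0]
    t = t0 + dt * np.arange(n_out)
    applied = np.empty(n_out)
    applied[: min(n_out, n_steps)] = dose_steps[: min(n_out, n_steps)]
    applied[-1] = dose_steps[min(n_out, n_steps) - 1] if n_out > 1 else dose_steps[0]
    if not np.all(np.isfinite(states)):
        bad = int(np.argmax(~np.isfinite(states).all(axis=1)))
        raise IntegrationError("non-finite state encountered", t0 + bad * dt)
    breach_time = None if breach_idx < 0 else float(t0 + breach_idx * dt)
    return Trajectory(t=t, states=states, dose=applied, breach_time=breach_time)


def _simulate_adaptive(x0, dose, dose_steps, t0, dt, n_steps, stop_on_breach, p):
    from scipy.integrate import solve_ivp

    x = _as_state_array(x0).copy()
    t_grid = t0 + dt * np.arange(n_steps + 1)
    states = np.empty((n_steps + 1, 3))
    states[0] = x
    breach_idx = 0 if x.sum() > p.viability_cap else -1
    # integrate piecewise over runs of constant dose
    change = np.nonzero(np.diff(dose_steps))[0] + 1
    seg_starts = np.concatenate(([0], change))
    seg_ends = np.concatenate((change, [n_steps]))
    done = stop_on_breach and breach_idx == 0
    for s, e in zip(seg_starts, seg_ends):
        if done:
            states = states[: s + 1]
            break
        lam = dose_steps[s]
        sol = solve_ivp(
            lambda t, y: vector_field(np.maximum(y, 0.0), lam, p),
            (t_grid[s], t_grid[e]), x, t_eval=t_grid[s + 1 : e + 1],
            method="RK45", rtol=1e-8, atol=1e-8,
        )
        if not sol.success:
            raise IntegrationError(f"solve_ivp failed: {sol.message}", t_grid[s])
        seg = np.clip(sol.y.T, 0.0, None)
        seg[seg < EXTINCTION_SNAP] = 0.0
        states[s + 1 : e + 1] = seg
        x = states[e].copy()
        if breach_idx < 0:
            over = np.nonzero(seg.sum(axis=1) > p.viability_cap)[0]
            if over.size:
                breach_idx = s + 1 + int(over[0])
                if stop_on_breach:
                    states = states[: breach_idx + 1]
                    done = True
    n_out = states.shape[0]
    applied = np.empty(n_out)
    applied[: min(n_out, n_steps)] = dose_steps[: min(n_out, n_steps)]
    applied[-1] = dose_steps[min(n_out, n_steps) - 1]
    breach_time = None if breach_idx < 0 else float(t_grid[breach_idx])
    return Trajectory(t=t_grid[:n_out], states=states, dose=applied, breach_time=breach_time)
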