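"""Q-matrix propagation of channel-state occupancy and macroscopic currents.

State occupancies of a continuous-time Markov channel model evolve as
``dp/dt = p Q(V(t), Ca(t))`` where ``Q`` is the infinitesimal generator.
Under time-varying voltage and Ca2+ the engine steps the trajectory with
piecewise-constant coefficients: within each step (length <= ``dt_max``)
the generator is frozen at the step midpoint and the exact matrix
exponential applied.  This keeps every step a proper stochastic map —
probabilities stay non-negative and sum to one regardless of stiffness —
which an off-the-shelf ODE solver does not guarantee.

Any model object exposing ``generator(constants, v_mV, ca_uM)``,
``n_states`` and ``open_indices`` can be propagated; the package provides
:class:`bksensor.mwc.TenStateRates` and
:class:`bksensor.synthetic.TwoStateCOModel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import InvalidArgumentError, NumericalFailureError
from .mwc import PhysicalConstants

__all__ = [
    "Waveform",
    "ChannelEnsemble",
    "OccupancyTrajectory",
    "stationary_distribution",
    "propagate",
    "macroscopic_current",
]

_QUANTITIES = ("voltage", "current", "calcium")
_UNIT_COLUMNS = {"voltage": "voltage_mV", "current": "current_pA", "calcium": "ca_uM"}


@dataclass(frozen=True)
class Waveform:
    """A sampled time series of one physical quantity.

    t         sample times (ms, strictly increasing)
    y         values (mV for voltage, pA for current, uM for calcium)
    quantity  one of 'voltage' | 'current' | 'calcium'
    """

    t: np.ndarray
    y: np.ndarray
    quantity: str

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if self.quantity not in _QUANTITIES:
            raise InvalidArgumentError(
                f"quantity must be one of {_QUANTITIES}, got {self.quantity!r}"
            )
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise InvalidArgumentError("t and y must be 1-D arrays of equal length")
        if t.size < 2:
            raise InvalidArgumentError("waveform needs at least two samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise InvalidArgumentError("waveform samples must be finite")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("t must be strictly increasing")
        if self.quantity == "calcium" and np.any(y < 0):
            raise InvalidArgumentError("calcium values must be >= 0")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    @property
    def column_name(self) -> str:
        """Column header used in the CSV dialect for this quantity."""
        return _UNIT_COLUMNS[self.quantity]

    def value_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation at time t (ms); clamped at the ends."""
        out = np.interp(np.asarray(t, dtype=float), self.t, self.y)
        return float(out) if out.ndim == 0 else out

    def segment(self, t0: float, t1: float) -> "Waveform":
        """Sub-waveform on [t0, t1] (inclusive of interpolated endpoints)."""
        if not (self.t[0] <= t0 < t1 <= self.t[-1]):
            raise InvalidArgumentError(f"[{t0}, {t1}] outside waveform span {self.span}")
        inside = (self.t > t0) & (self.t < t1)
        tt = np.concatenate(([t0], self.t[inside], [t1]))
        return Waveform(tt, self.value_at(tt), self.quantity)


@dataclass(frozen=True)
class ChannelEnsemble:
    """A homogeneous population of channels on one membrane.

    n         channel count
    g_single  single-channel conductance (pS)
    e_rev     reversal potential (mV)
    """

    n: int
    g_single: float
    e_rev: float

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise InvalidArgumentError(f"n must be a positive integer, got {self.n!r}")
        if not (np.isfinite(self.g_single) and self.g_single > 0):
            raise InvalidArgumentError(f"g_single must be > 0, got {self.g_single!r}")
        if not np.isfinite(self.e_rev):
            raise InvalidArgumentError("e_rev must be finite")

    def single_channel_current(self, v_mV: float | np.ndarray) -> float | np.ndarray:
        """i = g_single * (V - E), pS*mV -> pA (factor 1e-3)."""
        return self.g_single * 1e-3 * (np.asarray(v_mV) - self.e_rev)


@dataclass(frozen=True)
class OccupancyTrajectory:
    """State-probability vectors along a propagation grid.

    t  node times (ms); p  array (n_times, n_states), each row sums to 1.
    open_indices  slice selecting the open tier of the model.
    """

    t: np.ndarray
    p: np.ndarray
    open_indices: slice

    def __post_init__(self) -> None:
        sums = self.p.sum(axis=1)
        if np.any(self.p < -1e-10) or np.any(np.abs(sums - 1.0) > 1e-8):
            raise NumericalFailureError("occupancy vectors must be non-negative and sum to 1")

    def open_probability(self) -> np.ndarray:
        return self.p[:, self.open_indices].sum(axis=1)


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary probability vector p of a generator: p Q = 0, sum(p) = 1."""
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    if Q.shape != (n, n):
        raise InvalidArgumentError("generator must be square")
    if not np.all(np.isfinite(Q)):
        raise InvalidArgumentError("generator must be finite")
    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        p = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalFailureError(f"singular generator: {exc}") from exc
    resid = float(np.max(np.abs(p @ Q)))
    scale = max(1.0, float(np.max(np.abs(Q))))
    if resid > 1e-8 * scale or np.any(p < -1e-10):
        raise NumericalFailureError(
            f"stationary solve failed (residual {resid:.2e}, min p {p.min():.2e})"
        )
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def propagate(
    model,
    constants: PhysicalConstants,
    V: Waveform,
    Ca: Waveform,
    p0: np.ndarray,
    dt_max: float = 0.01,
    t_span: tuple[float, float] | None = None,
) -> OccupancyTrajectory:
    """Propagate state occupancy under time-varying voltage and Ca2+.

    The trajectory is advanced on a uniform grid of step <= ``dt_max`` ms;
    within each step the generator is frozen at the midpoint values of V
    and Ca and the exact matrix exponential applied.  Non-uniform input
    waveforms are linearly interpolated onto this grid.
    """
    if V.quantity != "voltage" or Ca.quantity != "calcium":
        raise InvalidArgumentError("propagate expects a voltage and a calcium waveform")
    if dt_max <= 0:
        raise InvalidArgumentError("dt_max must be > 0")
    t0 = max(V.t[0], Ca.t[0]) if t_span is None else t_span[0]
    t1 = min(V.t[-1], Ca.t[-1]) if t_span is None else t_span[1]
    if t1 <= t0:
        raise InvalidArgumentError(
            f"voltage span {V.span} and calcium span {Ca.span} do not overlap"
        )
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (model.n_states,) or abs(p0.sum() - 1.0) > 1e-8 or np.any(p0 < -1e-12):
        raise InvalidArgumentError("p0 must be a probability vector over the model states")

    n_steps = max(1, math.ceil((t1 - t0) / dt_max))
    dt = (t1 - t0) / n_steps
    times = t0 + dt * np.arange(n_steps + 1)
    v_mid = V.value_at(times[:-1] + dt / 2)
    ca_mid = np.clip(Ca.value_at(times[:-1] + dt / 2), 0.0, None)

    p = np.empty((n_steps + 1, model.n_states))
    p[0] = p0 / p0.sum()
    last_key = None
    step = None
    for k in range(n_steps):
        key = (float(v_mid[k]), float(ca_mid[k]))
        if key != last_key:  # step protocols have few distinct coefficient pairs
            step = expm(model.generator(constants, *key) * dt)
            last_key = key
        pk = p[k] @ step
        pk = np.clip(pk, 0.0, None)
        p[k + 1] = pk / pk.sum()
    return OccupancyTrajectory(times, p, model.open_indices)


def macroscopic_current(
    traj: OccupancyTrajectory, ens: ChannelEnsemble, V: Waveform
) -> Waveform:
    """Whole-cell current I(t) = n * g * P_o(t) * (V(t) - E), in pA."""
    if V.quantity != "voltage":
        raise InvalidArgumentError("macroscopic_current expects a voltage waveform")
    po = traj.open_probability()
    i = ens.n * ens.single_channel_current(V.value_at(traj.t)) * po
    return Waveform(traj.t, i, "current")
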