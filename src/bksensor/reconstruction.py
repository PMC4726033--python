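"""Reconstruction of the local Ca2+ time course from a measured BK current.

The inverse problem is solved in three steps:

1. a kinetic model fitted elsewhere supplies P_o(V, Ca) (any object with
   ``generator``/``open_indices``, typically
   :class:`bksensor.mwc.TenStateRates`);
2. the channel number n is read off a steady-state current at known
   voltage and Ca2+ via I = n*g*P_o*(V-E);
3. marching forward in time, the Ca2+ of each step is chosen so that the
   model current at the step end matches the measured current, the state
   vector carrying the full gating history.

The per-step search is either a seeded (mu+lambda) evolution strategy
with self-adaptive log-normal step sizes (``method='es'``) or bracketed
bisection (``method='bisection'``), which exploits the empirical
monotonicity of the one-step predicted current in Ca2+.  Both return the
advanced occupancy under the accepted Ca2+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .errors import (
    IllConditionedError,
    InvalidArgumentError,
    ReconstructionQualityError,
)
from .mwc import MWCParameters, PhysicalConstants, equilibrium_open_probability
from .qmatrix import ChannelEnsemble, Waveform, stationary_distribution

__all__ = [
    "ReconstructionConfig",
    "ReconstructionResult",
    "channel_number_from_steady_state",
    "solve_ca_at_step",
    "reconstruct_ca_timecourse",
]


@dataclass(frozen=True)
class ReconstructionConfig:
    """Controls of the stepwise inverse solver.

    dt              reconstruction step (ms); Ca2+ is frozen per step
    n_substeps      voltage substeps per Ca2+ step, so a coarse (noise
                    robust) Ca2+ step can still resolve a fast voltage
                    transient
    ca_bounds       [min, max] Ca2+ search interval (uM)
    es_mu, es_lambda  parent/offspring population sizes of the ES
    es_generations  generation cap per step
    tol             target relative current mismatch per step
    seed            seed for the ES mutations
    method          'es' | 'bisection'
    """

    dt: float = 0.05
    ca_bounds: tuple[float, float] = (1e-3, 200.0)
    es_mu: int = 5
    es_lambda: int = 20
    es_generations: int = 50
    tol: float = 1e-3
    seed: int = 0
    method: str = "bisection"
    n_substeps: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be > 0")
        lo, hi = self.ca_bounds
        if not (0 <= lo < hi):
            raise InvalidArgumentError("require 0 <= ca_min < ca_max")
        if self.tol <= 0:
            raise InvalidArgumentError("tol must be > 0")
        if self.method not in ("es", "bisection"):
            raise InvalidArgumentError("method must be 'es' or 'bisection'")
        if self.es_mu < 1 or self.es_lambda < self.es_mu:
            raise InvalidArgumentError("require es_lambda >= es_mu >= 1")
        if self.n_substeps < 1:
            raise InvalidArgumentError("n_substeps must be >= 1")


@dataclass(frozen=True)
class ReconstructionResult:
    """Reconstructed Ca2+ waveform with per-step diagnostics.

    residual    per-step relative current mismatch;
    flags       True where a step missed the current-match tolerance;
    bound_hits  True where the accepted Ca2+ sits on a search bound (the
                Ca2+ there is unidentifiable but consistent with the
                data whenever the step is not also flagged);
    n_used      channel number of the ensemble used for inversion.
    """

    ca: Waveform
    residual: np.ndarray
    n_used: int
    flags: np.ndarray
    bound_hits: np.ndarray

    @property
    def flagged_fraction(self) -> float:
        return float(np.mean(self.flags)) if self.flags.size else 0.0


def condition_current(wf: Waveform, window: int = 25, polyorder: int = 2) -> Waveform:
    """Smooth a noisy current in the log domain before inversion.

    Recording noise on a large voltage-clamp current is well described
    as multiplicative; smoothing log|I| with a zero-phase local
    polynomial (Savitzky-Golay) attenuates it without letting
    large-current samples bleed into small-current stretches — a linear
    filter applied to the raw trace would, because the current spans
    orders of magnitude across a voltage protocol.  Requires a current
    of a single sign (true whenever V stays on one side of E_rev).
    """
    from scipy.signal import savgol_filter

    if wf.quantity != "current":
        raise InvalidArgumentError("condition_current expects a current waveform")
    if window < polyorder + 2:
        raise InvalidArgumentError("smoothing window too small for the polynomial order")
    sign = np.sign(np.median(wf.y[np.abs(wf.y) > 0])) or 1.0
    mag = np.clip(sign * wf.y, 1e-3, None)
    sm = sign * np.exp(savgol_filter(np.log(mag), window, polyorder))
    return Waveform(wf.t, sm, "current")


def channel_number_from_steady_state(
    i_steady: float,
    g_single: float,
    v_mV: float,
    e_rev: float,
    ca_steady: float,
    model,
    constants: PhysicalConstants | None = None,
) -> int:
    """Channel count n = I_steady / (g * P_o(V, Ca) * (V - E)).

    ``model`` is either equilibrium :class:`MWCParameters` (closed-form
    P_o) or a kinetic model whose stationary distribution supplies P_o.
    """
    constants = constants or PhysicalConstants()
    if v_mV == e_rev:
        raise InvalidArgumentError("V must differ from the reversal potential")
    if isinstance(model, MWCParameters):
        po = float(equilibrium_open_probability(model, constants, v_mV, ca_steady))
    else:
        p = stationary_distribution(model.generator(constants, v_mV, ca_steady))
        po = float(p[model.open_indices].sum())
    if po < 1e-6:
        raise IllConditionedError(
            f"P_o = {po:.2e} at (V={v_mV} mV, Ca={ca_steady} uM); "
            "channel count is not recoverable from a silent ensemble"
        )
    return round(i_steady / (g_single * 1e-3 * po * (v_mV - e_rev)))


def _advance(model, constants, p, v_mV, ca, dt):
    """One step at frozen Ca; ``v_mV`` may be a sequence of substep
    midpoint voltages, in which case the step is split accordingly so a
    fast voltage transient is resolved inside a coarse Ca step."""
    v_list = np.atleast_1d(v_mV)
    sub = dt / v_list.size
    p1 = p
    for v in v_list:
        p1 = p1 @ expm(model.generator(constants, float(v), float(ca)) * sub)
    p1 = np.clip(p1, 0.0, None)
    return p1 / p1.sum()


def solve_ca_at_step(
    p_current: np.ndarray,
    target_i: float,
    v_mV: float,
    ens: ChannelEnsemble,
    model,
    dt: float,
    cfg: ReconstructionConfig,
    constants: PhysicalConstants | None = None,
    rng: np.random.Generator | None = None,
    i_scale: float | None = None,
    v_end_mV: float | None = None,
    ca_init: float | None = None,
) -> tuple[float, np.ndarray, float, bool]:
    """One reconstruction step: the Ca2+ minimising the current mismatch.

    Advances ``p_current`` through one step of length ``dt`` at frozen
    (V, Ca) and compares the resulting model current with ``target_i``.
    Returns (ca, advanced state, relative residual, flagged, at_bound).
    The residual is normalised by max(|target|, i_scale).  A step is
    flagged when the optimum misses ``cfg.tol``; a bound-constrained
    optimum is reported via ``at_bound`` and is never fatal.
    """
    constants = constants or PhysicalConstants()
    p_current = np.asarray(p_current, dtype=float)
    if p_current.shape != (model.n_states,) or abs(p_current.sum() - 1.0) > 1e-6:
        raise InvalidArgumentError("p_current must be a probability vector")
    lo, hi = cfg.ca_bounds
    scale = max(abs(target_i), i_scale if i_scale is not None else 1.0)
    # generator coefficients are frozen at v_mV (step midpoint); the
    # current is read out at the step-end voltage, matching the forward
    # engine's node-time current evaluation
    v_readout = float(np.atleast_1d(v_mV)[-1]) if v_end_mV is None else v_end_mV
    drive = ens.single_channel_current(v_readout)

    def predicted(ca: float) -> tuple[float, np.ndarray]:
        p1 = _advance(model, constants, p_current, v_mV, ca, dt)
        return ens.n * drive * float(p1[model.open_indices].sum()), p1

    i_lo, p_lo = predicted(lo)
    i_hi, p_hi = predicted(hi)
    increasing = i_hi >= i_lo
    # Clamp when the target is unattainable within the bounds (e.g. a
    # measured current exceeding the model's maximum attainable current,
    # or a near-zero current that even Ca = ca_min overshoots).
    i_min, i_max = sorted((i_lo, i_hi))
    if not (i_min < target_i < i_max):
        at_min = target_i <= i_min
        take_lo = at_min if increasing else not at_min
        ca, p1, i_at = (lo, p_lo, i_lo) if take_lo else (hi, p_hi, i_hi)
        resid = abs(i_at - target_i) / scale
        return ca, p1, resid, bool(resid > cfg.tol), True

    if cfg.method == "bisection":
        if not increasing:
            # monotonicity check failed; fall back to the ES on this step
            return _solve_es(predicted, target_i, scale, cfg, rng, ca_init)
        ca = brentq(
            lambda c: predicted(c)[0] - target_i, lo, hi, xtol=1e-6 * (hi - lo), rtol=1e-10
        )
        i_pred, p1 = predicted(ca)
        resid = abs(i_pred - target_i) / scale
        return float(ca), p1, resid, bool(resid > cfg.tol), False
    return _solve_es(predicted, target_i, scale, cfg, rng, ca_init)


def _solve_es(predicted, target_i, scale, cfg, rng, ca_init=None):
    """(mu+lambda) evolution strategy with self-adaptive log-normal step sizes.

    When ``ca_init`` is given (the previous step's Ca2+ during a marching
    reconstruction), part of the initial population is seeded around it
    with a small mutation scale; the rest is spread over the bounds to
    retain global coverage.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.ca_bounds
    width = hi - lo
    tau_sa = 1.0 / math.sqrt(2.0)  # self-adaptation learning rate (1-D)

    if ca_init is None:
        xs = rng.uniform(lo, hi, size=cfg.es_mu)
        sigmas = np.full(cfg.es_mu, 0.3 * width)
    else:
        # Marching continuation: where the objective is locally flat in Ca
        # (low open probability or saturation) any value in a wide band
        # meets the tolerance, so the population starts tightly around the
        # previous step's Ca; the self-adaptive step sizes grow if the
        # target cannot be matched locally.
        x0 = float(np.clip(ca_init, lo, hi))
        sigmas = np.full(cfg.es_mu, 0.005 * width)
        xs = np.clip(x0 + sigmas * rng.standard_normal(cfg.es_mu), lo, hi)
        xs[0] = x0

    def fitness(x):
        i_pred, p1 = predicted(float(x))
        return abs(i_pred - target_i) / scale, p1

    evals = [fitness(x) for x in xs]
    fits = np.array([e[0] for e in evals])
    best_idx = int(np.argmin(fits))
    best = (xs[best_idx], sigmas[best_idx], fits[best_idx], evals[best_idx][1])

    # The one-step current is only weakly sensitive to Ca (the occupancy
    # moves by O(rate*dt) within a step), so meeting the flag tolerance in
    # current leaves a wide equivalence class in Ca; iterate well past it.
    stop = min(cfg.tol * 1e-3, 1e-7)
    for _ in range(cfg.es_generations):
        if best[2] <= stop:
            break
        parent_idx = rng.integers(0, cfg.es_mu, size=cfg.es_lambda)
        off_sigma = sigmas[parent_idx] * np.exp(tau_sa * rng.standard_normal(cfg.es_lambda))
        off_sigma = np.clip(off_sigma, 1e-9 * width, width)
        off_x = np.clip(xs[parent_idx] + off_sigma * rng.standard_normal(cfg.es_lambda), lo, hi)
        off_evals = [fitness(x) for x in off_x]
        off_fits = np.array([e[0] for e in off_evals])

        pool_x = np.concatenate([xs, off_x])
        pool_s = np.concatenate([sigmas, off_sigma])
        pool_f = np.concatenate([fits, off_fits])
        pool_p = evals + off_evals
        order = np.argsort(pool_f)[: cfg.es_mu]
        xs, sigmas, fits = pool_x[order], pool_s[order], pool_f[order]
        evals = [pool_p[i] for i in order]
        if fits[0] < best[2]:
            best = (xs[0], sigmas[0], fits[0], evals[0][1])

    ca, _, resid, p1 = best
    at_bound = ca <= lo + 1e-9 * width or ca >= hi - 1e-9 * width
    return float(ca), p1, float(resid), bool(resid > cfg.tol), bool(at_bound)


def reconstruct_ca_timecourse(
    I: Waveform,
    V: Waveform,
    ens: ChannelEnsemble,
    model,
    cfg: ReconstructionConfig,
    ca0: float,
    constants: PhysicalConstants | None = None,
    t_start: float | None = None,
    t_stop: float | None = None,
) -> ReconstructionResult:
    """Sequential inverse solution for [Ca2+](t) over the trace span.

    The initial state is the stationary distribution at (V(t_start),
    ca0); each subsequent step inverts the measured current at the step
    end.  ``t_start`` defaults to the start of the common span (in
    practice one starts where the current rises clear of the noise).
    Raises :class:`ReconstructionQualityError` (with the partial result
    attached) when more than 20% of steps are flagged.
    """
    constants = constants or PhysicalConstants()
    if I.quantity != "current" or V.quantity != "voltage":
        raise InvalidArgumentError("expects a current and a voltage waveform")
    t0 = max(I.t[0], V.t[0]) if t_start is None else t_start
    t1 = min(I.t[-1], V.t[-1]) if t_stop is None else t_stop
    if t1 <= t0:
        raise InvalidArgumentError("current and voltage spans do not overlap")

    n_steps = max(1, math.ceil((t1 - t0) / cfg.dt))
    dt = (t1 - t0) / n_steps
    times = t0 + dt * np.arange(n_steps + 1)
    i_scale = float(np.max(np.abs(I.y)))
    rng = np.random.default_rng(cfg.seed)

    p = stationary_distribution(model.generator(constants, float(V.value_at(t0)), ca0))
    ca = np.empty(n_steps + 1)
    ca[0] = ca0
    residual = np.zeros(n_steps)
    flags = np.zeros(n_steps, dtype=bool)
    bound_hits = np.zeros(n_steps, dtype=bool)
    m = cfg.n_substeps
    for k in range(n_steps):
        v_mid = V.value_at(times[k] + dt * (np.arange(m) + 0.5) / m)
        target = float(I.value_at(times[k + 1]))
        ca[k + 1], p, residual[k], flags[k], bound_hits[k] = solve_ca_at_step(
            p, target, v_mid, ens, model, dt, cfg,
            constants=constants, rng=rng, i_scale=i_scale,
            v_end_mV=float(V.value_at(times[k + 1])), ca_init=float(ca[k]),
        )
    result = ReconstructionResult(
        ca=Waveform(times, ca, "calcium"),
        residual=residual,
        n_used=ens.n,
        flags=flags,
        bound_hits=bound_hits,
    )
    if result.flagged_fraction > 0.20:
        raise ReconstructionQualityError(
            f"{100 * result.flagged_fraction:.0f}% of steps missed the current-match "
            f"tolerance; reconstruction unreliable",
            result=result,
        )
    return result
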