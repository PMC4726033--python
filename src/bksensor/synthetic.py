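"""Seeded synthetic-data generators emulating the experimental inputs.

No raw recordings accompany the study this package operationalises, so
every analysis is exercised on synthetic data whose shapes follow the
experimental descriptions:

* flash-photolysis (caged-Ca2+ uncaging) transients — a sub-millisecond
  Ca2+ spike of tens of uM relaxing onto a ~10 uM global plateau;
* pseudo-action-potential voltage commands with an optional appended
  square test step;
* a minimal L-type (Cav1.2-like) Ca2+ current with linearly coupled
  local Ca2+ (the instantaneous-domain approximation);
* stochastic ensembles of independent Markov channels for non-stationary
  noise analysis;
* G-V tables from the equilibrium MWC open probability.

Every generator is a pure function of its spec and seed: identical
inputs give bit-identical outputs.  Default sampling is 50 kHz (0.02 ms),
the digitisation rate typical of fast whole-cell recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .errors import InvalidArgumentError
from .mwc import MWCParameters, PhysicalConstants, equilibrium_open_probability
from .qmatrix import ChannelEnsemble, Waveform
from .variance import EnsembleSweeps

__all__ = [
    "DEFAULT_SAMPLE_INTERVAL_MS",
    "TwoStateCOModel",
    "UncagingTransientSpec",
    "PseudoAPSpec",
    "CavSpec",
    "gen_uncaging_transient",
    "gen_pseudo_ap",
    "gen_cav_current",
    "simulate_stochastic_ensemble",
    "gen_gv_dataset",
    "spike_peak_time",
]

DEFAULT_SAMPLE_INTERVAL_MS = 0.02  # 50 kHz digitisation


@dataclass(frozen=True)
class TwoStateCOModel:
    """Minimal closed-open model of a Ca2+-gated channel.

    C -> O at k_b*Ca, O -> C at k_b*k_d; voltage-independent.  Relaxation
    after a Ca2+ step is a single exponential with tau = 1/(k_b*(Ca+k_d))
    and steady open probability Ca/(Ca+k_d) — the unit model used to read
    the forward binding rate off the fast rising phase.
    """

    k_b: float = 0.18  # uM^-1 ms^-1
    k_d: float = 10.0  # uM

    def __post_init__(self) -> None:
        if self.k_b <= 0 or self.k_d <= 0:
            raise InvalidArgumentError("k_b and k_d must be > 0")

    n_states = 2
    open_indices = slice(1, 2)

    def generator(self, constants: PhysicalConstants, v_mV: float, ca_uM: float) -> np.ndarray:
        kon = self.k_b * ca_uM
        koff = self.k_b * self.k_d
        return np.array([[-kon, kon], [koff, -koff]])

    def tau(self, ca_uM: float) -> float:
        return 1.0 / (self.k_b * (ca_uM + self.k_d))

    def p_open_inf(self, ca_uM: float) -> float:
        return ca_uM / (ca_uM + self.k_d)


# ---------------------------------------------------------------------------
# Uncaging Ca2+ transient
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncagingTransientSpec:
    """Biphasic Ca2+ time course following a UV flash.

    A fast spike (rise ``rise_tau``, decay ``decay_tau``) of peak
    ``ca_peak`` rides on a slow exponential approach (``plateau_tau``)
    from ``ca_base`` to the global plateau ``ca_plateau``.  Defaults give
    a 48.3 uM spike decaying with ~2.4 ms onto a 10 uM plateau, the
    regime reported for NP-EGTA photolysis in whole cell.
    """

    ca_base: float = 0.1
    ca_peak: float = 48.30
    ca_plateau: float = 10.0
    t_flash: float = 5.0
    rise_tau: float = 0.05
    decay_tau: float = 2.4
    plateau_tau: float = 10.0

    def __post_init__(self) -> None:
        if not (self.ca_peak > self.ca_plateau > self.ca_base >= 0):
            raise InvalidArgumentError("require ca_peak > ca_plateau > ca_base >= 0")
        for name in ("rise_tau", "decay_tau", "plateau_tau"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")


def spike_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time (after flash) at which (1-exp(-s/rise))*exp(-s/decay) peaks."""
    return rise_tau * math.log((rise_tau + decay_tau) / rise_tau)


def gen_uncaging_transient(spec: UncagingTransientSpec, t_grid: np.ndarray) -> Waveform:
    """Ca2+ waveform for a flash at ``spec.t_flash`` on the given grid.

    The trace is continuous, equals ``ca_base`` before the flash, peaks
    at ``ca_peak`` (the spike amplitude absorbs the small slow-phase
    contribution at the spike-peak time so the maximum is exact) and
    relaxes to ``ca_plateau``.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("t_grid must be strictly increasing")
    s = np.clip(t - spec.t_flash, 0.0, None)
    slow = (spec.ca_plateau - spec.ca_base) * (1.0 - np.exp(-s / spec.plateau_tau))

    s_pk = spike_peak_time(spec.rise_tau, spec.decay_tau)
    g = (1.0 - np.exp(-s / spec.rise_tau)) * np.exp(-s / spec.decay_tau)
    g_pk = (1.0 - math.exp(-s_pk / spec.rise_tau)) * math.exp(-s_pk / spec.decay_tau)
    slow_at_pk = (spec.ca_plateau - spec.ca_base) * (1.0 - math.exp(-s_pk / spec.plateau_tau))
    amplitude = spec.ca_peak - spec.ca_base - slow_at_pk
    ca = spec.ca_base + slow + amplitude * g / g_pk
    ca[t < spec.t_flash] = spec.ca_base
    return Waveform(t, np.clip(ca, 0.0, None), "calcium")


# ---------------------------------------------------------------------------
# Pseudo-action-potential command
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PseudoAPSpec:
    """Voltage-clamp command mimicking an action potential.

    Raised-cosine rise from ``v_rest`` to ``v_peak`` over ``rise_ms``
    then fall over ``fall_ms``; optionally followed, ``step_delay_ms``
    after repolarisation, by a square step to ``step_mV`` lasting
    ``step_duration_ms`` (the AP-plus-step protocol used to read channel
    number from noise analysis).
    """

    v_rest: float = -60.0
    v_peak: float = 40.0
    rise_ms: float = 1.0
    fall_ms: float = 2.0
    t_start: float = 2.0
    step_mV: float | None = None
    step_delay_ms: float = 2.0
    step_duration_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.v_peak <= self.v_rest:
            raise InvalidArgumentError("v_peak must exceed v_rest")
        if self.rise_ms <= 0 or self.fall_ms <= 0:
            raise InvalidArgumentError("rise_ms and fall_ms must be > 0")


def gen_pseudo_ap(spec: PseudoAPSpec, t_grid: np.ndarray) -> Waveform:
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("t_grid must be strictly increasing")
    v = np.full_like(t, spec.v_rest, dtype=float)
    amp = spec.v_peak - spec.v_rest
    s = t - spec.t_start
    rising = (s >= 0) & (s < spec.rise_ms)
    v[rising] = spec.v_rest + amp * 0.5 * (1 - np.cos(np.pi * s[rising] / spec.rise_ms))
    f = s - spec.rise_ms
    falling = (f >= 0) & (f < spec.fall_ms)
    v[falling] = spec.v_rest + amp * 0.5 * (1 + np.cos(np.pi * f[falling] / spec.fall_ms))
    if spec.step_mV is not None:
        t_step = spec.t_start + spec.rise_ms + spec.fall_ms + spec.step_delay_ms
        in_step = (t >= t_step) & (t < t_step + spec.step_duration_ms)
        v[in_step] = spec.step_mV
    return Waveform(t, v, "voltage")


# ---------------------------------------------------------------------------
# Cav-like Ca2+ current and coupled local Ca2+
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CavSpec:
    """Minimal single-gate L-type Ca2+ channel stand-in.

    The activation gate m relaxes to m_inf(V) = 1/(1+exp((v_half-V)/s))
    with time constant ``act_tau``; I_Ca = g_max*m*(V-e_ca) (inward
    negative).  Local Ca2+ at the sensor is coupled linearly to the
    instantaneous Ca2+ current — the zero-dimensional limit of a
    steady-state nanodomain: local_ca = ca_base + coupling*|I_Ca|.
    """

    g_max: float = 25.5  # nS
    e_ca: float = 60.0  # mV
    act_tau: float = 0.5  # ms
    v_half_act: float = -10.0  # mV
    slope_act: float = 6.0  # mV
    coupling: float = 0.025  # uM per pA
    ca_base: float = 0.1  # uM

    def __post_init__(self) -> None:
        for name in ("g_max", "act_tau", "slope_act", "coupling"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.ca_base < 0:
            raise InvalidArgumentError("ca_base must be >= 0")

    def m_inf(self, v_mV: float | np.ndarray) -> float | np.ndarray:
        return 1.0 / (1.0 + np.exp((self.v_half_act - np.asarray(v_mV)) / self.slope_act))


def gen_cav_current(spec: CavSpec, V: Waveform) -> tuple[Waveform, Waveform]:
    """Cav current (pA) and linearly coupled local Ca2+ (uM) under V(t)."""
    if V.quantity != "voltage":
        raise InvalidArgumentError("gen_cav_current expects a voltage waveform")
    t, v = V.t, V.y
    m = np.empty_like(v)
    m[0] = float(spec.m_inf(v[0]))
    dts = np.diff(t)
    for k, dt in enumerate(dts):
        m_tgt = float(spec.m_inf(0.5 * (v[k] + v[k + 1])))
        m[k + 1] = m_tgt + (m[k] - m_tgt) * math.exp(-dt / spec.act_tau)
    i_ca = spec.g_max * m * (v - spec.e_ca)  # nS*mV = pA
    local = spec.ca_base + spec.coupling * np.abs(i_ca)
    return Waveform(t, i_ca, "current"), Waveform(t, local, "calcium")


# ---------------------------------------------------------------------------
# Standard AP reconstruction scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APScenario:
    """The standard pseudo-AP + voltage-step benchmark for Ca2+ reconstruction.

    voltage     command waveform (AP to +20 mV, then a +50 mV test step)
    i_ca        Cav-like Ca2+ current under that command (pA)
    local_ca    ground-truth local Ca2+ at the sensor (uM)
    bk_current  noiseless forward-simulated BK current (pA)
    ensemble    the BK ensemble used (n=1662, 258 pS, E=-80 mV)
    rates       the kinetic model used
    t_start, t_stop  the reconstruction window (ms): from rest, through
                the AP, to where the command repolarises through ~-5 mV —
                the stretch over which the BK current actually constrains
                Ca2+.
    """

    voltage: Waveform
    i_ca: Waveform
    local_ca: Waveform
    bk_current: Waveform
    ensemble: ChannelEnsemble
    rates: object
    t_start: float
    t_stop: float

    @property
    def ca_peak(self) -> float:
        m = (self.local_ca.t >= self.t_start) & (self.local_ca.t <= self.t_stop)
        return float(self.local_ca.y[m].max())

    @property
    def ca0(self) -> float:
        return float(self.local_ca.value_at(self.t_start))


def standard_ap_scenario(
    rates=None, constants: PhysicalConstants | None = None
) -> APScenario:
    """Forward-simulate the standard pseudo-AP benchmark.

    The local Ca2+ follows the Cav current instantaneously and peaks at
    ~28 uM during the AP (a fast-deactivating Cav keeps Ca2+ near
    baseline once the command repolarises, where the slowly deactivating
    BK current carries no Ca2+ information).
    """
    from .mwc import TenStateRates
    from .qmatrix import macroscopic_current, propagate, stationary_distribution

    rates = rates or TenStateRates()
    constants = constants or PhysicalConstants()
    t = np.arange(0.0, 18.0001, DEFAULT_SAMPLE_INTERVAL_MS)
    ap = gen_pseudo_ap(
        PseudoAPSpec(
            v_rest=-60.0, v_peak=20.0, rise_ms=1.0, fall_ms=2.0, t_start=2.0,
            step_mV=50.0, step_delay_ms=0.5, step_duration_ms=10.0,
        ),
        t,
    )
    i_ca, local = gen_cav_current(CavSpec(act_tau=0.1, coupling=0.02), ap)
    ens = ChannelEnsemble(n=1662, g_single=258.0, e_rev=-80.0)
    p0 = stationary_distribution(rates.generator(constants, float(ap.y[0]), float(local.y[0])))
    traj = propagate(rates, constants, ap, local, p0, dt_max=0.01)
    bk = macroscopic_current(traj, ens, ap)
    bk = Waveform(t, bk.value_at(t), "current")
    return APScenario(
        voltage=ap, i_ca=i_ca, local_ca=local, bk_current=bk,
        ensemble=ens, rates=rates, t_start=1.0, t_stop=3.8,
    )


# ---------------------------------------------------------------------------
# Stochastic channel ensembles
# ---------------------------------------------------------------------------

def simulate_stochastic_ensemble(
    model,
    ens: ChannelEnsemble,
    V: Waveform,
    Ca: Waveform,
    n_sweeps: int,
    seed: int,
    dt_max: float = DEFAULT_SAMPLE_INTERVAL_MS,
    constants: PhysicalConstants | None = None,
) -> EnsembleSweeps:
    """Repeated sweeps of ``ens.n`` independent Markov channels.

    Channels evolve as a discrete-time chain on the propagation grid
    using the midpoint-frozen matrix exponential as the one-step
    transition matrix; state counts are advanced by multinomial sampling
    (exact for independent identical channels).  The recorded current is
    (open count) * g_single * (V - E).
    """
    if n_sweeps < 2:
        raise InvalidArgumentError("need at least 2 sweeps")
    constants = constants or PhysicalConstants()
    rng = np.random.default_rng(seed)

    t0, t1 = max(V.t[0], Ca.t[0]), min(V.t[-1], Ca.t[-1])
    if t1 <= t0:
        raise InvalidArgumentError("voltage and calcium spans do not overlap")
    n_steps = max(1, math.ceil((t1 - t0) / dt_max))
    dt = (t1 - t0) / n_steps
    times = t0 + dt * np.arange(n_steps + 1)
    v_nodes = V.value_at(times)
    v_mid = V.value_at(times[:-1] + dt / 2)
    ca_mid = np.clip(Ca.value_at(times[:-1] + dt / 2), 0.0, None)

    n_states = model.n_states
    from .qmatrix import stationary_distribution  # local import to avoid cycle at module load

    p0 = stationary_distribution(model.generator(constants, float(v_nodes[0]), float(Ca.value_at(t0))))
    counts = rng.multinomial(ens.n, p0, size=n_sweeps)  # (n_sweeps, n_states)

    open_idx = model.open_indices
    sweeps = np.empty((n_steps + 1, n_sweeps))
    i_single = ens.single_channel_current(v_nodes)  # pA per open channel at each node
    sweeps[0] = counts[:, open_idx].sum(axis=1) * i_single[0]

    last_key = None
    T = None
    for k in range(n_steps):
        key = (float(v_mid[k]), float(ca_mid[k]))
        if key != last_key:
            T = expm(model.generator(constants, *key) * dt)
            T = np.clip(T, 0.0, None)
            T /= T.sum(axis=1, keepdims=True)
            last_key = key
        new_counts = np.zeros_like(counts)
        for s in range(n_states):
            n_in_s = counts[:, s]
            if not np.any(n_in_s):
                continue
            new_counts += rng.multinomial(n_in_s, T[s])
        counts = new_counts
        sweeps[k + 1] = counts[:, open_idx].sum(axis=1) * i_single[k + 1]
    return EnsembleSweeps(times, sweeps)


def variance_benchmark_sweeps(
    n_channels: int = 1662,
    i_single_pA: float = 12.9,
    n_sweeps: int = 1000,
    seed: int = 0,
    t_end: float = 8.0,
) -> EnsembleSweeps:
    """Stochastic sweeps for non-stationary noise analysis at the published
    single-channel parameters (defaults: i = 12.9 pA at +50 mV, N = 1662).

    Independent two-state channels are driven by a 0<->9 uM Ca2+ pulse
    train (P_o cycling 0 <-> 0.9 with a 0.1 ms relaxation time).  The fast
    gating decorrelates the ensemble many times per sweep, which is what
    makes i and N recoverable to a few percent from 1000 sweeps; a single
    slow activation leaves too few independent gating transitions.
    """
    ens = ChannelEnsemble(n=n_channels, g_single=i_single_pA / 50.0 * 1e3, e_rev=0.0)
    model = TwoStateCOModel(k_b=1.0, k_d=1.0)  # tau = 0.1 ms at 9 uM
    V = Waveform(np.array([0.0, t_end]), np.array([50.0, 50.0]), "voltage")
    ts, ys, tt = [0.0], [0.0], 0.5
    while tt + 1.0 < t_end:
        ts += [tt, tt + 0.02, tt + 1.0, tt + 1.02]
        ys += [0.0, 9.0, 9.0, 0.0]
        tt += 2.0
    ts.append(t_end)
    ys.append(0.0)
    Ca = Waveform(np.array(ts), np.array(ys), "calcium")
    return simulate_stochastic_ensemble(model, ens, V, Ca, n_sweeps, seed, dt_max=0.01)


# ---------------------------------------------------------------------------
# G-V tables
# ---------------------------------------------------------------------------

def gen_gv_dataset(
    params: MWCParameters,
    voltages: np.ndarray,
    ca_uM: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    g_max: float = 1.0,
    constants: PhysicalConstants | None = None,
) -> pd.DataFrame:
    """Conductance-voltage table G(V) = g_max*P_o(V, Ca) + Gaussian noise.

    ``noise_sd`` is expressed as a fraction of ``g_max``.  Returns a
    DataFrame with columns ``voltage_mV``, ``conductance`` and ``ca_uM``.
    """
    constants = constants or PhysicalConstants()
    v = np.asarray(voltages, dtype=float)
    po = np.asarray(equilibrium_open_probability(params, constants, v, ca_uM))
    g = g_max * po
    if noise_sd > 0:
        g = g + np.random.default_rng(seed).normal(0.0, noise_sd * g_max, size=v.shape)
    return pd.DataFrame({"voltage_mV": v, "conductance": g, "ca_uM": ca_uM})
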