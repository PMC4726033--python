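"""Curve fits on currents and derived quantities.

Covers the analysis chain applied to flash-photolysis and voltage-clamp
data: Boltzmann fits of G-V and fast-fraction-voltage relations, the
biphasic (hooked) decomposition of flash-evoked currents, the two-state
closed-open rise fit that reads off the activation time constant, the
forward-binding-rate estimate k_b = 1/(tau*([Ca]_a + k_d)), and a global
fit of the full kinetic model to a family of current traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateInputError, FitFailureError, InvalidArgumentError
from .mwc import PhysicalConstants, TenStateRates
from .qmatrix import ChannelEnsemble, Waveform, macroscopic_current, propagate, stationary_distribution

__all__ = [
    "BoltzmannFit",
    "BiphasicDecomposition",
    "COFit",
    "KbEstimate",
    "TraceRecord",
    "GlobalFitReport",
    "fit_boltzmann",
    "decompose_biphasic",
    "fit_co_rise",
    "average_rising_calcium",
    "estimate_kb",
    "fit_mwc_global",
    "runs_test_pvalue",
]


# ---------------------------------------------------------------------------
# Boltzmann fits (G-V and Rf-V)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoltzmannFit:
    """y = y_max / (1 + exp((v_half - V)/slope)).

    ``form`` records which relation was fitted ('GV' or 'RfV'); the
    mathematics is identical.
    """

    v_half: float  # mV
    slope: float  # mV
    y_max: float
    se_v_half: float
    se_slope: float
    se_y_max: float
    rmse: float
    form: str = "GV"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise InvalidArgumentError("slope must be nonzero")
        if self.y_max <= 0:
            raise InvalidArgumentError("y_max must be > 0")

    def predict(self, v_mV: float | np.ndarray) -> float | np.ndarray:
        v = np.asarray(v_mV, dtype=float)
        out = self.y_max / (1.0 + np.exp((self.v_half - v) / self.slope))
        return float(out) if out.ndim == 0 else out


def _boltzmann(v, y_max, v_half, slope):
    return y_max / (1.0 + np.exp((v_half - v) / slope))


def fit_boltzmann(x: np.ndarray, y: np.ndarray, form: str = "GV") -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of a conductance-like curve."""
    if form not in ("GV", "RfV"):
        raise InvalidArgumentError(f"form must be 'GV' or 'RfV', got {form!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise InvalidArgumentError("need >= 4 (V, y) points")
    y_max0 = float(y.max()) * 1.05
    half = y_max0 / 2
    v_half0 = float(x[np.argmin(np.abs(y - half))])
    slope0 = max(1.0, float(np.ptp(x)) / 6.0)
    p0 = np.array([y_max0, v_half0, slope0])

    def resid(p):
        return _boltzmann(x, *p) - y

    sol = optimize.least_squares(resid, p0, method="lm", max_nfev=5000)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise FitFailureError("Boltzmann fit did not converge", last_iterate=sol.x)
    y_max, v_half, slope = sol.x
    dof = max(1, x.size - 3)
    rmse = float(np.sqrt(2 * sol.cost / dof))
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * rmse**2
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
    return BoltzmannFit(
        v_half=float(v_half),
        slope=float(slope),
        y_max=float(y_max),
        se_v_half=float(ses[1]),
        se_slope=float(ses[2]),
        se_y_max=float(ses[0]),
        rmse=rmse,
        form=form,
    )


# ---------------------------------------------------------------------------
# Biphasic decomposition of flash-evoked currents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiphasicDecomposition:
    """Fast + slow decomposition of a flash-evoked (hooked) current.

    The post-flash rise above the pre-flash steady level is modelled as
    a fast component that rises with tau_f, then decays with tau_f_off
    (producing the hook), plus a slow rising component with tau_s:

        dI(s) = h1 * g(s)/g_peak + h2 * (1 - exp(-s/tau_s)),
        g(s) = (1 - exp(-s/tau_f)) * exp(-s/tau_f_off).

    h1 is the fast amplitude measured at the hook maximum (g normalised
    to peak 1), h2 the slow amplitude, h = h1 + h2 the total flash
    response; r_f = h1/h and r_s = h2/h sum to one by construction.
    """

    tau_f: float  # ms
    tau_f_off: float  # ms
    tau_s: float  # ms
    h: float  # pA
    h1: float  # pA
    h2: float  # pA
    r_f: float
    r_s: float
    baseline: float  # pre-flash steady current (pA)
    rmse: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_f <= 1.0):
            raise InvalidArgumentError("r_f must lie in [0, 1]")
        if abs(self.r_f + self.r_s - 1.0) > 1e-12:
            raise InvalidArgumentError("r_f + r_s must equal 1")
        if self.tau_f >= self.tau_s:
            raise InvalidArgumentError("tau_f must be smaller than tau_s")


def _fast_shape(s: np.ndarray, tau_f: float, tau_off: float) -> np.ndarray:
    """(1-exp(-s/tau_f))*exp(-s/tau_off), normalised to unit peak."""
    s_pk = tau_f * math.log((tau_f + tau_off) / tau_f)
    g_pk = (1.0 - math.exp(-s_pk / tau_f)) * math.exp(-s_pk / tau_off)
    return (1.0 - np.exp(-s / tau_f)) * np.exp(-s / tau_off) / g_pk


def biphasic_model(
    s: np.ndarray, h1: float, h2: float, tau_f: float, tau_off: float, tau_s: float
) -> np.ndarray:
    return h1 * _fast_shape(s, tau_f, tau_off) + h2 * (1.0 - np.exp(-s / tau_s))


def decompose_biphasic(trace: Waveform, flash_time: float) -> BiphasicDecomposition:
    """Decompose a flash-evoked current into fast and slow components.

    The pre-flash steady current is subtracted, then the post-flash
    segment fitted to the fast-rise-and-decay plus slow-rise model.
    """
    if trace.quantity != "current":
        raise InvalidArgumentError("decompose_biphasic expects a current waveform")
    pre = trace.y[trace.t < flash_time]
    if pre.size < 3:
        raise InvalidArgumentError("no pre-flash baseline present")
    if trace.t[-1] - flash_time < 50.0:
        raise InvalidArgumentError("trace must extend >= 50 ms beyond the flash")
    baseline = float(pre.mean())
    noise = float(pre.std(ddof=1)) if pre.size > 1 else 0.0

    post = trace.t >= flash_time
    s = trace.t[post] - flash_time
    dI = trace.y[post] - baseline
    # 5-sigma detection floor: the max of ~10^3 baseline-noise samples
    # already reaches ~3.5 sigma
    if np.max(np.abs(dI)) <= max(5.0 * noise, 1e-12):
        raise DegenerateInputError("no detectable flash response above the noise floor")

    total = float(np.mean(dI[s > 0.8 * s[-1]]))  # late plateau
    hook = float(dI.max())
    h1_0 = max(hook - total, 0.05 * abs(total)) if hook > total else 0.3 * abs(total)
    h2_0 = max(total, 1e-3 * hook)
    lo = [0.0, 0.0, 1e-3, 0.05, 2.0]
    hi = [np.inf, np.inf, 1.8, 80.0, 500.0]

    def resid(p):
        return biphasic_model(s, *p) - dI

    # The objective has local minima in the time constants; multi-start on
    # tau_f and keep the best converged fit.
    sol = None
    for tau_f0 in (0.1, 0.3, 1.0):
        trial = optimize.least_squares(
            resid,
            np.array([h1_0, h2_0, tau_f0, 2.4, 10.0]),
            bounds=(lo, hi),
            max_nfev=10000,
        )
        if trial.success and (sol is None or trial.cost < sol.cost):
            sol = trial
    if sol is None:
        raise FitFailureError("biphasic decomposition did not converge")
    h1, h2, tau_f, tau_off, tau_s = sol.x
    h = h1 + h2
    if h <= 0:
        raise DegenerateInputError("fitted flash response has non-positive amplitude")
    rmse = float(np.sqrt(2 * sol.cost / max(1, s.size - 5)))
    return BiphasicDecomposition(
        tau_f=float(tau_f),
        tau_f_off=float(tau_off),
        tau_s=float(tau_s),
        h=float(h),
        h1=float(h1),
        h2=float(h2),
        r_f=float(h1 / h),
        r_s=float(h2 / h),
        baseline=baseline,
        rmse=rmse,
    )


# ---------------------------------------------------------------------------
# Closed-open rise fit and k_b estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class COFit:
    """Single-exponential rise I(t) = I_0 + a*(1 - exp(-t/tau)).

    ``runs_pvalue`` is a residual-structure diagnostic (two-sided runs
    test on residual signs): small values flag systematic misfit, e.g. a
    window that includes the hook or decay.
    """

    tau: float  # ms
    amplitude: float  # pA
    i_max: float  # pA (asymptote I_0 + a)
    i_0: float  # pA
    rmse: float
    runs_pvalue: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise InvalidArgumentError("tau must be > 0")


def runs_test_pvalue(residuals: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs test on the signs of residuals.

    Normal approximation; returns 1.0 when one sign is (nearly) absent,
    in which case the test is uninformative.
    """
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 < 2 or n2 < 2:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mean = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mean) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def fit_co_rise(segment: Waveform) -> COFit:
    """Fit the fast rising phase to the two-state (C-O) exponential.

    The caller restricts the segment to the rising phase; a segment with
    an overall negative trend is rejected as a misuse of the model.
    """
    if segment.quantity != "current":
        raise InvalidArgumentError("fit_co_rise expects a current waveform")
    t = segment.t - segment.t[0]
    y = segment.y
    if t.size < 4:
        raise InvalidArgumentError("need >= 4 samples")
    trend = stats.linregress(t, y)
    if trend.slope <= 0:
        raise FitFailureError(
            "segment is not rising; the C-O exponential models an activation phase",
            diagnostics={"trend_slope": float(trend.slope)},
        )
    a0 = float(y[-1] - y[0])
    tau0 = max(float(t[-1]) / 5.0, float(t[1]))
    p0 = np.array([float(y[0]), a0, tau0])

    def resid(p):
        i0, a, tau = p
        return i0 + a * (1.0 - np.exp(-t / tau)) - y

    sol = optimize.least_squares(
        resid, p0, bounds=([-np.inf, 0, 1e-6], [np.inf, np.inf, np.inf]), max_nfev=5000
    )
    if not sol.success or sol.x[2] <= 0:
        raise FitFailureError("C-O rise fit did not converge", last_iterate=sol.x)
    i0, a, tau = sol.x
    r = resid(sol.x)
    rmse = float(np.sqrt(np.mean(r**2)))
    return COFit(
        tau=float(tau),
        amplitude=float(a),
        i_max=float(i0 + a),
        i_0=float(i0),
        rmse=rmse,
        runs_pvalue=runs_test_pvalue(r),
    )


def average_rising_calcium(ca: Waveform, window: tuple[float, float]) -> float:
    """Time-averaged [Ca2+] (trapezoidal) over [t0, t_peak] (uM).

    The window is the fast rising phase of the uncaging spike, ending at
    the Ca2+ peak.
    """
    if ca.quantity != "calcium":
        raise InvalidArgumentError("average_rising_calcium expects a calcium waveform")
    t0, t1 = window
    if not (t1 > t0):
        raise InvalidArgumentError("window must have positive width")
    seg = ca.segment(t0, t1)
    return float(np.trapezoid(seg.y, seg.t) / (t1 - t0))


@dataclass(frozen=True)
class KbEstimate:
    """Forward Ca2+ binding rate from the fast activation time constant.

    k_b = 1/(tau*([Ca]_a + k_d)) in uM^-1 ms^-1, where tau is the fast
    rising time constant, [Ca]_a the rising-phase average Ca2+ and k_d
    the dissociation equilibrium constant of the sensor.
    """

    k_b: float  # uM^-1 ms^-1
    k_d: float  # uM
    ca_a: float  # uM
    tau: float  # ms
    ca_p: float | None = None  # peak Ca2+ (uM), when known

    def __post_init__(self) -> None:
        for name in ("k_b", "k_d", "ca_a", "tau"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if abs(self.k_b * self.tau * (self.ca_a + self.k_d) - 1.0) > 1e-9:
            raise InvalidArgumentError("k_b*tau*(ca_a + k_d) must equal 1")


def estimate_kb(tau: float, ca_a: float, k_d: float, ca_p: float | None = None) -> KbEstimate:
    """k_b = 1/(tau*(ca_a + k_d)); all inputs in ms and uM."""
    if tau <= 0 or ca_a <= 0 or k_d < 0:
        raise InvalidArgumentError("tau and ca_a must be > 0 and k_d >= 0")
    return KbEstimate(k_b=1.0 / (tau * (ca_a + k_d)), k_d=k_d, ca_a=ca_a, tau=tau, ca_p=ca_p)


# ---------------------------------------------------------------------------
# Global kinetic-model fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceRecord:
    """One experimental condition: fixed Ca2+, a voltage command and the
    recorded current."""

    ca_uM: float
    voltage: Waveform
    current: Waveform


@dataclass(frozen=True)
class GlobalFitReport:
    rates: TenStateRates
    rmse: float
    po_surface_v: np.ndarray
    po_surface_ca: np.ndarray
    po_surface: np.ndarray  # (n_v, n_ca)
    warnings: tuple[str, ...]
    n_evaluations: int


def _rates_to_vector(r: TenStateRates) -> np.ndarray:
    q_total = r.q_alpha + r.q_beta
    return np.array(
        [
            math.log10(r.k_b),
            math.log10(r.K_C),
            math.log10(r.K_O),
            math.log10(r.alpha0),
            math.log10(r.beta0),
            q_total,
            r.q_alpha / q_total if q_total > 0 else 1.0,
            r.phi,
        ]
    )


def _vector_to_rates(x: np.ndarray, n_sites: int) -> TenStateRates:
    kb, kc, ko, a0, b0 = (10.0**v for v in x[:5])
    # q_frac may exceed 1: the closing rate then carries a negative
    # partial charge, which the scheme admits
    q_total, q_frac, phi = x[5], x[6], min(max(x[7], 0.0), 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # candidate K_O >= K_C during search is fine
        return TenStateRates(
            k_b=kb, K_C=kc, K_O=ko, alpha0=a0, beta0=b0,
            q_alpha=q_total * q_frac, q_beta=q_total * (1 - q_frac),
            phi=phi, n_sites=n_sites,
        )


def _simulate_record(
    rates: TenStateRates,
    constants: PhysicalConstants,
    ens: ChannelEnsemble,
    rec: TraceRecord,
    dt_max: float,
) -> np.ndarray:
    ca_wf = Waveform(np.array(rec.voltage.span), np.full(2, rec.ca_uM), "calcium")
    p0 = stationary_distribution(
        rates.generator(constants, float(rec.voltage.y[0]), rec.ca_uM)
    )
    traj = propagate(rates, constants, rec.voltage, ca_wf, p0, dt_max=dt_max)
    model_i = macroscopic_current(traj, ens, rec.voltage)
    return model_i.value_at(rec.current.t)


def fit_mwc_global(
    dataset: list[TraceRecord],
    ens: ChannelEnsemble,
    init: TenStateRates,
    constants: PhysicalConstants | None = None,
    seed: int = 0,
    dt_max: float = 0.05,
    global_maxiter: int = 15,
    global_popsize: int = 8,
    log_halfwidth: float = 0.7,
    surface_shape: tuple[int, int] = (11, 9),
) -> GlobalFitReport:
    """Global fit of the 10-state kinetic model to a family of traces.

    Two-phase search: a seeded, bounded population-based global
    exploration (differential evolution in log-parameter space around
    ``init``) followed by derivative-free-friendly local refinement
    (scipy ``least_squares`` on the residual vector).  Identifiability
    is assessed on the Jacobian at the optimum; a flat direction attaches
    a warning rather than raising, since Markov-model fits are
    structurally degenerate — the fitted P_o(V, Ca) surface, which the
    report tabulates, is the meaningful contract.
    """
    constants = constants or PhysicalConstants()
    warns: list[str] = []
    ca_levels = sorted({rec.ca_uM for rec in dataset})
    v_levels = sorted({float(rec.voltage.y[-1]) for rec in dataset})
    if len(ca_levels) < 2:
        msg = (
            f"only {len(ca_levels)} Ca2+ level(s) in the dataset: K_C and K_O cannot "
            "both be constrained (non-identifiable fit)"
        )
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)
    if len(v_levels) < 3:
        msg = f"only {len(v_levels)} voltage level(s): voltage dependence weakly constrained"
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)

    scales = [max(1.0, float(np.max(np.abs(rec.current.y)))) for rec in dataset]
    n_eval = 0

    def residuals(x: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        try:
            rates = _vector_to_rates(x, init.n_sites)
            parts = [
                (_simulate_record(rates, constants, ens, rec, dt_max) - rec.current.y) / sc
                for rec, sc in zip(dataset, scales)
            ]
            return np.concatenate(parts)
        except Exception:
            return np.full(sum(rec.current.t.size for rec in dataset), 1e3)

    x0 = _rates_to_vector(init)
    lo = x0.copy()
    hi = x0.copy()
    lo[:5] -= log_halfwidth
    hi[:5] += log_halfwidth
    lo[5], hi[5] = max(0.2, x0[5] - 0.6), x0[5] + 0.6
    lo[6], hi[6] = min(0.0, x0[6] - 0.5), max(1.0, x0[6] + 0.5)
    lo[7], hi[7] = 0.0, 1.0

    de = optimize.differential_evolution(
        lambda x: float(np.sum(residuals(x) ** 2)),
        bounds=list(zip(lo, hi)),
        seed=seed,
        maxiter=global_maxiter,
        popsize=global_popsize,
        tol=1e-8,
        init="sobol",
        x0=x0,
        polish=False,
    )
    sol = optimize.least_squares(
        residuals, de.x, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=4000
    )
    best = sol.x if sol.cost <= np.sum(residuals(de.x) ** 2) / 2 else de.x
    rates = _vector_to_rates(best, init.n_sites)
    rmse = float(np.sqrt(np.mean(residuals(best) ** 2)))

    try:
        jtj = sol.jac.T @ sol.jac
        cond = float(np.linalg.cond(jtj))
        if not np.isfinite(cond) or cond > 1e10:
            msg = (
                f"objective is nearly flat along some parameter direction "
                f"(J'J condition number {cond:.2e}); parameters are not individually "
                "identifiable — trust the P_o surface, not the raw parameters"
            )
            warnings.warn(msg, stacklevel=2)
            warns.append(msg)
    except Exception:
        pass

    v_grid = np.linspace(min(v_levels + [float(dataset[0].voltage.y[0])]), max(v_levels), surface_shape[0])
    ca_grid = np.geomspace(max(min(ca_levels), 1e-3), max(max(ca_levels), 1e-2), surface_shape[1])
    eq = rates.to_equilibrium()
    from .mwc import equilibrium_open_probability

    surface = np.array(
        [[equilibrium_open_probability(eq, constants, v, ca) for ca in ca_grid] for v in v_grid]
    )
    return GlobalFitReport(
        rates=rates,
        rmse=rmse,
        po_surface_v=v_grid,
        po_surface_ca=ca_grid,
        po_surface=surface,
        warnings=tuple(warns),
        n_evaluations=n_eval,
    )
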