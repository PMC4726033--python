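"""Non-stationary noise (mean-variance) analysis of channel ensembles.

For N identical channels carrying single-channel current i, the ensemble
variance of the macroscopic current at a given mean I obeys the parabola

    sigma^2 = i*I - I^2/N,

which vanishes at I = 0 (all closed) and I = N*i (all open) and peaks at
half activation.  Fitting this relation to repeated sweeps of the same
protocol yields i and N without resolving single-channel events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import FitFailureError, InvalidArgumentError
from .qmatrix import Waveform

__all__ = [
    "EnsembleSweeps",
    "VarianceFit",
    "mean_variance_curve",
    "fit_variance_parabola",
    "subtract_blocked",
]


@dataclass(frozen=True)
class EnsembleSweeps:
    """Repeated current records of one protocol.

    t       times (ms); sweeps  array (n_times, n_sweeps) of currents (pA).
    """

    t: np.ndarray
    sweeps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        s = np.asarray(self.sweeps, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "sweeps", s)
        if s.ndim != 2 or s.shape[0] != t.size:
            raise InvalidArgumentError("sweeps must be (n_times, n_sweeps)")
        if s.shape[1] < 2:
            raise InvalidArgumentError("need at least 2 sweeps")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[1]


@dataclass(frozen=True)
class VarianceFit:
    """Single-channel current and channel count from a mean-variance fit."""

    i_single: float  # pA
    n_channels: float
    rmse: float  # pA^2
    se_i: float
    se_n: float

    def __post_init__(self) -> None:
        if self.i_single <= 0:
            raise InvalidArgumentError("i_single must be > 0")
        if self.n_channels < 1:
            raise InvalidArgumentError("n_channels must be >= 1")

    def variance_at(self, mean_current: float | np.ndarray) -> float | np.ndarray:
        I = np.asarray(mean_current, dtype=float)
        out = self.i_single * I - I**2 / self.n_channels
        return float(out) if out.ndim == 0 else out


def mean_variance_curve(s: EnsembleSweeps, bins: int = 50) -> np.ndarray:
    """Binned (mean current, ensemble variance) points from repeated sweeps.

    Per time point, the ensemble mean and unbiased (n-1) variance are
    computed across sweeps; points are then grouped into ``bins``
    equal-occupancy bins by mean current and both coordinates averaged
    within each bin.  Returns an array (n_bins, 2) of (I, sigma^2).

    A linear trend of per-sweep average current against sweep index
    (rundown/drift) triggers a warning — the parabola assumes
    stationarity across repetitions.
    """
    if s.n_sweeps < 2:
        raise InvalidArgumentError("need at least 2 sweeps")
    if bins < 1:
        raise InvalidArgumentError("bins must be >= 1")
    means = s.sweeps.mean(axis=1)
    variances = s.sweeps.var(axis=1, ddof=1)

    sweep_avg = s.sweeps.mean(axis=0)
    if s.n_sweeps >= 10 and np.ptp(sweep_avg) > 0:
        res = stats.linregress(np.arange(s.n_sweeps), sweep_avg)
        if res.pvalue < 0.05:
            warnings.warn(
                f"per-sweep mean current trends with sweep index "
                f"(slope {res.slope:.3g} pA/sweep, p={res.pvalue:.2g}); "
                "possible rundown — mean-variance analysis assumes stationarity",
                stacklevel=2,
            )

    order = np.argsort(means, kind="stable")
    chunks = np.array_split(order, min(bins, means.size))
    pts = np.array([[means[c].mean(), variances[c].mean()] for c in chunks if c.size])
    return pts


def _parabola_coefficients(I: np.ndarray, var: np.ndarray) -> np.ndarray:
    """OLS coefficients (i, 1/N) of sigma^2 = i*I - I^2/N."""
    X = np.column_stack([I, -(I**2)])
    coef, *_ = np.linalg.lstsq(X, var, rcond=None)
    return coef


def fit_variance_parabola(
    points: np.ndarray,
    sweeps: EnsembleSweeps | None = None,
    bins: int = 50,
    n_boot: int = 50,
    seed: int = 0,
) -> VarianceFit:
    """Least-squares fit of sigma^2 = i*I - I^2/N to (I, sigma^2) points.

    The model is linear in (i, 1/N), so the fit is an ordinary linear
    least squares on the design [I, -I^2] (delta method for N = 1/b).

    Standard errors: time samples within a sweep are correlated (the same
    channels persist over the gating relaxation time), so point-based SE
    formulas are poorly calibrated.  When the raw ``sweeps`` are given,
    the SEs come from a seeded bootstrap over sweeps — the exchangeable
    unit of the experiment; otherwise a heteroscedasticity-consistent
    (sandwich) formula serves as a rough fallback.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidArgumentError("points must be an (n, 2) array of (I, sigma^2)")
    I, var = pts[:, 0], pts[:, 1]
    if np.unique(I).size < 3:
        raise InvalidArgumentError("need >= 3 points with distinct mean currents")
    coef = _parabola_coefficients(I, var)
    i_single, inv_n = coef
    X = np.column_stack([I, -(I**2)])
    resid = var - X @ coef
    dof = max(1, I.size - 2)
    rmse = float(np.sqrt(resid @ resid / dof))
    if inv_n <= 0 or i_single <= 0:
        raise FitFailureError(
            "variance-mean relation is not concave-down (fitted N or i <= 0); "
            "data may lack high-open-probability coverage",
            last_iterate=coef,
            diagnostics={"i": float(i_single), "inv_n": float(inv_n), "rmse": rmse},
        )
    n = 1.0 / inv_n

    if sweeps is not None:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, sweeps.n_sweeps, size=sweeps.n_sweeps)
            rs = EnsembleSweeps(sweeps.t, sweeps.sweeps[:, idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bp = mean_variance_curve(rs, bins=bins)
            bc = _parabola_coefficients(bp[:, 0], bp[:, 1])
            if bc[0] > 0 and bc[1] > 0:
                boots.append([bc[0], 1.0 / bc[1]])
        boots = np.asarray(boots)
        se_i = float(boots[:, 0].std(ddof=1))
        se_n = float(boots[:, 1].std(ddof=1))
    else:
        xtx_inv = np.linalg.inv(X.T @ X)
        meat = X.T @ (X * (resid**2)[:, None]) * (I.size / dof)
        cov = xtx_inv @ meat @ xtx_inv
        se_i = float(np.sqrt(cov[0, 0]))
        se_n = float(np.sqrt(cov[1, 1])) * n**2
    return VarianceFit(
        i_single=float(i_single),
        n_channels=float(n),
        rmse=rmse,
        se_i=se_i,
        se_n=se_n,
    )


def subtract_blocked(total: Waveform, blocked: Waveform) -> Waveform:
    """Pointwise difference total - blocked (the blocker-isolated component).

    The blocked trace is resampled onto the total's time base by linear
    interpolation; its span must cover the total's to within one sample.
    """
    if total.quantity != "current" or blocked.quantity != "current":
        raise InvalidArgumentError("both waveforms must be currents")
    dt = float(np.median(np.diff(blocked.t)))
    if blocked.t[0] > total.t[0] + dt or blocked.t[-1] < total.t[-1] - dt:
        raise InvalidArgumentError(
            f"blocked span {blocked.span} does not cover total span {total.span}"
        )
    return Waveform(total.t, total.y - blocked.value_at(total.t), "current")
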