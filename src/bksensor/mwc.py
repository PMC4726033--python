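"""Monod-Wyman-Changeux (MWC) description of BK-channel gating.

The BK (large-conductance Ca2+- and voltage-activated K+) channel is modelled
as a concerted allosteric protein with ``n_sites`` identical Ca2+ binding
sites and a single voltage-dependent closed<->open conformational change.
With the default four sites this gives the classic 10-state scheme: five
closed states C0..C4 and five open states O0..O4, indexed by the number of
Ca2+ ions bound.

Two levels of description are provided:

* :class:`MWCParameters` — the equilibrium model.  The open probability is

  .. math::

     P_o(V, Ca) = \\frac{1}{1 + L(V)\\,
        \\left[\\frac{1 + Ca/K_C}{1 + Ca/K_O}\\right]^{n}},
     \\qquad L(V) = L(0)\\, e^{-QFV/RT}

  where :math:`L(0)` is the open-to-closed equilibrium constant of the
  Ca2+-free channel at 0 mV, :math:`Q` the equivalent gating charge, and
  :math:`K_C > K_O` the Ca2+ dissociation constants of the closed and open
  conformations.

* :class:`TenStateRates` — the kinetic model.  Ca2+ binds at a
  concentration-independent forward rate constant ``k_b`` on both tiers
  (off-rates ``k_b*K_C`` and ``k_b*K_O``), and the concerted C<->O step
  carries all of the voltage dependence.  Each bound Ca2+ multiplies the
  opening/closing equilibrium by ``K_C/K_O``; the fraction ``phi`` of that
  shift is applied to the opening rate and the remainder to the closing
  rate.  This parameterisation satisfies detailed balance around every
  elementary 4-state cycle by construction.

Units: time ms, voltage mV, concentration uM, rates ms^-1 (binding
uM^-1 ms^-1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "PhysicalConstants",
    "MWCParameters",
    "TenStateRates",
    "equilibrium_open_probability",
    "build_generator",
    "detailed_balance_report",
    "cycle_log_ratios",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant and absolute temperature.

    Defaults are SI CODATA values at the recording-room temperature of
    295 K (~22 C).
    """

    faraday: float = 96485.33212  # C/mol
    gas_constant: float = 8.31446261815324  # J/(mol K)
    temperature: float = 295.0  # K

    def __post_init__(self) -> None:
        for name in ("faraday", "gas_constant", "temperature"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidArgumentError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def f_over_rt(self) -> float:
        """F/(RT) in 1/V — the electrical distance scale."""
        return self.faraday / (self.gas_constant * self.temperature)

    def volt_factor(self, charge: float, v_mV: float | np.ndarray) -> float | np.ndarray:
        """exp(charge * F * V / (R T)) with V given in mV."""
        return np.exp(charge * self.f_over_rt * np.asarray(v_mV) * 1e-3)


@dataclass(frozen=True)
class MWCParameters:
    """Equilibrium MWC parameters of the BK gating model.

    L0      open-to-closed equilibrium constant of the Ca2+-free channel
            at 0 mV (dimensionless; large L0 = mostly closed at rest)
    Q       equivalent gating charge of the concerted transition (e0)
    K_C     closed-state Ca2+ dissociation constant (uM)
    K_O     open-state Ca2+ dissociation constant (uM)
    n_sites number of Ca2+ binding sites per channel
    """

    L0: float = 1000.0
    Q: float = 1.4
    K_C: float = 11.0
    K_O: float = 1.1
    n_sites: int = 4

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L0) and self.L0 > 0):
            raise InvalidArgumentError(f"L0 must be finite and > 0, got {self.L0!r}")
        if not np.isfinite(self.Q):
            raise InvalidArgumentError(f"Q must be finite, got {self.Q!r}")
        for name in ("K_C", "K_O"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidArgumentError(f"{name} must be finite and > 0, got {v!r}")
        if self.n_sites < 1 or int(self.n_sites) != self.n_sites:
            raise InvalidArgumentError(f"n_sites must be a positive integer, got {self.n_sites!r}")
        if self.K_O >= self.K_C:
            warnings.warn(
                "K_O >= K_C: Ca2+ binding does not favour opening; this is not a "
                "Ca2+-activated channel in the usual sense",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TenStateRates:
    """Kinetic rate constants of the 2*(n_sites+1)-state MWC scheme.

    k_b       Ca2+ forward binding rate constant (uM^-1 ms^-1), shared by
              the closed and open tiers
    K_C, K_O  dissociation constants (uM); off-rates are k_b*K_C, k_b*K_O
    alpha0    opening rate of the Ca2+-free channel at 0 mV (ms^-1)
    beta0     closing rate of the Ca2+-free channel at 0 mV (ms^-1)
    q_alpha   partial charge on the opening rate (e0)
    q_beta    partial charge on the closing rate (e0); q_alpha+q_beta = Q.
              A negative q_beta (closing accelerating with depolarisation)
              is admissible and steepens the voltage dependence of the
              activation time constant without changing the equilibrium.
    phi       fraction of the per-binding equilibrium shift (K_C/K_O)
              applied to the opening rate; the remainder divides the
              closing rate
    """

    k_b: float = 0.18
    K_C: float = 11.0
    K_O: float = 1.1
    alpha0: float = 0.008
    beta0: float = 8.0
    q_alpha: float = 1.9
    q_beta: float = -0.5
    phi: float = 0.5
    n_sites: int = 4

    def __post_init__(self) -> None:
        for name in ("k_b", "K_C", "K_O", "alpha0", "beta0"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidArgumentError(f"{name} must be finite and > 0, got {v!r}")
        if not (0.0 <= self.phi <= 1.0):
            raise InvalidArgumentError(f"phi must lie in [0, 1], got {self.phi!r}")
        if self.n_sites < 1 or int(self.n_sites) != self.n_sites:
            raise InvalidArgumentError(f"n_sites must be a positive integer, got {self.n_sites!r}")
        if self.K_O >= self.K_C:
            warnings.warn("K_O >= K_C: Ca2+ binding does not favour opening", stacklevel=2)

    @property
    def n_states(self) -> int:
        return 2 * (self.n_sites + 1)

    @property
    def open_indices(self) -> slice:
        """States are ordered C0..Cn, O0..On; the open tier is the second half."""
        return slice(self.n_sites + 1, 2 * (self.n_sites + 1))

    def to_equilibrium(self) -> MWCParameters:
        """Equilibrium parameters implied by the rates (L0 = beta0/alpha0)."""
        return MWCParameters(
            L0=self.beta0 / self.alpha0,
            Q=self.q_alpha + self.q_beta,
            K_C=self.K_C,
            K_O=self.K_O,
            n_sites=self.n_sites,
        )

    def generator(
        self, constants: PhysicalConstants, v_mV: float, ca_uM: float
    ) -> np.ndarray:
        return build_generator(self, constants, v_mV, ca_uM)


def equilibrium_open_probability(
    p: MWCParameters,
    c: PhysicalConstants,
    v_mV: float | np.ndarray,
    ca_uM: float | np.ndarray,
) -> float | np.ndarray:
    """Equilibrium open probability P_o(V, Ca) of the MWC model.

    Accepts scalars or broadcastable arrays of voltage (mV) and Ca2+ (uM).
    """
    v = np.asarray(v_mV, dtype=float)
    ca = np.asarray(ca_uM, dtype=float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(ca))):
        raise InvalidArgumentError("V and Ca must be finite")
    if np.any(ca < 0):
        raise InvalidArgumentError("Ca must be >= 0")
    L = p.L0 * c.volt_factor(-p.Q, v)
    allosteric = ((1.0 + ca / p.K_C) / (1.0 + ca / p.K_O)) ** p.n_sites
    po = 1.0 / (1.0 + L * allosteric)
    if po.ndim == 0:
        return float(po)
    return po


def build_generator(
    r: TenStateRates, c: PhysicalConstants, v_mV: float, ca_uM: float
) -> np.ndarray:
    """Instantaneous rate generator (Q-matrix) at fixed voltage and Ca2+.

    States are ordered C0..Cn, O0..On (n = n_sites).  Rows sum to zero;
    off-diagonal entries are transition rates in ms^-1.
    """
    if not (np.isfinite(v_mV) and np.isfinite(ca_uM)):
        raise InvalidArgumentError("V and Ca must be finite")
    if ca_uM < 0:
        raise InvalidArgumentError("Ca must be >= 0")
    n = r.n_sites
    m = n + 1
    Q = np.zeros((2 * m, 2 * m))
    ratio = r.K_C / r.K_O
    alpha_base = r.alpha0 * c.volt_factor(r.q_alpha, v_mV)
    beta_base = r.beta0 * c.volt_factor(-r.q_beta, v_mV)
    for i in range(m):
        ci, oi = i, m + i
        if i < n:  # Ca2+ binding, i -> i+1
            kon = (n - i) * r.k_b * ca_uM
            Q[ci, ci + 1] = kon
            Q[oi, oi + 1] = kon
        if i > 0:  # Ca2+ unbinding, i -> i-1
            Q[ci, ci - 1] = i * r.k_b * r.K_C
            Q[oi, oi - 1] = i * r.k_b * r.K_O
        Q[ci, oi] = alpha_base * ratio ** (i * r.phi)
        Q[oi, ci] = beta_base * ratio ** (-i * (1.0 - r.phi))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def cycle_log_ratios(Q: np.ndarray, n_sites: int) -> np.ndarray:
    """Log ratio of clockwise/counter-clockwise rate products for each
    elementary 4-cycle (C_i, C_{i+1}, O_{i+1}, O_i) of a generator matrix.

    Zero for a thermodynamically consistent scheme.  Requires all cycle
    rates to be nonzero (i.e. Ca > 0 for binding cycles).
    """
    m = n_sites + 1
    out = np.empty(n_sites)
    for i in range(n_sites):
        ci, cj, oi, oj = i, i + 1, m + i, m + i + 1
        cw = Q[ci, cj] * Q[cj, oj] * Q[oj, oi] * Q[oi, ci]
        ccw = Q[ci, oi] * Q[oi, oj] * Q[oj, cj] * Q[cj, ci]
        if cw <= 0 or ccw <= 0:
            raise InvalidArgumentError(
                f"cycle {i}: zero or negative rate encountered; cannot test balance"
            )
        out[i] = math.log(cw / ccw)
    return out


def detailed_balance_report(
    r: TenStateRates,
    c: PhysicalConstants | None = None,
    v_mV: float = 0.0,
    ca_uM: float = 1.0,
    tol: float = 1e-10,
) -> dict:
    """Thermodynamic-consistency report for the 10-state scheme.

    Builds the generator at (V, Ca) and reports, for each elementary
    4-cycle, the log ratio of clockwise to counter-clockwise rate
    products.  All must vanish (|log ratio| <= tol) for a scheme obeying
    detailed balance; the parameterisation used here guarantees this.
    """
    c = c or PhysicalConstants()
    if ca_uM <= 0:
        raise InvalidArgumentError("detailed balance test requires Ca > 0")
    Q = build_generator(r, c, v_mV, ca_uM)
    logs = cycle_log_ratios(Q, r.n_sites)
    return {
        "cycle_log_ratios": logs,
        "max_abs_log_ratio": float(np.max(np.abs(logs))),
        "balanced": bool(np.max(np.abs(logs)) <= tol),
        "tol": tol,
    }
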