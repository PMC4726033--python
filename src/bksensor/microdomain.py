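"""Channel-density and Ca2+ microdomain (coupling-distance) arithmetic.

Whole-cell counts and densities follow from elementary electrophysiology
(membrane area from capacitance, channel count from a saturating
current); the source-sensor distance follows from the linearised
buffered-diffusion point-source profile

    dCa(r) = i_Ca / (4 pi z F D r) * exp(-r / lambda),
    lambda = sqrt(D / (k_on [B])),

where i_Ca is the single-channel Ca2+ current, D the Ca2+ diffusion
coefficient, and lambda the length constant set by the mobile buffer's
forward rate k_on and free concentration [B].  A slow buffer (EGTA)
leaves nanodomains (<100 nm) untouched while a fast one (BAPTA)
collapses them — the classic diagnostic for coupling distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidArgumentError
from .mwc import PhysicalConstants

__all__ = [
    "CellGeometry",
    "BufferModel",
    "membrane_area",
    "channel_count_from_current",
    "density",
    "neighbors_per_sensor",
    "buffer_length_constant",
    "ca_at_distance",
    "distance_for_ca",
]

# Documented defaults for buffered diffusion (configuration, not results):
# D_Ca ~ 220 um^2/s in cytosol; EGTA k_on ~ 2.7e6 M^-1 s^-1, BAPTA ~ 4e8.
D_CA_DEFAULT = 220.0
K_ON_EGTA = 2.7e6
K_ON_BAPTA = 4.0e8


def membrane_area(c_total_pF: float, c_specific_uF_cm2: float = 1.0) -> float:
    """Membrane area (um^2) from whole-cell capacitance.

    1 pF at 1 uF/cm^2 corresponds to 100 um^2.
    """
    if c_total_pF <= 0 or c_specific_uF_cm2 <= 0:
        raise InvalidArgumentError("capacitances must be > 0")
    return c_total_pF / c_specific_uF_cm2 * 100.0


@dataclass(frozen=True)
class CellGeometry:
    """Whole-cell capacitance and the membrane area it implies."""

    c_total: float  # pF
    c_specific: float = 1.0  # uF/cm^2

    def __post_init__(self) -> None:
        if self.c_total <= 0 or self.c_specific <= 0:
            raise InvalidArgumentError("capacitances must be > 0")

    @property
    def area(self) -> float:
        """um^2"""
        return membrane_area(self.c_total, self.c_specific)


def channel_count_from_current(
    i_pA: float, g_single_pS: float, driving_force_mV: float, p_open: float = 1.0
) -> int:
    """Channel count from a macroscopic current at known unitary size.

    count = |I| / (g * (V - E) * P_o), with pS*mV -> pA handled.
    """
    if g_single_pS <= 0 or driving_force_mV <= 0 or p_open <= 0:
        raise InvalidArgumentError("g_single, driving force and p_open must be > 0")
    return round(abs(i_pA) / (g_single_pS * 1e-3 * driving_force_mV * p_open))


def density(count: float, area_um2: float) -> float:
    """Channels per um^2, reported to one decimal."""
    if area_um2 <= 0:
        raise InvalidArgumentError("area must be > 0")
    if count < 0:
        raise InvalidArgumentError("count must be >= 0")
    return round(count / area_um2, 1)


def neighbors_per_sensor(
    density_source: float, density_sensor: float
) -> tuple[float, tuple[int, int]]:
    """Expected number of source channels per sensor under uniform random
    placement: the density ratio, plus the integer bracket
    [floor(ratio), ceil(ratio)+1]."""
    if density_source <= 0 or density_sensor <= 0:
        raise InvalidArgumentError("densities must be > 0")
    ratio = density_source / density_sensor
    return ratio, (math.floor(ratio), math.ceil(ratio) + 1)


def buffer_length_constant(
    d_ca_um2_s: float, k_on_M_s: float, b_conc_mM: float
) -> float:
    """lambda = sqrt(D / (k_on [B])) in um.

    D in um^2/s, k_on in M^-1 s^-1, [B] in mM (so k_on*[B]*1e-3 is the
    buffering rate in s^-1).
    """
    if d_ca_um2_s <= 0 or k_on_M_s <= 0 or b_conc_mM <= 0:
        raise InvalidArgumentError("all buffer parameters must be > 0")
    return math.sqrt(d_ca_um2_s / (k_on_M_s * b_conc_mM * 1e-3))


@dataclass(frozen=True)
class BufferModel:
    """Linearised buffered-diffusion model around a point Ca2+ source.

    d_ca   Ca2+ diffusion coefficient (um^2/s)
    k_on   buffer forward binding rate (M^-1 s^-1)
    b_conc free buffer concentration (mM)
    i_ca   single-channel Ca2+ current (pA)
    z      ion valence
    """

    d_ca: float = D_CA_DEFAULT
    k_on: float = K_ON_EGTA
    b_conc: float = 5.0
    i_ca: float = 0.144  # 2.4 pS * 60 mV
    z: int = 2

    def __post_init__(self) -> None:
        for name in ("d_ca", "k_on", "b_conc", "i_ca"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.z < 1:
            raise InvalidArgumentError("z must be >= 1")

    @property
    def length_constant(self) -> float:
        """um"""
        return buffer_length_constant(self.d_ca, self.k_on, self.b_conc)


def ca_at_distance(
    bm: BufferModel, r_um: float | np.ndarray, constants: PhysicalConstants | None = None
) -> float | np.ndarray:
    """Steady-state Ca2+ elevation above baseline at distance r (uM).

    dCa(r) = i/(4 pi z F D r) * exp(-r/lambda); diverges as r -> 0
    (point source), so r must be strictly positive.
    """
    constants = constants or PhysicalConstants()
    r = np.asarray(r_um, dtype=float)
    if np.any(r <= 0):
        raise InvalidArgumentError("r must be > 0 (point-source singularity at r = 0)")
    # A -> mol/s via zF; um-based lengths: mol/m^3 = mM; *1e3 -> uM.
    amps = bm.i_ca * 1e-12
    denom = 4.0 * math.pi * bm.z * constants.faraday * (bm.d_ca * 1e-12) * (r * 1e-6)
    out = amps / denom * 1e3 * np.exp(-r / bm.length_constant)
    return float(out) if out.ndim == 0 else out


def distance_for_ca(
    bm: BufferModel,
    target_uM: float,
    bracket: tuple[float, float] = (0.01, 1.0),
    constants: PhysicalConstants | None = None,
) -> float:
    """Distance r (um) at which dCa(r) equals the target, by bracketed
    bisection to 0.1 nm.

    dCa is strictly decreasing in r, so the target must lie between
    dCa(r_max) and dCa(r_min).
    """
    constants = constants or PhysicalConstants()
    r_min, r_max = bracket
    if not (0 < r_min < r_max):
        raise InvalidArgumentError("require 0 < r_min < r_max")
    hi = ca_at_distance(bm, r_min, constants)
    lo = ca_at_distance(bm, r_max, constants)
    if not (lo <= target_uM <= hi):
        raise InvalidArgumentError(
            f"target {target_uM} uM outside attainable range [{lo:.3g}, {hi:.3g}] "
            f"on bracket {bracket}"
        )
    return float(
        brentq(lambda r: ca_at_distance(bm, r, constants) - target_uM, r_min, r_max, xtol=1e-4)
    )
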