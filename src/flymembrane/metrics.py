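"""Summary quantities: bandwidth, gain-bandwidth products, contrast gain
and the ATP cost of running the membrane.

Bandwidth follows the photoreceptor convention: only frequencies above
2 Hz count (the sub-2 Hz amplification produced by slow inactivation is
masked by phototransduction adaptation in vivo), the peak gain is the
maximum of |Z| over f >= 2 Hz, and the bandwidth is the highest
frequency at which the gain falls to 1/sqrt(2) of that peak.  The
gain-bandwidth product GBWP = peak gain x bandwidth; for a passive RC
membrane it equals 1/(2 pi C) independently of the conductance.

Contrast gain treats phototransduction as instantaneous: a light
contrast c(t) modulates the light conductance around its steady value,
equivalent to injecting I = g_light (E_L - V) c(t), so
T(f) = g_light (E_L - V) Z(f) in mV per unit contrast, and the
contrast-gain-bandwidth product cGBWP = peak |T| x bandwidth.

Energy cost is the ATP hydrolysis rate of the Na+/K+ pump, |I_P|/e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .linear_response import (
    FreezeSpec,
    ImpedanceSpectrum,
    membrane_admittance_function,
)
from .membrane import MembraneParams, OperatingPoint, solve_balance_at_voltage

__all__ = [
    "MetricsRecord",
    "ELEMENTARY_CHARGE",
    "bandwidth",
    "peak_gain",
    "gbwp",
    "contrast_gain",
    "peak_contrast_gain",
    "energy_cost",
    "passive_same_bandwidth_cost",
    "metrics_for_op",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C

_F_FLOOR = 2.0      # Hz, low-frequency floor for gain/bandwidth
_F_CEIL = 1000.0    # Hz, upper edge of the analysis band


def _magnitude_fn(
    source: ImpedanceSpectrum | Callable[[np.ndarray], np.ndarray],
) -> Callable[[np.ndarray], np.ndarray]:
    """|Z|(f) in GOhm from a spectrum's provenance or a callable.

    A spectrum produced by :func:`~flymembrane.linear_response.membrane_impedance`
    is backed by a closed form; for grid-only data fall back to log-log
    interpolation.
    """
    if callable(source):
        return lambda f: np.abs(np.asarray(source(np.asarray(f, dtype=float))))
    f_grid = np.asarray(source.f, dtype=float)
    mag = np.abs(np.asarray(source.Z))
    logf, logm = np.log(f_grid), np.log(mag)

    def interp(f):
        return np.exp(np.interp(np.log(np.asarray(f, dtype=float)), logf, logm))

    return interp


def peak_gain(
    source: ImpedanceSpectrum | Callable, f_lo: float = _F_FLOOR, f_hi: float = _F_CEIL
) -> tuple[float, float]:
    """(max |Z| in GOhm, argmax frequency in Hz) over [f_lo, f_hi]."""
    mag = _magnitude_fn(source)
    grid = np.logspace(math.log10(f_lo), math.log10(f_hi), 600)
    vals = mag(grid)
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if lo == hi:
        return float(vals[k]), float(grid[k])
    res = minimize_scalar(
        lambda f: -float(mag(f)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    f_pk = float(res.x)
    m_pk = float(mag(f_pk))
    if m_pk < vals[k]:  # guard: keep the grid point if refinement slipped
        return float(vals[k]), float(grid[k])
    return m_pk, f_pk


def bandwidth(
    source: ImpedanceSpectrum | Callable,
    f_lo: float = _F_FLOOR,
    f_hi: float = _F_CEIL,
) -> float:
    """Highest frequency (Hz) at which the gain magnitude falls to
    1/sqrt(2) of its peak over [f_lo, f_hi].

    The crossing is refined by bisection between grid points to well
    below 0.01 Hz.  If the magnitude never drops below the threshold
    inside the band, the upper band edge is returned (the membrane is
    faster than the analysis band).
    """
    mag = _magnitude_fn(source)
    m_pk, _ = peak_gain(source, f_lo, f_hi)
    thr = m_pk / math.sqrt(2.0)
    grid = np.logspace(math.log10(f_lo), math.log10(f_hi), 600)
    vals = mag(grid)
    below = vals < thr
    if not below.any():
        return f_hi
    # highest crossing: last index where the magnitude is still >= thr
    above_idx = np.nonzero(~below)[0]
    k = int(above_idx[-1])
    if k == grid.size - 1:
        return f_hi
    return float(
        brentq(lambda f: float(mag(f)) - thr, grid[k], grid[k + 1], xtol=1e-6)
    )


def gbwp(
    source: ImpedanceSpectrum | Callable,
    f_lo: float = _F_FLOOR,
    f_hi: float = _F_CEIL,
) -> float:
    """Gain-bandwidth product in MOhm*Hz."""
    m_pk, _ = peak_gain(source, f_lo, f_hi)
    return m_pk * 1e3 * bandwidth(source, f_lo, f_hi)


def contrast_gain(op: OperatingPoint, spectrum: ImpedanceSpectrum) -> np.ndarray:
    """|T(f)| in mV per unit contrast on the spectrum's frequency grid."""
    drive = op.g_light * (op.membrane.E_L - op.V)  # pA
    return np.abs(drive * spectrum.Z)  # pA * GOhm = mV


def peak_contrast_gain(
    op: OperatingPoint,
    source: ImpedanceSpectrum | Callable,
    f_lo: float = _F_FLOOR,
    f_hi: float = _F_CEIL,
) -> float:
    drive = abs(op.g_light * (op.membrane.E_L - op.V))
    m_pk, _ = peak_gain(source, f_lo, f_hi)
    return drive * m_pk


def energy_cost(op: OperatingPoint) -> float:
    """Na+/K+ pump ATP consumption (molecules/s): |I_P| / e."""
    return abs(op.I_P) * 1e-12 / ELEMENTARY_CHARGE


def passive_same_bandwidth_cost(
    target_bandwidth: float,
    V: float,
    membrane: MembraneParams | None = None,
) -> float:
    """ATP cost (molecules/s) of a passive membrane matching a bandwidth.

    Builds a pure RC membrane whose corner frequency equals
    ``target_bandwidth`` (total conductance 2 pi C B), partitions the
    conductance into a K+ part and a depolarising part so that the ionic
    balance holds at ``V``, and returns the pump cost.  Raises if the
    partition would need negative conductances.
    """
    mem = membrane or MembraneParams()
    g_total = 2.0 * math.pi * target_bandwidth * mem.capacitance * 1e-3  # nS
    dK = mem.E_K - V
    dL = mem.E_L - V
    coeff = mem.na_fraction + (mem.exchanger_na_in / 2.0) * mem.ca_fraction
    # balance fixes the ratio g_L/g_K at this voltage
    ratio = -(mem.pump_na_out / mem.pump_k_in) * dK / (coeff * dL)
    if ratio <= 0:
        raise ValueError("no feasible partition at this voltage")
    g_K = g_total / (1.0 + ratio)
    g_L = g_total - g_K
    if g_K < mem.g_K_leak or g_L < mem.g_L_leak:
        raise ValueError(
            "partition infeasible: required conductances fall below the leaks"
        )
    I_P = -g_K * dK / mem.pump_k_in  # pA
    return abs(I_P) * 1e-12 / ELEMENTARY_CHARGE


@dataclass(frozen=True)
class MetricsRecord:
    """Headline numbers for one operating point / freeze / modulation."""

    V: float                    # mV
    bandwidth: float            # Hz
    peak_gain: float            # MOhm
    gbwp: float                 # MOhm*Hz
    peak_contrast_gain: float   # mV per unit contrast
    cgbwp: float                # mV*Hz
    energy_cost: float          # ATP/s
    modulation: str = "none"
    freeze: str = "none"


def metrics_for_op(
    op: OperatingPoint,
    freeze: FreezeSpec | None = None,
    modulation_tag: str = "none",
    freeze_tag: str = "none",
) -> MetricsRecord:
    """Evaluate all summary metrics at one operating point."""
    y = membrane_admittance_function(op, freeze)
    z = lambda f: 1.0 / y(f)
    m_pk, _ = peak_gain(z)
    bw = bandwidth(z)
    pcg = peak_contrast_gain(op, z)
    return MetricsRecord(
        V=op.V,
        bandwidth=bw,
        peak_gain=m_pk * 1e3,
        gbwp=m_pk * 1e3 * bw,
        peak_contrast_gain=pcg,
        cgbwp=pcg * bw,
        energy_cost=energy_cost(op),
        modulation=modulation_tag,
        freeze=freeze_tag,
    )
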