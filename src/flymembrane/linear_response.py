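"""Small-signal impedance of the active membrane (RrLC equivalent circuit).

Linearising a Hodgkin-Huxley conductance g = gbar * h * m^gamma around a
steady state yields, besides the steady (chord) conductance 1/R, one
phenomenological resistor-inductor branch per gating variable shunting
the membrane capacitance:

    R   = 1 / (gbar m^gamma h)
    r   = 1 / [(V - E_K) gbar h  d(m_inf^gamma)/dV],   L   = tau_m r
    r_h = 1 / [(V - E_K) gbar m^gamma  d(h_inf)/dV],   L_h = tau_h r_h

For a K+ conductance above E_K the activation branch is positive
(negative feedback, inductive "shunt peaking") while the inactivation
branch is negative (positive feedback).  A conductance with partial or
multi-mode inactivation is split into additive components that are
either non-inactivating or carry a single inactivation mode, and each
component is linearised separately.

The impedance of one component and of the whole membrane:

    1/Z_c(f) = 1/R + (1/r)/(1 + i 2 pi f tau_m) + (1/r_h)/(1 + i 2 pi f tau_h)
    1/Z(f)   = sum_c 1/Z_c(f) + g_K,leak + g_L,leak + g_light + i 2 pi f C

The steady light conductance loads the membrane exactly like a leak and
is included as a passive shunt; pump and exchanger currents are held
fixed and do not enter.  Gating variables can be selectively frozen
(pinned at reference values), which removes their branch and bakes the
frozen value into R; freezing everything leaves a pure RC membrane.

Units: branch elements in GOhm and GOhm*s (1/nS = GOhm), frequencies Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .membrane import OperatingPoint

__all__ = [
    "RrLCBranch",
    "FreezeSpec",
    "ImpedanceSpectrum",
    "branch_elements",
    "component_impedance",
    "membrane_branches",
    "membrane_admittance_function",
    "membrane_impedance",
    "passive_equivalent",
    "default_frequency_grid",
]

_MS = 1e-3  # ms -> s


def default_frequency_grid() -> np.ndarray:
    """Logarithmic grid, 0.1-1000 Hz, 400 points: resolves both the
    sub-2 Hz amplification and the corner region."""
    return np.logspace(-1.0, 3.0, 400)


@dataclass(frozen=True)
class FreezeSpec:
    """Which gating variables are pinned at their reference values.

    ``frozen`` holds (channel name, gate name) pairs; a frozen gate
    contributes no dynamic branch, only its steady conductance.
    """

    frozen: frozenset[tuple[str, str]] = frozenset()

    @classmethod
    def none(cls) -> "FreezeSpec":
        return cls(frozenset())

    @classmethod
    def all_gates(cls, op: OperatingPoint) -> "FreezeSpec":
        pairs = {
            (name, gate) for name, gates in op.gates.items() for gate in gates
        }
        return cls(frozenset(pairs))

    @classmethod
    def inactivation_only(cls, op: OperatingPoint) -> "FreezeSpec":
        pairs = {
            (name, gate)
            for name, gates in op.gates.items()
            for gate in gates
            if gate != "m"
        }
        return cls(frozenset(pairs))

    @classmethod
    def all_except_channel(cls, op: OperatingPoint, active: str) -> "FreezeSpec":
        pairs = {
            (name, gate)
            for name, gates in op.gates.items()
            for gate in gates
            if name != active
        }
        return cls(frozenset(pairs))

    def is_frozen(self, channel: str, gate: str) -> bool:
        return (channel, gate) in self.frozen


@dataclass(frozen=True)
class RrLCBranch:
    """Linearised elements of one conductance component.

    ``R`` (GOhm) is always present.  ``r``/``L`` (GOhm, GOhm*s) form the
    activation branch and ``r_h``/``L_h`` the inactivation branch; either
    branch is ``None`` when the gate is absent, frozen, or its steady
    curve has zero slope at the operating voltage (infinite branch
    resistance).  ``label`` is "<channel>/<component index>".
    """

    R: float
    r: float | None = None
    L: float | None = None
    r_h: float | None = None
    L_h: float | None = None
    tau_m: float | None = None  # s
    tau_h: float | None = None  # s
    label: str = ""

    def admittance(self, f: float | np.ndarray) -> complex | np.ndarray:
        """Branch admittance in nS at frequency f (Hz)."""
        y = 1.0 / self.R + 0j * np.asarray(f, dtype=float)
        if self.r is not None:
            y = y + (1.0 / self.r) / (1.0 + 2j * math.pi * f * self.tau_m)
        if self.r_h is not None:
            y = y + (1.0 / self.r_h) / (1.0 + 2j * math.pi * f * self.tau_h)
        return y


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex membrane impedance on a frequency grid.

    ``Z`` is in GOhm.  ``meta`` records provenance: operating voltage,
    freeze specification and modulation context.
    """

    f: np.ndarray
    Z: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    @property
    def magnitude_MOhm(self) -> np.ndarray:
        return np.abs(self.Z) * 1e3


def _finite_or_none(x: float) -> float | None:
    return x if math.isfinite(x) and x != 0.0 else None


def branch_elements(
    op: OperatingPoint,
    channel_name: str,
    component_index: int,
    freeze: FreezeSpec | None = None,
) -> RrLCBranch:
    """RrLC elements for one component of one channel at ``op``.

    The component's share of the maximal conductance is
    fraction * gbar.  Frozen gates keep their steady value inside R and
    lose their dynamic branch.  At V = E_K or where a steady-state curve
    is flat, the corresponding branch resistance diverges and the branch
    is reported absent rather than raising a division error.
    """
    freeze = freeze or FreezeSpec.none()
    ch = next(c for c in op.channels if c.name == channel_name)
    comp = ch.components[component_index]
    gamma = ch.activation_exponent
    V = op.V
    gates = op.gates[channel_name]
    m = gates["m"]
    h = 1.0 if comp.scheme is None else gates[comp.gate]
    gbar_k = ch.g_max * comp.fraction  # nS
    dV = V - ch.reversal  # mV above E_K

    g_steady = gbar_k * m**gamma * h  # nS
    R = math.inf if g_steady == 0.0 else 1.0 / g_steady  # GOhm

    r = L = tau_m = None
    if not freeze.is_frozen(channel_name, "m") and gbar_k > 0.0:
        # d(m_inf^gamma)/dV via the chain rule on the activation scheme
        # (for the printed bracket^(1/gamma) forms this reduces to the
        # derivative of the underlying sigmoid)
        dmg = gamma * m ** (gamma - 1) * ch.activation.steady_state_slope(V)
        denom = dV * gbar_k * h * dmg  # nS
        r_val = math.inf if denom == 0.0 else 1.0 / denom
        r = _finite_or_none(r_val)
        if r is not None:
            tau_m = ch.activation.time_constant(V) * _MS
            L = tau_m * r

    r_h = L_h = tau_h = None
    if (
        comp.scheme is not None
        and not freeze.is_frozen(channel_name, comp.gate)
        and gbar_k > 0.0
    ):
        dh = comp.scheme.steady_state_slope(V)
        denom = dV * gbar_k * m**gamma * dh  # nS
        rh_val = math.inf if denom == 0.0 else 1.0 / denom
        r_h = _finite_or_none(rh_val)
        if r_h is not None:
            tau_h = comp.scheme.time_constant(V) * _MS
            L_h = tau_h * r_h

    return RrLCBranch(
        R=R, r=r, L=L, r_h=r_h, L_h=L_h, tau_m=tau_m, tau_h=tau_h,
        label=f"{channel_name}/{component_index}",
    )


def component_impedance(branch: RrLCBranch, f: float | np.ndarray) -> complex | np.ndarray:
    """Impedance (GOhm) of a single linearised component at f (Hz)."""
    return 1.0 / branch.admittance(f)


def membrane_branches(
    op: OperatingPoint, freeze: FreezeSpec | None = None
) -> list[RrLCBranch]:
    out = []
    for ch in op.channels:
        for k in range(len(ch.components)):
            out.append(branch_elements(op, ch.name, k, freeze))
    return out


def membrane_admittance_function(
    op: OperatingPoint, freeze: FreezeSpec | None = None
) -> Callable[[float | np.ndarray], complex | np.ndarray]:
    """Total membrane admittance Y(f) in nS as a closed-form callable.

    Y(f) = sum_c 1/Z_c + g_K,leak + (g_L,leak + g_light) + i 2 pi f C.
    """
    branches = membrane_branches(op, freeze)
    mem = op.membrane
    g_passive = mem.g_K_leak + mem.g_L_leak + op.g_light  # nS
    cap = mem.capacitance * 1e-3  # pF -> nS/Hz (2*pi*f*C)

    def admittance(f):
        y = g_passive + 2j * math.pi * np.asarray(f, dtype=float) * cap
        for b in branches:
            y = y + b.admittance(f)
        return y

    return admittance


def membrane_impedance(
    op: OperatingPoint,
    freeze: FreezeSpec | None = None,
    f_grid: Sequence[float] | np.ndarray | None = None,
) -> ImpedanceSpectrum:
    """Impedance spectrum of the whole photoreceptor at an operating point."""
    if f_grid is None:
        f_grid = default_frequency_grid()
    f = np.asarray(f_grid, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency grid")
    Z = 1.0 / membrane_admittance_function(op, freeze)(f)
    meta = {
        "V_mV": op.V,
        "g_light_nS": op.g_light,
        "frozen": sorted(freeze.frozen) if freeze else [],
    }
    return ImpedanceSpectrum(f=f, Z=Z, meta=meta)


def passive_equivalent(
    op: OperatingPoint, f_grid: Sequence[float] | np.ndarray | None = None
) -> ImpedanceSpectrum:
    """Impedance of the passive membrane with identical total (chord)
    conductance and capacitance: every gating variable frozen."""
    return membrane_impedance(op, FreezeSpec.all_gates(op), f_grid)
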