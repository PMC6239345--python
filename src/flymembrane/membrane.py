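"""Steady-state ionic balance of the photoreceptor membrane.

The membrane is a single electrical compartment holding the three
voltage-dependent K+ conductances, a K+ leak, a depolarising leak with
the reversal potential of the light-induced current (LiC), the light
conductance itself, a Na+/K+ ATPase and a Na+/Ca2+ exchanger.  At a
steady depolarisation V every net ionic current (K+, Na+, Ca2+) must
vanish; because the LiC carries a fixed Na+:Ca2+ fraction and the pump
and exchanger have fixed stoichiometries, this yields a linear system
in (g_light, I_P, I_E) at each voltage:

    I(K)  = g_K(V) (E_K - V) + 2 I_P            = 0
    I(Na) = f_Na g_L (E_L - V) - 3 I_P - 3 I_E  = 0
    I(Ca) = f_Ca g_L (E_L - V) + 2 I_E          = 0

with g_L = g_light + g_L,leak.  The pump current I_P is the cycle rate
times the elementary charge (2 K+ in, 3 Na+ out, one ATP per cycle;
net charge export of one e per cycle), so the hyperpolarising charge
current it contributes to the membrane is -I_P; likewise -I_E for the
exchanger (3 Na+ in per Ca2+ out).  The dark resting potential is the
voltage at which the solved light conductance is exactly zero.

Units: mV, nS, pA, pF (1 nS * 1 mV = 1 pA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from scipy.optimize import brentq

from .channels import ChannelModel

__all__ = [
    "MembraneParams",
    "OperatingPoint",
    "solve_balance_at_voltage",
    "find_dark_rest",
    "sweep_light_levels",
    "re_equilibrate",
    "STANDARD_GRID",
]

#: Depolarisations (mV) named repeatedly in the sweep analyses: dark rest,
#: low light, two intermediate levels and two high levels up to the chosen
#: maximum steady-state depolarisation of -36 mV.
STANDARD_GRID: tuple[float, ...] = (-68.0, -59.0, -52.0, -44.0, -41.0, -36.0)


@dataclass(frozen=True)
class MembraneParams:
    """Fixed electrical and stoichiometric constants of the membrane."""

    capacitance: float = 50.0   # pF
    E_K: float = -85.0          # mV
    E_L: float = 5.0            # mV, reversal of the light-induced current
    g_K_leak: float = 2.1       # nS
    g_L_leak: float = 0.803     # nS, depolarising leak with reversal E_L
    na_fraction: float = 0.74   # Na+ share of the LiC
    ca_fraction: float = 0.26   # Ca2+ share of the LiC
    pump_k_in: int = 2          # K+ in per ATPase cycle
    pump_na_out: int = 3        # Na+ out per ATPase cycle
    exchanger_na_in: int = 3    # Na+ in per exchanger cycle
    exchanger_ca_out: int = 1   # Ca2+ out per exchanger cycle

    def __post_init__(self) -> None:
        if abs(self.na_fraction + self.ca_fraction - 1.0) > 1e-12:
            raise ValueError("LiC ionic fractions must sum to 1")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if min(self.g_K_leak, self.g_L_leak) < 0:
            raise ValueError("leak conductances must be non-negative")


@dataclass(frozen=True)
class OperatingPoint:
    """A self-consistent steady state of the membrane.

    ``gates`` maps channel name -> gate name -> value; ``conductances``
    holds the per-channel steady conductances (nS).  ``feasible`` is
    False when the balance requires a negative light conductance, i.e.
    the requested voltage lies below the dark resting potential.
    """

    V: float
    g_light: float
    I_P: float
    I_E: float
    gates: Mapping[str, Mapping[str, float]]
    conductances: Mapping[str, float]
    channels: tuple[ChannelModel, ...]
    membrane: MembraneParams
    feasible: bool = True

    @property
    def g_K_total(self) -> float:
        """Total K+ conductance (channels + K+ leak, nS)."""
        return sum(self.conductances.values()) + self.membrane.g_K_leak

    @property
    def g_L_total(self) -> float:
        """Total depolarising conductance (light + leak, nS)."""
        return self.g_light + self.membrane.g_L_leak

    @property
    def total_conductance(self) -> float:
        """Chord conductance of the whole membrane (nS)."""
        return self.g_K_total + self.g_L_total

    def residuals(self) -> tuple[float, float, float]:
        """Residuals (pA) of the three zero-net-flux equations."""
        mem = self.membrane
        dK = mem.E_K - self.V
        dL = mem.E_L - self.V
        i_k = self.g_K_total * dK + mem.pump_k_in * self.I_P
        i_na = (
            mem.na_fraction * self.g_L_total * dL
            - mem.pump_na_out * self.I_P
            - mem.exchanger_na_in * self.I_E
        )
        i_ca = mem.ca_fraction * self.g_L_total * dL + 2 * mem.exchanger_ca_out * self.I_E
        return i_k, i_na, i_ca


def _steady_gates(
    channels: Sequence[ChannelModel],
    V: float,
    gate_overrides: Mapping[str, Mapping[str, float]] | None,
) -> dict[str, dict[str, float]]:
    gates: dict[str, dict[str, float]] = {}
    for ch in channels:
        g = ch.steady_gates(V)
        if gate_overrides and ch.name in gate_overrides:
            g.update(gate_overrides[ch.name])
        gates[ch.name] = g
    return gates


def solve_balance_at_voltage(
    V: float,
    channels: Sequence[ChannelModel],
    membrane: MembraneParams | None = None,
    gate_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> OperatingPoint:
    """Solve the ionic balance at a fixed voltage.

    Gate variables sit at their steady-state values for ``V`` unless
    pinned through ``gate_overrides`` (used by the freeze studies).  The
    balance is linear in (g_light, I_P, I_E) and solved in closed form;
    a negative solved light conductance marks the point infeasible (the
    voltage lies below the dark resting potential) rather than raising.
    """
    mem = membrane or MembraneParams()
    gates = _steady_gates(channels, V, gate_overrides)
    conductances = {ch.name: ch.conductance(gates[ch.name]) for ch in channels}
    g_K = sum(conductances.values()) + mem.g_K_leak

    dK = mem.E_K - V
    dL = mem.E_L - V
    # Eliminate I_P and I_E from the Na+ equation:
    #   f_Na gL dL + (3/2) g_K dK + (3/2) f_Ca gL dL = 0
    coeff = mem.na_fraction + (mem.exchanger_na_in / 2.0) * mem.ca_fraction
    if abs(dL) < 1e-12:
        raise ValueError("voltage coincides with the LiC reversal potential")
    g_L = -(mem.pump_na_out / mem.pump_k_in) * g_K * dK / (coeff * dL)
    g_light = g_L - mem.g_L_leak
    I_P = -g_K * dK / mem.pump_k_in
    I_E = -mem.ca_fraction * g_L * dL / (2.0 * mem.exchanger_ca_out)
    feasible = g_light >= -1e-9
    return OperatingPoint(
        V=V,
        g_light=g_light,
        I_P=I_P,
        I_E=I_E,
        gates=gates,
        conductances=conductances,
        channels=tuple(channels),
        membrane=mem,
        feasible=feasible,
    )


def find_dark_rest(
    channels: Sequence[ChannelModel],
    membrane: MembraneParams | None = None,
    bracket: tuple[float, float] = (-90.0, -30.0),
    gate_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> OperatingPoint:
    """Dark resting potential: the voltage at which the balance admits
    zero light conductance.  Brent root find on g_light(V)."""
    mem = membrane or MembraneParams()

    def residual(V: float) -> float:
        return solve_balance_at_voltage(V, channels, mem, gate_overrides).g_light

    lo, hi = bracket
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise RuntimeError(
            "no dark resting potential in bracket "
            f"[{lo}, {hi}] mV (g_light residuals {r_lo:.3g}, {r_hi:.3g} nS)"
        )
    v_rest = brentq(residual, lo, hi, xtol=1e-10, rtol=8.9e-16)
    op = solve_balance_at_voltage(v_rest, channels, mem, gate_overrides)
    # the root is exact to solver tolerance; pin the residual to zero
    return replace(op, g_light=0.0, feasible=True)


def sweep_light_levels(
    V_grid: Sequence[float],
    channels: Sequence[ChannelModel],
    membrane: MembraneParams | None = None,
    gate_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> list[OperatingPoint]:
    """Operating points along a depolarising grid of steady voltages."""
    return [
        solve_balance_at_voltage(V, channels, membrane, gate_overrides)
        for V in V_grid
    ]


def re_equilibrate(
    reference: OperatingPoint,
    modulated_channels: Sequence[ChannelModel],
    membrane: MembraneParams | None = None,
    bracket: tuple[float, float] = (-90.0, -20.0),
) -> OperatingPoint:
    """New steady state after a channel edit at fixed light conductance.

    The modulation protocol holds leak and light conductances at the
    reference values and lets the voltage settle; pump and exchanger
    currents follow.  Root find on the solved g_light(V) against the
    reference value.
    """
    mem = membrane or reference.membrane

    def residual(V: float) -> float:
        return (
            solve_balance_at_voltage(V, modulated_channels, mem).g_light
            - reference.g_light
        )

    lo, hi = bracket
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise RuntimeError(
            f"re-equilibration bracket [{lo}, {hi}] mV does not enclose a root"
        )
    v_new = brentq(residual, lo, hi, xtol=1e-10, rtol=8.9e-16)
    op = solve_balance_at_voltage(v_new, modulated_channels, mem)
    return replace(op, g_light=reference.g_light)
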