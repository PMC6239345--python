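"""Hodgkin-Huxley gating of the voltage-dependent K+ conductances of
*Drosophila melanogaster* R1-6 photoreceptors.

Three conductances shape the photoreceptor membrane: the fast,
partially inactivating Shaker current (g = gbar * h * m^3), the slower
Shab delayed rectifier with two modes of inactivation
(g = gbar * (xi*h1 + (1-xi)*h2) * m^2) and a very slowly activating,
non-inactivating "Novel" conductance (g = gbar * m) first seen in
double shaker,shab mutants.  All steady-state curves and time
constants are closed-form functions of membrane voltage (mV), with
time constants in ms.

Neuromodulation is represented by editing the gating curves:

* serotonin replaces the Shaker and Shab steady-state curves with their
  depolarised-shifted variants and evaluates the time-constant curves at
  a shifted voltage (Shaker: tau_m at V-31.4 mV, tau_h at V-25 mV;
  Shab: tau_m at V-13.7 mV, tau_h1 at V-10 mV),
* PIP2 depletion (light-dependent modulation) shifts the Shab
  steady-state activation curve 10 mV towards negative potentials,
* Ca2+/calmodulin scales the maximal Shab conductance.

Voltages are mV, conductances nS, times ms throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping

__all__ = [
    "GatingScheme",
    "InactivationComponent",
    "ChannelModel",
    "ModulationState",
    "build_channel_set",
    "gating_value",
    "gating_tau",
    "channel_conductance",
    "accelerate_inactivation",
    "shaker_channel",
    "shab_channel",
    "novel_channel",
    "channel_set_to_config",
    "channel_set_from_config",
    "DEFAULT_G_MAX",
    "E_K",
]

#: K+ reversal potential shared by the three channels and the K+ leak (mV).
E_K = -85.0

#: Maximal conductances (nS) for Shaker, Shab and the Novel conductance.
#: These are not constrained directly by voltage-clamp literature; they are
#: the output of the documented calibration (`experiments.calibrate_gbar`)
#: against four printed facts of the whole-membrane model: the dark resting
#: potential (-68 mV), the dark input resistance (just below 300 MOhm), the
#: dark bandwidth (about 26 Hz) and the ATP consumption at the brightest
#: steady state (5.6e8 ATP/s at -36 mV).
DEFAULT_G_MAX: Mapping[str, float] = {
    "Shaker": 16.0737,
    "Shab": 36.4213,
    "Novel": 2.1249,
}

_EXPM1_GUARD = 1e-9  # mV guard band around removable singularities


def _logistic(x: float) -> float:
    """Numerically stable 1/(1+exp(-x))."""
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _ratio_expm1(x: float, s: float) -> float:
    """x / (exp(x/s) - 1) with its analytic limit s at x -> 0."""
    if abs(x) < _EXPM1_GUARD:
        return s
    return x / math.expm1(x / s)


@dataclass(frozen=True)
class GatingScheme:
    """One first-order gating variable.

    ``steady_state`` maps voltage (mV) to the equilibrium open
    probability in (0, 1); ``time_constant`` maps voltage to the
    relaxation time (ms); ``steady_state_slope`` is the closed-form
    voltage derivative of ``steady_state`` (1/mV).
    """

    steady_state: Callable[[float], float]
    time_constant: Callable[[float], float]
    steady_state_slope: Callable[[float], float]

    def shifted_steady_state(self, dv: float) -> "GatingScheme":
        """Evaluate the steady-state curve at ``V + dv`` (``dv`` > 0 moves
        the curve towards more negative potentials); time constant kept."""
        base_ss, base_slope = self.steady_state, self.steady_state_slope
        return replace(
            self,
            steady_state=lambda V: base_ss(V + dv),
            steady_state_slope=lambda V: base_slope(V + dv),
        )

    def shifted_time_constant(self, dv: float) -> "GatingScheme":
        """Evaluate the time-constant curve at ``V - dv`` (``dv`` > 0 moves
        the curve towards more positive potentials); steady state kept."""
        base_tau = self.time_constant
        return replace(self, time_constant=lambda V: base_tau(V - dv))


def _power_sigmoid_scheme(
    vhalf: float, slope: float, root: int, tau: Callable[[float], float]
) -> GatingScheme:
    """Activation scheme m = [logistic((V - vhalf)/slope)]^(1/root).

    The conductance uses m^root, so the underlying sigmoid is the open
    fraction of the activation gate stack.
    """

    def steady(V: float) -> float:
        return _logistic((V - vhalf) / slope) ** (1.0 / root)

    def dsteady(V: float) -> float:
        s = _logistic((V - vhalf) / slope)
        # d/dV s^(1/root) = (1/root) s^(1/root - 1) s (1-s) / slope
        return (1.0 / root) * s ** (1.0 / root) * (1.0 - s) / slope

    return GatingScheme(steady, tau, dsteady)


def _falling_sigmoid_sum_scheme(
    terms: tuple[tuple[float, float, float], ...], tau: Callable[[float], float]
) -> GatingScheme:
    """Inactivation scheme sum_k a_k / (1 + exp((v_k + V)/s_k))."""

    def steady(V: float) -> float:
        return sum(a * _logistic(-(v + V) / s) for a, v, s in terms)

    def dsteady(V: float) -> float:
        out = 0.0
        for a, v, s in terms:
            l = _logistic(-(v + V) / s)
            out -= a * l * (1.0 - l) / s
        return out

    return GatingScheme(steady, tau, dsteady)


# --- Shaker -----------------------------------------------------------------

def _shaker_tau_m(V: float) -> float:
    return 1.0 / (
        0.00817 * math.exp((-V + 1.62) / 24.7)
        + 0.0581 * _ratio_expm1(-V - 59.6, 4.50)
    )


def _shaker_tau_h1(V: float) -> float:
    return 1.0 / (
        0.230 * math.exp((-V - 193.0) / 31.3)
        + 0.0437 * _ratio_expm1(-V + 13.5, 11.1)
    )


def _shaker_activation(serotonin: bool) -> GatingScheme:
    scheme = _power_sigmoid_scheme(
        vhalf=11.7 if serotonin else -23.7,
        slope=12.9 if serotonin else 12.8,
        root=3,
        tau=_shaker_tau_m,
    )
    if serotonin:
        scheme = scheme.shifted_time_constant(31.4)
    return scheme


def _shaker_inactivation(serotonin: bool) -> GatingScheme:
    terms = (
        ((0.8, 27.1, 4.3), (0.2, 52.9, 10.5))
        if serotonin
        else ((0.8, 55.3, 3.9), (0.2, 74.8, 10.7))
    )
    scheme = _falling_sigmoid_sum_scheme(terms, _shaker_tau_h1)
    if serotonin:
        scheme = scheme.shifted_time_constant(25.0)
    return scheme


# --- Shab -------------------------------------------------------------------

def _shab_tau_m(V: float) -> float:
    return 1.0 / (
        0.116 * math.exp((-V - 25.7) / 32.2)
        + 0.00659 * _ratio_expm1(-V - 23.8, 1.35)
    )


def _shab_tau_h1(V: float) -> float:
    return 335.0 * math.exp(V / 71.3) + 73.2


def _shab_tau_h2(V: float) -> float:
    return 3000.0


def _shab_activation(serotonin: bool, pip2_depleted: bool) -> GatingScheme:
    scheme = _power_sigmoid_scheme(
        vhalf=12.7 if serotonin else -1.0,
        slope=9.5 if serotonin else 9.1,
        root=2,
        tau=_shab_tau_m,
    )
    if serotonin:
        scheme = scheme.shifted_time_constant(13.7)
    if pip2_depleted:
        # light-dependent modulation: 10 mV leftward shift of the
        # steady-state activation curve only
        scheme = scheme.shifted_steady_state(10.0)
    return scheme


def _shab_inactivation(serotonin: bool, tau: Callable[[float], float],
                       shift_tau: bool) -> GatingScheme:
    terms = ((1.0, 15.7, 7.2),) if serotonin else ((1.0, 25.7, 6.4),)
    scheme = _falling_sigmoid_sum_scheme(terms, tau)
    if serotonin and shift_tau:
        scheme = scheme.shifted_time_constant(10.0)
    return scheme


# --- Novel ------------------------------------------------------------------

def _novel_tau_m(V: float) -> float:
    return 13.0 + 165.0 * math.exp(-2.0 * ((V + 19.4) / 30.0) ** 2)


def _novel_activation() -> GatingScheme:
    return _power_sigmoid_scheme(vhalf=-1.0, slope=9.1, root=2,
                                 tau=_novel_tau_m)


# --- channel assembly -------------------------------------------------------

@dataclass(frozen=True)
class InactivationComponent:
    """One additive slice of a channel's conductance.

    ``fraction`` is the weight of this slice (fractions of one channel sum
    to one).  ``scheme`` is the gating of its inactivation variable, or
    ``None`` for a slice that does not inactivate (h identically 1).
    ``gate`` names the state variable ("h1", "h2", or "" when absent).
    """

    fraction: float
    scheme: GatingScheme | None
    gate: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"component fraction {self.fraction} outside [0, 1]")


@dataclass(frozen=True)
class ChannelModel:
    """A voltage-dependent K+ conductance g = gbar * h * m^gamma."""

    name: str
    g_max: float
    activation: GatingScheme
    activation_exponent: int
    components: tuple[InactivationComponent, ...]
    reversal: float = E_K

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError(f"{self.name}: g_max must be non-negative")
        if self.activation_exponent not in (1, 2, 3):
            raise ValueError(f"{self.name}: unsupported activation exponent")
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: component fractions sum to {total}")

    # -- steady-state evaluation --------------------------------------------

    def gate_names(self) -> tuple[str, ...]:
        names = ["m"]
        names += [c.gate for c in self.components if c.scheme is not None]
        return tuple(names)

    def steady_gates(self, V: float) -> dict[str, float]:
        gates = {"m": self.activation.steady_state(V)}
        for c in self.components:
            if c.scheme is not None:
                gates[c.gate] = c.scheme.steady_state(V)
        return gates

    def conductance(self, gates: Mapping[str, float]) -> float:
        """Conductance (nS) at the given gate values."""
        return channel_conductance(self, gates)

    def steady_conductance(self, V: float) -> float:
        return self.conductance(self.steady_gates(V))


@dataclass(frozen=True)
class ModulationState:
    """Which neuromodulatory edits are applied to the channel set."""

    serotonin: bool = False
    pip2_depleted: bool = False
    shab_scale: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.serotonin, bool) or not isinstance(
            self.pip2_depleted, bool
        ):
            raise ValueError("modulation flags must be booleans")
        if not self.shab_scale > 0:
            raise ValueError("shab_scale must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            not self.serotonin
            and not self.pip2_depleted
            and self.shab_scale == 1.0
        )


def shaker_channel(g_max: float, modulation: ModulationState | None = None) -> ChannelModel:
    mod = modulation or ModulationState()
    xi = 0.13  # fraction of Shaker that fails to inactivate
    return ChannelModel(
        name="Shaker",
        g_max=g_max,
        activation=_shaker_activation(mod.serotonin),
        activation_exponent=3,
        components=(
            InactivationComponent(xi, None),
            InactivationComponent(1.0 - xi, _shaker_inactivation(mod.serotonin), "h1"),
        ),
    )


def shab_channel(g_max: float, modulation: ModulationState | None = None) -> ChannelModel:
    mod = modulation or ModulationState()
    xi = 0.7  # weight of the fast mode of inactivation
    return ChannelModel(
        name="Shab",
        g_max=g_max * mod.shab_scale,
        activation=_shab_activation(mod.serotonin, mod.pip2_depleted),
        activation_exponent=2,
        components=(
            InactivationComponent(
                xi, _shab_inactivation(mod.serotonin, _shab_tau_h1, True), "h1"
            ),
            InactivationComponent(
                1.0 - xi, _shab_inactivation(mod.serotonin, _shab_tau_h2, False), "h2"
            ),
        ),
    )


def novel_channel(g_max: float, modulation: ModulationState | None = None) -> ChannelModel:
    return ChannelModel(
        name="Novel",
        g_max=g_max,
        activation=_novel_activation(),
        activation_exponent=1,
        components=(InactivationComponent(1.0, None),),
    )


_BUILDERS = {"Shaker": shaker_channel, "Shab": shab_channel, "Novel": novel_channel}


def build_channel_set(
    modulation: ModulationState | None = None,
    g_max: Mapping[str, float] | None = None,
) -> tuple[ChannelModel, ...]:
    """Build the (Shaker, Shab, Novel) channel set under a modulation state.

    ``g_max`` maps channel names to maximal conductances in nS and
    defaults to the calibrated :data:`DEFAULT_G_MAX`.
    """
    mod = modulation or ModulationState()
    gbar = dict(DEFAULT_G_MAX)
    if g_max is not None:
        unknown = set(g_max) - set(gbar)
        if unknown:
            raise ValueError(f"unknown channel names: {sorted(unknown)}")
        gbar.update(g_max)
    for name, g in gbar.items():
        if g < 0:
            raise ValueError(f"negative maximal conductance for {name}")
    return tuple(_BUILDERS[name](gbar[name], mod) for name in ("Shaker", "Shab", "Novel"))


def gating_value(scheme: GatingScheme, V: float) -> float:
    """Steady-state value of a gating variable at voltage V (mV)."""
    return scheme.steady_state(V)


def gating_tau(scheme: GatingScheme, V: float) -> float:
    """Relaxation time constant of a gating variable at voltage V (ms)."""
    return scheme.time_constant(V)


def channel_conductance(channel: ChannelModel, gates: Mapping[str, float]) -> float:
    """Conductance (nS) of ``channel`` at explicit gate values.

    ``gates`` maps gate names ("m", "h1", "h2") to values in [0, 1];
    the composite inactivation is the fraction-weighted sum over
    components, so g = sum_k gbar * fraction_k * h_k * m^gamma.
    """
    for name, x in gates.items():
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"gate {name}={x} outside [0, 1]")
    m_pow = gates["m"] ** channel.activation_exponent
    g = 0.0
    for c in channel.components:
        h = 1.0 if c.scheme is None else gates[c.gate]
        g += channel.g_max * c.fraction * h * m_pow
    return g


def accelerate_inactivation(channels: tuple[ChannelModel, ...]) -> tuple[ChannelModel, ...]:
    """Replace every inactivation time constant by the activation time
    constant of the same channel, leaving all steady-state curves intact.

    This converts the slow positive feedback of inactivation into a
    feedback as fast as activation, the comparison used to show that slow
    inactivation saves energy.
    """
    out = []
    for ch in channels:
        comps = tuple(
            c if c.scheme is None
            else replace(c, scheme=replace(c.scheme, time_constant=ch.activation.time_constant))
            for c in ch.components
        )
        out.append(replace(ch, components=comps))
    return tuple(out)


# --- config round-trip ------------------------------------------------------

def channel_set_to_config(
    channels: tuple[ChannelModel, ...], modulation: ModulationState
) -> dict:
    """Serializable description of a channel set (inverse of
    :func:`channel_set_from_config`).

    The gating formulas are code, identified by channel name; the config
    carries the free parameters: maximal conductances, exponents and
    component fractions, plus the modulation flags.
    """
    base_shab = next(ch for ch in channels if ch.name == "Shab").g_max / modulation.shab_scale
    cfg_channels = {}
    for ch in channels:
        cfg_channels[ch.name] = {
            "g_max_nS": base_shab if ch.name == "Shab" else ch.g_max,
            "gamma": ch.activation_exponent,
            "components": [
                {"fraction": c.fraction, "inactivating": c.scheme is not None}
                for c in ch.components
            ],
        }
    return {
        "channels": cfg_channels,
        "modulation": {
            "serotonin": modulation.serotonin,
            "pip2_depleted": modulation.pip2_depleted,
            "shab_scale": modulation.shab_scale,
        },
    }


def channel_set_from_config(cfg: dict) -> tuple[tuple[ChannelModel, ...], ModulationState]:
    mod_cfg = cfg.get("modulation", {})
    modulation = ModulationState(
        serotonin=bool(mod_cfg.get("serotonin", False)),
        pip2_depleted=bool(mod_cfg.get("pip2_depleted", False)),
        shab_scale=float(mod_cfg.get("shab_scale", 1.0)),
    )
    g_max = {name: float(c["g_max_nS"]) for name, c in cfg["channels"].items()}
    return build_channel_set(modulation, g_max), modulation
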