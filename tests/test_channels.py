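"""Gating curves, conductance composition and neuromodulatory edits."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from flymembrane import (
    ModulationState,
    build_channel_set,
    channel_conductance,
    gating_tau,
    gating_value,
)
from flymembrane.channels import (
    _novel_tau_m,
    _shab_tau_h1,
    _shab_tau_m,
    _shaker_tau_h1,
    _shaker_tau_m,
    accelerate_inactivation,
    channel_set_from_config,
    channel_set_to_config,
)

GBAR = {"Shaker": 10.0, "Shab": 10.0, "Novel": 10.0}

voltages = st.floats(min_value=-120.0, max_value=60.0)


def _set(mod=None):
    return build_channel_set(mod or ModulationState(), GBAR)


class TestSteadyStateCurves:
    def test_activation_midpoints(self):
        """Half-activation of the underlying sigmoids sits at the printed
        midpoint voltages, before the fractional exponent."""
        shaker, shab, novel = _set()
        assert shaker.activation.steady_state(-23.7) == pytest.approx(0.5 ** (1 / 3), rel=1e-12)
        assert shab.activation.steady_state(-1.0) == pytest.approx(0.5 ** (1 / 2), rel=1e-12)
        assert novel.activation.steady_state(-1.0) == pytest.approx(0.5 ** (1 / 2), rel=1e-12)
        assert shab.components[0].scheme.steady_state(-25.7) == pytest.approx(0.5, rel=1e-12)

    def test_serotonin_midpoints(self):
        shaker, shab, _ = _set(ModulationState(serotonin=True))
        assert shaker.activation.steady_state(11.7) == pytest.approx(0.5 ** (1 / 3), rel=1e-12)
        assert shab.activation.steady_state(12.7) == pytest.approx(0.5 ** (1 / 2), rel=1e-12)

    def test_pip2_shifts_shab_activation_left(self):
        _, shab, novel = _set(ModulationState(pip2_depleted=True))
        assert shab.activation.steady_state(-11.0) == pytest.approx(0.5 ** (1 / 2), rel=1e-12)
        # Novel shares the unmodulated curve shape and is untouched
        assert novel.activation.steady_state(-1.0) == pytest.approx(0.5 ** (1 / 2), rel=1e-12)

    def test_shab_scale_halves_gmax_only(self):
        base_shab = _set()[1]
        mod_shab = _set(ModulationState(shab_scale=0.5))[1]
        assert mod_shab.g_max == pytest.approx(0.5 * base_shab.g_max)
        for v in (-80.0, -50.0, -20.0):
            assert mod_shab.activation.steady_state(v) == pytest.approx(
                base_shab.activation.steady_state(v), rel=1e-12
            )

    @settings(max_examples=200, deadline=None)
    @given(v=voltages)
    def test_range_and_positivity(self, v):
        """Steady states live in (0, 1); time constants are positive."""
        for ch in _set() + _set(ModulationState(serotonin=True)):
            m = gating_value(ch.activation, v)
            assert 0.0 < m < 1.0
            assert gating_tau(ch.activation, v) > 0.0
            for comp in ch.components:
                if comp.scheme is not None:
                    h = gating_value(comp.scheme, v)
                    assert 0.0 < h < 1.0
                    assert gating_tau(comp.scheme, v) > 0.0

    @settings(max_examples=100, deadline=None)
    @given(v=st.floats(min_value=-100.0, max_value=40.0))
    def test_monotonicity(self, v):
        """Activation curves rise with voltage, inactivation curves fall."""
        dv = 0.5
        for ch in _set():
            act = ch.activation.steady_state
            assert act(v + dv) > act(v)
            for comp in ch.components:
                if comp.scheme is not None:
                    assert comp.scheme.steady_state(v + dv) < comp.scheme.steady_state(v)

    @settings(max_examples=200, deadline=None)
    @given(v=voltages)
    def test_slope_matches_finite_difference(self, v):
        """Closed-form steady-state derivatives agree with a central
        difference of step 1e-3 mV to 1e-5 relative."""
        h = 1e-3
        for ch in _set():
            schemes = [ch.activation] + [
                c.scheme for c in ch.components if c.scheme is not None
            ]
            for scheme in schemes:
                fd = (scheme.steady_state(v + h) - scheme.steady_state(v - h)) / (2 * h)
                slope = scheme.steady_state_slope(v)
                assert slope == pytest.approx(fd, rel=1e-5, abs=1e-12)


class TestTimeConstants:
    def test_printed_values(self):
        assert _shab_tau_h1(0.0) == pytest.approx(408.2)
        assert _novel_tau_m(-19.4) == pytest.approx(178.0)
        # Shab slow mode is voltage independent
        for v in (-90.0, -50.0, 0.0):
            assert gating_tau(_set()[1].components[1].scheme, v) == 3000.0

    @pytest.mark.parametrize(
        "tau, v0",
        [
            (_shaker_tau_m, -59.6),
            (_shaker_tau_h1, 13.5),
            (_shab_tau_m, -23.8),
        ],
    )
    def test_removable_singularities(self, tau, v0):
        """The 0/0 points of the rate denominators are filled by the
        analytic limit and the curves are continuous there."""
        ref = tau(v0)
        assert math.isfinite(ref) and ref > 0
        for eps in (1e-6, -1e-6):
            assert abs(tau(v0 + eps) - ref) < 1e-6 * ref


class TestConductanceComposition:
    def test_shaker_failing_fraction(self):
        shaker = _set()[0]
        g = channel_conductance(shaker, {"m": 1.0, "h1": 0.0})
        assert g == pytest.approx(0.13 * shaker.g_max, rel=1e-12)

    def test_zero_activation_zero_conductance(self):
        for ch in _set():
            gates = {g: 0.0 if g == "m" else 1.0 for g in ch.gate_names()}
            assert channel_conductance(ch, gates) == 0.0

    def test_full_gates_give_gmax(self):
        shab = _set()[1]
        g = channel_conductance(shab, {"m": 1.0, "h1": 1.0, "h2": 1.0})
        assert g == pytest.approx(shab.g_max, rel=1e-12)

    @settings(max_examples=250, deadline=None)
    @given(
        v=voltages,
        m=st.floats(min_value=0.0, max_value=1.0),
        h=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_component_split_conserves_conductance(self, v, m, h):
        """Summing over split components equals evaluating the composite
        inactivation variable directly (Shaker: xi + (1-xi) h; Shab with
        equal mode values: h itself)."""
        shaker, shab, _ = _set()
        g_split = channel_conductance(shaker, {"m": m, "h1": h})
        composite = 0.13 + 0.87 * h
        assert g_split == pytest.approx(shaker.g_max * composite * m**3, rel=1e-12, abs=1e-300)
        g_split = channel_conductance(shab, {"m": m, "h1": h, "h2": h})
        assert g_split == pytest.approx(shab.g_max * h * m**2, rel=1e-12, abs=1e-300)

    def test_gate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            channel_conductance(_set()[0], {"m": 1.2, "h1": 0.5})

    def test_negative_gmax_rejected(self):
        with pytest.raises(ValueError):
            build_channel_set(ModulationState(), {"Shaker": -1.0})

    def test_bad_modulation_rejected(self):
        with pytest.raises(ValueError):
            ModulationState(shab_scale=0.0)
        with pytest.raises(ValueError):
            ModulationState(serotonin="yes")


class TestModulationComposition:
    def test_serotonin_and_pip2_compose(self):
        """With both edits on, the Shab activation midpoint is the serotonin
        midpoint shifted 10 mV leftward."""
        _, shab, _ = _set(ModulationState(serotonin=True, pip2_depleted=True))
        assert shab.activation.steady_state(2.7) == pytest.approx(0.5 ** (1 / 2), rel=1e-12)

    def test_serotonin_tau_shift(self):
        base = _set()[0]
        sero = _set(ModulationState(serotonin=True))[0]
        for v in (-70.0, -40.0, -10.0):
            assert sero.activation.time_constant(v) == pytest.approx(
                base.activation.time_constant(v - 31.4), rel=1e-12
            )
            assert sero.components[1].scheme.time_constant(v) == pytest.approx(
                base.components[1].scheme.time_constant(v - 25.0), rel=1e-12
            )

    def test_accelerated_inactivation_uses_activation_tau(self):
        fast = accelerate_inactivation(_set())
        for ch in fast:
            for comp in ch.components:
                if comp.scheme is not None:
                    for v in (-70.0, -45.0):
                        assert comp.scheme.time_constant(v) == pytest.approx(
                            ch.activation.time_constant(v), rel=1e-12
                        )
                    # steady state untouched
                    assert 0.0 < comp.scheme.steady_state(v) < 1.0


def test_config_round_trip():
    mod = ModulationState(serotonin=True, shab_scale=0.5)
    channels = build_channel_set(mod, GBAR)
    cfg = channel_set_to_config(channels, mod)
    rebuilt, mod2 = channel_set_from_config(cfg)
    assert mod2 == mod
    for a, b in zip(channels, rebuilt):
        assert a.name == b.name
        assert a.g_max == pytest.approx(b.g_max, rel=1e-12)
        for v in (-80.0, -50.0, -20.0):
            assert a.activation.steady_state(v) == pytest.approx(
                b.activation.steady_state(v), rel=1e-12
            )
    assert channel_set_to_config(rebuilt, mod2) == cfg
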