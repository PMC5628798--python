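"""Model-core unit and property tests: response functions, temperature
factors, drift wiring and the two algebraically equivalent firing-response
forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coolmass import _kernels
from coolmass.model_core import (ModelParameters, TemperatureSpec,
                                 POPULATIONS, drift, eeg_output,
                                 effective_gain, firing_response,
                                 firing_response_equivalent, psp_kernel,
                                 temperature_factor)


class TestTemperatureFactor:
    @pytest.mark.parametrize("q10, T, T0, expected", [
        (1.8, 31.0, 31.0, 1.0),                  # zero exponent
        (1.0, 15.0, 31.0, 1.0),                  # unit base
        (1.8, 15.0, 31.0, 0.3904487095766203),   # 1.8 ** -1.6
        (2.0, 41.0, 31.0, 2.0),                  # one decade warmer
    ])
    def test_values(self, q10, T, T0, expected):
        assert temperature_factor(q10, T, T0) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_rejects_nonpositive_q10(self):
        with pytest.raises(ValueError):
            temperature_factor(0.0, 15.0, 31.0)
        with pytest.raises(ValueError):
            temperature_factor(-1.5, 15.0, 31.0)


class TestFiringResponse:
    def test_half_maximum_at_threshold(self, params):
        assert firing_response(params.v_th, params) == pytest.approx(
            params.e0, rel=1e-12)

    def test_saturation_limits(self, params):
        assert firing_response(1e6, params) == pytest.approx(2 * params.e0)
        assert firing_response(-1e6, params) == pytest.approx(0.0, abs=1e-12)
        # extreme inputs saturate instead of overflowing
        assert np.isfinite(firing_response(1e300, params))

    def test_resting_rate(self, params):
        # direct evaluation of 5 / (1 + e^3.36) at v = 0
        assert firing_response(0.0, params) == pytest.approx(
            0.16784611640741262, rel=1e-12)

    def test_cooling_amplifies_membrane_potential(self, params,
                                                  cooled_syn_int):
        # the reciprocal intrinsic factor raises the rate at positive v
        warm = firing_response(3.0, params)
        cold = firing_response(3.0, params, cooled_syn_int)
        assert cold > warm

    @given(v=st.floats(-50, 50), q_int=st.floats(1.0, 2.0),
           T=st.floats(15.0, 31.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equivalent_form_identity(self, v, q_int, T):
        """The threshold-scaled form equals the potential-scaled form."""
        params = ModelParameters()
        temp = TemperatureSpec(T=T, T0=31.0, variant="SYN_INT",
                               q_syn=1.8, q_int=q_int)
        a = firing_response(v, params, temp)
        b = firing_response_equivalent(v, params, temp)
        assert abs(a - b) < 1e-12 * (2 * params.e0)

    @given(v=st.floats(-100, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, v):
        params = ModelParameters()
        r = firing_response(v, params)
        assert 0.0 <= r <= 2 * params.e0
        assert firing_response(v + 1.0, params) >= r

    @given(v=st.floats(-20, 20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing_off_saturation(self, v):
        params = ModelParameters()
        assert firing_response(v + 0.5, params) > firing_response(v, params)


class TestEffectiveGain:
    def test_ntd_has_no_temperature_dependence(self, params):
        temp = TemperatureSpec(T=15.0, variant="NTD", q_syn=1.8)
        for pop in POPULATIONS:
            assert effective_gain(pop, params, temp) == params.gain(pop)

    def test_syn_int_attenuates_all_gains(self, params, cooled_syn_int):
        factor = 1.8 ** -1.6
        assert effective_gain("SIN", params, cooled_syn_int) == \
            pytest.approx(28.66 * factor, rel=1e-12)
        assert effective_gain("PY", params, cooled_syn_int) == \
            pytest.approx(5.0 * factor, rel=1e-12)

    def test_exc_sin_fin_split(self, params):
        temp = TemperatureSpec(T=15.0, variant="EXC_SIN_FIN",
                               q_syn_ex=1.5, q_syn_sin=1.2, q_syn_fin=1.0)
        assert effective_gain("FIN", params, temp) == pytest.approx(87.73)
        assert effective_gain("SIN", params, temp) == pytest.approx(
            28.66 * 1.2 ** -1.6, rel=1e-12)
        assert effective_gain("EX", params, temp) == pytest.approx(
            5.0 * 1.5 ** -1.6, rel=1e-12)

    def test_exc_inh_groups_glutamate_and_gaba(self, params):
        temp = TemperatureSpec(T=15.0, variant="EXC_INH",
                               q_syn_exc=1.4, q_syn_inh=1.1)
        assert effective_gain("PY", params, temp) == \
            effective_gain("EX", params, temp) / params.G_EX * params.G_PY
        assert effective_gain("SIN", params, temp) == pytest.approx(
            28.66 * 1.1 ** -1.6, rel=1e-12)

    def test_unknown_population(self, params, cooled_syn_int):
        with pytest.raises(KeyError):
            effective_gain("XX", params, cooled_syn_int)


class TestPspKernel:
    def test_zero_at_origin_and_peak(self):
        assert psp_kernel(0.0, 5.0, 100.0) == 0.0
        # calculus maximum at t = 1/g with value G/e
        assert psp_kernel(0.01, 5.0, 100.0) == pytest.approx(
            1.8393972058572117, rel=1e-12)

    def test_linearity_in_temperature_factor(self):
        t = np.linspace(0, 0.1, 50)
        full = psp_kernel(t, 5.0, 100.0, 1.0)
        half = psp_kernel(t, 5.0, 100.0, 0.5)
        assert np.allclose(half, 0.5 * full, rtol=1e-14)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            psp_kernel(-0.01, 5.0, 100.0)


class TestDrift:
    def test_at_origin(self, params):
        """Hand-computed drift at the zero state with zero input."""
        temp = TemperatureSpec()
        out = drift(np.zeros(10), 0.0, params, temp)
        s0 = firing_response(0.0, params)
        assert np.allclose(out[:5], 0.0)
        expected = np.array([
            params.G_PY * params.g_PY * s0,
            params.G_EX * params.g_EX * params.C_EX_PY * s0,
            params.G_SIN * params.g_SIN * params.C_SIN_PY * s0,
            params.G_FIN * params.g_FIN * params.C_FIN_PY * s0,
            params.G_SIN * params.g_SIN * s0,
        ])
        assert np.allclose(out[5:], expected, rtol=1e-12)

    def test_ntd_equals_untempered_drift(self, params, rng):
        """NTD at any temperature is exactly the temperature-free model."""
        x = rng.normal(0, 5, 10)
        ntd_cold = TemperatureSpec(T=15.0, variant="NTD", q_syn=1.9,
                                   q_int=1.7)
        base = TemperatureSpec()
        assert np.array_equal(drift(x, 90.0, params, ntd_cold),
                              drift(x, 90.0, params, base))

    def test_any_variant_at_baseline_temperature_is_ntd(self, params, rng):
        x = rng.normal(0, 5, 10)
        for variant in ("SYN", "INT", "SYN_INT", "EXC_INH", "EXC_SIN_FIN"):
            temp = TemperatureSpec(T=31.0, T0=31.0, variant=variant,
                                   q_syn=1.8, q_int=1.6, q_syn_exc=1.4,
                                   q_syn_inh=1.2, q_syn_ex=1.3,
                                   q_syn_sin=1.2, q_syn_fin=1.5)
            assert np.allclose(drift(x, 90.0, params, temp),
                               drift(x, 90.0, params, TemperatureSpec()),
                               rtol=1e-14)

    def test_compiled_kernel_matches_reference_drift(self, params,
                                                     cooled_syn_int, rng):
        """The numba fast path reproduces the pure-Python drift exactly."""
        coeffs = _kernels.pack_coeffs(params, cooled_syn_int)
        for _ in range(20):
            x = rng.normal(0, 8, 10)
            p = rng.uniform(0, 200)
            a = drift(x, p, params, cooled_syn_int)
            b = _kernels.drift10(x, p, *coeffs)
            assert np.allclose(a, b, rtol=1e-13, atol=1e-10)

    def test_dimension_check(self, params):
        with pytest.raises(ValueError):
            drift(np.zeros(9), 90.0, params, TemperatureSpec())


class TestEegOutput:
    def test_linear_combination(self):
        x = np.zeros(10)
        assert eeg_output(x) == 0.0
        x[1], x[2], x[3] = 2.0, 0.5, 0.3
        assert eeg_output(x) == pytest.approx(1.2)


class TestSerialization:
    def test_parameters_round_trip(self, params):
        assert ModelParameters.from_dict(params.to_dict()) == params

    def test_temperature_round_trip(self, cooled_syn_int):
        d = cooled_syn_int.to_dict()
        assert TemperatureSpec.from_dict(d) == cooled_syn_int

    def test_unknown_keys_rejected(self):
        with pytest.raises(KeyError):
            ModelParameters.from_dict({"G_SIN": 28.0, "bogus": 1.0})

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(G_FIN=-1.0)
        with pytest.raises(ValueError):
            TemperatureSpec(variant="SYNERGY")
        with pytest.raises(ValueError):
            TemperatureSpec(q_int=0.0)

    def test_derived_connectivity(self, params):
        assert params.C_EX_PY == 0.8 * params.C_PY_EX
        assert params.C_PY_SIN == 0.25 * params.C_PY_EX
        assert params.C_PY_FIN == 0.3 * params.C_PY_EX
        assert params.C_SIN_PY == 0.25 * params.C_PY_EX
        assert params.C_FIN_PY == 0.8 * params.C_PY_EX
        assert params.C_SIN_FIN == 0.1 * params.C_PY_EX
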