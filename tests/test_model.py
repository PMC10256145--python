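"""Cascade-model unit and property tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contrastnorm.model import (
    ModelParams,
    SignalTrace,
    band_pass,
    dynamic_nl,
    high_pass,
    low_pass,
    make_pulse,
    run_cascade,
    static_nl,
    steady_state_voltage,
)

DT = 0.001


def trace(values, dt=DT):
    return SignalTrace(values=np.asarray(values, dtype=float), dt=dt)


class TestLowPass:
    def test_zero_input_stays_zero(self):
        out = low_pass(trace(np.zeros(100)), tau=0.2)
        assert np.all(out.values == 0)

    def test_step_response_closed_form(self):
        tau = 0.2
        out = low_pass(trace(np.ones(5000)), tau=tau)
        # value at t = tau is 1 - 1/e; discretization shifts by at most dt/tau
        idx = round(tau / DT)
        assert out.values[idx] == pytest.approx(1 - np.exp(-1), abs=3 * DT / tau)
        assert out.values[-1] == pytest.approx(1.0, abs=1e-9)  # DC gain 1

    def test_invalid_tau_raises(self):
        with pytest.raises(ValueError):
            low_pass(trace(np.ones(10)), tau=0.0)

    def test_linearity(self, rng):
        x = trace(rng.standard_normal(400))
        z = trace(rng.standard_normal(400))
        a, b = 2.5, -1.3
        combo = low_pass(trace(a * x.values + b * z.values), 0.2).values
        sep = a * low_pass(x, 0.2).values + b * low_pass(z, 0.2).values
        assert np.allclose(combo, sep, atol=1e-9)


class TestBandPass:
    def test_kills_dc(self):
        out = band_pass(trace(np.ones(20000)), 0.2, 0.3)
        assert abs(out.values[-1]) < 1e-9

    def test_zero_input(self):
        assert np.all(band_pass(trace(np.zeros(50)), 0.2, 0.3).values == 0)

    def test_step_response_matches_convolution_oracle(self):
        """Discrete band-pass output equals direct convolution with the
        discrete impulse response (delta input through the same filters)."""
        n = 4000
        step = np.ones(n)
        out = band_pass(trace(step), 0.2, 0.3).values
        delta = np.zeros(n)
        delta[0] = 1.0
        impulse = band_pass(trace(delta), 0.2, 0.3).values
        oracle = np.convolve(step, impulse)[:n]
        assert np.allclose(out, oracle, atol=1e-6)
        assert np.argmax(out) == np.argmax(oracle)

    def test_linearity(self, rng):
        x = trace(rng.standard_normal(300))
        z = trace(rng.standard_normal(300))
        combo = band_pass(trace(0.7 * x.values + 0.1 * z.values), 0.2, 0.3).values
        sep = 0.7 * band_pass(x, 0.2, 0.3).values + 0.1 * band_pass(z, 0.2, 0.3).values
        assert np.allclose(combo, sep, atol=1e-9)


class TestStaticNL:
    def test_half_saturation_point(self):
        for k in (0.1, 0.2, 1.0, 7.0):
            out = static_nl(trace([k]), k=k)
            assert out.values[0] == pytest.approx(0.5)

    def test_zero_maps_to_zero_and_negative_rectified(self):
        out = static_nl(trace([0.0, -3.0]), k=0.5)
        assert np.all(out.values == 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.01, 100),
        k=st.floats(0.01, 10),
        x=st.floats(-5, 5),
    )
    def test_joint_scaling_invariance(self, a, k, x):
        """y(a*x, a*k) == y(x, k): the divisive form has no intrinsic scale."""
        y1 = static_nl(trace([x]), k=k).values[0]
        y2 = static_nl(trace([a * x]), k=a * k).values[0]
        assert y2 == pytest.approx(y1, abs=1e-12)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            static_nl(trace([1.0]), k=0.0)


class TestDynamicNL:
    def test_rest_stays_at_rest(self):
        out = dynamic_nl(trace(np.zeros(100)), ModelParams(k=1.0, nl_mode="dynamic"))
        assert np.all(out.values == 0)

    def test_first_iterate_hand_computed(self):
        # y(dt) = (1*1 + 0*100) / (1 + 1 + 100) = 1/102
        out = dynamic_nl(trace([1.0, 1.0, 1.0]), ModelParams(k=1.0, nl_mode="dynamic"))
        assert out.values[1] == pytest.approx(1.0 / 102.0, abs=1e-15)

    def test_constant_drive_converges_to_steady_state(self):
        params = ModelParams(k=1.0, nl_mode="dynamic")
        out = dynamic_nl(trace(np.ones(5000)), params)
        assert out.values[-1] == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize(
        "g,k",
        list(itertools.product([0.1, 0.5, 1.0, 2.0, 5.0], [0.1, 0.2, 1.0, 3.0])),
    )
    def test_steady_state_matches_closed_form_on_grid(self, g, k):
        params = ModelParams(k=k, nl_mode="dynamic")
        # run long enough for the slowest (small g + k) membrane to relax
        n = int(40 * params.c_over_dt / (g + k)) + 10
        out = dynamic_nl(trace(np.full(n, g)), params)
        assert out.values[-1] == pytest.approx(
            steady_state_voltage(g, k), abs=1e-9
        )

    def test_bounded_by_reversal_potential(self, rng):
        x = trace(np.abs(rng.standard_normal(2000)) * 10)
        out = dynamic_nl(x, ModelParams(k=0.2, nl_mode="dynamic"))
        assert np.all(out.values >= 0) and np.all(out.values <= 1.0)

    def test_relaxation_faster_for_larger_k(self):
        """The inhibitory conductance shortens the membrane time constant:
        time to 63% of steady state decreases with k."""
        t63 = {}
        for k in (0.2, 1.0):
            params = ModelParams(k=k, nl_mode="dynamic")
            out = dynamic_nl(trace(np.ones(5000)), params).values
            target = 0.632 * steady_state_voltage(1.0, k)
            t63[k] = np.argmax(out >= target)
        assert t63[1.0] < t63[0.2]

    def test_degenerates_to_static_when_capacitance_vanishes(self, rng):
        x = np.abs(rng.standard_normal(200))
        params = ModelParams(k=0.7, nl_mode="dynamic", c_over_dt=0.0)
        dyn = dynamic_nl(trace(x), params).values
        stat = static_nl(trace(x), k=0.7).values
        # one-step lag
        assert np.allclose(dyn[1:], stat[:-1], atol=1e-12)

    def test_all_zero_denominator_raises(self):
        params = ModelParams(k=0.0, nl_mode="dynamic", c_over_dt=0.0)
        with pytest.raises(ValueError):
            dynamic_nl(trace([0.0, 0.0]), params)


class TestCascade:
    def test_zero_in_zero_out(self):
        for mode in ("static", "dynamic"):
            out = run_cascade(trace(np.zeros(100)), ModelParams(nl_mode=mode))
            assert np.all(out.values == 0)

    def test_static_mode_joint_scaling_equivalence(self):
        """Scaling pulse amplitude and k together leaves the static-mode
        response unchanged — surround strength and stimulus amplitude are
        interchangeable for a memoryless divisive nonlinearity."""
        a = run_cascade(make_pulse(0.2), ModelParams(k=0.2, nl_mode="static"))
        b = run_cascade(make_pulse(1.0), ModelParams(k=1.0, nl_mode="static"))
        assert np.abs(a.values - b.values).max() < 1e-10

    def test_dynamic_mode_k_controls_end_of_pulse_level(self):
        """With membrane dynamics, strong normalization (k=1) always ends
        the pulse at a lower fraction of peak than weak normalization."""
        end_idx = round(2.0 / DT) - 1  # pulse offset (1 s rest + 1 s pulse)
        levels = {}
        for k in (0.2, 1.0):
            levels[k] = [
                run_cascade(
                    make_pulse(amp), ModelParams(k=k, nl_mode="dynamic"),
                    normalize=True,
                ).values[end_idx]
                for amp in (0.2, 1.0)
            ]
        assert max(levels[1.0]) < min(levels[0.2])

    def test_normalized_output_peaks_at_one(self):
        out = run_cascade(make_pulse(1.0), ModelParams(k=0.2), normalize=True)
        assert out.values.max() == pytest.approx(1.0)


class TestMakePulse:
    def test_integral_equals_amplitude_times_duration(self):
        p = make_pulse(1.0, duration=1.0, total=3.0, dt=DT)
        assert p.values.sum() * DT == pytest.approx(1.0)
        assert p.values.size == 3000

    def test_zero_amplitude_is_zero_trace(self):
        assert np.all(make_pulse(0.0).values == 0)

    def test_invalid_durations(self):
        with pytest.raises(ValueError):
            make_pulse(1.0, duration=0.0)
        with pytest.raises(ValueError):
            make_pulse(1.0, duration=5.0, total=3.0)


class TestParams:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            ModelParams(tau_lp=-0.1)
        with pytest.raises(ValueError):
            ModelParams(nl_mode="other")

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("model:\n  k: 1.0\n  nl_mode: dynamic\n")
        p = ModelParams.from_yaml(path)
        assert p.k == 1.0 and p.nl_mode == "dynamic"
        with pytest.raises(ValueError):
            ModelParams.from_dict({"bogus": 1})


def test_trace_csv_roundtrip(tmp_path, rng):
    x = SignalTrace(values=rng.standard_normal(20), dt=0.01)
    path = tmp_path / "trace.csv"
    x.to_csv(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    assert np.allclose(arr[:, 0], x.times)
    assert np.allclose(arr[:, 1], x.values)
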