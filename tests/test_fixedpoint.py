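"""Tests for the Q-format register arithmetic and fixed-point circuits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurotouch.afferent import AfferentSpec, run_afferent
from neurotouch.fixedpoint import (Q13_18, WIDE_ORACLE_FORMAT, Diagnostics,
                                   FixedPointFormat, FixedState, FixedValue,
                                   _mul_raw, _quantize_raw, dequantize,
                                   fixed_initial_state, fixed_step,
                                   from_hex_lines, quantize, quantize_params,
                                   shift_mul, simulate_trace_fixed,
                                   to_hex_lines)
from neurotouch.models import (DEFAULT_H, MODEL_NAMES, NeuronParams,
                               NeuronState, SimConfig, simulate_trace,
                               step_model)
from neurotouch.stimulus import TrapezoidSpec, trapezoid


class TestQuantize:

    def test_exact_power_of_two(self):
        assert quantize(0.0078125).raw == 2048  # 2**-7 on the 2**-18 grid

    def test_zero(self):
        assert quantize(0.0).raw == 0

    def test_saturates_at_range_maximum(self):
        fv = quantize(10_000.0)
        assert fv.raw == Q13_18.raw_max
        assert fv.value == pytest.approx(8192.0 - 2.0 ** -18)

    def test_saturates_at_range_minimum(self):
        assert quantize(-10_000.0).raw == Q13_18.raw_min

    def test_rejects_non_finite(self):
        for bad in (float("nan"), float("inf"), -float("inf")):
            with pytest.raises(ValueError):
                quantize(bad)

    def test_invalid_format_rejected(self):
        with pytest.raises(ValueError):
            FixedPointFormat(total_bits=32, int_bits=13, frac_bits=17)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(raw=st.integers(Q13_18.raw_min, Q13_18.raw_max))
    def test_quantize_dequantize_roundtrip(self, raw):
        fv = FixedValue(raw=raw)
        assert quantize(dequantize(fv)).raw == raw


class TestShiftMul:

    def test_quarter_shift(self):
        # 1.0 * 0.25 -> 0.25 (M2 of the improved circuit)
        assert shift_mul(FixedValue(raw=262144), 0.25).raw == 65536

    def test_times_sixteen(self):
        # 1.0 * 16 -> 16.0 (C42 of the improved circuit)
        assert shift_mul(FixedValue(raw=262144), 16.0).raw == 4194304

    def test_identity_shift(self):
        assert shift_mul(FixedValue(raw=12345), 1.0).raw == 12345

    def test_rejects_non_power_of_two(self):
        with pytest.raises(ValueError):
            shift_mul(FixedValue(raw=1), 0.3)

    def test_left_shift_saturates(self):
        diag = Diagnostics()
        out = shift_mul(FixedValue(raw=Q13_18.raw_max), 16.0, diag)
        assert out.raw == Q13_18.raw_max and diag.saturations == 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(raw=st.integers(Q13_18.raw_min, Q13_18.raw_max),
           k=st.integers(-6, 5), sign=st.sampled_from([1.0, -1.0]))
    def test_matches_generic_multiply(self, raw, k, sign):
        """Shift path equals full multiplication for power-of-two coefficients."""
        coeff = sign * 2.0 ** k
        coeff_raw = _quantize_raw(coeff, Q13_18)
        expected = _mul_raw(coeff_raw, raw, Q13_18, None)
        assert shift_mul(FixedValue(raw=raw), coeff).raw == expected


class TestFixedStep:

    def test_improved_lqif_from_rest(self):
        # v=0, I=1: v' = h*(C41*1) = 0.5 * 0.0078125 = 0.00390625, exact.
        params = NeuronParams.improved_lqif()
        qp = quantize_params(params)
        i_raw = _quantize_raw(1.0, Q13_18)
        out = fixed_step("lqif", FixedState(v_raw=0), i_raw, i_raw, qp, "SA")
        assert out.v_raw / Q13_18.scale == 0.00390625

    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_zero_state_zero_input_qif_family_stays_zero(self, model):
        params = NeuronParams.for_model(model)
        qp = quantize_params(params)
        state = fixed_initial_state(model, qp)
        nxt = fixed_step(model, state, 0, 0, qp, "SA")
        if model in ("qif", "lqif"):
            assert nxt.v_raw == 0 and not nxt.spiked

    def test_shift_requires_power_of_two_params(self):
        qp = quantize_params(NeuronParams.for_model("lqif"))  # C42=40: not 2**k
        with pytest.raises(ValueError):
            fixed_step("lqif", FixedState(v_raw=0), 0, 262144, qp, "FA",
                       shift=True)

    def test_shift_multiply_identity_random_steps(self):
        """Shift-based and multiply-based improved L-QIF agree bit for bit."""
        params = NeuronParams.improved_lqif()
        qp = quantize_params(params)
        rng = np.random.default_rng(1234)
        for _ in range(3000):
            v = int(rng.integers(Q13_18.raw_min, Q13_18.raw_max))
            i0 = int(rng.integers(0, 200 * Q13_18.scale))
            i1 = int(rng.integers(0, 200 * Q13_18.scale))
            at = "SA" if rng.random() < 0.5 else "FA"
            mul = fixed_step("lqif", FixedState(v_raw=v), i0, i1, qp, at)
            sh = fixed_step("lqif", FixedState(v_raw=v), i0, i1, qp, at,
                            shift=True)
            assert mul == sh

    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_wide_format_tracks_float_reference(self, model):
        """With 48 fractional bits a step is a near-exact float step."""
        params = NeuronParams.for_model(model)
        fmt = WIDE_ORACLE_FORMAT
        qp = quantize_params(params, fmt=fmt)
        rng = np.random.default_rng(99)
        two_var = model in ("izh", "lizh")
        for _ in range(500):
            v = rng.uniform(-90.0, 29.0)
            u = rng.uniform(-30.0, 30.0)
            i0 = rng.uniform(0.0, 150.0)
            i1 = i0 + rng.uniform(-0.25, 0.25)
            at = "SA" if rng.random() < 0.5 else "FA"
            ref = step_model(model, NeuronState(v=v, u=u if two_var else None),
                             i0, i1, params, DEFAULT_H, at)
            fs = FixedState(v_raw=_quantize_raw(v, fmt),
                            u_raw=_quantize_raw(u, fmt) if two_var else None)
            out = fixed_step(model, fs, _quantize_raw(i0, fmt),
                             _quantize_raw(i1, fmt), qp, at)
            assert out.spiked == ref.spiked
            assert abs(out.v_raw / fmt.scale - ref.v) < 1e-9


class TestTraceFidelity:

    @pytest.mark.parametrize("model", MODEL_NAMES)
    @pytest.mark.parametrize("afferent_type", ["SA", "FA"])
    def test_q13_18_spike_count_close_to_float(self, model, afferent_type,
                                               family_amps):
        """Register quantization barely perturbs the spike count (<= 5%)."""
        from neurotouch.stimulus import MODEL_FAMILY
        amp = family_amps[MODEL_FAMILY[model]]
        prof = trapezoid(TrapezoidSpec(0.0, 10.0, 80.0, 10.0, amp),
                         duration=100.0)
        config = SimConfig(duration=100.0, model=model,
                           afferent_type=afferent_type)
        _, st_float = simulate_trace(config, None, prof.f)
        _, st_fixed, diag = simulate_trace_fixed(config, None, prof.f)
        tol = max(1, int(round(0.05 * st_float.size)))
        assert abs(st_fixed.size - st_float.size) <= tol
        assert diag.saturations == 0

    def test_saturation_never_wraps(self):
        """An overdriven circuit pins at the register bound and counts it."""
        config = SimConfig(duration=1.0, model="qif", afferent_type="SA")
        current = np.full(config.n_steps, 9000.0)  # above the Q13.18 range
        trace, _, diag = simulate_trace_fixed(config, None, current)
        assert diag.saturations > 0
        assert np.all(np.abs(trace) <= Q13_18.max_value)


class TestKernelEquivalence:
    """The compiled batch kernels are bit-identical to the scalar paths."""

    @pytest.mark.parametrize("model", MODEL_NAMES)
    @pytest.mark.parametrize("afferent_type", ["SA", "FA"])
    def test_float_and_fixed_kernels_match_scalar(self, model, afferent_type):
        prof = trapezoid(TrapezoidSpec(2.0, 5.0, 25.0, 8.0, 20.0),
                         duration=50.0)
        config = SimConfig(duration=50.0, model=model,
                           afferent_type=afferent_type)
        tr_f, st_f = simulate_trace(config, None, prof.f)
        tr_q, st_q, _ = simulate_trace_fixed(config, None, prof.f)
        resp_f = run_afferent(prof, AfferentSpec(afferent_type=afferent_type,
                                                 model=model,
                                                 arithmetic="float"))
        resp_q = run_afferent(prof, AfferentSpec(afferent_type=afferent_type,
                                                 model=model,
                                                 arithmetic="fixed"))
        assert np.array_equal(resp_f.trace, tr_f)
        assert np.array_equal(resp_f.spike_times, st_f)
        assert np.array_equal(resp_q.trace, tr_q)
        assert np.array_equal(resp_q.spike_times, st_q)


class TestHexDump:

    def test_roundtrip(self):
        raws = [0, 1, -1, Q13_18.raw_max, Q13_18.raw_min, 2048, -2048]
        lines = to_hex_lines(raws)
        assert lines[0] == "00000000" and lines[2] == "ffffffff"
        assert from_hex_lines(lines) == raws

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            to_hex_lines([Q13_18.raw_max + 1])
        with pytest.raises(ValueError):
            from_hex_lines(["1ffffffff"])
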