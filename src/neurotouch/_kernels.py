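"""Batched numba kernels for long population runs.

These kernels are exact mirrors of the scalar references
(:func:`neurotouch.models.simulate_trace` and
:func:`neurotouch.fixedpoint.simulate_trace_fixed`): same operation order,
same truncation and saturation rules, so the results agree bit for bit.
They exist purely for speed -- a haptic trial is 4 s at h = 2**-7 ms, i.e.
512k updates per afferent, which is impractical in pure Python at population
scale.

The fixed-point kernel works on int64 raw register images and is valid for
formats up to 32 total bits (double-width products must fit in int64); the
callers enforce that.  Multiplication by a power-of-two coefficient truncates
identically to the logical shifter, so the same kernel serves both the
generic-multiplier and the shift-based circuits.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Parameter-vector layout shared with QuantizedParams.as_array() and the
# float analogue below.
_A, _B, _C, _D, _K1, _K2, _M1, _M2 = 0, 1, 2, 3, 4, 5, 6, 7
_VPEAK, _VRESET, _CSA, _CFA, _H = 8, 9, 10, 11, 12
_C004, _C5, _C140, _C625 = 13, 14, 15, 16

MODEL_IDS = {"izh": 0, "lizh": 1, "qif": 2, "lqif": 3}


def float_param_vector(params, h: float) -> np.ndarray:
    """Float parameter vector in the shared kernel layout."""
    return np.array(
        [params.a, params.b, params.c, params.d, params.k1, params.k2,
         params.M1, params.M2, params.v_peak, params.v_reset,
         params.C_in_sa, params.C_in_fa, h, 0.04, 5.0, 140.0, 62.5],
        dtype=np.float64)


@njit(cache=True)
def sim_float(model_id, fa, force, gain, extra, p, trace, spikes):
    """Simulate one unit in float64.  Returns the spike count.

    ``I[k] = gain * force[k] + extra[k]`` (``extra`` may be empty).
    ``trace`` and ``spikes`` must have the same length as ``force``.
    """
    n = force.shape[0]
    has_extra = extra.shape[0] == n
    store_trace = trace.shape[0] == n
    a, b, c, d = p[_A], p[_B], p[_C], p[_D]
    k1, k2 = p[_K1], p[_K2]
    M1, M2 = p[_M1], p[_M2]
    v_peak, v_reset = p[_VPEAK], p[_VRESET]
    Csa, Cfa, h = p[_CSA], p[_CFA], p[_H]

    two_var = model_id <= 1
    if two_var:
        v = c
        u = b * c
    else:
        v = v_reset
        u = 0.0

    count = 0
    for k in range(n):
        i0 = gain * force[k]
        if has_extra:
            i0 = i0 + extra[k]
        if k + 1 < n:
            i1 = gain * force[k + 1]
            if has_extra:
                i1 = i1 + extra[k + 1]
        else:
            i1 = i0
        if model_id == 0:
            if fa:
                vn = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u) + Cfa * (i1 - i0)
            else:
                vn = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + Csa * i0)
            un = u + h * a * (b * v - u)
        elif model_id == 1:
            if fa:
                vn = v + h * (k1 * abs(v + 62.5) - k2 - u) + Cfa * (i1 - i0)
            else:
                vn = v + h * (k1 * abs(v + 62.5) - k2 - u + Csa * i0)
            un = u + h * a * (b * v - u)
        elif model_id == 2:
            if fa:
                vn = v + h * (M1 * v * v) + Cfa * (i1 - i0)
            else:
                vn = v + h * (M1 * v * v + Csa * i0)
            un = u
        else:
            if fa:
                vn = v + h * (M2 * abs(v)) + Cfa * (i1 - i0)
            else:
                vn = v + h * (M2 * abs(v) + Csa * i0)
            un = u
        if vn >= v_peak:
            if store_trace:
                trace[k] = v_peak
            spikes[k] = 1
            count += 1
            if two_var:
                v = c
                u = un + d
            else:
                v = v_reset
                u = un
        else:
            if store_trace:
                trace[k] = vn
            v = vn
            u = un
    return count


@njit(cache=True, inline="always")
def _sat64(raw, raw_min, raw_max):
    if raw > raw_max:
        return raw_max, 1
    if raw < raw_min:
        return raw_min, 1
    return raw, 0


@njit(cache=True)
def sim_fixed(model_id, fa, force, gain, extra, qp, frac, raw_min, raw_max,
              trace_raw, spikes):
    """Simulate one unit entirely in fixed point (int64 register images).

    The float drive ``gain * force[k] + extra[k]`` is quantized sample by
    sample (round half away from zero, saturating); every product is
    truncated back to the register grid; additions saturate.  Returns
    ``(spike_count, saturation_count)``.
    """
    n = force.shape[0]
    has_extra = extra.shape[0] == n
    store_trace = trace_raw.shape[0] == n
    scale = np.float64(np.int64(1) << frac)
    sat_count = 0

    a, b, c, d = qp[_A], qp[_B], qp[_C], qp[_D]
    k1, k2 = qp[_K1], qp[_K2]
    M1, M2 = qp[_M1], qp[_M2]
    v_peak, v_reset = qp[_VPEAK], qp[_VRESET]
    Csa, Cfa, h = qp[_CSA], qp[_CFA], qp[_H]
    c_004, c_5, c_140, c_625 = qp[_C004], qp[_C5], qp[_C140], qp[_C625]

    two_var = model_id <= 1
    if two_var:
        v = c
        u, s = _sat64((b * c) >> frac, raw_min, raw_max)
        sat_count += s
    else:
        v = v_reset
        u = np.int64(0)

    # Quantize the first drive sample.
    x = gain * force[0]
    if has_extra:
        x = x + extra[0]
    if x >= 0.0:
        i0 = np.int64(np.floor(x * scale + 0.5))
    else:
        i0 = -np.int64(np.floor(-x * scale + 0.5))
    i0, s = _sat64(i0, raw_min, raw_max)
    sat_count += s

    count = 0
    for k in range(n):
        if k + 1 < n:
            x = gain * force[k + 1]
            if has_extra:
                x = x + extra[k + 1]
            if x >= 0.0:
                i1 = np.int64(np.floor(x * scale + 0.5))
            else:
                i1 = -np.int64(np.floor(-x * scale + 0.5))
            i1, s = _sat64(i1, raw_min, raw_max)
            sat_count += s
        else:
            i1 = i0

        if model_id == 0:
            t1, s = _sat64((c_004 * v) >> frac, raw_min, raw_max); sat_count += s
            t1, s = _sat64((t1 * v) >> frac, raw_min, raw_max); sat_count += s
            t2, s = _sat64((c_5 * v) >> frac, raw_min, raw_max); sat_count += s
            br, s = _sat64(t1 + t2, raw_min, raw_max); sat_count += s
            br, s = _sat64(br + c_140, raw_min, raw_max); sat_count += s
            br, s = _sat64(br - u, raw_min, raw_max); sat_count += s
            if not fa:
                t3, s = _sat64((Csa * i0) >> frac, raw_min, raw_max); sat_count += s
                br, s = _sat64(br + t3, raw_min, raw_max); sat_count += s
            t4, s = _sat64((h * br) >> frac, raw_min, raw_max); sat_count += s
            vn, s = _sat64(v + t4, raw_min, raw_max); sat_count += s
            if fa:
                di, s = _sat64(i1 - i0, raw_min, raw_max); sat_count += s
                t5, s = _sat64((Cfa * di) >> frac, raw_min, raw_max); sat_count += s
                vn, s = _sat64(vn + t5, raw_min, raw_max); sat_count += s
        elif model_id == 1:
            sv, s = _sat64(v + c_625, raw_min, raw_max); sat_count += s
            if sv < 0:
                av, s = _sat64(-sv, raw_min, raw_max); sat_count += s
            else:
                av = sv
            t1, s = _sat64((k1 * av) >> frac, raw_min, raw_max); sat_count += s
            br, s = _sat64(t1 - k2, raw_min, raw_max); sat_count += s
            br, s = _sat64(br - u, raw_min, raw_max); sat_count += s
            if not fa:
                t3, s = _sat64((Csa * i0) >> frac, raw_min, raw_max); sat_count += s
                br, s = _sat64(br + t3, raw_min, raw_max); sat_count += s
            t4, s = _sat64((h * br) >> frac, raw_min, raw_max); sat_count += s
            vn, s = _sat64(v + t4, raw_min, raw_max); sat_count += s
            if fa:
                di, s = _sat64(i1 - i0, raw_min, raw_max); sat_count += s
                t5, s = _sat64((Cfa * di) >> frac, raw_min, raw_max); sat_count += s
                vn, s = _sat64(vn + t5, raw_min, raw_max); sat_count += s
        elif model_id == 2:
            t1, s = _sat64((M1 * v) >> frac, raw_min, raw_max); sat_count += s
            t1, s = _sat64((t1 * v) >> frac, raw_min, raw_max); sat_count += s
            if fa:
                t4, s = _sat64((h * t1) >> frac, raw_min, raw_max); sat_count += s
                vn, s = _sat64(v + t4, raw_min, raw_max); sat_count += s
                di, s = _sat64(i1 - i0, raw_min, raw_max); sat_count += s
                t5, s = _sat64((Cfa * di) >> frac, raw_min, raw_max); sat_count += s
                vn, s = _sat64(vn + t5, raw_min, raw_max); sat_count += s
            else:
                t3, s = _sat64((Csa * i0) >> frac, raw_min, raw_max); sat_count += s
                br, s = _sat64(t1 + t3, raw_min, raw_max); sat_count += s
                t4, s = _sat64((h * br) >> frac, raw_min, raw_max); sat_count += s
                vn, s = _sat64(v + t4, raw_min, raw_max); sat_count += s
        else:
            if v < 0:
                av, s = _sat64(-v, raw_min, raw_max); sat_count += s
            else:
                av = v
            t1, s = _sat64((M2 * av) >> frac, raw_min, raw_max); sat_count += s
            if fa:
                t4, s = _sat64((h * t1) >> frac, raw_min, raw_max); sat_count += s
                vn, s = _sat64(v + t4, raw_min, raw_max); sat_count += s
                di, s = _sat64(i1 - i0, raw_min, raw_max); sat_count += s
                t5, s = _sat64((Cfa * di) >> frac, raw_min, raw_max); sat_count += s
                vn, s = _sat64(vn + t5, raw_min, raw_max); sat_count += s
            else:
                t3, s = _sat64((Csa * i0) >> frac, raw_min, raw_max); sat_count += s
                br, s = _sat64(t1 + t3, raw_min, raw_max); sat_count += s
                t4, s = _sat64((h * br) >> frac, raw_min, raw_max); sat_count += s
                vn, s = _sat64(v + t4, raw_min, raw_max); sat_count += s

        if two_var:
            r, s = _sat64((b * v) >> frac, raw_min, raw_max); sat_count += s
            r, s = _sat64(r - u, raw_min, raw_max); sat_count += s
            r, s = _sat64((a * r) >> frac, raw_min, raw_max); sat_count += s
            r, s = _sat64((h * r) >> frac, raw_min, raw_max); sat_count += s
            un, s = _sat64(u + r, raw_min, raw_max); sat_count += s
        else:
            un = u

        if vn >= v_peak:
            if store_trace:
                trace_raw[k] = v_peak
            spikes[k] = 1
            count += 1
            if two_var:
                v = c
                un2, s = _sat64(un + d, raw_min, raw_max); sat_count += s
                u = un2
            else:
                v = v_reset
                u = un
        else:
            if store_trace:
                trace_raw[k] = vn
            v = vn
            u = un
        i0 = i1
    return count, sat_count
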