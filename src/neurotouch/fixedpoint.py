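"""Bit-accurate emulation of the digital afferent circuits.

The hardware solves every state variable in a signed 32-bit register with
1 sign bit, 13 integer bits and 18 fractional bits (Q13.18): resolution
``2**-18``, range ``[-8192, 8192 - 2**-18]``.  This module reproduces that
arithmetic exactly on Python integers:

* quantization is round-to-nearest (half away from zero) with saturation;
* every multiplication computes the full double-width product and truncates
  it back to the register grid (floor, i.e. toward -inf), mirroring a single
  shared register width per signal;
* additions saturate instead of wrapping, and every saturation event is
  counted in a :class:`Diagnostics` record -- wrap-around would fabricate
  spikes that the digital circuits never show.

When a coefficient is a power of two (the "improved" L-QIF parameter set:
``M2 = 0.25``, ``C41 = 0.5``, ``C42 = 16``), the product reduces to an
arithmetic shift; :func:`shift_mul` implements the shifter and is bit-for-bit
identical to the generic multiply for such coefficients.

The same update ordering is used by the batched numba kernels in
``neurotouch._kernels``; tests assert bit identity between the two paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import (DEFAULT_H, TWO_VAR_MODELS, NeuronParams, SimConfig,
                     normalize_afferent_type)

__all__ = [
    "FixedPointFormat",
    "FixedValue",
    "Diagnostics",
    "Q13_18",
    "WIDE_ORACLE_FORMAT",
    "quantize",
    "dequantize",
    "shift_mul",
    "is_power_of_two",
    "QuantizedParams",
    "quantize_params",
    "FixedState",
    "fixed_initial_state",
    "fixed_step",
    "simulate_trace_fixed",
    "to_hex_lines",
    "from_hex_lines",
]


@dataclass(frozen=True)
class FixedPointFormat:
    """Signed two's-complement fixed-point register format.

    ``total_bits = 1 (sign) + int_bits + frac_bits``.  Real value of a raw
    register image ``r`` is ``r * 2**-frac_bits``.
    """

    total_bits: int = 32
    int_bits: int = 13
    frac_bits: int = 18

    def __post_init__(self) -> None:
        if self.total_bits != 1 + self.int_bits + self.frac_bits:
            raise ValueError("total_bits must equal 1 + int_bits + frac_bits")
        if self.int_bits < 0 or self.frac_bits < 0 or self.total_bits < 2:
            raise ValueError("invalid fixed-point format")

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def raw_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def resolution(self) -> float:
        return 2.0 ** -self.frac_bits

    @property
    def min_value(self) -> float:
        return self.raw_min / self.scale

    @property
    def max_value(self) -> float:
        return self.raw_max / self.scale


#: Register format of the digital circuits.
Q13_18 = FixedPointFormat(32, 13, 18)
#: Wide format used only as a near-float oracle in equivalence tests.
WIDE_ORACLE_FORMAT = FixedPointFormat(64, 15, 48)


@dataclass
class Diagnostics:
    """Saturation counter for a fixed-point run (overflow never wraps)."""

    saturations: int = 0


@dataclass(frozen=True)
class FixedValue:
    """A register image together with its format."""

    raw: int
    fmt: FixedPointFormat = Q13_18

    def __post_init__(self) -> None:
        if not (self.fmt.raw_min <= self.raw <= self.fmt.raw_max):
            raise ValueError(f"raw value {self.raw} outside register range")

    @property
    def value(self) -> float:
        return self.raw / self.fmt.scale

    @classmethod
    def from_float(cls, x: float, fmt: FixedPointFormat = Q13_18,
                   diag: Optional[Diagnostics] = None) -> "FixedValue":
        return cls(_quantize_raw(x, fmt, diag), fmt)


def _sat(raw: int, fmt: FixedPointFormat, diag: Optional[Diagnostics]) -> int:
    if raw > fmt.raw_max:
        if diag is not None:
            diag.saturations += 1
        return fmt.raw_max
    if raw < fmt.raw_min:
        if diag is not None:
            diag.saturations += 1
        return fmt.raw_min
    return raw


def _quantize_raw(x: float, fmt: FixedPointFormat,
                  diag: Optional[Diagnostics] = None) -> int:
    if not math.isfinite(x):
        raise ValueError(f"cannot quantize non-finite value {x!r}")
    if x >= 0:
        raw = math.floor(x * fmt.scale + 0.5)
    else:
        raw = -math.floor(-x * fmt.scale + 0.5)
    return _sat(raw, fmt, diag)


def quantize(x: float, fmt: FixedPointFormat = Q13_18,
             diag: Optional[Diagnostics] = None) -> FixedValue:
    """Round ``x`` to the nearest register grid point, saturating at range."""
    return FixedValue(_quantize_raw(x, fmt, diag), fmt)


def dequantize(fv: FixedValue) -> float:
    return fv.value


def _mul_raw(a: int, b: int, fmt: FixedPointFormat,
             diag: Optional[Diagnostics]) -> int:
    # Full double-width product, truncated back to the register grid.
    # Arithmetic right shift of a negative integer floors toward -inf,
    # matching the truncation of a two's-complement barrel shifter.
    return _sat((a * b) >> fmt.frac_bits, fmt, diag)


def _add_raw(a: int, b: int, fmt: FixedPointFormat,
             diag: Optional[Diagnostics]) -> int:
    return _sat(a + b, fmt, diag)


def is_power_of_two(coeff: float) -> Optional[int]:
    """Return ``k`` such that ``|coeff| == 2**k``, or ``None``."""
    if coeff == 0 or not math.isfinite(coeff):
        return None
    mantissa, exponent = math.frexp(abs(coeff))
    if mantissa != 0.5:
        return None
    return exponent - 1


def shift_mul(x: FixedValue, coeff: float,
              diag: Optional[Diagnostics] = None) -> FixedValue:
    """Multiply a register by a power-of-two coefficient using shifts.

    ``coeff`` must equal ``+/- 2**k``.  Right shifts truncate toward -inf,
    left shifts saturate on overflow; a negative coefficient negates the
    operand *before* the shift, so the result is bit-identical to the
    truncating two's-complement multiplier for every input.
    """
    k = is_power_of_two(coeff)
    if k is None:
        raise ValueError(f"coefficient {coeff!r} is not a power of two")
    fmt = x.fmt
    raw = -x.raw if coeff < 0 else x.raw
    raw = raw << k if k >= 0 else raw >> (-k)
    return FixedValue(_sat(raw, fmt, diag), fmt)


@dataclass(frozen=True)
class QuantizedParams:
    """All model constants pre-quantized to one register format."""

    fmt: FixedPointFormat
    a: int
    b: int
    c: int
    d: int
    k1: int
    k2: int
    M1: int
    M2: int
    v_peak: int
    v_reset: int
    C_sa: int
    C_fa: int
    h: int
    c_004: int   # the Izhikevich quadratic gain 0.04
    c_5: int
    c_140: int
    c_625: int   # the linearization offset 62.5

    def as_array(self) -> np.ndarray:
        """Parameter vector consumed by the numba kernels (fixed layout)."""
        return np.array(
            [self.a, self.b, self.c, self.d, self.k1, self.k2, self.M1,
             self.M2, self.v_peak, self.v_reset, self.C_sa, self.C_fa,
             self.h, self.c_004, self.c_5, self.c_140, self.c_625],
            dtype=np.int64)


def quantize_params(params: NeuronParams, h: float = DEFAULT_H,
                    fmt: FixedPointFormat = Q13_18) -> QuantizedParams:
    q = lambda x: _quantize_raw(x, fmt)
    return QuantizedParams(
        fmt=fmt, a=q(params.a), b=q(params.b), c=q(params.c), d=q(params.d),
        k1=q(params.k1), k2=q(params.k2), M1=q(params.M1), M2=q(params.M2),
        v_peak=q(params.v_peak), v_reset=q(params.v_reset),
        C_sa=q(params.C_in_sa), C_fa=q(params.C_in_fa), h=q(h),
        c_004=q(0.04), c_5=q(5.0), c_140=q(140.0), c_625=q(62.5))


@dataclass(frozen=True)
class FixedState:
    """Register images of the membrane state (``u_raw`` only for Izh family)."""

    v_raw: int
    u_raw: Optional[int] = None
    spiked: bool = False


def fixed_initial_state(model: str, qp: QuantizedParams) -> FixedState:
    if model in TWO_VAR_MODELS:
        u0 = _mul_raw(qp.b, qp.c, qp.fmt, None)
        return FixedState(v_raw=qp.c, u_raw=u0)
    return FixedState(v_raw=qp.v_reset)


def _abs_raw(raw: int, fmt: FixedPointFormat, diag: Optional[Diagnostics]) -> int:
    return _sat(-raw, fmt, diag) if raw < 0 else raw


def fixed_step(model: str, state: FixedState, i_now_raw: int, i_next_raw: int,
               qp: QuantizedParams, afferent_type: str = "SA", *,
               shift: bool = False,
               diag: Optional[Diagnostics] = None) -> FixedState:
    """One fully fixed-point update of the chosen model.

    Every product is truncated back to the register grid immediately
    (one shared register width per signal); additions saturate.  With
    ``shift=True`` every multiplication whose coefficient is a power of two is
    routed through the logical shifter instead of the generic multiplier --
    this requires a shift-realizable parameter set such as
    :meth:`neurotouch.models.NeuronParams.improved_lqif` and is bit-identical
    to the multiplier path.
    """
    fmt = qp.fmt
    fa = normalize_afferent_type(afferent_type) == "FA"
    v = state.v_raw
    u = state.u_raw

    if shift:
        def mul_coeff(coeff_raw: int, x: int) -> int:
            k = is_power_of_two(coeff_raw / fmt.scale)
            if k is None:
                raise ValueError(
                    "shift arithmetic requires power-of-two coefficients; "
                    "use the improved L-QIF parameter set")
            raw = -x if coeff_raw < 0 else x
            raw = raw << k if k >= 0 else raw >> (-k)
            return _sat(raw, fmt, diag)
    else:
        def mul_coeff(coeff_raw: int, x: int) -> int:
            return _mul_raw(coeff_raw, x, fmt, diag)

    if model == "izh":
        t1 = _mul_raw(_mul_raw(qp.c_004, v, fmt, diag), v, fmt, diag)
        bracket = _add_raw(t1, _mul_raw(qp.c_5, v, fmt, diag), fmt, diag)
        bracket = _add_raw(bracket, qp.c_140, fmt, diag)
        bracket = _add_raw(bracket, -u, fmt, diag)
        if not fa:
            bracket = _add_raw(bracket, _mul_raw(qp.C_sa, i_now_raw, fmt, diag), fmt, diag)
        vn = _add_raw(v, _mul_raw(qp.h, bracket, fmt, diag), fmt, diag)
        if fa:
            di = _sat(i_next_raw - i_now_raw, fmt, diag)
            vn = _add_raw(vn, _mul_raw(qp.C_fa, di, fmt, diag), fmt, diag)
    elif model == "lizh":
        av = _abs_raw(_add_raw(v, qp.c_625, fmt, diag), fmt, diag)
        bracket = _add_raw(_mul_raw(qp.k1, av, fmt, diag), -qp.k2, fmt, diag)
        bracket = _add_raw(bracket, -u, fmt, diag)
        if not fa:
            bracket = _add_raw(bracket, _mul_raw(qp.C_sa, i_now_raw, fmt, diag), fmt, diag)
        vn = _add_raw(v, _mul_raw(qp.h, bracket, fmt, diag), fmt, diag)
        if fa:
            di = _sat(i_next_raw - i_now_raw, fmt, diag)
            vn = _add_raw(vn, _mul_raw(qp.C_fa, di, fmt, diag), fmt, diag)
    elif model == "qif":
        t1 = _mul_raw(_mul_raw(qp.M1, v, fmt, diag), v, fmt, diag)
        if fa:
            vn = _add_raw(v, _mul_raw(qp.h, t1, fmt, diag), fmt, diag)
            di = _sat(i_next_raw - i_now_raw, fmt, diag)
            vn = _add_raw(vn, _mul_raw(qp.C_fa, di, fmt, diag), fmt, diag)
        else:
            bracket = _add_raw(t1, _mul_raw(qp.C_sa, i_now_raw, fmt, diag), fmt, diag)
            vn = _add_raw(v, _mul_raw(qp.h, bracket, fmt, diag), fmt, diag)
    elif model == "lqif":
        t1 = mul_coeff(qp.M2, _abs_raw(v, fmt, diag))
        if fa:
            vn = _add_raw(v, mul_coeff(qp.h, t1), fmt, diag)
            di = _sat(i_next_raw - i_now_raw, fmt, diag)
            vn = _add_raw(vn, mul_coeff(qp.C_fa, di), fmt, diag)
        else:
            bracket = _add_raw(t1, mul_coeff(qp.C_sa, i_now_raw), fmt, diag)
            vn = _add_raw(v, mul_coeff(qp.h, bracket), fmt, diag)
    else:
        raise ValueError(f"unknown model {model!r}")

    # Recovery variable (old v, exactly as in the float reference).
    if model in TWO_VAR_MODELS:
        r = _add_raw(_mul_raw(qp.b, v, fmt, diag), -u, fmt, diag)
        un = _add_raw(u, _mul_raw(qp.h, _mul_raw(qp.a, r, fmt, diag), fmt, diag), fmt, diag)
    else:
        un = None

    if vn >= qp.v_peak:
        if model in TWO_VAR_MODELS:
            return FixedState(v_raw=qp.c, u_raw=_add_raw(un, qp.d, fmt, diag), spiked=True)
        return FixedState(v_raw=qp.v_reset, spiked=True)
    return FixedState(v_raw=vn, u_raw=un)


def simulate_trace_fixed(config: SimConfig, params: Optional[NeuronParams],
                         current: Sequence[float],
                         fmt: FixedPointFormat = Q13_18, *, shift: bool = False,
                         ) -> Tuple[np.ndarray, np.ndarray, Diagnostics]:
    """Fixed-point counterpart of :func:`neurotouch.models.simulate_trace`.

    The float current series is quantized sample by sample to ``fmt`` (this is
    what the ADC-facing registers of the circuit hold); all state updates then
    run entirely in fixed point.  Returns the dequantized voltage trace (with
    ``v_peak`` stored at spike steps), spike times in ms and the saturation
    diagnostics.
    """
    if params is None:
        params = NeuronParams.for_model(config.model)
    current = np.asarray(current, dtype=np.float64)
    if current.ndim != 1 or current.shape[0] != config.n_steps:
        raise ValueError(
            f"current length {current.shape} does not match duration/h = {config.n_steps}")
    if not np.all(np.isfinite(current)):
        raise ValueError("current series contains non-finite values")

    diag = Diagnostics()
    qp = quantize_params(params, config.h, fmt)
    model = config.model
    state = fixed_initial_state(model, qp)
    n = config.n_steps
    i_raw = [_quantize_raw(float(x), fmt, diag) for x in current]

    trace_raw = np.empty(n, dtype=np.float64)
    spike_steps: List[int] = []
    for k in range(n):
        i1 = i_raw[k + 1] if k + 1 < n else i_raw[k]
        state = fixed_step(model, state, i_raw[k], i1, qp,
                           config.afferent_type, shift=shift, diag=diag)
        if state.spiked:
            trace_raw[k] = qp.v_peak
            spike_steps.append(k)
        else:
            trace_raw[k] = state.v_raw
    spike_times = (np.asarray(spike_steps, dtype=np.float64) + 1.0) * config.h
    return trace_raw / fmt.scale, spike_times, diag


def to_hex_lines(raws: Sequence[int], fmt: FixedPointFormat = Q13_18) -> List[str]:
    """Render raw register images as two's-complement hex words, one per line.

    The dump matches what an HDL simulator prints for an ``N``-bit register,
    so traces can be diffed against hardware simulation logs.
    """
    digits = (fmt.total_bits + 3) // 4
    mask = (1 << fmt.total_bits) - 1
    lines = []
    for raw in raws:
        if not (fmt.raw_min <= raw <= fmt.raw_max):
            raise ValueError(f"raw value {raw} outside register range")
        lines.append(format(raw & mask, f"0{digits}x"))
    return lines


def from_hex_lines(lines: Sequence[str], fmt: FixedPointFormat = Q13_18) -> List[int]:
    """Inverse of :func:`to_hex_lines` (sign-extends each word)."""
    sign_bit = 1 << (fmt.total_bits - 1)
    full = 1 << fmt.total_bits
    out = []
    for line in lines:
        word = int(line.strip(), 16)
        if word >= full:
            raise ValueError(f"hex word {line!r} wider than {fmt.total_bits} bits")
        out.append(word - full if word & sign_bit else word)
    return out
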