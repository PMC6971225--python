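"""The afferent front end: one force channel wired to one spiking model.

A single artificial afferent is a force-to-current transduction stage followed
by one of the four spiking models.  The force signal ``f(t)`` (mN, uniformly
sampled) maps to the model input current as ``I[n] = gain_jitter * f[n]``; the
per-model coupling weights are applied inside the model equations.  An
optional 10-bit ADC stage first maps the force onto 0..1023 quantization
levels over a configured full-scale force, mimicking the sensor interface
board of the hardware system.

Optional background activity is modelled as Poisson-timed rectangular current
pulses added to the drive -- this reproduces the spontaneous raster activity
of a hardware population without touching the deterministic core (noise is
off by default and all quantitative characterizations run without it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .fixedpoint import Q13_18, Diagnostics, FixedPointFormat, quantize_params
from .models import (DEFAULT_H, NeuronParams, SimConfig,
                     normalize_afferent_type)

__all__ = [
    "ForceProfile",
    "AdcConfig",
    "AfferentSpec",
    "AfferentResponse",
    "force_to_current",
    "run_afferent",
    "ARITHMETIC_MODES",
]

ARITHMETIC_MODES = ("float", "fixed", "fixed-shift")


@dataclass(frozen=True)
class ForceProfile:
    """A uniformly sampled force time series (mN)."""

    f: np.ndarray
    h: float = DEFAULT_H

    def __post_init__(self) -> None:
        f = np.ascontiguousarray(np.asarray(self.f, dtype=np.float64))
        object.__setattr__(self, "f", f)
        if f.ndim != 1:
            raise ValueError("force profile must be one-dimensional")
        if not np.all(np.isfinite(f)):
            raise ValueError("force profile contains non-finite values")
        if np.any(f < 0):
            raise ValueError("force must be non-negative")
        if not (math.isfinite(self.h) and self.h > 0):
            raise ValueError(f"sampling step h must be positive, got {self.h!r}")

    @property
    def t(self) -> np.ndarray:
        """Time grid in ms."""
        return np.arange(self.f.shape[0]) * self.h

    @property
    def duration(self) -> float:
        return self.f.shape[0] * self.h


@dataclass(frozen=True)
class AdcConfig:
    """Sensor-interface ADC: force mapped to integer levels 0..2**bits - 1."""

    bits: int = 10
    full_scale: float = 100.0  # mN mapped to the top code

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError("ADC needs at least one bit")
        if not self.full_scale > 0:
            raise ValueError("full-scale force must be positive")

    @property
    def levels(self) -> int:
        return (1 << self.bits) - 1


@dataclass(frozen=True)
class AfferentSpec:
    """Complete description of one artificial afferent."""

    afferent_type: str = "SA"
    model: str = "lqif"
    params: Optional[NeuronParams] = None
    arithmetic: str = "float"
    fmt: FixedPointFormat = Q13_18
    gain_jitter: float = 1.0
    noise_rate: float = 0.0          # Hz, Poisson background pulse rate
    noise_amplitude: float = 5.0     # pulse height in force units
    noise_width: float = 5.0         # pulse width, ms
    adc: Optional[AdcConfig] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "afferent_type",
                           normalize_afferent_type(self.afferent_type))
        if self.arithmetic not in ARITHMETIC_MODES:
            raise ValueError(
                f"arithmetic must be one of {ARITHMETIC_MODES}, got {self.arithmetic!r}")
        if not (math.isfinite(self.gain_jitter) and self.gain_jitter > 0):
            raise ValueError("gain_jitter must be positive")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be non-negative")
        if self.params is None:
            object.__setattr__(self, "params", NeuronParams.for_model(self.model))

    @property
    def uses_fixed(self) -> bool:
        return self.arithmetic in ("fixed", "fixed-shift")


@dataclass(frozen=True)
class AfferentResponse:
    """Output of one afferent run."""

    spike_times: np.ndarray  # ms
    trace: np.ndarray        # membrane potential, mV (v_peak at spike steps)
    diagnostics: Diagnostics = field(default_factory=Diagnostics)


def force_to_current(profile: ForceProfile, spec: AfferentSpec) -> np.ndarray:
    """Transduce a force profile into the model input current.

    Without an ADC this is ``I[n] = gain_jitter * f[n]``; with one, the force
    is first quantized to integer levels over the configured full scale
    (saturating at the top code), and the levels are what gets weighted.
    """
    f = profile.f
    if spec.adc is not None:
        levels = np.floor(f / spec.adc.full_scale * spec.adc.levels + 0.5)
        f = np.clip(levels, 0, spec.adc.levels)
    return spec.gain_jitter * f


def _noise_pulses(n_steps: int, h: float, rate_hz: float, amplitude: float,
                  width_ms: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson-timed rectangular current pulses (background activity)."""
    duration_s = n_steps * h / 1000.0
    n_events = rng.poisson(rate_hz * duration_s)
    extra = np.zeros(n_steps, dtype=np.float64)
    if n_events == 0:
        return extra
    starts = np.sort(rng.integers(0, n_steps, size=n_events))
    width = max(1, int(round(width_ms / h)))
    for s in starts:
        extra[s:s + width] += amplitude
    return extra


def run_afferent(profile: ForceProfile, spec: AfferentSpec,
                 seed: Optional[int] = None) -> AfferentResponse:
    """Run one afferent over a force profile.

    ``seed`` is required iff ``spec.noise_rate > 0``.  With noise and jitter
    disabled this reduces exactly to the underlying deterministic simulators.
    Long profiles are dispatched to the compiled kernels, which are
    bit-identical to the scalar references.
    """
    if spec.noise_rate > 0 and seed is None:
        raise ValueError("a seed is required when noise_rate > 0")
    n = profile.f.shape[0]
    extra = np.zeros(0, dtype=np.float64)
    if spec.noise_rate > 0:
        rng = np.random.default_rng(seed)
        extra = _noise_pulses(n, profile.h, spec.noise_rate,
                              spec.noise_amplitude, spec.noise_width, rng)

    f = profile.f
    if spec.adc is not None:
        levels = np.floor(f / spec.adc.full_scale * spec.adc.levels + 0.5)
        f = np.clip(levels, 0, spec.adc.levels)
    f = np.ascontiguousarray(f, dtype=np.float64)

    model_id = _kernels.MODEL_IDS[spec.model]
    fa = spec.afferent_type == "FA"
    diag = Diagnostics()
    spikes = np.zeros(n, dtype=np.uint8)
    if spec.uses_fixed:
        fmt = spec.fmt
        if fmt.total_bits > 32:
            # Wide formats exceed int64 double-width products; use the exact
            # scalar path (arbitrary-precision integers).
            from .fixedpoint import simulate_trace_fixed
            config = SimConfig(duration=n * profile.h, h=profile.h,
                               afferent_type=spec.afferent_type, model=spec.model)
            current = spec.gain_jitter * f
            if extra.shape[0] == n:
                current = current + extra
            trace, spike_times, diag = simulate_trace_fixed(
                config, spec.params, current, fmt,
                shift=(spec.arithmetic == "fixed-shift"))
            return AfferentResponse(spike_times=spike_times, trace=trace,
                                    diagnostics=diag)
        qp = quantize_params(spec.params, profile.h, fmt).as_array()
        trace_raw = np.empty(n, dtype=np.int64)
        _, sats = _kernels.sim_fixed(model_id, fa, f, spec.gain_jitter, extra,
                                     qp, fmt.frac_bits, fmt.raw_min,
                                     fmt.raw_max, trace_raw, spikes)
        diag.saturations = int(sats)
        trace = trace_raw / fmt.scale
    else:
        p = _kernels.float_param_vector(spec.params, profile.h)
        trace = np.empty(n, dtype=np.float64)
        _kernels.sim_float(model_id, fa, f, spec.gain_jitter, extra, p,
                           trace, spikes)
    spike_times = (np.flatnonzero(spikes).astype(np.float64) + 1.0) * profile.h
    return AfferentResponse(spike_times=spike_times, trace=trace,
                            diagnostics=diag)
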