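"""Populations of digital afferents over a sensor grid.

The hardware system runs 27 digital afferents per force sensor (10 SA-I and
17 FA-I); over the default 3x3 sensor grid that is 243 afferents, 90 SA-I and
153 FA-I -- the SA/FA proportion follows the innervation ratio of the human
fingertip.  Each afferent of sensor ``s`` is driven only by force channel
``s``.  The default unit is the improved L-QIF circuit (all coefficients
powers of two) evaluated in shift-based Q13.18 fixed point, exactly as on the
FPGA.

The hardware evaluates all units in parallel; the software runs them
sequentially but draws every unit's jitter and noise from its own
counter-derived random stream, so results are independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels
from .afferent import AdcConfig, AfferentSpec, _noise_pulses
from .fixedpoint import Q13_18, FixedPointFormat, quantize_params
from .models import DEFAULT_H, NeuronParams

__all__ = ["PopulationLayout", "Unit", "Population", "SpikeRaster",
           "build_population", "run_population"]


@dataclass(frozen=True)
class PopulationLayout:
    """Counts and common settings of an afferent population."""

    n_sensors: int = 9
    sa_per_sensor: int = 10
    fa_per_sensor: int = 17
    model: str = "lqif"
    params: Optional[NeuronParams] = None
    arithmetic: str = "fixed-shift"
    fmt: FixedPointFormat = Q13_18
    jitter_cv: float = 0.05   # per-unit multiplicative gain spread
    noise_rate: float = 0.0   # Hz of background pulses per unit
    noise_amplitude: float = 5.0
    noise_width: float = 5.0
    adc: Optional[AdcConfig] = None

    def __post_init__(self) -> None:
        if self.n_sensors < 1 or self.sa_per_sensor < 0 or self.fa_per_sensor < 0:
            raise ValueError("invalid population counts")
        if self.sa_per_sensor + self.fa_per_sensor < 1:
            raise ValueError("each sensor needs at least one afferent")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be non-negative")
        if self.params is None:
            # The hardware population runs the shift-friendly parameter set.
            default = (NeuronParams.improved_lqif() if self.model == "lqif"
                       else NeuronParams.for_model(self.model))
            object.__setattr__(self, "params", default)

    @property
    def per_sensor(self) -> int:
        return self.sa_per_sensor + self.fa_per_sensor

    @property
    def n_units(self) -> int:
        return self.n_sensors * self.per_sensor

    @property
    def n_sa(self) -> int:
        return self.n_sensors * self.sa_per_sensor

    @property
    def n_fa(self) -> int:
        return self.n_sensors * self.fa_per_sensor


@dataclass(frozen=True)
class Unit:
    """One afferent of the population."""

    unit_id: str
    sensor: int
    spec: AfferentSpec
    noise_seed: int


@dataclass(frozen=True)
class Population:
    layout: PopulationLayout
    units: Tuple[Unit, ...]
    seed: int

    @property
    def types(self) -> np.ndarray:
        return np.array([u.spec.afferent_type for u in self.units])

    @property
    def sensors(self) -> np.ndarray:
        return np.array([u.sensor for u in self.units], dtype=np.int64)


def build_population(layout: PopulationLayout, seed: int = 0) -> Population:
    """Instantiate per-unit specs with seeded jitter/noise streams.

    Units are ordered SA before FA within a sensor, sensors in row-major grid
    order (S1..S9 for the 3x3 grid).  Unit ``i`` draws its gain jitter from
    ``SeedSequence(seed, i)``, so any subset of units is reproducible
    independently of the others.
    """
    units: List[Unit] = []
    sigma = math.sqrt(math.log(1.0 + layout.jitter_cv ** 2))
    i = 0
    for sensor in range(layout.n_sensors):
        for j in range(layout.per_sensor):
            aff_type = "SA" if j < layout.sa_per_sensor else "FA"
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
            gain = float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma))) \
                if sigma > 0 else 1.0
            noise_seed = int(rng.integers(0, 2 ** 31))
            spec = AfferentSpec(
                afferent_type=aff_type, model=layout.model, params=layout.params,
                arithmetic=layout.arithmetic, fmt=layout.fmt, gain_jitter=gain,
                noise_rate=layout.noise_rate, noise_amplitude=layout.noise_amplitude,
                noise_width=layout.noise_width, adc=layout.adc)
            rank = j if aff_type == "SA" else j - layout.sa_per_sensor
            units.append(Unit(unit_id=f"S{sensor + 1}-{aff_type}{rank + 1}",
                              sensor=sensor, spec=spec, noise_seed=noise_seed))
            i += 1
    return Population(layout=layout, units=tuple(units), seed=seed)


@dataclass
class SpikeRaster:
    """Spike trains of a whole population for one scenario."""

    unit_ids: List[str]
    types: np.ndarray        # "SA" / "FA" per unit
    sensors: np.ndarray      # sensor index per unit
    spike_times: List[np.ndarray]  # ms, sorted, one array per unit
    duration: float          # ms
    h: float = DEFAULT_H

    def __post_init__(self) -> None:
        n = len(self.unit_ids)
        if not (len(self.spike_times) == n == len(self.types) == len(self.sensors)):
            raise ValueError("raster fields have inconsistent lengths")
        for st in self.spike_times:
            if st.size and (st[0] < 0 or st[-1] > self.duration
                            or np.any(np.diff(st) < 0)):
                raise ValueError("spike times must be sorted within [0, duration]")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def counts(self, window: Optional[Tuple[float, float]] = None,
               type_filter: str = "both") -> np.ndarray:
        """Spike count per unit in a window (default: the whole run)."""
        t0, t1 = window if window is not None else (0.0, self.duration)
        mask = self._type_mask(type_filter)
        return np.array([np.count_nonzero((st >= t0) & (st < t1))
                         for st, m in zip(self.spike_times, mask) if m],
                        dtype=np.int64)

    def _type_mask(self, type_filter: str) -> np.ndarray:
        if type_filter in ("both", "all"):
            return np.ones(self.n_units, dtype=bool)
        return self.types == type_filter.upper().replace("-I", "")

    def to_dataframe(self):
        """Long-format table: afferent_id, type, sensor, spike_time_ms."""
        import pandas as pd
        rows = {"afferent_id": [], "type": [], "sensor": [], "spike_time_ms": []}
        for uid, typ, sensor, st in zip(self.unit_ids, self.types, self.sensors,
                                        self.spike_times):
            rows["afferent_id"].extend([uid] * st.size)
            rows["type"].extend([typ] * st.size)
            rows["sensor"].extend([int(sensor)] * st.size)
            rows["spike_time_ms"].extend(st.tolist())
        return pd.DataFrame(rows)

    def plot(self, path=None, figsize=(10, 6)):
        """Raster figure with separate SA and FA panels."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(2, 1, sharex=True, figsize=figsize)
        for ax, typ, color in zip(axes, ("SA", "FA"), ("tab:green", "tab:blue")):
            row = 0
            for uid, t, st in zip(self.unit_ids, self.types, self.spike_times):
                if t != typ:
                    continue
                if st.size:
                    ax.vlines(st / 1000.0, row + 0.1, row + 0.9, color=color,
                              linewidth=0.4)
                row += 1
            ax.set_ylabel(f"{typ}-I afferent")
            ax.set_ylim(0, max(row, 1))
        axes[1].set_xlabel("time (s)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _render_forces(scenario, n_sensors: int, h: float) -> np.ndarray:
    if hasattr(scenario, "render"):
        forces = scenario.render(h)
    else:
        forces = np.asarray(scenario, dtype=np.float64)
    forces = np.atleast_2d(forces)
    if forces.shape[0] != n_sensors:
        raise ValueError(
            f"scenario provides {forces.shape[0]} force channels for "
            f"{n_sensors} sensors")
    return np.ascontiguousarray(forces, dtype=np.float64)


def run_population(population: Population, scenario,
                   seed: int = 0) -> SpikeRaster:
    """Run every afferent of the population against its sensor channel.

    ``scenario`` is a :class:`neurotouch.stimulus.StimulusScenario` (or any
    object with ``render(h) -> (n_sensors, n_steps)``, or a plain 2-D force
    array).  Deterministic per seed; with noise off the result is independent
    of the seed entirely.
    """
    layout = population.layout
    h = DEFAULT_H
    forces = _render_forces(scenario, layout.n_sensors, h)
    if layout.adc is not None:
        levels = np.floor(forces / layout.adc.full_scale * layout.adc.levels + 0.5)
        forces = np.clip(levels, 0, layout.adc.levels)
    n_steps = forces.shape[1]

    qp = quantize_params(layout.params, h, layout.fmt).as_array()
    p = _kernels.float_param_vector(layout.params, h)
    model_id = _kernels.MODEL_IDS[layout.model]
    use_fixed = layout.arithmetic in ("fixed", "fixed-shift")
    if use_fixed and layout.fmt.total_bits > 32:
        raise ValueError("population kernels support register widths up to 32 bits")

    spikes = np.zeros(n_steps, dtype=np.uint8)
    # Empty trace buffers: population runs keep spike times only.
    trace_f = np.empty(0, dtype=np.float64)
    trace_raw = np.empty(0, dtype=np.int64)
    no_extra = np.zeros(0, dtype=np.float64)

    spike_times: List[np.ndarray] = []
    for unit in population.units:
        spec = unit.spec
        extra = no_extra
        if spec.noise_rate > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(unit.noise_seed,)))
            extra = _noise_pulses(n_steps, h, spec.noise_rate,
                                  spec.noise_amplitude, spec.noise_width, rng)
        f = forces[unit.sensor]
        fa = spec.afferent_type == "FA"
        spikes[:] = 0
        if use_fixed:
            _kernels.sim_fixed(model_id, fa, f, spec.gain_jitter, extra, qp,
                               layout.fmt.frac_bits, layout.fmt.raw_min,
                               layout.fmt.raw_max, trace_raw, spikes)
        else:
            _kernels.sim_float(model_id, fa, f, spec.gain_jitter, extra, p,
                               trace_f, spikes)
        spike_times.append((np.flatnonzero(spikes).astype(np.float64) + 1.0) * h)

    return SpikeRaster(unit_ids=[u.unit_id for u in population.units],
                       types=population.types, sensors=population.sensors,
                       spike_times=spike_times, duration=n_steps * h, h=h)
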