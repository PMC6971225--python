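"""Synthetic force stimuli: trapezoids, grid touch scenarios, haptic grasps.

No recorded force data ship with the package; every experiment is emulated:

* **Reference trapezoid** -- the 100-ms ramp-plateau-ramp indentation used to
  characterize the four spiking models.  Its amplitude is the one quantity the
  characterization never fixes numerically, so it is recovered by
  :func:`calibrate_reference_amplitude`: bisection on the plateau amplitude
  until the anchor model of each family (Izhikevich for the two-variable
  family, QIF for the one-variable family) reproduces its reference 100-ms
  average rate.  The non-anchor models of a family are then genuine
  consistency checks.
* **Grid scenarios** -- sequences of touch episodes on the 3x3 force-sensor
  grid: randomly chosen sensor subsets, with randomized amplitudes, ramp
  velocities and durations per episode.
* **Haptic grasp experiment** -- a five-sensor glove grasping three objects of
  increasing weight with 3, 4 or 5 fingers, 20 repetitions each: 180 labelled
  trials of 4 s (3 s hold) recorded from a 135-afferent population
  (50 SA-I + 85 FA-I), the input of the rate-coding decoder.

All times are in milliseconds, forces in mN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .afferent import ForceProfile
from .models import DEFAULT_H, SimConfig, simulate_trace
from .population import PopulationLayout, build_population, run_population

__all__ = [
    "TrapezoidSpec", "StimulusScenario", "HapticDesign", "TrialSet",
    "trapezoid", "grid_scenario", "haptic_dataset",
    "REFERENCE_TRAPEZOID", "REFERENCE_DURATION", "CALIBRATION_TARGETS_HZ",
    "MODEL_FAMILY", "reference_rate", "calibrate_reference_amplitude",
    "family_amplitudes",
]


@dataclass(frozen=True)
class TrapezoidSpec:
    """One ramp-plateau-ramp indentation episode (times ms, amplitude mN)."""

    t_on: float
    rise: float
    hold: float
    fall: float
    amplitude: float

    def __post_init__(self) -> None:
        for name in ("t_on", "rise", "hold", "fall"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if not (math.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ValueError("amplitude must be finite and >= 0")

    @property
    def t_end(self) -> float:
        return self.t_on + self.rise + self.hold + self.fall

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Exact piecewise-linear evaluation on a time grid (no smoothing)."""
        f = np.zeros_like(t)
        r0, r1 = self.t_on, self.t_on + self.rise
        h1 = r1 + self.hold
        f1 = h1 + self.fall
        if self.rise > 0:
            m = (t >= r0) & (t < r1)
            f[m] = self.amplitude * (t[m] - r0) / self.rise
        m = (t >= r1) & (t < h1)
        f[m] = self.amplitude
        if self.fall > 0:
            m = (t >= h1) & (t < f1)
            f[m] = self.amplitude * (f1 - t[m]) / self.fall
        return f


def trapezoid(spec: TrapezoidSpec, h: float = DEFAULT_H,
              duration: Optional[float] = None) -> ForceProfile:
    """Render a trapezoid episode as a uniformly sampled force profile."""
    if duration is None:
        duration = spec.t_end
    if spec.t_end > duration + 1e-9:
        raise ValueError(
            f"trapezoid ends at {spec.t_end} ms, beyond the {duration} ms window")
    n = int(round(duration / h))
    t = np.arange(n) * h
    return ForceProfile(f=spec.sample(t), h=h)


@dataclass(frozen=True)
class StimulusScenario:
    """Per-sensor lists of trapezoid episodes over a common duration."""

    n_sensors: int
    duration: float
    events: Tuple[Tuple[TrapezoidSpec, ...], ...]

    def __post_init__(self) -> None:
        if len(self.events) != self.n_sensors:
            raise ValueError("need one event list per sensor")
        for sensor, evs in enumerate(self.events):
            last_end = -math.inf
            for ev in sorted(evs, key=lambda e: e.t_on):
                if ev.t_end > self.duration + 1e-9:
                    raise ValueError(
                        f"episode on sensor {sensor} ends beyond the scenario")
                if ev.t_on < last_end - 1e-9:
                    raise ValueError(
                        f"overlapping episodes on sensor {sensor}")
                last_end = ev.t_end

    def render(self, h: float = DEFAULT_H) -> np.ndarray:
        """Force matrix of shape (n_sensors, n_steps)."""
        n = int(round(self.duration / h))
        t = np.arange(n) * h
        forces = np.zeros((self.n_sensors, n), dtype=np.float64)
        for sensor, evs in enumerate(self.events):
            for ev in evs:
                forces[sensor] += ev.sample(t)
        return forces


#: Default eight-episode touch sequence on the 3x3 grid (0-based sensors):
#: one, two or three sensors pressed per episode.
DEFAULT_GRID_PATTERN: Tuple[Tuple[int, ...], ...] = (
    (0,), (2, 4), (1,), (3, 5, 8), (3,), (5, 7), (7,), (0, 6))


def grid_scenario(pattern: Optional[Sequence[Sequence[int]]] = None,
                  n_sensors: int = 9, duration: float = 60_000.0,
                  seed: int = 0,
                  amplitude_range: Tuple[float, float] = (10.0, 40.0),
                  rise_range: Tuple[float, float] = (500.0, 2000.0),
                  hold_range: Tuple[float, float] = (1000.0, 3000.0),
                  fall_range: Tuple[float, float] = (500.0, 2000.0),
                  gap_range: Tuple[float, float] = (500.0, 1500.0),
                  start: float = 4000.0,
                  pin_demo_timing: Optional[bool] = None) -> StimulusScenario:
    """Compose a sequence of randomized touch episodes on the sensor grid.

    Episodes run one after another from ``start`` (the initial silence shows
    only background activity).  Durations, ramp velocities and amplitudes are
    drawn per episode from the given ranges; untouched sensors stay at zero.
    With the default pattern the first two episodes reproduce the documented
    demonstration timing: sensor S1 pressed from 4 s (2 s rise, 3.5 s hold,
    1 s fall), then S3+S5 together from 14 s (3 s rise, 2 s hold, 1 s fall)
    with more force on S3 than on S5.
    """
    if pin_demo_timing is None:
        pin_demo_timing = pattern is None
    if pattern is None:
        pattern = DEFAULT_GRID_PATTERN
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    events: List[List[TrapezoidSpec]] = [[] for _ in range(n_sensors)]
    t = start
    pinned = {0: (2000.0, 3500.0, 1000.0), 1: (3000.0, 2000.0, 1000.0)} \
        if pin_demo_timing else {}
    pinned_start = {1: 14_000.0} if pin_demo_timing else {}
    for idx, sensors in enumerate(pattern):
        for s in sensors:
            if not 0 <= s < n_sensors:
                raise ValueError(f"sensor {s} outside the {n_sensors}-sensor grid")
        t = max(t, pinned_start.get(idx, t))
        if idx in pinned:
            rise, hold, fall = pinned[idx]
        else:
            rise = rng.uniform(*rise_range)
            hold = rng.uniform(*hold_range)
            fall = rng.uniform(*fall_range)
        amps = sorted((rng.uniform(*amplitude_range) for _ in sensors),
                      reverse=True)
        for s, amp in zip(sensors, amps):
            events[s].append(TrapezoidSpec(t_on=t, rise=rise, hold=hold,
                                           fall=fall, amplitude=amp))
        t += rise + hold + fall + rng.uniform(*gap_range)
    if t > duration:
        raise ValueError(
            f"episode sequence ends at {t:.0f} ms, beyond the "
            f"{duration:.0f} ms scenario")
    return StimulusScenario(n_sensors=n_sensors, duration=duration,
                            events=tuple(tuple(e) for e in events))


# --------------------------------------------------------------------------
# Reference characterization and amplitude calibration
# --------------------------------------------------------------------------

#: Timing of the 100-ms reference trapezoid (plateau-dominated window).
REFERENCE_TRAPEZOID = dict(t_on=0.0, rise=10.0, hold=80.0, fall=10.0)
REFERENCE_DURATION = 100.0  # ms

#: 100-ms average rates that anchor the amplitude calibration, one per model
#: family: the Izhikevich model for the two-variable family (shared amplitude
#: with L-Izh) and the QIF model for the one-variable family (shared with
#: L-QIF).
CALIBRATION_TARGETS_HZ = {"izh": 760.0, "qif": 880.0}

#: Model -> family anchor.
MODEL_FAMILY = {"izh": "izh", "lizh": "izh", "qif": "qif", "lqif": "qif"}


def _reference_profile(amplitude: float, h: float) -> ForceProfile:
    spec = TrapezoidSpec(amplitude=amplitude, **REFERENCE_TRAPEZOID)
    return trapezoid(spec, h=h, duration=REFERENCE_DURATION)


def reference_rate(model: str, amplitude: float, h: float = DEFAULT_H,
                   arithmetic: str = "float",
                   afferent_type: str = "SA") -> float:
    """100-ms average firing rate (Hz) on the reference trapezoid."""
    profile = _reference_profile(amplitude, h)
    config = SimConfig(duration=REFERENCE_DURATION, h=h,
                       afferent_type=afferent_type, model=model)
    if arithmetic == "float":
        _, spikes = simulate_trace(config, None, profile.f)
    else:
        from .fixedpoint import simulate_trace_fixed
        _, spikes, _ = simulate_trace_fixed(
            config, None, profile.f, shift=(arithmetic == "fixed-shift"))
    return spikes.size / (REFERENCE_DURATION / 1000.0)


def calibrate_reference_amplitude(anchor_model: str = "izh",
                                  target_hz: Optional[float] = None,
                                  h: float = DEFAULT_H,
                                  max_amplitude: float = 4096.0) -> float:
    """Recover the reference-trapezoid amplitude by bisection.

    Returns the smallest amplitude at which the anchor model's SA-I 100-ms
    average rate reaches ``target_hz`` (spike counts are monotone
    non-decreasing in the plateau amplitude, so bisection is sound).  The
    procedure is deterministic; the result is the single calibration constant
    of the anchor's model family.
    """
    if target_hz is None:
        target_hz = CALIBRATION_TARGETS_HZ[anchor_model]
    target_spikes = int(round(target_hz * REFERENCE_DURATION / 1000.0))

    def count(amp: float) -> int:
        return int(round(reference_rate(anchor_model, amp, h)
                         * REFERENCE_DURATION / 1000.0))

    lo, hi = 0.0, 1.0
    while count(hi) < target_spikes:
        hi *= 2.0
        if hi > max_amplitude:
            raise RuntimeError(
                f"target rate {target_hz} Hz unreachable below amplitude "
                f"{max_amplitude}")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if count(mid) >= target_spikes:
            hi = mid
        else:
            lo = mid
    return hi


def family_amplitudes(h: float = DEFAULT_H) -> Dict[str, float]:
    """Calibrated reference amplitudes for both model families."""
    return {anchor: calibrate_reference_amplitude(anchor, h=h)
            for anchor in CALIBRATION_TARGETS_HZ}


# --------------------------------------------------------------------------
# Haptic grasp experiment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HapticDesign:
    """Design of the glove grasp experiment.

    Three objects of increasing weight are grasped with 3, 4 or 5 fingers,
    20 repetitions per combination: 180 labelled 4-s trials with a fixed 3-s
    hold.  The grip force of an object is shared equally among the engaged
    fingers and perturbed per finger by multiplicative lognormal noise with
    the configured coefficient of variation.  One five-sensor population of
    50 SA-I and 85 FA-I improved-L-QIF afferents (fixed-point, shift
    arithmetic) records every trial.
    """

    object_forces: Tuple[Tuple[str, float], ...] = (
        ("A", 25.0), ("B", 50.0), ("C", 100.0))  # total grip force, mN
    finger_conditions: Tuple[int, ...] = (3, 4, 5)
    repetitions: int = 20
    trial_duration: float = 4000.0
    hold_duration: float = 3000.0
    rise: float = 500.0
    fall: float = 500.0
    sa_per_sensor: int = 10
    fa_per_sensor: int = 17
    n_fingers: int = 5
    force_noise_cv: float = 0.2
    jitter_cv: float = 0.05

    def __post_init__(self) -> None:
        weights = [w for _, w in self.object_forces]
        if sorted(weights) != weights or len(set(weights)) != len(weights):
            raise ValueError("object forces must be strictly increasing (A < B < C)")
        if self.rise + self.hold_duration + self.fall > self.trial_duration + 1e-9:
            raise ValueError("grasp episode does not fit in the trial")
        if max(self.finger_conditions) > self.n_fingers:
            raise ValueError("finger condition exceeds the number of sensors")
        if self.repetitions < 1:
            raise ValueError("need at least one repetition")
        if self.force_noise_cv < 0:
            raise ValueError("force_noise_cv must be non-negative")

    @property
    def n_trials(self) -> int:
        return len(self.object_forces) * len(self.finger_conditions) * self.repetitions

    @property
    def sa_count(self) -> int:
        return self.n_fingers * self.sa_per_sensor

    @property
    def fa_count(self) -> int:
        return self.n_fingers * self.fa_per_sensor

    @property
    def n_units(self) -> int:
        return self.sa_count + self.fa_count

    def layout(self) -> PopulationLayout:
        return PopulationLayout(n_sensors=self.n_fingers,
                                sa_per_sensor=self.sa_per_sensor,
                                fa_per_sensor=self.fa_per_sensor,
                                jitter_cv=self.jitter_cv)


@dataclass
class TrialSet:
    """Labelled spike responses of a population over many trials."""

    labels: np.ndarray            # object label per trial
    conditions: np.ndarray        # engaged-finger count per trial
    unit_ids: List[str]
    unit_types: np.ndarray        # "SA"/"FA" per unit
    unit_sensors: np.ndarray
    spike_times: List[List[np.ndarray]]  # [trial][unit] -> ms
    duration: float
    h: float = DEFAULT_H

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.conditions) == len(self.spike_times)):
            raise ValueError("per-trial fields have inconsistent lengths")

    @property
    def n_trials(self) -> int:
        return len(self.labels)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def type_mask(self, type_filter: str) -> np.ndarray:
        if type_filter in ("both", "all"):
            return np.ones(self.n_units, dtype=bool)
        token = type_filter.upper().replace("-I", "")
        if token not in ("SA", "FA"):
            raise ValueError(f"unknown type filter {type_filter!r}")
        return self.unit_types == token

    def counts(self, window: Optional[Tuple[float, float]] = None,
               type_filter: str = "both") -> np.ndarray:
        """Spike-count matrix (n_trials x n_selected_units) in a window."""
        t0, t1 = window if window is not None else (0.0, self.duration)
        if not (0.0 <= t0 < t1 <= self.duration + 1e-9):
            raise ValueError(f"window ({t0}, {t1}) outside trial duration")
        mask = self.type_mask(type_filter)
        idx = np.flatnonzero(mask)
        out = np.empty((self.n_trials, idx.size), dtype=np.int64)
        for i, trial in enumerate(self.spike_times):
            for j, u in enumerate(idx):
                st = trial[u]
                out[i, j] = np.count_nonzero((st >= t0) & (st < t1))
        return out

    def save(self, path) -> None:
        """Serialize to a compressed NPZ bundle (lossless spike times)."""
        flat = []
        offsets = np.zeros(self.n_trials * self.n_units + 1, dtype=np.int64)
        k = 0
        for trial in self.spike_times:
            for st in trial:
                flat.append(st)
                k += 1
                offsets[k] = offsets[k - 1] + st.size
        flat_arr = (np.concatenate(flat) if flat else
                    np.zeros(0, dtype=np.float64))
        np.savez_compressed(
            path, labels=self.labels, conditions=self.conditions,
            unit_ids=np.array(self.unit_ids), unit_types=self.unit_types,
            unit_sensors=self.unit_sensors, spikes=flat_arr, offsets=offsets,
            duration=np.float64(self.duration), h=np.float64(self.h))

    @classmethod
    def load(cls, path) -> "TrialSet":
        with np.load(path, allow_pickle=False) as data:
            labels = data["labels"].astype(str)
            conditions = data["conditions"].astype(np.int64)
            unit_ids = [str(u) for u in data["unit_ids"]]
            unit_types = data["unit_types"].astype(str)
            unit_sensors = data["unit_sensors"].astype(np.int64)
            flat = data["spikes"]
            offsets = data["offsets"]
            duration = float(data["duration"])
            h = float(data["h"])
        n_units = len(unit_ids)
        spike_times = []
        k = 0
        for _ in range(len(labels)):
            trial = []
            for _ in range(n_units):
                trial.append(flat[offsets[k]:offsets[k + 1]])
                k += 1
            spike_times.append(trial)
        return cls(labels=labels, conditions=conditions, unit_ids=unit_ids,
                   unit_types=unit_types, unit_sensors=unit_sensors,
                   spike_times=spike_times, duration=duration, h=h)


def haptic_dataset(design: HapticDesign = HapticDesign(),
                   seed: int = 0) -> TrialSet:
    """Simulate the full haptic grasp experiment.

    For every trial the engaged fingers (always starting from the thumb,
    i.e. sensors 0..k-1) receive a trapezoid whose plateau equals the object
    grip force divided by the engaged-finger count, perturbed per finger by
    lognormal noise with ``design.force_noise_cv``; disengaged fingers stay at
    zero.  The five-sensor, 135-afferent population then produces the
    labelled rasters.  Deterministic per seed.
    """
    layout = design.layout()
    population = build_population(layout, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1001,)))
    sigma = math.sqrt(math.log(1.0 + design.force_noise_cv ** 2)) \
        if design.force_noise_cv > 0 else 0.0

    n_steps = int(round(design.trial_duration / DEFAULT_H))
    t = np.arange(n_steps) * DEFAULT_H

    labels: List[str] = []
    conditions: List[int] = []
    spike_times: List[List[np.ndarray]] = []
    for obj, force in design.object_forces:
        for fingers in design.finger_conditions:
            base = TrapezoidSpec(t_on=0.0, rise=design.rise,
                                 hold=design.hold_duration, fall=design.fall,
                                 amplitude=1.0)
            unit_shape = base.sample(t)
            for _ in range(design.repetitions):
                forces = np.zeros((design.n_fingers, n_steps), dtype=np.float64)
                share = force / fingers
                for finger in range(fingers):
                    amp = share
                    if sigma > 0:
                        amp *= float(np.exp(rng.normal(-0.5 * sigma * sigma,
                                                       sigma)))
                    forces[finger] = amp * unit_shape
                raster = run_population(population, forces, seed=seed)
                labels.append(obj)
                conditions.append(fingers)
                spike_times.append(raster.spike_times)

    return TrialSet(labels=np.array(labels), conditions=np.array(conditions),
                    unit_ids=[u.unit_id for u in population.units],
                    unit_types=population.types,
                    unit_sensors=population.sensors, spike_times=spike_times,
                    duration=design.trial_duration, h=DEFAULT_H)
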