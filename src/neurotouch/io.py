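"""File round-tripping for the standard artifact formats.

Force series travel as two-column CSV (``time_ms,value``); spike trains as
``afferent_id,spike_time_ms`` CSV; full population rasters as long-format CSV
(``afferent_id,type,sensor,spike_time_ms``) or lossless NPZ.  Spike times are
written at full double precision -- they are exact multiples of the step h,
so round trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .afferent import ForceProfile
from .models import DEFAULT_H
from .population import SpikeRaster

__all__ = [
    "write_force_csv", "read_force_csv",
    "write_spike_csv", "read_spike_csv",
    "write_raster_csv", "save_raster_npz", "load_raster_npz",
    "write_trace_csv",
    "dump_yaml", "load_yaml",
]


def write_force_csv(path, profile: ForceProfile) -> None:
    pd.DataFrame({"time_ms": profile.t, "value": profile.f}).to_csv(
        path, index=False)


def read_force_csv(path) -> ForceProfile:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise ValueError("force CSV needs at least two samples")
    steps = np.diff(t)
    h = float(steps[0])
    if not np.allclose(steps, h, rtol=0, atol=1e-9 * max(h, 1.0)):
        raise ValueError("force CSV is not uniformly sampled")
    return ForceProfile(f=df["value"].to_numpy(dtype=np.float64), h=h)


def write_spike_csv(path, spike_times: np.ndarray, afferent_id: str = "A1") -> None:
    pd.DataFrame({"afferent_id": [afferent_id] * len(spike_times),
                  "spike_time_ms": spike_times}).to_csv(path, index=False)


def read_spike_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_raster_csv(path, raster: SpikeRaster) -> None:
    raster.to_dataframe().to_csv(path, index=False)


def save_raster_npz(path, raster: SpikeRaster) -> None:
    flat = (np.concatenate(raster.spike_times) if raster.n_units else
            np.zeros(0))
    offsets = np.zeros(raster.n_units + 1, dtype=np.int64)
    for i, st in enumerate(raster.spike_times):
        offsets[i + 1] = offsets[i] + st.size
    np.savez_compressed(path, unit_ids=np.array(raster.unit_ids),
                        types=raster.types, sensors=raster.sensors,
                        spikes=flat, offsets=offsets,
                        duration=np.float64(raster.duration),
                        h=np.float64(raster.h))


def load_raster_npz(path) -> SpikeRaster:
    with np.load(path, allow_pickle=False) as data:
        unit_ids = [str(u) for u in data["unit_ids"]]
        types = data["types"].astype(str)
        sensors = data["sensors"].astype(np.int64)
        flat = data["spikes"]
        offsets = data["offsets"]
        duration = float(data["duration"])
        h = float(data["h"])
    spike_times = [flat[offsets[i]:offsets[i + 1]] for i in range(len(unit_ids))]
    return SpikeRaster(unit_ids=unit_ids, types=types, sensors=sensors,
                       spike_times=spike_times, duration=duration, h=h)


def write_trace_csv(path, trace: np.ndarray, h: float = DEFAULT_H) -> None:
    pd.DataFrame({"time_ms": (np.arange(len(trace)) + 1) * h,
                  "v_mV": trace}).to_csv(path, index=False)


def dump_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
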