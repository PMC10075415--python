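"""CSV and config readers/writers for all artifacts.

Everything is plain CSV (tracks, loop tables, flower fields, discovery
profiles, fit tables) or flat YAML/JSON config — small, diff-able files.
"""

from __future__ import annotations


from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .environment import FlowerField
from .motion import Loop, Track
from .observables import loop_observables
from .params import ModelParams

__all__ = [
    "write_track_csv", "read_track_csv",
    "write_loop_table", "write_field_csv", "read_field_csv",
    "write_profile_csv", "load_config", "save_config",
]


def write_track_csv(track: Track, path) -> None:
    """Track CSV with header ``t,x,y`` (seconds, metres, nest at origin)."""
    df = pd.DataFrame({"t": track.times,
                       "x": track.positions[:, 0],
                       "y": track.positions[:, 1]})
    df.to_csv(path, index=False, float_format="%.6f")


def read_track_csv(path, sampling_interval: float | None = None) -> Track:
    df = pd.read_csv(path)
    times = df["t"].to_numpy(dtype=float)
    if sampling_interval is None:
        sampling_interval = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    return Track(times=times,
                 positions=df[["x", "y"]].to_numpy(dtype=float),
                 sampling_interval=sampling_interval)


def write_loop_table(loops: Sequence[Loop], nest, path) -> None:
    """One row per loop: id, size, the four observables, censoring flag."""
    rows = []
    for i, loop in enumerate(loops):
        obs = loop_observables(loop, nest)
        rows.append({
            "loop_id": i,
            "n_points": len(loop),
            "length_m": obs.loop_length,
            "extension_m": obs.loop_extension,
            "intersections_per100m": obs.intersections_per_100m,
            "redepartures_per100m": obs.redepartures_per_100m,
            "censored": loop.censored,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def write_field_csv(field: FlowerField, path) -> None:
    df = pd.DataFrame({
        "flower_id": np.arange(field.n_flowers),
        "x": field.positions[:, 0],
        "y": field.positions[:, 1],
        "diameter": field.flower_diameter,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_field_csv(path, density: float = float("nan"),
                   extent: float = float("nan")) -> FlowerField:
    df = pd.read_csv(path)
    diameter = float(df["diameter"].iloc[0]) if len(df) else 0.0
    return FlowerField(positions=df[["x", "y"]].to_numpy(dtype=float),
                       flower_diameter=diameter, density=density,
                       extent=extent)


def write_profile_csv(profile, path) -> None:
    df = pd.DataFrame({
        "bin_lo": profile.bin_edges[:-1],
        "bin_hi": profile.bin_edges[1:],
        "p_discovery": profile.probability,
        "n_flowers": profile.n_flowers,
    })
    df.to_csv(path, index=False)


_CONFIG_EXTRA_KEYS = {"seed", "out", "verbosity"}


def load_config(path) -> dict:
    """Load a flat YAML/JSON config; split into (ModelParams, extras).

    Returns a dict with key ``params`` (a :class:`ModelParams`) plus any of
    the run-level keys (seed, out, verbosity).  Unknown keys are rejected.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat mapping")
    extras = {k: data.pop(k) for k in list(data) if k in _CONFIG_EXTRA_KEYS}
    params = ModelParams.from_dict(data)  # rejects unknown keys
    return {"params": params, **extras}


def save_config(params: ModelParams, path, **extras) -> None:
    data = {**params.to_dict(), **extras}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
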