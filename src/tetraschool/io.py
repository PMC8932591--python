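"""Configuration files and trajectory/observable serialization.

Configurations are flat YAML or JSON documents with all physical values in
metres and seconds; unknown keys are rejected so that typos fail loudly.
Trajectories are written as plain CSV with a JSON metadata sidecar carrying
the full configuration echo and seed, which is enough to regenerate the run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kernel import InteractionParams
from .kinematics import KickStatistics
from .observables import ObservableSeries
from .simulator import SimulationConfig, TrajectoryRecord

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "write_trajectory_csv",
    "write_observables_csv",
]

_PARAM_KEYS = {f.name for f in dataclasses.fields(InteractionParams)}
_KICK_KEYS = {f.name for f in dataclasses.fields(KickStatistics)}
_TOP_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)} - {"params", "kick_stats"}


def config_to_dict(config: SimulationConfig) -> dict:
    """Flat dictionary representation of a configuration."""
    out = {k: getattr(config, k) for k in sorted(_TOP_KEYS)}
    out.update({k: getattr(config.params, k) for k in sorted(_PARAM_KEYS)})
    out.update({k: getattr(config.kick_stats, k) for k in sorted(_KICK_KEYS)})
    return out


def config_from_dict(doc: dict) -> SimulationConfig:
    """Build a configuration from a flat dictionary, rejecting unknown keys."""
    doc = dict(doc)
    unknown = set(doc) - _TOP_KEYS - _PARAM_KEYS - _KICK_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    params = InteractionParams(**{k: doc.pop(k) for k in list(doc) if k in _PARAM_KEYS})
    kick = KickStatistics(**{k: doc.pop(k) for k in list(doc) if k in _KICK_KEYS})
    return SimulationConfig(params=params, kick_stats=kick, **doc)


def load_config(path) -> SimulationConfig:
    """Read a YAML (.yaml/.yml) or JSON (.json) configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config_from_dict(doc)


def save_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    doc = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


def write_trajectory_csv(record: TrajectoryRecord, path) -> None:
    """Write snapshots and kick events to CSV plus a JSON metadata sidecar.

    Columns: ``time,fish_id,x,y,heading,speed,event_type`` with event_type
    "snapshot" or "kick"; kick rows carry the post-kick state columns where
    they are defined and NaN otherwise.
    """
    path = Path(path)
    frames = []
    n_t, n = record.headings.shape
    frames.append(pd.DataFrame({
        "time": np.repeat(record.times, n),
        "fish_id": np.tile(np.arange(n), n_t),
        "x": record.positions[:, :, 0].ravel(),
        "y": record.positions[:, :, 1].ravel(),
        "heading": record.headings.ravel(),
        "speed": record.speeds.ravel(),
        "event_type": "snapshot",
    }))
    if record.kick_time is not None:
        frames.append(pd.DataFrame({
            "time": record.kick_time,
            "fish_id": record.kick_fish,
            "x": np.nan,
            "y": np.nan,
            "heading": np.nan,
            "speed": np.nan,
            "event_type": "kick",
        }))
    df = pd.concat(frames, ignore_index=True).sort_values(
        ["time", "event_type", "fish_id"], kind="stable"
    )
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({
        "config": config_to_dict(record.config),
        "seed": record.config.seed,
        "code_version": __version__,
    }, indent=2, default=str))


def write_observables_csv(series: ObservableSeries, path) -> None:
    """Write an observable time series as ``time,D,P,M`` CSV."""
    pd.DataFrame({
        "time": series.times,
        "D": series.dispersion,
        "P": series.polarization,
        "M": series.milling,
    }).to_csv(Path(path), index=False)
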