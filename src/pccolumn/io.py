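"""Run configuration, serialization and result bundles.

A :class:`RunConfig` gathers every knob of a run under a single top-level
seed and round-trips through YAML; unknown keys are rejected so stale
configs fail loudly.  Result bundles write traces to HDF5, tables to CSV,
reconstructions to PNG (plus CSV) and a JSON manifest carrying the config
copy, the frozen motif, the seed and versions, under file names that are
deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml
from PIL import Image

from .dynamics import DynamicsParams
from .metrics import SimulationTrace
from .microcircuit import CellType, MotifSpec
from .network import Network, NetworkConfig
from .plasticity import LearningConfig
from .protocols import ProtocolConfig
from .stimuli import NoiseConfig

__all__ = [
    "DatasetConfig",
    "RunConfig",
    "load_config",
    "save_results",
    "save_trace",
    "load_trace",
    "save_weights",
    "load_weights",
]


@dataclass
class DatasetConfig:
    """Synthetic-dataset parameters used by the training subcommand."""

    kind: str = "lowrank"
    n: int = 16
    side: int = 8
    k: int = 4
    n_holdout: int = 4


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs"
    motif_source: str = "default"  # "default", "search:first-valid" or a YAML path
    network: NetworkConfig = field(default_factory=NetworkConfig)
    learning: LearningConfig = field(default_factory=LearningConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)


_LEAF_TYPES = (DynamicsParams,)


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or cls.__name__} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        sub = f"{path}.{name}" if path else name
        ftype = f.type if isinstance(f.type, type) else None
        default = getattr(cls, name, None)
        # nested dataclasses are declared via default_factory
        factory = f.default_factory if f.default_factory is not dataclasses.MISSING else None
        if factory is not None and dataclasses.is_dataclass(factory):
            kwargs[name] = _build_dataclass(factory, value, sub)
        elif name == "silenced":
            kwargs[name] = frozenset(CellType(str(v)) for v in value)
        elif name in ("tau_grid", "noise_grid"):
            kwargs[name] = tuple(float(v) for v in value)
        elif name == "motif":
            kwargs[name] = None if value is None else MotifSpec.from_dict(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config at {path or cls.__name__}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults fill omissions,
    unknown keys and invalid values are rejected naming the field."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build_dataclass(RunConfig, data, "")


def config_to_dict(config) -> dict:
    """Dataclass tree to plain-JSON-safe dict."""

    def conv(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            if isinstance(x, MotifSpec):
                return x.to_dict()
            return {f.name: conv(getattr(x, f.name)) for f in dataclasses.fields(x)}
        if isinstance(x, frozenset):
            return sorted(v.value if isinstance(v, CellType) else v for v in x)
        if isinstance(x, tuple):
            return list(x)
        if isinstance(x, np.generic):
            return x.item()
        return x

    return conv(config)


def config_hash(config) -> str:
    payload = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def save_trace(trace: SimulationTrace, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=trace.t)
        grp = f.create_group("rates")
        for name, series in trace.series.items():
            grp.create_dataset(name, data=series)


def load_trace(path) -> SimulationTrace:
    with h5py.File(path, "r") as f:
        t = f["t"][:]
        series = {name: f["rates"][name][:] for name in f["rates"]}
    return SimulationTrace(t, series)


def save_weights(network: Network, path) -> None:
    """Weights and final state to HDF5 (datasets /W and /rates/<pop>)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=network.W)
        grp = f.create_group("rates")
        for name, rates in network.state_dict().populations.items():
            grp.create_dataset(name, data=rates)
        f.attrs["motif"] = yaml.safe_dump(network.motif.to_dict())
        f.attrs["feedback_scale"] = network.feedback_scale


def load_weights(path, config: NetworkConfig) -> Network:
    with h5py.File(path, "r") as f:
        W = f["W"][:]
        motif = MotifSpec.from_dict(yaml.safe_load(f.attrs["motif"]))
        feedback_scale = float(f.attrs["feedback_scale"])
    net = Network(config, motif, W)
    net.feedback_scale = feedback_scale
    return net


def save_results(bundle: dict, directory) -> list[Path]:
    """Write a result bundle and return the created paths.

    ``bundle`` may contain ``traces`` (name -> SimulationTrace), ``tables``
    (name -> DataFrame), ``images`` (name -> 2-D array in [0, 1]),
    ``network`` and ``manifest`` (JSON-safe dict; a config hash, the motif
    in use and wall time are added).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    prefix = ""
    manifest = dict(bundle.get("manifest", {}))
    if "config" in manifest:
        prefix = config_hash(manifest["config"]) + "_"
    for name, trace in bundle.get("traces", {}).items():
        p = directory / f"{prefix}{name}.h5"
        save_trace(trace, p)
        written.append(p)
    for name, table in bundle.get("tables", {}).items():
        p = directory / f"{prefix}{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    for name, img in bundle.get("images", {}).items():
        arr = np.asarray(img, dtype=float)
        png = directory / f"{prefix}{name}.png"
        Image.fromarray(np.uint8(np.clip(arr, 0, 1) * 255)).save(png)
        written.append(png)
        csv = directory / f"{prefix}{name}.csv"
        np.savetxt(csv, arr, delimiter=",")
        written.append(csv)
    if "network" in bundle:
        p = directory / f"{prefix}weights.h5"
        save_weights(bundle["network"], p)
        written.append(p)
    manifest.setdefault("wall_time", time.strftime("%Y-%m-%dT%H:%M:%S"))
    p = directory / f"{prefix}manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(p)
    return written
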