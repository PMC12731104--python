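"""Container I/O: HDF5 epochs, montage/scheme/adjacency text files and run
manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import yaml

from .montage import Montage, PartitionScheme
from .preprocessing import EpochedEEG

__all__ = ["SchemaError", "read_epochs", "write_epochs", "read_montage",
           "write_montage", "read_scheme", "write_scheme",
           "write_adjacency", "read_adjacency", "write_manifest"]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    pass


def write_epochs(epochs: EpochedEEG, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["channel_names"] = list(epochs.channel_names)
        f.attrs["class_names"] = list(epochs.class_names)
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_epochs(path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        for ds in ("data", "labels"):
            if ds not in f:
                raise SchemaError(f"epochs file missing dataset {ds!r}")
        for attr in ("fs", "channel_names"):
            if attr not in f.attrs:
                raise SchemaError(f"epochs file missing attribute {attr!r}")
        version = int(f.attrs.get("schema_version", 1))
        if version > SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema version {version}")
        data = f["data"][()]
        labels = f["labels"][()]
        fs = float(f.attrs["fs"])
        names = tuple(str(n) for n in f.attrs["channel_names"])
        class_names = tuple(
            str(n) for n in f.attrs.get(
                "class_names", ("left_hand", "right_hand", "feet", "tongue")))
    if data.ndim != 3 or len(names) != data.shape[1]:
        raise SchemaError(
            "channel-name count does not match data channel dimension")
    return EpochedEEG(data, fs, labels, names, class_names)


def write_montage(montage: Montage, path) -> None:
    lines = ["label\tx\ty\tz"]
    for name, (x, y, z) in zip(montage.channel_names, montage.coords):
        lines.append(f"{name}\t{x:.10g}\t{y:.10g}\t{z:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_montage(path) -> Montage:
    names, coords = [], []
    lines = Path(path).read_text().strip().splitlines()
    if not lines or lines[0].split("\t")[0] != "label":
        raise SchemaError("montage file must start with a 'label\\tx\\ty\\tz' header")
    for line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != 4:
            raise SchemaError(f"malformed montage row: {line!r}")
        names.append(parts[0])
        coords.append([float(v) for v in parts[1:]])
    return Montage(tuple(names), np.array(coords))


def write_scheme(scheme: PartitionScheme, path) -> None:
    doc = {"name": scheme.name,
           "partitions": {pid: list(chans)
                          for pid, chans in scheme.partitions}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scheme(path) -> PartitionScheme:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "partitions" not in doc:
        raise SchemaError("scheme file must contain a 'partitions' mapping")
    parts = tuple((pid, tuple(chans))
                  for pid, chans in doc["partitions"].items())
    return PartitionScheme(str(doc.get("name", Path(path).stem)), parts)


def write_adjacency(labels, values: np.ndarray, path) -> None:
    labels = list(labels)
    lines = ["\t".join([""] + labels)]
    for name, row in zip(labels, np.asarray(values, dtype=float)):
        lines.append("\t".join([name] + [f"{v:.10g}" for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_adjacency(path) -> tuple[list[str], np.ndarray]:
    lines = [l for l in Path(path).read_text().splitlines() if l]
    labels = lines[0].split("\t")[1:]
    values = np.array([[float(v) for v in line.split("\t")[1:]]
                       for line in lines[1:]])
    return labels, values


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seed: int | None,
                   inputs=()) -> Path:
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
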