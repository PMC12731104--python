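"""Electrode geometry and the task-driven four-partition scheme.

The 22-channel montage used throughout is the central 10-20/10-10 grid
(Fz..POz).  Positions are idealized points on a unit sphere obtained by an
inverse azimuthal-equidistant projection of the flat electrode grid; only
relative distances matter downstream (the Gaussian kernel bandwidth is the
median pairwise distance, so any consistent rescaling of the montage is
equivalent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "PartitionScheme",
    "OverlapIndex",
    "SchemeValidationError",
    "builtin_montage_22",
    "builtin_scheme_dataset_a",
    "overlap_index",
    "validate_scheme",
]


class SchemeValidationError(ValueError):
    """Raised when a partition scheme is inconsistent with its montage."""

    def __init__(self, message: str, offending: list[str] | None = None):
        super().__init__(message)
        self.offending = offending or []


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels with 3-D head-frame positions."""

    channel_names: tuple[str, ...]
    coords: np.ndarray  # (N, 3)

    def __post_init__(self):
        names = self.channel_names
        if len(names) < 2:
            raise ValueError("montage needs at least 2 channels")
        if len(set(names)) != len(names) or any(not n for n in names):
            raise ValueError("channel names must be unique and non-empty")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(names), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(names)} channels"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("montage coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    def index_of(self, names) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.channel_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"channels not in montage: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def subset_coords(self, names) -> np.ndarray:
        return self.coords[self.index_of(names)]


@dataclass(frozen=True)
class PartitionScheme:
    """Named, ordered collection of exactly four labelled channel subsets."""

    name: str
    partitions: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        if len(self.partitions) != 4:
            raise ValueError("a partition scheme holds exactly 4 partitions")

    @property
    def partition_names(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.partitions)

    def members(self, pid: str) -> tuple[str, ...]:
        for p, chans in self.partitions:
            if p == pid:
                return chans
        raise KeyError(pid)

    def union(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, chans in self.partitions:
            for c in chans:
                seen.setdefault(c)
        return tuple(seen)


@dataclass(frozen=True)
class OverlapIndex:
    membership: dict[str, frozenset[str]]
    multiplicity: dict[str, int] = field(default_factory=dict)

    def channels_with_multiplicity(self, k: int) -> set[str]:
        return {c for c, m in self.multiplicity.items() if m == k}


# Flat-grid coordinates (column, row) for the central 10-10 electrodes.
# Columns: z-line = 0, odd numbers left (negative), even right; rows front
# (positive y) to back.  One grid unit corresponds to a 10% arc (pi/10 rad).
_GRID: dict[str, tuple[float, float]] = {
    "Fz": (0, 2),
    "FC3": (-2, 1), "FC1": (-1, 1), "FCz": (0, 1), "FC2": (1, 1), "FC4": (2, 1),
    "C5": (-3, 0), "C3": (-2, 0), "C1": (-1, 0), "Cz": (0, 0),
    "C2": (1, 0), "C4": (2, 0), "C6": (3, 0),
    "CP3": (-2, -1), "CP1": (-1, -1), "CPz": (0, -1), "CP2": (1, -1), "CP4": (2, -1),
    "P1": (-1, -2), "Pz": (0, -2), "P2": (1, -2),
    "POz": (0, -3),
}

_ARC_PER_UNIT = math.pi / 10.0


def _grid_to_sphere(col: float, row: float) -> tuple[float, float, float]:
    r = math.hypot(col, row)
    theta = r * _ARC_PER_UNIT  # inclination from the vertex (Cz)
    if r == 0:
        return (0.0, 0.0, 1.0)
    s = math.sin(theta) / r
    return (col * s, row * s, math.cos(theta))


def builtin_montage_22() -> Montage:
    """Idealized unit-sphere montage for the 22 central electrodes."""
    names = tuple(_GRID)
    coords = np.array([_grid_to_sphere(*_GRID[n]) for n in names])
    return Montage(names, coords)


_DATASET_A_PARTITIONS = (
    ("P1", ("FC3", "FC1", "C5", "C3", "C1", "CP3", "CP1")),
    ("P2", ("Fz", "FC1", "FCz", "FC2", "C1", "Cz", "C2", "CP1", "CPz", "CP2")),
    ("P3", ("FC2", "FC4", "C6", "C4", "C2", "CP4", "CP2")),
    ("P4", ("POz", "P1", "Pz", "P2", "C1", "Cz", "C2", "CP1", "CPz", "CP2")),
)


def builtin_scheme_dataset_a() -> PartitionScheme:
    """The built-in four-partition scheme over the 22-channel montage."""
    return PartitionScheme("dataset_a", _DATASET_A_PARTITIONS)


def overlap_index(scheme: PartitionScheme) -> OverlapIndex:
    """Per-channel partition membership and multiplicity.

    Pure function of the scheme's set structure: channel order inside a
    partition is irrelevant.
    """
    membership: dict[str, set[str]] = {}
    for pid, chans in scheme.partitions:
        for c in chans:
            membership.setdefault(c, set()).add(pid)
    frozen = {c: frozenset(s) for c, s in membership.items()}
    mult = {c: len(s) for c, s in frozen.items()}
    return OverlapIndex(frozen, mult)


def validate_scheme(scheme: PartitionScheme, montage: Montage) -> dict:
    """Check a scheme against a montage.

    Returns a report dict with per-partition sizes; raises
    :class:`SchemeValidationError` naming offending channels or partitions.
    """
    known = set(montage.channel_names)
    unknown: list[str] = []
    empty: list[str] = []
    sizes: dict[str, int] = {}
    for pid, chans in scheme.partitions:
        sizes[pid] = len(chans)
        if len(chans) == 0:
            empty.append(pid)
        unknown.extend(c for c in chans if c not in known)
    if empty:
        raise SchemeValidationError(
            f"empty partitions: {empty}", offending=empty
        )
    if unknown:
        raise SchemeValidationError(
            f"channels not in montage: {sorted(set(unknown))}",
            offending=sorted(set(unknown)),
        )
    union = scheme.union()
    return {
        "scheme": scheme.name,
        "sizes": sizes,
        "n_distinct": len(union),
        "covers_montage": set(union) == known,
        "valid": True,
    }
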