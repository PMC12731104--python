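"""Spatial graph construction: Gaussian-median-distance adjacency, the
partition graph filter, cosine-similarity adjacency and shared normalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Montage, PartitionScheme

__all__ = [
    "GMDParams",
    "GraphFilter",
    "GraphError",
    "pairwise_distances",
    "gmd_delta",
    "gmd_adjacency",
    "ised_adjacency",
    "gaussian_filter",
    "apply_filter",
    "cosine_adjacency",
    "sym_normalize",
    "partition_filters",
]


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class GMDParams:
    """Gaussian kernel bandwidth: delta is the median pairwise electrode
    distance (delta^2 plays the role of 4 l^2 for correlation length l)."""

    delta: float

    def __post_init__(self):
        if not self.delta > 0:
            raise GraphError("delta must be positive")


@dataclass(frozen=True)
class GraphFilter:
    labels: tuple[str, ...]
    operator: np.ndarray  # (N, N); rows sum to 0 for self-looped input


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def gmd_delta(coords: np.ndarray) -> GMDParams:
    """Median of Euclidean distances over all unordered electrode pairs."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise GraphError("need at least 2 electrodes")
    d = pairwise_distances(coords)
    iu = np.triu_indices(coords.shape[0], k=1)
    delta = float(np.median(d[iu]))
    if delta == 0:
        raise GraphError("coincident electrodes: median pair distance is 0")
    return GMDParams(delta)


def gmd_adjacency(coords: np.ndarray, params: GMDParams | None = None,
                  labels=None, cutoff: bool = True) -> np.ndarray:
    """Gaussian-median-distance adjacency.

    Entry rule: 1 at zero distance, exp(-d^2/delta^2) for 0 < d <= delta,
    and exactly 0 beyond delta (hard sparsification; disable with
    ``cutoff=False``).
    """
    if params is None:
        params = gmd_delta(coords)
    d = pairwise_distances(coords)
    a = np.exp(-(d ** 2) / params.delta ** 2)
    a[d == 0] = 1.0
    if cutoff:
        a[d > params.delta] = 0.0
    return a


def ised_adjacency(coords: np.ndarray) -> np.ndarray:
    """Inverse-square-Euclidean-distance comparator: w = 1/d^2, diagonal 1.

    No cutoff: every distinct pair keeps a nonzero weight.
    """
    d = pairwise_distances(coords)
    with np.errstate(divide="ignore"):
        a = 1.0 / d ** 2
    a[d == 0] = 1.0
    return a


def gaussian_filter(adjacency: np.ndarray, labels=None) -> GraphFilter:
    """Random-walk Laplacian filter F = I - D_out^{-1} A.

    For a self-looped nonnegative adjacency every row degree is positive and
    F annihilates constant signals (rows sum to zero).
    """
    a = np.asarray(adjacency, dtype=float)
    deg = a.sum(axis=1)
    if np.any(deg <= 0):
        raise GraphError("zero row degree in adjacency")
    f = np.eye(a.shape[0]) - a / deg[:, None]
    lab = tuple(labels) if labels is not None else tuple(
        f"n{i}" for i in range(a.shape[0]))
    return GraphFilter(lab, f)


def apply_filter(filt: GraphFilter, x: np.ndarray, labels=None) -> np.ndarray:
    """Apply F along the channel axis of (..., channels, samples) data."""
    if labels is not None and tuple(labels) != filt.labels:
        raise GraphError(
            f"channel labels do not match filter: {list(labels)} vs "
            f"{list(filt.labels)}"
        )
    x = np.asarray(x, dtype=float)
    if x.shape[-2] != filt.operator.shape[0]:
        raise GraphError("channel dimension does not match filter")
    return filt.operator @ x


def cosine_adjacency(features: np.ndarray, clamp: str = "relu") -> np.ndarray:
    """Pairwise cosine similarity of node feature rows.

    Negative similarities are clamped to 0 (``clamp='relu'``, default) or
    replaced by their absolute value (``clamp='abs'``) so degree
    normalization stays well-defined.
    """
    x = np.asarray(features, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise GraphError(f"zero-norm feature row at node index {zero[0]}")
    xn = x / norms[:, None]
    a = xn @ xn.T
    a = np.clip(a, -1.0, 1.0)
    if clamp == "relu":
        a = np.maximum(a, 0.0)
    elif clamp == "abs":
        a = np.abs(a)
    else:
        raise ValueError(f"unknown clamp mode {clamp!r}")
    return a


def sym_normalize(a: np.ndarray) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} with degrees the row sums of A + I."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise GraphError("sym_normalize expects nonnegative entries")
    at = a + np.eye(a.shape[0])
    d = at.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return dinv[:, None] * at * dinv[None, :]


def partition_filters(scheme: PartitionScheme, montage: Montage,
                      cutoff: bool = True) -> dict[str, GraphFilter]:
    """GMD graph filter for every partition of a scheme.

    delta is recomputed per partition from that partition's electrode
    geometry (static across trials).
    """
    out: dict[str, GraphFilter] = {}
    for pid, chans in scheme.partitions:
        coords = montage.subset_coords(chans)
        a = gmd_adjacency(coords, gmd_delta(coords), cutoff=cutoff)
        out[pid] = gaussian_filter(a, labels=chans)
    return out
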