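"""The three-branch network: local temporal-graph branch, partition branch
with overlap-averaged fusion, and a residual global graph branch with a
dynamic cosine-similarity adjacency, followed by a two-layer classifier.

Node features entering graph layers are the per-electrode convolutional
feature maps, average-pooled along time to ``feature_frames`` frames and
flattened (conv-channels x frames); this keeps the parameter budget near
the half-million mark at the default configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, avgpool_to, concat, softmax_cross_entropy
from .graphs import gaussian_filter, gmd_adjacency, gmd_delta, ised_adjacency
from .layers import BatchNorm1d, Conv1d, Dropout, Linear, MaxPool1d
from .montage import Montage, PartitionScheme, overlap_index

__all__ = ["ModelConfig", "AblationSpec", "FeatureMap", "LPGGNet",
           "loss", "softmax"]


@dataclass(frozen=True)
class ModelConfig:
    n_classes: int = 4
    kernel1_len: int = 85
    kernel2_len: int = 30
    conv_channels: tuple[int, int] = (16, 32)
    pool_len: int = 2
    gcn_hidden: int = 128
    fc_hidden: int = 64
    feature_frames: int = 4
    dropout: float = 0.5
    K: int = 1  # first-order Chebyshev receptive field; fixed
    cosine_clamp: str = "relu"
    shared_global_adjacency: bool = False

    def __post_init__(self):
        if self.kernel1_len < 1 or self.kernel2_len < 1:
            raise ValueError("kernel lengths must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.K != 1:
            raise ValueError("only the K=1 first-order update is supported")


@dataclass(frozen=True)
class AblationSpec:
    use_local: bool = True
    use_partition: bool = True
    use_global: bool = True
    local_adjacency: str = "pdc"       # "pdc" | "pearson"
    partition_metric: str = "gmd"      # "gmd" | "ised"
    use_partitioning: bool = True
    use_residual: bool = True

    def __post_init__(self):
        if not (self.use_local or self.use_partition or self.use_global):
            raise ValueError("at least one branch must be enabled")


@dataclass
class FeatureMap:
    """Per-node feature tensor (trials x nodes x features) with node labels."""
    values: Tensor
    labels: tuple[str, ...]


class _TemporalBlock:
    """Two valid 1-D convolutions along time with BN + ReLU, and max pooling
    after each convolution only when ``with_pool``."""

    def __init__(self, cfg: ModelConfig, with_pool: bool,
                 rng: np.random.Generator):
        c1, c2 = cfg.conv_channels
        self.conv1 = Conv1d(1, c1, cfg.kernel1_len, rng)
        self.bn1 = BatchNorm1d(c1)
        self.conv2 = Conv1d(c1, c2, cfg.kernel2_len, rng)
        self.bn2 = BatchNorm1d(c2)
        self.pool = MaxPool1d(cfg.pool_len) if with_pool else None

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        z = self.bn1(self.conv1(x), train).relu()
        if self.pool is not None:
            z = self.pool(z)
        z = self.bn2(self.conv2(z), train).relu()
        if self.pool is not None:
            z = self.pool(z)
        return z

    @property
    def bns(self):
        return [self.bn1, self.bn2]

    def parameters(self):
        return (self.conv1.parameters() + self.bn1.parameters()
                + self.conv2.parameters() + self.bn2.parameters())


def _cosine_sym_adjacency(z: Tensor, clamp: str) -> Tensor:
    """Per-trial cosine-similarity adjacency of (B, N, F) node features,
    clamped to [0, 1] and symmetrically degree-normalized with a self-loop."""
    b, n, _ = z.shape
    ss = (z * z).sum(axis=2, keepdims=True)
    zn = z * (ss + 1e-24) ** -0.5
    a = zn @ zn.swapaxes(1, 2)
    a = a.clamp(-1.0, 1.0)
    if clamp == "relu":
        a = a.clamp(0.0, None)
    elif clamp == "abs":
        a = (a * a + 1e-24) ** 0.5
    else:
        raise ValueError(f"unknown cosine clamp mode {clamp!r}")
    at = a + Tensor(np.eye(n))
    d = at.sum(axis=2, keepdims=True)
    dinv = d ** -0.5
    return at * dinv * dinv.swapaxes(1, 2)


def _gcn(adj: Tensor | np.ndarray, x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    adj_t = adj if isinstance(adj, Tensor) else Tensor(adj)
    return (adj_t @ x @ w + b).gelu()


class LPGGNet:
    """Local / partition / global graph network.

    Parameters
    ----------
    config : architecture widths and kernel sizes.
    montage : electrode geometry (defines node order).
    scheme : four-partition scheme; its union must equal the montage when
        the partition branch is enabled.
    local_adjacency : normalized (N, N) adjacency for the local graph layer
        (typically the PDC adjacency averaged over training trials).
    ablation : which branches/components to instantiate.
    seed : initialization seed.
    """

    def __init__(self, config: ModelConfig, montage: Montage,
                 scheme: PartitionScheme | None = None,
                 local_adjacency: np.ndarray | None = None,
                 ablation: AblationSpec = AblationSpec(),
                 seed: int = 0):
        self.config = config
        self.montage = montage
        self.scheme = scheme
        self.ablation = ablation
        rng = np.random.default_rng(seed)
        self.rng = rng
        self._dropout_rng = np.random.default_rng(seed + 1)
        n = len(montage.channel_names)
        c1, c2 = config.conv_channels
        part_width = c2 * config.feature_frames
        self._params: list[Tensor] = []
        self._graph_weights: list[Tensor] = []

        fuse_width = 0
        if ablation.use_local:
            if local_adjacency is None:
                raise ValueError("local branch enabled but no adjacency given")
            if local_adjacency.shape != (n, n):
                raise ValueError("local adjacency does not match montage size")
            self.local_adj = np.asarray(local_adjacency, dtype=float)
            self.local_tb = _TemporalBlock(config, with_pool=True, rng=rng)
            self.local_w = _glorot_t(rng, part_width, config.gcn_hidden)
            self.local_b = Tensor(np.zeros(config.gcn_hidden),
                                  requires_grad=True)
            self._params += self.local_tb.parameters()
            self._params += [self.local_w, self.local_b]
            self._graph_weights.append(self.local_w)
            fuse_width += config.gcn_hidden

        if ablation.use_partition:
            if scheme is None:
                raise ValueError("partition branch enabled but no scheme given")
            self._build_partitions(n)
            fuse_width += part_width

        if not (ablation.use_local or ablation.use_partition):
            # Global-only ablation: feed pooled temporal features directly.
            self.raw_tb = _TemporalBlock(config, with_pool=True, rng=rng)
            self._params += self.raw_tb.parameters()
            fuse_width += part_width

        self.fuse_width = fuse_width
        if ablation.use_global:
            self.g1_w = _glorot_t(rng, fuse_width, fuse_width)
            self.g1_b = Tensor(np.zeros(fuse_width), requires_grad=True)
            self.g2_w = _glorot_t(rng, fuse_width, fuse_width)
            self.g2_b = Tensor(np.zeros(fuse_width), requires_grad=True)
            self._params += [self.g1_w, self.g1_b, self.g2_w, self.g2_b]
            self._graph_weights += [self.g1_w, self.g2_w]

        self.fc1 = Linear(n * fuse_width, config.fc_hidden, rng)
        self.fc2 = Linear(config.fc_hidden, config.n_classes, rng)
        self.drop = Dropout(config.dropout)
        self._params += self.fc1.parameters() + self.fc2.parameters()

    # -- construction helpers ---------------------------------------------
    def _build_partitions(self, n: int):
        cfg, ab = self.config, self.ablation
        if ab.use_partitioning:
            scheme = self.scheme
            if set(scheme.union()) != set(self.montage.channel_names):
                raise ValueError(
                    "partition scheme union must cover the montage exactly")
            parts = scheme.partitions
        else:
            parts = (("all", self.montage.channel_names),)
        self.partition_defs = []
        self.partition_tbs = []
        for pid, chans in parts:
            coords = self.montage.subset_coords(chans)
            if ab.partition_metric == "gmd":
                adj = gmd_adjacency(coords, gmd_delta(coords))
            elif ab.partition_metric == "ised":
                adj = ised_adjacency(coords)
            else:
                raise ValueError(
                    f"unknown partition metric {ab.partition_metric!r}")
            filt = gaussian_filter(adj, labels=chans)
            idx = self.montage.index_of(chans)
            tb = _TemporalBlock(cfg, with_pool=False, rng=self.rng)
            self.partition_defs.append((pid, chans, idx, filt.operator))
            self.partition_tbs.append(tb)
            self._params += tb.parameters()
        if ab.use_partitioning:
            self.overlap = overlap_index(self.scheme)
        else:
            self.overlap = None

    # -- public API ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return self._params

    def _batchnorms(self):
        bns = []
        for attr in ("local_tb", "raw_tb"):
            if hasattr(self, attr):
                bns += getattr(self, attr).bns
        for tb in getattr(self, "partition_tbs", []):
            bns += tb.bns
        return bns

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learned state keyed by stable names (parameter order is
        deterministic for a given config/ablation)."""
        state = {f"param_{i:03d}": p.data for i, p in enumerate(self._params)}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn_{i:02d}_mean"] = bn.running_mean
            state[f"bn_{i:02d}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self._params):
            src = state[f"param_{i:03d}"]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for param_{i:03d}")
            p.data = np.array(src, dtype=float)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.array(state[f"bn_{i:02d}_mean"], dtype=float)
            bn.running_var = np.array(state[f"bn_{i:02d}_var"], dtype=float)

    def graph_weights(self) -> list[Tensor]:
        """Weight matrices of graph layers (targets of the extra L2 penalty)."""
        return self._graph_weights

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self._params))

    def temporal_block(self, x: np.ndarray, with_pool: bool,
                       train: bool = False) -> Tensor:
        """Run a standalone temporal block on (trials, nodes, samples) data."""
        tb = _TemporalBlock(self.config, with_pool, np.random.default_rng(0))
        b, n, t = x.shape
        z = tb(Tensor(x.reshape(b * n, 1, t)), train)
        return z.reshape(b, n, *z.shape[1:])

    def _node_features(self, z: Tensor, b: int, n: int) -> Tensor:
        """(B*N, C, L) conv output -> (B, N, C*frames) node features."""
        z = avgpool_to(z, self.config.feature_frames)
        return z.reshape(b, n, -1)

    def local_branch(self, x: np.ndarray, train: bool) -> FeatureMap:
        b, n, t = x.shape
        z = self.local_tb(Tensor(x.reshape(b * n, 1, t)), train)
        feats = self._node_features(z, b, n)
        out = _gcn(self.local_adj, feats, self.local_w, self.local_b)
        return FeatureMap(out, self.montage.channel_names)

    def partition_branch(self, x: np.ndarray, train: bool) -> list[FeatureMap]:
        b = x.shape[0]
        outs = []
        for (pid, chans, idx, op), tb in zip(self.partition_defs,
                                             self.partition_tbs):
            xp = op @ x[:, idx, :]                      # graph-filtered signal
            np_, t = xp.shape[1], xp.shape[2]
            z = tb(Tensor(xp.reshape(b * np_, 1, t)), train)
            outs.append(FeatureMap(self._node_features(z, b, np_), chans))
        return outs

    def partition_fuse(self, parts: list[FeatureMap]) -> FeatureMap:
        """Average the feature vectors of channels shared across partitions;
        one output row per distinct channel, in montage order."""
        widths = {fm.values.shape[2] for fm in parts}
        if len(widths) != 1:
            raise ValueError(f"feature-length mismatch across copies: {widths}")
        locs: dict[str, list[tuple[FeatureMap, int]]] = {}
        for fm in parts:
            for i, c in enumerate(fm.labels):
                locs.setdefault(c, []).append((fm, i))
        order = [c for c in self.montage.channel_names if c in locs]
        cols = []
        for c in order:
            copies = [fm.values[:, i:i + 1, :] for fm, i in locs[c]]
            acc = copies[0]
            for extra in copies[1:]:
                acc = acc + extra
            cols.append(acc * (1.0 / len(copies)))
        return FeatureMap(concat(cols, axis=1), tuple(order))

    def global_branch(self, z_fuse: Tensor, train: bool) -> Tensor:
        cfg, ab = self.config, self.ablation
        a1 = _cosine_sym_adjacency(z_fuse, cfg.cosine_clamp)
        z1 = _gcn(a1, z_fuse, self.g1_w, self.g1_b)
        s = z_fuse + z1 if ab.use_residual else z1
        a2 = a1 if cfg.shared_global_adjacency else _cosine_sym_adjacency(
            s, cfg.cosine_clamp)
        z2 = _gcn(a2, s, self.g2_w, self.g2_b)
        return z2 + z_fuse if ab.use_residual else z2

    def forward(self, x: np.ndarray, train: bool = False) -> Tensor:
        """Class logits (trials x n_classes) for (trials, channels, samples)
        input."""
        x = np.asarray(x, dtype=float)
        if x.shape[1] != len(self.montage.channel_names):
            raise ValueError("channel dimension does not match montage")
        ab = self.ablation
        pieces = []
        if ab.use_local:
            pieces.append(self.local_branch(x, train).values)
        if ab.use_partition:
            fused = self.partition_fuse(self.partition_branch(x, train))
            if fused.labels != self.montage.channel_names:
                raise ValueError("fused node set does not match montage order")
            pieces.append(fused.values)
        if not pieces:
            b, n, t = x.shape
            z = self.raw_tb(Tensor(x.reshape(b * n, 1, t)), train)
            pieces.append(self._node_features(z, b, n))
        z_fuse = pieces[0] if len(pieces) == 1 else concat(pieces, axis=2)
        if ab.use_global:
            z_out = self.global_branch(z_fuse, train)
        else:
            z_out = z_fuse
        b = x.shape[0]
        h = self.fc1(z_out.reshape(b, -1)).relu()
        h = self.drop(h, train, self._dropout_rng)
        return self.fc2(h)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x, train=False).data
        return softmax(logits)

    def training_loss(self, x: np.ndarray, labels: np.ndarray,
                      l2_coeff: float = 0.0) -> Tensor:
        logits = self.forward(x, train=True)
        out = softmax_cross_entropy(logits, labels)
        if l2_coeff > 0 and self._graph_weights:
            penalty = None
            for w in self._graph_weights:
                term = (w * w).sum()
                penalty = term if penalty is None else penalty + term
            out = out + penalty * l2_coeff
        return out


def _glorot_t(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)),
                  requires_grad=True)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of probability scores against integer labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= scores.shape[1]:
        raise ValueError("label outside valid class range")
    p = scores[np.arange(scores.shape[0]), labels]
    return float(-np.log(p).mean())
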