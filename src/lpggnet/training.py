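"""Training loop (Adam), evaluation metrics and the ablation matrix."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .autodiff import Tensor
from .connectivity import pdc_adjacency, pearson_adjacency
from .model import AblationSpec, LPGGNet, ModelConfig, softmax
from .montage import Montage, PartitionScheme
from .preprocessing import EpochedEEG

__all__ = ["TrainConfig", "MetricsReport", "TrainingError", "Adam",
           "train", "evaluate", "confusion_matrix", "accuracy", "kappa",
           "compare_models", "run_ablation", "ABLATION_GRID_MODULES"]


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    dropout: float = 0.5
    l2_coeff: float = 0.069      # extra L2 penalty on graph-layer weights
    batch_size: int = 64
    weight_decay: float = 0.01   # optimizer-level L2 on all weights
    epochs: int = 300
    seed: int = 0
    n_repeats: int = 5
    mvar_order: int = 5
    pdc_band: tuple[float, float] = (8.0, 30.0)

    def __post_init__(self):
        for name in ("lr", "batch_size", "epochs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    kappa: float
    confusion: np.ndarray
    per_repeat: tuple[float, ...] = ()


class Adam:
    """Adam with classic (coupled) L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_local_adjacency(epochs: EpochedEEG, config: TrainConfig,
                          ablation: AblationSpec) -> np.ndarray | None:
    if not ablation.use_local:
        return None
    if ablation.local_adjacency == "pdc":
        return pdc_adjacency(epochs, order=config.mvar_order,
                             band=config.pdc_band)
    if ablation.local_adjacency == "pearson":
        return pearson_adjacency(epochs)
    raise ValueError(f"unknown local adjacency {ablation.local_adjacency!r}")


def train(epochs_train: EpochedEEG, config: TrainConfig,
          model_config: ModelConfig, montage: Montage,
          scheme: PartitionScheme | None = None,
          ablation: AblationSpec = AblationSpec(),
          local_adjacency: np.ndarray | None = None,
          ) -> tuple[LPGGNet, dict]:
    """Train an LPGGNet on epoched data; returns (model, history).

    The local adjacency (PDC by default) is estimated from the training
    epochs unless supplied.  All randomness is drawn from ``config.seed``.
    """
    y = epochs_train.labels
    if len(np.unique(y)) < 2:
        raise TrainingError("training set must contain at least 2 classes")
    model_config = replace(model_config, dropout=config.dropout)
    if ablation.use_local and local_adjacency is None:
        local_adjacency = build_local_adjacency(epochs_train, config, ablation)
    model = LPGGNet(model_config, montage, scheme=scheme,
                    local_adjacency=local_adjacency, ablation=ablation,
                    seed=config.seed)
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    x = epochs_train.data
    n = x.shape[0]
    history = {"loss": [], "train_accuracy": []}
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            opt.zero_grad()
            logits = model.forward(x[idx], train=True)
            from .autodiff import softmax_cross_entropy
            out = softmax_cross_entropy(logits, y[idx])
            if config.l2_coeff > 0 and model.graph_weights():
                penalty = None
                for w in model.graph_weights():
                    term = (w * w).sum()
                    penalty = term if penalty is None else penalty + term
                out = out + penalty * config.l2_coeff
            if not np.isfinite(out.data):
                raise TrainingError(
                    f"non-finite loss at step {opt.t}: {out.data}")
            out.backward()
            opt.step()
            losses.append(float(out.data))
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["train_accuracy"].append(correct / n)
    return model, history


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = 4) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(y_true, dtype=int),
                    np.asarray(y_pred, dtype=int)):
        cm[t, p] += 1
    return cm


def accuracy(confusion: np.ndarray) -> float:
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    if cm.size == 0 or total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa: (P_a - P_e) / (1 - P_e)."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    if cm.size == 0 or total == 0:
        raise ValueError("empty confusion matrix")
    pa = np.trace(cm) / total
    pe = float((cm.sum(axis=1) / total) @ (cm.sum(axis=0) / total))
    if pe == 1.0:
        raise ValueError("expected agreement P_e = 1; kappa undefined")
    return float((pa - pe) / (1.0 - pe))


def evaluate(model: LPGGNet, epochs: EpochedEEG,
             batch_size: int = 32) -> MetricsReport:
    preds = []
    for start in range(0, epochs.n_trials, batch_size):
        scores = model.predict_proba(epochs.data[start:start + batch_size])
        preds.append(scores.argmax(axis=1))
    y_pred = np.concatenate(preds)
    cm = confusion_matrix(epochs.labels, y_pred,
                          n_classes=model.config.n_classes)
    return MetricsReport(accuracy(cm), kappa(cm), cm)


def compare_models(acc_a, acc_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-subject
    accuracies.  All-zero differences return p = 1.0 by convention."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired accuracy vectors of equal length >= 5")
    if np.all(a == b):
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)


# Module-level ablation grid mirroring the seven branch on/off combinations.
ABLATION_GRID_MODULES: dict[str, AblationSpec] = {
    "local_only": AblationSpec(True, False, False),
    "partition_only": AblationSpec(False, True, False),
    "global_only": AblationSpec(False, False, True),
    "local_removed": AblationSpec(False, True, True),
    "partition_removed": AblationSpec(True, False, True),
    "global_removed": AblationSpec(True, True, False),
    "ours": AblationSpec(True, True, True),
}


def run_ablation(epochs_train: EpochedEEG, epochs_test: EpochedEEG,
                 specs: dict[str, AblationSpec], config: TrainConfig,
                 model_config: ModelConfig, montage: Montage,
                 scheme: PartitionScheme | None = None,
                 ) -> dict[str, MetricsReport]:
    """Train/evaluate one model per ablation spec with identical seeds."""
    results: dict[str, MetricsReport] = {}
    for name, spec in specs.items():
        model, _ = train(epochs_train, config, model_config, montage,
                         scheme=scheme, ablation=spec)
        results[name] = evaluate(model, epochs_test)
    return results
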