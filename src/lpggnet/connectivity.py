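"""MVAR fitting and partial directed coherence (PDC).

PDC uses the spectral coefficient matrix ``Abar(f) = I - sum_r A_r
exp(-i 2 pi f r / fs)`` with source-column normalization, so that for every
frequency and source j the squared entries of column j sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import EpochedEEG

__all__ = [
    "MVARModel",
    "PDCMatrix",
    "ConnectivityError",
    "fit_mvar",
    "fit_mvar_trial",
    "pdc",
    "band_averaged_pdc",
    "pdc_adjacency",
    "pearson_adjacency",
    "sym_normalize_directed",
]


class ConnectivityError(ValueError):
    pass


@dataclass(frozen=True)
class MVARModel:
    """Vector autoregressive model: x_t = sum_r A_r x_{t-r} + e_t."""

    coeffs: np.ndarray          # (p, N, N); coeffs[r-1][i, j] = influence j -> i at lag r
    innovation_cov: np.ndarray  # (N, N)

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
            raise ValueError("coeffs must be (p, N, N)")
        if coeffs.shape[0] < 1:
            raise ValueError("order must be >= 1")
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "innovation_cov",
                           np.asarray(self.innovation_cov, dtype=float))

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


@dataclass(frozen=True)
class PDCMatrix:
    freqs: np.ndarray   # (F,) Hz
    values: np.ndarray  # (F, N, N); values[f, i, j] = influence j -> i, in [0, 1]

    def band_mean(self, low: float, high: float) -> np.ndarray:
        mask = (self.freqs >= low) & (self.freqs <= high)
        if not mask.any():
            raise ConnectivityError(f"no frequencies in band ({low}, {high})")
        return self.values[mask].mean(axis=0)


def fit_mvar_trial(x: np.ndarray, order: int) -> MVARModel:
    """Least-squares MVAR fit on a single (channels x samples) trial."""
    x = np.asarray(x, dtype=float)
    n, t = x.shape
    if order < 1:
        raise ConnectivityError("order must be >= 1")
    if t <= order + n:
        raise ConnectivityError(
            f"trial too short for identifiability: {t} samples, order {order}, "
            f"{n} channels"
        )
    # Regress x_t on [x_{t-1}; ...; x_{t-p}] by OLS.
    y = x[:, order:].T                                     # (T-p, N)
    lagged = [x[:, order - r:t - r].T for r in range(1, order + 1)]
    z = np.concatenate(lagged, axis=1)                     # (T-p, N*p)
    beta, _, rank, _ = np.linalg.lstsq(z, y, rcond=None)
    if rank < z.shape[1]:
        raise ConnectivityError("rank-deficient lag regressor matrix")
    coeffs = np.stack(
        [beta[r * n:(r + 1) * n, :].T for r in range(order)], axis=0
    )
    resid = y - z @ beta
    dof = max(y.shape[0] - z.shape[1], 1)
    cov = resid.T @ resid / dof
    return MVARModel(coeffs, cov)


def fit_mvar(epochs: EpochedEEG, order: int = 5) -> list[MVARModel]:
    """One least-squares MVAR model per trial."""
    return [fit_mvar_trial(epochs.data[t], order) for t in range(epochs.n_trials)]


def pdc(model: MVARModel, freqs: np.ndarray, fs: float) -> PDCMatrix:
    """Partial directed coherence of an MVAR model on a frequency grid."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > fs / 2):
        raise ConnectivityError("frequencies must lie in [0, fs/2]")
    p, n = model.order, model.n_channels
    lags = np.arange(1, p + 1)
    # phase[f, r] = exp(-i 2 pi f r / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / fs)
    abar = np.eye(n)[None, :, :] - np.einsum("fr,rij->fij", phase, model.coeffs)
    mag = np.abs(abar)
    col_norm = np.sqrt((mag ** 2).sum(axis=1, keepdims=True))  # (F, 1, N)
    if np.any(col_norm == 0):
        raise ConnectivityError("degenerate spectral coefficient column")
    return PDCMatrix(freqs, mag / col_norm)


def band_averaged_pdc(epochs: EpochedEEG, order: int = 5,
                      band: tuple[float, float] = (8.0, 30.0),
                      freq_step: float = 1.0) -> np.ndarray:
    """Raw trial- and band-averaged PDC matrix (diagonal kept)."""
    low, high = band
    if not (0 < low < high <= epochs.fs / 2):
        raise ConnectivityError(f"band ({low}, {high}) outside (0, fs/2]")
    if epochs.n_trials < 1:
        raise ConnectivityError("need at least one trial")
    freqs = np.arange(low, high + 1e-9, freq_step)
    acc = np.zeros((epochs.n_channels, epochs.n_channels))
    for model in fit_mvar(epochs, order):
        acc += pdc(model, freqs, epochs.fs).values.mean(axis=0)
    return acc / epochs.n_trials


def sym_normalize_directed(a: np.ndarray) -> np.ndarray:
    """Self-looped degree normalization D^{-1/2} (A + I) D^{-1/2}.

    Degrees are row sums of A + I; works for directed (asymmetric) input.
    """
    a = np.asarray(a, dtype=float)
    at = a + np.eye(a.shape[0])
    d = at.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return dinv[:, None] * at * dinv[None, :]


def pdc_adjacency(epochs: EpochedEEG, order: int = 5,
                  band: tuple[float, float] = (8.0, 30.0),
                  freq_step: float = 1.0,
                  symmetrize: bool = False) -> np.ndarray:
    """Normalized PDC adjacency: band/trial-averaged PDC, zero diagonal,
    then D^{-1/2}(A+I)D^{-1/2}."""
    a = band_averaged_pdc(epochs, order=order, band=band, freq_step=freq_step)
    np.fill_diagonal(a, 0.0)
    if symmetrize:
        a = 0.5 * (a + a.T)
    return sym_normalize_directed(a)


def pearson_adjacency(epochs: EpochedEEG) -> np.ndarray:
    """Ablation comparator: trial-averaged absolute Pearson correlation,
    zero diagonal, same normalization as the PDC adjacency."""
    n = epochs.n_channels
    acc = np.zeros((n, n))
    for t in range(epochs.n_trials):
        acc += np.abs(np.corrcoef(epochs.data[t]))
    a = acc / epochs.n_trials
    np.fill_diagonal(a, 0.0)
    return sym_normalize_directed(a)
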