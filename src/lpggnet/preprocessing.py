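"""Epochs container, band-pass filtering and per-trace standardization."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = ["EpochedEEG", "PreprocessingError", "bandpass", "zscore", "drop_channels"]


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class EpochedEEG:
    """Trials x channels x samples with labels and channel metadata."""

    data: np.ndarray          # (n_trials, n_channels, n_samples)
    fs: float                 # sampling rate, Hz
    labels: np.ndarray        # (n_trials,) integer class ids
    channel_names: tuple[str, ...]
    class_names: tuple[str, ...] = ("left_hand", "right_hand", "feet", "tongue")

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not np.all(np.isfinite(data)):
            raise ValueError("data must be finite")
        if labels.shape != (data.shape[0],):
            raise ValueError("labels length must equal trial count")
        if len(self.channel_names) != data.shape[1]:
            raise ValueError("channel_names length must equal channel dimension")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def bandpass(epochs: EpochedEEG, low_hz: float = 0.5, high_hz: float = 40.0,
             order: int = 6) -> EpochedEEG:
    """Zero-phase Butterworth band-pass applied per trial and channel.

    The filter is designed at the given order in the band-pass sense and
    applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is the squared design response and the phase is zero.
    """
    if not (0 < low_hz < high_hz < epochs.fs / 2):
        raise PreprocessingError(
            f"invalid band edges ({low_hz}, {high_hz}) for fs={epochs.fs}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=epochs.fs, output="sos")
    out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=np.ascontiguousarray(out))


def zscore(epochs: EpochedEEG, per_trial: bool = True) -> EpochedEEG:
    """Standardize each trace to zero mean, unit standard deviation.

    per_trial=True (default) standardizes every (trial, channel) trace over
    time; per_trial=False uses per-channel statistics pooled across trials.
    """
    x = epochs.data
    if per_trial:
        mean = x.mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1, keepdims=True)
        bad = np.argwhere(sd[..., 0] == 0)
        if bad.size:
            t, c = bad[0]
            raise PreprocessingError(
                f"zero-variance trace at trial {t}, channel "
                f"{epochs.channel_names[c]!r}"
            )
    else:
        mean = x.mean(axis=(0, 2), keepdims=True)
        sd = x.std(axis=(0, 2), keepdims=True)
        bad = np.argwhere(sd[0, :, 0] == 0)
        if bad.size:
            c = bad[0][0]
            raise PreprocessingError(
                f"zero-variance channel {epochs.channel_names[c]!r}"
            )
    return replace(epochs, data=(x - mean) / sd)


def drop_channels(epochs: EpochedEEG, names) -> EpochedEEG:
    """Remove channels by label (e.g. EOG channels)."""
    drop = set(names)
    unknown = drop - set(epochs.channel_names)
    if unknown:
        raise PreprocessingError(f"cannot drop unknown channels: {sorted(unknown)}")
    keep = [i for i, n in enumerate(epochs.channel_names) if n not in drop]
    return replace(
        epochs,
        data=epochs.data[:, keep, :],
        channel_names=tuple(epochs.channel_names[i] for i in keep),
    )
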