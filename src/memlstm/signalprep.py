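"""Preprocessing and dataset construction for LFP forecasting.

The forecasting pipeline turns a single-channel recording into
supervised (window, response) pairs: Gaussian smoothing to suppress
measurement noise, a chronological 4:1 train/test split, z-normalization
whose statistics come from the training segment only (no leakage), and
stride-1 windows of ``L`` past samples paired with the next sample as
the response.  Multistep forecasts are produced autoregressively: each
prediction is appended to the window, which then slides by one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import (
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)

#: Default sampling interval in ms: a five-step horizon spans 40 ms.
DEFAULT_DT_MS = 8.0

#: Default input window length in samples.
DEFAULT_WINDOW = 20


@dataclass
class Recording:
    """A single-channel time series with its sampling interval."""

    samples: np.ndarray
    dt_ms: float = DEFAULT_DT_MS
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.dt_ms <= 0:
            raise ConfigError("dt_ms must be positive")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class WindowedDataset:
    """Supervised (input window, scalar response) pairs.

    ``inputs`` has shape (N - L, L); ``targets[k]`` is the sample
    immediately following window ``k``.  ``normalization`` records the
    (mean, sd) applied to the underlying recording, if any.
    """

    inputs: np.ndarray
    targets: np.ndarray
    L: int = DEFAULT_WINDOW
    normalization: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.targets)


def gaussian_filter(rec: Recording, sigma_samples: float = 2.0) -> Recording:
    """Smooth a recording with a normalized Gaussian kernel.

    The kernel is truncated at 4 sigma and the signal is reflect-padded,
    so a constant signal passes through unchanged and the output length
    equals the input length.
    """
    if sigma_samples <= 0:
        raise ConfigError("sigma_samples must be positive")
    smoothed = gaussian_filter1d(
        rec.samples, sigma=sigma_samples, mode="reflect", truncate=4.0
    )
    return Recording(smoothed, dt_ms=rec.dt_ms, subject_id=rec.subject_id)


def zscore_fit_apply(train_segment, *other_segments):
    """Normalize to zero mean / unit variance using training statistics.

    Mean and population SD are estimated on ``train_segment`` only and
    applied to every segment, so test data never influence the
    normalization.  Returns ``(normalized_segments, (mean, sd))`` where
    ``normalized_segments`` is a list (train first).
    """
    train = np.asarray(train_segment, dtype=float)
    if train.size < 2:
        raise InsufficientDataError("training segment needs >= 2 samples")
    mean = float(np.mean(train))
    sd = float(np.std(train))
    if sd == 0.0:
        raise DegenerateInputError("training segment has zero variance")
    out = [(np.asarray(seg, dtype=float) - mean) / sd
           for seg in (train, *other_segments)]
    return out, (mean, sd)


def make_windows(rec: Recording, L: int = DEFAULT_WINDOW) -> WindowedDataset:
    """Slide a stride-1 window of L samples; the next sample is the target.

    A recording of N samples yields exactly N - L pairs; pair ``k`` is
    ``(samples[k : k+L], samples[k+L])``.
    """
    x = rec.samples
    n = len(x)
    if L < 1:
        raise ConfigError("window length must be >= 1")
    if n <= L:
        raise InsufficientDataError(
            f"need more than {L} samples to build windows, got {n}"
        )
    idx = np.arange(n - L)[:, None] + np.arange(L)[None, :]
    return WindowedDataset(inputs=x[idx], targets=x[L:].copy(), L=L)


def split_4to1(rec: Recording) -> tuple[Recording, Recording]:
    """Chronological 4:1 split: first floor(0.8 N) samples train, rest test."""
    n = len(rec)
    if n < 5:
        raise InsufficientDataError("need at least 5 samples for a 4:1 split")
    cut = int(np.floor(0.8 * n))
    train = Recording(rec.samples[:cut], dt_ms=rec.dt_ms, subject_id=rec.subject_id)
    test = Recording(rec.samples[cut:], dt_ms=rec.dt_ms, subject_id=rec.subject_id)
    return train, test


def multistep_predict(model, window, steps: int) -> np.ndarray:
    """Autoregressive rollout of a forecaster from one seed window.

    ``model`` must expose ``predict_batch(windows) -> (B,)``.  Each
    prediction is appended to the window, which slides by one; with
    ``steps=1`` this is a single forward pass.
    """
    out = multistep_predict_batch(model, np.asarray(window, float)[None, :], steps)
    return out[0]


def multistep_predict_batch(model, windows: np.ndarray, steps: int) -> np.ndarray:
    """Vectorized rollout from many seed windows at once.

    Returns an array of shape (n_windows, steps); column ``s-1`` holds
    the horizon-``s`` forecasts.
    """
    if steps < 1:
        raise ConfigError("steps must be >= 1")
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    if windows.shape[1] < 1:
        raise InvalidInputError("seed windows must be non-empty")
    preds = np.empty((windows.shape[0], steps))
    cur = windows.copy()
    for s in range(steps):
        yhat = np.asarray(model.predict_batch(cur), dtype=float).ravel()
        preds[:, s] = yhat
        cur = np.concatenate([cur[:, 1:], yhat[:, None]], axis=1)
    return preds
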