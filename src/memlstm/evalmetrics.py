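"""Forecast scoring: RMSE, step curves and high-amplitude event metrics.

An interictal-like high-amplitude event is a sample run whose deviation
from the signal mean exceeds ``k_sd`` standard deviations (default 5).
Exceedance is two-sided because LFP spikes can be negative-going.
Contiguous supra-threshold runs collapse to a single event at the index
of largest absolute deviation.  Predicted events are extracted from the
forecast series with the same rule and matched one-to-one to ground
truth within a sample tolerance, giving event-level precision/recall on
the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)
from .signalprep import Recording, make_windows, multistep_predict_batch


@dataclass
class EventSet:
    """Detected event peak positions plus the threshold that produced them."""

    indices: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) <= 0):
            raise InvalidInputError("event indices must be sorted and unique")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class StepCurve:
    """RMSE as a function of the autoregressive prediction horizon."""

    steps: np.ndarray
    rmse_values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.rmse_values):
            raise InvalidInputError("steps and rmse_values must share a length")


def rmse(y, yhat) -> float:
    """Root-mean-square error sqrt((1/N) * sum (y_n - yhat_n)^2)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise InvalidInputError("y and yhat must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def detect_events(signal, k_sd: float = 5.0, merge_gap_samples: int = 0) -> EventSet:
    """Find samples deviating from the mean by more than ``k_sd`` SDs.

    The threshold is ``k_sd * std(signal)`` applied to ``|x - mean|``,
    so detection is invariant to adding a constant.  Adjacent
    supra-threshold samples form one event located at the run's
    extremum; runs separated by at most ``merge_gap_samples`` are
    treated as one event (a transient can dip briefly below threshold
    mid-course), with 0 meaning strictly contiguous runs only.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 2:
        raise InvalidInputError("signal must have at least 2 samples")
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateInputError("constant signal: event threshold undefined")
    dev = np.abs(x - np.mean(x))
    above = dev > k_sd * sd
    # run boundaries of the supra-threshold mask
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    starts, stops = list(edges[::2]), list(edges[1::2])
    if merge_gap_samples > 0:
        merged_starts, merged_stops = starts[:1], stops[:1]
        for s, e in zip(starts[1:], stops[1:]):
            if s - merged_stops[-1] <= merge_gap_samples:
                merged_stops[-1] = e
            else:
                merged_starts.append(s)
                merged_stops.append(e)
        starts, stops = merged_starts, merged_stops
    peaks = [int(s + np.argmax(dev[s:e])) for s, e in zip(starts, stops)]
    return EventSet(indices=np.asarray(peaks, dtype=int),
                    threshold_used=float(np.mean(x) + k_sd * sd))


def event_precision_recall(
    truth: EventSet | np.ndarray,
    predicted: EventSet | np.ndarray,
    tol_samples: int = 5,
):
    """Greedy one-to-one event matching within ``±tol_samples``.

    Events are walked in index order; a predicted event matches the
    earliest unmatched true event within tolerance.  Returns
    ``(precision, recall, matches)`` with precision and recall on the
    0-100 scale.  With no predicted events precision is 100 by
    convention (no false alarms); with no true events recall is 100.
    """
    if tol_samples < 0:
        raise ConfigError("tol_samples must be >= 0")
    t = np.asarray(truth.indices if isinstance(truth, EventSet) else truth, int)
    p = np.asarray(
        predicted.indices if isinstance(predicted, EventSet) else predicted, int
    )
    matches = 0
    i = j = 0
    while i < len(t) and j < len(p):
        if abs(int(t[i]) - int(p[j])) <= tol_samples:
            matches += 1
            i += 1
            j += 1
        elif t[i] < p[j]:
            i += 1
        else:
            j += 1
    precision = 100.0 if len(p) == 0 else 100.0 * matches / len(p)
    recall = 100.0 if len(t) == 0 else 100.0 * matches / len(t)
    return precision, recall, matches


def horizon_forecast(model, test: Recording | np.ndarray, horizon: int,
                     L: int = 20):
    """Fixed-horizon forecast series over a test recording.

    Rolls the model out ``horizon`` steps from every admissible true
    window and keeps the final step, so entry ``k`` is the horizon-``s``
    forecast of ``samples[k + L - 1 + s]``.  Returns ``(yhat, y)``
    aligned truth/forecast arrays.
    """
    x = test.samples if isinstance(test, Recording) else np.asarray(test, float)
    if horizon < 1:
        raise ConfigError("horizon must be >= 1")
    if len(x) < L + horizon:
        raise InsufficientDataError("test segment shorter than window + horizon")
    n_seed = len(x) - L - horizon + 1
    idx = np.arange(n_seed)[:, None] + np.arange(L)[None, :]
    preds = multistep_predict_batch(model, x[idx], horizon)
    return preds[:, -1], x[L + horizon - 1:]


def rmse_vs_step(model, test: Recording | np.ndarray, max_steps: int,
                 L: int = 20) -> StepCurve:
    """RMSE at each horizon 1..max_steps via autoregressive rollout.

    For every horizon ``s`` the model is rolled out from every test
    window whose horizon-``s`` target exists; shared rollout prefixes
    are computed once.
    """
    x = test.samples if isinstance(test, Recording) else np.asarray(test, float)
    if max_steps < 1:
        raise ConfigError("max_steps must be >= 1")
    if len(x) <= L:
        raise InsufficientDataError("test segment shorter than one window")
    n_seed = len(x) - L  # windows with at least a 1-step target
    idx = np.arange(n_seed)[:, None] + np.arange(L)[None, :]
    preds = multistep_predict_batch(model, x[idx], max_steps)
    steps = np.arange(1, max_steps + 1)
    values = np.empty(max_steps)
    for s in steps:
        m = len(x) - L - s + 1  # windows admissible at this horizon
        if m < 1:
            raise InsufficientDataError(f"no admissible windows at horizon {s}")
        values[s - 1] = rmse(x[L + s - 1:], preds[:m, s - 1])
    return StepCurve(steps=steps, rmse_values=values)
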