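"""Metrics: RMSE, event detection, matching, step curves — vs brute force."""

import numpy as np
import pytest

from memlstm.errors import (
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)
from memlstm.evalmetrics import (
    EventSet,
    detect_events,
    event_precision_recall,
    horizon_forecast,
    rmse,
    rmse_vs_step,
)
from memlstm.lstm import PersistenceForecaster
from memlstm.signalprep import Recording


class TestRMSE:
    def test_identical_series_give_zero(self):
        x = np.random.default_rng(0).normal(size=30)
        assert rmse(x, x) == 0.0

    def test_unit_offset(self):
        assert rmse([0, 0, 0], [1, 1, 1]) == 1.0

    def test_hand_arithmetic_example(self):
        assert rmse([1, 2, 3], [2, 4, 6]) == pytest.approx(np.sqrt(14 / 3), rel=1e-12)

    def test_squared_rmse_times_n_is_sse(self):
        rng = np.random.default_rng(1)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        sse = np.sum((y - yhat) ** 2)
        assert rmse(y, yhat) ** 2 * 50 == pytest.approx(sse, rel=1e-12)

    def test_mismatched_or_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            rmse([1, 2], [1, 2, 3])
        with pytest.raises(InvalidInputError):
            rmse([], [])


class TestDetectEvents:
    def test_bounded_noise_yields_no_events(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        x = x / np.max(np.abs((x - x.mean()) / x.std())) * 4.9  # max |z| < 5
        assert len(detect_events(x, 5.0)) == 0

    def test_single_spike_on_unit_background(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        x = (x - x.mean()) / x.std()
        x[777] = 10.0
        # manual threshold oracle
        assert 5.0 * np.std(x) < np.abs(x[777] - np.mean(x))
        events = detect_events(x, 5.0)
        assert list(events.indices) == [777]

    def test_adjacent_suprathreshold_samples_collapse_to_one(self):
        x = np.random.default_rng(4).normal(size=1000) * 0.1
        x[500] = 8.0
        x[501] = 9.0
        events = detect_events(x, 5.0)
        assert list(events.indices) == [501]

    def test_merge_gap_joins_split_transients(self):
        x = np.random.default_rng(5).normal(size=2000) * 0.1
        x[300] = 9.0
        x[303] = 8.5  # dips below threshold in between
        assert len(detect_events(x, 5.0)) == 2
        assert len(detect_events(x, 5.0, merge_gap_samples=3)) == 1

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=1500)
        x[100] = 12.0
        a = detect_events(x, 5.0)
        b = detect_events(x + 42.0, 5.0)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_negative_going_events_detected(self):
        x = np.random.default_rng(7).normal(size=1500) * 0.1
        x[800] = -9.0
        assert list(detect_events(x, 5.0).indices) == [800]

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateInputError):
            detect_events(np.ones(100))


def _brute_force_matching(truth, predicted, tol):
    """Independent oracle: in-order scan, earliest unmatched partner."""
    truth = sorted(truth)
    used = [False] * len(truth)
    matches = 0
    for p in sorted(predicted):
        for i, t in enumerate(truth):
            if not used[i] and abs(t - p) <= tol:
                used[i] = True
                matches += 1
                break
            if t > p + tol:
                break
    return matches


class TestEventMatching:
    def test_perfect_prediction_scores_100_100(self):
        truth = EventSet(indices=np.array([5, 20, 60]), threshold_used=1.0)
        p, r, m = event_precision_recall(truth, truth, tol_samples=0)
        assert (p, r, m) == (100.0, 100.0, 3)

    def test_exhaustive_matching_example(self):
        p, r, m = event_precision_recall(
            np.array([10, 50, 90]), np.array([11, 52, 70]), tol_samples=3
        )
        assert m == 2
        assert p == pytest.approx(66.67, abs=0.01)
        assert r == pytest.approx(66.67, abs=0.01)

    def test_empty_prediction_convention(self):
        p, r, m = event_precision_recall(np.array([3, 9]), np.array([], dtype=int), 5)
        assert (p, r, m) == (100.0, 0.0, 0)

    def test_empty_truth_convention(self):
        p, r, m = event_precision_recall(np.array([], dtype=int), np.array([4]), 5)
        assert (p, r, m) == (0.0, 100.0, 0)

    def test_matching_is_one_to_one(self):
        # two predictions near one true event: only one may match
        p, r, m = event_precision_recall(np.array([50]), np.array([48, 52]), 5)
        assert m == 1 and p == 50.0 and r == 100.0

    def test_agrees_with_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            truth = np.unique(rng.integers(0, 200, size=rng.integers(0, 12)))
            pred = np.unique(rng.integers(0, 200, size=rng.integers(0, 12)))
            tol = int(rng.integers(0, 8))
            _, _, m = event_precision_recall(truth, pred, tol)
            assert m == _brute_force_matching(truth, pred, tol)
            assert m <= min(len(truth), len(pred))  # one-to-one


class TestStepCurve:
    def test_perfect_oracle_model_gives_zero_curve(self):
        # persistence is an exact oracle for a constant signal
        const = Recording(np.ones(100))
        curve = rmse_vs_step(PersistenceForecaster(), const, max_steps=4, L=10)
        np.testing.assert_allclose(curve.rmse_values, 0.0, atol=1e-15)

    def test_persistence_on_ramp_matches_closed_form(self):
        a = 0.25
        ramp = Recording(a * np.arange(300.0))
        curve = rmse_vs_step(PersistenceForecaster(), ramp, max_steps=5, L=20)
        # persistence forecasts the last seen value; at horizon s the truth
        # has advanced by a*s everywhere on a linear ramp
        np.testing.assert_allclose(curve.rmse_values, a * np.arange(1, 6), rtol=1e-12)

    def test_horizon_forecast_alignment(self):
        x = np.arange(40.0)
        yhat, y = horizon_forecast(PersistenceForecaster(), x, horizon=3, L=10)
        np.testing.assert_array_equal(y, x[12:])
        # persistence at horizon 3 reports the window's last sample
        np.testing.assert_array_equal(yhat, x[9:-3])

    def test_insufficient_test_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            rmse_vs_step(PersistenceForecaster(), Recording(np.ones(10)), 2, L=20)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ConfigError):
            rmse_vs_step(PersistenceForecaster(), Recording(np.ones(30)), 0, L=20)
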