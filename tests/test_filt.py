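"""Transition detection, contamination tuning, stage-1 metrics, relabeling."""

import numpy as np
import pandas as pd
import pytest

from gescon.data import FeatureTable
from gescon.filt import (
    FiltError,
    NullTransitionFilter,
    fit_detector,
    flag_outliers,
    relabel_transitions,
    stage1_accuracy,
    stage1_precision,
    tune_contamination,
)

from .conftest import grid_recording


def _table(X, labels=None):
    X = np.asarray(X, dtype=float)
    n = len(X)
    return FeatureTable(
        features=pd.DataFrame(X, columns=[f"d{i}" for i in range(X.shape[1])]),
        labels=np.asarray(labels if labels is not None else ["Null"] * n, dtype=object),
        reps=np.zeros(n, dtype=int),
    )


@pytest.fixture(scope="module")
def gaussian_cloud():
    rng = np.random.default_rng(0)
    return rng.normal(0.0, 1.0, size=(400, 4))


class TestDetector:
    def test_contamination_fraction_flagged_on_training(self, gaussian_cloud):
        det = fit_detector(_table(gaussian_cloud), contamination=0.25)
        flags = det.predict(gaussian_cloud)
        assert flags.mean() == pytest.approx(0.25, abs=0.03)

    def test_cutoff_matches_empirical_quantile(self, gaussian_cloud):
        det = fit_detector(_table(gaussian_cloud), contamination=0.10)
        d = det.mahalanobis_sq(gaussian_cloud)
        # the cutoff is the (1 - contamination) quantile of training distances
        assert np.quantile(d, 0.90) == pytest.approx(det.cutoff_, rel=0.02)

    def test_far_points_flagged(self, gaussian_cloud):
        far = np.full((20, 4), 15.0)
        X = np.vstack([gaussian_cloud, far])
        det = fit_detector(_table(X), contamination=0.05)
        flags = det.predict(X)
        assert flags[-20:].all()
        assert flags[:-20].mean() < 0.05

    def test_center_is_inlier(self, gaussian_cloud):
        det = fit_detector(_table(gaussian_cloud), contamination=0.1)
        assert not det.predict(det.location_[None, :])[0]

    def test_flags_monotone_in_distance(self, gaussian_cloud):
        det = fit_detector(_table(gaussian_cloud), contamination=0.2)
        pts = np.random.default_rng(1).normal(0, 3, size=(200, 4))
        d = det.mahalanobis_sq(pts)
        flags = det.predict(pts)
        order = np.argsort(d)
        # once flagged along the distance ordering, always flagged
        assert np.all(np.diff(flags[order].astype(int)) >= 0)

    def test_contamination_bounds(self, gaussian_cloud):
        with pytest.raises(ValueError):
            fit_detector(_table(gaussian_cloud), contamination=0.6)
        with pytest.raises(ValueError):
            fit_detector(_table(gaussian_cloud), contamination=0.0)

    def test_too_few_rows(self):
        with pytest.raises(FiltError):
            fit_detector(_table(np.zeros((10, 3))), contamination=0.1)

    def test_column_mismatch(self, gaussian_cloud):
        det = fit_detector(_table(gaussian_cloud), contamination=0.1)
        other = _table(gaussian_cloud[:, :3])
        with pytest.raises(ValueError):
            flag_outliers(det, other)


class TestStage1Metrics:
    def test_no_flags_gives_perfect_accuracy(self):
        labels = np.array(["Null"] * 5 + ["Fist"] * 5, dtype=object)
        flags = np.zeros(10, dtype=bool)
        assert stage1_accuracy(flags, labels, "Null") == 1.0
        assert stage1_precision(flags, labels, "Null") == 1.0

    def test_all_flagged_half_null(self):
        labels = np.array(["Null"] * 5 + ["Fist"] * 5, dtype=object)
        flags = np.ones(10, dtype=bool)
        assert stage1_accuracy(flags, labels, "Null") == 0.5
        assert stage1_precision(flags, labels, "Null") == 0.5

    def test_hand_evaluated_mixture(self):
        # 100 rows: 10 flagged in Null, 5 flagged outside, 85 unflagged
        labels = np.array(["Null"] * 10 + ["Fist"] * 5 + ["Pinch"] * 85, dtype=object)
        flags = np.array([True] * 15 + [False] * 85)
        assert stage1_accuracy(flags, labels, "Null") == pytest.approx(0.95)
        assert stage1_precision(flags, labels, "Null") == pytest.approx(10 / 15)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        labels = np.array(["Null"] * 40 + ["Fist"] * 60, dtype=object)
        flags = rng.random(100) < 0.3
        perm = rng.permutation(100)
        assert stage1_precision(flags, labels, "Null") == stage1_precision(
            flags[perm], labels[perm], "Null"
        )
        assert stage1_accuracy(flags, labels, "Null") == stage1_accuracy(
            flags[perm], labels[perm], "Null"
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            stage1_accuracy(np.zeros(3, bool), np.array(["Null"] * 4, object), "Null")


class TestTuning:
    def _separable_case(self):
        rng = np.random.default_rng(3)
        null_train = rng.normal(0, 1, size=(200, 4))
        hold_null = np.vstack([rng.normal(0, 1, (180, 4)), np.full((20, 4), 25.0)])
        hold_other = rng.normal(0, 1, (100, 4))
        holdout = _table(
            np.vstack([hold_null, hold_other]),
            labels=["Null"] * 200 + ["Fist"] * 100,
        )
        return _table(null_train), holdout

    def test_separable_case_reaches_perfect_precision(self):
        null_train, holdout = self._separable_case()
        c, report, _ = tune_contamination(null_train, holdout, grid=(0.02, 0.05, 0.10, 0.25))
        # only the far 'Null' shell sits outside the tightest cutoff
        assert report.precision == 1.0
        assert c == 0.02

    def test_singleton_grid_returned(self):
        null_train, holdout = self._separable_case()
        c, _, _ = tune_contamination(null_train, holdout, grid=(0.25,))
        assert c == 0.25

    def test_equal_precision_tie_prefers_larger_contamination(self):
        rng = np.random.default_rng(4)
        null_train = _table(rng.normal(0, 1, size=(200, 4)))
        # holdout: inliers exactly at the center plus a far 'Null' shell that
        # both cutoffs flag in full -> precision 1.0 twice, tie rule decides
        X = np.vstack([np.zeros((40, 4)), np.full((10, 4), 50.0)])
        holdout = _table(X, labels=["Null"] * 20 + ["Fist"] * 20 + ["Null"] * 10)
        c, report, _ = tune_contamination(null_train, holdout, grid=(0.02, 0.05))
        assert report.precision == 1.0
        assert c == 0.05

    def test_empty_grid_rejected(self):
        null_train, holdout = self._separable_case()
        with pytest.raises(ValueError):
            tune_contamination(null_train, holdout, grid=())


class TestRelabel:
    def _rec(self, flags_at, labels=None):
        labels = labels or ["A"] * 2 + ["Null"] * 6 + ["B"] * 2
        rec = grid_recording(labels)
        flags = np.zeros(len(labels), dtype=bool)
        flags[list(flags_at)] = True
        return rec, flags

    def test_central_flags_split_window(self):
        # Null run occupies indices 2..7; flags at n3,n4 (indices 4,5)
        rec, flags = self._rec([4, 5])
        out = relabel_transitions(rec, flags)
        assert list(out.recording.prompt_labels) == ["A", "A", "A", "A", "B", "B", "B", "B"]
        assert out.n_dropped == 2

    def test_flag_at_window_start_relabels_all_to_next(self):
        rec, flags = self._rec([2])  # first Null sample flagged
        out = relabel_transitions(rec, flags)
        assert list(out.recording.prompt_labels) == ["A", "A", "B", "B", "B", "B", "B", "B", "B"]

    def test_zero_flags_drops_whole_window(self):
        rec, flags = self._rec([])
        out = relabel_transitions(rec, flags)
        assert list(out.recording.prompt_labels) == ["A", "A", "B", "B"]
        assert out.n_dropped == 6

    def test_session_boundary_null_dropped(self):
        labels = ["Null"] * 3 + ["A"] * 2 + ["Null"] * 2
        rec = grid_recording(labels)
        flags = np.ones(len(labels), dtype=bool)
        out = relabel_transitions(rec, flags)
        assert list(out.recording.prompt_labels) == ["A", "A"]

    def test_output_never_contains_null_and_never_grows(self, separable_sessions):
        rec, _ = separable_sessions
        nf = NullTransitionFilter(random_state=0).fit(rec)
        out = nf.transform(rec)
        assert "Null" not in set(out.recording.prompt_labels)
        assert out.recording.n <= rec.n

    def test_recovery_on_separable_subject(self, separable_sessions):
        """Relabeled lag/tail samples recover their oracle gesture label."""
        rec, _ = separable_sessions
        nf = NullTransitionFilter(random_state=0).fit(rec)
        assert nf.stage1_holdout_.precision >= 0.95
        out = nf.transform(rec)
        mask = out.relabeled & (out.recording.true_labels != "Null")
        agree = (out.recording.prompt_labels[mask] == out.recording.true_labels[mask]).mean()
        assert agree >= 0.9
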