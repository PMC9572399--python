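"""FILT: unsupervised transition detection inside 'Null' and label repair.

The prompting application labels every sample in the 3 s countdown between
gestures as 'Null', but users spend most of that window still holding the
previous gesture or already holding the next one — only the brief physical
transition is truly transitional.  FILT treats those transition samples as
geometric outliers of the 'Null' class in rate-of-change (CapDelta) feature
space, locates them with a robust-covariance elliptic envelope, and then
repairs the window by rule: samples before the first flagged outlier are
relabeled as the previous gesture, samples after the last one as the next
gesture, and the flagged span itself is dropped.

Stage-1 quality is scored with precision (flagged samples that fall inside
'Null' over all flagged samples) and a stage-1 accuracy that treats
unflagged samples as true negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.covariance import EllipticEnvelope

from .data import (
    DEFAULT_VOCAB,
    FeatureTable,
    GestureRecording,
    LabelVocabulary,
    segment_repetitions,
)
from .features import build_feature_table

#: Contamination values searched during tuning; includes the 0.25 start.
DEFAULT_CONTAMINATION_GRID = (0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
INITIAL_CONTAMINATION = 0.25


class FiltError(RuntimeError):
    """Transition detection could not be fitted or tuned."""


class TransitionDetector(BaseEstimator):
    """Robust-covariance ellipse flagging the contamination tail as outliers.

    A minimum-covariance-determinant location/shape estimate defines squared
    Mahalanobis distances; the cutoff is the ``(1 - contamination)`` quantile
    of the training distances, so the contamination fraction of training rows
    is flagged.  The MCD support fraction follows the contamination value.
    """

    def __init__(self, contamination: float = INITIAL_CONTAMINATION, random_state: int = 0):
        self.contamination = contamination
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None):
        if not 0.0 < self.contamination <= 0.5:
            raise ValueError("contamination must be in (0, 0.5]")
        X = np.asarray(X, dtype=float)
        if len(X) < 20:
            raise FiltError("need at least 20 'Null' training rows")
        env = EllipticEnvelope(
            contamination=self.contamination,
            support_fraction=min(max(1.0 - self.contamination, 0.55), 1.0),
            random_state=self.random_state,
        )
        try:
            env.fit(X)
        except (np.linalg.LinAlgError, ValueError):
            # singular scatter: regularize with a tiny seeded jitter, then give up
            rng = np.random.default_rng(self.random_state)
            jitter = rng.normal(0.0, 1e-6, X.shape)
            try:
                env.fit(X + jitter)
            except (np.linalg.LinAlgError, ValueError) as err:
                raise FiltError(f"singular covariance in transition detector: {err}")
        self.envelope_ = env
        self.location_ = env.location_
        self.shape_ = env.covariance_
        # offset_ is the contamination-quantile of -dist^2 on the training data
        self.cutoff_ = -float(env.offset_)
        self.n_features_in_ = X.shape[1]
        return self

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature columns do not match the fitted detector")
        return self.envelope_.mahalanobis(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean outlier flags: distance strictly above the cutoff."""
        return self.mahalanobis_sq(X) > self.cutoff_


@dataclass
class Stage1Report:
    """Precision/accuracy of the transition-detection stage."""

    precision: float
    accuracy: float
    contamination: float
    n_flagged: int
    n_total: int
    flags: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "accuracy": self.accuracy,
            "contamination": self.contamination,
            "n_flagged": self.n_flagged,
            "n_total": self.n_total,
        }


def fit_detector(
    null_train: FeatureTable, contamination: float, random_state: int = 0
) -> TransitionDetector:
    """Fit the elliptic detector on 'Null'-labeled training rows."""
    det = TransitionDetector(contamination=contamination, random_state=random_state)
    det.fit(null_train.X)
    det.columns_ = null_train.columns
    return det


def flag_outliers(det: TransitionDetector, table: FeatureTable) -> np.ndarray:
    if getattr(det, "columns_", None) is not None and table.columns != det.columns_:
        raise ValueError("feature columns do not match the fitted detector")
    return det.predict(table.X)


def stage1_precision(flags: np.ndarray, prompt_labels: np.ndarray, null_label: str) -> float:
    """Flagged-and-'Null' over all flagged (1.0 when nothing is flagged)."""
    flags = np.asarray(flags, dtype=bool)
    prompt_labels = np.asarray(prompt_labels, dtype=object)
    if len(flags) != len(prompt_labels):
        raise ValueError("flags and labels must be aligned")
    n_flagged = int(flags.sum())
    if n_flagged == 0:
        return 1.0
    tp = int(np.sum(flags & (prompt_labels == null_label)))
    return tp / n_flagged


def stage1_accuracy(flags: np.ndarray, prompt_labels: np.ndarray, null_label: str) -> float:
    """(outliers inside 'Null' + non-outliers) / total samples."""
    flags = np.asarray(flags, dtype=bool)
    prompt_labels = np.asarray(prompt_labels, dtype=object)
    if len(flags) != len(prompt_labels):
        raise ValueError("flags and labels must be aligned")
    tp = int(np.sum(flags & (prompt_labels == null_label)))
    tn = int(np.sum(~flags))
    return (tp + tn) / len(flags)


def _stage1_report(
    det: TransitionDetector,
    table: FeatureTable,
    null_label: str,
    keep_flags: bool = False,
) -> Stage1Report:
    flags = flag_outliers(det, table)
    return Stage1Report(
        precision=stage1_precision(flags, table.labels, null_label),
        accuracy=stage1_accuracy(flags, table.labels, null_label),
        contamination=det.contamination,
        n_flagged=int(flags.sum()),
        n_total=table.n,
        flags=flags if keep_flags else None,
    )


def tune_contamination(
    null_train: FeatureTable,
    holdout: FeatureTable,
    grid=DEFAULT_CONTAMINATION_GRID,
    null_label: str = DEFAULT_VOCAB.null_label,
    random_state: int = 0,
) -> tuple[float, Stage1Report, TransitionDetector]:
    """Pick the contamination whose holdout precision is closest to 1.

    Ties are broken toward the larger contamination (more transitions
    found).  Raises :class:`FiltError` if no grid value flags anything.
    """
    if len(grid) == 0:
        raise ValueError("contamination grid must be nonempty")
    best = None
    any_flags = False
    for c in grid:
        det = fit_detector(null_train, c, random_state=random_state)
        report = _stage1_report(det, holdout, null_label)
        if report.n_flagged > 0:
            any_flags = True
        key = (report.precision, c)  # precision closest to 1, then larger c
        if best is None or key >= best[0]:
            best = (key, c, report, det)
    if not any_flags:
        raise FiltError("no contamination value flagged any outliers")
    return best[1], best[2], best[3]


@dataclass
class RelabelOutcome:
    """Result of applying the transition-repair rules to one recording."""

    recording: GestureRecording
    source_index: np.ndarray  # kept sample positions in the input recording
    relabeled: np.ndarray  # kept samples whose prompt label was rewritten
    n_dropped: int


def relabel_transitions(
    rec: GestureRecording,
    flags: np.ndarray,
    vocab: LabelVocabulary = DEFAULT_VOCAB,
) -> RelabelOutcome:
    """Repair 'Null' windows around the flagged transition span.

    Within each 'Null' run: samples before the first flagged sample take the
    previous gesture's label, samples after the last flagged sample take the
    next gesture's label, and the flagged span (inclusive) is dropped.  Runs
    with no flags, or without a gesture on one side (session start/end), are
    dropped entirely — the transition cannot be localized there.  The output
    contains no 'Null' labels and is no longer on a uniform time grid.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != rec.n:
        raise ValueError("flags must align with the recording")
    segments = segment_repetitions(rec)
    runs = segments.runs
    keep: list[np.ndarray] = []
    new_labels: list[np.ndarray] = []
    relabeled: list[np.ndarray] = []
    n_dropped = 0
    for k, run in enumerate(runs):
        idx = np.arange(run.start, run.stop)
        if run.label != vocab.null_label:
            keep.append(idx)
            new_labels.append(rec.prompt_labels[idx])
            relabeled.append(np.zeros(len(idx), dtype=bool))
            continue
        prev_label = runs[k - 1].label if k > 0 else None
        next_label = runs[k + 1].label if k + 1 < len(runs) else None
        if prev_label == vocab.null_label or next_label == vocab.null_label:
            raise RuntimeError("adjacent Null runs should be impossible")
        flagged = idx[flags[idx]]
        if prev_label is None or next_label is None or len(flagged) == 0:
            n_dropped += len(idx)
            continue
        first, last = flagged[0], flagged[-1]
        before = idx[idx < first]
        after = idx[idx > last]
        n_dropped += len(idx) - len(before) - len(after)
        if len(before):
            keep.append(before)
            new_labels.append(np.full(len(before), prev_label, dtype=object))
            relabeled.append(np.ones(len(before), dtype=bool))
        if len(after):
            keep.append(after)
            new_labels.append(np.full(len(after), next_label, dtype=object))
            relabeled.append(np.ones(len(after), dtype=bool))
    if not keep:
        raise FiltError("transition repair removed every sample")
    kept_idx = np.concatenate(keep)
    order = np.argsort(kept_idx, kind="stable")
    kept_idx = kept_idx[order]
    labels = np.concatenate(new_labels)[order]
    relabeled_mask = np.concatenate(relabeled)[order]
    out = rec.take(kept_idx)
    out.prompt_labels = labels
    return RelabelOutcome(
        recording=out,
        source_index=kept_idx,
        relabeled=relabeled_mask,
        n_dropped=n_dropped,
    )


class NullTransitionFilter(BaseEstimator):
    """The full FILT stage as a fit/transform estimator.

    ``fit`` tunes the contamination on Data1 (detector trained on a 35%
    seeded split of Data1's 'Null' rows in CapDelta space, precision scored
    on the remaining Data1 rows); ``transform`` flags and repairs any
    session with the *fitted* detector — Data2 never influences fitting.
    """

    def __init__(
        self,
        contamination_grid=DEFAULT_CONTAMINATION_GRID,
        train_frac: float = 0.35,
        random_state: int = 0,
    ):
        self.contamination_grid = contamination_grid
        self.train_frac = train_frac
        self.random_state = random_state

    def fit(self, rec: GestureRecording, vocab: LabelVocabulary = DEFAULT_VOCAB):
        table = build_feature_table(rec, "CapDelta")
        null_idx = np.flatnonzero(table.labels == vocab.null_label)
        if len(null_idx) < 20:
            raise FiltError("too few 'Null' samples to fit the detector")
        rng = np.random.default_rng(self.random_state)
        perm = rng.permutation(null_idx)
        k = math.floor(self.train_frac * len(null_idx))
        train_idx = np.sort(perm[:k])
        holdout_idx = np.sort(
            np.setdiff1d(np.arange(table.n), train_idx, assume_unique=False)
        )
        contamination, report, det = tune_contamination(
            table.take(train_idx),
            table.take(holdout_idx),
            grid=self.contamination_grid,
            null_label=vocab.null_label,
            random_state=self.random_state,
        )
        self.vocab_ = vocab
        self.contamination_ = contamination
        self.detector_ = det
        self.stage1_holdout_ = report
        return self

    def stage1(self, rec: GestureRecording) -> Stage1Report:
        """Flag a full session and score the stage-1 metrics on it."""
        table = build_feature_table(rec, "CapDelta")
        return _stage1_report(self.detector_, table, self.vocab_.null_label, keep_flags=True)

    def transform(self, rec: GestureRecording) -> RelabelOutcome:
        report = self.stage1(rec)
        return relabel_transitions(rec, report.flags, self.vocab_)
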