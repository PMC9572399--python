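"""Time Series Consolidation: confusion-driven merging of gesture classes.

Users are not reliable in reproducing all gestures; classes that blur into
each other across repetitions within one session will not survive a second
session.  TSC measures this with repetition-wise forward-chaining: batch
``b`` trains a classifier, batch ``b+1`` validates it, and the
row-normalized confusion matrices are averaged.  A threshold search (T1)
finds the largest per-class-accuracy threshold recognising a target number
of gestures, a Consolidation Algorithm (CA) merges each sub-threshold class
into its most-confused partner (with 'Neutral', 'Fist' and — where present
— 'Null' protected from being merged away), and a second, tighter round
(in-session confusion matrix, upward threshold search T2, second CA pass)
refines the merge.  The composed mapping yields a smaller gesture set
tailored to the individual user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, clone

from .data import (
    DEFAULT_VOCAB,
    DataError,
    FeatureTable,
    LabelVocabulary,
    split_35_65,
)

BAD_CLASS_THRESHOLD = 0.8


class BatchError(ValueError):
    """Gesture repetition counts do not form equal batches."""


@dataclass(frozen=True)
class TscConfig:
    """Threshold-search constants (all on a rounded 3-decimal grid)."""

    thresh_start: float = 0.99
    thresh_min: float = 0.70
    g_target: int = 10
    g_min: int = 5
    step_down: float = 0.005
    step_up: float = 0.001
    g_targ2: int = 5
    g_max: int = 10  # recorded by the search but never consulted


DEFAULT_CONFIG = TscConfig()


@dataclass(frozen=True)
class ThresholdOutcome:
    """Result of a threshold search: recognised-class count and threshold."""

    g_recog: int | None  # None encodes Fail
    thresh: float
    config: TscConfig = DEFAULT_CONFIG

    @property
    def failed(self) -> bool:
        return self.g_recog is None


@dataclass(frozen=True)
class AveragedCM:
    """Row-normalized confusion matrix averaged over repetition batches.

    ``matrix[r, c]`` is the mean fraction of class ``labels[r]`` validation
    samples predicted as ``labels[c]``, averaged over the batches in which
    class ``r`` had validation samples; a row unsupported in every batch is
    NaN.  ``row_support`` counts the batches contributing to each row.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    n_batches_used: int
    row_support: np.ndarray | None = None

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


def _round3(x: float) -> float:
    return round(x, 3)


# ---------------------------------------------------------------------------
# batching and averaged confusion matrices


def repetition_batches(
    table: FeatureTable,
    null_label: str = DEFAULT_VOCAB.null_label,
    strict: bool = True,
) -> list[np.ndarray]:
    """Partition samples into time-ordered repetition batches.

    Every gesture must have the same repetition count ``b_MAX``; batch ``b``
    holds each gesture's ``b``-th repetition.  A label with a different run
    count (the 'Null' windows, of which there are roughly one per prompt)
    has its time-ordered runs divided into ``b_MAX`` consecutive groups.

    ``strict=False`` relaxes the equal-count requirement for tables whose
    repetitions have been altered upstream (transition repair fuses
    back-to-back repetitions of the same gesture): ``b_MAX`` becomes the
    largest gesture run count and a short gesture is simply absent from the
    surplus batches, which the averaged confusion matrix tolerates.
    """
    labels = np.unique(table.labels.astype(str))
    runs_by_label: dict[str, list[np.ndarray]] = {}
    for lab in labels:
        idx = np.flatnonzero(table.labels == lab)
        if len(idx) == 0:
            continue
        reps = table.reps[idx]
        # consecutive-run grouping within this label, in time order
        boundaries = np.flatnonzero(np.diff(reps) != 0) + 1
        runs_by_label[lab] = np.split(idx, boundaries)
    gesture_counts = {
        lab: len(r) for lab, r in runs_by_label.items() if lab != null_label
    }
    counts = set(gesture_counts.values())
    if len(counts) != 1:
        if strict:
            raise BatchError(f"unequal repetition counts per gesture: {gesture_counts}")
        b_max = max(counts)
    else:
        b_max = counts.pop()
    if b_max < 2:
        raise BatchError("need at least 2 repetitions per gesture")
    batches: list[list[np.ndarray]] = [[] for _ in range(b_max)]
    for lab, runs in runs_by_label.items():
        for b, chunk in enumerate(np.array_split(np.arange(len(runs)), b_max)):
            for r in chunk:
                batches[b].append(runs[r])
    return [np.sort(np.concatenate(b)) for b in batches]


def confusion_counts(y_true, y_pred, labels: tuple[str, ...]) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return mat


def row_normalize(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize rows to sums of 1; unsupported rows become NaN."""
    support = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = counts / support[:, None]
    mat[support == 0] = np.nan
    return mat, support


def averaged_cm(
    table: FeatureTable,
    classifier: BaseEstimator,
    vocab: LabelVocabulary = DEFAULT_VOCAB,
    strict_batches: bool = True,
) -> AveragedCM:
    """Forward-chaining repetition splits: train on batch b, validate on b+1.

    Each per-split confusion matrix is row-normalized before averaging, and
    a class's row is averaged only over the splits in which it had
    validation samples.  The divisor is therefore the number of confusion
    matrices actually computed (one fewer than the number of batches).
    """
    batches = repetition_batches(table, vocab.null_label, strict=strict_batches)
    if len(batches) < 2:
        raise BatchError("need at least 2 batches")
    labels = tuple(map(str, vocab.order(set(table.labels.astype(str)))))
    acc = np.zeros((len(labels), len(labels)))
    row_n = np.zeros(len(labels))
    for b in range(len(batches) - 1):
        train_idx, val_idx = batches[b], batches[b + 1]
        clf = clone(classifier)
        clf.fit(table.X[train_idx], table.labels[train_idx].astype(str))
        pred = clf.predict(table.X[val_idx])
        counts = confusion_counts(table.labels[val_idx].astype(str), pred, labels)
        mat, support = row_normalize(counts)
        present = support > 0
        acc[present] += mat[present]
        row_n += present
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / row_n[:, None]
    mean[row_n == 0] = np.nan
    return AveragedCM(
        labels=labels,
        matrix=mean,
        n_batches_used=len(batches) - 1,
        row_support=row_n,
    )


# ---------------------------------------------------------------------------
# threshold searches


def t1_iteration_bound(config: TscConfig = DEFAULT_CONFIG) -> int:
    """Worst-case iteration count of the downward search."""
    steps = round((config.thresh_start - config.thresh_min) / config.step_down, 9)
    return (int(np.ceil(steps)) + 1) * (config.g_target - config.g_min + 1)


def t2_iteration_bound(thresh_start2: float, config: TscConfig = DEFAULT_CONFIG) -> int:
    """Worst-case iteration count of the upward search."""
    return int(np.ceil(round((1.0 - thresh_start2) / config.step_up, 9))) + 1


def t1_search(cm: AveragedCM | np.ndarray, config: TscConfig = DEFAULT_CONFIG) -> ThresholdOutcome:
    """Downward threshold search with target-count relaxation.

    Count diagonal entries >= thresh; while too few are recognised, lower
    the threshold in 0.005 steps to the floor, then reset the threshold and
    relax the target by one gesture, down to ``g_min``; if the floor is hit
    at the minimum target the search fails.
    """
    diag = cm.diagonal if isinstance(cm, AveragedCM) else np.asarray(cm, dtype=float)
    diag = np.where(np.isnan(diag), -np.inf, diag)
    thresh = _round3(config.thresh_start)
    g_target = config.g_target
    g_max = config.g_target  # recorded, never used (kept for fidelity)
    del g_max
    bound = t1_iteration_bound(config)
    iterations = 0
    while True:
        iterations += 1
        if iterations > bound:  # structural termination guarantee
            raise RuntimeError("threshold search exceeded its iteration bound")
        g_recog = int(np.sum(diag >= thresh))
        if g_recog < g_target:
            if thresh > config.thresh_min:
                thresh = _round3(thresh - config.step_down)
            elif g_target > config.g_min:
                thresh = _round3(config.thresh_start)
                g_target -= 1
            else:
                return ThresholdOutcome(g_recog=None, thresh=thresh, config=config)
        else:
            return ThresholdOutcome(g_recog=g_recog, thresh=thresh, config=config)


def t2_search(
    cm: AveragedCM | np.ndarray,
    thresh_start2: float,
    g_targ2: int = DEFAULT_CONFIG.g_targ2,
    config: TscConfig = DEFAULT_CONFIG,
) -> ThresholdOutcome:
    """Upward refinement: raise the threshold while more than ``g_targ2``
    classes stay above it, stopping at 1.0."""
    diag = cm.diagonal if isinstance(cm, AveragedCM) else np.asarray(cm, dtype=float)
    diag = np.where(np.isnan(diag), -np.inf, diag)
    thresh = _round3(thresh_start2)
    bound = t2_iteration_bound(thresh, config)
    iterations = 0
    while True:
        iterations += 1
        if iterations > bound:  # structural termination guarantee
            raise RuntimeError("threshold search exceeded its iteration bound")
        g_recog = int(np.sum(diag >= thresh))
        if g_recog > g_targ2 and thresh < 1.0:
            thresh = _round3(thresh + config.step_up)
        else:
            return ThresholdOutcome(g_recog=g_recog, thresh=thresh, config=config)


# ---------------------------------------------------------------------------
# consolidation


@dataclass(frozen=True)
class MergeMap:
    """Mapping from merged-away labels to retained labels.

    ``raw`` is the chain-rule dictionary exactly as the consolidation pass
    produced it; ``resolved`` is its fixpoint closure (no retained label is
    itself a key), which is what :func:`apply_merge` uses.
    """

    raw: dict
    resolved: dict

    def apply(self, labels) -> np.ndarray:
        labels = np.asarray(labels, dtype=object)
        return np.array([self.resolved.get(l, l) for l in labels], dtype=object)

    def retained(self, universe) -> list[str]:
        return [lab for lab in universe if lab not in self.resolved]

    def __len__(self) -> int:
        return len(self.resolved)


def _resolve(mapping: dict) -> dict:
    """Fixpoint closure of a merge dictionary.

    Chains are followed to their terminal label; self-maps are dropped.  In
    a cycle (possible through the chain rule) every member is mapped to the
    cycle's first-inserted label, which stays retained.
    """
    order = {k: i for i, k in enumerate(mapping)}
    resolved: dict = {}
    for key in mapping:
        seen = [key]
        cur = key
        while cur in mapping:
            nxt = mapping[cur]
            if nxt in seen:
                cycle = seen[seen.index(nxt):]
                cur = min(cycle, key=lambda c: order[c])
                break
            seen.append(nxt)
            cur = nxt
        if cur != key:
            resolved[key] = cur
    return resolved


def ca_consolidate(
    cm: AveragedCM,
    thresh: float,
    vocab: LabelVocabulary = DEFAULT_VOCAB,
    protected: tuple[str, ...] | None = None,
) -> MergeMap:
    """Consolidation Algorithm: merge sub-threshold classes into their most
    confused partner.

    Rows are visited in vocabulary order.  For a row whose diagonal is below
    the threshold, the off-diagonal argmax names the partner; if the partner
    was itself already merged the chain rule maps into the partner's target.
    A protection pass then guarantees that protected labels ('Neutral',
    'Fist', and 'Null' when it is a class) absorb merges instead of being
    merged away: an entry keyed by a protected label is inverted so its
    partner maps into the protected label (entries between two protected
    labels are dropped).  Rows of all zeros are skipped with a warning.
    """
    if not 0.0 < thresh <= 1.0:
        raise ValueError("thresh must be in (0, 1]")
    if protected is None:
        protected = tuple(
            lab for lab in cm.labels if lab in vocab.protected or lab == vocab.null_label
        )
    labels = cm.labels
    g_map: dict = {}
    for r, lab in enumerate(labels):
        row = cm.matrix[r]
        if np.all(np.isnan(row)):
            continue
        if np.nansum(row) == 0:
            warnings.warn(f"confusion row for {lab!r} is all zeros; skipped")
            continue
        if not row[r] < thresh:  # NaN diagonal also skips
            continue
        off = row.copy()
        off[r] = -np.inf
        off = np.where(np.isnan(off), -np.inf, off)
        g_j = labels[int(np.argmax(off))]  # argmax ties -> earliest label
        if g_j not in g_map:
            g_map[lab] = g_j
        else:
            g_map[lab] = g_map[g_j]
    raw = dict(g_map)
    # protection pass: invert entries that would merge a protected label away
    for p in [lab for lab in labels if lab in protected]:
        if p in g_map:
            target = g_map.pop(p)
            if target in protected:
                continue  # neither protected label merges
            g_map[target] = p
    resolved = _resolve(g_map)
    # protected labels must never be keys after resolution
    for p in protected:
        resolved.pop(p, None)
    return MergeMap(raw=raw, resolved=resolved)


def apply_merge(table: FeatureTable, merge: MergeMap, vocab: LabelVocabulary = DEFAULT_VOCAB) -> FeatureTable:
    """Relabel a feature table through a resolved merge map."""
    unknown = set(map(str, table.labels)) - set(vocab.all_labels)
    if unknown:
        raise DataError(f"labels outside vocabulary: {sorted(unknown)}")
    return table.with_labels(merge.apply(table.labels))


# ---------------------------------------------------------------------------
# adjusted metrics


def class_adjust(class_count: int) -> int:
    """Add the 'Null' class removed by the filter stage back to the count."""
    return class_count + 1


def acc_adjust(mean_acc: float, n_classes: int, acc_stage1: float) -> float:
    """Fold the filter stage's accuracy into the class-averaged accuracy."""
    if not (0.0 <= mean_acc <= 1.0 and 0.0 <= acc_stage1 <= 1.0):
        raise ValueError("accuracies must be in [0, 1]")
    return (mean_acc * n_classes + acc_stage1) / class_adjust(n_classes)


def class_bad(cm: AveragedCM | np.ndarray, threshold: float = BAD_CLASS_THRESHOLD) -> int:
    """Number of classes whose per-class accuracy falls below 80%."""
    diag = cm.diagonal if isinstance(cm, AveragedCM) else np.asarray(cm, dtype=float)
    return int(np.sum(diag < threshold))


# ---------------------------------------------------------------------------
# the full two-round procedure


@dataclass
class TscRound:
    cm: AveragedCM
    outcome: ThresholdOutcome
    merge: MergeMap | None


@dataclass
class TscFit:
    merge_map: MergeMap | None
    round1: TscRound
    round2: TscRound | None
    failed: bool


def tsc_fit(
    table: FeatureTable,
    classifier: BaseEstimator,
    vocab: LabelVocabulary = DEFAULT_VOCAB,
    config: TscConfig = DEFAULT_CONFIG,
    seed: int = 0,
    strict_batches: bool = True,
) -> TscFit:
    """Run the full two-round consolidation on (already scaled) Data1.

    Round 1: averaged repetition-batch confusion matrix, downward threshold
    search, first consolidation pass.  Round 2: relabel Data1, train on a
    stratified 35% split, form the single in-session confusion matrix on the
    hold-out, raise the threshold (T2) and consolidate again.  The returned
    map is the resolved composition of both passes.
    """
    cm1 = averaged_cm(table, classifier, vocab, strict_batches=strict_batches)
    t1 = t1_search(cm1, config)
    if t1.failed:
        return TscFit(
            merge_map=None,
            round1=TscRound(cm=cm1, outcome=t1, merge=None),
            round2=None,
            failed=True,
        )
    map1 = ca_consolidate(cm1, t1.thresh, vocab)
    round1 = TscRound(cm=cm1, outcome=t1, merge=map1)

    merged = apply_merge(table, map1, vocab)
    train, test = split_35_65(merged, seed=seed)
    clf = clone(classifier)
    clf.fit(train.X, train.labels.astype(str))
    pred = clf.predict(test.X)
    labels2 = tuple(map(str, vocab.order(set(merged.labels.astype(str)))))
    counts = confusion_counts(test.labels.astype(str), pred, labels2)
    mat, support = row_normalize(counts)
    cm2 = AveragedCM(labels=labels2, matrix=mat, n_batches_used=1, row_support=support)
    t2 = t2_search(cm2, thresh_start2=t1.thresh, g_targ2=config.g_targ2, config=config)
    map2 = ca_consolidate(cm2, t2.thresh, vocab)
    round2 = TscRound(cm=cm2, outcome=t2, merge=map2)

    composed: dict = {}
    for lab in vocab.all_labels:
        m1 = map1.resolved.get(lab, lab)
        m2 = map2.resolved.get(m1, m1)
        if m2 != lab:
            composed[lab] = m2
    merge_map = MergeMap(raw=composed, resolved=_resolve(composed))
    return TscFit(merge_map=merge_map, round1=round1, round2=round2, failed=False)


class TimeSeriesConsolidator(BaseEstimator):
    """Sklearn-style wrapper around :func:`tsc_fit`.

    ``fit`` consumes a scaled Data1 :class:`FeatureTable` and exposes
    ``merge_map_``, ``round1_`` and ``round2_``; ``transform`` relabels any
    feature table through the learned map.
    """

    def __init__(
        self,
        classifier: BaseEstimator,
        config: TscConfig = DEFAULT_CONFIG,
        seed: int = 0,
    ):
        self.classifier = classifier
        self.config = config
        self.seed = seed

    def fit(self, table: FeatureTable, vocab: LabelVocabulary = DEFAULT_VOCAB):
        result = tsc_fit(table, self.classifier, vocab, self.config, self.seed)
        self.vocab_ = vocab
        self.failed_ = result.failed
        self.merge_map_ = result.merge_map
        self.round1_ = result.round1
        self.round2_ = result.round2
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if self.failed_:
            raise RuntimeError("consolidation failed; no merge map available")
        return apply_merge(table, self.merge_map_, self.vocab_)
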