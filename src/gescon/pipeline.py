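"""Per-user pipeline search and the four label-handling methods.

A pipeline is (feature set, scaler, classifier + hyperparameters).  The
full grid — 6 feature sets x 3 scalers x (14 KNN configurations + SVC +
balanced random forest) = 288 pipelines — is searched exhaustively on
Data1, scored by weighted F1 on the in-session 65% hold-out, and the winner
is carried to inter-session validation on Data2.  Four methods differ in
how mislabeled/unreliable data is handled before that search:

RAWSIS   — no correction (the baseline),
FILTSIS  — transition repair (FILT) on both sessions,
RAWTSC   — class consolidation (TSC) learned on Data1,
FILTTSC  — FILT followed by TSC.

Nothing computed from Data2 ever enters fitting, scaling, tuning or
selection; Data2 is touched only to produce validation predictions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data import (
    DEFAULT_VOCAB,
    FeatureTable,
    GestureRecording,
    LabelVocabulary,
)
from .features import (
    FEATURE_SETS,
    RedundancyFilter,
    SCALER_KINDS,
    apply_scaler,
    build_feature_table,
    fit_scaler,
)
from .filt import NullTransitionFilter, Stage1Report
from .tsc import (
    AveragedCM,
    DEFAULT_CONFIG,
    MergeMap,
    TscConfig,
    apply_merge,
    class_adjust,
    acc_adjust,
    class_bad,
    confusion_counts,
    row_normalize,
    tsc_fit,
)

logger = logging.getLogger(__name__)

METHODS = ("RAWSIS", "FILTSIS", "RAWTSC", "FILTTSC")

KNN_NEIGHBORS = (19, 21, 23, 25, 27, 29, 31)
KNN_METRICS = ("manhattan", "euclidean")
BRF_TREES = 200


@dataclass(frozen=True)
class PipelineSpec:
    """One point of the exhaustive search grid."""

    feature_set: str
    scaler: str
    classifier: str  # KNN | SVC | BRF
    n_neighbors: int | None = None
    metric: str | None = None

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.scaler not in SCALER_KINDS:
            raise ValueError(f"unknown scaler {self.scaler!r}")
        if self.classifier == "KNN":
            if self.n_neighbors not in KNN_NEIGHBORS or self.metric not in KNN_METRICS:
                raise ValueError("illegal KNN hyperparameters")
        elif self.classifier in ("SVC", "BRF"):
            if self.n_neighbors is not None or self.metric is not None:
                raise ValueError(f"{self.classifier} takes no KNN hyperparameters")
        else:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def id(self) -> str:
        if self.classifier == "KNN":
            return f"{self.feature_set}/{self.scaler}/KNN(k={self.n_neighbors},{self.metric})"
        return f"{self.feature_set}/{self.scaler}/{self.classifier}"


def enumerate_pipelines() -> list[PipelineSpec]:
    """The full 288-spec cross product of the search grid."""
    specs: list[PipelineSpec] = []
    for fs in FEATURE_SETS:
        for sc in SCALER_KINDS:
            for k in KNN_NEIGHBORS:
                for metric in KNN_METRICS:
                    specs.append(
                        PipelineSpec(fs, sc, "KNN", n_neighbors=k, metric=metric)
                    )
            specs.append(PipelineSpec(fs, sc, "SVC"))
            specs.append(PipelineSpec(fs, sc, "BRF"))
    return specs


def reduced_pipelines() -> list[PipelineSpec]:
    """A small, fast sub-grid for batch experiments.

    Two base feature sets, unscaled vs standardised, and two KNN
    configurations — KNN dominates the full grid's winners and this subset
    spans the axes (features, scaling, distance metric) that matter.
    """
    specs: list[PipelineSpec] = []
    for fs in ("Cap", "Caps"):
        for sc in ("none", "standard"):
            specs.append(PipelineSpec(fs, sc, "KNN", n_neighbors=19, metric="manhattan"))
            specs.append(PipelineSpec(fs, sc, "KNN", n_neighbors=25, metric="euclidean"))
    return specs


def make_classifier(spec: PipelineSpec, seed: int = 0) -> BaseEstimator:
    """Instantiate the classifier named by a pipeline spec.

    The balanced random forest is a 200-tree random forest with
    per-bootstrap class rebalancing (``class_weight='balanced_subsample'``),
    covering the class imbalances consolidation can create.
    """
    if spec.classifier == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.n_neighbors, metric=spec.metric)
    if spec.classifier == "SVC":
        return SVC(kernel="rbf", random_state=seed)  # defaults; no tuning
    return RandomForestClassifier(
        n_estimators=BRF_TREES,
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )


def weighted_f1(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1 = 2PR/(P+R).

    Classes (taken from the true labels) with P + R = 0 contribute 0.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValueError("label arrays must be aligned and nonempty")
    total = 0.0
    n = len(y_true)
    for lab in np.unique(y_true.astype(str)):
        tp = np.sum((y_true == lab) & (y_pred == lab))
        fp = np.sum((y_true != lab) & (y_pred == lab))
        fn = np.sum((y_true == lab) & (y_pred != lab))
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        total += (tp + fn) / n * f1
    return float(total)


# ---------------------------------------------------------------------------
# selection


def _stratified_indices(
    labels: np.ndarray, seed: int, train_frac: float = 0.35
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class 35/65 split of row positions (floor on the train side)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object).astype(str)
    train_rows: list[np.ndarray] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        perm = rng.permutation(idx)
        train_rows.append(perm[: math.floor(train_frac * len(idx))])
    train_idx = np.sort(np.concatenate(train_rows)).astype(int)
    test_idx = np.setdiff1d(np.arange(len(labels)), train_idx)
    return train_idx, test_idx


@dataclass
class SelectionResult:
    spec: PipelineSpec
    f1: float
    scores: dict  # spec id -> f1 (failed specs absent)


def _session_tables(
    rec: GestureRecording,
    feature_sets,
    optim_columns: dict | None = None,
) -> tuple[dict, dict]:
    """Build the requested feature tables for one recording.

    ``Optim*`` column choices are fitted on this recording when
    ``optim_columns`` is None (the Data1 role) and reused verbatim otherwise
    (the Data2 role), so a second session can never influence selection.
    """
    tables: dict = {}
    columns: dict = dict(optim_columns or {})
    base_cache: dict = {}
    for fs in feature_sets:
        base_id = fs.removeprefix("Optim") if fs.startswith("Optim") else fs
        if base_id not in base_cache:
            base_cache[base_id] = build_feature_table(rec, base_id)
        table = base_cache[base_id]
        if fs.startswith("Optim"):
            if fs not in columns:
                filt = RedundancyFilter().fit(table.features, table.labels)
                columns[fs] = filt.columns_
            table = table.with_columns(columns[fs])
            table.feature_set = fs
        tables[fs] = table
    return tables, columns


def select_pipeline(
    data1: GestureRecording,
    seed: int,
    specs: list[PipelineSpec] | None = None,
    vocab: LabelVocabulary = DEFAULT_VOCAB,
) -> SelectionResult:
    """Exhaustive in-session search: train on the 35% split, score weighted
    F1 on the 65% hold-out, return the best spec (ties keep grid order)."""
    if specs is None:
        specs = enumerate_pipelines()
    if not specs:
        raise ValueError("no pipeline specs to search")
    feature_sets = sorted({s.feature_set for s in specs}, key=FEATURE_SETS.index)
    tables, _ = _session_tables(data1, feature_sets)

    # one stratified split shared by every spec (rows identical across sets)
    any_table = next(iter(tables.values()))
    train_idx, test_idx = _stratified_indices(any_table.labels, seed)

    scaled_cache: dict = {}
    best: tuple[float, int] | None = None
    best_spec: PipelineSpec | None = None
    scores: dict = {}
    for i, spec in enumerate(specs):
        key = (spec.feature_set, spec.scaler)
        if key not in scaled_cache:
            table = tables[spec.feature_set]
            train_tab = table.take(train_idx)
            test_tab = table.take(test_idx)
            try:
                scaler = fit_scaler(spec.scaler, train_tab)
            except ValueError as err:
                logger.warning("scaler %s failed on %s: %s", spec.scaler, spec.feature_set, err)
                scaled_cache[key] = None
            else:
                scaled_cache[key] = (
                    apply_scaler(scaler, train_tab),
                    apply_scaler(scaler, test_tab),
                )
        if scaled_cache[key] is None:
            continue
        train_tab, test_tab = scaled_cache[key]
        clf = make_classifier(spec, seed=seed)
        try:
            clf.fit(train_tab.X, train_tab.labels.astype(str))
            pred = clf.predict(test_tab.X)
        except Exception as err:  # a failing spec is skipped, not fatal
            logger.warning("spec %s failed to fit: %s", spec.id, err)
            continue
        f1 = weighted_f1(test_tab.labels, pred)
        scores[spec.id] = f1
        logger.debug("spec %s f1=%.4f", spec.id, f1)
        if best is None or f1 > best[0]:
            best = (f1, i)
            best_spec = spec
    if best_spec is None:
        raise RuntimeError("every pipeline spec failed to fit")
    logger.info("selected %s (f1=%.4f)", best_spec.id, best[0])
    return SelectionResult(spec=best_spec, f1=best[0], scores=scores)


# ---------------------------------------------------------------------------
# the four methods


def _cm_dict(labels, matrix) -> dict:
    return {"labels": list(labels), "matrix": np.asarray(matrix).tolist()}


@dataclass
class MethodReport:
    """Per-subject, per-method result bundle."""

    method: str
    subject_id: str
    spec: PipelineSpec | None
    selection_f1: float | None
    in_session_cm: AveragedCM | None
    inter_session_cm: AveragedCM | None
    mean_acc_in: float | None
    mean_acc_is: float | None
    classes_retained: int | None
    class_bad_is: int | None
    classes_adjusted: int | None = None  # FILT methods: retained + 1
    acc_adjust_in: float | None = None
    acc_adjust_is: float | None = None
    stage1_in: Stage1Report | None = None
    stage1_is: Stage1Report | None = None
    merge_map: MergeMap | None = None
    failed: bool = False

    @property
    def headline_accuracy_is(self) -> float | None:
        """Adjusted inter-session accuracy for FILT methods, raw otherwise."""
        return self.acc_adjust_is if self.acc_adjust_is is not None else self.mean_acc_is

    @property
    def headline_classes(self) -> int | None:
        return (
            self.classes_adjusted
            if self.classes_adjusted is not None
            else self.classes_retained
        )

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "subject_id": self.subject_id,
            "failed": self.failed,
            "pipeline": self.spec.id if self.spec else None,
            "selection_f1": self.selection_f1,
            "mean_acc_in": self.mean_acc_in,
            "mean_acc_is": self.mean_acc_is,
            "classes_retained": self.classes_retained,
            "class_bad_is": self.class_bad_is,
            "classes_adjusted": self.classes_adjusted,
            "acc_adjust_in": self.acc_adjust_in,
            "acc_adjust_is": self.acc_adjust_is,
        }
        if self.stage1_in is not None:
            out["stage1"] = {
                "in_session": self.stage1_in.to_dict(),
                "inter_session": self.stage1_is.to_dict() if self.stage1_is else None,
            }
        if self.merge_map is not None:
            out["merge_map"] = dict(self.merge_map.resolved)
        if self.in_session_cm is not None:
            out["in_session_cm"] = _cm_dict(
                self.in_session_cm.labels, self.in_session_cm.matrix
            )
        if self.inter_session_cm is not None:
            out["inter_session_cm"] = _cm_dict(
                self.inter_session_cm.labels, self.inter_session_cm.matrix
            )
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _prepare_spec_tables(
    data1: GestureRecording,
    data2: GestureRecording,
    spec: PipelineSpec,
    seed: int,
) -> tuple[FeatureTable, FeatureTable, np.ndarray, np.ndarray]:
    """Build and scale both sessions' tables for one spec.

    The redundancy-filter columns and the scaler statistics both come from
    Data1 (the scaler from its 35% training split) and are applied, never
    refitted, to Data2.
    """
    tables1, optim_cols = _session_tables(data1, [spec.feature_set])
    tables2, _ = _session_tables(data2, [spec.feature_set], optim_columns=optim_cols)
    t1, t2 = tables1[spec.feature_set], tables2[spec.feature_set]
    train_idx, test_idx = _stratified_indices(t1.labels, seed)
    scaler = fit_scaler(spec.scaler, t1.take(train_idx))
    t1s = apply_scaler(scaler, t1)
    t2s = apply_scaler(scaler, t2)
    return t1s, t2s, train_idx, test_idx


def _evaluate(
    clf, table_train: FeatureTable, eval_tables: list[FeatureTable], label_order
) -> list[AveragedCM]:
    clf.fit(table_train.X, table_train.labels.astype(str))
    cms = []
    for tab in eval_tables:
        pred = clf.predict(tab.X)
        counts = confusion_counts(tab.labels.astype(str), pred, tuple(label_order))
        mat, support = row_normalize(counts)
        cms.append(
            AveragedCM(labels=tuple(label_order), matrix=mat, n_batches_used=1, row_support=support)
        )
    return cms


def _mean_diag(cm: AveragedCM) -> float:
    return float(np.nanmean(cm.diagonal))


def run_method(
    method: str,
    data1: GestureRecording,
    data2: GestureRecording,
    seed: int,
    specs: list[PipelineSpec] | None = None,
    vocab: LabelVocabulary = DEFAULT_VOCAB,
    tsc_config: TscConfig = DEFAULT_CONFIG,
) -> MethodReport:
    """Run one of the four methods end to end for one subject.

    Selection, scaling, filtering and consolidation are all fitted on Data1;
    Data2 appears only as validation input.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")

    stage1_in = stage1_is = None
    merge_map = None
    classes_adjusted = None
    acc_in_adj = acc_is_adj = None

    work1, work2 = data1, data2
    if method.startswith("FILT"):
        nf = NullTransitionFilter(random_state=seed).fit(data1, vocab)
        stage1_in = nf.stage1_holdout_  # precision/accuracy on held-out Data1
        out1 = nf.transform(data1)
        stage1_is = nf.stage1(data2)
        out2 = nf.transform(data2)
        stage1_in.flags = None
        stage1_is.flags = None
        work1, work2 = out1.recording, out2.recording

    selection = select_pipeline(work1, seed=seed, specs=specs, vocab=vocab)
    spec = selection.spec
    t1s, t2s, train_idx, test_idx = _prepare_spec_tables(work1, work2, spec, seed)

    if method.endswith("TSC"):
        fit = tsc_fit(
            t1s,
            make_classifier(spec, seed),
            vocab,
            tsc_config,
            seed=seed,
            strict_batches=not method.startswith("FILT"),
        )
        if fit.failed:
            return MethodReport(
                method=method,
                subject_id=data1.subject_id,
                spec=spec,
                selection_f1=selection.f1,
                in_session_cm=None,
                inter_session_cm=None,
                mean_acc_in=None,
                mean_acc_is=None,
                classes_retained=None,
                class_bad_is=None,
                failed=True,
            )
        merge_map = fit.merge_map
        t1s = apply_merge(t1s, merge_map, vocab)
        t2s = apply_merge(t2s, merge_map, vocab)

    label_order = [str(l) for l in vocab.order(set(t1s.labels.astype(str)))]
    clf = make_classifier(spec, seed)
    cm_in, cm_is = _evaluate(
        clf, t1s.take(train_idx), [t1s.take(test_idx), t2s], label_order
    )
    mean_in, mean_is = _mean_diag(cm_in), _mean_diag(cm_is)
    retained = len(label_order)

    if method.startswith("FILT"):
        classes_adjusted = class_adjust(retained)
        acc_in_adj = acc_adjust(mean_in, retained, stage1_in.accuracy)
        acc_is_adj = acc_adjust(mean_is, retained, stage1_is.accuracy)

    return MethodReport(
        method=method,
        subject_id=data1.subject_id,
        spec=spec,
        selection_f1=selection.f1,
        in_session_cm=cm_in,
        inter_session_cm=cm_is,
        mean_acc_in=mean_in,
        mean_acc_is=mean_is,
        classes_retained=retained,
        class_bad_is=class_bad(cm_is),
        classes_adjusted=classes_adjusted,
        acc_adjust_in=acc_in_adj,
        acc_adjust_is=acc_is_adj,
        stage1_in=stage1_in,
        stage1_is=stage1_is,
        merge_map=merge_map,
    )
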