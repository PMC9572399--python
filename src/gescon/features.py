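"""Feature engineering and scaling for capacitive gesture streams.

Three base feature sets are available: ``Cap`` (the 8 raw channel counts),
``CapDelta`` (per-channel first differences, the rate-of-change features)
and ``Caps`` (their concatenation).  Each has an ``Optim*`` variant that
has passed through a redundancy filter which greedily drops features that
are near-duplicates (absolute Pearson correlation above ``rho_max``) of a
retained feature, preferring the feature with higher mutual information
with the class label.  The filter is a declared stand-in for automatic
correlation-based feature selection; its retained-column choice is made on
the fitting session and reused unchanged elsewhere.

Scaling is min-max normalisation or standardisation, fitted only on the
35% Data1 training split and applied without clipping — out-of-range
values on later data are the signal that the stationarity assumption was
violated, so they are deliberately preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import mutual_info_classif

from .data import (
    DataError,
    FeatureTable,
    GestureRecording,
    segment_repetitions,
)

FEATURE_SETS = ("Cap", "CapDelta", "Caps", "OptimCap", "OptimCapDelta", "OptimCaps")
SCALER_KINDS = ("none", "minmax", "standard")

CAP_COLUMNS = tuple(f"cap{i}" for i in range(1, 9))
DELTA_COLUMNS = tuple(f"dcap{i}" for i in range(1, 9))


def delta_features(rec: GestureRecording) -> np.ndarray:
    """Per-sample rate-of-change: reading[t] - reading[t-1], first row 0."""
    if rec.n < 1:
        raise DataError("recording must have at least one sample")
    deltas = np.zeros_like(rec.channels)
    deltas[1:] = rec.channels[1:] - rec.channels[:-1]
    return deltas


def base_feature_frame(rec: GestureRecording, set_id: str) -> pd.DataFrame:
    if set_id in ("Cap", "OptimCap"):
        return pd.DataFrame(rec.channels, columns=list(CAP_COLUMNS))
    if set_id in ("CapDelta", "OptimCapDelta"):
        return pd.DataFrame(delta_features(rec), columns=list(DELTA_COLUMNS))
    if set_id in ("Caps", "OptimCaps"):
        return pd.DataFrame(
            np.hstack([rec.channels, delta_features(rec)]),
            columns=list(CAP_COLUMNS) + list(DELTA_COLUMNS),
        )
    raise ValueError(f"unknown feature set {set_id!r}")


def build_feature_table(
    rec: GestureRecording, set_id: str, rho_max: float = 0.9
) -> FeatureTable:
    """Build the per-sample feature table for one recording.

    ``Optim*`` sets run the redundancy filter on this recording's own
    features and labels; when a shared column choice across sessions is
    needed (as in the learning pipelines) fit :class:`RedundancyFilter`
    once and apply its columns instead.
    """
    if set_id not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_id!r}")
    frame = base_feature_frame(rec, set_id)
    reps = segment_repetitions(rec).rep_ids
    table = FeatureTable(
        features=frame,
        labels=rec.prompt_labels,
        reps=reps,
        subject_id=rec.subject_id,
        session_id=rec.session_id,
        feature_set=set_id,
    )
    if set_id.startswith("Optim"):
        table = redundancy_filter(table, rho_max=rho_max)
        table.feature_set = set_id
    return table


class RedundancyFilter(BaseEstimator, TransformerMixin):
    """Greedy correlation-based redundancy filter.

    Features are visited in decreasing label mutual information (ties keep
    input order); a feature is retained iff its absolute Pearson
    correlation with every already-retained feature is <= ``rho_max``.
    Constant features carry no correlation signal and are retained last.
    """

    def __init__(self, rho_max: float = 0.9, random_state: int = 0):
        self.rho_max = rho_max
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        if X.shape[1] < 2:
            raise ValueError("redundancy filtering needs at least 2 features")
        cols = list(X.columns)
        values = X.to_numpy(dtype=float)
        sd = values.std(axis=0)
        varying = [i for i in range(len(cols)) if sd[i] > 0]
        constant = [i for i in range(len(cols)) if sd[i] == 0]
        y_codes = pd.factorize(np.asarray(y, dtype=object))[0]
        mi = np.zeros(len(cols))
        if varying:
            mi[varying] = mutual_info_classif(
                values[:, varying], y_codes, random_state=self.random_state
            )
        # decreasing MI; ties broken by input order
        order = sorted(varying, key=lambda i: (-mi[i], i))
        corr = np.corrcoef(values[:, varying], rowvar=False) if varying else None
        pos = {idx: k for k, idx in enumerate(varying)}
        kept: list[int] = []
        for i in order:
            if all(abs(corr[pos[i], pos[j]]) <= self.rho_max for j in kept):
                kept.append(i)
        # original column order, constants last
        self.columns_ = [cols[i] for i in sorted(kept)] + [cols[i] for i in constant]
        self.mutual_info_ = dict(zip(cols, mi.tolist()))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.columns_]


def redundancy_filter(table: FeatureTable, rho_max: float = 0.9) -> FeatureTable:
    """Functional wrapper: filter a feature table against its own labels."""
    filt = RedundancyFilter(rho_max=rho_max).fit(table.features, table.labels)
    out = table.with_columns(filt.columns_)
    return out


@dataclass
class ScalerModel:
    """Fitted per-feature scaling parameters.

    ``minmax`` maps a feature to ``(x - min) / (max - min)`` with training
    statistics; ``standard`` to ``(x - mean) / sd``; ``none`` is identity.
    Values outside the training range are passed through unclipped.
    """

    kind: str
    columns: list[str]
    loc: np.ndarray | None = None  # min or mean
    scale: np.ndarray | None = None  # (max - min) or sd
    fitted_on: str = ""

    def transform_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != self.columns:
            raise ValueError("feature columns do not match the fitted scaler")
        if self.kind == "none":
            return X.copy()
        values = (X.to_numpy(dtype=float) - self.loc) / self.scale
        return pd.DataFrame(values, columns=self.columns, index=X.index)


def fit_scaler(kind: str, train: FeatureTable) -> ScalerModel:
    """Fit a scaler on the training split only (never refit downstream)."""
    if kind not in SCALER_KINDS:
        raise ValueError(f"unknown scaler kind {kind!r}")
    cols = train.columns
    desc = f"{train.subject_id}/{train.session_id}/{train.feature_set}"
    if kind == "none":
        return ScalerModel(kind="none", columns=cols, fitted_on=desc)
    values = train.X
    if kind == "minmax":
        lo = values.min(axis=0)
        hi = values.max(axis=0)
        if np.any(hi <= lo):
            bad = [c for c, l, h in zip(cols, lo, hi) if h <= l]
            raise ValueError(f"zero-range features under minmax scaling: {bad}")
        return ScalerModel(kind="minmax", columns=cols, loc=lo, scale=hi - lo, fitted_on=desc)
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    if np.any(sd <= 0):
        bad = [c for c, s in zip(cols, sd) if s <= 0]
        raise ValueError(f"zero-variance features under standardisation: {bad}")
    return ScalerModel(kind="standard", columns=cols, loc=mu, scale=sd, fitted_on=desc)


def apply_scaler(model: ScalerModel, table: FeatureTable) -> FeatureTable:
    return FeatureTable(
        features=model.transform_frame(table.features),
        labels=table.labels,
        reps=table.reps,
        subject_id=table.subject_id,
        session_id=table.session_id,
        feature_set=table.feature_set,
    )
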