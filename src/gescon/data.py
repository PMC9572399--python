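"""Canonical data model for prompted-gesture sensor sessions.

A recording is a time-ordered stream of 8 capacitive channel counts sampled
at 20 Hz, each sample carrying the label the prompting application assigned
to it: one of ten gesture names while a gesture was held, or ``'Null'``
during the transition countdown between prompts.  Synthetic recordings
additionally carry an oracle ``true_label`` column so that label-repair and
consolidation algorithms can be scored.

Two sessions are recorded per subject: ``Data1`` (used for all fitting,
tuning and selection) and ``Data2`` (used exclusively for inter-session
validation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

SAMPLE_RATE_HZ = 20.0
SAMPLE_STEP_S = 1.0 / SAMPLE_RATE_HZ

#: Gesture names in the prompting application's canonical order.
GESTURES = (
    "Point Middle",
    "Neutral",
    "Spread",
    "Fist",
    "Thumb Up",
    "Pinch",
    "Thumb Adduct",
    "Point Index",
    "Point Two",
    "Chuck Grasp",
)
NULL_LABEL = "Null"
PROTECTED_GESTURES = ("Neutral", "Fist")

CHANNEL_COLUMNS = tuple(f"ch{i}" for i in range(1, 9))
N_CHANNELS = 8


class SchemaError(ValueError):
    """A stream file does not have the expected column layout."""


class DataError(ValueError):
    """A stream's contents violate the recording invariants."""


class StratificationError(ValueError):
    """A class is too small to be split in a stratified way."""


@dataclass(frozen=True)
class LabelVocabulary:
    """The 11-label vocabulary: ten gestures plus the transition label.

    ``protected`` gestures may absorb merges during consolidation but are
    never merged away themselves, so the tailored interface always keeps
    the two most intuitively distinct hand states.
    """

    gestures: tuple[str, ...] = GESTURES
    null_label: str = NULL_LABEL
    protected: tuple[str, ...] = PROTECTED_GESTURES

    def __post_init__(self) -> None:
        labels = (self.null_label, *self.gestures)
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be distinct")
        if self.null_label in self.gestures:
            raise ValueError("null label must not be a gesture")
        if not set(self.protected) <= set(self.gestures):
            raise ValueError("protected labels must be gestures")

    @property
    def all_labels(self) -> tuple[str, ...]:
        """Null first, then gestures — the order used for confusion matrices."""
        return (self.null_label, *self.gestures)

    def order(self, labels) -> list[str]:
        """Sort labels into vocabulary order; unknown labels go last, sorted."""
        rank = {lab: i for i, lab in enumerate(self.all_labels)}
        return sorted(labels, key=lambda lab: (rank.get(lab, len(rank)), str(lab)))


DEFAULT_VOCAB = LabelVocabulary()


@dataclass
class GestureRecording:
    """One session's time-ordered samples."""

    subject_id: str
    session_id: str
    times: np.ndarray
    channels: np.ndarray  # (n, 8) nonnegative counts
    prompt_labels: np.ndarray  # (n,) str
    true_labels: np.ndarray | None = None  # synthetic data only

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        self.prompt_labels = np.asarray(self.prompt_labels, dtype=object)
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=object)
        n = len(self.times)
        if self.channels.shape != (n, N_CHANNELS):
            raise DataError(
                f"channels shape {self.channels.shape} does not match "
                f"{n} samples x {N_CHANNELS} channels"
            )
        if len(self.prompt_labels) != n:
            raise DataError("prompt_labels length mismatch")
        if self.true_labels is not None and len(self.true_labels) != n:
            raise DataError("true_labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.times)

    def validate(self, vocab: LabelVocabulary = DEFAULT_VOCAB, grid: bool = True) -> None:
        """Check the full recording invariants.

        ``grid=False`` skips the constant 20 Hz step check; recordings that
        have passed through transition filtering have samples removed and no
        longer sit on a uniform grid.
        """
        if self.n == 0:
            raise DataError("empty recording")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if grid and not np.allclose(np.diff(self.times), SAMPLE_STEP_S, atol=1e-9):
            raise DataError("times must advance in constant 0.05 s steps")
        if not np.all(np.isfinite(self.channels)) or np.any(self.channels < 0):
            raise DataError("channels must be finite nonnegative counts")
        allowed = set(vocab.all_labels)
        bad = set(self.prompt_labels) - allowed
        if bad:
            raise DataError(f"prompt labels outside vocabulary: {sorted(bad)}")

    def take(self, idx: np.ndarray) -> "GestureRecording":
        idx = np.asarray(idx)
        return replace(
            self,
            times=self.times[idx],
            channels=self.channels[idx],
            prompt_labels=self.prompt_labels[idx],
            true_labels=None if self.true_labels is None else self.true_labels[idx],
        )


@dataclass(frozen=True)
class Run:
    """A maximal run of identical prompt labels."""

    start: int  # first sample index (inclusive)
    stop: int  # past-the-end sample index
    label: str
    rank: int  # 0-based occurrence index of this label among its runs


@dataclass
class RepetitionIndex:
    """Run-length segmentation of a recording's prompt labels."""

    rep_ids: np.ndarray  # (n,) int, strictly increasing run id per sample
    runs: list[Run]

    def counts_per_label(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for run in self.runs:
            out[run.label] = out.get(run.label, 0) + 1
        return out


def segment_repetitions(rec: GestureRecording) -> RepetitionIndex:
    """Segment a recording into maximal runs of identical prompt labels.

    Adjacent repetitions of the same gesture are separated by a 'Null'
    prompt, so run boundaries are exactly the repetition boundaries; the
    prompt sequence itself is the only repetition marker the protocol has.
    """
    labels = rec.prompt_labels
    if len(labels) == 0:
        raise DataError("cannot segment an empty recording")
    change = np.empty(len(labels), dtype=bool)
    change[0] = True
    change[1:] = labels[1:] != labels[:-1]
    rep_ids = np.cumsum(change) - 1
    starts = np.flatnonzero(change)
    stops = np.append(starts[1:], len(labels))
    seen: dict[str, int] = {}
    runs = []
    for start, stop in zip(starts, stops):
        lab = labels[start]
        rank = seen.get(lab, 0)
        seen[lab] = rank + 1
        runs.append(Run(int(start), int(stop), str(lab), rank))
    return RepetitionIndex(rep_ids=rep_ids, runs=runs)


@dataclass
class FeatureTable:
    """Per-sample feature vectors with labels and repetition ids."""

    features: pd.DataFrame
    labels: np.ndarray  # (n,) str
    reps: np.ndarray  # (n,) int run id
    subject_id: str = ""
    session_id: str = ""
    feature_set: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.reps = np.asarray(self.reps, dtype=int)
        n = len(self.features)
        if len(self.labels) != n or len(self.reps) != n:
            raise DataError("feature table arrays must be aligned")
        if self.features.isna().any().any():
            raise DataError("feature table must not contain missing values")
        if self.features.columns.duplicated().any():
            raise DataError("feature column names must be unique")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def columns(self) -> list[str]:
        return list(self.features.columns)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def take(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            reps=self.reps[idx],
            subject_id=self.subject_id,
            session_id=self.session_id,
            feature_set=self.feature_set,
        )

    def with_labels(self, labels) -> "FeatureTable":
        return FeatureTable(
            features=self.features,
            labels=np.asarray(labels, dtype=object),
            reps=self.reps,
            subject_id=self.subject_id,
            session_id=self.session_id,
            feature_set=self.feature_set,
        )

    def with_columns(self, cols: list[str]) -> "FeatureTable":
        return FeatureTable(
            features=self.features[cols],
            labels=self.labels,
            reps=self.reps,
            subject_id=self.subject_id,
            session_id=self.session_id,
            feature_set=self.feature_set,
        )

    def class_counts(self) -> dict[str, int]:
        labs, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# stream I/O


def read_recording(
    path,
    subject_id: str = "",
    session_id: str = "Data1",
    vocab: LabelVocabulary = DEFAULT_VOCAB,
) -> GestureRecording:
    """Read a session stream CSV (``time,ch1..ch8,prompt[,true_label]``).

    The ``time`` column is optional; when absent it is reconstructed from
    the 20 Hz grid, matching the fixed-rate streaming application.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing channel columns: {missing}")
    extra_ch = [c for c in df.columns if c.startswith("ch") and c not in CHANNEL_COLUMNS]
    if extra_ch:
        raise SchemaError(f"unexpected channel columns: {extra_ch}")
    if "prompt" not in df.columns:
        raise SchemaError("missing 'prompt' column")
    if "time" in df.columns:
        times = df["time"].to_numpy(dtype=float)
    else:
        times = np.arange(len(df)) * SAMPLE_STEP_S
    if np.any(np.diff(times) <= 0):
        raise DataError("time column must be strictly increasing")
    rec = GestureRecording(
        subject_id=subject_id,
        session_id=session_id,
        times=times,
        channels=df[list(CHANNEL_COLUMNS)].to_numpy(dtype=float),
        prompt_labels=df["prompt"].to_numpy(dtype=object),
        true_labels=(
            df["true_label"].to_numpy(dtype=object) if "true_label" in df.columns else None
        ),
    )
    rec.validate(vocab, grid=False)
    return rec


def write_recording(rec: GestureRecording, path) -> None:
    """Write a recording in the canonical CSV dialect (UTF-8, '.' decimal)."""
    data = {"time": rec.times}
    for i, col in enumerate(CHANNEL_COLUMNS):
        data[col] = rec.channels[:, i]
    data["prompt"] = rec.prompt_labels
    if rec.true_labels is not None:
        data["true_label"] = rec.true_labels
    # shortest exact decimal per value, so read o write round-trips bit-for-bit
    pd.DataFrame(data).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# splitting


def split_35_65(
    table: FeatureTable, seed: int, train_frac: float = 0.35
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified shuffled train/test split with a 35% train share.

    The per-class train count is ``floor(train_frac * n_class)``
    (deterministic and conservative).  Every class must have at least two
    samples so both halves can be populated.
    """
    rng = np.random.default_rng(seed)
    labels = table.labels.astype(str)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            raise StratificationError(f"class {lab!r} has fewer than 2 samples")
        perm = rng.permutation(idx)
        k = math.floor(train_frac * len(idx))
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    train = np.sort(np.concatenate(train_idx)).astype(int)
    test = np.sort(np.concatenate(test_idx)).astype(int)
    return table.take(train), table.take(test)
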