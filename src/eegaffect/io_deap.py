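"""Reading, labelling and splitting DEAP-layout subject recordings.

The DEAP preprocessed release stores one file per participant holding two
arrays: ``data`` with shape (40 trials, 40 channels, 8064 samples) at 128 Hz
and ``labels`` with shape (40, 4) carrying the self-assessed ratings
(valence, arousal, dominance, liking), each on a 1-9 scale.  This module
reads that layout from three containers (the native pickle, MATLAB v5 files
and a plain ``.npz`` archive), binarizes ratings at a threshold into
low/high classes and produces reproducible train/test partitions.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RATING_DIMENSIONS = ("valence", "arousal", "dominance", "liking")
#: dimensions that are actually classified; dominance is read but unused
CLASSIFIED_DIMENSIONS = ("valence", "arousal", "liking")

RATING_MIN = 1.0
RATING_MAX = 9.0
DEFAULT_THRESHOLD = 5.0
LOW, HIGH = 0, 1

CANONICAL_N_TRIALS = 40
CANONICAL_N_CHANNELS = 40
CANONICAL_N_SAMPLES = 8064
CANONICAL_FS = 128.0


class FormatError(ValueError):
    """A container is missing a required block."""


class ShapeError(ValueError):
    """Signal/rating arrays have incompatible shapes."""


class ValidationError(ValueError):
    """Array contents violate the data-model invariants."""


@dataclass
class EEGTrialSet:
    """One participant's trials: signal block plus per-trial ratings.

    ``signals`` has shape (n_trials, n_channels, n_samples); ``ratings`` has
    shape (n_trials, 4) ordered (valence, arousal, dominance, liking), each
    value in [1, 9].
    """

    signals: np.ndarray
    ratings: np.ndarray
    sampling_rate: float = CANONICAL_FS
    participant_id: str = "s00"
    channel_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.signals.ndim != 3:
            raise ShapeError(
                f"signals must be 3-D (trials, channels, samples), got {self.signals.shape}"
            )
        if self.ratings.ndim != 2 or self.ratings.shape[1] != 4:
            raise ShapeError(f"ratings must be (n_trials, 4), got {self.ratings.shape}")
        if self.signals.shape[0] != self.ratings.shape[0]:
            raise ShapeError(
                f"{self.signals.shape[0]} trials of signal vs {self.ratings.shape[0]} rating rows"
            )
        if not np.all(np.isfinite(self.signals)):
            raise ValidationError("non-finite signal values")
        bad = np.where((self.ratings < RATING_MIN) | (self.ratings > RATING_MAX))[0]
        if bad.size:
            raise ValidationError(f"rating outside [1, 9] at trial index {int(bad[0])}")
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(self.n_channels)]
        elif len(self.channel_names) != self.n_channels:
            raise ShapeError("channel_names length does not match channel count")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def ratings_for(self, dimension: str) -> np.ndarray:
        return self.ratings[:, RATING_DIMENSIONS.index(dimension)]


@dataclass
class BinaryLabelSet:
    """Low/high labels for one affect dimension, thresholded at ``threshold``."""

    dimension: str
    labels: np.ndarray  # int array of LOW/HIGH
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (LOW, HIGH)).all():
            raise ValidationError("labels must be 0 (low) or 1 (high)")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class TrialSplit:
    """Disjoint, exhaustive train/test index partition."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction_train: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        n = self.train_indices.size + self.test_indices.size
        union = np.union1d(self.train_indices, self.test_indices)
        if union.size != n or not np.array_equal(union, np.arange(n)):
            raise ValidationError("train/test indices must partition range(n)")


# ---------------------------------------------------------------------------
# container readers / writers


def _build_set(data: np.ndarray, labels: np.ndarray, participant_id: str) -> EEGTrialSet:
    data = np.asarray(data)
    labels = np.asarray(labels)
    if data.ndim != 3:
        raise ShapeError(f"data block must be 3-D, got shape {data.shape}")
    if labels.ndim != 2 or labels.shape[1] != 4:
        raise ShapeError(f"label block must be (n_trials, 4), got {labels.shape}")
    if data.shape[0] != labels.shape[0]:
        raise ShapeError("data and label blocks disagree on the number of trials")
    return EEGTrialSet(signals=data, ratings=labels, participant_id=participant_id)


def read_subject(path: str | Path, format: Optional[str] = None) -> EEGTrialSet:
    """Read one participant file (``deap-pickle``, ``mat`` or ``npz``).

    The format is inferred from the suffix when not given (.dat/.pkl → pickle,
    .mat → MATLAB, .npz → numpy archive).  The file must contain a ``data``
    and a ``labels`` block in the DEAP layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".dat": "deap-pickle", ".pkl": "deap-pickle", ".mat": "mat", ".npz": "npz"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise FormatError(f"cannot infer container format from suffix {path.suffix!r}")
    pid = path.stem
    if format == "deap-pickle":
        with open(path, "rb") as fh:
            obj = pickle.load(fh, encoding="latin1")
        blocks = obj
    elif format == "mat":
        from scipy.io import loadmat

        blocks = loadmat(str(path))
    elif format == "npz":
        blocks = np.load(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    for key in ("data", "labels"):
        if key not in blocks:
            raise FormatError(f"{path}: missing {key!r} block")
    return _build_set(blocks["data"], blocks["labels"], pid)


def write_subject(tset: EEGTrialSet, path: str | Path, format: Optional[str] = None) -> Path:
    """Write a trial set to any supported container (lossless round-trip)."""
    path = Path(path)
    if format is None:
        format = {".dat": "deap-pickle", ".pkl": "deap-pickle", ".mat": "mat", ".npz": "npz"}.get(
            path.suffix.lower(), "npz"
        )
    if format == "deap-pickle":
        with open(path, "wb") as fh:
            pickle.dump({"data": tset.signals, "labels": tset.ratings}, fh)
    elif format == "mat":
        from scipy.io import savemat

        savemat(str(path), {"data": tset.signals, "labels": tset.ratings})
    elif format == "npz":
        np.savez(path, data=tset.signals, labels=tset.ratings)
    else:
        raise FormatError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# labels and splits


def binarize(
    ratings: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    dimension: str = "valence",
) -> BinaryLabelSet:
    """Map ratings in [1, 9] to low/high: high iff rating >= threshold."""
    ratings = np.asarray(ratings, dtype=float)
    bad = np.where((ratings < RATING_MIN) | (ratings > RATING_MAX))[0]
    if bad.size:
        raise ValidationError(f"rating outside [1, 9] at index {int(bad[0])}")
    labels = np.where(ratings >= threshold, HIGH, LOW)
    return BinaryLabelSet(dimension=dimension, labels=labels, threshold=threshold)


def split_trials(
    n_trials: int,
    fraction_train: float = 0.70,
    seed: int = 0,
    stratify_on: Optional[BinaryLabelSet] = None,
) -> TrialSplit:
    """Seeded shuffled 70/30-style partition of trial indices.

    With ``stratify_on``, each class is split separately so both partitions
    keep the global class proportion to within one trial.
    """
    if n_trials < 2:
        raise ValidationError("need at least 2 trials to split")
    if not 0.0 < fraction_train < 1.0:
        raise ValidationError("fraction_train must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(fraction_train * n_trials))
    n_train = min(max(n_train, 1), n_trials - 1)
    if stratify_on is None:
        perm = rng.permutation(n_trials)
        train, test = perm[:n_train], perm[n_train:]
    else:
        y = stratify_on.labels
        if y.size != n_trials:
            raise ShapeError("stratify labels length does not match n_trials")
        train_parts, test_parts = [], []
        remainder = 0.0
        for cls in (HIGH, LOW):
            idx = np.where(y == cls)[0]
            idx = rng.permutation(idx)
            exact = fraction_train * idx.size + remainder
            k = int(round(exact))
            remainder = exact - k
            train_parts.append(idx[:k])
            test_parts.append(idx[k:])
        train = rng.permutation(np.concatenate(train_parts))
        test = rng.permutation(np.concatenate(test_parts))
    return TrialSplit(np.sort(train), np.sort(test), fraction_train, seed)


def labels_table(
    label_sets: Sequence[BinaryLabelSet],
    split: Optional[TrialSplit] = None,
    ratings: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Long-form table (trial_index, dimension, rating, binary_label, partition)."""
    rows = []
    for ls in label_sets:
        part = np.full(len(ls), "", dtype=object)
        if split is not None:
            part[split.train_indices] = "train"
            part[split.test_indices] = "test"
        for i, lab in enumerate(ls.labels):
            rows.append(
                {
                    "trial_index": i,
                    "dimension": ls.dimension,
                    "rating": float(ratings[i]) if ratings is not None else np.nan,
                    "binary_label": "high" if lab == HIGH else "low",
                    "partition": part[i],
                }
            )
    return pd.DataFrame(rows)
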