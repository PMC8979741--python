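"""Dataset assembly, label binarisation, splitting and CSV interchange.

The trial-level view of a DEAP-style dataset is participant-major,
trial-minor: 32 participants x 40 trials = 1280 rows.  Ratings are
continuous self-assessment scores in [0, 9] with column order
(valence, arousal, dominance, liking); labels are binarised with the
strict ``rating > 5`` rule, ties at exactly 5 going to class 0.
"""

from __future__ import annotations

import pickle
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantRecord",
    "TrialTable",
    "SplitIndex",
    "FormatError",
    "ShapeError",
    "assemble_trials",
    "binarize_ratings",
    "split_train_test",
    "write_feature_csv",
    "read_feature_csv",
    "load_deap_participant",
]

RATING_COLUMNS = ("valence", "arousal", "dominance", "liking")
LABEL_COLUMNS = ("arousal", "valence")
N_EEG_CHANNELS = 32


class FormatError(ValueError):
    """Unrecognised or corrupt participant container."""


class ShapeError(ValueError):
    """Array geometry does not match expectations."""


@dataclass
class ParticipantRecord:
    """One subject's trials: EEG data plus continuous self-ratings."""

    participant_id: str
    data: np.ndarray      # (n_trials, n_channels, n_samples)
    ratings: np.ndarray   # (n_trials, 4) in RATING_COLUMNS order

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError(
                f"participant {self.participant_id}: data must have 3 axes "
                f"(trials, channels, samples), got {self.data.ndim}"
            )
        if self.ratings.ndim != 2 or self.ratings.shape[1] != 4:
            raise ShapeError(
                f"participant {self.participant_id}: ratings must be (trials, 4)"
            )
        if self.data.shape[0] != self.ratings.shape[0]:
            raise ShapeError(
                f"participant {self.participant_id}: trial counts disagree "
                f"({self.data.shape[0]} data vs {self.ratings.shape[0]} ratings)"
            )
        if np.any(self.ratings < 0) or np.any(self.ratings > 9):
            raise ValueError(
                f"participant {self.participant_id}: ratings must lie in [0, 9]"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class TrialTable:
    """Flat trial-level table over all participants."""

    data: np.ndarray               # (n, channels, samples)
    ratings: np.ndarray            # (n, 4)
    participant_ids: np.ndarray    # (n,) str
    trial_indices: np.ndarray      # (n,) int

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class SplitIndex:
    """Disjoint train/test row index sets covering ``range(n)`` exactly."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        tr, te = set(self.train_ids.tolist()), set(self.test_ids.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")
        n = len(tr) + len(te)
        if tr | te != set(range(n)):
            raise ValueError("train/test indices do not partition range(n)")


def assemble_trials(records: list[ParticipantRecord]) -> TrialTable:
    """Stack participant records into one participant-major trial table."""
    if not records:
        raise ValueError("no participant records given")
    ref = records[0].data.shape[1:]
    for rec in records:
        if rec.data.shape[1:] != ref:
            raise ShapeError(
                f"participant {rec.participant_id}: geometry {rec.data.shape[1:]} "
                f"differs from {records[0].participant_id}'s {ref}"
            )
    data = np.concatenate([r.data for r in records], axis=0)
    ratings = np.concatenate([r.ratings for r in records], axis=0)
    pids = np.concatenate(
        [np.full(r.n_trials, r.participant_id, dtype=object) for r in records]
    )
    tidx = np.concatenate([np.arange(r.n_trials) for r in records])
    return TrialTable(data, ratings, pids, tidx)


def binarize_ratings(
    ratings: np.ndarray, targets: tuple[str, ...] = LABEL_COLUMNS
) -> pd.DataFrame:
    """Binarise continuous 0-9 ratings: label 1 iff rating > 5, else 0.

    ``ratings`` is (n, 4) in (valence, arousal, dominance, liking) order;
    the returned frame has one {0,1} column per requested target.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] != 4:
        raise ShapeError("ratings must be an (n, 4) array")
    if ratings.size and (ratings.min() < 0 or ratings.max() > 9):
        raise ValueError("ratings must lie in [0, 9]")
    col = {name: i for i, name in enumerate(RATING_COLUMNS)}
    out = {}
    for t in targets:
        if t not in col:
            raise ValueError(f"unknown rating target {t!r}")
        out[t] = (ratings[:, col[t]] > 5.0).astype(int)
    return pd.DataFrame(out)


def split_train_test(n: int, test_fraction: float = 0.1, seed: int = 0) -> SplitIndex:
    """Seeded shuffled split; |test| = round(n * test_fraction).

    With the DEAP geometry (n = 1280) and the default fraction this yields
    the canonical 1152/128 train/test sizes.
    """
    if n < 2:
        raise ValueError(f"need at least 2 rows to split, got {n}")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndex(
        train_ids=np.sort(perm[n_test:]), test_ids=np.sort(perm[:n_test]), seed=seed
    )


def write_feature_csv(
    features: pd.DataFrame,
    labels: pd.DataFrame | None,
    features_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write feature (and optionally label) matrices as headered CSV."""
    features = pd.DataFrame(features)
    if labels is not None:
        labels = pd.DataFrame(labels)
        if len(labels) != len(features):
            raise ValueError(
                f"row counts disagree: {len(features)} features vs {len(labels)} labels"
            )
        if labels_path is None:
            raise ValueError("labels given but labels_path missing")
    features.to_csv(features_path, index=False)
    if labels is not None:
        labels.to_csv(labels_path, index=False)


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:  # keep the offending line visible
        raise FormatError(f"malformed CSV {path}: {exc}") from exc


def read_feature_csv(
    features_path: str | Path, labels_path: str | Path | None = None
):
    """Read feature (and optionally label) CSVs written by
    :func:`write_feature_csv`; round-trips are lossless at float precision."""
    features = _read_csv(features_path)
    if labels_path is None:
        return features
    return features, _read_csv(labels_path)


def load_deap_participant(path: str | Path) -> ParticipantRecord:
    """Load one participant from a ``.npz`` container or a DEAP-style
    pickled mapping (``data`` 40x40x8064 with EEG in the first 32 channel
    slots, ``labels``/``ratings`` 40x4).

    Only the 32 EEG channels are returned; peripheral physiological
    channels, if present, are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = None
    try:
        with np.load(path, allow_pickle=False) as npz:
            mapping = {k: npz[k] for k in npz.files}
    except (zipfile.BadZipFile, OSError, ValueError):
        try:
            with open(path, "rb") as fh:
                obj = pickle.load(fh, encoding="latin1")
            if isinstance(obj, dict):
                mapping = obj
        except Exception as exc:
            raise FormatError(f"unrecognised participant container: {path}") from exc
    if mapping is None:
        raise FormatError(f"unrecognised participant container: {path}")
    data = None
    for key in ("data",):
        if key in mapping:
            data = np.asarray(mapping[key], dtype=float)
    ratings = None
    for key in ("ratings", "labels"):
        if key in mapping:
            ratings = np.asarray(mapping[key], dtype=float)
            break
    if data is None or ratings is None:
        raise FormatError(
            f"{path}: container must hold 'data' and 'ratings'/'labels' arrays"
        )
    if data.ndim != 3:
        raise ShapeError(f"{path}: data must be (trials, channels, samples)")
    if data.shape[1] > N_EEG_CHANNELS:
        data = data[:, :N_EEG_CHANNELS, :]
    elif data.shape[1] < N_EEG_CHANNELS:
        raise ShapeError(
            f"{path}: expected >= {N_EEG_CHANNELS} channels, got {data.shape[1]}"
        )
    # ratings arrive on the 1-9 SAM scale in real DEAP exports; clip tiny
    # numeric excursions but reject grossly out-of-range values.
    if ratings.size and (ratings.min() < -1e-9 or ratings.max() > 9 + 1e-9):
        raise ValueError(f"{path}: ratings outside [0, 9]")
    ratings = np.clip(ratings, 0.0, 9.0)
    return ParticipantRecord(path.stem, data, ratings)
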