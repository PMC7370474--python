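"""Balanced Random Forest (BRF) for imbalanced binary outcomes.

With 74 instability events against 209 uneventful resections (1:2.82), a
forest trained on the raw data leans toward the majority class. The BRF
ensemble counters the imbalance by training m independent random forests,
each on a balanced bootstrap drawing exactly n rows with replacement from
each class, and classifying by the sign of the summed forest votes:

    BRF(x) = sgn( sum_i RF_i(x) ),  RF_i(x) in {-1, +1}

with the minority class encoded +1 and a zero vote sum resolved to the
minority class (conservative toward the rare, clinically dangerous outcome).

Each voter's out-of-bag rows (training rows absent from its balanced
bootstrap) are retained for permutation-importance diagnostics; evaluation
on held-out data is the caller's job (see `splits`), so the ensemble vote
never sees test rows during training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import Cohort

__all__ = [
    "BRFConfig",
    "BRFModel",
    "split_by_class",
    "balanced_resample",
    "train_brf",
    "predict_brf",
    "predict_score",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BRFConfig:
    """m: number of base forests (odd reduces vote ties); n: per-class
    bootstrap size (None = minority-class size in the training data);
    features_per_split: int or "sqrt"."""

    m: int = 21
    n: int | None = None
    trees_per_forest: int = 100
    features_per_split: int | str = "sqrt"
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.trees_per_forest < 1:
            raise ValueError("m and trees_per_forest must be >= 1")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1 (or None for the minority size)")


@dataclass
class BRFModel:
    forests: list[RandomForestClassifier]
    minority_label: int
    majority_label: int
    config: BRFConfig
    feature_names: list[str]
    train_indices: list[np.ndarray]          # per-forest balanced-bootstrap multisets
    X_train: np.ndarray = field(repr=False, default=None)
    y_train: np.ndarray = field(repr=False, default=None)

    @property
    def label_encoding(self) -> dict[int, int]:
        return {self.minority_label: +1, self.majority_label: -1}

    def oob_rows(self, i: int) -> np.ndarray:
        """Training rows not drawn into forest i's balanced bootstrap."""
        return np.setdiff1d(np.arange(len(self.y_train)), self.train_indices[i])


def _extract_xy(data, y=None, feature_names=None):
    if isinstance(data, Cohort):
        X = data.features[data.feature_names].to_numpy(dtype=float)
        return X, data.labels, data.feature_names
    X = pd.DataFrame(data)
    names = feature_names or [str(c) for c in X.columns]
    if y is None:
        raise ValueError("labels required when not passing a Cohort")
    return X.to_numpy(dtype=float), np.asarray(y, dtype=int), names


def split_by_class(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of (majority, minority) classes; ties assign majority to
    label 0 (logged)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, found {classes.tolist()}")
    if counts[0] == counts[1]:
        logger.info("class sizes tied at %d; assigning majority to label %s",
                    counts[0], classes[0])
        maj, mino = classes[0], classes[1]
    else:
        maj = classes[np.argmax(counts)]
        mino = classes[np.argmin(counts)]
    return np.flatnonzero(y == maj), np.flatnonzero(y == mino)


def balanced_resample(majority: np.ndarray, minority: np.ndarray, n: int,
                      seed: int = 0) -> np.ndarray:
    """Index multiset of 2n rows: n drawn with replacement from each class."""
    if len(majority) == 0 or len(minority) == 0:
        raise ValueError("both class subsets must be nonempty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return np.concatenate([rng.choice(majority, size=n, replace=True),
                           rng.choice(minority, size=n, replace=True)])


def train_brf(data, config: BRFConfig = BRFConfig(), y=None,
              feature_names=None) -> BRFModel:
    """Train m forests, each on an independent balanced resample.

    ``data`` may be a Cohort or a feature matrix with ``y``. Per-forest seeds
    derive deterministically from ``config.seed``.
    """
    X, y, names = _extract_xy(data, y, feature_names)
    maj_rows, min_rows = split_by_class(y)
    maj_label, min_label = int(y[maj_rows[0]]), int(y[min_rows[0]])
    n = config.n if config.n is not None else len(min_rows)

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(2 * config.m) % (2**31)
    forests, multisets = [], []
    for i in range(config.m):
        try:
            idx = balanced_resample(maj_rows, min_rows, n, seed=int(seeds[2 * i]))
            forest = RandomForestClassifier(
                n_estimators=config.trees_per_forest,
                max_features=config.features_per_split,
                random_state=int(seeds[2 * i + 1]))
            forest.fit(X[idx], y[idx])
        except Exception as exc:
            raise RuntimeError(f"training base forest {i} failed: {exc}") from exc
        forests.append(forest)
        multisets.append(idx)
    return BRFModel(forests, min_label, maj_label, config, list(names),
                    multisets, X_train=X, y_train=y)


def _check_rows(model: BRFModel, rows) -> np.ndarray:
    if isinstance(rows, Cohort):
        rows = rows.features
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in rows.columns]
        if missing:
            raise ValueError(f"rows lack training columns: {missing}")
        rows = rows[model.feature_names]
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature columns, got {X.shape}")
    return X


def _forest_votes(model: BRFModel, X: np.ndarray) -> np.ndarray:
    """(m, n_rows) matrix of hard +/-1 votes (minority = +1)."""
    votes = np.empty((len(model.forests), len(X)), dtype=int)
    for i, forest in enumerate(model.forests):
        votes[i] = np.where(forest.predict(X) == model.minority_label, 1, -1)
    return votes


def predict_brf(model: BRFModel, rows) -> np.ndarray:
    """Sign-vote class labels; a zero vote sum resolves to the minority class."""
    X = _check_rows(model, rows)
    total = _forest_votes(model, X).sum(axis=0)
    return np.where(total >= 0, model.minority_label, model.majority_label)


def predict_score(model: BRFModel, rows) -> np.ndarray:
    """Minority-class score in [0, 1]: mean of the base forests' estimated
    minority-class probabilities (used for ROC construction)."""
    X = _check_rows(model, rows)
    probs = np.zeros(len(X))
    for forest in model.forests:
        col = list(forest.classes_).index(model.minority_label)
        probs += forest.predict_proba(X)[:, col]
    return probs / len(model.forests)


def save_model(model: BRFModel, path: str | Path) -> None:
    """Single-archive serialization: config, encoding, audit multisets, forests."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> BRFModel:
    model = joblib.load(path)
    if not isinstance(model, BRFModel):
        raise TypeError(f"{path} does not contain a BRF model")
    return model
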