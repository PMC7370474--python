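"""Relief-F feature weighting and threshold-based retention.

Relief-F scores each attribute by contrasting a reference patient with its k
nearest neighbours of the same outcome class ("hits") and of the other class
("misses"): an attribute that differs between hits is penalized, one that
differs between misses is rewarded, with miss contributions weighted by class
priors (the Kononenko multi-class update). Weights are accumulated over m
sampled reference patients and divided by m*k, so with diffs in [0, 1] every
weight lies in [-1, 1].

The study retained the 10 of 18 predictors whose (differently scaled) printed
weights exceeded -24; that published weight table ships as a fixture so the
retention and top-k steps can be applied to it directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import Cohort, FeatureSpec

__all__ = [
    "ReliefConfig",
    "diff",
    "relief_f_weights",
    "select_above",
    "top_k",
    "load_reference_weights",
]


@dataclass(frozen=True)
class ReliefConfig:
    """m: reference instances sampled ("all" = every row); k: neighbours per
    class; cap_k: shrink k to smallest-class-size - 1 instead of erroring;
    range_epsilon: denominator guard for constant features."""

    m: int | str = "all"
    k: int = 10
    seed: int = 0
    range_epsilon: float = 1e-12
    cap_k: bool = True

    def __post_init__(self):
        if self.m != "all" and (not isinstance(self.m, int) or self.m < 1):
            raise ValueError('m must be a positive integer or "all"')
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.range_epsilon <= 0:
            raise ValueError("range_epsilon must be > 0")


def diff(spec: FeatureSpec, a: float, b: float, observed_range: float,
         range_epsilon: float = 1e-12) -> float:
    """Per-attribute contrast in [0, 1]: identity mismatch for nominal
    attributes, range-normalized absolute difference otherwise."""
    if spec.is_nominal:
        return 0.0 if a == b else 1.0
    return abs(a - b) / max(observed_range, range_epsilon)


def _as_table(weights: np.ndarray, raw: np.ndarray, names: list[str]) -> pd.DataFrame:
    table = pd.DataFrame({"feature": names, "weight": weights, "weight_raw": raw})
    return (table.sort_values(["weight", "feature"], ascending=[False, True])
            .reset_index(drop=True))


def relief_f_weights(cohort: Cohort, config: ReliefConfig = ReliefConfig()) -> pd.DataFrame:
    """Relief-F weight table, ordered weight-descending (ties by name).

    Returns columns ``feature``, ``weight`` (normalized by m*k, in [-1, 1])
    and ``weight_raw`` (the accumulated sum before normalization; the scale
    the study's printed table resembles). Deterministic given ``config.seed``:
    neighbour ties break by position in a seeded shuffle.
    """
    X = cohort.features[cohort.feature_names].to_numpy(dtype=float)
    y = cohort.labels
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("Relief-F needs at least two outcome classes")
    smallest = classes[np.argmin(counts)]
    k = config.k
    if k > counts.min() - 1:
        if config.cap_k:
            k = int(counts.min()) - 1
        else:
            raise ValueError(
                f"k={config.k} exceeds available neighbours in class {smallest} "
                f"(size {counts.min()})")
    if k < 1:
        raise ValueError(f"class {smallest} too small for any same-class neighbour")

    nominal = np.array([s.is_nominal for s in cohort.schema])
    ranges = X.max(axis=0) - X.min(axis=0)
    scale = np.maximum(ranges, config.range_epsilon)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    class_rows = {c: np.flatnonzero(y == c) for c in classes}

    rng = np.random.default_rng(config.seed)
    tie_rank = np.empty(n)
    tie_rank[rng.permutation(n)] = np.arange(n)

    if config.m == "all":
        refs = np.arange(n)
    else:
        if config.m > n:
            raise ValueError(f"m={config.m} exceeds cohort size {n}")
        refs = rng.choice(n, size=config.m, replace=False)
    m_eff = len(refs)

    W = np.zeros(p)
    for r in refs:
        d = np.where(nominal[None, :], (X != X[r]).astype(float),
                     np.abs(X - X[r]) / scale)
        dist = d.sum(axis=1)
        cls_r = y[r]
        for c in classes:
            rows = class_rows[c]
            if c == cls_r:
                rows = rows[rows != r]
            order = rows[np.lexsort((tie_rank[rows], dist[rows]))][:k]
            contribution = d[order].sum(axis=0)
            if c == cls_r:
                W -= contribution
            else:
                W += priors[c] / (1.0 - priors[cls_r]) * contribution

    raw = W.copy()
    W /= m_eff * k
    return _as_table(W, raw, cohort.feature_names)


def select_above(weights: pd.DataFrame, cutoff: float) -> list[str]:
    """Features with weight strictly greater than ``cutoff``, weight-ordered."""
    return weights.loc[weights["weight"] > cutoff, "feature"].tolist()


def top_k(weights: pd.DataFrame, k: int) -> list[str]:
    """First k entries of the ordered weight table."""
    if not 1 <= k <= len(weights):
        raise ValueError(f"k must lie in [1, {len(weights)}]")
    return weights["feature"].head(k).tolist()


def load_reference_weights() -> pd.DataFrame:
    """The published Relief-F weights of the 18 predictors in the reference
    cohort (fixture; the original scale is not recomputable from summaries)."""
    with resources.files("pheoihd.data").joinpath("relief_weights_reference.csv").open() as fh:
        table = pd.read_csv(fh)
    table["weight_raw"] = table["weight"]
    return (table.sort_values(["weight", "feature"], ascending=[False, True])
            .reset_index(drop=True))
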