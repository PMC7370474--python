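"""Forest variable importance (MDA, MDG) and the cross-ranking consensus rule.

MDA (mean decrease accuracy) permutes one feature at a time on rows the
forest did not train on and records the drop in accuracy; MDG (mean decrease
Gini) sums the node-weighted Gini impurity reductions of every split on the
feature. The study ranked features by MDA, MDG and Relief-F, took the top
five of each list, and kept features appearing in at least two lists as the
final predictors (BMI, tumor size, urine VMA ratio, CT difference, age).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .brf import BRFModel

__all__ = [
    "ConsensusConfig",
    "mda",
    "mdg",
    "consensus_select",
    "build_importance_table",
    "load_reference_importance",
]


@dataclass(frozen=True)
class ConsensusConfig:
    k: int = 5           # top-list depth
    min_lists: int = 2   # lists a feature must appear in

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 1 <= self.min_lists <= 3:
            raise ValueError("min_lists must lie in [1, 3]")


# ---------------------------------------------------------------------------
# MDA

def _single_model_mda(predict, X: np.ndarray, y: np.ndarray,
                      permutations: int, rng: np.random.Generator) -> np.ndarray:
    base = float(np.mean(predict(X) == y))
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drop = 0.0
        for _ in range(permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drop += base - float(np.mean(predict(Xp) == y))
        scores[j] = drop / permutations
    return scores


def mda(model, X=None, y=None, permutations: int = 10, seed: int = 0) -> pd.Series:
    """Permutation importance in accuracy percent points.

    For a BRF model, each base forest is scored on its own out-of-bag rows
    (training rows absent from its balanced bootstrap) and the scores are
    averaged over forests; forests with no out-of-bag rows are skipped with a
    warning. For a plain fitted estimator, held-out ``X``/``y`` are required
    and must be disjoint from its training rows.
    """
    rng = np.random.default_rng(seed)
    if isinstance(model, BRFModel):
        totals = np.zeros(len(model.feature_names))
        used = 0
        for i, forest in enumerate(model.forests):
            oob = model.oob_rows(i)
            if oob.size == 0:
                warnings.warn(f"base forest {i} has no out-of-bag rows; skipped")
                continue
            totals += _single_model_mda(forest.predict, model.X_train[oob],
                                        model.y_train[oob], permutations, rng)
            used += 1
        if used == 0:
            raise RuntimeError("no base forest had out-of-bag rows")
        return pd.Series(100.0 * totals / used, index=model.feature_names, name="mda")
    if X is None or y is None:
        raise ValueError("held-out X and y are required for a plain model")
    X = pd.DataFrame(X)
    names = [str(c) for c in X.columns]
    scores = _single_model_mda(model.predict, X.to_numpy(dtype=float),
                               np.asarray(y), permutations, rng)
    return pd.Series(100.0 * scores, index=names, name="mda")


# ---------------------------------------------------------------------------
# MDG

def _tree_gini_decrease(tree, n_features: int) -> np.ndarray:
    """Per-feature sum of node-weighted impurity decreases in one tree,
    weights normalized by the root's weighted sample count."""
    t = tree.tree_
    total_weight = t.weighted_n_node_samples[0]
    scores = np.zeros(n_features)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        w = t.weighted_n_node_samples
        decrease = (w[node] * t.impurity[node]
                    - w[left] * t.impurity[left]
                    - w[right] * t.impurity[right]) / total_weight
        scores[t.feature[node]] += decrease
    return scores


def mdg(model, feature_names=None) -> pd.Series:
    """Gini importance: per-feature impurity decrease summed over splits,
    averaged over trees (and over base forests for BRF). Nonnegative; a
    feature never split on scores exactly 0."""
    if isinstance(model, BRFModel):
        per_forest = [mdg(f, model.feature_names).to_numpy()
                      for f in model.forests]
        return pd.Series(np.mean(per_forest, axis=0), index=model.feature_names,
                         name="mdg")
    if isinstance(model, RandomForestClassifier):
        n = model.n_features_in_
        scores = np.mean([_tree_gini_decrease(t, n) for t in model.estimators_],
                         axis=0)
    elif isinstance(model, DecisionTreeClassifier):
        n = model.n_features_in_
        scores = _tree_gini_decrease(model, n)
    else:
        raise TypeError(f"cannot extract Gini decreases from {type(model).__name__}")
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(n)]
    return pd.Series(scores, index=list(names), name="mdg")


# ---------------------------------------------------------------------------
# consensus

def _ranked(scores: pd.Series) -> list[str]:
    frame = scores.rename("score").rename_axis("feature").reset_index()
    frame = frame.sort_values(["score", "feature"], ascending=[False, True])
    return frame["feature"].tolist()


def consensus_select(mda_scores: pd.Series, mdg_scores: pd.Series,
                     relief_scores: pd.Series,
                     config: ConsensusConfig = ConsensusConfig()) -> list[str]:
    """Features present in at least ``min_lists`` of the three top-k rankings.

    Output ordered by number of supporting lists (descending), then best rank
    across lists, then rank sum, then name.
    """
    lists = [_ranked(s) for s in (mda_scores, mdg_scores, relief_scores)]
    if any(config.k > len(l) for l in lists):
        raise ValueError(f"k={config.k} exceeds the number of ranked features")
    tops = [l[:config.k] for l in lists]
    tally: dict[str, list[int]] = {}
    for top in tops:
        for rank, feat in enumerate(top, start=1):
            tally.setdefault(feat, []).append(rank)
    chosen = [(f, ranks) for f, ranks in tally.items() if len(ranks) >= config.min_lists]
    chosen.sort(key=lambda fr: (-len(fr[1]), min(fr[1]), sum(fr[1]), fr[0]))
    return [f for f, _ in chosen]


def build_importance_table(mda_scores: pd.Series, mdg_scores: pd.Series,
                           relief_scores: pd.Series) -> pd.DataFrame:
    """Combined table with per-list ranks (1 = most important per list)."""
    table = pd.DataFrame({"mda": mda_scores, "mdg": mdg_scores,
                          "relief": relief_scores}).rename_axis("feature")
    for col in ("mda", "mdg", "relief"):
        table[f"rank_{col}"] = table[col].rank(ascending=False, method="min").astype("Int64")
    return table.sort_values("rank_mda").reset_index()


def load_reference_importance() -> pd.DataFrame:
    """Published MDA/MDG/Relief-F scores of the 10 retained predictors in the
    reference cohort (fixture; not recomputable without the clinical data)."""
    with resources.files("pheoihd.data").joinpath("importance_reference.csv").open() as fh:
        return pd.read_csv(fh)
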