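"""Validation schemes (hold-out, k-fold CV, bootstrap subsets) and the
classifier benchmark grid.

The study compared seven classifiers under nine train/test divisions:
hold-out at 80/20, 70/30 and 60/40, cross-validation at 5, 10 and 15 folds,
and bootstrap subsets of 50, 100 and 200 samples. Split construction is
implemented here to the study's arithmetic (hold-out train size is
floor(n*frac), which yields the 114-sample test set of the 60/40 division of
283 patients); the baseline classifiers are delegated to scikit-learn.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from . import metrics as mx

__all__ = [
    "SplitScheme",
    "SplitPlan",
    "BenchmarkReport",
    "make_holdout",
    "make_kfold",
    "make_bootstrap",
    "build_plan",
    "default_schemes",
    "default_classifiers",
    "run_benchmark",
]


@dataclass(frozen=True)
class SplitScheme:
    family: str                       # holdout | kfold | bootstrap
    train_frac: float | None = None
    k: int | None = None
    subset_size: int | None = None
    repeats: int = 10
    stratified: bool = True

    def __post_init__(self):
        required = {"holdout": "train_frac", "kfold": "k", "bootstrap": "subset_size"}
        if self.family not in required:
            raise ValueError(f"unknown scheme family {self.family!r}")
        if getattr(self, required[self.family]) is None:
            raise ValueError(f"{self.family} scheme requires {required[self.family]}")

    @property
    def label(self) -> str:
        if self.family == "holdout":
            return f"holdout_{round(100 * self.train_frac)}"
        if self.family == "kfold":
            return f"cv_{self.k}"
        return f"bootstrap_{self.subset_size}"


@dataclass
class SplitPlan:
    """(train, test) index pairs over a cohort of size n; pairs are disjoint
    within themselves and test sets are never empty."""

    pairs: list[tuple[np.ndarray, np.ndarray]]
    n: int
    label: str = ""
    seed: int = 0

    def __post_init__(self):
        for train, test in self.pairs:
            if len(test) == 0:
                raise ValueError("empty test set in split plan")
            if np.intersect1d(train, test).size:
                raise ValueError("train/test leakage in split plan")
            for idx in (train, test):
                if len(idx) and (idx.min() < 0 or idx.max() >= self.n):
                    raise ValueError("split indices out of range")


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:short]] += 1
    return base


def make_holdout(n: int, train_frac: float, stratified: bool = True,
                 labels=None, seed: int = 0) -> SplitPlan:
    """Single split with train size floor(n*train_frac); stratified mode
    preserves label proportions with largest-remainder rounding."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    train_size = int(np.floor(n * train_frac))
    if stratified and labels is not None:
        labels = np.asarray(labels)
        strata, counts = np.unique(labels, return_counts=True)
        small = strata[counts < 2]
        if small.size:
            warnings.warn(
                f"strata {small.tolist()} have fewer than 2 members; "
                "degrading them to unstratified assignment")
        quotas = train_frac * counts
        takes = _largest_remainder(quotas, train_size)
        train_parts = []
        for s, take, cnt in zip(strata, takes, counts):
            rows = rng.permutation(np.flatnonzero(labels == s))
            train_parts.append(rows[:take])
        train = np.sort(np.concatenate(train_parts))
    else:
        perm = rng.permutation(n)
        train = np.sort(perm[:train_size])
    test = np.setdiff1d(np.arange(n), train)
    return SplitPlan([(train, test)], n, f"holdout_{round(100 * train_frac)}", seed)


def make_kfold(n: int, k: int, stratified: bool = True, labels=None,
               seed: int = 0) -> SplitPlan:
    """k folds partitioning {0..n-1}; fold sizes differ by at most 1.

    Stratified mode splits each label stratum as evenly as possible and
    assigns per-stratum remainders greedily to the currently smallest folds,
    which keeps total fold sizes within 1 of each other.
    """
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratified and labels is not None:
        labels = np.asarray(labels)
        for s in np.unique(labels):
            rows = rng.permutation(np.flatnonzero(labels == s))
            base, extra = divmod(len(rows), k)
            sizes = np.full(k, base)
            order = np.argsort([len(f) for f in folds], kind="stable")
            sizes[order[:extra]] += 1
            start = 0
            for j in range(k):
                folds[j].extend(rows[start:start + sizes[j]])
                start += sizes[j]
    else:
        rows = rng.permutation(n)
        for j, part in enumerate(np.array_split(rows, k)):
            folds[j].extend(part)
    all_idx = np.arange(n)
    pairs = []
    for j in range(k):
        test = np.sort(np.asarray(folds[j], dtype=int))
        pairs.append((np.setdiff1d(all_idx, test), test))
    return SplitPlan(pairs, n, f"cv_{k}", seed)


def make_bootstrap(n: int, subset_size: int, repeats: int = 10,
                   seed: int = 0) -> SplitPlan:
    """Per repeat: train multiset of ``subset_size`` rows drawn with
    replacement; test = rows never drawn, subsampled (without replacement) to
    at most ``subset_size``. Guarantees train/test disjointness."""
    if not 1 <= subset_size <= n:
        raise ValueError(f"subset_size must lie in [1, {n}]")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(repeats):
        train = np.sort(rng.integers(0, n, size=subset_size))
        pool = np.setdiff1d(np.arange(n), train)
        if pool.size == 0:
            raise ValueError(
                "no out-of-sample rows left for the test set; "
                "use a smaller subset_size")
        take = min(subset_size, pool.size)
        test = np.sort(rng.choice(pool, size=take, replace=False))
        pairs.append((train, test))
    return SplitPlan(pairs, n, f"bootstrap_{subset_size}", seed)


def build_plan(scheme: SplitScheme, n: int, labels=None, seed: int = 0) -> SplitPlan:
    if scheme.family == "holdout":
        return make_holdout(n, scheme.train_frac, scheme.stratified, labels, seed)
    if scheme.family == "kfold":
        return make_kfold(n, scheme.k, scheme.stratified, labels, seed)
    return make_bootstrap(n, scheme.subset_size, scheme.repeats, seed)


def default_schemes() -> list[SplitScheme]:
    """The study's nine validation settings."""
    return ([SplitScheme("holdout", train_frac=f) for f in (0.8, 0.7, 0.6)]
            + [SplitScheme("kfold", k=k) for k in (5, 10, 15)]
            + [SplitScheme("bootstrap", subset_size=b) for b in (50, 100, 200)])


def default_classifiers() -> dict[str, object]:
    """The study's seven-model roster, mapped to scikit-learn estimators.

    CART maps to a Gini tree and C4.5 to an entropy tree; C5.0 (a proprietary
    C4.5 successor) is approximated by a cost-complexity-pruned entropy tree
    and C5.0-boosted by AdaBoost over shallow entropy trees.
    """
    return {
        "logistic_regression": LogisticRegression(max_iter=2000),
        "naive_bayes": GaussianNB(),
        "cart": DecisionTreeClassifier(criterion="gini"),
        "c45": DecisionTreeClassifier(criterion="entropy", min_samples_leaf=2),
        "c50": DecisionTreeClassifier(criterion="entropy", ccp_alpha=0.005),
        "c50_boosted": AdaBoostClassifier(
            estimator=DecisionTreeClassifier(criterion="entropy", max_depth=3),
            n_estimators=50),
        "random_forest": RandomForestClassifier(n_estimators=100),
    }


@dataclass
class BenchmarkReport:
    """accuracy / AUC grids (rows = classifier, columns = scheme), per-cell
    confusion matrices, per-cell seeds and any per-cell failure diagnostics."""

    accuracy: pd.DataFrame
    auc: pd.DataFrame
    confusions: dict = field(default_factory=dict)
    cell_seeds: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        acc = self.accuracy.copy()
        acc.insert(0, "metric", "accuracy")
        auc_ = self.auc.copy()
        auc_.insert(0, "metric", "auc")
        combined = pd.concat([acc, auc_]).rename_axis("classifier").reset_index()
        combined.sort_values(["classifier", "metric"]).to_csv(path, index=False)


def _cell_seed(base_seed: int, *parts) -> int:
    digest = hashlib.sha256(":".join(map(str, (base_seed,) + parts)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_benchmark(X, y, schemes: Sequence[SplitScheme] | None = None,
                  classifiers: Mapping[str, object] | None = None,
                  seed: int = 0) -> BenchmarkReport:
    """Fit every classifier under every validation scheme.

    Per cell, accuracy and AUC are unweighted means over the scheme's
    train/test parts; AUC comes from this package's trapezoidal ROC on the
    estimator's class-probability scores. A classifier that fails on a part
    marks its cell failed (NaN) and the grid continues.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    schemes = list(schemes) if schemes is not None else default_schemes()
    classifiers = dict(classifiers) if classifiers is not None else default_classifiers()

    cols = [s.label for s in schemes]
    acc = pd.DataFrame(np.nan, index=list(classifiers), columns=cols)
    auc_grid = pd.DataFrame(np.nan, index=list(classifiers), columns=cols)
    report = BenchmarkReport(acc, auc_grid)

    for scheme in schemes:
        plan_seed = _cell_seed(seed, "plan", scheme.label)
        plan = build_plan(scheme, len(y), labels=y, seed=plan_seed)
        for name, proto in classifiers.items():
            cell = (name, scheme.label)
            fit_seed = _cell_seed(seed, "fit", name, scheme.label)
            report.cell_seeds[cell] = {"plan": plan_seed, "fit": fit_seed}
            accs, aucs, cms = [], [], []
            try:
                for part_i, (train, test) in enumerate(plan.pairs):
                    est = clone(proto)
                    if "random_state" in est.get_params():
                        est.set_params(random_state=(fit_seed + part_i) % (2**31))
                    est.fit(X.iloc[train], y[train])
                    pred = est.predict(X.iloc[test])
                    cm = mx.confusion(y[test], pred, positive_label=0)
                    cms.append(cm)
                    accs.append(mx.metric_set(cm).accuracy)
                    proba = est.predict_proba(X.iloc[test])
                    pos_col = list(est.classes_).index(0)
                    aucs.append(mx.auc_from_scores(proba[:, pos_col], y[test],
                                                   positive_label=0))
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                report.failures[cell] = f"{type(exc).__name__}: {exc}"
                continue
            report.confusions[cell] = cms
            report.accuracy.loc[name, scheme.label] = float(np.mean(accs))
            report.auc.loc[name, scheme.label] = float(np.mean(aucs))
    return report
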