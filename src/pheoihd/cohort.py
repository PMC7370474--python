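"""Synthetic patient cohorts with the statistical structure of the study population.

The original clinical dataset (283 pheochromocytoma resections, 74 with
intraoperative hemodynamic instability) is not publicly available, so every
downstream stage of this package is driven by cohorts drawn from the published
class-conditional summary statistics: normal distributions for the mean±SD
variables, a lognormal for the median(IQR) urine-metabolite ratio, and
Bernoulli/categorical draws for the comorbidity and management indicators.

Features are sampled independently given the outcome class; the source tables
give no correlation structure (see the methods note for what this does and
does not emulate).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "LABEL_COLUMN",
    "FeatureSpec",
    "CohortConfig",
    "Cohort",
    "default_specs",
    "study_counts",
    "lognormal_from_quantiles",
    "sample_cohort",
    "summarize_cohort",
    "recovered_params",
    "design_matrix",
    "set_encoding_mode",
]

LABEL_COLUMN = "ihd"

KINDS = frozenset({"normal", "lognormal", "bernoulli", "multinomial", "ordinal"})
ENCODINGS = frozenset({"numerical", "categorical"})
_PROB_TOL = 1e-9
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class FeatureSpec:
    """Class-conditional generative description of one clinical variable.

    ``params_by_class`` maps the outcome class (0 = no IHD, 1 = IHD) to the
    distribution parameters: ``{"mean","sd"}`` for normal, ``{"median","q1","q3"}``
    for lognormal, ``{"p"}`` for Bernoulli, ``{"probs"}`` for multinomial/ordinal.
    ``encoding`` records how the variable enters models ("numerical" keeps the
    integer codes, "categorical" one-hot expands / nominal-diffs them) — the
    study treated the ASA score and the hypertension grade both ways.
    """

    name: str
    kind: str
    params_by_class: Mapping[int, Mapping[str, object]]
    encoding: str = "numerical"
    categories: tuple | None = None
    support: tuple[float | None, float | None] = (None, None)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"{self.name}: unknown encoding {self.encoding!r}")
        lo, hi = self.support
        if lo is not None and hi is not None and lo >= hi:
            raise ValueError(f"{self.name}: truncation bounds out of order")
        for cls, p in self.params_by_class.items():
            self._validate_params(cls, p)

    def _validate_params(self, cls: int, p: Mapping[str, object]) -> None:
        if self.kind == "normal":
            if p["sd"] < 0:
                raise ValueError(f"{self.name}[{cls}]: negative SD")
        elif self.kind == "lognormal":
            if not (0 < p["q1"] <= p["median"] <= p["q3"]):
                raise ValueError(f"{self.name}[{cls}]: quantiles must satisfy 0 < q1 <= median <= q3")
        elif self.kind == "bernoulli":
            if not 0 <= p["p"] <= 1:
                raise ValueError(f"{self.name}[{cls}]: p outside [0, 1]")
        else:  # multinomial / ordinal
            probs = np.asarray(p["probs"], dtype=float)
            if self.categories is None or len(self.categories) != len(probs):
                raise ValueError(f"{self.name}: categories/probs length mismatch")
            if (probs < 0).any() or abs(probs.sum() - 1.0) > _PROB_TOL:
                raise ValueError(f"{self.name}[{cls}]: probabilities must be >= 0 and sum to 1")

    @property
    def is_nominal(self) -> bool:
        """True when values compare by identity (0/1 mismatch distance)."""
        if self.kind in ("bernoulli", "multinomial"):
            return True
        return self.kind == "ordinal" and self.encoding == "categorical"

    @property
    def is_continuous(self) -> bool:
        return self.kind in ("normal", "lognormal")


@dataclass(frozen=True)
class CohortConfig:
    n_total: int
    prevalence: float
    specs: tuple[FeatureSpec, ...]
    seed: int = 0

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        names = [s.name for s in self.specs]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "specs", tuple(self.specs))


@dataclass
class Cohort:
    """A feature table with binary IHD labels and the generating schema."""

    features: pd.DataFrame
    labels: np.ndarray
    schema: tuple[FeatureSpec, ...]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree on row count")
        missing = [s.name for s in self.schema if s.name not in self.features.columns]
        if missing:
            raise ValueError(f"features table lacks schema columns: {missing}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.schema]

    def spec(self, name: str) -> FeatureSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, rows: np.ndarray) -> "Cohort":
        return Cohort(self.features.iloc[rows].reset_index(drop=True),
                      self.labels[rows], self.schema)

    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        path = Path(path)
        out = self.features.copy()
        out[LABEL_COLUMN] = self.labels
        out.to_csv(path, index=False)
        if schema_path is None:
            schema_path = path.with_suffix(".schema.json")
        Path(schema_path).write_text(json.dumps(
            [_spec_to_dict(s) for s in self.schema], indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, schema_path: str | Path | None = None) -> "Cohort":
        path = Path(path)
        table = pd.read_csv(path)
        if LABEL_COLUMN not in table.columns:
            raise ValueError(f"cohort CSV must contain a {LABEL_COLUMN!r} column")
        labels = table.pop(LABEL_COLUMN).to_numpy(dtype=int)
        if schema_path is None:
            schema_path = path.with_suffix(".schema.json")
        schema = tuple(_spec_from_dict(d)
                       for d in json.loads(Path(schema_path).read_text()))
        return cls(table, labels, schema)


def _spec_to_dict(s: FeatureSpec) -> dict:
    return {
        "name": s.name, "kind": s.kind, "encoding": s.encoding,
        "categories": list(s.categories) if s.categories else None,
        "support": list(s.support),
        "params_by_class": {str(c): dict(p) for c, p in s.params_by_class.items()},
    }


def _spec_from_dict(d: Mapping) -> FeatureSpec:
    return FeatureSpec(
        name=d["name"], kind=d["kind"], encoding=d["encoding"],
        categories=tuple(d["categories"]) if d.get("categories") else None,
        support=tuple(d.get("support", (None, None))),
        params_by_class={int(c): dict(p) for c, p in d["params_by_class"].items()},
    )


# ---------------------------------------------------------------------------
# population fixture

def _population_raw() -> dict:
    with resources.files("pheoihd.data").joinpath("population_specs.yaml").open() as fh:
        return yaml.safe_load(fh)


def _percent_to_probs(percent: Sequence[float], where: str) -> tuple[float, ...]:
    p = np.asarray(percent, dtype=float) / 100.0
    total = p.sum()
    if abs(total - 1.0) > 0.01:
        raise ValueError(f"{where}: category percentages sum to {100 * total:.1f}, not 100")
    return tuple(p / total)  # absorb table rounding slack


def default_specs(encoding_mode: str | None = None) -> list[FeatureSpec]:
    """The 18 predictors of the study population, one FeatureSpec each.

    Parameters are loaded from the versioned ``population_specs.yaml`` fixture.
    ``encoding_mode`` of ``"numerical"`` or ``"categorical"`` overrides the
    encoding of every ordered-categorical predictor (ASA score, hypertension
    grade), mirroring the study's two dataset variants.
    """
    raw = _population_raw()
    specs: list[FeatureSpec] = []
    for name, entry in raw["features"].items():
        kind = entry["kind"]
        params: dict[int, dict] = {}
        for cls, p in entry["by_class"].items():
            cls = int(cls)
            if kind == "bernoulli":
                params[cls] = {"p": float(p["percent"]) / 100.0}
            elif kind in ("ordinal", "multinomial"):
                params[cls] = {"probs": _percent_to_probs(p["percent"], f"{name}[{cls}]")}
            else:
                params[cls] = {k: float(v) for k, v in p.items()}
        specs.append(FeatureSpec(
            name=name, kind=kind, params_by_class=params,
            encoding=entry.get("encoding", "numerical"),
            categories=tuple(entry["categories"]) if "categories" in entry else None,
            support=tuple(entry.get("support", (None, None))),
        ))
    if encoding_mode is not None:
        specs = set_encoding_mode(specs, encoding_mode)
    return specs


def set_encoding_mode(specs: Sequence[FeatureSpec], mode: str) -> list[FeatureSpec]:
    """Force every ordered-categorical spec to the given encoding."""
    if mode not in ENCODINGS:
        raise ValueError(f"unknown encoding mode {mode!r}")
    return [replace(s, encoding=mode) if s.kind in ("ordinal", "multinomial") else s
            for s in specs]


def study_counts() -> tuple[int, int]:
    """(total patients, IHD cases) of the reference cohort: (283, 74)."""
    raw = _population_raw()
    return int(raw["n_total"]), int(raw["n_cases"])


def default_config(n_total: int | None = None, prevalence: float | None = None,
                   seed: int = 0, encoding_mode: str | None = None) -> CohortConfig:
    n_ref, cases = study_counts()
    return CohortConfig(
        n_total=n_ref if n_total is None else n_total,
        prevalence=cases / n_ref if prevalence is None else prevalence,
        specs=tuple(default_specs(encoding_mode)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sampling

_Z75 = stats.norm.ppf(0.75)  # 0.6744897...


def lognormal_from_quantiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Convert a reported median and interquartile range to lognormal (mu, sigma).

    mu = ln(median); sigma = (ln q3 - ln q1) / (2 z_0.75). The implied lognormal
    has exactly the given median and quartiles (sigma = 0 degenerates to a point
    mass at the median).
    """
    if not (0 < q1 <= median <= q3):
        raise ValueError("quantiles must satisfy 0 < q1 <= median <= q3")
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * _Z75)
    return mu, sigma


def _draw_feature(rng: np.random.Generator, spec: FeatureSpec, cls: int,
                  size: int) -> np.ndarray:
    p = spec.params_by_class[cls]
    if spec.kind == "normal":
        draw = lambda k: rng.normal(p["mean"], p["sd"], size=k)
    elif spec.kind == "lognormal":
        mu, sigma = lognormal_from_quantiles(p["median"], p["q1"], p["q3"])
        draw = lambda k: rng.lognormal(mu, sigma, size=k)
    elif spec.kind == "bernoulli":
        return rng.binomial(1, p["p"], size=size).astype(float)
    else:
        cats = np.asarray(spec.categories, dtype=float)
        return rng.choice(cats, size=size, p=np.asarray(p["probs"], dtype=float))

    x = draw(size)
    lo, hi = spec.support
    if lo is None and hi is None:
        return x
    for _ in range(_MAX_REDRAWS):
        bad = np.zeros(size, dtype=bool)
        if lo is not None:
            bad |= x <= lo
        if hi is not None:
            bad |= x >= hi
        if not bad.any():
            return x
        x[bad] = draw(int(bad.sum()))
    raise RuntimeError(
        f"{spec.name}[{cls}]: support {spec.support} retains (almost) no mass "
        f"after {_MAX_REDRAWS} redraw rounds")


def sample_cohort(config: CohortConfig) -> Cohort:
    """Draw a cohort: Bernoulli(prevalence) labels, then class-conditional features.

    Fully reproducible from ``config.seed``; truncated variables are redrawn
    until inside their support (bounded retries).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    labels = (rng.random(n) < config.prevalence).astype(int)
    columns: dict[str, np.ndarray] = {}
    for spec in config.specs:
        col = np.empty(n, dtype=float)
        for cls in (0, 1):
            idx = np.flatnonzero(labels == cls)
            if idx.size:
                col[idx] = _draw_feature(rng, spec, cls, idx.size)
        if not spec.is_continuous:
            col = col.astype(int)
        columns[spec.name] = col
    return Cohort(pd.DataFrame(columns), labels, tuple(config.specs))


# ---------------------------------------------------------------------------
# summaries

def recovered_params(cohort: Cohort) -> dict[str, dict[int, dict]]:
    """Empirical analogue of each spec's parameters, per class.

    The round-trip surface: sampling with ``sample_cohort`` and summarizing with
    this function recovers the configured parameters up to sampling error.
    An absent class yields ``{"absent": True}`` rather than silent NaNs.
    """
    out: dict[str, dict[int, dict]] = {}
    for spec in cohort.schema:
        per_class: dict[int, dict] = {}
        for cls in (0, 1):
            x = cohort.features[spec.name].to_numpy()[cohort.labels == cls]
            if x.size == 0:
                per_class[cls] = {"absent": True}
                continue
            if spec.kind == "normal":
                per_class[cls] = {"mean": float(x.mean()), "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0}
            elif spec.kind == "lognormal":
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                per_class[cls] = {"median": float(med), "q1": float(q1), "q3": float(q3)}
            elif spec.kind == "bernoulli":
                per_class[cls] = {"p": float(x.mean())}
            else:
                cats = np.asarray(spec.categories)
                counts = np.array([(x == c).sum() for c in cats], dtype=float)
                per_class[cls] = {"probs": tuple(counts / counts.sum())}
        out[spec.name] = per_class
    return out


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-feature, per-class summary table in the clinical-report style:
    mean ± SD, median (IQR), or n (percent)."""
    params = recovered_params(cohort)
    rows = []
    for spec in cohort.schema:
        for cls in (0, 1):
            p = params[spec.name][cls]
            n_cls = int((cohort.labels == cls).sum())
            if p.get("absent"):
                text = "absent"
            elif spec.kind == "normal":
                text = f"{p['mean']:.1f} ± {p['sd']:.1f}"
            elif spec.kind == "lognormal":
                text = f"{p['median']:.2f} ({p['q1']:.2f}–{p['q3']:.2f})"
            elif spec.kind == "bernoulli":
                text = f"{round(p['p'] * n_cls)} ({100 * p['p']:.1f}%)"
            else:
                text = "/".join(f"{100 * q:.1f}" for q in p["probs"]) + "%"
            rows.append({"feature": spec.name, "class": cls, "kind": spec.kind,
                         "n": n_cls, "summary": text})
    return pd.DataFrame(rows)


def design_matrix(cohort: Cohort, features: Sequence[str] | None = None,
                  mode: str | None = None) -> pd.DataFrame:
    """Model-ready matrix: numerical columns pass through, categorical-encoded
    multi-level variables are one-hot expanded (``name_cat`` columns).

    ``mode`` overrides every ordered-categorical spec's encoding, realizing the
    study's "numerical dataset" vs "categorical dataset" variants.
    """
    names = list(features) if features is not None else cohort.feature_names
    blocks: list[pd.DataFrame] = []
    for name in names:
        spec = cohort.spec(name)
        encoding = spec.encoding if mode is None else (
            mode if spec.kind in ("ordinal", "multinomial") else spec.encoding)
        col = cohort.features[name]
        n_levels = len(spec.categories) if spec.categories else 2
        if encoding == "categorical" and n_levels > 2 and not spec.is_continuous:
            dummies = pd.DataFrame(
                {f"{name}_{c}": (col == c).astype(float) for c in spec.categories})
            blocks.append(dummies)
        else:
            blocks.append(col.astype(float).to_frame(name))
    return pd.concat(blocks, axis=1)
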