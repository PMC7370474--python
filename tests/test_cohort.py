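import math

import numpy as np
import pytest
from scipy import stats

from pheoihd.cohort import (
    Cohort,
    CohortConfig,
    FeatureSpec,
    default_config,
    default_specs,
    design_matrix,
    lognormal_from_quantiles,
    recovered_params,
    sample_cohort,
    set_encoding_mode,
    study_counts,
    summarize_cohort,
)


class TestDefaultSpecs:
    def test_eighteen_predictors(self):
        specs = default_specs()
        assert len(specs) == 18
        assert len({s.name for s in specs}) == 18

    def test_transcribed_parameters(self):
        by_name = {s.name: s for s in default_specs()}
        bmi = by_name["bmi"].params_by_class
        assert bmi[0] == {"mean": 24.1, "sd": 3.5}
        assert bmi[1] == {"mean": 21.9, "sd": 2.7}
        assert by_name["chd"].params_by_class[0]["p"] == pytest.approx(0.316)
        assert by_name["chd"].params_by_class[1]["p"] == pytest.approx(0.500)
        hyp = by_name["hypertension"].params_by_class[0]["probs"]
        assert hyp == pytest.approx((0.392, 0.225, 0.383))
        assert abs(sum(hyp) - 1.0) < 1e-9

    def test_all_category_probabilities_normalized(self):
        for spec in default_specs():
            for cls, p in spec.params_by_class.items():
                if "probs" in p:
                    assert abs(sum(p["probs"]) - 1.0) < 1e-9

    def test_encoding_mode_switch(self):
        numeric = {s.name: s.encoding for s in default_specs("numerical")}
        categ = {s.name: s.encoding for s in default_specs("categorical")}
        assert numeric["asa"] == "numerical" and categ["asa"] == "categorical"
        assert numeric["hypertension"] == "numerical"
        assert categ["hypertension"] == "categorical"
        # binary and continuous features are untouched
        assert numeric["bmi"] == categ["bmi"] == "numerical"


class TestLognormalFromQuantiles:
    def test_degenerate_point_mass(self):
        assert lognormal_from_quantiles(1, 1, 1) == (0.0, 0.0)

    def test_unit_parameters_by_construction(self):
        z = stats.norm.ppf(0.75)
        mu, sigma = lognormal_from_quantiles(math.e, math.e * math.exp(-z),
                                             math.e * math.exp(z))
        assert mu == pytest.approx(1.0, abs=1e-12)
        assert sigma == pytest.approx(1.0, abs=1e-12)

    def test_quantiles_recovered_numerically(self):
        # independent oracle: invert the fitted lognormal's quantile function.
        # A two-parameter lognormal anchored at the median can match both
        # quartiles exactly only when they are log-symmetric; what the fit
        # preserves exactly is the median and the log-IQR width.
        mu, sigma = lognormal_from_quantiles(1.4, 0.9, 2.2)
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        assert dist.ppf(0.50) == pytest.approx(1.4, abs=1e-9)
        q1, q3 = dist.ppf(0.25), dist.ppf(0.75)
        assert math.log(q3) - math.log(q1) == pytest.approx(
            math.log(2.2) - math.log(0.9), abs=1e-9)
        assert q1 == pytest.approx(0.9, abs=0.01)
        assert q3 == pytest.approx(2.2, abs=0.02)

    def test_log_symmetric_quartiles_recovered_exactly(self):
        z = stats.norm.ppf(0.75)
        med, spread = 1.4, 0.45
        mu, sigma = lognormal_from_quantiles(
            med, med * math.exp(-spread), med * math.exp(spread))
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        assert dist.ppf(0.25) == pytest.approx(med * math.exp(-spread), abs=1e-9)
        assert dist.ppf(0.75) == pytest.approx(med * math.exp(spread), abs=1e-9)

    @pytest.mark.parametrize("bad", [(0, 0, 1), (1.0, 2.0, 3.0), (2.0, 1.0, 1.5),
                                     (1.0, -1.0, 2.0)])
    def test_invalid_quantiles_rejected(self, bad):
        with pytest.raises(ValueError):
            lognormal_from_quantiles(*bad)


class TestSpecValidation:
    def test_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FeatureSpec("x", "ordinal", {0: {"probs": (0.5, 0.4)}},
                        categories=(0, 1))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec("x", "normal", {0: {"mean": 0, "sd": -1}})

    def test_misordered_support_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec("x", "normal", {0: {"mean": 0, "sd": 1}}, support=(2, 1))

    def test_config_rejects_bad_prevalence_and_duplicates(self):
        spec = FeatureSpec("x", "normal", {0: {"mean": 0, "sd": 1},
                                           1: {"mean": 0, "sd": 1}})
        with pytest.raises(ValueError):
            CohortConfig(10, 1.5, (spec,))
        with pytest.raises(ValueError):
            CohortConfig(10, 0.5, (spec, spec))


class TestSampling:
    def test_zero_prevalence_gives_all_controls(self):
        cfg = default_config(n_total=50, prevalence=0.0, seed=3)
        assert sample_cohort(cfg).labels.sum() == 0

    def test_case_count_within_binomial_interval(self):
        n, cases = study_counts()
        cohort = sample_cohort(default_config(seed=5))
        lo, hi = stats.binom.ppf([0.005, 0.995], n, cases / n)
        assert lo <= cohort.labels.sum() <= hi

    def test_bit_identical_under_same_seed(self):
        a = sample_cohort(default_config(n_total=200, seed=9))
        b = sample_cohort(default_config(n_total=200, seed=9))
        assert a.features.equals(b.features)
        assert (a.labels == b.labels).all()

    def test_truncation_respected(self):
        spec = FeatureSpec("x", "normal",
                           {0: {"mean": 0.5, "sd": 2.0}, 1: {"mean": 0.5, "sd": 2.0}},
                           support=(0.0, 1.0))
        cfg = CohortConfig(5000, 0.3, (spec,), seed=1)
        x = sample_cohort(cfg).features["x"]
        assert (x > 0).all() and (x < 1).all()

    def test_zero_mass_support_errors(self):
        spec = FeatureSpec("x", "normal",
                           {0: {"mean": 0.0, "sd": 0.001},
                            1: {"mean": 0.0, "sd": 0.001}},
                           support=(50.0, 51.0))
        with pytest.raises(RuntimeError, match="support"):
            sample_cohort(CohortConfig(100, 0.3, (spec,), seed=1))

    def test_class_mean_recovery_large_n(self):
        cohort = sample_cohort(default_config(n_total=100_000, seed=2))
        bmi0 = cohort.features["bmi"].to_numpy()[cohort.labels == 0]
        se = 3.5 / math.sqrt(len(bmi0))
        assert abs(bmi0.mean() - 24.1) < 3 * se


class TestSummaries:
    def test_constant_feature_summary(self):
        from conftest import make_cohort
        cohort = make_cohort({"x": [7.0, 7.0, 7.0, 7.0]}, [0, 0, 1, 1],
                             specs=(FeatureSpec("x", "normal",
                                                {0: {"mean": 7, "sd": 0},
                                                 1: {"mean": 7, "sd": 0}}),))
        params = recovered_params(cohort)
        assert params["x"][0] == {"mean": 7.0, "sd": 0.0}

    def test_absent_class_flagged_not_nan(self):
        from conftest import make_cohort
        cohort = make_cohort({"x": [1.0, 2.0, 3.0]}, [0, 0, 0])
        params = recovered_params(cohort)
        assert params["x"][1] == {"absent": True}
        table = summarize_cohort(cohort)
        row = table[(table["feature"] == "x") & (table["class"] == 1)]
        assert row["summary"].item() == "absent"

    def test_summary_table_has_row_per_feature_and_class(self):
        cohort = sample_cohort(default_config(n_total=120, seed=4))
        table = summarize_cohort(cohort)
        assert len(table) == 2 * 18


class TestDesignMatrix:
    def test_categorical_one_hot_and_numerical_passthrough(self):
        cohort = sample_cohort(default_config(n_total=150, seed=6))
        X = design_matrix(cohort)
        # default encodings: ASA categorical (3 dummies), hypertension numerical
        assert {"asa_1", "asa_2", "asa_3"} <= set(X.columns)
        assert "hypertension" in X.columns
        numeric = design_matrix(cohort, mode="numerical")
        assert list(numeric.columns) == cohort.feature_names

    def test_feature_subset_selection(self):
        cohort = sample_cohort(default_config(n_total=50, seed=6))
        X = design_matrix(cohort, features=["bmi", "size"])
        assert list(X.columns) == ["bmi", "size"]


class TestRoundTripIO:
    def test_csv_round_trip(self, tmp_path):
        cohort = sample_cohort(default_config(n_total=60, seed=8))
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = Cohort.from_csv(path)
        assert (back.labels == cohort.labels).all()
        assert back.feature_names == cohort.feature_names
        assert np.allclose(back.features.to_numpy(float),
                           cohort.features.to_numpy(float))
        assert [s.kind for s in back.schema] == [s.kind for s in cohort.schema]
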