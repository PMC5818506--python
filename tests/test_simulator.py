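"""Synthetic cohorts, empirical power replication, and strata balance."""

import math

import numpy as np
import pandas as pd
import pytest
from conftest import ORACLE_REPS, agreement_band
from scipy.stats import kstest

from rbgplan import (
    CohortModel,
    InfeasibleDesignError,
    MultiVariantDesign,
    ParameterError,
    SingleVariantDesign,
    empirical_power,
    grs_exposure_gradient,
    mv_recall_power,
    simulate_grs_cohort,
    simulate_sv_cohort,
    strata_balance_report,
    sv_recall_power,
)
from rbgplan.cli import default_variants

CONFOUNDED = dict(
    r2_xg=0.03,
    r2_yx=0.3,
    confounder_effects=((0.2, 0.1), (0.2, 0.1), (0.2, 0.1)),
)


def grs_model(n=100_000, n_variants=50, seed=7, **kw):
    params = {**CONFOUNDED, **kw}
    return CohortModel(n, default_variants(n_variants), seed=seed, **params)


class TestSingleVariantCohort:
    def test_hwe_genotype_frequencies(self):
        n = 1_000_000
        cohort = simulate_sv_cohort(n, maf=0.3, beta=0.0, seed=5)
        counts = cohort["dosage"].value_counts()
        for dosage, expected in ((0, 0.49), (1, 0.42), (2, 0.09)):
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(counts[dosage] / n - expected) <= 3 * se

    def test_phenotype_contrast_is_twice_beta(self):
        cohort = simulate_sv_cohort(1_000_000, maf=0.2, beta=0.3, seed=5)
        by_geno = cohort.groupby("dosage")["phenotype"].mean()
        assert by_geno[2] - by_geno[0] == pytest.approx(0.6, abs=0.01)

    def test_deterministic_under_seed(self):
        a = simulate_sv_cohort(500, 0.2, 0.3, seed=42)
        b = simulate_sv_cohort(500, 0.2, 0.3, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_sv_cohort(500, 0.2, 0.3, seed=43)
        assert not a["phenotype"].equals(c["phenotype"])

    @pytest.mark.parametrize("kwargs", [{"n": 0}, {"n": 100, "maf": 0.0}])
    def test_rejects_bad_inputs(self, kwargs):
        with pytest.raises(ParameterError):
            simulate_sv_cohort(**{"n": 100, "maf": 0.2, "beta": 0.0, **kwargs})


class TestGrsCohort:
    def test_raw_grs_variance_matches_theory(self):
        model = grs_model()
        cohort = simulate_grs_cohort(model)
        mafs = np.array([v[0] for v in model.variants])
        weights = np.array([v[1] for v in model.variants])
        raw = cohort[[f"dosage_{i + 1}" for i in range(len(mafs))]].to_numpy() @ weights
        theory = float((2 * mafs * (1 - mafs)) @ weights**2)
        assert raw.var() == pytest.approx(theory, rel=0.02)

    def test_standardized_grs_is_near_normal(self):
        cohort = simulate_grs_cohort(grs_model())
        assert kstest(cohort["grs"], "norm").statistic < 0.01

    def test_confounders_independent_of_grs(self):
        model = grs_model()
        cohort = simulate_grs_cohort(model)
        bound = 3 / math.sqrt(model.n_individuals)
        for j in (1, 2, 3):
            r = np.corrcoef(cohort["grs"], cohort[f"conf_{j}"])[0, 1]
            assert abs(r) <= bound  # correlation SE is 1/sqrt(n) under independence

    def test_column_order_is_fixed(self):
        cohort = simulate_grs_cohort(grs_model(n=500, n_variants=3))
        assert list(cohort.columns) == [
            "id",
            "dosage_1",
            "dosage_2",
            "dosage_3",
            "grs",
            "exposure",
            "outcome",
            "conf_1",
            "conf_2",
            "conf_3",
        ]

    def test_deterministic_under_seed(self):
        a = simulate_grs_cohort(grs_model(n=2000))
        b = simulate_grs_cohort(grs_model(n=2000))
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_empty_variant_list(self):
        with pytest.raises(ParameterError):
            CohortModel(100, (), 0.03, 0.3)

    def test_rejects_overcommitted_variance_budget(self):
        with pytest.raises(ParameterError):
            CohortModel(100, ((0.3, 1.0),), 0.5, 0.3, ((0.8, 0.0),))


class TestEmpiricalPower:
    N_REPS = 10_000

    def test_type_one_error_calibrated_under_sv_null(self):
        null = SingleVariantDesign(0.2, 0.0, 100)
        result = empirical_power(null, n_reps=self.N_REPS, seed=2)
        for p in (result.power_recall, result.power_random):
            assert abs(p - 0.05) <= 3 * max(result.mc_se, 1 / self.N_REPS)

    def test_type_one_error_calibrated_under_mv_null(self):
        null = MultiVariantDesign(0.0, 0.3, 0.05, 300)
        result = empirical_power(null, n_reps=self.N_REPS, seed=2)
        for p in (result.power_recall, result.power_random):
            assert abs(p - 0.05) <= 3 * max(result.mc_se, 1 / self.N_REPS)

    def test_sv_recall_matches_analytic(self):
        d = SingleVariantDesign(0.2, 0.3, 100)
        result = empirical_power(d, n_reps=ORACLE_REPS, seed=3)
        assert abs(result.power_recall - sv_recall_power(d)) <= agreement_band(
            result.power_recall
        )

    def test_mv_recall_matches_analytic(self):
        d = MultiVariantDesign(0.03, 0.3, 0.05, 300)
        result = empirical_power(d, n_reps=ORACLE_REPS, seed=3)
        assert abs(result.power_recall - mv_recall_power(d)) <= agreement_band(
            result.power_recall
        )

    def test_deterministic_under_seed(self):
        d = SingleVariantDesign(0.2, 0.3, 60)
        assert empirical_power(d, 200, seed=9) == empirical_power(d, 200, seed=9)

    def test_rejects_undersized_replicate_count(self):
        with pytest.raises(ParameterError):
            empirical_power(SingleVariantDesign(0.2, 0.3, 100), n_reps=50, seed=1)

    def test_infeasible_recall_raises(self):
        d = MultiVariantDesign(0.03, 0.3, 0.05, 300)
        with pytest.raises(InfeasibleDesignError):
            empirical_power(d, n_reps=200, seed=1, cohort_size=1000)

    def test_replicate_streams_stable_as_replicates_grow(self):
        # stream for replicate i depends only on (seed, i), so extending the
        # replicate count never reshuffles earlier replicates
        from rbgplan.simulate import _rep_rng

        first = _rep_rng(5, 3).standard_normal(4)
        again = _rep_rng(5, 3).standard_normal(4)
        np.testing.assert_array_equal(first, again)


class TestExposureGradient:
    def test_tail_contrast_matches_prediction(self):
        model = grs_model()
        cohort = simulate_grs_cohort(model)
        k = int(0.05 * model.n_individuals)
        order = np.argsort(cohort["grs"].to_numpy())
        top = cohort["exposure"].to_numpy()[order[-k:]]
        bottom = cohort["exposure"].to_numpy()[order[:k]]
        observed = top.mean() - bottom.mean()
        predicted = grs_exposure_gradient(MultiVariantDesign(0.03, 0.3, 0.05, 300))
        se = math.sqrt(top.var() / k + bottom.var() / k)
        assert abs(observed - predicted) <= 3 * se


class TestStrataBalance:
    def test_grs_strata_balanced_but_exposure_strata_confounded(self):
        report = strata_balance_report(grs_model(), cut_fraction=0.30)
        confounders = [v for v in report.table.index if v.startswith("conf_")]
        for var in confounders:
            row = report.table.loc[var]
            assert abs(row["smd_grs_strata"]) <= 3 * row["se_grs_strata"]
        exposure_hits = sum(
            abs(report.table.loc[v, "smd_exposure_strata"])
            > 3 * report.table.loc[v, "se_exposure_strata"]
            for v in confounders
        )
        assert exposure_hits >= 1

    def test_balance_robust_to_strong_confounding(self):
        strong = grs_model(
            confounder_effects=((0.5, 0.3), (0.3, 0.2)), n=50_000, seed=11
        )
        report = strata_balance_report(strong, cut_fraction=0.30)
        for var in ("conf_1", "conf_2"):
            row = report.table.loc[var]
            assert abs(row["smd_grs_strata"]) <= 3 * row["se_grs_strata"]
            assert abs(row["smd_exposure_strata"]) > 3 * row["se_exposure_strata"]

    def test_unconfounded_model_balanced_both_ways(self):
        clean = grs_model(confounder_effects=((0.0, 0.0), (0.0, 0.0)), n=50_000, seed=13)
        report = strata_balance_report(clean, cut_fraction=0.30)
        for var in ("conf_1", "conf_2"):
            row = report.table.loc[var]
            assert abs(row["smd_grs_strata"]) <= 3 * row["se_grs_strata"]
            assert abs(row["smd_exposure_strata"]) <= 3 * row["se_exposure_strata"]

    def test_rejects_degenerate_strata(self):
        with pytest.raises(ParameterError):
            strata_balance_report(grs_model(n=200), cut_fraction=0.30)
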