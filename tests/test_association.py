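"""Per-SNP regressions, Hardy-Weinberg checks and internal-coefficient models."""

import numpy as np
import pandas as pd
import pytest

from psacorrect.association import (
    covariate_balance_check,
    fit_internal_model,
    hwe_test,
    hwe_test_from_dosages,
    per_snp_linear,
    per_snp_logistic,
    select_stratum,
    unadjusted_variance_explained,
)
from psacorrect.cohort import CohortTable
from psacorrect.exceptions import ConfigError, DataError, SeparationError
from psacorrect.scores import psa_panel


def _table(df: pd.DataFrame) -> CohortTable:
    return CohortTable(df, panel_ids=[c for c in df.columns if c.startswith("rs")])


class TestHWE:
    def test_exact_hwe_proportions_give_p_one(self):
        res = hwe_test(25, 50, 25)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # counts (10,10,10): freq 0.5, expected (7.5, 15, 7.5), chi2 = 10/3
        res = hwe_test(10, 10, 10)
        assert res.statistic == pytest.approx(10 / 3, abs=1e-12)
        assert res.p_value == pytest.approx(0.0679, abs=1e-3)

    def test_monomorphic_flagged(self):
        res = hwe_test(0, 0, 50)
        assert res.monomorphic and res.p_value is None

    def test_exact_test_matches_enumeration(self):
        """Exact p equals a direct enumeration of heterozygote-count
        probabilities conditional on the allele counts."""
        from math import comb

        def brute(n0, n1, n2):
            n = n0 + n1 + n2
            rare = min(2 * n0 + n1, 2 * n2 + n1)
            probs = {}
            for h in range(rare % 2, rare + 1, 2):
                r_hom = (rare - h) // 2
                c_hom = n - h - r_hom
                # multinomial weight of the genotype configuration
                w = 2**h * comb(n, h) * comb(n - h, r_hom)
                probs[h] = w
            total = sum(probs.values())
            obs = probs[n1] / total
            return sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12))

        for counts in [(10, 10, 10), (5, 20, 25), (1, 2, 47), (0, 10, 40)]:
            assert hwe_test(*counts, method="exact").p_value == \
                pytest.approx(brute(*counts), rel=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ConfigError):
            hwe_test(-1, 2, 3)
        with pytest.raises(ConfigError):
            hwe_test(0, 0, 0)

    def test_from_dosages_ignores_missing(self):
        d = pd.Series([0, 1, 2, None, 1])
        res = hwe_test_from_dosages(d)
        assert res.counts == (1, 2, 1)


class TestLinear:
    def test_binary_dosage_beta_equals_group_difference(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 2, 200)
        psa = 4.0 + 0.7 * d + rng.normal(0, 1, 200)
        df = pd.DataFrame({"subject_id": range(200), "psa": psa, "age": 60.0,
                           "centre": "X", "risk_group": "low", "rs1": d})
        res = per_snp_linear(_table(df), "rs1", stratum="all")
        diff = psa[d == 1].mean() - psa[d == 0].mean()
        assert res.effect == pytest.approx(diff, abs=1e-10)

    def test_null_effect_recovered_on_synthetic_cohort(self, sim_cohort):
        """Aggressive-panel SNPs have no PSA effect in the generator, so the
        per-allele beta should sit within 3 SE of zero."""
        res = per_snp_linear(sim_cohort, "rs1994198", covariates=("age", "centre"),
                             stratum="low_risk")
        se = (res.ci_high - res.ci_low) / (2 * 1.959964)
        assert abs(res.effect) < 3 * se

    def test_constant_dosage_flagged(self):
        df = pd.DataFrame({"subject_id": range(10), "psa": np.linspace(3, 9, 10),
                           "age": 60.0, "centre": "X", "risk_group": "low",
                           "rs1": 1})
        res = per_snp_linear(_table(df), "rs1")
        assert res.flag == "constant_dosage"
        assert np.isnan(res.effect)

    def test_variance_explained_engineered_r2(self):
        """A SNP constructed to explain ~2% of PSA variance yields R^2 near
        0.02 from the unadjusted fit."""
        rng = np.random.default_rng(1)
        n = 10_000
        d = rng.binomial(2, 0.5, n).astype(float)
        var_d = 2 * 0.5 * 0.5
        beta = np.sqrt(0.02 / (var_d * (1 - 0.02)))   # residual sd 1
        psa = 5.0 + beta * d + rng.normal(0, 1, n)
        df = pd.DataFrame({"subject_id": range(n), "psa": psa, "age": 60.0,
                           "centre": "X", "risk_group": "low", "rs1": d})
        r2, f = unadjusted_variance_explained(_table(df), "rs1")
        assert r2 == pytest.approx(0.02, abs=0.005)
        assert f > 100

    def test_constant_psa_gives_zero_r2(self):
        df = pd.DataFrame({"subject_id": range(20), "psa": 5.0, "age": 60.0,
                           "centre": "X", "risk_group": "low",
                           "rs1": np.r_[np.zeros(10), np.ones(10)]})
        r2, f = unadjusted_variance_explained(_table(df), "rs1")
        assert r2 == 0.0 and f == 0.0


class TestLogistic:
    def test_two_class_per_allele_or_equals_cross_product_ratio(self):
        """With only dosage classes 1 and 2 present, the per-allele ML
        estimate collapses to the 2x2 odds ratio; counts here follow the
        published KLK3 genotype distribution (high: 29 CT / 155 TT,
        low: 75 CT / 609 TT) whose closed form is ~0.658."""
        rows = []
        for dosage, group, n in [(1, "high", 29), (2, "high", 155),
                                 (1, "low", 75), (2, "low", 609)]:
            rows += [{"subject_id": f"{group}{dosage}_{i}", "psa": 5.0,
                      "age": 60.0, "centre": "X", "risk_group": group,
                      "rs17632542": dosage} for i in range(n)]
        res = per_snp_logistic(_table(pd.DataFrame(rows)), "rs17632542")
        closed_form = (155 / 609) / (29 / 75)
        assert res.effect == pytest.approx(closed_form, abs=1e-6)
        assert res.effect == pytest.approx(0.659, abs=1e-3)

    def test_null_or_recovered_on_synthetic_cohort(self, sim_cohort):
        res = per_snp_logistic(sim_cohort, "rs4054823", covariates=("age",))
        log_or = np.log(res.effect)
        se = (np.log(res.ci_high) - np.log(res.ci_low)) / (2 * 1.959964)
        assert abs(log_or) < 3 * se

    def test_separation_raises(self):
        df = pd.DataFrame({
            "subject_id": range(40), "psa": 5.0, "age": 60.0, "centre": "X",
            "risk_group": ["high"] * 20 + ["low"] * 20,
            "rs1": [2] * 20 + [0] * 20,
        })
        with pytest.raises(SeparationError):
            per_snp_logistic(_table(df), "rs1")

    def test_single_class_rejected(self):
        df = pd.DataFrame({"subject_id": range(10), "psa": 5.0, "age": 60.0,
                           "centre": "X", "risk_group": "low",
                           "rs1": np.r_[np.zeros(5), np.ones(5)]})
        with pytest.raises(DataError):
            per_snp_logistic(_table(df), "rs1")


class TestInternalModels:
    def test_null_predictors_give_chance_auc(self):
        rng = np.random.default_rng(2)
        n = 5_000
        df = pd.DataFrame({
            "subject_id": range(n),
            "psa": rng.lognormal(1.5, 0.3, n),
            "age": 60.0, "centre": "X",
            "risk_group": np.where(rng.random(n) < 0.2, "high", "low"),
        })
        res = fit_internal_model(_table(df), include_psa=True, name="null")
        assert res.auc.auc == pytest.approx(0.5, abs=0.02)

    def test_nested_model_auc_essentially_non_decreasing_in_sample(self, sim_cohort):
        """Adding predictors to a nested logistic model should not reduce
        in-sample discrimination by more than a sliver: ML maximises the
        likelihood rather than the AUC, so tiny decreases are possible, but
        anything beyond rounding-scale indicates a broken fit."""
        p4 = psa_panel()
        m1 = fit_internal_model(sim_cohort, include_psa=True, name="m1")
        m2 = fit_internal_model(sim_cohort, include_psa=True, psa_snps=p4, name="m2")
        assert m2.auc.auc >= m1.auc.auc - 0.005


class TestStrataAndBalance:
    def test_stratum_selection(self, sim_cohort):
        df = sim_cohort.data
        assert len(select_stratum(sim_cohort, "low_risk")) == (df["risk_group"] == "low").sum()
        n_young = len(select_stratum(sim_cohort, "age<65"))
        n_old = len(select_stratum(sim_cohort, "age>=65"))
        assert n_young + n_old == len(df)
        with pytest.raises(ConfigError):
            select_stratum(sim_cohort, "nope")

    def test_balance_detects_constructed_confounding(self):
        rng = np.random.default_rng(3)
        n = 2_000
        d = rng.binomial(2, 0.4, n).astype(float)
        pc_corr = 0.3 * (d - d.mean()) / d.std() + np.sqrt(1 - 0.09) * rng.normal(size=n)
        df = pd.DataFrame({"subject_id": range(n), "psa": 5.0, "age": 60.0,
                           "centre": "X", "risk_group": "low", "rs1": d,
                           "PC1": pc_corr, "PC2": rng.normal(size=n),
                           "PC3": 1.0})
        out = covariate_balance_check(_table(df), "rs1").set_index("pc")
        assert out.loc["PC1", "p_value"] < 0.001
        assert out.loc["PC2", "p_value"] > 0.001
        assert out.loc["PC3", "flag"] == "constant"
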