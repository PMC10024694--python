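"""Trio simulator: Mendelian consistency, HWE, variance-fraction truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import famgreml as fg
from famgreml.pheno import SMFQ, PhenotypeTable, score_scale
from famgreml.simulate import SimulationConfig, expected_components


def _config(**kw):
    defaults = dict(n_families=300, n_snps=200, n_causal=200, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_overfull_variance_rejected(self):
        with pytest.raises(ValueError, match="exceed 1"):
            _config(v_o=0.6, v_m=0.5, rho_m=0.5)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(maf_low=0.0),
            dict(maf_low=0.3, maf_high=0.2),
            dict(maf_high=0.6),
            dict(n_causal=500),
            dict(rho_m=1.5),
            dict(v_o=-0.1),
            dict(beta_batch=(0.0,)),
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            _config(**kw)


class TestGenotypes:
    def test_mendelian_consistency_everywhere(self):
        cohort = fg.simulate_trio_genotypes(_config(n_families=500, n_snps=300))
        # independent elementwise check, not the cohort's own counter
        c, m, f = (cohort.child_genotypes.astype(int),
                   cohort.mother_genotypes.astype(int),
                   cohort.father_genotypes.astype(int))
        lo = (m == 2).astype(int) + (f == 2).astype(int)
        hi = (m > 0).astype(int) + (f > 0).astype(int)
        assert np.all((c >= lo) & (c <= hi))
        assert cohort.mendelian_error_count() == 0

    def test_homozygous_parents_force_child_genotype(self):
        cohort = fg.simulate_trio_genotypes(_config(n_families=400, n_snps=300))
        both_zero = (cohort.mother_genotypes == 0) & (cohort.father_genotypes == 0)
        both_two = (cohort.mother_genotypes == 2) & (cohort.father_genotypes == 2)
        assert np.all(cohort.child_genotypes[both_zero] == 0)
        assert np.all(cohort.child_genotypes[both_two] == 2)

    def test_heterozygosity_at_maf_half(self):
        # HWE at p = 0.5: expected heterozygosity 0.5
        cfg = _config(n_families=10_000, n_snps=50, n_causal=50,
                      maf_low=0.5, maf_high=0.5)
        cohort = fg.simulate_trio_genotypes(cfg)
        het = (cohort.child_genotypes == 1).mean()
        se = np.sqrt(0.25 / (cfg.n_families * cfg.n_snps))
        assert abs(het - 0.5) < 3 * se

    def test_same_seed_bit_identical(self):
        a = fg.simulate_trio_genotypes(_config())
        b = fg.simulate_trio_genotypes(_config())
        assert np.array_equal(a.child_genotypes, b.child_genotypes)
        assert np.array_equal(a.mother_genotypes, b.mother_genotypes)
        assert np.array_equal(a.batch, b.batch)

    def test_cross_relatedness_matches_mendelian_expectation(self):
        # child vs own parent relatedness ~ 0.5 with sd ~ 1/sqrt(M)
        cfg = _config(n_families=2000, n_snps=1000)
        cohort = fg.simulate_trio_genotypes(cfg)
        cross = fg.compute_cross_grm(cohort.child_genotypes, cohort.mother_genotypes)
        diag = np.diag(cross.values)
        assert abs(diag.mean() - 0.5) < 3 * diag.std() / np.sqrt(len(diag))
        # per-entry spread consistent with 1/sqrt(M) theory (factor-2 band)
        assert 0.5 / np.sqrt(cfg.n_snps) < diag.std() < 2.5 / np.sqrt(cfg.n_snps)


class TestExpectedComponents:
    def test_worked_example(self):
        truth = expected_components(_config(v_o=0.3, v_m=0.15, rho_m=0.5))
        assert truth.v_om == pytest.approx(0.5 * np.sqrt(0.045), abs=1e-12)
        assert truth.v_om == pytest.approx(0.1061, abs=5e-5)

    def test_zero_correlation_gives_zero_covariance(self):
        assert expected_components(_config(rho_m=0.0)).v_om == 0.0

    def test_perfect_correlation_symmetry(self):
        truth = expected_components(_config(v_o=0.2, v_m=0.2, rho_m=1.0))
        assert truth.v_om == pytest.approx(0.2, abs=1e-12)

    @given(
        v_o=st.floats(0.0, 0.4), v_m=st.floats(0.0, 0.3),
        rho=st.floats(-1.0, 1.0),
    )
    def test_fractions_sum_to_one(self, v_o, v_m, rho):
        try:
            cfg = _config(v_o=v_o, v_m=v_m, rho_m=rho)
        except ValueError:
            return
        t = expected_components(cfg)
        assert t.v_o + t.v_m + t.v_f + t.v_om + t.v_of + t.v_e == pytest.approx(1.0, abs=1e-9)
        assert np.sign(t.v_om) in (0.0, np.sign(rho)) or t.v_om == 0.0


@pytest.fixture(scope="module")
def big():
    cfg = SimulationConfig(n_families=50_000, n_snps=400, n_causal=400,
                           v_o=0.3, v_m=0.15, rho_m=0.5, seed=31)
    cohort = fg.simulate_trio_genotypes(cfg)
    pheno = fg.simulate_phenotypes(cohort, cfg)
    return cfg, cohort, pheno


class TestPhenotypes:

    def test_variance_fractions_match_truth(self, big):
        cfg, _, pheno = big
        truth = fg.expected_components(cfg)
        n = cfg.n_families
        g_o = pheno.data["g_o"].to_numpy()
        g_m = pheno.data["g_m"].to_numpy()
        # variance of a score: MC SE ~ v * sqrt(2/n)
        assert abs(g_o.var() - truth.v_o) < 3 * truth.v_o * np.sqrt(2 / n) + 3e-3
        assert abs(g_m.var() - truth.v_m) < 3 * truth.v_m * np.sqrt(2 / n) + 3e-3
        # the covariance component is twice cov(g_o, g_m)
        cov = np.cov(g_o, g_m)[0, 1]
        se_cov = np.sqrt((g_o.var() * g_m.var() + cov**2) / n)
        assert abs(2 * cov - truth.v_om) < 3 * 2 * se_cov

    def test_total_variance_is_one_before_covariates(self, big):
        cfg, cohort, pheno = big
        covar_part = (cfg.beta_sex * cohort.child_sex
                      + np.asarray(cfg.beta_batch)[cohort.batch])
        core = pheno.raw_score - covar_part
        assert core.var() == pytest.approx(1.0, abs=0.02)

    def test_sex_effect_recovered_by_regression(self, big):
        cfg, cohort, pheno = big
        sex = cohort.child_sex.astype(float)
        X = np.column_stack([np.ones_like(sex), sex])
        beta = np.linalg.lstsq(X, pheno.raw_score, rcond=None)[0]
        se = pheno.raw_score.std() / np.sqrt(cfg.n_families * sex.var())
        assert abs(beta[1] - cfg.beta_sex) < 3 * se

    def test_no_nurture_means_no_parental_variance(self):
        cfg = SimulationConfig(n_families=20_000, n_snps=300, n_causal=300,
                               v_o=0.3, v_m=0.0, v_f=0.0, rho_m=0.0, seed=8)
        cohort = fg.simulate_trio_genotypes(cfg)
        pheno = fg.simulate_phenotypes(cohort, cfg)
        assert np.allclose(pheno.data["g_m"], 0.0)
        assert np.allclose(pheno.data["g_f"], 0.0)

    def test_seed_variation_is_statistically_stable(self):
        ests = []
        for seed in (101, 202):
            cfg = SimulationConfig(n_families=30_000, n_snps=300, n_causal=300, seed=seed)
            cohort = fg.simulate_trio_genotypes(cfg)
            pheno = fg.simulate_phenotypes(cohort, cfg)
            ests.append(pheno.data["g_o"].to_numpy().var())
        # both close to truth, hence to each other
        assert abs(ests[0] - ests[1]) < 6 * 0.3 * np.sqrt(2 / 30_000)


class TestQuestionnaire:
    def _latent(self, values):
        n = len(values)
        return PhenotypeTable(
            pd.DataFrame(
                {"fid": [f"F{i}" for i in range(n)], "iid": [f"F{i}-C" for i in range(n)],
                 "raw": values, "valid": True, "standardized": values}
            )
        )

    def test_no_missingness_when_rate_zero(self):
        items = fg.simulate_questionnaire(self._latent(np.zeros(200)), SMFQ,
                                          missing_rate=0.0, seed=1)
        assert not items.drop(columns=["fid", "iid"]).isna().any().any()

    def test_floor_of_coding(self):
        # latent far below every threshold: all items at the minimum category
        items = fg.simulate_questionnaire(self._latent(np.full(50, -50.0)), SMFQ, seed=2)
        totals = score_scale(items, SMFQ).raw_score
        assert np.all(totals == 13)

    def test_item_total_correlations_positive(self):
        rng = np.random.default_rng(3)
        latent = rng.standard_normal(5000)
        items = fg.simulate_questionnaire(self._latent(latent), SMFQ, seed=3)
        vals = items.drop(columns=["fid", "iid"]).to_numpy()
        total = vals.sum(axis=1)
        for j in range(vals.shape[1]):
            rest = total - vals[:, j]
            assert np.corrcoef(vals[:, j], rest)[0, 1] > 0

    def test_missing_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="missing_rate"):
            fg.simulate_questionnaire(self._latent(np.zeros(10)), SMFQ, missing_rate=1.5)

    def test_deterministic_given_seed(self):
        latent = self._latent(np.linspace(-2, 2, 100))
        a = fg.simulate_questionnaire(latent, SMFQ, missing_rate=0.1, seed=9)
        b = fg.simulate_questionnaire(latent, SMFQ, missing_rate=0.1, seed=9)
        pd.testing.assert_frame_equal(a, b)
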