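"""Association engine: OLS/logistic correctness, genomic control, parental
rescaling, cohort slices, and allele-frequency grids."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lifegwas import gwas
from lifegwas.simcohort import CausalEffect, SimConfig, simulate_study


class TestAssocQuant:
    def test_exact_linear_fit(self):
        G = np.array([[0.0], [1.0], [2.0], [1.0], [0.0]])
        y = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        tab = gwas.assoc_quant(G, y)
        assert tab["beta"][0] == pytest.approx(1.0, abs=1e-12)

    def test_null_p_values_uniform(self, rng):
        n, m = 2000, 5000
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        tab = gwas.assoc_quant(G, y)
        frac = (tab["p_uc"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / m)
        assert abs(frac - 0.05) < 3 * se

    def test_matches_normal_equations_oracle(self, rng):
        """OLS betas/SEs agree with statsmodels to 1e-8 relative."""
        import statsmodels.api as sm

        n, m, c = 1000, 50, 3
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        G[rng.random((n, m)) < 0.02] = np.nan  # exercise per-variant paths
        C = rng.normal(size=(n, c))
        y = rng.normal(size=n) + C @ np.array([0.5, -0.2, 0.1])
        tab = gwas.assoc_quant(G, y, covariates=C)
        for j in range(m):
            rows = ~np.isnan(G[:, j])
            X = sm.add_constant(np.column_stack([C[rows], G[rows, j]]))
            fit = sm.OLS(y[rows], X).fit()
            assert tab["beta"][j] == pytest.approx(fit.params[-1], rel=1e-8)
            assert tab["se"][j] == pytest.approx(fit.bse[-1], rel=1e-8)

    def test_dilution_halves_parental_effect(self):
        cfg = SimConfig(
            n_offspring=60_000, n_variants=2,
            maf_spectrum=("uniform", 0.2, 0.2),
            causal_effects=(CausalEffect(0, "paternal_lifespan", 3.0),),
            missing_death_base_rate=0.0, birth_year_range=(1886, 1895),
            seed=41,
        )
        study = simulate_study(cfg)
        tab = gwas.assoc_quant(study.genotypes,
                               study.cohort["lifespan"].to_numpy())
        se = tab["se"][0]
        assert tab["beta"][0] == pytest.approx(1.5, abs=3 * se)

    def test_zero_variance_genotype_skipped(self):
        G = np.column_stack([np.ones(20), np.arange(20) % 3]).astype(float)
        y = np.arange(20, dtype=float)
        tab = gwas.assoc_quant(G, y)
        assert tab["skipped"][0] and not tab["skipped"][1]


class TestAssocCaseControl:
    def test_quantile_thresholds(self):
        ages = np.arange(1.0, 101.0)
        G = np.tile(np.array([[0.0], [1.0]]), (50, 1))
        tab = gwas.assoc_case_control(G, ages, case_tail=0.05)
        # cases: ages 96-100 (5), controls: ages <= 50 (median)
        assert tab.attrs["case_threshold"] == pytest.approx(95.05)
        assert tab.attrs["control_threshold"] == pytest.approx(50.5)

    def test_null_lambda_near_one(self, rng):
        n, m = 4000, 800
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        ages = rng.normal(70, 8, size=n)
        tab = gwas.assoc_case_control(G, ages, case_tail=0.10)
        cal, _ = gwas.genomic_control(tab)
        assert cal.lam == pytest.approx(1.0, abs=0.1)

    def test_documented_age_defaults(self):
        d = gwas.AGE_CC_DEFAULTS
        assert d["case_tail"] == 0.05
        assert d["case_age"] == {"M": 86, "F": 87}
        assert d["control_age"] == {"M": 65, "F": 64}

    def test_empty_case_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            gwas.assoc_case_control(
                np.ones((0, 1)), np.array([]), case_tail=0.05)


class TestGenomicControl:
    def test_lambda_definitional(self):
        z = np.sqrt(np.full(101, gwas.CHI2_1_MEDIAN))
        tab = pd.DataFrame({"z": z, "p_uc": 0.5})
        cal, _ = gwas.genomic_control(tab)
        assert cal.lam == pytest.approx(1.0, abs=1e-12)

    def test_lambda_anchor_value(self):
        # median chi2 0.494234 = 0.455936 * 1.084
        z = np.sqrt(np.full(51, 0.494234))
        cal, _ = gwas.genomic_control(pd.DataFrame({"z": z}))
        assert cal.lam == pytest.approx(1.084, abs=1e-3)

    def test_correction_divides_chi2(self):
        # chi2 30 under lambda 1.2 -> 25 -> P 5.73e-7
        z = np.concatenate([
            np.sqrt(np.full(100, 1.2 * gwas.CHI2_1_MEDIAN)),
            [np.sqrt(30.0)],
        ])
        cal, tab = gwas.genomic_control(pd.DataFrame({"z": z}))
        assert cal.lam == pytest.approx(1.2, rel=1e-9)
        assert tab["p_gc"].iloc[-1] == pytest.approx(
            stats.chi2.sf(25.0, 1), rel=1e-6)
        assert tab["p_gc"].iloc[-1] == pytest.approx(5.73e-7, rel=1e-3)

    def test_deflation_not_applied(self):
        z = np.sqrt(np.full(51, 0.5 * gwas.CHI2_1_MEDIAN))
        cal, tab = gwas.genomic_control(pd.DataFrame({"z": z}))
        assert cal.lam < 1
        assert tab["p_gc"].iloc[0] == pytest.approx(
            stats.chi2.sf(0.5 * gwas.CHI2_1_MEDIAN, 1), rel=1e-9)


class TestThresholdAndRescale:
    def test_bonferroni_study_scale(self):
        assert gwas.significance_threshold(0.05, 540_852) == pytest.approx(
            9.24e-8, rel=5e-3)

    def test_bonferroni_single_test(self):
        assert gwas.significance_threshold(0.05, 1) == 0.05

    def test_invalid_m_raises(self):
        with pytest.raises(ValueError):
            gwas.significance_threshold(0.05, 0)

    def test_rescale_doubles_beta_se_quadruples_h2(self):
        tab = pd.DataFrame({
            "beta": [0.325, 0.0], "se": [0.045, 0.1],
            "z": [7.2, 0.0], "p_uc": [1e-12, 1.0], "maf": [0.49, 0.2],
        })
        tab.attrs["scale"] = "offspring"
        tab = gwas.per_snp_variance_explained(tab, phenotypic_variance=166.2)
        out = gwas.rescale_parental(tab)
        assert out["beta"][0] == pytest.approx(0.65)
        assert out["se"][0] == pytest.approx(0.09)
        assert out["beta"][1] == 0.0
        assert out["h2_snp"][0] == pytest.approx(4 * tab["h2_snp"][0])
        assert out["z"][0] == tab["z"][0]

    def test_double_rescale_rejected(self):
        tab = pd.DataFrame({"beta": [1.0], "se": [0.1]})
        tab.attrs["scale"] = "offspring"
        once = gwas.rescale_parental(tab)
        with pytest.raises(ValueError, match="already"):
            gwas.rescale_parental(once)


class TestCohortSlices:
    def test_default_slices_are_the_eleven_windows(self):
        assert len(gwas.DEFAULT_COHORT_SLICES) == 11
        assert gwas.DEFAULT_COHORT_SLICES[0] == (1886, 1894)
        assert gwas.DEFAULT_COHORT_SLICES[-1] == (1935, 1940)

    def test_effect_restricted_to_early_cohorts_recovered(self, rng):
        # causal effect present only for parents born before 1920
        n = 40_000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        birth = rng.integers(1886, 1941, size=n)
        beta_parental = 4.0
        effect = np.where(birth < 1920, beta_parental / 2, 0.0)
        y = 76 + effect * g + rng.normal(0, 12, size=n)
        cohort = pd.DataFrame({"birth_year": birth, "lifespan": y})
        res = gwas.cohort_slice_effects(
            g[:, None], cohort, 0,
            slices=((1886, 1910), (1925, 1940)),
        )
        early, late = res.iloc[0], res.iloc[1]
        assert abs(early["beta"] - beta_parental / 2) < 2 * early["se"]
        assert abs(late["beta"]) < 2 * late["se"]

    def test_single_slice_equals_assoc_quant(self, causal_study):
        cohort = causal_study.cohort
        y = cohort["lifespan"].to_numpy()
        res = gwas.cohort_slice_effects(
            causal_study.genotypes, cohort, 0,
            slices=((1886, 1905),),
        )
        direct = gwas.assoc_quant(causal_study.genotypes[:, :1], y)
        assert res["beta"][0] == pytest.approx(direct["beta"][0])
        assert res["se"][0] == pytest.approx(direct["se"][0])

    def test_sparse_slice_flagged_empty(self):
        cohort = pd.DataFrame({
            "birth_year": [1900, 1900], "lifespan": [70.0, 80.0]})
        res = gwas.cohort_slice_effects(
            np.array([[1.0], [1.0]]), cohort, 0, slices=((1930, 1940),))
        assert res["empty"][0] and np.isnan(res["beta"][0])


class TestAFGrid:
    def _cohort(self, rng, n):
        return pd.DataFrame({
            "birth_year": rng.integers(1886, 1941, size=n),
            "lifespan": rng.uniform(40, 120, size=n),
        })

    def test_min_n_masking(self, rng):
        n = 499  # every cell below the mask threshold
        cohort = self._cohort(rng, n)
        g = rng.binomial(2, 0.2, size=(n, 1)).astype(float)
        maf, counts = gwas.af_by_lifespan_grid(
            g, cohort, 0, lifespan_bins=np.array([40.0, 120.0]),
            cohort_slices=((1886, 1940),), min_n=500)
        assert counts.iloc[0, 0] == 499
        assert np.isnan(maf.iloc[0, 0])

    def test_constant_frequency_grid_flat(self, rng):
        n = 60_000
        cohort = self._cohort(rng, n)
        g = rng.binomial(2, 0.2, size=(n, 1)).astype(float)
        maf, counts = gwas.af_by_lifespan_grid(
            g, cohort, 0, lifespan_bins=np.arange(40.0, 121.0, 20.0),
            cohort_slices=((1886, 1912), (1913, 1940)), min_n=500)
        vals = maf.to_numpy()
        ns = counts.to_numpy()
        ok = ~np.isnan(vals)
        se = np.sqrt(0.2 * 0.8 / (2 * ns[ok]))
        assert (np.abs(vals[ok] - 0.2) < 4 * se).all()

    def test_constructed_enrichment_detected(self, rng):
        n = 40_000
        cohort = self._cohort(rng, n)
        in_cell = ((cohort["birth_year"] <= 1912)
                   & (cohort["lifespan"] >= 80)).to_numpy()
        p = np.where(in_cell, 0.35, 0.20)
        g = rng.binomial(2, p).astype(float)[:, None]
        maf, counts = gwas.af_by_lifespan_grid(
            g, cohort, 0, lifespan_bins=np.array([40.0, 80.0, 120.0]),
            cohort_slices=((1886, 1912), (1913, 1940)), min_n=500)
        cell_n = counts.iloc[0, 1]
        se = np.sqrt(0.35 * 0.65 / (2 * cell_n))
        assert abs(maf.iloc[0, 1] - 0.35) < 3 * se
        assert abs(maf.iloc[1, 0] - 0.20) < 3 * np.sqrt(
            0.2 * 0.8 / (2 * counts.iloc[1, 0]))
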