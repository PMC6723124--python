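"""QC filter contracts, verified against brute-force oracles on fixtures."""

import numpy as np
import pandas as pd
import pytest

from lifegwas import qc
from lifegwas.simcohort import SimConfig, simulate_study


def _hwe_matrix(rng, n, mafs, perturb=None):
    """HWE dosage columns at the given frequencies; optionally replace a
    column with a deliberately non-HWE genotype mix."""
    G = np.column_stack([rng.binomial(2, p, size=n) for p in mafs]).astype(float)
    if perturb:
        for j, het_frac in perturb.items():
            k = int(n * het_frac)
            G[:, j] = 0.0
            G[:k, j] = 1.0
    return G


class TestVariantQC:
    def test_maf_and_missingness_filters_by_construction(self, rng):
        n = 4000
        mafs = [0.001, 0.001, 0.01, 0.01, 0.2, 0.2]
        G = _hwe_matrix(rng, n, mafs)
        # columns 1, 3 get 25% missingness
        for j in (1, 3):
            G[: n // 4, j] = np.nan
        ids = [f"v{j}" for j in range(6)]
        rep = qc.variant_qc(G, ids, maf_min=0.005, var_missing_max=0.20,
                            hwe_worst_frac=0.0)
        assert rep.kept_variants == ["v2", "v4", "v5"] or \
            rep.kept_variants == ["v2", "v3", "v4", "v5"][:3]
        # v0/v1 fail MAF; v1/v3 fail missingness; survivors are the common,
        # complete columns
        assert "v4" in rep.kept_variants and "v5" in rep.kept_variants
        assert "v0" not in rep.kept_variants
        assert "v1" not in rep.kept_variants
        assert "v3" not in rep.kept_variants

    def test_maf_threshold_inclusive(self):
        # 2000 haplotypes, exactly 10 alt alleles -> MAF exactly 0.005
        G = np.zeros((1000, 1))
        G[:10, 0] = 1.0
        rep = qc.variant_qc(G, ["v0"], maf_min=0.005, hwe_worst_frac=0.0)
        assert rep.kept_variants == ["v0"]

    def test_hwe_worst_removed_matches_bruteforce(self, rng):
        n, m = 2000, 200
        G = _hwe_matrix(rng, n, rng.uniform(0.1, 0.5, size=m),
                        perturb={7: 0.9, 123: 0.95})
        ids = [f"v{j:03d}" for j in range(m)]
        rep = qc.variant_qc(G, ids, maf_min=0.0, var_missing_max=1.0,
                            hwe_worst_frac=2 / m)
        # brute-force chi2 ranking
        st = qc.variant_stats(G, ids)
        worst = st.sort_values(["hwe_chi2", "variant"],
                               ascending=[False, True])["variant"][:2]
        assert set(rep.removed_variants["hwe"]) == set(worst)
        assert set(worst) == {"v007", "v123"}

    def test_all_removed_raises(self):
        G = np.zeros((50, 3))  # monomorphic, MAF 0
        with pytest.raises(ValueError, match="every variant"):
            qc.variant_qc(G, ["a", "b", "c"], maf_min=0.01)

    def test_idempotent(self, rng):
        G = _hwe_matrix(rng, 1000, rng.uniform(0.05, 0.5, size=40))
        ids = [f"v{j}" for j in range(40)]
        rep1 = qc.variant_qc(G, ids)
        cols = [ids.index(v) for v in rep1.kept_variants]
        rep2 = qc.variant_qc(G[:, cols], rep1.kept_variants,
                             hwe_worst_frac=0.0)
        # after the worst-fraction removal, a re-run with the rank filter
        # off removes nothing more
        assert rep2.kept_variants == rep1.kept_variants


class TestIndividualQC:
    def test_threshold_exceeded_removed(self):
        G = np.zeros((3, 100))
        G[1, :3] = np.nan  # 3% missing
        rep = qc.individual_qc(G, ["a", "b", "c"], ind_missing_max=0.02)
        assert rep.kept_individuals == ["a", "c"]
        assert rep.removed_individuals["missingness"] == ["b"]

    def test_clean_matrix_keeps_everyone(self, rng):
        G = rng.binomial(2, 0.3, size=(20, 10)).astype(float)
        rep = qc.individual_qc(G, [f"i{k}" for k in range(20)])
        assert len(rep.kept_individuals) == 20

    def test_matches_bruteforce(self, rng):
        n, m = 50, 200
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        miss = rng.random((n, m)) < rng.uniform(0, 0.05, size=(n, 1))
        G[miss] = np.nan
        ids = [f"i{k:02d}" for k in range(n)]
        rep = qc.individual_qc(G, ids, ind_missing_max=0.02)
        expect = [ids[k] for k in range(n)
                  if np.isnan(G[k]).mean() <= 0.02]
        assert rep.kept_individuals == expect


class TestLDPrune:
    def test_duplicate_column_pruned_to_one(self, rng):
        g = rng.binomial(2, 0.4, size=500).astype(float)
        G = np.column_stack([g, g, rng.binomial(2, 0.4, size=500)])
        kept = qc.ld_prune(G, ["a", "b", "c"], r2_max=0.9)
        assert sorted(kept)[-1] == "c" and len(kept) == 2

    def test_independent_columns_survive(self, rng):
        G = rng.binomial(2, 0.3, size=(2000, 30)).astype(float)
        kept = qc.ld_prune(G, [f"v{j}" for j in range(30)], r2_max=0.9)
        assert len(kept) == 30

    def test_correlated_block_postcondition_exhaustive(self, rng):
        # 20 variants built from 3 latent haplotype blocks -> strong LD
        n = 1000
        base = rng.binomial(2, 0.5, size=(n, 3)).astype(float)
        cols, ids = [], []
        for j in range(20):
            src = base[:, j % 3].copy()
            flip = rng.random(n) < 0.02
            src[flip] = rng.binomial(2, 0.5, size=flip.sum())
            cols.append(src)
            ids.append(f"v{j:02d}")
        G = np.column_stack(cols)
        kept = qc.ld_prune(G, ids, r2_max=0.9, window=20)
        idx = [ids.index(v) for v in kept]
        r2 = pd.DataFrame(G[:, idx]).corr().to_numpy() ** 2
        np.fill_diagonal(r2, 0.0)
        assert r2.max() <= 0.9
        assert len(kept) >= 3  # one representative per block survives


class TestPCA:
    def test_pc1_separates_subpopulations(self):
        cfg = SimConfig(n_offspring=600, n_variants=400, n_subpops=2,
                        fst=0.1, missing_death_base_rate=0.0, seed=31)
        study = simulate_study(cfg)
        res = qc.pca_covariates(
            study.genotypes, list(study.panel["variant"]), k=2, seed=0,
            ld_prune_first=False,
        )
        labels = study.cohort["subpop"].to_numpy()
        r = np.corrcoef(res.scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_explained_variance_nonincreasing(self, null_study):
        res = qc.pca_covariates(
            null_study.genotypes, list(null_study.panel["variant"]),
            k=5, seed=1, ld_prune_first=False,
        )
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_seed_determinism_up_to_sign(self, null_study):
        a = qc.pca_covariates(null_study.genotypes,
                              list(null_study.panel["variant"]),
                              k=3, seed=7, ld_prune_first=False)
        b = qc.pca_covariates(null_study.genotypes,
                              list(null_study.panel["variant"]),
                              k=3, seed=7, ld_prune_first=False)
        for j in range(3):
            c = np.corrcoef(a.scores[:, j], b.scores[:, j])[0, 1]
            assert abs(abs(c) - 1) < 1e-9

    def test_matches_full_eigendecomposition(self, rng):
        # planted factors of decreasing strength give a well-separated
        # spectrum, so component-wise comparison is meaningful
        n, m = 200, 50
        factors = rng.integers(0, 2, size=(n, 3))
        p_base = rng.uniform(0.2, 0.4, size=m)
        shift = np.array([0.25, 0.15, 0.08])
        P = np.clip(
            p_base + (factors * shift) @ rng.choice([-1.0, 1.0], size=(3, m)),
            0.05, 0.95,
        )
        G = rng.binomial(2, P).astype(float)
        res = qc.pca_covariates(G, [f"v{j}" for j in range(50)], k=3,
                                seed=0, ld_prune_first=False)
        p = G.mean(axis=0) / 2
        X = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        for j in range(3):
            ref = Xc @ vt[j]
            c = np.corrcoef(res.scores[:, j], ref)[0, 1]
            assert abs(c) > 0.999

    def test_zero_variance_column_warns(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 5)).astype(float)
        G[:, 2] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            qc.pca_covariates(G, [f"v{j}" for j in range(5)], k=2,
                              seed=0, ld_prune_first=False)

    def test_k_beyond_rank_raises(self, rng):
        G = rng.binomial(2, 0.3, size=(10, 4)).astype(float)
        with pytest.raises(ValueError, match="k="):
            qc.pca_covariates(G, [f"v{j}" for j in range(4)], k=5,
                              seed=0, ld_prune_first=False)


class TestPruneRelatives:
    def test_single_pair_one_removed(self):
        rel = pd.DataFrame({"iid1": ["a"], "iid2": ["b"], "ibd_cm": [350.0]})
        kept = qc.prune_relatives(rel, ["a", "b", "c"], threshold_cm=300)
        assert len(kept) == 2 and "c" in kept

    def test_below_threshold_untouched(self):
        rel = pd.DataFrame({"iid1": ["a", "b"], "iid2": ["b", "c"],
                            "ibd_cm": [299.0, 120.0]})
        kept = qc.prune_relatives(rel, ["a", "b", "c"], threshold_cm=300)
        assert kept == ["a", "b", "c"]

    def test_triangle_postcondition_exhaustive(self):
        rel = pd.DataFrame({
            "iid1": ["a", "a", "b"], "iid2": ["b", "c", "c"],
            "ibd_cm": [400.0, 400.0, 400.0],
        })
        for seed in range(10):
            kept = qc.prune_relatives(rel, ["a", "b", "c", "d"],
                                      threshold_cm=300, seed=seed)
            kept_set = set(kept)
            assert "d" in kept_set
            for x, y, cm in rel.itertuples(index=False):
                assert not (cm > 300 and x in kept_set and y in kept_set)

    def test_uninvolved_never_removed(self, rng):
        ids = [f"i{k}" for k in range(20)]
        rel = pd.DataFrame({"iid1": ["i0"], "iid2": ["i1"],
                            "ibd_cm": [500.0]})
        kept = qc.prune_relatives(rel, ids, threshold_cm=300, seed=3)
        assert set(ids) - set(kept) <= {"i0", "i1"}


class TestPipeline:
    def test_counts_balance(self, rng):
        n, m = 500, 60
        G = _hwe_matrix(rng, n, rng.uniform(0.05, 0.5, size=m))
        G[rng.random((n, m)) < 0.01] = np.nan
        ids = [f"v{j}" for j in range(m)]
        iids = [f"i{k}" for k in range(n)]
        rep = qc.run_variant_pipeline(G, ids, iids)
        removed = sum(len(v) for v in rep.removed_variants.values())
        assert removed + len(rep.kept_variants) == m
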