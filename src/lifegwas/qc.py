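"""Genotype and sample quality control for array-based association mapping.

Filters follow common GWAS practice: a minor-allele-frequency floor,
per-variant and per-individual missingness ceilings, removal of the
fraction of variants deviating most strongly from Hardy-Weinberg
proportions, greedy windowed LD pruning, PCA covariates on a
near-linkage-equilibrium SNP subset, and removal of close relatives by
pairwise IBD.

Fixed filter order used by :func:`run_variant_pipeline`: variant
missingness -> MAF -> HWE worst-fraction -> individual missingness ->
LD pruning.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

DEFAULT_MAF_MIN = 0.005
DEFAULT_VAR_MISSING_MAX = 0.20
DEFAULT_IND_MISSING_MAX = 0.02
DEFAULT_HWE_WORST_FRAC = 0.01
DEFAULT_LD_R2_MAX = 0.9
DEFAULT_IBD_THRESHOLD_CM = 300.0


@dataclasses.dataclass
class QCReport:
    """Outcome of a QC pass: what survived, what was removed, and why."""

    kept_variants: list[str] | None = None
    removed_variants: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    kept_individuals: list[str] | None = None
    removed_individuals: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    variant_stats: pd.DataFrame | None = None

    def summary(self) -> dict:
        out: dict = {}
        if self.kept_variants is not None:
            out["n_variants_kept"] = len(self.kept_variants)
            out["variants_removed"] = {
                k: len(v) for k, v in self.removed_variants.items()
            }
        if self.kept_individuals is not None:
            out["n_individuals_kept"] = len(self.kept_individuals)
            out["individuals_removed"] = {
                k: len(v) for k, v in self.removed_individuals.items()
            }
        return out


@dataclasses.dataclass
class PCResult:
    """Principal-component scores (n x k) and explained-variance shares."""

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    snp_subset: list[str]


# ---------------------------------------------------------------------------
# per-variant statistics
# ---------------------------------------------------------------------------

def variant_stats(genotypes: np.ndarray, variant_ids: list[str]) -> pd.DataFrame:
    """Per-variant MAF, missingness, and HWE chi-square.

    The HWE statistic is a goodness-of-fit chi-square of the observed
    0/1/2 counts against (p^2, 2pq, q^2) at the estimated frequency.
    Monomorphic variants get statistic 0.
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    miss = np.isnan(G)
    n_obs = n - miss.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_hat = np.nansum(G, axis=0) / (2 * np.maximum(n_obs, 1))
    maf = np.minimum(p_hat, 1 - p_hat)

    n0 = np.nansum(G == 0, axis=0)
    n1 = np.nansum(G == 1, axis=0)
    n2 = np.nansum(G == 2, axis=0)
    q = 1 - p_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        e0 = n_obs * q**2
        e1 = n_obs * 2 * p_hat * q
        e2 = n_obs * p_hat**2
        chi2 = np.zeros(m)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0)
            chi2 += term
    chi2[(p_hat == 0) | (p_hat == 1)] = 0.0
    return pd.DataFrame(
        {
            "variant": variant_ids,
            "maf": maf,
            "missingness": miss.sum(axis=0) / n,
            "hwe_chi2": chi2,
            "n_obs": n_obs,
        }
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def variant_qc(
    genotypes: np.ndarray,
    variant_ids: list[str],
    maf_min: float = DEFAULT_MAF_MIN,
    var_missing_max: float = DEFAULT_VAR_MISSING_MAX,
    hwe_worst_frac: float = DEFAULT_HWE_WORST_FRAC,
) -> QCReport:
    """MAF floor (inclusive), missingness ceiling (inclusive), then removal
    of the ``ceil(hwe_worst_frac * m_surviving)`` variants with the largest
    HWE chi-square (ties broken by variant id).

    Raises ``ValueError`` if nothing survives.
    """
    st = variant_stats(genotypes, variant_ids).set_index("variant")
    removed: dict[str, list[str]] = {}

    miss_fail = st.index[st["missingness"] > var_missing_max].tolist()
    removed["missingness"] = miss_fail
    st1 = st.drop(index=miss_fail)

    maf_fail = st1.index[st1["maf"] < maf_min].tolist()
    removed["maf"] = maf_fail
    st2 = st1.drop(index=maf_fail)

    if len(st2) == 0:
        raise ValueError("variant QC removed every variant")

    n_hwe = int(np.ceil(hwe_worst_frac * len(st2))) if hwe_worst_frac > 0 else 0
    if n_hwe > 0:
        # deterministic: largest chi2 first, then lexical id
        ranked = st2.assign(_id=st2.index).sort_values(
            ["hwe_chi2", "_id"], ascending=[False, True]
        )
        hwe_fail = ranked.index[:n_hwe].tolist()
    else:
        hwe_fail = []
    removed["hwe"] = hwe_fail
    kept = [v for v in variant_ids if v in set(st2.index) - set(hwe_fail)]
    if not kept:
        raise ValueError("variant QC removed every variant")
    return QCReport(
        kept_variants=kept,
        removed_variants=removed,
        variant_stats=st.reset_index(),
    )


def individual_qc(
    genotypes: np.ndarray,
    individual_ids: list[str],
    ind_missing_max: float = DEFAULT_IND_MISSING_MAX,
) -> QCReport:
    """Remove individuals whose genotype missingness exceeds the ceiling."""
    G = np.asarray(genotypes, dtype=float)
    frac = np.isnan(G).mean(axis=1)
    removed = [iid for iid, f in zip(individual_ids, frac) if f > ind_missing_max]
    kept = [iid for iid, f in zip(individual_ids, frac) if f <= ind_missing_max]
    if not kept:
        raise ValueError("individual QC removed every individual")
    return QCReport(
        kept_individuals=kept,
        removed_individuals={"missingness": removed},
    )


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(G: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete."""
    r = pd.DataFrame(G).corr().to_numpy()
    return np.nan_to_num(r) ** 2


def ld_prune(
    genotypes: np.ndarray,
    variant_ids: list[str],
    r2_max: float = DEFAULT_LD_R2_MAX,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy windowed LD pruning.

    Slides a ``window``-variant window in ``step`` increments; within each
    window, while any surviving pair has r^2 > ``r2_max``, the member with
    the lower MAF is removed (tie: the higher column index).  After the
    pass no surviving pair within any window exceeds ``r2_max``.
    """
    G = np.asarray(genotypes, dtype=float)
    m = G.shape[1]
    st = variant_stats(G, variant_ids)
    maf = st["maf"].to_numpy()
    alive = np.ones(m, dtype=bool)

    for start in range(0, max(m - 1, 1), step):
        idx = np.arange(start, min(start + window, m))
        idx = idx[alive[idx]]
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(G[:, idx])
        np.fill_diagonal(r2, 0.0)
        local_alive = np.ones(idx.size, dtype=bool)
        while True:
            sub = r2.copy()
            sub[~local_alive, :] = 0.0
            sub[:, ~local_alive] = 0.0
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] <= r2_max:
                break
            vi, vj = idx[i], idx[j]
            if maf[vi] < maf[vj]:
                drop = i
            elif maf[vj] < maf[vi]:
                drop = j
            else:
                drop = i if vi > vj else j  # tie: higher column index
            local_alive[drop] = False
        alive[idx[~local_alive]] = False
    return [variant_ids[k] for k in range(m) if alive[k]]


# ---------------------------------------------------------------------------
# PCA covariates
# ---------------------------------------------------------------------------

def pca_covariates(
    genotypes: np.ndarray,
    variant_ids: list[str],
    n_snps_subset: int | None = None,
    k: int = 10,
    seed: int | np.random.Generator = 0,
    ld_prune_first: bool = True,
    ld_r2: float = 0.2,
) -> PCResult:
    """Top-``k`` genotype principal components for stratification control.

    SNPs are optionally LD-pruned at r^2 < ``ld_r2`` and subsampled to
    ``n_snps_subset``, then standardized (centered, scaled by
    sqrt(2 p (1-p))); missing dosages contribute 0 after centering.
    Zero-variance columns are dropped with a warning.  Uses the randomized
    SVD solver, which matches a full eigendecomposition on small problems.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    G = np.asarray(genotypes, dtype=float)
    ids = list(variant_ids)
    if ld_prune_first:
        ids = ld_prune(G, list(variant_ids), r2_max=ld_r2)
        cols = [variant_ids.index(v) for v in ids]
        G = G[:, cols]
    if n_snps_subset is not None and n_snps_subset < G.shape[1]:
        pick = np.sort(rng.choice(G.shape[1], size=n_snps_subset, replace=False))
        G = G[:, pick]
        ids = [ids[i] for i in pick]

    p_hat = np.nansum(G, axis=0) / (2 * np.sum(~np.isnan(G), axis=0))
    scale = np.sqrt(2 * p_hat * (1 - p_hat))
    with np.errstate(invalid="ignore"):
        ok = (scale > 0) & (np.nanstd(G, axis=0) > 0)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} zero-variance SNP columns before PCA",
            stacklevel=2,
        )
        G, p_hat, scale = G[:, ok], p_hat[ok], scale[ok]
        ids = [v for v, keep in zip(ids, ok) if keep]
    if k > min(G.shape[0], G.shape[1]):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(G.shape)}")

    X = (G - 2 * p_hat) / scale
    X = np.nan_to_num(X)  # missing -> mean after centering

    from sklearn.decomposition import PCA

    pca = PCA(
        n_components=k, svd_solver="randomized",
        random_state=int(rng.integers(2**31 - 1)),
    )
    scores = pca.fit_transform(X)
    return PCResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        snp_subset=ids,
    )


# ---------------------------------------------------------------------------
# relatedness pruning
# ---------------------------------------------------------------------------

def prune_relatives(
    relatedness: pd.DataFrame,
    individual_ids: list[str],
    threshold_cm: float = DEFAULT_IBD_THRESHOLD_CM,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Remove individuals until no pair shares more than ``threshold_cm``.

    ``relatedness`` is a long-format table ``iid1, iid2, ibd_cm``
    (symmetric; unlisted pairs are 0).  While any pair exceeds the
    threshold, one member of an exceeding pair is removed uniformly at
    random (seeded).  Individuals in no exceeding pair are never removed.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    kept = set(individual_ids)
    pairs = relatedness[relatedness["ibd_cm"] > threshold_cm][["iid1", "iid2"]]
    active = [
        (a, b) for a, b in pairs.itertuples(index=False) if a in kept and b in kept
    ]
    while active:
        a, b = active[int(rng.integers(len(active)))]
        kept.discard(a if rng.random() < 0.5 else b)
        active = [(x, y) for x, y in active if x in kept and y in kept]
    return [iid for iid in individual_ids if iid in kept]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_variant_pipeline(
    genotypes: np.ndarray,
    variant_ids: list[str],
    individual_ids: list[str],
    maf_min: float = DEFAULT_MAF_MIN,
    var_missing_max: float = DEFAULT_VAR_MISSING_MAX,
    ind_missing_max: float = DEFAULT_IND_MISSING_MAX,
    hwe_worst_frac: float = DEFAULT_HWE_WORST_FRAC,
    ld_r2_max: float = DEFAULT_LD_R2_MAX,
    ld_window: int = 50,
    ld_step: int = 5,
) -> QCReport:
    """Full QC pass in the fixed order: variant missingness -> MAF -> HWE
    -> individual missingness -> LD pruning.  Returns a combined report.
    """
    v_rep = variant_qc(genotypes, variant_ids, maf_min, var_missing_max,
                       hwe_worst_frac)
    v_idx = [variant_ids.index(v) for v in v_rep.kept_variants]
    G1 = np.asarray(genotypes, dtype=float)[:, v_idx]

    i_rep = individual_qc(G1, individual_ids, ind_missing_max)
    i_idx = [individual_ids.index(i) for i in i_rep.kept_individuals]
    G2 = G1[i_idx, :]

    kept_after_ld = ld_prune(G2, v_rep.kept_variants, ld_r2_max, ld_window, ld_step)
    removed_ld = [v for v in v_rep.kept_variants if v not in set(kept_after_ld)]
    return QCReport(
        kept_variants=kept_after_ld,
        removed_variants={**v_rep.removed_variants, "ld_prune": removed_ld},
        kept_individuals=i_rep.kept_individuals,
        removed_individuals=i_rep.removed_individuals,
        variant_stats=v_rep.variant_stats,
    )
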