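"""Minimal LD-score regression: heritability and genetic correlation.

Under a polygenic model, the expected association chi-square of variant j
grows linearly in its LD score ell_j (the summed squared correlation with
variants inside a genetic-distance window):

    E[chi2_j] = 1 + N h2 ell_j / M

so the slope of a weighted regression of chi-square on N ell / M
estimates the SNP heritability h2, and the intercept separates
confounding (stratification, cryptic relatedness) from polygenicity.
For two traits the product z1 z2 regressed on sqrt(N1 N2) ell / M
estimates the genetic covariance; shared samples shift the intercept to
r_p N12 / sqrt(N1 N2), which can be supplied as a constraint when the
phenotypic correlation r_p and overlap N12 are known.

Standard errors come from a delete-a-block jackknife over contiguous
variant blocks.  Regression weights are 1 / max(ell, 1), a deliberate
simplification of the full heteroskedasticity weighting.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

DEFAULT_N_BLOCKS = 200
DEFAULT_WINDOW_CM = 1.0


@dataclasses.dataclass
class H2Estimate:
    h2: float
    se: float
    intercept: float
    mean_chi2: float
    ratio: float  # (intercept - 1) / (mean_chi2 - 1); confounding share


@dataclasses.dataclass
class RgEstimate:
    rg: float
    se: float
    gencov: float
    gencov_intercept: float
    constrained: bool
    h2_1: float
    h2_2: float


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------

def compute_ld_scores(
    genotypes: np.ndarray,
    panel: pd.DataFrame,
    window_cm: float = DEFAULT_WINDOW_CM,
    n_ref: int | None = None,
) -> pd.DataFrame:
    """Per-variant LD scores in symmetric cM windows.

    ``ell_j = sum_k r2_adj(j, k)`` over variants k on the same chromosome
    with ``|cM_j - cM_k| <= window_cm`` (self term included), where
    ``r2_adj = r2 - (1 - r2) / (n_ref - 2)`` is the finite-reference bias
    adjustment.  ``n_ref`` defaults to the number of rows; pass
    ``n_ref=None`` on small fixtures deliberately to include the
    adjustment, or a large value to approximate raw r^2.

    Returns a DataFrame ``variant, chrom, cm, ell``.
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if m != len(panel):
        raise ValueError("panel/genotype dimension mismatch")
    if n_ref is None:
        n_ref = n
    if n_ref <= 2:
        raise ValueError("n_ref must exceed 2")

    cm = panel["cm"].to_numpy(dtype=float)
    chrom = panel["chrom"].to_numpy()
    ell = np.zeros(m)
    Gc = G - np.nanmean(G, axis=0, keepdims=True)
    Gc = np.nan_to_num(Gc)
    norms = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))

    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = idx[np.argsort(cm[idx], kind="stable")]
        cms = cm[order]
        lo = 0
        for a, j in enumerate(order):
            while cms[a] - cms[lo] > window_cm:
                lo += 1
            hi = a
            while hi + 1 < len(order) and cms[hi + 1] - cms[a] <= window_cm:
                hi += 1
            win = order[lo:hi + 1]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Gc[:, j] @ Gc[:, win]) / (norms[j] * norms[win])
            r2 = np.nan_to_num(r) ** 2
            r2_adj = r2 - (1 - r2) / (n_ref - 2)
            ell[j] = float(r2_adj.sum())
    return pd.DataFrame(
        {"variant": panel["variant"], "chrom": chrom, "cm": cm, "ell": ell}
    )


# ---------------------------------------------------------------------------
# weighted regression core
# ---------------------------------------------------------------------------

def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray,
         intercept: float | None) -> tuple[float, float]:
    """Weighted LS of y on x.  ``intercept=None`` -> free intercept.

    Returns (slope, intercept)."""
    if intercept is None:
        X = np.column_stack([np.ones_like(x), x])
        WX = X * w[:, None]
        coef = np.linalg.solve(X.T @ WX, WX.T @ y)
        return float(coef[1]), float(coef[0])
    yc = y - intercept
    slope = float(np.sum(w * x * yc) / np.sum(w * x * x))
    return slope, float(intercept)


def _jackknife(values: np.ndarray) -> float:
    """Jackknife SE from delete-one-block estimates."""
    b = len(values)
    return float(np.sqrt((b - 1) / b * np.sum((values - values.mean()) ** 2)))


def _block_slices(m: int, n_blocks: int) -> list[np.ndarray]:
    return [np.arange(m)[s] for s in
            (slice(int(i * m / n_blocks), int((i + 1) * m / n_blocks))
             for i in range(n_blocks))
            if int(s.start) < int(s.stop)]


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

def estimate_h2(
    chi2: np.ndarray,
    ldscores: np.ndarray,
    n: float,
    m_variants: int | None = None,
    constrain_intercept: bool = False,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> H2Estimate:
    """SNP heritability from the chi-square ~ LD-score regression.

    ``chi2`` are per-variant association chi-squares (z^2), ``ldscores``
    the matching LD scores, ``n`` the GWA sample size and ``m_variants``
    the number of variants the heritability is defined over (defaults to
    ``len(chi2)``).  ``constrain_intercept`` pins the intercept at 1 (no
    confounding).  SE by delete-a-block jackknife.
    """
    chi2 = np.asarray(chi2, dtype=float)
    ell = np.asarray(ldscores, dtype=float)
    if np.ptp(ell) == 0:
        raise ValueError("LD scores have zero variance; slope unidentifiable")
    M = m_variants if m_variants is not None else len(chi2)
    x = n * ell / M
    w = 1.0 / np.maximum(ell, 1.0)
    fixed = 1.0 if constrain_intercept else None

    slope, icpt = _wls(x, chi2, w, fixed)
    mask = np.ones(len(chi2), dtype=bool)
    blocks = _block_slices(len(chi2), min(n_blocks, len(chi2)))
    deletes = []
    for blk in blocks:
        mask[:] = True
        mask[blk] = False
        s, _ = _wls(x[mask], chi2[mask], w[mask], fixed)
        deletes.append(s)
    se = _jackknife(np.asarray(deletes))
    mean_chi2 = float(chi2.mean())
    ratio = (
        (icpt - 1) / (mean_chi2 - 1) if mean_chi2 > 1 else np.nan
    )
    return H2Estimate(h2=slope, se=se, intercept=icpt,
                      mean_chi2=mean_chi2, ratio=ratio)


# ---------------------------------------------------------------------------
# genetic correlation
# ---------------------------------------------------------------------------

def estimate_rg(
    z1: np.ndarray,
    z2: np.ndarray,
    ldscores: np.ndarray,
    n1: float,
    n2: float,
    n12: float = 0.0,
    r_p: float = 0.0,
    constrain: bool = False,
    m_variants: int | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> RgEstimate:
    """Cross-trait genetic correlation from summary z-scores.

    The slope of z1 z2 on sqrt(N1 N2) ell / M estimates the genetic
    covariance.  With ``constrain=True`` the per-trait heritability
    intercepts are pinned at 1 and the covariance intercept at
    ``r_p * N12 / sqrt(N1 N2)`` (its expectation under sample overlap
    N12 with phenotypic correlation r_p); otherwise all intercepts are
    free.  ``rg = gencov / sqrt(h2_1 h2_2)``; values beyond +-1.25
    trigger a warning but are reported raw.  SE by block jackknife of the
    full ratio.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    ell = np.asarray(ldscores, dtype=float)
    M = m_variants if m_variants is not None else len(z1)
    w = 1.0 / np.maximum(ell, 1.0)
    x_co = np.sqrt(n1 * n2) * ell / M
    x1 = n1 * ell / M
    x2 = n2 * ell / M
    co_icpt = r_p * n12 / np.sqrt(n1 * n2) if constrain else None
    h_icpt = 1.0 if constrain else None

    def _rg_on(mask: np.ndarray) -> tuple[float, float, float, float]:
        gencov, gicpt = _wls(x_co[mask], (z1 * z2)[mask], w[mask], co_icpt)
        h2_1, _ = _wls(x1[mask], (z1**2)[mask], w[mask], h_icpt)
        h2_2, _ = _wls(x2[mask], (z2**2)[mask], w[mask], h_icpt)
        if h2_1 <= 0 or h2_2 <= 0:
            return np.nan, gencov, h2_1, h2_2
        return gencov / np.sqrt(h2_1 * h2_2), gencov, h2_1, h2_2

    full = np.ones(len(z1), dtype=bool)
    rg, gencov, h2_1, h2_2 = _rg_on(full)
    if h2_1 <= 0 or h2_2 <= 0:
        warnings.warn("non-positive heritability; rg undefined", stacklevel=2)
    if np.isfinite(rg) and abs(rg) > 1.25:
        warnings.warn(f"|rg| = {abs(rg):.3f} > 1.25", stacklevel=2)

    deletes = []
    mask = np.ones(len(z1), dtype=bool)
    for blk in _block_slices(len(z1), min(n_blocks, len(z1))):
        mask[:] = True
        mask[blk] = False
        deletes.append(_rg_on(mask)[0])
    deletes = np.asarray(deletes)
    se = _jackknife(deletes[np.isfinite(deletes)]) if np.isfinite(
        deletes).any() else np.nan

    used_icpt = co_icpt if constrain else _wls(x_co, z1 * z2, w, None)[1]
    return RgEstimate(
        rg=rg, se=se, gencov=gencov, gencov_intercept=float(used_icpt),
        constrained=constrain, h2_1=h2_1, h2_2=h2_2,
    )


# ---------------------------------------------------------------------------
# summary-statistic generator (the LDSC model's own data-generating process)
# ---------------------------------------------------------------------------

def simulate_sumstats(
    ldscores: np.ndarray,
    n1: float,
    h2_1: float,
    n2: float | None = None,
    h2_2: float | None = None,
    rg: float = 0.0,
    n12: float = 0.0,
    r_p: float = 0.0,
    m_variants: int | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw z-scores from the polygenic summary-statistic model.

    Marginal variance of z_i is ``1 + N_i h2_i ell / M``; for a trait
    pair the covariance is ``sqrt(N1 N2) rg sqrt(h2_1 h2_2) ell / M +
    r_p N12 / sqrt(N1 N2)``.  This is the generative counterpart of
    :func:`estimate_h2` / :func:`estimate_rg` and serves parameter-
    recovery tests; it does not model linked causal effects beyond what
    the LD scores encode.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ell = np.asarray(ldscores, dtype=float)
    M = m_variants if m_variants is not None else len(ell)
    v1 = 1 + n1 * h2_1 * ell / M
    if n2 is None:
        z1 = rng.normal(0.0, np.sqrt(v1))
        return pd.DataFrame({"ell": ell, "z1": z1})
    assert h2_2 is not None
    v2 = 1 + n2 * h2_2 * ell / M
    cov = (np.sqrt(n1 * n2) * rg * np.sqrt(h2_1 * h2_2) * ell / M
           + r_p * n12 / np.sqrt(n1 * n2))
    rho = np.clip(cov / np.sqrt(v1 * v2), -0.999, 0.999)
    e1 = rng.normal(size=len(ell))
    e2 = rng.normal(size=len(ell))
    z1 = np.sqrt(v1) * e1
    z2 = np.sqrt(v2) * (rho * e1 + np.sqrt(1 - rho**2) * e2)
    return pd.DataFrame({"ell": ell, "z1": z1, "z2": z2})
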