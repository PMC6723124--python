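"""Single-variant association mapping with genomic control.

Quantitative traits (parental lifespan in years, or age) are analyzed by
per-variant ordinary least squares of phenotype on allele dosage plus
covariates; the age-tail design is a logistic case/control comparison of
the oldest tail against below-median controls.  Because the design
regresses a *parent's* phenotype on the *offspring's* dosage, estimated
effects sit on the offspring-dose scale and are doubled (variance shares
quadrupled) by :func:`rescale_parental` to express them per parental
allele.

P values use the large-sample normal approximation of beta/SE throughout;
at the sample sizes this design needs (10^5), the difference from the t
distribution is far below rounding.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = 0.455936

#: birth-cohort slices used for cohort-specific effect analyses
DEFAULT_COHORT_SLICES: tuple[tuple[int, int], ...] = (
    (1886, 1894), (1894, 1902), (1902, 1908), (1908, 1912), (1912, 1916),
    (1916, 1920), (1920, 1924), (1924, 1928), (1928, 1932), (1932, 1936),
    (1935, 1940),
)

#: documented defaults of the age-tail case/control framework: the case
#: threshold is the upper 5% tail (86 yr for men, 87 for women) and the
#: control threshold the median age (65 yr men, 64 women)
AGE_CC_DEFAULTS = {
    "case_tail": 0.05,
    "case_age": {"M": 86, "F": 87},
    "control_age": {"M": 65, "F": 64},
}


@dataclasses.dataclass
class GCCalibration:
    """Genomic-control inflation factor lambda = median(chi2) / 0.455936."""

    lam: float
    method: str = "median chi2 / chi2_1 median; correction floored at 1"

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lambda must be positive")


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    return np.column_stack([np.ones(n), C])


def _assoc_columns(G: np.ndarray, y: np.ndarray, Q: np.ndarray,
                   dof: int) -> tuple[np.ndarray, ...]:
    """Frisch-Waugh OLS for many complete dosage columns at once."""
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    den = np.einsum("ij,ij->j", G_r, G_r)
    ok = den > 1e-12
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    num = G_r.T @ y_r
    beta[ok] = num[ok] / den[ok]
    rss = float(y_r @ y_r) - beta[ok] * num[ok]
    sigma2 = rss / dof
    se[ok] = np.sqrt(np.maximum(sigma2, 0.0) / den[ok])
    return beta, se, ok


def assoc_quant(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of a quantitative phenotype on allele dosage.

    Rows with missing phenotype are dropped globally; genotype missingness
    is handled per variant by complete-case analysis (no dosage
    imputation).  Zero-variance dosages and collinear fits are skipped
    with ``skipped=True``.

    Returns an association table with columns ``variant, n, maf,
    missingness, beta, se, z, p_uc, skipped`` and ``attrs['scale'] =
    'offspring'`` (see :func:`rescale_parental`).
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n_all, m = G.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    keep = ~np.isnan(y)
    if covariates is not None:
        C_full = _design(covariates, n_all)[:, 1:]
        keep &= ~np.isnan(C_full).any(axis=1)
    G, y = G[keep], y[keep]
    n = len(y)
    if n < 3:
        raise ValueError("fewer than 3 phenotyped individuals")
    X = _design(covariates[keep] if covariates is not None else None, n)
    Q, _ = np.linalg.qr(X)
    dof = n - X.shape[1] - 1
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")

    col_nan = np.isnan(G).any(axis=0)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    n_used = np.full(m, n)

    complete = ~col_nan
    if complete.any():
        b, s, ok = _assoc_columns(G[:, complete], y, Q, dof)
        beta[complete], se[complete] = b, s
    for j in np.flatnonzero(col_nan):  # per-variant complete cases
        rows = ~np.isnan(G[:, j])
        nj = int(rows.sum())
        n_used[j] = nj
        if nj < X.shape[1] + 2:
            continue
        Xj = X[rows]
        Qj, _ = np.linalg.qr(Xj)
        bj, sj, okj = _assoc_columns(
            G[rows, j][:, None], y[rows], Qj, nj - Xj.shape[1] - 1
        )
        beta[j], se[j] = bj[0], sj[0]

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    p_hat = np.nansum(G, axis=0) / (2 * np.sum(~np.isnan(G), axis=0))
    out = pd.DataFrame(
        {
            "variant": variant_ids,
            "n": n_used,
            "maf": np.minimum(p_hat, 1 - p_hat),
            "missingness": np.isnan(G).mean(axis=0),
            "beta": beta,
            "se": se,
            "z": z,
            "p_uc": np.clip(p, np.nextafter(0, 1), 1.0),
            "skipped": ~np.isfinite(beta),
        }
    )
    out.attrs["scale"] = "offspring"
    return out


def assoc_case_control(
    genotypes: np.ndarray,
    ages: np.ndarray,
    case_tail: float = 0.05,
    covariates: np.ndarray | None = None,
    variant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Age-tail case/control GWA by per-variant logistic regression.

    Cases are individuals above the ``1 - case_tail`` age quantile;
    controls are at or below the median age; the gap between the two
    thresholds is excluded.  Perfect separation or non-convergence flags
    the variant as skipped rather than raising.
    """
    import statsmodels.api as sm

    G = np.asarray(genotypes, dtype=float)
    age = np.asarray(ages, dtype=float)
    m = G.shape[1]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    if age.size == 0 or np.isnan(age).all():
        raise ValueError("empty case or control set")
    case_thr = np.nanquantile(age, 1 - case_tail)
    ctrl_thr = np.nanmedian(age)
    is_case = age >= case_thr
    is_ctrl = age <= ctrl_thr
    use = is_case | is_ctrl
    if not is_case.any() or not is_ctrl.any():
        raise ValueError("empty case or control set")
    y = is_case[use].astype(float)
    Gs = G[use]
    C = _design(covariates[use] if covariates is not None else None, int(use.sum()))

    rows = []
    for j in range(m):
        g = Gs[:, j]
        ok = ~np.isnan(g)
        gj, yj, Cj = g[ok], y[ok], C[ok]
        p_hat = gj.mean() / 2 if len(gj) else np.nan
        rec = {
            "variant": variant_ids[j],
            "n": int(ok.sum()),
            "maf": min(p_hat, 1 - p_hat),
            "missingness": float((~ok).mean()),
            "beta": np.nan, "se": np.nan, "z": np.nan, "p_uc": np.nan,
            "skipped": True,
        }
        if np.nanstd(gj) > 0:
            try:
                with np.errstate(all="ignore"):
                    fit = sm.Logit(yj, np.column_stack([Cj, gj])).fit(
                        disp=0, maxiter=100
                    )
                b, s = fit.params[-1], fit.bse[-1]
                if np.isfinite(b) and np.isfinite(s) and s > 0 and s < 100:
                    zj = b / s
                    rec.update(
                        beta=b, se=s, z=zj,
                        p_uc=float(2 * stats.norm.sf(abs(zj))), skipped=False,
                    )
            except Exception:
                pass  # separation / singular fit stays flagged
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["scale"] = "offspring"
    out.attrs["case_threshold"] = float(case_thr)
    out.attrs["control_threshold"] = float(ctrl_thr)
    return out


# ---------------------------------------------------------------------------
# genomic control and thresholds
# ---------------------------------------------------------------------------

def genomic_control(assoc: pd.DataFrame) -> tuple[GCCalibration, pd.DataFrame]:
    """Estimate lambda and add genomic-control-corrected P values.

    lambda = median(z^2) / 0.455936.  Correction divides each chi-square
    by max(lambda, 1) — deflation is never applied — and converts back to
    a two-sided P via the chi-square(1 df) survival function.
    """
    ok = assoc["z"].notna()
    if not ok.any():
        raise ValueError("association table has no usable z scores")
    chi2 = assoc.loc[ok, "z"].to_numpy() ** 2
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    corrected = assoc.copy()
    corrected["p_gc"] = np.nan
    corrected.loc[ok, "p_gc"] = stats.chi2.sf(chi2 / max(lam, 1.0), df=1)
    corrected.attrs.update(assoc.attrs)
    corrected.attrs["lambda_gc"] = lam
    return GCCalibration(lam=lam), corrected


def significance_threshold(alpha: float, m: int) -> float:
    """Bonferroni family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def rescale_parental(assoc: pd.DataFrame) -> pd.DataFrame:
    """Rescale offspring-dose estimates to the parental allelic dose.

    The genotyped offspring carries half the phenotyped parent's expected
    allelic dose, so beta and SE are doubled (z and P unchanged) and any
    per-SNP variance-explained or heritability column is quadrupled.
    Applying twice is an error: the table carries a scale flag.
    """
    if assoc.attrs.get("scale") == "parental":
        raise ValueError("association table already on the parental scale")
    out = assoc.copy()
    out["beta"] = out["beta"] * 2
    out["se"] = out["se"] * 2
    for col in ("h2_snp", "var_explained"):
        if col in out.columns:
            out[col] = out[col] * 4
    out.attrs.update(assoc.attrs)
    out.attrs["scale"] = "parental"
    return out


def per_snp_variance_explained(assoc: pd.DataFrame,
                               phenotypic_variance: float) -> pd.DataFrame:
    """Add the per-SNP variance share beta^2 * 2 p (1-p) / P_var (fraction)."""
    out = assoc.copy()
    pq2 = 2 * out["maf"] * (1 - out["maf"])
    out["h2_snp"] = out["beta"] ** 2 * pq2 / phenotypic_variance
    out.attrs.update(assoc.attrs)
    return out


# ---------------------------------------------------------------------------
# cohort-sliced analyses
# ---------------------------------------------------------------------------

def cohort_slice_effects(
    genotypes: np.ndarray,
    cohort: pd.DataFrame,
    variant: int | str,
    slices: tuple[tuple[int, int], ...] = DEFAULT_COHORT_SLICES,
    covariates: np.ndarray | None = None,
    variant_ids: list[str] | None = None,
    phenotype_col: str = "lifespan",
    birth_col: str = "birth_year",
) -> pd.DataFrame:
    """Per-birth-cohort effect of one variant: (slice, beta, se, n).

    Runs :func:`assoc_quant` on the rows whose parent birth year falls in
    each inclusive ``[start, end]`` slice.  Slices with fewer than two
    informative individuals are flagged empty (NaN effect).
    """
    G = np.asarray(genotypes, dtype=float)
    j = variant if isinstance(variant, int) else variant_ids.index(variant)
    birth = cohort[birth_col].to_numpy()
    y_all = cohort[phenotype_col].to_numpy(dtype=float)
    rows = []
    for start, end in slices:
        sel = (birth >= start) & (birth <= end) & ~np.isnan(y_all)
        g = G[sel, j:j + 1]
        informative = np.sum(~np.isnan(g[:, 0]))
        if informative < 2 or np.nanstd(g[:, 0]) == 0:
            rows.append({"slice_start": start, "slice_end": end,
                         "beta": np.nan, "se": np.nan, "n": int(informative),
                         "empty": True})
            continue
        tab = assoc_quant(
            g, y_all[sel],
            covariates[sel] if covariates is not None else None,
        )
        rows.append({
            "slice_start": start, "slice_end": end,
            "beta": float(tab["beta"][0]), "se": float(tab["se"][0]),
            "n": int(tab["n"][0]), "empty": bool(tab["skipped"][0]),
        })
    return pd.DataFrame(rows)


def af_by_lifespan_grid(
    genotypes: np.ndarray,
    cohort: pd.DataFrame,
    variant: int | str,
    lifespan_bins: np.ndarray,
    cohort_slices: tuple[tuple[int, int], ...] = DEFAULT_COHORT_SLICES,
    min_n: int = 500,
    variant_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minor-allele frequency in (birth-cohort x lifespan-bin) cells.

    ``lifespan_bins`` are bin edges over the lifespan window.  Cells with
    fewer than ``min_n`` informative individuals are masked (NaN).
    Returns ``(maf_grid, n_grid)`` with cohort slices as rows.
    """
    G = np.asarray(genotypes, dtype=float)
    j = variant if isinstance(variant, int) else variant_ids.index(variant)
    dose = G[:, j]
    birth = cohort["birth_year"].to_numpy()
    life = cohort["lifespan"].to_numpy(dtype=float)

    # grid-wide minor-allele orientation, fixed across cells
    p_all = np.nanmean(dose) / 2
    minor_dose = dose if p_all <= 0.5 else 2 - dose

    edges = np.asarray(lifespan_bins, dtype=float)
    labels = [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(len(edges) - 1)]
    maf = np.full((len(cohort_slices), len(labels)), np.nan)
    counts = np.zeros_like(maf, dtype=int)
    for r, (start, end) in enumerate(cohort_slices):
        in_slice = (birth >= start) & (birth <= end)
        for c in range(len(labels)):
            in_bin = (life >= edges[c]) & (life < edges[c + 1])
            sel = in_slice & in_bin & ~np.isnan(dose)
            counts[r, c] = int(sel.sum())
            if counts[r, c] >= min_n:
                maf[r, c] = np.nanmean(minor_dose[sel]) / 2
    index = [f"{s}-{e}" for s, e in cohort_slices]
    return (
        pd.DataFrame(maf, index=index, columns=labels),
        pd.DataFrame(counts, index=index, columns=labels),
    )
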