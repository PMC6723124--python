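"""Design-stage computations for a parent-offspring lifespan GWA.

* Transmission power simulation: how often a single additive allele of a
  given frequency and parental effect reaches genome-wide significance
  when the parent's phenotype is regressed on the offspring's dosage.
* Effect dilution: the offspring-dose slope recovers half of the
  generating parental effect (parent-offspring genotype correlation 1/2).
* Censorship estimation: the fraction of a birth cohort presumed alive at
  the snapshot, inferred by inflating the observed complete lifespans by
  the tail mass of a fully observed baseline cohort's lifespan
  distribution beyond each year's observable maximum.
* The privacy identifiability ratio m/n (reported SNPs over cohort size),
  with re-identification power scaling as sqrt(m/n).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 5.0e-8


# ---------------------------------------------------------------------------
# single-SNP transmission replicates
# ---------------------------------------------------------------------------

def _simulate_transmission(
    p: float, beta_parental: float, n: int, total_variance: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One replicate: (parent dosage, offspring dosage, parent phenotype)."""
    g_par = rng.binomial(2, p, size=n)
    sigma_g2 = beta_parental**2 * 2 * p * (1 - p)
    if sigma_g2 >= total_variance:
        raise ValueError("genetic variance exceeds total phenotypic variance")
    eps = rng.normal(0.0, np.sqrt(total_variance - sigma_g2), size=n)
    y = beta_parental * g_par + eps
    transmitted = (g_par == 2).astype(np.int8)
    het = g_par == 1
    transmitted[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    g_off = transmitted + (rng.random(n) < p).astype(np.int8)
    return g_par, g_off, y


def _fast_slope(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple-regression slope and two-sided normal-approximation P."""
    g = g.astype(float)
    gc = g - g.mean()
    den = float(gc @ gc)
    if den <= 0:
        return np.nan, 1.0
    beta = float(gc @ y) / den
    resid = y - y.mean() - beta * gc
    sigma2 = float(resid @ resid) / (len(y) - 2)
    se = np.sqrt(sigma2 / den)
    z = beta / se
    return beta, float(2 * stats.norm.sf(abs(z)))


def power_replicate(
    p: float,
    beta_parental: float,
    n: int,
    total_variance: float = 166.2,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, bool, float]:
    """One full transmission replicate and its single-SNP regression.

    Returns ``(beta_offspring, p_value, significant, beta_parent)`` where
    ``beta_parent`` is the slope from regressing the same phenotypes on
    the parents' own dosages (the undiluted estimate).
    """
    if not 0 < p < 1:
        raise ValueError("allele frequency must be in (0, 1)")
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    g_par, g_off, y = _simulate_transmission(p, beta_parental, n, total_variance, rng)
    b_off, pval = _fast_slope(g_off, y)
    b_par, _ = _fast_slope(g_par, y)
    return b_off, pval, bool(pval < alpha), b_par


def power_grid(
    ps: Sequence[float],
    betas: Sequence[float],
    ns: Sequence[int],
    replicates: int = 50,
    alpha: float = DEFAULT_ALPHA,
    total_variance: float = 166.2,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Monte-Carlo power over a (frequency x effect x cohort size) grid.

    Power per cell is the fraction of ``replicates`` independent
    transmission simulations whose offspring-dose regression reaches
    ``alpha``.  Each replicate draws fresh parents and mates.  The table
    also records the mean offspring- and parental-dose slope estimates
    and the analytic power approximation (see :func:`analytic_power`).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    for p in ps:
        for beta in betas:
            for n in ns:
                hits = 0
                b_off_sum = 0.0
                b_par_sum = 0.0
                for _ in range(replicates):
                    b_off, pval, sig, b_par = power_replicate(
                        p, beta, n, total_variance, alpha, rng
                    )
                    hits += sig
                    b_off_sum += b_off
                    b_par_sum += b_par
                rows.append({
                    "p": p, "beta_parental": beta, "n": n,
                    "replicates": replicates, "alpha": alpha,
                    "power": hits / replicates,
                    "mean_beta_offspring": b_off_sum / replicates,
                    "mean_beta_parental": b_par_sum / replicates,
                    "power_analytic": analytic_power(
                        p, beta, n, total_variance, alpha
                    ),
                })
    return pd.DataFrame(rows)


def analytic_power(
    p: float, beta_parental: float, n: int,
    total_variance: float = 166.2, alpha: float = DEFAULT_ALPHA,
) -> float:
    """Closed-form power approximation for the diluted single-SNP test.

    The offspring-dose slope is beta/2 with dosage variance 2pq, giving a
    non-centrality parameter NCP = N (beta/2)^2 2pq / sigma^2 for the
    1-df association chi-square; power is Phi(sqrt(NCP) - z_{alpha/2}).
    """
    b = beta_parental / 2.0
    var_g = 2 * p * (1 - p)
    resid = total_variance - b**2 * var_g
    ncp = n * b**2 * var_g / resid
    return float(stats.norm.cdf(np.sqrt(ncp) - stats.norm.isf(alpha / 2)))


def dilution_ratio(grid: pd.DataFrame) -> float:
    """Mean over grid cells of (mean offspring slope / parental effect).

    Cells with a zero generating effect are excluded with a warning; the
    closed form predicts 0.5 independent of allele frequency.
    """
    import warnings

    usable = grid["beta_parental"] != 0
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} zero-effect cells from the "
            "dilution ratio", stacklevel=2,
        )
    if not usable.any():
        raise ValueError("no non-null cells in grid")
    ratios = grid.loc[usable, "mean_beta_offspring"] / grid.loc[
        usable, "beta_parental"]
    return float(ratios.mean())


# ---------------------------------------------------------------------------
# permutation calibration of the inflation factor
# ---------------------------------------------------------------------------

def permutation_lambda(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    n_permutations: int = 20,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Genomic-control lambda under repeated phenotype permutation.

    Permuting the phenotype against the genotypes destroys every true
    association while preserving the (possibly non-normal) phenotype
    distribution, so the lambda distribution should center at 1.  Uses
    the closed-form simple-regression chi-square per variant (equivalent
    to the association engine without covariates) with the genotype
    matrix centered once and reused across permutations.
    """
    from .gwas import CHI2_1_MEDIAN

    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    G = np.asarray(genotypes, dtype=np.float32)
    y0 = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(y0)
    G, y0 = G[keep], y0[keep]
    n = len(y0)
    Gc = G - G.mean(axis=0, keepdims=True)
    den = np.einsum("ij,ij->j", Gc, Gc)
    ok = den > 0

    lams = []
    for k in range(n_permutations):
        y = rng.permutation(y0)
        yc = (y - y.mean()).astype(np.float32)
        num = Gc.T @ yc
        syy = float(yc @ yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = num[ok] ** 2 / (den[ok] * syy)
        chi2 = (n - 2) * r2 / (1 - r2)
        lams.append({"permutation": k,
                     "lam": float(np.median(chi2) / CHI2_1_MEDIAN)})
    return pd.DataFrame(lams)


# ---------------------------------------------------------------------------
# censorship estimation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CensorshipEstimate:
    """Per-birth-year assumed-censorship fractions and their aggregate.

    ``per_year`` has columns ``birth_year, n_complete, observable_max,
    baseline_cdf, est_alive, fraction``; ``cumulative`` is the
    complete-count-weighted aggregate over the target range.
    """

    per_year: pd.DataFrame
    cumulative: float
    baseline_years: tuple[int, int]
    target_years: tuple[int, int]


def estimate_censorship(
    lifespans_by_birth_year: Mapping[int, np.ndarray] | pd.DataFrame,
    baseline_years: tuple[int, int] = (1886, 1910),
    target_years: tuple[int, int] = (1911, 1940),
    snapshot_year: int = 2016,
    lifespan_window: tuple[float, float] = (40.0, 120.0),
) -> CensorshipEstimate:
    """Estimate the alive (assumed right-censored) fraction per birth year.

    The baseline cohorts are old enough that essentially all lifespans in
    the window are complete at the snapshot; their pooled empirical CDF F
    serves as the reference lifespan distribution.  A target birth year y
    can only exhibit lifespans up to ``c_y = snapshot_year - y``; the
    complete count ``n_complete(y)`` therefore represents only the F(c_y)
    quantile of the cohort, and the individuals still alive are estimated
    as ``n_complete * (1 - F(c_y)) / F(c_y)``.  The annual fraction is
    ``alive / (alive + n_complete)``; years with ``c_y`` beyond the
    window maximum have fraction 0, and years where F(c_y) = 0 are
    flagged undefined (NaN).

    ``lifespans_by_birth_year`` maps birth year to an array of *observed
    complete* lifespans, or is a DataFrame with ``birth_year`` and
    ``lifespan`` columns (missing lifespans ignored).
    """
    if isinstance(lifespans_by_birth_year, pd.DataFrame):
        df = lifespans_by_birth_year[["birth_year", "lifespan"]].dropna()
        data = {int(y): g["lifespan"].to_numpy()
                for y, g in df.groupby("birth_year")}
    else:
        data = {int(y): np.asarray(v, dtype=float)
                for y, v in lifespans_by_birth_year.items()}

    lo, hi = lifespan_window
    pooled = np.concatenate([
        data[y][(data[y] >= lo) & (data[y] <= hi)]
        for y in data if baseline_years[0] <= y <= baseline_years[1]
    ] or [np.array([])])
    if pooled.size == 0:
        raise ValueError("baseline cohorts contain no complete lifespans")
    pooled.sort()

    def F(x: float) -> float:
        return float(np.searchsorted(pooled, x, side="right")) / pooled.size

    rows = []
    for y in range(target_years[0], target_years[1] + 1):
        c_y = snapshot_year - y
        ls = data.get(y, np.array([]))
        n_complete = int(((ls >= lo) & (ls <= hi)).sum())
        if c_y >= hi:
            rows.append((y, n_complete, c_y, 1.0, 0.0, 0.0))
            continue
        Fc = F(c_y)
        if Fc == 0.0:
            rows.append((y, n_complete, c_y, 0.0, np.nan, np.nan))
            continue
        alive = n_complete * (1 - Fc) / Fc
        frac = alive / (alive + n_complete) if (alive + n_complete) > 0 else np.nan
        rows.append((y, n_complete, c_y, Fc, alive, frac))
    per_year = pd.DataFrame(
        rows, columns=["birth_year", "n_complete", "observable_max",
                       "baseline_cdf", "est_alive", "fraction"],
    )
    tot_alive = per_year["est_alive"].sum(skipna=True)
    tot_complete = per_year["n_complete"].sum()
    cumulative = (
        float(tot_alive / (tot_alive + tot_complete))
        if tot_alive + tot_complete > 0 else np.nan
    )
    return CensorshipEstimate(
        per_year=per_year, cumulative=cumulative,
        baseline_years=baseline_years, target_years=target_years,
    )


# ---------------------------------------------------------------------------
# privacy
# ---------------------------------------------------------------------------

def privacy_ratio(m: int, n: int) -> tuple[float, float]:
    """Identifiability ratio of reported SNPs to cohort size.

    Returns ``(m/n, sqrt(m/n))``; re-identification power from released
    summary statistics scales with the square root of the ratio.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ratio = m / n
    return ratio, float(np.sqrt(ratio))
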