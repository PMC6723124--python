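"""Two-study summary-statistic harmonization and Stouffer meta-analysis.

Combines per-variant z-scores from two GWA studies with weights
proportional to sqrt(N) (the sample-size scheme of METAL), after aligning
effect alleles between studies, dropping allele mismatches and
low-frequency variants, and deflating each study's z by the square root
of its genomic-inflation factor.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

SUMSTAT_COLUMNS = ["variant", "chr", "pos", "ea", "oa", "z", "n", "eaf"]
VALID_ALLELES = {"A", "C", "G", "T"}
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
DEFAULT_META_ALPHA = 5.0e-8


def read_sumstats(path: str | Path, beta_se: bool = False) -> pd.DataFrame:
    """Read a summary-statistic TSV.

    Expected columns ``variant chr pos ea oa z n eaf``; with
    ``beta_se=True`` the table instead carries ``beta`` and ``se``
    columns, converted on read to ``z = beta / se``.
    """
    df = pd.read_csv(path, sep="\t")
    if beta_se:
        df = df.assign(z=df["beta"] / df["se"]).drop(columns=["beta", "se"])
    missing = set(SUMSTAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
    return validate_sumstats(df)


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    if df["variant"].duplicated().any():
        dups = df.loc[df["variant"].duplicated(), "variant"].head().tolist()
        raise ValueError(f"duplicate variant ids within a study: {dups}")
    bad = ~(df["ea"].isin(VALID_ALLELES) & df["oa"].isin(VALID_ALLELES))
    if bad.any():
        raise ValueError("alleles must be single bases A/C/G/T")
    if (df["n"] <= 0).any():
        raise ValueError("sample sizes must be positive")
    if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
        raise ValueError("effect-allele frequencies must lie in (0, 1)")
    return df


def harmonize_studies(
    a: pd.DataFrame,
    b: pd.DataFrame,
    maf_min: float = 0.005,
) -> pd.DataFrame:
    """Intersect two studies on variant id and align effect alleles.

    * Same effect/other alleles: retained as-is.
    * Swapped alleles: study b's z sign is flipped (and its frequency
      complemented).
    * Any other allele combination: dropped as a mismatch.
    * Strand-ambiguous variants (A/T, C/G) are dropped when the
      frequency comparison cannot resolve orientation (the frequencies
      are closer after complementing than before).
    * Variants with minor-allele frequency below ``maf_min`` in either
      study are dropped (inclusive threshold: MAF == maf_min survives).

    Returns the paired table with columns ``variant, z_a, n_a, z_b, n_b,
    eaf_a, eaf_b`` plus position columns from study a.
    """
    validate_sumstats(a)
    validate_sumstats(b)
    merged = a.merge(b, on="variant", suffixes=("_a", "_b"))

    same = (merged["ea_a"] == merged["ea_b"]) & (merged["oa_a"] == merged["oa_b"])
    swapped = (merged["ea_a"] == merged["oa_b"]) & (merged["oa_a"] == merged["ea_b"])
    merged = merged[same | swapped].copy()
    flip = (merged["ea_a"] == merged["oa_b"]) & (merged["oa_a"] == merged["ea_b"])
    merged.loc[flip, "z_b"] = -merged.loc[flip, "z_b"]
    merged.loc[flip, "eaf_b"] = 1 - merged.loc[flip, "eaf_b"]

    ambiguous = [
        (ea, oa) in AMBIGUOUS_PAIRS
        for ea, oa in zip(merged["ea_a"], merged["oa_a"])
    ]
    ambiguous = np.asarray(ambiguous)
    freq_inconclusive = np.abs(
        merged["eaf_a"] - (1 - merged["eaf_b"])
    ) < np.abs(merged["eaf_a"] - merged["eaf_b"])
    merged = merged[~(ambiguous & freq_inconclusive.to_numpy())]

    maf_a = np.minimum(merged["eaf_a"], 1 - merged["eaf_a"])
    maf_b = np.minimum(merged["eaf_b"], 1 - merged["eaf_b"])
    merged = merged[(maf_a >= maf_min) & (maf_b >= maf_min)]

    keep = ["variant", "chr_a", "pos_a", "ea_a", "oa_a",
            "z_a", "n_a", "eaf_a", "z_b", "n_b", "eaf_b"]
    return merged[keep].rename(
        columns={"chr_a": "chr", "pos_a": "pos", "ea_a": "ea", "oa_a": "oa"}
    ).reset_index(drop=True)


def stouffer_meta(
    paired: pd.DataFrame,
    lambda_a: float = 1.0,
    lambda_b: float = 1.0,
    alpha: float = DEFAULT_META_ALPHA,
) -> pd.DataFrame:
    """Sample-size-weighted z-score meta-analysis of a harmonized pair.

    Each study's z is first deflated by sqrt(max(lambda, 1)) (per-study
    genomic control; deflation below 1 is not applied), then combined as

        z_meta = (w_a z_a + w_b z_b) / sqrt(w_a^2 + w_b^2),  w = sqrt(N).

    Two-sided P from the normal distribution; ``significant`` marks
    P < ``alpha``.
    """
    if (paired["n_a"] <= 0).any() or (paired["n_b"] <= 0).any():
        raise ValueError("sample sizes must be positive")
    za = paired["z_a"] / np.sqrt(max(lambda_a, 1.0))
    zb = paired["z_b"] / np.sqrt(max(lambda_b, 1.0))
    wa = np.sqrt(paired["n_a"].to_numpy(dtype=float))
    wb = np.sqrt(paired["n_b"].to_numpy(dtype=float))
    z_meta = (wa * za + wb * zb) / np.sqrt(wa**2 + wb**2)
    p = 2 * stats.norm.sf(np.abs(z_meta))

    def _dir(z: pd.Series) -> np.ndarray:
        return np.where(z > 0, "+", np.where(z < 0, "-", "0"))

    out = paired.copy()
    out["z_meta"] = z_meta
    out["p"] = p
    out["direction"] = np.char.add(_dir(za).astype(str), _dir(zb).astype(str))
    out["significant"] = p < alpha
    return out
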