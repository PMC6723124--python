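"""Synthetic parent-offspring cohorts with a genealogy-snapshot observation model.

The generator mimics the statistical structure a proxy-phenotype lifespan
GWA assumes: a large random-mating population at Hardy-Weinberg
equilibrium, additive lifespan loci measured in years per allele acting on
the *parental* phenotype, perfect Mendelian segregation to a genotyped
offspring, and an observation process in which death years may be missing
either because the parent was alive at the snapshot (true right-censorship)
or because the death was simply never recorded.

Key scales and defaults
-----------------------
* Lifespans are years; analyses consider the window [40, 120].
* Total phenotypic variance defaults to 166.2 yr^2, with environmental
  variance chosen as the remainder after the configured genetic variance.
* Median lifespan defaults: paternal 76, maternal 82.
* Birth cohorts 1886-1940 observed at a 2016 snapshot; roughly 1/3 of
  pre-snapshot deaths lack a death record.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TRAITS = ("paternal_lifespan", "maternal_lifespan", "age")

#: total autosomal genetic map length (cM) used for pedigree IBD scores
AUTOSOMAL_MAP_CM = 3545.0

#: expected IBD sharing (cM) between first-degree relatives on that map
FIRST_DEGREE_IBD_CM = AUTOSOMAL_MAP_CM / 2.0


@dataclasses.dataclass(frozen=True)
class CausalEffect:
    """An additive locus: ``beta`` years per allele on the parental scale."""

    variant: int
    trait: str
    beta: float

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}; expected one of {TRAITS}")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort and its observation model.

    ``maf_spectrum`` is ``(family, low, high)`` with family ``"uniform"``
    or ``"loguniform"``; draws are clamped to [0.001, 0.5].
    ``causal_effects`` carry parental-scale effects (years per allele); the
    offspring-dosage regression slope is therefore expected to be beta/2.
    """

    n_offspring: int = 10_000
    n_variants: int = 100
    maf_spectrum: tuple[str, float, float] = ("uniform", 0.01, 0.5)
    causal_effects: tuple[CausalEffect, ...] = ()
    total_phenotypic_variance: float = 166.2
    birth_year_range: tuple[int, int] = (1886, 1940)
    snapshot_year: int = 2016
    lifespan_window: tuple[float, float] = (40.0, 120.0)
    median_lifespan: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"paternal": 76.0, "maternal": 82.0}
    )
    missing_death_base_rate: float = 1.0 / 3.0
    genotype_missing_rate: float = 0.0
    n_subpops: int = 1
    fst: float = 0.0
    chip_split: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring < 1 or self.n_variants < 1:
            raise ValueError("n_offspring and n_variants must be positive")
        for name in ("missing_death_base_rate", "genotype_missing_rate", "chip_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.total_phenotypic_variance <= 0:
            raise ValueError("total_phenotypic_variance must be > 0")
        if not self.lifespan_window[0] < self.lifespan_window[1]:
            raise ValueError("lifespan_window must be ordered")
        if not self.birth_year_range[0] <= self.birth_year_range[1]:
            raise ValueError("birth_year_range must be ordered")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        fam = self.maf_spectrum[0]
        if fam not in ("uniform", "loguniform"):
            raise ValueError(f"unknown maf_spectrum family {fam!r}")
        for eff in self.causal_effects:
            if not 0 <= eff.variant < self.n_variants:
                raise ValueError(
                    f"causal variant index {eff.variant} out of range "
                    f"[0, {self.n_variants})"
                )

    def effects_for(self, trait: str) -> np.ndarray:
        """Dense parental-scale effect vector (years/allele) for ``trait``."""
        beta = np.zeros(self.n_variants)
        for eff in self.causal_effects:
            if eff.trait == trait:
                beta[eff.variant] += eff.beta
        return beta


def _rng(config: SimConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return np.random.default_rng(config.seed) if rng is None else rng


# ---------------------------------------------------------------------------
# variant panel
# ---------------------------------------------------------------------------

def simulate_variant_panel(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a variant panel: positions, alleles, frequencies, true effects.

    Returns a DataFrame with columns ``variant, chrom, pos, cm, ref, alt,
    p`` and one ``beta_<trait>`` column per trait (zeros except at
    configured causal loci).  Frequencies are drawn from the configured
    spectrum and clamped to [0.001, 0.5]; positions are strictly increasing
    within each chromosome, with genetic position at 1 cM/Mb.
    """
    rng = _rng(config, rng)
    m = config.n_variants
    fam, lo, hi = config.maf_spectrum
    if fam == "uniform":
        p = rng.uniform(lo, hi, size=m)
    else:  # loguniform
        p = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))
    p = np.clip(p, 0.001, 0.5)

    n_chrom = min(22, m)
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=m))
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        gaps = rng.integers(5_000, 200_000, size=idx.size)
        pos[idx] = 10_000 + np.cumsum(gaps)

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4

    panel = pd.DataFrame(
        {
            "variant": [f"snp{i:06d}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "cm": pos / 1e6,
            "ref": bases[ref_i],
            "alt": bases[alt_i],
            "p": p,
        }
    )
    for trait in TRAITS:
        panel[f"beta_{trait}"] = config.effects_for(trait)
    return panel


def subpop_frequencies(
    panel: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-subpopulation allele frequencies, shape (n_subpops, m).

    Discrete structure follows the Balding-Nichols model: subpopulation
    frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral
    frequency p with differentiation F = ``config.fst``.
    """
    p = panel["p"].to_numpy()
    if config.n_subpops == 1 or config.fst == 0.0:
        return np.tile(p, (config.n_subpops, 1))
    f = config.fst
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    freqs = rng.beta(a, b, size=(config.n_subpops, p.size))
    return np.clip(freqs, 1e-4, 1 - 1e-4)


# ---------------------------------------------------------------------------
# parents
# ---------------------------------------------------------------------------

def simulate_parent_cohort(
    panel: pd.DataFrame,
    config: SimConfig,
    trait: str,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Simulate phenotyped parents: HWE genotypes and an additive phenotype.

    One phenotyped parent per eventual offspring.  The phenotype is
    ``sum(beta * dosage) + eps`` with ``eps ~ Normal(0, sigma_E^2)`` and
    ``sigma_E^2`` set so the total variance matches the configured
    phenotypic variance.  Lifespans are shifted to the sex-specific median
    and kept inside the lifespan window by resampling the environmental
    term (clipping would pile mass on the boundaries).

    Returns ``(genotypes, cohort, subpop_freqs)``: an int8 dosage matrix,
    a cohort table of the phenotyped parents, and the per-subpopulation
    frequency matrix used (needed to draw the random mates).

    Raises ``ValueError`` when the configured genetic variance meets or
    exceeds the total phenotypic variance.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    rng = _rng(config, rng)
    n, m = config.n_offspring, config.n_variants

    freqs = subpop_frequencies(panel, config, rng)
    subpop = rng.integers(0, config.n_subpops, size=n)
    G = np.empty((n, m), dtype=np.int8)
    for s in range(config.n_subpops):
        rows = np.flatnonzero(subpop == s)
        if rows.size:
            G[rows] = rng.binomial(2, freqs[s], size=(rows.size, m)).astype(np.int8)

    beta = config.effects_for(trait)
    p = panel["p"].to_numpy()
    sigma_g2 = float(np.sum(beta**2 * 2 * p * (1 - p)))
    if sigma_g2 >= config.total_phenotypic_variance:
        raise ValueError(
            f"genetic variance {sigma_g2:.3f} >= total phenotypic variance "
            f"{config.total_phenotypic_variance:.3f}"
        )
    sigma_e = np.sqrt(config.total_phenotypic_variance - sigma_g2)

    genetic = G @ beta
    genetic_c = genetic - float(np.sum(2 * p * beta))  # center at HWE mean

    if trait == "paternal_lifespan":
        center, sex = config.median_lifespan["paternal"], "M"
    elif trait == "maternal_lifespan":
        center, sex = config.median_lifespan["maternal"], "F"
    else:  # age: a generic quantitative trait of the genotyped generation
        center = (config.snapshot_year - config.birth_year_range[1]
                  + config.snapshot_year - config.birth_year_range[0]) / 2.0
        sex = None

    lo, hi = config.lifespan_window
    eps = rng.normal(0.0, sigma_e, size=n)
    value = center + genetic_c + eps
    # truncated resampling of the environmental term only
    for _ in range(1000):
        bad = np.flatnonzero((np.rint(value) < lo) | (np.rint(value) > hi))
        if bad.size == 0:
            break
        eps[bad] = rng.normal(0.0, sigma_e, size=bad.size)
        value[bad] = center + genetic_c[bad] + eps[bad]
    else:  # pragma: no cover
        raise RuntimeError("lifespan truncation did not converge")
    value = np.rint(value)  # genealogies record years, not days

    if trait == "age":
        birth = (config.snapshot_year - value).astype(int)
        death = np.full(n, np.nan)
        lifespan = np.full(n, np.nan)
        age = value
    else:
        y0, y1 = config.birth_year_range
        birth = rng.integers(y0, y1 + 1, size=n)
        lifespan = value
        death = birth + lifespan
        age = config.snapshot_year - birth

    sexes = (
        np.full(n, sex)
        if sex is not None
        else np.where(rng.random(n) < 0.5, "M", "F")
    )
    cohort = pd.DataFrame(
        {
            "iid": [f"P{i:07d}" for i in range(n)],
            "sex": sexes,
            "birth_year": birth.astype(int),
            "death_year": death,
            "lifespan": lifespan,
            "age": np.asarray(age, dtype=float),
            "chip": pd.array([pd.NA] * n, dtype="string"),
            "subpop": subpop,
        }
    )
    return G, cohort, freqs


# ---------------------------------------------------------------------------
# transmission
# ---------------------------------------------------------------------------

def transmit_offspring(
    parent_genotypes: np.ndarray,
    panel: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    subpop: np.ndarray | None = None,
    subpop_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Mendelian transmission: one allele from the phenotyped parent, one
    from a random mate drawn from the population at HWE.

    A parent of dosage 0 or 2 transmits its only allele type; a
    heterozygote transmits the alternate allele with probability 1/2.  The
    mate's transmitted allele is Bernoulli(p) with p the (subpopulation)
    alternate-allele frequency.  The mate is never phenotyped.
    """
    rng = _rng(config, rng)
    G = np.asarray(parent_genotypes)
    n, m = G.shape
    if m != len(panel):
        raise ValueError("panel/genotype dimension mismatch")

    transmitted = (G == 2).astype(np.int8)
    het = G == 1
    transmitted[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)

    if subpop_freqs is None or subpop is None:
        p = panel["p"].to_numpy()
        mate_allele = (rng.random((n, m)) < p).astype(np.int8)
    else:
        mate_allele = np.empty((n, m), dtype=np.int8)
        for s in range(subpop_freqs.shape[0]):
            rows = np.flatnonzero(subpop == s)
            if rows.size:
                mate_allele[rows] = (
                    rng.random((rows.size, m)) < subpop_freqs[s]
                ).astype(np.int8)
    return transmitted + mate_allele


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def apply_observation_model(
    cohort: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    genotypes: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Apply the snapshot observation process.

    * Parents whose death postdates the snapshot are alive: their death
      year (and hence lifespan) is unobservable — true right-censorship.
    * Among pre-snapshot deaths, the death record is additionally missing
      at ``missing_death_base_rate``, independent of lifespan.
    * Chip version is assigned v1/v2 by ``chip_split``.
    * Genotype entries, when a dosage matrix is supplied, are set missing
      (NaN) at ``genotype_missing_rate``.

    Lifespan values themselves are never altered, only their observability.
    """
    rng = _rng(config, rng)
    obs = cohort.copy()
    n = len(obs)

    death = obs["death_year"].to_numpy(dtype=float)
    alive = death > config.snapshot_year
    lost = (~alive) & ~np.isnan(death) & (
        rng.random(n) < config.missing_death_base_rate
    )
    hide = alive | lost
    obs.loc[hide, "death_year"] = np.nan
    obs.loc[hide, "lifespan"] = np.nan

    obs["chip"] = np.where(rng.random(n) < config.chip_split, "v1", "v2")

    G_obs: np.ndarray | None = None
    if genotypes is not None:
        G_obs = np.asarray(genotypes, dtype=float).copy()
        if config.genotype_missing_rate > 0:
            mask = rng.random(G_obs.shape) < config.genotype_missing_rate
            G_obs[mask] = np.nan
    return obs, G_obs


# ---------------------------------------------------------------------------
# one-call study simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Study:
    """A simulated proxy-phenotype study, post observation model.

    ``genotypes`` are the offspring dosages (float, NaN = missing) and
    ``cohort`` the *phenotyped parents* (one per offspring, aligned by
    row) with observability already applied.  ``truth`` keeps the fully
    observed parent table for oracle checks.
    """

    config: SimConfig
    trait: str
    panel: pd.DataFrame
    genotypes: np.ndarray
    cohort: pd.DataFrame
    truth: pd.DataFrame
    parent_genotypes: np.ndarray


def simulate_study(config: SimConfig, trait: str = "paternal_lifespan") -> Study:
    """Run the full generative pipeline for one trait.

    Parents are simulated at HWE with the configured additive effects,
    offspring genotypes follow by Mendelian transmission with random
    mates, and the observation model censors death records and introduces
    genotype missingness.  Deterministic given ``config`` (seed included).
    """
    rng = np.random.default_rng(config.seed)
    panel = simulate_variant_panel(config, rng)
    parent_G, parents, freqs = simulate_parent_cohort(panel, config, trait, rng)
    off_G = transmit_offspring(
        parent_G, panel, config, rng,
        subpop=parents["subpop"].to_numpy(), subpop_freqs=freqs,
    )
    observed, off_G_obs = apply_observation_model(parents, config, rng, off_G)
    assert off_G_obs is not None
    return Study(
        config=config,
        trait=trait,
        panel=panel,
        genotypes=off_G_obs,
        cohort=observed,
        truth=parents,
        parent_genotypes=parent_G,
    )


def pedigree_relatedness(
    cohort: pd.DataFrame,
    ibd_cm: float = FIRST_DEGREE_IBD_CM,
) -> pd.DataFrame:
    """True pedigree-based pairwise IBD scores (cM) from parent links.

    Emits one row per first-degree pair derivable from ``father``/
    ``mother`` columns: parent-offspring pairs (when the parent is itself
    a row) and sibling pairs (rows sharing a parent id).  Both receive the
    expected first-degree sharing, half the autosomal map (~1772 cM).
    Unrelated pairs are omitted (score 0).
    """
    cols = {"father", "mother"} & set(cohort.columns)
    rows: list[tuple[str, str, float]] = []
    ids = set(cohort["iid"])
    for col in sorted(cols):
        links = cohort[["iid", col]].dropna()
        # parent-offspring
        for iid, par in links.itertuples(index=False):
            if par in ids:
                rows.append((iid, par, ibd_cm))
        # siblings
        for _, grp in links.groupby(col):
            sibs = sorted(grp["iid"])
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    rows.append((sibs[i], sibs[j], ibd_cm))
    out = pd.DataFrame(rows, columns=["iid1", "iid2", "ibd_cm"])
    return out.drop_duplicates(subset=["iid1", "iid2"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PHENO_COLUMNS = ["iid", "sex", "birth_year", "death_year", "lifespan", "age",
                 "chip", "subpop"]


def export_dataset(
    genotypes: np.ndarray,
    panel: pd.DataFrame,
    cohort: pd.DataFrame,
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write genotypes as VCFv4.2 (GT only) and the cohort as a TSV.

    Dosages encode as 0 -> ``0/0``, 1 -> ``0/1``, 2 -> ``1/1`` and missing
    (NaN) -> ``./.``.  Returns ``(vcf_path, pheno_path)``.  Read back with
    :func:`load_dataset`; dosage and phenotype values round-trip exactly.
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if m != len(panel) or n != len(cohort):
        raise ValueError("dimension mismatch between genotypes, panel, cohort")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = prefix.with_suffix(".vcf")
    pheno_path = prefix.with_suffix(".pheno.tsv")

    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description='
                 '"Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(panel["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(cohort["iid"].astype(str)) + "\n")
        for j, row in enumerate(panel.itertuples(index=False)):
            gts = "\t".join(
                gt_code.get(G[i, j], "./.") if not np.isnan(G[i, j]) else "./."
                for i in range(n)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant}\t{row.ref}\t{row.alt}"
                f"\t.\t.\tCM={row.cm:.6f}\tGT\t{gts}\n"
            )

    cohort.to_csv(pheno_path, sep="\t", index=False, columns=[
        c for c in PHENO_COLUMNS if c in cohort.columns
    ])
    return vcf_path, pheno_path


def load_dataset(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read a dataset written by :func:`export_dataset`.

    Returns ``(genotypes, panel, cohort)``; genotypes are float dosages
    with NaN for missing calls.
    """
    from cyvcf2 import VCF

    prefix = Path(prefix)
    vcf = VCF(str(prefix.with_suffix(".vcf")))
    samples = vcf.samples
    rows, meta = [], []
    for var in vcf:
        dose = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            a = gt[:2]
            dose[i] = np.nan if min(a) < 0 else float(sum(a))
        rows.append(dose)
        meta.append(
            (var.ID, int(var.CHROM), var.POS, float(var.INFO.get("CM", np.nan)),
             var.REF, var.ALT[0])
        )
    vcf.close()
    G = np.array(rows).T if rows else np.empty((len(samples), 0))
    panel = pd.DataFrame(
        meta, columns=["variant", "chrom", "pos", "cm", "ref", "alt"]
    )
    cohort = pd.read_csv(prefix.with_suffix(".pheno.tsv"), sep="\t")
    if list(cohort["iid"]) != samples:
        raise ValueError("phenotype TSV sample order does not match VCF")
    return G, panel, cohort
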