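# lifegwas

Tools for designing and analyzing **parent-offspring ("proxy-phenotype")
lifespan GWAS**: association studies in which the phenotype is a deceased
parent's lifespan and the genotype comes from their living, genotyped
offspring.

## The problem

Lifespan is a property of the deceased, but DNA is collected from the
living. One workaround is to regress a parent's complete lifespan on the
offspring's allele dosage. Under Mendelian segregation the offspring
carries, in expectation, **half** of the phenotyped parent's allelic
dose, so a true additive effect of β years per parental allele appears as
β/2 years per offspring allele:

    E[β̂_offspring] = β_parental / 2        (cov(G_par, G_off) = pq, var(G_off) = 2pq)

Effects and per-SNP variance shares estimated on the offspring scale are
therefore doubled and quadrupled, respectively, to express them on the
parental scale. The dilution also costs power: detecting β = 0.75
yr/allele at MAF 0.20 at genome-wide significance (*P* < 5×10⁻⁸) takes
roughly 170,000 genotyped offspring for 90% power.

Genealogy-linked cohorts add an observation problem: a parent missing a
death year may be alive (truly right-censored) *or* dead with the record
simply never entered. The package estimates the alive ("assumed
censored") fraction of younger birth cohorts from the lifespan
distribution of an old, fully observed baseline cohort.

## What's here

| module | contents |
|---|---|
| `lifegwas.simcohort` | synthetic parent-offspring cohorts: HWE genotypes, additive lifespan loci (years/allele), Mendelian transmission, 2016-snapshot observation model, VCF/TSV export |
| `lifegwas.qc` | MAF/missingness/HWE filters, LD pruning, PCA covariates, IBD-based relative pruning |
| `lifegwas.gwas` | per-variant OLS and age-tail logistic association, genomic control λ, Bonferroni thresholds, parental rescaling, birth-cohort slices, MAF-by-lifespan grids |
| `lifegwas.design` | transmission power simulation, effect dilution, censorship estimation, privacy m/n ratio |
| `lifegwas.ldsc` | LD scores in 1 cM windows, SNP heritability and genetic correlation with constrained intercepts, block-jackknife SEs |
| `lifegwas.meta` | two-study harmonization (allele orientation, strand-ambiguity, MAF floor) and √N-weighted Stouffer meta-analysis |

Numbered drivers under `analysis/` run each stage end-to-end on
synthetic data and write tables under `results/`.

## Worked example

Power and dilution for the headline design point:

```python
>>> from lifegwas.design import power_grid, dilution_ratio
>>> grid = power_grid(ps=[0.2], betas=[0.75], ns=[170_000],
...                   replicates=200, seed=101)
>>> round(float(grid["power"].iloc[0]), 3)
0.9
>>> round(float(grid["power_analytic"].iloc[0]), 3)
0.909
```

A 0.75 yr/allele parental effect at MAF 0.20 is detected at *P* < 5×10⁻⁸
in ~90% of replicate cohorts of 170,000 offspring; the Monte-Carlo power
agrees with the closed-form non-centrality approximation
Φ(√NCP − z_{α/2}), NCP = N(β/2)²·2pq/σ².

```python
>>> from lifegwas.design import dilution_ratio
>>> grid = power_grid(ps=[0.05, 0.2, 0.5], betas=[1.0, 2.0, 3.8],
...                   ns=[100_000], replicates=40, seed=105)
>>> round(dilution_ratio(grid), 3)
0.501
```

The offspring-dose slope recovers half the generating parental effect,
independent of allele frequency — the factor-2 rescaling applied by
`lifegwas.gwas.rescale_parental`.

A full pipeline run (simulate → QC → association → genomic control →
rescale) is in `analysis/04_gwas_pipeline.py`; on a 30,000-offspring
cohort with two planted loci (+3.0 and −2.0 yr/allele, parental scale)
it prints:

```
lambda = 1.091; Bonferroni threshold 6.31e-05; 2 significant variants (parental-scale effects):
  variant      maf      beta       se         p_uc         p_gc
snp000010 0.411923  2.627944 0.264970 3.480250e-23 2.168694e-21
snp000400 0.411410 -1.994604 0.255704 6.168345e-15 8.074327e-14
```

Both planted effects are recovered on the parental scale within sampling
error.

## Command line

Thin wrappers exist for the file-in/file-out stages:

```sh
lifegwas simulate --n-offspring 5000 --n-variants 100 --seed 1 --out scratch/toy
lifegwas power --p-grid 0.2 --beta-grid 0.75 --n-grid 170000 --reps 50 --seed 1 --out scratch/power.tsv
lifegwas censorship scratch/toy.pheno.tsv --out scratch/cens.tsv
lifegwas meta --a a.tsv --b b.tsv --maf-min 0.005 --out scratch/meta.tsv
```

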