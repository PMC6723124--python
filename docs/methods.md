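# Methods

## The generative model

`simcohort` simulates the statistical situation a proxy-phenotype
lifespan GWA assumes.

**Genotypes.** Each phenotyped parent draws dosage ~ Binomial(2, p) per
variant (Hardy-Weinberg proportions) at frequencies from a configurable
spectrum clamped to [0.001, 0.5]. With discrete population structure
(`n_subpops`, `fst`), subpopulation frequencies follow the
Balding-Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F); structure is
otherwise off by default. Variants are unlinked; linkage disequilibrium,
when a test needs it, is constructed explicitly in the fixture (noisy
copies of latent columns), because the LD-score stage is the only
consumer and its regressors only require *known* LD.

**Phenotype.** Parental lifespan (years) is

    L = median_sex + Σ_j β_j (g_j − 2 p_j) + ε,   ε ~ N(0, σ²_E)

with σ²_E = σ²_P − Σ β²·2pq so the total variance matches `σ²_P`
(default **166.2 yr²**, a realistic phenotypic variance for lifespan in
the 40–120 window; sex-specific medians default to 76 paternal / 82
maternal). Lifespans outside [40, 120] are handled by **resampling ε**,
not clipping — clipping would put probability atoms on the boundaries
and distort the variance. Values are rounded to whole years, as
genealogical records are; the rounding adds ~1/12 yr² (≤0.05% of σ²_P).
Effects β are stated on the **parental** scale throughout.

**Transmission.** Each offspring receives one allele sampled uniformly
from the phenotyped parent's two and one Bernoulli(p) allele from an
unphenotyped random mate — perfect Mendelian segregation, exactly one
phenotyped parent per offspring. This fixes cor(G_par, G_off) = 1/2 and
hence the β/2 dilution of the offspring-dose regression slope.

**Observation model.** At the snapshot year (default 2016), parents
whose death postdates the snapshot lose their death year (true
right-censorship); among pre-snapshot deaths the record is additionally
missing at `missing_death_base_rate` (default 1/3) independent of
lifespan; genotype calls are erased at `genotype_missing_rate`; a chip
version (v1/v2) is assigned by `chip_split`. Lifespan *values* are never
altered, only observability — the un-censored table is retained for
oracle tests.

**What the generator does not emulate:** linkage disequilibrium along
the genome, assortative mating, lifespan-dependent record loss,
secular mortality trends within cohorts, genotyping batch effects beyond
a binary chip label, and age-varying allelic effects (cohort-slice tests
construct these explicitly). Passing tests therefore demonstrate the
estimators' behavior under the stated model, not robustness to these
real-data features.

## Association engine

Per-variant OLS of phenotype on dosage plus covariates, computed by
residualizing on the covariate design once (QR) and applying the
Frisch–Waugh identity across all complete columns simultaneously;
variants with missing calls fall back to per-variant complete-case fits
(no dosage imputation). Two-sided P values use the normal approximation
of β/SE; at the sample sizes the design requires (10⁴–10⁵) the
difference from the t reference is far below output precision. The
age-tail case/control framework fits per-variant logistic regressions
(cases above the upper-tail age quantile, controls at or below the
median, the gap excluded); separation or non-convergence flags the
variant rather than aborting the scan.

Genomic control: λ = median(χ²)/0.455936 (the χ²₁ median); the
correction divides χ² by max(λ, 1) — deflation is never applied,
following common GC practice. The permutation-calibration path
(`design.permutation_lambda`) uses the closed-form simple-regression
χ² = (n−2)r²/(1−r²) with the centered genotype matrix reused across
permutations; it is algebraically identical to the engine without
covariates (asserted by test) and keeps 20 permutations of a
10,000 × 5,000 scan under a minute.

Parental rescaling doubles β and SE and quadruples variance-explained
shares; the ×4 follows from β×2 at fixed genotype variance and is
verified by simulation. The association table carries a scale flag so
the rescaling cannot be applied twice.

## QC

Fixed filter order: variant missingness (≤20%) → MAF (≥0.5%, inclusive
thresholds) → removal of the worst `ceil(0.01·m)` variants by HWE
goodness-of-fit χ² (rank-based, ties broken by variant id) → individual
missingness (≤2%) → greedy windowed LD pruning (r² > 0.9 removes the
lower-MAF member; tie → higher column index; default 50-SNP window,
step 5 — window sizes are a convention, configurable). PCA covariates
standardize dosages by √(2p̂(1−p̂)), mean-impute missing entries after
centering, and use a randomized SVD (matching the full decomposition on
small instances to |r| ≥ 0.999 per component). Relative pruning consumes
a long-format pairwise IBD table (cM) and removes one member of an
exceeding pair uniformly at random until no pair exceeds 300 cM; IBD
*detection* is out of scope, but the generator emits true
pedigree-based scores (first-degree ≈ 1772 cM on a 3545-cM autosomal
map) so the operation is testable end-to-end.

## Design-stage computations

**Power.** Each replicate simulates fresh parents and mates, regresses
the parental phenotype on offspring dosage, and scores significance at
α = 5×10⁻⁸; power is the significant fraction of replicates. The
analytic check is Φ(√NCP − z_{α/2}) with NCP = N(β/2)²·2pq/σ²_resid;
Monte-Carlo and analytic values agree within 0.05 across the tested
grid. The headline point (p = 0.20, β = 0.75 yr, N = 170,000,
σ² = 166.2) gives power ≈ 0.90 — the default total variance makes this
cell internally consistent with the analytic value (0.909), which is
what motivated adopting 166.2 yr² as the default.

**Censorship.** For a fully observed baseline cohort range (default
birth years 1886–1910 at a 2016 snapshot) the pooled empirical CDF F of
lifespans in [40, 120] is the reference. A target year y can only show
lifespans up to c_y = snapshot − y, so its complete count represents the
F(c_y) quantile of the cohort; the alive count is estimated as
n_complete·(1−F(c_y))/F(c_y) and the annual assumed-censored fraction as
alive/(alive + n_complete). This odds-style inflation is one natural
reconstruction of the baseline principle; it is exposed as a named
strategy so alternatives can be slotted in. It is exact when target
cohorts share the baseline lifespan distribution and degrades gracefully
(recovering generator truth within ~2 SE in tests) under moderate
distributional drift. c_y ≥ 120 returns 0; F(c_y) = 0 is flagged
undefined. The cumulative fraction aggregates counts, not fractions.

**Privacy.** m/n and √(m/n) for m reported SNPs over n individuals.

## LD-score stage

LD scores sum adjusted r² (r² − (1−r²)/(n_ref−2)) over ±1 cM windows,
self term included. Heritability is the slope of a weighted regression
of χ² on N·ℓ/M with weights 1/max(ℓ, 1) — a deliberate simplification of
the reference implementation's iterative heteroskedasticity weights that
costs some efficiency but none of the identification. Intercepts may be
constrained (1 for h²; r_p·N12/√(N1·N2) for the genetic covariance under
sample overlap). SEs come from a delete-a-block jackknife (default 200
contiguous blocks). r_g = gencov/√(h²₁·h²₂); |r_g| > 1.25 warns but is
reported raw. Parental-dose rescaling (×4) is applied *downstream*,
never inside this module, preserving the single-application contract.
`simulate_sumstats` draws z-scores from the model's own bivariate
process and backs the parameter-recovery tests (h² = 0.04, r_g = 0.7
recovered within 2 jackknife SE).

## Meta-analysis

Harmonization intersects on variant id, flips z (and complements the
frequency) when effect/other alleles are swapped, drops other allele
combinations, drops strand-ambiguous (A/T, C/G) variants when the
frequency comparison is inconclusive (closer after complementing than
before), and applies an inclusive 0.5% MAF floor in both studies.
Combination is Stouffer's method with weights √N after per-study GC
deflation by √max(λ, 1): z_meta = Σwz/√Σw². Effect sizes themselves are
not meta-analyzed; β/SE inputs are converted to z on read.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen for precision
per CPU-second: power at the headline cell uses 200 replicates
(binomial SE ≈ 0.021 at power 0.9); dilution uses a 3×3 (p, β) grid at
N = 100,000 × 40 replicates (ratio SE < 0.01); λ calibration uses
≥10,000 phenotyped parents × 5,000 null variants × 20 permutations
(SE of mean λ ≈ 0.007). Analysis drivers use comparable sizes. Seeds
are threaded explicitly everywhere; identical configurations reproduce
bit-identical outputs.

## Known limitations

- No LD in generated genotypes (see above); LD-dependent behavior is
  exercised only through constructed fixtures.
- The censorship estimator assumes the baseline lifespan distribution
  transfers to target cohorts; secular mortality improvement biases it.
- The logistic scan refits per variant (no score-test shortcut); it is
  the slowest path and intended for candidate sets, not genome scans.
- Case/control and quantitative age analyses treat age as a generic
  quantitative trait of the genotyped generation; cohort-frequency
  effects that make age genetically informative are not modeled by the
  generator.
- `estimate_rg`'s jackknife treats blocks as exchangeable; with strong
  per-chromosome heterogeneity the SE is optimistic.
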