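# Methods

## The trait and the analysis

Rice plant height (cm) is treated as a quantitative trait measured on
inbred lines in replicated multi-environment trials. The pipeline links
two populations: a *diversity panel* (many unrelated inbred varieties,
genetically structured) used to discover height-associated markers and
train a predictor, and a *biparental RIL population* (recombinant inbred
lines from a single cross, near-homozygous mosaics of the two parental
genomes) used as an independent validation set. Markers are multi-allelic
(SSR/indel-style); an allele is identified by its PCR band size in bp and
treated as an opaque categorical label throughout — band sizes are
categories, never magnitudes.

## Association scan

Population structure confounds marker–trait association in a diversity
panel, so each line receives q structure covariates: the top
principal-component scores of the centered allele-indicator matrix (one
0/1/2 allele-count column per marker allele; missing calls imputed to the
allele's mean count). PCs are a standard deterministic substitute for
subpopulation-membership (Q-matrix) covariates; no kinship random effect
is fitted. Default q = 3.

For one marker in one environment the response is each line's mean height
over replicates. The marker enters as a categorical factor: one class per
homozygous allele, heterozygous calls as their own class, classes with
fewer than 3 carriers pooled into "other" (this keeps multi-allelic fits
full-rank; markers left with fewer than two classes are skipped). The
test is the nested-model F:

    F = [(RSS_reduced − RSS_full)/Δdf] / [RSS_full/df_full]

with the reduced model intercept + covariates and the full model adding
the marker-class indicators; p comes from the F distribution and the
marker R² is the incremental sum of squares over the total centered sum
of squares, (RSS_reduced − RSS_full)/TSS. This incremental-SS definition
of marker R² is a convention of this package (association tools differ in
which partial R² they print). The reported best allele is the allele
whose homozygous carriers have the highest *raw* mean height —
deliberately unadjusted for covariates, since it is meant to name the
allele a breeder would select on; alleles with fewer than 3 carriers are
only considered when no better-supported allele exists.

The scan tests every (marker, environment) pair and keeps p < α
(default α = 0.01, a fixed per-test threshold with no multiplicity
correction — the convention of this style of marker survey). "Stable"
loci are markers significant in at least `min_environments` environments
(default 2), each paired with its height-increasing allele by majority
vote across environments (ties broken by the environment with the
smallest p), ranked by environment count then best p. The ladder extends
this ranking with the remaining significant markers so it always has
enough loci.

## Genotypic values, pyramiding score, height model

Each locus collapses to a genotypic value: +2 iff homozygous for the
locus's increasing allele, −2 for any other homozygote, 0 for a
heterozygous or missing call. The 0 class is this package's decision: the
±2 coding is defined only for homozygotes (the material is inbred), and 0
is the unique symmetric completion — worth remembering when scoring
non-inbred user data. The pyramiding score x of a line over an ordered
locus set of L loci is the sum of its genotypic values, so x ∈ [−2L, 2L]
in steps of 2 (steps of 1 only if 0-valued calls occur).

The height model is simple OLS, y = a·x + b, fitted closed-form
(a = Sxy/Sxx, b = ȳ − a·x̄) with the 1-df slope F test; prediction is
exactly a·x + b for any integer score. The model ladder refits on the
first k loci of the ranking for k = 2..10; the training response is each
line's mean height over the designated training environments (all
environments by default — a location subset can be configured, since a
model trained in one location only predicts heights for that location).
Model files store coefficients at full precision (`repr`); printed
equations round to 5 decimals.

Degenerate inputs raise explicit errors: a constant score vector (slope
undefined), fewer than 3 lines, an empty locus set. A constant response
yields slope 0 and F = 0 rather than an error.

## Validation and variance partition

**AAE.** For each validation line, P = predict(model, x) and R = the
line's mean observed height over the designated environments;
AAE = (1/n) Σ |P − R|. The absolute value is essential — signed errors
would cancel — and implies the bound |mean(P) − mean(R)| ≤ AAE, asserted
on every report.

**AAD matrix.** For every environment pair, the mean over shared lines of
|line mean in one environment − line mean in the other|; line means per
environment (not replicate-level values) are compared. Its off-diagonal
extremes form the natural-variation band: how much a genetically
identical line moves between seasons, the yardstick for whether a
predictor's AAE is "good".

**Two-way ANOVA.** Fixed-effects genotype × environment ANOVA with
sequential (Type I) sums of squares in the order genotype, environment,
interaction, error from within-cell replicates. The SS are computed by
nested projections — one-factor RSS by group means, the additive model by
least squares on treatment-coded indicators, the interaction model as
cell means — which handles unbalanced replicate counts; complete
genotype×environment crossing is assumed. On balanced data Type I SS are
order-invariant (asserted to 1e-8 in tests). Percent contributions divide
by the model (non-error) SS only, so the three factor percents sum
to 100. F tests use the error mean square; designs without within-cell
replication are rejected because the error term is inestimable.

## Synthetic data generator

The generator produces data with exactly the structure the analysis
assumes; it defines the study conditions for every stochastic test.

**Panel.** `n_lines` fully homozygous lines in `n_subpopulations`
subpopulations. Per marker, panel-wide allele frequencies are Dirichlet(1)
draws (floored at ~5% so every allele stays representable), and each
subpopulation draws its frequencies from Dirichlet(base·(1−F)/F) — the
Balding–Nichols construction, with `subpop_divergence` F = 0.15 by
default, a realistic between-subspecies differentiation for rice. Each
line samples one allele per marker from its subpopulation and is recorded
as the homozygous call. `n_qtl` markers are designated QTLs; at each, the
allele nearest 50% frequency is the increasing allele (maximising the
segregating variance the scan must find) with effect +s cm per allele
copy (default s = 2.5, i.e. a 5 cm homozygote contrast, giving per-marker
R² of a few percent — the size class a marker survey of a polygenic trait
reports). Default scale: 273 lines × 218 markers on 12 chromosomes,
3 alleles/marker, 3 subpopulations, 10 QTLs.

**RIL population.** Each chromosome of each line is a first-order Markov
mosaic over the two parental origins: a fair coin at the first marker,
then a switch between adjacent markers with probability R = 2r/(1+2r),
where r is the Haldane recombination fraction ½(1 − e^(−2d)) of the map
distance — the classical expected recombinant fraction between RIL lines
derived by repeated selfing (map expansion, no interference). Parents
must be homozygous; where they share an allele all offspring carry it.
`residual_het_rate` defaults to 0 (advanced-generation RILs are treated
as fully inbred; generation-specific heterozygosity is not modelled).

**Phenotypes.** height(i,j,k) = grand_mean + Σ_q s_q·copies(i,q) + g_i +
e_j + (ge)_ij + ε_ijk with independent zero-mean normal components at
variances (σ²_g, σ²_e, σ²_ge, σ²_ε). The defaults

| component | σ² (cm²) |
|---|---|
| genotype | 152.0 |
| environment | 9.3 |
| G×E | 49.5 |
| residual | 10.7 |

with grand mean 115 cm, 5 environments × 3 replicates, were derived once
from the expected-mean-square identities of the balanced two-way random
model (E[MS_G] = σ²_ε + rσ²_ge + reσ²_g etc.) so that a 219-line × 5 × 3
trial partitions its model SS ≈ 76% genotype / 4% environment / 20% G×E —
the genotype-dominated regime typical of multi-year rice height trials.
`expected_anova_percents` exposes the same identity so round-trip tests
compare against the configured expectation, not a hard-coded number. In
the full synthetic study the RIL polygenic variance is reduced by Σs²_q
(the expected QTL variance at segregation frequency ½) so the *total*
genotypic component stays at the configured value with QTLs planted, and
the grand mean is offset by the realized mean QTL contribution so the
population mean sits at the configured 115 cm despite the one-sided
(+s per copy) effect parameterization.

What the generator does **not** emulate: linkage disequilibrium between
panel markers beyond shared subpopulation frequencies (panel markers are
drawn independently), epistasis (effects are purely additive; the
interaction between specific locus pairs reported for real material is a
listed non-goal), allele-frequency clines within subpopulations,
genotyping error, and non-normal environmental effects. Passing tests
therefore demonstrate that the statistics are computed correctly and
behave as designed under the assumed model — not that the model captures
every feature of real field data.

## Numerical and design choices

- Least squares everywhere via `numpy.linalg.lstsq`; RSS computed from
  explicit residuals (robust to rank-deficient indicator blocks). The F
  numerator is clipped at 0 against roundoff; an exactly saturated full
  model reports F = ∞ with p at the smallest positive float, keeping p in
  (0, 1].
- A constant response short-circuits to F = 0, R² = 0 (nothing to
  explain) rather than 0/0.
- PCA for structure covariates uses SVD with a deterministic sign
  convention (largest-magnitude loading positive), so runs are
  bit-reproducible.
- All files are TSV with mandatory headers; `NA` is the only missing
  token; calls serialize as `allele1/allele2` with the pair stored
  unordered (sorted). Floats are written with `repr` and parsed with
  round-trip precision, so write→read is exact.
- One master seed drives everything; per-stage seeds derive from it via
  `numpy.random.SeedSequence` (kept below 2³¹). Identical config + seed
  gives byte-identical output bundles.
- Test and acceptance problem sizes: the stochastic suites run at the
  study's own scale (273 × 218 panel, 219-line RIL, 20 regenerations
  where averaging is needed) because the whole pipeline runs in seconds;
  only incidental unit-test datasets are smaller.

## Known limitations

- No kinship/REML mixed model: structure correction is PC covariates
  only, which under-corrects cryptic relatedness within subpopulations.
- Type I (sequential) SS with complete crossing assumed; Type II/III and
  incomplete designs are out of scope.
- The ladder's locus ordering is the stability ranking (or a
  user-supplied list); it does not search for the best-predicting subset,
  and equal weights (±2) are used at every locus rather than
  effect-size-weighted values.
- Scores of partially heterozygous or missing genotypes lean on the
  0-encoding decision documented above.
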