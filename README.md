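# pyraheight

Marker-based prediction of rice plant height by allele pyramiding.

Plant height in rice is a classic quantitative trait: it is controlled by
many loci of modest effect and is strongly shaped by the growing
environment, yet it must be tuned precisely in breeding because both very
tall and very short plants lose yield. `pyraheight` implements, as a
tested and reusable pipeline, the breeding-oriented analysis that turns a
set of height-associated molecular markers into a height predictor:

1. **Association scan.** On a structured diversity panel of inbred lines
   scored at multi-allelic markers (allele labels are PCR band sizes in
   bp), each marker is tested per environment with a nested-model F test —
   intercept + principal-component structure covariates + marker-class
   indicators against the covariate-only model — on the line-mean heights.
   Markers with p < 0.01 are reported with their F, p, marker R² and the
   allele whose homozygous carriers are tallest.
2. **Genotypic values and the pyramiding score.** Each trait-associated
   locus is encoded +2 (homozygous for the height-increasing allele),
   −2 (any other homozygote) or 0 (heterozygous/missing). The pyramiding
   score of a line is x = Σ genotypic values over an ordered locus set.
3. **The height model.** Ordinary least squares of line height on the
   score: **y = a·x + b** (y in cm). A "ladder" of models over the first
   k = 2..10 ranked loci asks how many loci a usable predictor needs.
4. **Cross-population validation.** Models trained on the panel are
   applied to an independent biparental RIL population; accuracy is the
   average absolute error AAE = (1/n) Σ |P_i − R_i| between predicted and
   observed line means.
5. **Environmental context.** A two-way ANOVA (sequential Type I SS:
   genotype, environment, G×E) partitions the trial variance, and the
   pairwise between-season average-absolute-difference (AAD) matrix gives
   the natural variation band a predictor should be judged against.

Because such field datasets are typically not public, the package ships a
first-class synthetic-data module that generates the whole study design —
a structured panel with planted QTLs (Balding–Nichols subpopulation
allele frequencies), a biparental RIL population (Haldane map function,
RIL-adjusted recombination fraction 2r/(1+2r)) and replicated
multi-environment phenotypes with configurable genotype / environment /
G×E / residual variance components.

## Worked example

```bash
pyraheight run-all --seed 1 --out results/demo
```

prints

```
34 associations over 13 markers; AAE(k=5) = 9.71 cm; natural variation 8.14-9.82 cm; ANOVA % G/E/GxE = 76.11/1.73/22.16
```

meaning: at p < 0.01 the scan found 34 marker–trait associations over 13
distinct markers (10 planted QTLs plus a few false positives at the
nominal rate); the 5-locus model predicts independent RIL line heights to
about 9.7 cm average absolute error — comparable to the 8.1–9.8 cm the
same lines move between growing seasons — and genotype dominates the
variance partition (76%), with G×E (22%) far ahead of the environment
main effect (2%). All intermediate tables (association results, ranked
loci, per-line scores, one model file per k, the ladder summary, the AAE
report, the AAD matrix and the ANOVA table) are written under
`results/demo/`.

The same stages are exposed individually (`simulate`, `associate`,
`score`, `fit`, `predict`, `evaluate`, `anova`), and the numbered scripts
under `analysis/` run the study as a narrative:

```bash
python analysis/01_simulate_populations.py --seed 1
python analysis/02_association_scan.py
python analysis/03_pyramiding_effect.py
python analysis/04_model_ladder.py
python analysis/05_variance_partition.py
```

A fitted model file stores its coefficients at full precision; e.g. with
a saved 2-locus model `y = 5.47816 x + 137.12733`, `pyraheight predict
--model model.tsv --x 0` prints `137.12733` — the intercept is the
prediction for a line scoring 0, and each +2 score step (one more
homozygous increasing locus) adds 2a cm.

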