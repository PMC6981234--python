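# brainatlas

Statistical machinery for multi-region brain expression and
open-chromatin atlases built from a small, balanced animal panel — the
kind of design where eight individuals (2 sexes x 2 age groups x 2
animals per cell) are each sampled across dozens of brain regions.

At that scale, naive per-gene tests for sex- or age-related expression
are unreliable: the theoretical null is wrong (few individuals, strong
within-individual correlation) and covariates can confound each other.
`brainatlas` implements the bespoke inference such atlases need,
end-to-end and fully testable on synthetic data, plus the standard
downstream procedures of the regulatory arm.

## What it computes

**Covariate-related genes.** Counts are modeled per gene as a
negative-binomial mixed-effect model with log link,

    Y ~ NB(mu, theta),   log mu = alpha_sex + beta_age + gamma_region + delta_indiv,

with `delta_indiv ~ N(0, sigma^2)` a per-individual random intercept,
fitted by a Laplace approximation (penalized IRLS inside, profile
optimization of `(theta, sigma^2)` outside).  To test one covariate free
of the other, individuals are pooled within each level of the other
covariate and exhaustively reassigned — 18 distinct assignments for the
balanced 2x2x2 design, counting label-swap mirror images once.  Every
gene is refitted under every assignment; the pooled signed z-values give
an empirical null whose normal component `N(delta0, sigma0^2)` is
estimated by truncated-normal ML on the central quantile range, in the
spirit of Efron's local-fdr machinery.  Genes are selected by a
tail-area FDR under that estimated null (FDR < 0.1, |log2FC| > 1).

**Region-specific genes.** NB likelihood-ratio test of
`~ region + individual` against `~ individual` (chi-square, R-1 df),
gated at BH FDR < 0.05 and fold-change > 2.

**Module-region gating.** Module eigengene = first principal component
of the standardized module submatrix; association = Pearson r against a
binary region indicator with Student asymptotic p
(`t = r*sqrt(n-2)/sqrt(1-r^2)`); gate r >= 0.8, p < 0.01.

**ATAC procedures.** 1-bp union-merge of region peak sets into consensus
peaks with reproducibility labels; TMM normalization (30% M-trim, 5%
A-trim, precision-weighted, geometric-mean-1 factors — agrees with
edgeR to 1e-5); peak-gene linking by Pearson correlation over
same-chromosome pairs (r > 0.7, BH FDR < 0.1) with peak-TSS distances;
promoter/exon/intron/distal feature annotation; 2x2 chi-square for
enhancer-overlap enrichment.

**Transcript screening.** Exact-coordinate exon/intron sensitivity and
precision against a reference, F1 = 2SP/(S+P), and selection of the
assembly expression threshold as the mean of the per-level F1 argmaxes
over the 0.5..9.5 grid; a two-predictor coding call (coding only if both
agree); and the five-rule lncRNA cascade (intergenic/antisense, >= 1 kb
from coding genes, non-coding by at least one predictor, >= 200 nt,
multi-exonic) with a per-rule audit.

**Synthetic data.** Generators for NB counts under the mixed model on
the balanced design, peak/expression matrices with planted correlations,
and toy reference/assembled annotations with planted exact-match
fractions — so every stage above is exercised against known truth.

## Worked example

```
$ python analysis/01_simulate_data.py
null counts: (200, 32), effect counts: (200, 32)
planted sex-related genes: 10 of 200 (contrast ln 4)
...

$ python analysis/02_covariate_genes.py
permutation plan: 18 assignments; convergence 100.0%
empirical null: delta0=+0.023 sigma0=1.189 p0=0.909
12 genes called at FDR<0.1 & |log2FC|>1: 10 true / 2 false (sensitivity 1.00, FDP 0.17)
```

Reading it: the plan enumerates all 18 label reassignments; the pooled
permutation z-values are over-dispersed relative to N(0,1)
(sigma0 ≈ 1.19 — exactly why the empirical-null correction exists), and
selection against the corrected null recovers all ten planted genes with
two false calls at the nominal FDR 0.1.

The other drivers follow the same pattern: `03_region_genes.py` (LRT
recovers 20/20 planted region-specific genes with 0 background calls),
`04_module_traits.py` (only the planted module-region pair passes the
r >= 0.8 gate), `05_atac_linking.py` (consensus peaks, TMM factors,
199/200 planted peak-gene links recovered with 0 spurious),
`06_transcript_screen.py` (exon/intron F1 optima 6.5/4.5 combine to a
final threshold of 5.5; the lncRNA cascade audit).

A `brainatlas` CLI exposes each stage (`simulate`, `diffcov`,
`region-lrt`, `module-trait`, `merge-peaks`, `tmm`, `link-peaks`,
`annotate-peaks`, `sweep-f1`, `lnc-filter`, `run`); see
`brainatlas --help`.

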