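# Methods

This note documents the statistical machinery implemented in
`brainatlas`, its assumptions, the defaults and why they are set where
they are, and what the synthetic-data tests do and do not demonstrate.

## The count model

Per gene g, read counts are modeled as negative binomial with a log link:

    Y_gijkls ~ NB(mu_gijkl, theta_g)
    log mu_gijkl = alpha_gi + beta_gj + gamma_gk + delta_gl

with sex level i ∈ {0,1}, age level j ∈ {0,1}, region k = 1..R,
individual l, replicate s.  alpha, beta, gamma are fixed effects;
delta_l ~ N(0, sigma_g^2) is a per-individual random intercept shared by
all of that individual's samples; theta_g is the NB size parameter, with
Var(Y) = mu + mu^2/theta.  The display is over-parameterized, so the
implementation uses treatment coding: an explicit intercept with sex=0,
age=0 and the first region as references.  The contrasts alpha_1-alpha_0
and beta_1-beta_0 are the quantities tested; selection uses
log2FC = (natural-log contrast)/ln 2, because the model link is natural
log while the selection rule is stated on the log2 scale.

The random-effect variance is read as a per-gene scalar sigma_g^2 common
to all individuals: with a single observation set per individual,
individual-specific variances are not identifiable.

### Estimation

The marginal likelihood is approximated by Laplace's method.  For fixed
(theta, sigma^2) an inner penalized IRLS (Fisher scoring with
step-halving, so the penalized objective never decreases) finds the joint
mode of (fixed effects, random effects); the Laplace objective adds the
log-determinant correction, which is diagonal per individual because the
random effect enters block-wise.  The outer layer profiles
(log theta, log sigma^2) by coordinate-wise bounded 1-D minimization
(full bounds on the first sweep, a shrinking local bracket afterwards),
stopping when the relative objective change falls below 1e-8 or after
200 sweeps; fits that stop on the iteration cap are flagged
non-converged.  There is no random initialization anywhere: fits are
deterministic functions of the data.

Wald inference uses the fixed-effect block of the inverse penalized
Hessian at the optimum.  sigma^2 is bounded below at ~1e-8; at that
boundary the model is an ordinary NB GLM and the coefficients match an
independent GLM fit to 1e-4 (tested).

At this design size (8 individuals) Wald and likelihood-ratio p-values
agree within a factor of ~1.5 for null genes but diverge for strong
contrasts, where the reduced model can absorb the effect into the
random-effect variance; the package uses Wald p-values in the
permutation pipeline, which only requires a fixed, monotone
transformation of the evidence per fit.

### Region test

Subregion-specific genes use a likelihood-ratio test between
fixed-effect NB GLMs `~ region + individual` versus `~ individual`
(chi-square, R-1 df), with the dispersion profiled on the full model and
held fixed for the reduced fit — the same structure as the usual
count-model LRT for a factor.  Per-region fold-changes are each region's
fitted mean over the arithmetic mean of the other regions' fitted means;
the selection gate is BH-adjusted FDR < 0.05 and fold-change > 2.

## Permutation empirical null

For the sex test, the four individuals within each age level are pooled
and reassigned to the two sex cells in every possible way (C(4,2) = 6
per age level, independently across levels → 36), and two assignments
differing only by a simultaneous swap of the sex labels in both age
levels are counted once, giving 18 distinct assignments — the identity
among them.  The age test is the mirror image.  Individuals move as
whole blocks (all regions/replicates together), preserving
within-individual correlation.  Unbalanced designs are rejected: the
label-swap equivalence needs equal cell sizes.

Every gene is refitted under every assignment; the signed Wald z-values
of all assignments are pooled.  Because the pool mixes the permutation
distribution of true nulls with that of alternatives, it is wider than
the theoretical N(0,1) (the synthetic runs show sigma0 ≈ 1.2-1.4 even
with zero effects, from the dependence structure of refits on shared
data).  The null component N(delta0, sigma0^2) is therefore estimated
from the central region of the pooled z's by truncated-normal maximum
likelihood, with the null proportion p0 given by the observed central
mass over the fitted normal mass on that interval.

The central interval defaults to the central 75% quantile range.  The
sampling error of the sigma0 MLE grows quickly as the window narrows
(at the central 50% its SD at n = 10,000 is ~0.16, too coarse to be
useful); at 75% the SD is ~0.04 while a 10% contamination of
alternatives at z = 3 still inflates sigma0 by only ~0.06.  The fraction
is configurable.

Selection computes, for each threshold t = |z_g|, the tail-area estimate

    FDR(t) = p0 · G · P(|Z| >= t | N(delta0, sigma0^2)) / #{g' : |z_g'| >= t}

monotonized q-value style (each gene takes the minimum over thresholds
at or below its own |z|), and declares a gene significant when
FDR < 0.1 and |log2FC| > 1.  Point estimates only; no interval
construction around the FDR and no per-gene local-fdr curves.
Non-converged permuted fits are excluded from pooling and their rate is
reported; above 20% a warning is attached to the run report.

## Module-trait gating

Module memberships are consumed, not discovered.  The module eigengene
is the first right singular vector of the gene-standardized submatrix
(unit norm, sign-aligned to correlate positively with the module's mean
profile); variance explained is the first squared singular value over
the total.  Module-region association is the Pearson correlation between
the eigengene and a binary region indicator with the Student asymptotic
p-value (t = r·sqrt(n-2)/sqrt(1-r^2), n-2 df); the gate is r >= 0.8 and
p < 0.01 by default, with r configurable (the cortical-lobe analyses
gate at 0.9).

## ATAC procedures

Consensus peaks are the transitive union-merge of the region peak sets:
intervals overlapping by >= 1 bp merge, book-ended intervals do not.
Each consensus peak records which input sets contributed an overlapping
interval; the reproducibility label is that count.  Merging is
order-independent and idempotent (tested against a union-find oracle).

TMM scaling factors follow the standard trimmed-mean-of-M-values
construction: reference = the sample whose library-scaled upper quartile
is closest to the mean upper quartile; per sample, M- and A-values over
features positive in both sample and reference; double trim (30% of M,
5% of A, by ranks); weights = inverse asymptotic (delta-method) variance
of M; factors normalized to geometric mean 1.  The implementation agrees
with edgeR's `calcNormFactors` to 1e-5 on random matrices (tested via
Rscript).  Normalized peak intensity is log2(TMM-scaled count + 1) where
the scaled count rescales each sample to the geometric-mean effective
library size.

Peak-gene linking computes Pearson correlations for all same-chromosome
peak-gene pairs, converts to two-sided p-values through the t transform,
BH-adjusts across all tested pairs, and retains links with r > 0.7 and
FDR < 0.1, attaching the peak-TSS distance.  Gene expression enters the
linker as any variance-stabilized matrix; the bundled default is
log2(library-size-scaled count + 1), a monotone stand-in chosen because
the linking contract only needs approximate variance stabilization — the
transform is configurable by passing a different matrix.

Peak-TSS distance is 0 when the TSS (first transcribed base; start on
'+', end-1 on '-') lies inside the peak, else the distance to the nearer
peak edge using end-1 for the right edge of the half-open interval.
Feature annotation classifies with priority promoter > exon > intron >
distal intergenic, promoter meaning overlap of [TSS-w, TSS+w) with
w = 1 kb by default.  Enhancer-overlap enrichment is a Pearson
chi-square on the 2x2 table without continuity correction.

## Assembly evaluation and lncRNA screen

Assembly accuracy at the exon or intron level counts unique
(chrom, start, end, strand) features and uses exact-coordinate matching:
sensitivity = matched reference features / reference features, precision
= matched assembled features / assembled features, combined as
F1 = 2SP/(S+P) (0 at S=P=0).  Over the expression-filter grid 0.5..9.5
(step 0.5), the final threshold is the arithmetic mean of the exon-level
and intron-level F1 argmaxes, ties breaking toward the smaller
threshold; this combination uniquely reproduces a final threshold of 5.5
from per-level optima 6.5 and 4.5.

A transcript is called coding only when both coding-potential predictors
call it coding (maximal specificity).  The lncRNA cascade retains
transcripts that are (i) intergenic or antisense against the reference,
(ii) >= 1 kb from the nearest protein-coding gene, (iii) called
non-coding by at least one predictor, (iv) >= 200 nt of summed exon
length, and (v) multi-exonic.  The length/exon exclusion is read
disjunctively (exclude if short OR mono-exonic): the conjunctive reading
would retain long single-exon transcripts, contradicting the >200-nt
multi-exon definition used throughout; the boundary itself retains
exactly-200-nt transcripts.  The non-coding clause follows the stated
"either" (the coding call uses "both"); a `noncoding_mode="both"` switch
is provided.  Distances exclude opposite-strand genes the candidate
overlaps — otherwise every antisense transcript would sit at distance 0
and the antisense clause of rule (i) could never fire.  Every excluded
transcript carries an audit of the exact rules it failed; survivors and
rejections partition the input.

## Synthetic data

`simulate_counts` draws from the generative model above on the balanced
design: 2 sexes x 2 age levels x n individuals per cell (2 by default,
matching the eight-animal study design), each individual observed in all
R regions and s replicates (s = 1 by default — the dataset has one
sample per region per individual).  Defaults: baseline mean 100 counts,
theta = 5, individual random-effect SD 0.3, per-gene region-effect SD
0.3 — chosen as a realistic bulk-RNA-seq regime in which the variance is
several-fold the mean.  R defaults to 4 in the analysis runs: the
number of regions entering the covariate model is left free here (the
study's own model display and region panel differ on it), and the
permutation machinery is invariant to R.  Effect genes are a seeded
random subset of round(fraction x G) genes; truth flags are returned.

`simulate_linked_signals` plants bivariate-normal pairs with expected
correlation target_r through a shared latent factor; cross-pairs are
independent.  `simulate_annotations` builds disjoint 3-exon loci and
derives an assembled set by breaking chosen exon-boundary subsets so the
planted exon- and intron-level exact-match sensitivities are hit
exactly (up to one transcript's granularity).  Full decoupling is
structurally impossible at the corners — matching all exons forces all
introns, and matching all introns forces the middle exon — and such
combinations raise an error rather than being silently approximated.

What the synthetic data does **not** emulate: library-size variation and
compositional bias, gene-length and GC effects, correlated gene-gene
structure beyond the planted modules/factors, read-level artifacts,
zero-inflation, and realistic genome geometry (annotation loci are
regular and disjoint).  Passing tests demonstrate the inferential
machinery is calibrated and recovers planted structure under the model's
own assumptions; they do not certify performance on real libraries.

## Problem sizes and numerical choices

The statistical acceptance checks run at desk scale: the covariate
pipeline's type-I check uses G = 200 genes x 3 seeds and the effect-
recovery check G = 200 x 2 seeds (R = 4 regions, 18 refits per gene
each), parameter recovery uses G = 500 single fits, link recovery 1,000
planted + 10,000 null pairs, and the empirical-null check n = 10,000
z-values — sizes chosen so the full suite completes in minutes on one
CPU while leaving the acceptance bands untouched.

Numerical details: eta is clipped at ±30 inside IRLS; theta is profiled
on log-scale in [e^-6, e^14] and sigma^2 in [e^-18, e^6]; the truncated-
normal MLE starts from the central sample moments and uses Nelder-Mead
with fatol 1e-9; BH adjustment and chi-square/t/normal tails come from
statsmodels/scipy.  All-zero genes raise a degenerate-fit error;
rank-deficient designs are rejected up front; zero-variance module genes
are dropped with a warning and an all-constant module is an error.

## Known limitations

* The Laplace approximation with 8 individuals gives slightly
  anti-conservative Wald tests for strong effects; the permutation null
  absorbs most, but not all, of this at selection time.
* sigma^2 is estimated by ML (not REML) and is biased low at this number
  of individuals; the covariate contrasts themselves are unbiased to
  within the tested 10%.
* The empirical-null estimator assumes the central window is dominated
  by nulls; it degrades when alternatives exceed roughly a quarter of
  genes or sit near zero.
* The fdrci-style confidence interval around the FDR estimate is not
  implemented (point estimates only), and module discovery, peak
  calling, differential-peak testing, and coding-potential prediction
  are consumed as inputs, never re-implemented.
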