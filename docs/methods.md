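# Methods

This package reimplements, on synthetic data, a complete epigenome-wide
association study (EWAS) meta-analysis of chronological age in human skeletal
muscle methylomes, together with a muscle epigenetic clock. This note
documents the statistical models, the choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not establish.

## Per-cohort EWAS

Each cohort is analysed separately (cohorts differ in age distribution,
array coverage and design, so joint normalization would confound age with
dataset). Per CpG, the methylation beta value (fraction methylated, in
[0, 1]) is regressed on age with adjustment for sex, BMI, diabetes status,
batch and time point wherever the cohort records them; covariates that are
absent, entirely missing or constant in a cohort are dropped with a warning,
and samples missing a retained covariate are excluded (complete case, never
imputed). Effects are reported on the beta scale — i.e. methylation
fraction per year — because that is the interpretable unit ("% methylation
per decade"); an M-value option (`scale="m"`) exists but is off by default.

**Repeated measures.** Cohorts with several samples per subject (or twin
pairs) are handled with a single consensus within-block correlation: per-probe
intraclass correlations of OLS residuals (one-way ANOVA by subject/twin-pair
block) are combined by a 15%-trimmed mean on the Fisher-z scale, and every
probe is then refit by GLS under the exchangeable-correlation model with that
consensus rho (analytic block whitening). With rho = 0 this reduces exactly
to OLS, which the tests assert at 1e-10.

**Variance moderation.** Residual variances are shrunk toward a scaled
inverse chi-square prior fitted by matching the first two moments of log s^2
(digamma/trigamma matching; the trigamma inverse is solved by Newton
iteration). The posterior variance is (d0 s0^2 + d s^2)/(d0 + d) and the
moderated t has d0 + d degrees of freedom. When the log-variance moments
imply no hypervariability the prior degrees of freedom are infinite and all
probes share the pooled variance. Probes with zero residual variance or too
few usable samples are flagged degenerate: their effect is reported but
their p-value is missing and they are excluded from null fitting.

**Empirical-null correction (bias and inflation).** Unmeasured confounding
shifts and scales the null distribution of EWAS test statistics. Moderated-t
p-values are converted to probit z-scores (signed normal quantiles), and a
three-component Gaussian mixture is fit by EM: a free central null component
(mu0, sigma0) plus one negative-mean and one positive-mean alternative whose
standard deviations are bounded below by sigma0 and whose means are kept at
least 2 sigma0 away from mu0. The 2-sigma separation matters: without it the
alternative components absorb ordinary null tail mass and sigma0 is
underestimated by ~5-7% on pure-null data, which inflates type-I error; with
it, recovery on a mu0 x sigma0 grid with 10% contamination is within ±0.03
(bias) and ±0.05 (inflation) at 50 000 z-scores. Ten random restarts are
run and the best likelihood kept; if every restart fails, a robust
median/MAD null is used. Both the statistics and the effect sizes are
corrected (b' = b − mu0·se, se' = sigma0·se), so the meta-analysis consumes
corrected uncertainties, not just corrected p-values.

## Meta-analysis

Fixed-effects inverse-variance weighting per CpG: w_i = 1/se_i^2,
b_meta = Σ w b / Σ w, se_meta = (Σ w)^(-1/2), two-sided normal p. Only CpGs
with finite corrected estimates in at least 6 of the 10 cohorts are
meta-analysed (arrays differ: the 27k/450k/EPIC-like coverage subsets mean
the probe overlap is imperfect). Cochran's Q and I^2 = max(0, (Q−(k−1))/Q)
are reported per CpG but never used to filter. Benjamini-Hochberg FDR is
computed once over the coverage-filtered universe; CpGs with q < 0.005 are
DMPs. Direction comes from the sign of b_meta; an exactly-zero effect (a
measure-zero tie) counts as hypermethylated, documented because the hypo/hyper
percentages must sum to 100. Sensitivity re-runs accept either a set of
cohort ids to drop or a sample predicate (e.g. remove all diabetic samples),
and report the correlation of meta-effects plus a DMP-call cross-tab against
the full run.

## DMR calling

Squared corrected meta z-scores (chi-square with 1 df under the null) are
smoothed along each chromosome with a Gaussian kernel, sigma = lambda/C with
lambda = 1000 bp and C = 2. The kernel is truncated at 3 sigma for
tractability; the truncation is tested against the full kernel on fixtures
whose probe clusters are separated by much more than 3 sigma. The smoothed
statistic S_i = Σ K z^2 / Σ K is referred to a scaled chi-square by
two-moment (Satterthwaite) matching: nu_i = (Σ K)^2 / Σ K^2 and
p_i = P(chi2_nu > nu S). Smoothed p-values are BH-corrected over all probes;
CpGs with smoothed FDR < 0.005 are chained greedily, starting a new region
when the gap exceeds lambda (a gap of exactly lambda stays in the region),
and regions need at least 2 CpGs (a one-CpG "region" is just a DMP).
Candidate regions must pass all three statistics below 0.005 to be emitted:

- Fisher combination of member meta p-values (chi-square with 2m df),
  BH-adjusted **across candidate regions** — the multiplicity interpretation
  adopted here, since candidates are data-selected;
- Stouffer combination z_S = Σ z/√m of the signed meta z-scores, two-sided;
- the harmonic mean of the member FDRs.

The region effect is the inverse-variance-weighted mean of member
meta-effects and fixes the hypo/hyper label; mixed-sign member counts are
retained in the output for transparency. On the standard benchmark (50
spiked blocks of 3-8 CpGs at 0.0008 beta/yr among 10 000 probes, ten
cohorts) the caller recovers >= 80% of blocks with <= 2 false regions and
>= 95% direction concordance; on null simulations it emits on average
<= 0.1 region per replicate.

## Enrichment and integration

**Context enrichment** counts CpGs (the analysed, coverage-filtered probes)
as members of hypo-DMRs, hyper-DMRs, or neither, cross-tabulated against
CpG-island context (island / shore <= 2 kb / shelf 2-4 kb / open sea > 4 kb),
chromatin state, or TF-binding class (CTCF / EZH2 / both / none), and runs a
Pearson chi-square with per-cell residuals (O−E)/√E. CpG-level counting is
used because it makes the margins well defined; category levels with
expected count < 1 are pooled into "other".

**Gene-set enrichment** corrects for the CpG-count bias: genes with more
probes are more likely to harbour a DMR by chance, and functional categories
have correlated gene sizes, so a naive hypergeometric test inflates badly
(the calibration benchmark measures >20% rejections of null sets at the 5%
level). The per-gene selection weight is the empirical probability of being
a DMG as an isotonic (monotone) function of CpG count; each set's odds
parameter is the ratio of mean weights inside versus outside the set, and
the p-value is the Wallenius noncentral hypergeometric upper tail. With
equal weights this reduces exactly to the central hypergeometric (checked
against exhaustive enumeration). The single-odds Wallenius approximation is
mildly conservative under strong within-set weight heterogeneity; the
calibration benchmark shows near-nominal type-I (~0.02-0.05).

**Multi-omic overlap.** A gene with >= 1 annotated DMR is a differentially
methylated gene (DMG); gene annotation includes body/promoter probes and
enhancer-linked genes. DMGs are crossed with external DE lists in 2x2
chi-square tests over an explicit gene universe (the genes with >= 1
analysed CpG); the odds ratio uses the Haldane 0.5 correction when a cell is
empty. Direction classification votes per (DMR, DE gene) pair: "negative"
when expression and methylation change in opposite directions, stratified by
whether the DMR's member CpGs lie mostly in active-transcription states
(Tx/TxWk/EnhG).

## Epigenetic clock

Datasets are reduced to shared probes and calibrated to a gold-standard
reference — the dataset with the widest age range, the natural analog of
fixing the most age-diverse cohort. Calibration is a per-sample
beta-mixture quantile map: each sample's values are fit with a 3-component
beta mixture (EM with a moment-matching M-step, deterministic tercile
initialization plus 4 jittered restarts, best likelihood kept; tercile
moment fit as the non-convergence fallback), each value is assigned to its
most probable component, and mapped through the component CDF onto the
reference component's inverse CDF. The map is monotone within components,
near-identity when target and reference distributions agree (max deviation
< 0.01 at 20 000 probes per sample), and idempotent to < 1e-3 median change.

Age enters through F(age) = log(age+1) − log(adult_age+1) below the adult
knot and (age − adult_age)/(adult_age+1) above, with adult_age = 20 years
(the standard human knot; exposed in the model and stored with it). The
clock is an elastic net on F(age) with L1/L2 mixing 0.5 and penalty strength
chosen by internal 10-fold CV over a 30-value path (mixing and path length
are this package's hyperparameter defaults). Features are standardized for
the fit — the convention of penalized-regression practice — so probes with
compressed variance near the methylation extremes are not penalized out of
the model; coefficients are stored back on the beta-value scale. On the
clock benchmark, standardization is what keeps probe selection precise
(>= 90% of selected probes carry true age signal, versus ~40% when
penalizing raw beta values). Only nonzero-coefficient probes are retained. Prediction inverts the transform exactly; model probes absent
from a dataset are imputed from their stored training means, with an error
above 20% missing.

Accuracy is estimated by leave-one-dataset-out cross-validation. The
held-out dataset influences nothing on the training side: the reference
choice, calibration summary and penalty selection all use training datasets
only. Per-sample target mixtures are fit on each sample's own values alone,
which makes them reusable across folds without leakage. A held-out dataset
with constant age has undefined correlation (reported missing); constant
predictions (an intercept-only clock, as on pure-noise data) are scored
r = 0, since they carry no age association.

## Synthetic data: what it emulates, and what it does not

The generator emits 10 cohorts mirroring the heterogeneity of real muscle
methylome studies: sample sizes 22-282 (~905 samples), cohort-specific age
windows spanning 18-89 years, ~71% male overall, 27k/450k/EPIC-like probe
coverage (0.4/0.8/1.0 of the probe panel), repeated measures (1-4 samples
per subject), one twin cohort, batch structure, and age-BMI confounding
(r = 0.3 within cohorts by default, always adjusted in the EWAS). Methylation
is generated on the latent logistic scale (see the module docstring for the
emission model) with residual sd 0.15, subject sd 0.08 and batch sd 0.05 —
chosen to give beta-scale residual sds of a few percent at mid-methylation,
typical of array data. Baselines come from a three-component logit mixture
so the classic bimodal beta distribution emerges. True age effects are
spiked in blocks of 2-10 adjacent CpGs (i.e. within CpG-island clusters,
where adjacency at < 500 bp exists), at 0.0008 beta/year (0.8%/decade) by
default with ±20% jitter, 57% of blocks negative — the realistic effect
regime for muscle ageing. Truth slopes are recorded on the beta scale via
the delta method at the probe baseline.

The generator does **not** emulate: probe-level spatial correlation beyond
the spiked blocks (neighbouring null CpGs are independent, so the DMR
false-positive benchmark is friendlier than real data, where correlated
nulls can chain); cell-composition heterogeneity; sex-chromosome dosage;
array measurement error structure (type I/II probe chemistry); or genuine
annotation (toy chromosomes, tiled states). Passing benchmarks therefore
establishes internal statistical correctness — calibration, error control,
recovery under the assumed model — not performance on real arrays.

## Numerical choices and degenerate inputs

- Beta values are clipped to (0.001, 0.999) at emission and (1e-6, 1−1e-6)
  inside mixture fits; p-values are clipped away from 0 before logs.
- Zero residual variance is detected at s^2 <= 1e-16 (beta-scale variances
  of real probes are orders of magnitude larger).
- EM stopping: relative log-likelihood change < 1e-8 per observation
  (Gaussian mixture) or < 1e-6 (beta mixture); restart counts 10 and 5.
- Chromatin-state ties (overlapping intervals) resolve to the interval with
  the smallest start; probes on chromosomes absent from the state track get
  the quiescent state and are flagged imputed.
- Coordinates are 0-based half-open internally; BED is passed through
  untouched; probe TSV positions are 1-based (manifest convention) and
  converted on ingest/export. Strand is ignored throughout (beta values are
  strand-symmetric summaries).
- All randomness flows from one root seed, split per cohort by hashing the
  dataset id, so results are independent of cohort iteration order and
  bit-reproducible.

## Benchmark problem sizes

The standard conditions used by the test suite and the reproduction script:
10 000 probes and the ten standard cohorts for null calibration (20
replicates), FDR control (20 replicates of a 90/10 null/spiked mixture) and
DMR recovery (50 blocks); 50 000 z-scores for the 3x3 empirical-null grid;
2 000 genes / 400 tilted null sets for gene-set calibration and 5 000 genes
/ 200 replicates for overlap calibration; 8 cohorts x 5 000 probes with
~300 clock CpGs for the LODO clock benchmark plus a pure-noise control.

## Known limitations

- The empirical-null EM assumes a well-separated alternative; signal milder
  than ~2 null sds is absorbed into the null component (by construction),
  which is the conservative direction for error control.
- The Wallenius single-odds approximation understates within-set weight
  heterogeneity; its conservatism grows with set-size heterogeneity.
- The BH adjustment of the Fisher region statistic across data-selected
  candidate regions is one defensible multiplicity interpretation among
  several; the raw Fisher p is retained in the output.
- The clock benchmark's near-perfect correlations reflect the generator's
  clean shared signal; real muscle clocks face between-study technical
  variation that calibration only partly removes.
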