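# metamethyl

An end-to-end, tested reimplementation of an epigenome-wide association
study (EWAS) meta-analysis of chronological age in human skeletal muscle
methylomes, together with a muscle epigenetic clock — exercised on a
synthetic multi-cohort methylome generator so every stage runs and is
verifiable without any controlled-access data.

**Who it is for.** Researchers who want a transparent, reproducible version
of the muscle-ageing methylome analysis stack: per-cohort EWAS with
empirical-null correction, fixed-effects meta-analysis across heterogeneous
cohorts, kernel-smoothed region calling, bias-corrected enrichment,
multi-omic overlap, and a calibrated elastic-net age predictor.

## The statistics

Per cohort, each CpG's beta value (methylation fraction) is regressed on age
with covariate adjustment and, for repeated measures, GLS under a consensus
within-subject correlation. Variances are moderated by empirical-Bayes
shrinkage; the probit z-scores are corrected for bias and inflation with an
empirical-null Gaussian-mixture fit (z' = (z − μ₀)/σ₀). Cohorts are combined
per CpG by inverse-variance weighting,

    w_i = 1/se_i²,  b_meta = Σ w_i b_i / Σ w_i,  se_meta = (Σ w_i)^(−1/2),

with Cochran's Q and I² reporting heterogeneity, over CpGs present in ≥ 6 of
the 10 cohorts; CpGs at Benjamini–Hochberg FDR < 0.005 are differentially
methylated positions (DMPs). DMRs come from Gaussian-kernel smoothing of
z² (λ = 1000 bp, σ = λ/2) with Satterthwaite chi-square p-values, gap-based
aggregation, and three region statistics (Fisher, Stouffer, harmonic-mean
FDR) all thresholded at 0.005. Gene-set enrichment corrects the CpG-count
bias with a Wallenius noncentral hypergeometric test. The clock is an
elastic net on transformed age F(age) after beta-mixture quantile
calibration to a gold-standard dataset, evaluated by leave-one-dataset-out
(LODO) cross-validation. Details and design rationale: `docs/methods.md`.

## Worked example

The numbered drivers under `analysis/` run the whole study on the standard
synthetic conditions (ten cohorts emulating published muscle studies, ~905 samples, 10 000 probes,
50 spiked age-effect regions at ~0.8% methylation change per decade):

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_ewas_meta.py       --seed 1
python analysis/03_call_dmrs.py       --seed 1
python analysis/04_enrichment_integration.py --seed 1
python analysis/05_muscle_clock.py    --seed 1
```

With `--seed 1` this prints (abridged):

```
simulated 10 cohorts, 905 samples, 10000 probes; 50 spiked regions (250 CpGs with a true age effect)
cohortB: rho=0.20 bias=-0.018 inflation=1.027
...
meta-analyzed 10000 CpGs present in >= 6 cohorts
237 DMPs at FDR < 0.005: 68% hypo / 32% hyper; mean change 0.80%/decade (hypo), 0.86%/decade (hyper)
50 DMRs (29 hypo / 21 hyper) spanning 90 genes
recovered 100% of spiked blocks with 0 false regions; direction concordance 100%
island_context: chi2=901.1 p=2.16e-191 (significant)
mrna: 26% of DE genes are DMGs (chi2=62.6, p=2.55e-15, OR=5.52)
negative methylation-expression relationship in 61% of votes
LODO: mean r = 0.99, median error = 1.0 years; final clock uses 117 CpGs (91% carrying true age signal)
```

Reading these numbers: the per-cohort inflation factors sit near 1 (the
empirical-null correction leaves calibrated cohorts almost untouched); the
237 DMPs recover the spiked ~0.8%/decade effect size; all 50 spiked regions
are found with no false DMRs; DMR CpGs are island-enriched (the spiked
blocks live in CpG-dense clusters); DMGs overlap the simulated
differential-expression lists far beyond chance with the configured ~63%
negative methylation–expression relationship; and the clock predicts
held-out cohorts' ages to ~1 year median error, selecting almost only CpGs
that truly carry age signal. Tables land in `results/`, large matrices in
`scratch/`.

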