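"""Seeded synthetic benchmarks exercising every pipeline stage.

Each routine simulates data under stated conditions, runs the pipeline, and
returns summary metrics.  They are shared between the test suite and the
reproduction script so both always measure the same quantities.  Problem
sizes (10 000 probes, the ten standard cohorts, 20 replicates for the
replicated checks, 50 spiked blocks, 8 clock cohorts with 5 000 probes)
are the package's standard benchmark conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import MethylationDataset
from .dmr_calling import DmrConfig
from .enrichment_integration import geneset_enrichment, omics_overlap
from .epigenetic_clock import lodo_evaluate
from .ewas import estimate_empirical_null
from .meta_analysis import call_dmps
from .pipeline import run_pipeline
from .synthetic_data import (
    CohortSpec,
    SimulationConfig,
    SimulationTruth,
    build_toy_annotation,
    simulate_de_list,
    simulate_multicohort,
)

__all__ = [
    "null_calibration",
    "empirical_null_grid",
    "dmr_benchmark",
    "fdr_benchmark",
    "enrichment_calibration",
    "overlap_calibration",
    "clock_benchmark",
    "clock_cohorts",
]


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------


def null_calibration(
    seed: int, n_replicates: int = 20, n_probes: int = 10_000
) -> dict:
    """Replicated null simulations (no age effect anywhere).

    Checks that per-cohort bias/inflation-corrected p-values are uniform,
    that their 0.05 type-I rate is nominal, and that DMP and DMR calls at
    FDR 0.005 are essentially absent.
    """
    type_i = []
    ks_p = None
    n_dmps = []
    n_dmrs = []
    config = SimulationConfig(n_probes=n_probes, slope_scale=0.0, seed=_child_seed(seed, 99))
    annotation, _, _ = build_toy_annotation(config)
    for rep in range(n_replicates):
        rep_seed = _child_seed(seed, 100 + rep)
        datasets, _ = simulate_multicohort(annotation, config, seed=rep_seed)
        result = run_pipeline(datasets, annotation, seed=rep_seed)
        pvals = np.concatenate(
            [r.table["p_corr"].dropna().to_numpy() for r in result.ewas]
        )
        type_i.append(float(np.mean(pvals < 0.05)))
        if rep == 0:
            # KS uniformity on the largest cohort's corrected p-values
            big = max(result.ewas, key=lambda r: r.table["p_corr"].notna().sum())
            ks_p = float(stats.kstest(big.table["p_corr"].dropna(), "uniform").pvalue)
        n_dmps.append(len(result.dmps.probes))
        n_dmrs.append(0 if result.dmrs is None else len(result.dmrs))
    return {
        "ks_p": ks_p,
        "type_i": float(np.mean(type_i)),
        "total_dmps": int(np.sum(n_dmps)),
        "mean_dmps": float(np.mean(n_dmps)),
        "mean_dmrs": float(np.mean(n_dmrs)),
        "n_replicates": n_replicates,
        "n_probes": n_probes,
    }


# ---------------------------------------------------------------------------
# empirical-null recovery
# ---------------------------------------------------------------------------


def empirical_null_grid(
    seed: int,
    n: int = 50_000,
    pi0: float = 0.9,
    mus: tuple[float, ...] = (-0.2, 0.0, 0.2),
    sigmas: tuple[float, ...] = (1.0, 1.3, 1.6),
) -> dict:
    """Recover known bias/inflation from contaminated z-score vectors.

    Each grid point draws ``pi0`` null mass from N(mu0, sigma0^2) plus
    symmetric alternative mass shifted by +-4 sigma0; reports the largest
    absolute estimation errors over the grid.
    """
    rng = np.random.default_rng(_child_seed(seed, 200))
    rows = []
    for mu0 in mus:
        for s0 in sigmas:
            n_null = int(round(pi0 * n))
            n_alt = (n - n_null) // 2
            z = np.concatenate(
                [
                    rng.normal(mu0, s0, n_null),
                    rng.normal(mu0 - 4 * s0, s0, n_alt),
                    rng.normal(mu0 + 4 * s0, s0, n - n_null - n_alt),
                ]
            )
            mu_hat, s_hat, pi_hat = estimate_empirical_null(
                z, seed=_child_seed(seed, 201)
            )
            rows.append(
                {
                    "mu0": mu0,
                    "sigma0": s0,
                    "mu_hat": mu_hat,
                    "sigma_hat": s_hat,
                    "pi_hat": pi_hat,
                    "mu_err": abs(mu_hat - mu0),
                    "sigma_err": abs(s_hat - s0),
                }
            )
    grid = pd.DataFrame(rows)
    return {
        "grid": grid,
        "max_mu_err": float(grid["mu_err"].max()),
        "max_sigma_err": float(grid["sigma_err"].max()),
        "n": n,
    }


# ---------------------------------------------------------------------------
# DMR recovery benchmark
# ---------------------------------------------------------------------------


def dmr_benchmark(seed: int, n_probes: int = 10_000, n_regions: int = 50) -> dict:
    """Spiked-block recovery: 50 blocks of 3-8 CpGs at 0.8%/decade.

    Reports block-level sensitivity, false DMR count, and direction
    concordance with the spiked signs, plus the full pipeline objects for
    downstream reuse.
    """
    run_seed = _child_seed(seed, 300)
    config = SimulationConfig(
        n_probes=n_probes,
        n_spiked_regions=n_regions,
        dmr_block_len=(3, 8),
        slope_scale=0.0008,
        seed=run_seed,
    )
    annotation, tracks, gene_map = build_toy_annotation(config)
    datasets, truth = simulate_multicohort(annotation, config)
    result = run_pipeline(datasets, annotation, seed=run_seed)
    dmrs = result.dmrs

    def overlaps(region, emitted) -> pd.DataFrame:
        return emitted[
            (emitted["chrom"] == region.chrom)
            & (emitted["end"] > region.start)
            & (emitted["start"] < region.end)
        ]

    hits = 0
    concordant = 0
    recovered = 0
    for region in truth.spiked_regions.itertuples():
        hit = overlaps(region, dmrs)
        if len(hit):
            hits += 1
            recovered += 1
            called_sign = -1 if hit.iloc[0]["direction"] == "hypo" else 1
            if called_sign == region.sign:
                concordant += 1
    truth_iv = truth.spiked_regions
    false = 0
    for row in dmrs.itertuples():
        m = truth_iv[
            (truth_iv["chrom"] == row.chrom)
            & (truth_iv["end"] > row.start)
            & (truth_iv["start"] < row.end)
        ]
        if len(m) == 0:
            false += 1
    return {
        "sensitivity": hits / len(truth.spiked_regions),
        "false_dmrs": false,
        "direction_concordance": concordant / recovered if recovered else np.nan,
        "n_dmrs": len(dmrs),
        "result": result,
        "truth": truth,
        "annotation": annotation,
        "tracks": tracks,
        "gene_map": gene_map,
        "config": config,
    }


# ---------------------------------------------------------------------------
# FDR control
# ---------------------------------------------------------------------------


def fdr_benchmark(
    seed: int, n_replicates: int = 20, n_probes: int = 10_000
) -> dict:
    """Mixed 90% null / 10% spiked simulations; FDP of q < 0.005 DMP calls."""
    false_calls = 0
    total_calls = 0
    config = SimulationConfig(
        n_probes=n_probes,
        frac_age_cpgs=0.10,
        slope_scale=0.0008,
        seed=_child_seed(seed, 399),
    )
    annotation, _, _ = build_toy_annotation(config)
    for rep in range(n_replicates):
        rep_seed = _child_seed(seed, 400 + rep)
        datasets, truth = simulate_multicohort(annotation, config, seed=rep_seed)
        result = run_pipeline(datasets, annotation, call_regions=False, seed=rep_seed)
        called = result.dmps.probes
        truth_null = truth.beta_slope.reindex(called) == 0
        false_calls += int(truth_null.sum())
        total_calls += len(called)
    return {
        "fdp": false_calls / total_calls if total_calls else 0.0,
        "false_calls": false_calls,
        "total_calls": total_calls,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# enrichment calibration
# ---------------------------------------------------------------------------


def enrichment_calibration(
    seed: int,
    n_genes: int = 2_000,
    n_selected: int = 300,
    n_sets: int = 400,
    set_size: int = 100,
) -> dict:
    """Gene-set test calibration under pure CpG-count-driven selection.

    Genes get CpG counts between 1 and 60; the "DMG" selection is drawn with
    probability proportional to the count, so any enrichment a naive test
    sees is bias.  Null sets mimic real functional categories, whose member
    genes have correlated sizes: each set samples genes with its own
    count-dependent tilt (toward CpG-rich or CpG-poor genes), while staying
    independent of selection given the counts.  They are tested with the
    bias-corrected Wallenius test and the uncorrected hypergeometric tail.
    """
    rng = np.random.default_rng(_child_seed(seed, 500))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    counts = pd.Series(
        np.concatenate(
            [
                rng.integers(1, 6, int(0.55 * n_genes)),
                rng.integers(6, 21, int(0.30 * n_genes)),
                rng.integers(21, 61, n_genes - int(0.55 * n_genes) - int(0.30 * n_genes)),
            ]
        ).astype(float),
        index=genes,
    )
    w = counts.to_numpy() / counts.sum()
    selected_idx = rng.choice(n_genes, size=n_selected, replace=False, p=w)
    dmg_genes = [genes[i] for i in selected_idx]
    gene_sets = {}
    for j in range(n_sets):
        tilt = rng.uniform(-1.0, 1.0)  # per-set preference for CpG-rich/poor genes
        pw = counts.to_numpy() ** tilt
        pw = pw / pw.sum()
        members = rng.choice(n_genes, size=set_size, replace=False, p=pw)
        gene_sets[f"set{j:03d}"] = [genes[i] for i in members]
    corrected = geneset_enrichment(dmg_genes, counts, gene_sets, genes)
    # naive central hypergeometric on the same tables
    naive_p = stats.hypergeom.sf(
        corrected["n_de_in_set"].to_numpy() - 1,
        n_genes,
        corrected["n_set"].to_numpy(),
        n_selected,
    )
    return {
        "type_i_corrected": float(np.mean(corrected["p"] < 0.05)),
        "type_i_uncorrected": float(np.mean(naive_p < 0.05)),
        "n_sets": n_sets,
    }


def overlap_calibration(
    seed: int,
    n_genes: int = 5_000,
    n_dmgs: int = 1_000,
    n_de: int = 500,
    n_replicates: int = 200,
) -> dict:
    """Omics-overlap chi-square: null calibration at odds 1, power at odds 5."""
    rng = np.random.default_rng(_child_seed(seed, 600))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    dmgs = set(rng.choice(genes, size=n_dmgs, replace=False))
    empty_regions = pd.DataFrame(columns=["chrom", "start", "end", "sign", "probe_ids"])
    empty_ann = pd.DataFrame(columns=["genes"])
    truth = SimulationTruth(
        beta_slope=pd.Series(dtype=float),
        spiked_regions=empty_regions,
        true_dmgs=dmgs,
        cohort_probes={},
        injected_bias={},
        injected_inflation={},
    )
    null_rej = 0
    power_rej = 0
    for rep in range(n_replicates):
        de_null = simulate_de_list(
            truth, empty_ann, genes, odds=1.0, n_de=n_de, seed=_child_seed(seed, 700 + rep)
        )
        de_alt = simulate_de_list(
            truth, empty_ann, genes, odds=5.0, n_de=n_de, seed=_child_seed(seed, 900 + rep)
        )
        null_rej += omics_overlap(dmgs, de_null.index, genes).p < 0.05
        power_rej += omics_overlap(dmgs, de_alt.index, genes).p < 0.005
    return {
        "null_rejection_rate_0p05": null_rej / n_replicates,
        "power_odds5_at_0p005": power_rej / n_replicates,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# clock benchmark
# ---------------------------------------------------------------------------


def clock_cohorts() -> tuple[CohortSpec, ...]:
    """Eight single-time-point cohorts with varied but overlapping age windows."""
    return (
        CohortSpec("clockA", "EPIC", 60, 1, 18, 89, 47.0, 20.0, 0.7, 1.0),
        CohortSpec("clockB", "EPIC", 55, 1, 20, 77, 55.0, 14.0, 0.6, 1.0),
        CohortSpec("clockC", "450k", 50, 1, 18, 60, 35.0, 11.0, 0.8, 0.9),
        CohortSpec("clockD", "EPIC", 45, 1, 25, 80, 50.0, 15.0, 0.7, 1.0),
        CohortSpec("clockE", "450k", 45, 1, 18, 70, 40.0, 14.0, 0.5, 0.9),
        CohortSpec("clockF", "EPIC", 40, 1, 30, 89, 58.0, 15.0, 0.8, 1.0),
        CohortSpec("clockG", "EPIC", 40, 1, 18, 55, 33.0, 10.0, 0.9, 1.0),
        CohortSpec("clockH", "450k", 35, 1, 22, 85, 52.0, 17.0, 0.6, 0.9),
    )


def clock_benchmark(
    seed: int, n_probes: int = 5_000, with_noise_control: bool = True
) -> dict:
    """LODO clock accuracy on 8 cohorts with ~300 true clock CpGs.

    The signal condition spikes ~300 CpGs at 0.1%/year; the control uses the
    identical cohorts with no age effect anywhere, where the clock should
    carry no age association.
    """
    run_seed = _child_seed(seed, 1000)
    config = SimulationConfig(
        cohorts=clock_cohorts(),
        n_probes=n_probes,
        frac_age_cpgs=0.06,
        dmr_block_len=(2, 10),
        slope_scale=0.001,
        seed=run_seed,
    )
    annotation, _, _ = build_toy_annotation(config)
    datasets, truth = simulate_multicohort(annotation, config)
    evaluation = lodo_evaluate(datasets, seed=run_seed)
    # full-data model: fraction of selected probes that carry true age signal
    from .epigenetic_clock import (
        _reference_dataset,
        calibrate_to_reference,
        fit_beta_mixture,
        fit_sample_mixtures,
        train_clock,
    )

    mixtures = fit_sample_mixtures(datasets, run_seed)
    ref_ds = _reference_dataset(datasets)
    ref_vals = ref_ds.beta.to_numpy(float)
    ref_mix = fit_beta_mixture(ref_vals[np.isfinite(ref_vals)], seed=run_seed)
    calibrated = [
        calibrate_to_reference(d, ref_mix, mixtures, seed=run_seed) for d in datasets
    ]
    model = train_clock(calibrated, seed=run_seed, calibration_reference=ref_mix.to_dict())
    true_clock_cpgs = set(truth.beta_slope.index[truth.beta_slope != 0])
    precision = (
        np.mean([p in true_clock_cpgs for p in model.probe_ids])
        if model.probe_ids
        else np.nan
    )
    out = {
        "mean_r": evaluation.mean_r,
        "median_error": evaluation.median_error,
        "selection_precision": float(precision),
        "n_selected": len(model.probe_ids),
        "n_true_clock_cpgs": len(true_clock_cpgs),
        "evaluation": evaluation,
        "truth": truth,
        "datasets": datasets,
        "model": model,
        "n_probes": n_probes,
    }
    if with_noise_control:
        null_config = SimulationConfig(
            cohorts=clock_cohorts(), n_probes=n_probes, slope_scale=0.0, seed=run_seed
        )
        null_ann, _, _ = build_toy_annotation(null_config)
        null_data, _ = simulate_multicohort(null_ann, null_config)
        null_eval = lodo_evaluate(null_data, seed=run_seed)
        out["noise_mean_r"] = null_eval.mean_r
        out["noise_median_error"] = null_eval.median_error
    return out
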