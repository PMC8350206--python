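"""End-to-end orchestration: per-cohort EWAS -> meta-analysis -> DMRs."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation_io import MethylationDataset
from .dmr_calling import DmrConfig, call_dmrs
from .ewas import DEFAULT_COVARIATES, EwasResult, run_ewas
from .meta_analysis import (
    DMP_FDR_DEFAULT,
    MIN_COHORTS_DEFAULT,
    DmpCall,
    MetaResult,
    call_dmps,
    run_meta_analysis,
)

__all__ = ["PipelineResult", "run_pipeline", "exclude_samples"]


def exclude_samples(datasets, predicate):
    """Drop samples matching ``predicate(SampleRecord) -> bool`` from every
    cohort (for sensitivity re-runs such as removing diabetic samples);
    cohorts left without samples are dropped entirely."""
    out = []
    for ds in datasets:
        keep = [s.sample_id for s in ds.samples if not predicate(s)]
        if keep:
            out.append(ds.subset_samples(keep))
    return out


@dataclass
class PipelineResult:
    ewas: list[EwasResult]
    meta: MetaResult
    dmps: DmpCall
    dmrs: pd.DataFrame | None


def run_pipeline(
    datasets: list[MethylationDataset],
    annotation: pd.DataFrame | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    min_cohorts: int = MIN_COHORTS_DEFAULT,
    q_threshold: float = DMP_FDR_DEFAULT,
    dmr_config: DmrConfig = DmrConfig(),
    call_regions: bool = True,
    seed: int = 0,
) -> PipelineResult:
    """Run the EWAS meta-analysis pipeline on a list of cohorts.

    DMR calling requires a probe annotation; pass ``call_regions=False`` (or
    no annotation) to stop at DMPs.
    """
    ewas_results = [run_ewas(ds, covariates, seed=seed) for ds in datasets]
    meta = run_meta_analysis(ewas_results, min_cohorts=min_cohorts)
    dmps = call_dmps(meta, q_threshold)
    dmrs = None
    if call_regions and annotation is not None:
        dmrs = call_dmrs(meta, annotation, dmr_config)
    return PipelineResult(ewas=ewas_results, meta=meta, dmps=dmps, dmrs=dmrs)
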