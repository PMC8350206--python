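"""Shared fixtures: tiny hand-built objects plus one seeded signal simulation."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from metamethyl.annotation_io import GenomicTrack, MethylationDataset, SampleRecord
from metamethyl.pipeline import run_pipeline
from metamethyl.synthetic_data import (
    SimulationConfig,
    build_toy_annotation,
    simulate_multicohort,
)

logging.getLogger("metamethyl").setLevel(logging.ERROR)


@pytest.fixture()
def toy_dataset() -> MethylationDataset:
    """Four samples, three probes, ages spanning three decades."""
    beta = pd.DataFrame(
        {
            "s1": [0.50, 0.20, 0.90],
            "s2": [0.52, 0.25, 0.88],
            "s3": [0.54, 0.22, 0.91],
            "s4": [0.56, 0.27, 0.89],
        },
        index=["cgA", "cgB", "cgC"],
    )
    samples = [
        SampleRecord("s1", "u1", 20.0),
        SampleRecord("s2", "u2", 30.0),
        SampleRecord("s3", "u3", 40.0),
        SampleRecord("s4", "u4", 50.0),
    ]
    return MethylationDataset("toy", beta, samples)


@pytest.fixture()
def toy_tracks():
    """One island, two overlapping states, one CTCF site on chr1."""
    islands = GenomicTrack("islands")
    islands.add("chr1", 1_000, 1_500)
    states = GenomicTrack("states")
    states.add("chr1", 0, 5_000, "Enh")
    states.add("chr1", 900, 2_000, "TssA")
    ctcf = GenomicTrack("ctcf")
    ctcf.add("chr1", 4_000, 4_200)
    ezh2 = GenomicTrack("ezh2")
    ezh2.add("chr1", 1_000, 1_500)
    return {"islands": islands, "states": states, "ctcf": ctcf, "ezh2": ezh2}


@pytest.fixture(scope="session")
def signal_sim():
    """One seeded multi-cohort simulation with spiked regions, plus its
    pipeline run; shared across meta/DMR/enrichment tests (read-only)."""
    config = SimulationConfig(
        n_probes=4_000,
        n_spiked_regions=30,
        dmr_block_len=(3, 8),
        slope_scale=0.0012,
        frac_hypo=0.6,
        seed=11,
    )
    annotation, tracks, gene_map = build_toy_annotation(config)
    datasets, truth = simulate_multicohort(annotation, config)
    result = run_pipeline(datasets, annotation, seed=11)
    return {
        "config": config,
        "annotation": annotation,
        "tracks": tracks,
        "gene_map": gene_map,
        "datasets": datasets,
        "truth": truth,
        "result": result,
    }


@pytest.fixture(scope="session")
def bimodal_betas():
    """20 000 draws from a classic bimodal methylation mixture."""
    rng = np.random.default_rng(3)

    def draw(n):
        comp = rng.choice(3, size=n, p=[0.4, 0.2, 0.4])
        return np.where(
            comp == 0,
            rng.beta(2, 20, n),
            np.where(comp == 1, rng.beta(5, 5, n), rng.beta(20, 2, n)),
        )

    return draw
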