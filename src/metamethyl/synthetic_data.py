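"""Multi-cohort methylome simulator.

Generates the inputs the analysis assumes without any download: a toy probe
annotation (islands, chromatin states, TF sites, genes), per-cohort beta
matrices with realistic heterogeneity (differing age windows, array coverage,
repeated measures, batches, covariate-age confounding), spiked age-effect
regions of adjacent CpGs, and external differential-expression gene lists.

Emission model
--------------
Methylation is generated on the latent logistic scale per probe ``g`` and
sample ``s``::

    y_gs = alpha_g + beta_g * age_s + gamma_g' cov_s + u_subject(s) + b_batch(s) + eps_gs
    beta_value = sigmoid(y_gs)  clipped to (0.001, 0.999)

with ``eps ~ N(0, noise_sd^2)``.  ``alpha_g`` is drawn from a three-component
mixture so the classic bimodal beta-value distribution emerges.  True age
effects are specified on the beta-value scale (fraction per year, e.g. 0.0008
is 0.8% per decade) and converted to the latent scale at the probe's baseline
via the delta method (``beta_latent = beta_beta / (p (1 - p))``); the recorded
truth slope is the implied beta-scale slope, matching how effect sizes are
reported downstream.

Randomness is one root seed split per cohort by hashing the dataset id, so
results do not depend on cohort iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotation_io import (
    GenomicTrack,
    MethylationDataset,
    SampleRecord,
    annotate_probes,
)

__all__ = [
    "CohortSpec",
    "SimulationConfig",
    "SimulationTruth",
    "default_config",
    "build_toy_annotation",
    "simulate_multicohort",
    "simulate_de_list",
    "simulate_de_lists",
]

_CHROM_STATES = [
    ("TssA", 0.05),
    ("TssFlnk", 0.05),
    ("Tx", 0.15),
    ("TxWk", 0.15),
    ("Enh", 0.10),
    ("EnhG", 0.05),
    ("TssBiv", 0.03),
    ("EnhBiv", 0.03),
    ("ReprPC", 0.09),
    ("Quies", 0.30),
]


@dataclass(frozen=True)
class CohortSpec:
    """Design of one simulated cohort (loosely mirrors real muscle cohorts)."""

    dataset_id: str
    array_label: str  # "27k" / "450k" / "EPIC"
    n_subjects: int
    samples_per_subject: int
    age_min: float
    age_max: float
    age_mean: float
    age_sd: float
    pct_male: float
    coverage_fraction: float
    has_t2d: bool = False
    n_batches: int = 1
    twins: bool = False

    @property
    def n_samples(self) -> int:
        return self.n_subjects * self.samples_per_subject


def _default_cohorts() -> tuple[CohortSpec, ...]:
    # ten cohorts spanning 18-89 years, ~905 samples, ~71% male overall;
    # array coverage emulates 27k/450k/EPIC probe subsets
    return (
        CohortSpec("cohortA", "EPIC", 282, 1, 20, 77, 59.4, 7.9, 0.54, 1.0, has_t2d=True),
        CohortSpec("cohortB", "EPIC", 78, 3, 18, 45, 32.0, 8.1, 0.80, 1.0, n_batches=2),
        CohortSpec("cohortC", "450k", 65, 1, 23, 61, 44.0, 8.2, 0.0, 0.8, has_t2d=True),
        CohortSpec("cohortD", "EPIC", 21, 3, 20, 39, 26.0, 5.9, 1.0, 1.0),
        CohortSpec("cohortE", "EPIC", 28, 2, 23, 58, 38.9, 10.0, 1.0, 1.0),
        CohortSpec("cohortF", "27k", 51, 1, 21, 77, 50.0, 17.0, 1.0, 0.4),
        CohortSpec("cohortG", "450k", 48, 1, 18, 89, 47.0, 26.0, 1.0, 0.8),
        CohortSpec("cohortH", "EPIC", 16, 3, 20, 71, 45.4, 22.3, 1.0, 1.0),
        CohortSpec("cohortI", "EPIC", 9, 4, 19, 39, 29.0, 6.0, 1.0, 1.0),
        CohortSpec("cohortJ", "27k", 22, 1, 53, 80, 68.0, 8.0, 0.45, 0.4, has_t2d=True, twins=True),
    )


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the standard study conditions."""

    cohorts: tuple[CohortSpec, ...] = field(default_factory=_default_cohorts)
    n_probes: int = 10_000
    frac_age_cpgs: float = 0.05
    n_spiked_regions: int | None = None  # overrides frac_age_cpgs when set
    dmr_block_len: tuple[int, int] = (2, 10)
    slope_scale: float = 0.0008  # beta fraction / year (0.8% per decade)
    frac_hypo: float = 0.57
    noise_sd: float = 0.15  # latent-scale residual sd
    batch_sd: float = 0.05
    subject_sd: float = 0.08
    sex_sd: float = 0.05
    bmi_slope_sd: float = 0.003
    t2d_sd: float = 0.05
    time_sd: float = 0.03
    confounding: float = 0.3  # age-BMI correlation within cohorts
    unmeasured_confounder_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_age_cpgs", "frac_hypo"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.slope_scale < 0:
            raise ValueError("slope_scale must be >= 0")
        for c in self.cohorts:
            if not 0 < c.coverage_fraction <= 1:
                raise ValueError(f"{c.dataset_id}: coverage_fraction out of (0,1]")
            if c.samples_per_subject > c.n_samples:
                raise ValueError(f"{c.dataset_id}: repeated measures exceed samples")


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated run, for parameter-recovery tests."""

    beta_slope: pd.Series  # per-probe true slope, beta fraction / year
    spiked_regions: pd.DataFrame  # chrom, start, end, sign, probe_ids
    true_dmgs: set[str]
    cohort_probes: dict[str, pd.Index]
    injected_bias: dict[str, float]
    injected_inflation: dict[str, float]


def _cohort_rng(seed: int, dataset_id: str) -> np.random.Generator:
    key = zlib.crc32(dataset_id.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# toy annotation
# ---------------------------------------------------------------------------


def build_toy_annotation(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, GenomicTrack], dict[str, tuple[str, ...]]]:
    """Lay probes on two toy chromosomes and build matching context tracks.

    Probes are a mixture of island clusters (50-200 bp spacing) and background
    probes (2-20 kb spacing); islands, chromatin-state tiles, CTCF sites and
    EZH2 sites (preferentially over islands) are emitted as tracks, and probes
    are grouped into genes of widely varying CpG counts (1-60) so gene-set
    enrichment sees the real CpG-count bias.  Returns the annotated probe
    table, the tracks, and the probe -> genes map.
    """
    if config.n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = _cohort_rng(seed if seed is not None else config.seed, "annotation")

    n = config.n_probes
    probe_ids = [f"cg{i:07d}" for i in range(n)]
    chroms: list[str] = []
    positions: list[int] = []
    islands = GenomicTrack("islands")

    per_chrom = [n - n // 2, n // 2]
    idx = 0
    for ci, n_chrom in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = 10_000
        placed = 0
        while placed < n_chrom:
            if rng.random() < 0.06:  # island cluster
                size = min(int(rng.integers(4, 16)), n_chrom - placed)
                first = cursor
                for _ in range(size):
                    chroms.append(chrom)
                    positions.append(cursor)
                    cursor += int(rng.integers(50, 201))
                    placed += 1
                    idx += 1
                islands.add(chrom, first - 100, cursor + 100)
                cursor += int(rng.integers(500, 8_001))
            else:  # background probe; some sit close enough to flank an island
                chroms.append(chrom)
                positions.append(cursor)
                if rng.random() < 0.35:
                    cursor += int(rng.integers(300, 4_001))
                else:
                    cursor += int(rng.integers(4_000, 20_001))
                placed += 1
                idx += 1

    probes = pd.DataFrame({"chrom": chroms, "pos": positions}, index=probe_ids)

    # chromatin states tiled over each chromosome
    states = GenomicTrack("states")
    labels = [s for s, _ in _CHROM_STATES]
    weights = np.array([w for _, w in _CHROM_STATES])
    weights = weights / weights.sum()
    for ci in range(2):
        chrom = f"chr{ci + 1}"
        end = int(probes.loc[probes["chrom"] == chrom, "pos"].max()) + 10_000
        cursor = 0
        while cursor < end:
            length = int(rng.integers(5_000, 50_001))
            state = labels[int(rng.choice(len(labels), p=weights))]
            states.add(chrom, cursor, cursor + length, state)
            cursor += length

    # CTCF: random intervals; EZH2: preferentially over islands
    ctcf = GenomicTrack("ctcf")
    for ci in range(2):
        chrom = f"chr{ci + 1}"
        end = int(probes.loc[probes["chrom"] == chrom, "pos"].max()) + 10_000
        for _ in range(max(1, n // 200)):
            start = int(rng.integers(0, end))
            ctcf.add(chrom, start, start + int(rng.integers(500, 2_000)))
    ezh2 = GenomicTrack("ezh2")
    for chrom in islands.chroms():
        for start, stop, _ in islands.intervals(chrom):
            if rng.random() < 0.3:
                ezh2.add(chrom, start, stop)
    for ci in range(2):
        chrom = f"chr{ci + 1}"
        end = int(probes.loc[probes["chrom"] == chrom, "pos"].max()) + 10_000
        for _ in range(max(1, n // 500)):
            start = int(rng.integers(0, end))
            ezh2.add(chrom, start, start + int(rng.integers(500, 2_000)))

    # genes: consecutive probes share a gene; CpG counts span 1..60.
    # first two genes are forced to the extremes the enrichment bias needs.
    gene_map: dict[str, list[str]] = {p: [] for p in probe_ids}
    gene_sizes: list[int] = [35, 1]
    while sum(gene_sizes) < n:
        u = rng.random()
        if u < 0.55:
            gene_sizes.append(int(rng.integers(1, 6)))
        elif u < 0.85:
            gene_sizes.append(int(rng.integers(6, 21)))
        else:
            gene_sizes.append(int(rng.integers(21, 61)))
    pos_iter = 0
    gene_names = []
    for gi, size in enumerate(gene_sizes):
        gene = f"GENE{gi:05d}"
        gene_names.append(gene)
        for p in probe_ids[pos_iter : pos_iter + size]:
            gene_map[p].append(gene)
        pos_iter += size
        if pos_iter >= n:
            break
    # enhancer-linked genes: ~2% of probes link to a random distant gene
    n_links = max(1, n // 50)
    link_probes = rng.choice(n, size=n_links, replace=False)
    for pi in link_probes:
        gene = gene_names[int(rng.integers(0, len(gene_names)))]
        if gene not in gene_map[probe_ids[pi]]:
            gene_map[probe_ids[pi]].append(gene)

    gene_map_t = {p: tuple(sorted(g)) for p, g in gene_map.items()}
    annotation = annotate_probes(
        probes, islands, states, {"ctcf": ctcf, "ezh2": ezh2}, gene_map_t
    )
    tracks = {"islands": islands, "states": states, "ctcf": ctcf, "ezh2": ezh2}
    return annotation, tracks, gene_map_t


# ---------------------------------------------------------------------------
# cohort emission
# ---------------------------------------------------------------------------


def _truncnorm(rng, lo, hi, mean, sd, size):
    """Rejection-sampled truncated normal (windows here are wide, so cheap)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _pick_spiked_regions(
    annotation: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, int, int, int, list[str]]]:
    """Choose non-overlapping blocks of adjacent CpGs (gaps <= 500 bp)."""
    runs: list[list[int]] = []
    ann = annotation.reset_index()
    order = np.lexsort((ann["pos"].to_numpy(), ann["chrom"].to_numpy()))
    ann = ann.iloc[order]
    current: list[int] = []
    prev_chrom, prev_pos = None, None
    for i, row in enumerate(ann.itertuples()):
        if (
            prev_chrom == row.chrom
            and prev_pos is not None
            and row.pos - prev_pos <= 500
        ):
            current.append(i)
        else:
            if len(current) >= config.dmr_block_len[0]:
                runs.append(current)
            current = [i]
        prev_chrom, prev_pos = row.chrom, row.pos
    if len(current) >= config.dmr_block_len[0]:
        runs.append(current)

    if config.n_spiked_regions is not None:
        n_target_regions = config.n_spiked_regions
        n_target_probes = None
    else:
        n_target_regions = None
        n_target_probes = int(round(config.frac_age_cpgs * config.n_probes))

    rng.shuffle(runs)
    regions = []
    spiked = 0
    lo, hi = config.dmr_block_len
    for run in runs:
        if n_target_regions is not None and len(regions) >= n_target_regions:
            break
        if n_target_probes is not None and spiked >= n_target_probes:
            break
        length = int(rng.integers(lo, hi + 1))
        length = min(length, len(run))
        start_at = int(rng.integers(0, len(run) - length + 1))
        members = run[start_at : start_at + length]
        sign = -1 if rng.random() < config.frac_hypo else 1
        rows = ann.iloc[members]
        regions.append(
            (
                rows["chrom"].iloc[0],
                int(rows["pos"].min()),
                int(rows["pos"].max()) + 1,
                sign,
                list(rows["probe_id"]),
            )
        )
        spiked += length
    if n_target_regions is not None and len(regions) < n_target_regions:
        raise ValueError(
            f"annotation supports only {len(regions)} spiked regions, "
            f"{n_target_regions} requested"
        )
    return regions


def simulate_multicohort(
    annotation: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[MethylationDataset], SimulationTruth]:
    """Emit one beta matrix + sample sheet per cohort, with ground truth."""
    seed = config.seed if seed is None else seed
    truth_rng = _cohort_rng(seed, "truth")
    n = len(annotation)
    probe_ids = annotation.index

    # baselines: three-component logit mixture -> bimodal beta values
    comp = truth_rng.choice(3, size=n, p=[0.40, 0.20, 0.40])
    alpha = np.where(
        comp == 0,
        truth_rng.normal(-2.2, 0.6, n),
        np.where(comp == 1, truth_rng.normal(0.0, 0.8, n), truth_rng.normal(2.2, 0.6, n)),
    )
    p_base = expit(alpha)
    deriv = np.clip(p_base * (1 - p_base), 0.03, None)

    beta_slope = np.zeros(n)
    regions = []
    if config.slope_scale > 0:
        chosen = _pick_spiked_regions(annotation, config, truth_rng)
        probe_pos = {p: i for i, p in enumerate(probe_ids)}
        for chrom, start, end, sign, members in chosen:
            for p in members:
                mag = config.slope_scale * truth_rng.uniform(0.8, 1.2)
                beta_slope[probe_pos[p]] = sign * mag
            regions.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "sign": sign,
                    "probe_ids": tuple(members),
                }
            )
    spiked_regions = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "sign", "probe_ids"]
    )
    latent_slope = beta_slope / deriv

    # covariate effects shared across cohorts (biology, not batch)
    sex_eff = truth_rng.normal(0, config.sex_sd, n)
    bmi_eff = truth_rng.normal(0, config.bmi_slope_sd, n)
    t2d_eff = truth_rng.normal(0, config.t2d_sd, n)
    time_eff = truth_rng.normal(0, config.time_sd, n)

    datasets = []
    cohort_probes: dict[str, pd.Index] = {}
    injected_bias: dict[str, float] = {}
    injected_inflation: dict[str, float] = {}

    for spec in config.cohorts:
        rng = _cohort_rng(seed, spec.dataset_id)
        n_cov = int(round(spec.coverage_fraction * n))
        sel = np.sort(rng.choice(n, size=n_cov, replace=False))
        cohort_idx = probe_ids[sel]
        cohort_probes[spec.dataset_id] = cohort_idx

        ages_subj = _truncnorm(
            rng, spec.age_min, spec.age_max, spec.age_mean, spec.age_sd, spec.n_subjects
        )
        male = rng.random(spec.n_subjects) < spec.pct_male
        z_age = (ages_subj - spec.age_mean) / max(spec.age_sd, 1e-9)
        r = config.confounding
        bmi = 26 + 4 * (r * z_age + np.sqrt(max(1 - r**2, 0.0)) * rng.normal(size=spec.n_subjects))
        if spec.has_t2d:
            t2d = (rng.random(spec.n_subjects) < np.where(z_age > 0, 0.3, 0.15)).astype(int)
        else:
            t2d = np.zeros(spec.n_subjects, dtype=int)
        u_subject = rng.normal(0, config.subject_sd, size=(spec.n_subjects, n_cov))
        if spec.twins:
            pair = np.repeat(np.arange((spec.n_subjects + 1) // 2), 2)[: spec.n_subjects]
            pair_eff = rng.normal(0, config.subject_sd, size=((spec.n_subjects + 1) // 2, n_cov))
            u_subject = 0.5 * u_subject + 0.5 * pair_eff[pair]
        else:
            pair = None
        batch_assign = rng.integers(0, spec.n_batches, size=spec.n_subjects)
        batch_eff = rng.normal(0, config.batch_sd, size=(spec.n_batches, n_cov))

        if config.unmeasured_confounder_sd > 0:
            conf = 0.5 * z_age + rng.normal(size=spec.n_subjects)
            load = rng.normal(0, config.unmeasured_confounder_sd, n_cov)
            injected_bias[spec.dataset_id] = float(config.unmeasured_confounder_sd)
            injected_inflation[spec.dataset_id] = float(config.unmeasured_confounder_sd)
        else:
            conf = None
            load = None
            injected_bias[spec.dataset_id] = 0.0
            injected_inflation[spec.dataset_id] = 0.0

        samples: list[SampleRecord] = []
        columns = []
        mats = []
        a = alpha[sel]
        bl = latent_slope[sel]
        sx = sex_eff[sel]
        bm = bmi_eff[sel]
        td = t2d_eff[sel]
        tm = time_eff[sel]
        for si in range(spec.n_subjects):
            for ti in range(spec.samples_per_subject):
                age = float(ages_subj[si] + 0.1 * ti)
                sid = f"{spec.dataset_id}_s{si:03d}"
                sample_id = f"{sid}_t{ti}"
                y = (
                    a
                    + bl * age
                    + sx * (1.0 if male[si] else 0.0)
                    + bm * (bmi[si] - 26.0)
                    + td * t2d[si]
                    + tm * ti
                    + u_subject[si]
                    + batch_eff[batch_assign[si]]
                    + rng.normal(0, config.noise_sd, n_cov)
                )
                if conf is not None:
                    y = y + load * conf[si]
                mats.append(np.clip(expit(y), 0.001, 0.999))
                columns.append(sample_id)
                samples.append(
                    SampleRecord(
                        sample_id=sample_id,
                        subject_id=sid,
                        age=age,
                        sex="M" if male[si] else "F",
                        bmi=float(bmi[si]),
                        t2d=int(t2d[si]) if spec.has_t2d else None,
                        batch=f"b{batch_assign[si]}" if spec.n_batches > 1 else None,
                        time_point=f"T{ti}" if spec.samples_per_subject > 1 else None,
                        twin_pair=f"{spec.dataset_id}_p{pair[si]:02d}" if pair is not None else None,
                    )
                )
        beta = pd.DataFrame(np.column_stack(mats), index=cohort_idx, columns=columns)
        datasets.append(
            MethylationDataset(
                dataset_id=spec.dataset_id,
                beta=beta,
                samples=samples,
                array_label=spec.array_label,
            )
        )

    # true DMGs: genes carried by any spiked probe
    true_dmgs: set[str] = set()
    for members in spiked_regions["probe_ids"]:
        for p in members:
            true_dmgs.update(annotation.loc[p, "genes"])

    truth = SimulationTruth(
        beta_slope=pd.Series(beta_slope, index=probe_ids, name="beta_slope"),
        spiked_regions=spiked_regions,
        true_dmgs=true_dmgs,
        cohort_probes=cohort_probes,
        injected_bias=injected_bias,
        injected_inflation=injected_inflation,
    )
    return datasets, truth


# ---------------------------------------------------------------------------
# external DE lists
# ---------------------------------------------------------------------------


def _gene_direction(truth: SimulationTruth, annotation: pd.DataFrame) -> dict[str, int]:
    """Dominant true methylation sign per DMG (+1 hyper / -1 hypo)."""
    votes: dict[str, int] = {}
    for row in truth.spiked_regions.itertuples():
        genes: set[str] = set()
        for p in row.probe_ids:
            genes.update(annotation.loc[p, "genes"])
        for g in genes:
            votes[g] = votes.get(g, 0) + row.sign
    return {g: (1 if v >= 0 else -1) for g, v in votes.items()}


def simulate_de_list(
    truth: SimulationTruth,
    annotation: pd.DataFrame,
    universe: Sequence[str],
    odds: float,
    n_de: int,
    seed: int,
    p_negative: float = 0.63,
) -> pd.DataFrame:
    """One differential-expression gene list with per-gene direction.

    Genes are drawn without replacement with probability proportional to
    ``odds`` for true DMGs and 1 otherwise; the expression direction of a DMG
    opposes its methylation direction with probability ``p_negative``
    (the "negative relationship"), and non-DMG directions are symmetric.
    """
    if odds < 1:
        raise ValueError("odds must be >= 1")
    universe = sorted(universe)
    if n_de > len(universe):
        raise ValueError(f"n_de={n_de} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(b"de"),)))
    if n_de == 0:
        return pd.DataFrame({"direction": pd.Series(dtype=int)}, index=pd.Index([], name="gene"))
    is_dmg = np.array([g in truth.true_dmgs for g in universe])
    w = np.where(is_dmg, odds, 1.0)
    w = w / w.sum()
    pick = rng.choice(len(universe), size=n_de, replace=False, p=w)
    meth_dir = _gene_direction(truth, annotation)
    genes, directions = [], []
    for i in sorted(pick):
        g = universe[i]
        if g in meth_dir:
            opposed = rng.random() < p_negative
            d = -meth_dir[g] if opposed else meth_dir[g]
        else:
            d = 1 if rng.random() < 0.5 else -1
        genes.append(g)
        directions.append(d)
    return pd.DataFrame({"direction": directions}, index=pd.Index(genes, name="gene"))


def simulate_de_lists(
    truth: SimulationTruth,
    annotation: pd.DataFrame,
    universe: Sequence[str],
    odds: float,
    n_de_mrna: int,
    n_de_protein: int,
    seed: int,
    p_negative: float = 0.63,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """mRNA-analog and protein-analog DE lists from independent draws."""
    mrna = simulate_de_list(truth, annotation, universe, odds, n_de_mrna, seed, p_negative)
    protein = simulate_de_list(
        truth, annotation, universe, odds, n_de_protein, seed + 104_729, p_negative
    )
    return mrna, protein
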