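"""Kernel-smoothed differentially methylated region (DMR) detection.

Squared meta-analysis z-scores (chi-square with 1 df under the null) are
smoothed along each chromosome with a Gaussian kernel of bandwidth
``sigma = lambda / C`` (default 1000 bp / 2), truncated at 3 sigma.  The
smoothed statistic at each CpG is referred to a scaled chi-square via
two-moment (Satterthwaite) matching, the smoothed p-values are BH-corrected,
and significant CpGs within ``lambda`` of each other are aggregated into
candidate regions.  Emitted DMRs must pass all three region-level criteria:
BH-adjusted Fisher combination p, Stouffer combination p, and the harmonic
mean of member FDRs, each below 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import map_region_to_genes
from .meta_analysis import MetaResult, bh_fdr

__all__ = [
    "DmrConfig",
    "smooth_statistics",
    "call_candidate_regions",
    "region_statistics",
    "filter_and_annotate_dmrs",
    "call_dmrs",
]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class DmrConfig:
    """Tuning of the DMR caller (defaults follow the 1000 bp kernel idiom)."""

    lambda_bp: float = 1000.0  # max gap between member CpGs, and kernel span
    C: float = 2.0  # kernel scaling, sigma = lambda / C
    fdr_cpg: float = 0.005  # per-CpG smoothed FDR threshold
    min_cpgs: int = 2
    fisher_threshold: float = 0.005
    stouffer_threshold: float = 0.005
    hmfdr_threshold: float = 0.005

    def __post_init__(self) -> None:
        if self.lambda_bp <= 0 or self.C <= 0:
            raise ValueError("lambda_bp and C must be positive")

    @property
    def sigma(self) -> float:
        return self.lambda_bp / self.C


def smooth_statistics(
    positions: np.ndarray,
    chroms: np.ndarray,
    z: np.ndarray,
    config: DmrConfig = DmrConfig(),
) -> pd.DataFrame:
    """Gaussian-kernel smoothing of z^2 with Satterthwaite p-values.

    Probes must be sorted by (chrom, pos); smoothing never crosses
    chromosomes.  For CpG i with kernel weights K_ij (K_ii = 1, zero beyond
    3 sigma), the smoothed statistic is S_i = sum K z^2 / sum K; under the
    null E[S] = 1 and Var[S] = 2 sum K^2 / (sum K)^2, so S is referred to
    chi-square with nu = (sum K)^2 / sum K^2 degrees of freedom via
    P(chi2_nu > nu S).
    """
    positions = np.asarray(positions, dtype=float)
    chroms = np.asarray(chroms)
    z = np.asarray(z, dtype=float)
    order_ok = True
    for c in pd.unique(chroms):
        sel = chroms == c
        if np.any(np.diff(positions[sel]) < 0):
            order_ok = False
    if not order_ok:
        raise ValueError("probes must be sorted by (chrom, pos)")
    sigma = config.sigma
    cutoff = 3.0 * sigma
    z2 = z**2
    S = np.empty(len(z))
    nu = np.empty(len(z))
    for c in pd.unique(chroms):
        sel = np.where(chroms == c)[0]
        pos = positions[sel]
        lo = np.searchsorted(pos, pos - cutoff, side="left")
        hi = np.searchsorted(pos, pos + cutoff, side="right")
        for ii, (l, h) in enumerate(zip(lo, hi)):
            d = pos[l:h] - pos[ii]
            K = np.exp(-(d**2) / (2 * sigma**2))
            ksum = K.sum()
            k2sum = (K**2).sum()
            S[sel[ii]] = float(K @ z2[sel[l:h]]) / ksum
            nu[sel[ii]] = ksum**2 / k2sum
    p = stats.chi2.sf(nu * S, nu)
    return pd.DataFrame({"S": S, "nu": nu, "p_smooth": p})


def call_candidate_regions(
    smoothed: pd.DataFrame,
    positions: np.ndarray,
    chroms: np.ndarray,
    config: DmrConfig = DmrConfig(),
) -> list[np.ndarray]:
    """Group CpGs significant after smoothing into gap-limited regions.

    Smoothed p-values are BH-corrected over all probes; CpGs below
    ``fdr_cpg`` are chained greedily along each chromosome, starting a new
    region when the gap exceeds ``lambda_bp`` (a gap exactly equal to the
    bandwidth stays in the region).  Regions with fewer than ``min_cpgs``
    members are discarded.  Returns index arrays into the input order.
    """
    q = bh_fdr(smoothed["p_smooth"].to_numpy())
    sig = np.where(q < config.fdr_cpg)[0]
    regions: list[np.ndarray] = []
    current: list[int] = []
    for i in sig:
        if current and chroms[i] == chroms[current[-1]] and (
            positions[i] - positions[current[-1]] <= config.lambda_bp
        ):
            current.append(i)
        else:
            if len(current) >= config.min_cpgs:
                regions.append(np.array(current))
            current = [int(i)]
    if len(current) >= config.min_cpgs:
        regions.append(np.array(current))
    return regions


def region_statistics(
    p: np.ndarray, q: np.ndarray, z: np.ndarray, b: np.ndarray, se: np.ndarray
) -> dict:
    """The three region-level combination statistics plus effect summary.

    Fisher: X = -2 sum ln p on chi-square with 2m df; Stouffer:
    z_S = sum z / sqrt(m), two-sided; HMFDR: harmonic mean of member q.
    The region effect is the inverse-variance-weighted mean of member
    meta-effects; direction is hypo when it is negative.
    """
    p = np.clip(np.asarray(p, dtype=float), _TINY, 1.0)
    q = np.clip(np.asarray(q, dtype=float), _TINY, 1.0)
    m = len(p)
    fisher_x = -2.0 * np.sum(np.log(p))
    fisher_p = float(stats.chi2.sf(fisher_x, 2 * m))
    z_s = float(np.sum(z) / np.sqrt(m))
    stouffer_p = float(2 * stats.norm.sf(abs(z_s)))
    hmfdr = float(m / np.sum(1.0 / q))
    w = 1.0 / np.asarray(se, dtype=float) ** 2
    mean_b = float(np.sum(w * b) / np.sum(w))
    return {
        "fisher_p": fisher_p,
        "stouffer_z": z_s,
        "stouffer_p": stouffer_p,
        "hmfdr": hmfdr,
        "mean_b": mean_b,
        "direction": "hypo" if mean_b < 0 else "hyper",
    }


def filter_and_annotate_dmrs(
    candidates: pd.DataFrame,
    annotation: pd.DataFrame | None,
    config: DmrConfig = DmrConfig(),
) -> pd.DataFrame:
    """Threshold candidate regions on all three statistics and annotate genes.

    The Fisher combination p is BH-adjusted across candidate regions before
    thresholding; Stouffer p and HMFDR are thresholded as computed.  Emitted
    DMRs are sorted by (chrom, start).
    """
    if candidates.empty:
        return candidates.assign(genes=pd.Series(dtype=object))
    cand = candidates.copy()
    cand["fisher_adj"] = bh_fdr(cand["fisher_p"].to_numpy())
    keep = (
        (cand["fisher_adj"] < config.fisher_threshold)
        & (cand["stouffer_p"] < config.stouffer_threshold)
        & (cand["hmfdr"] < config.hmfdr_threshold)
    )
    out = cand[keep].copy()
    if annotation is not None:
        out["genes"] = [
            map_region_to_genes(row.chrom, int(row.start), int(row.end), annotation)
            for row in out.itertuples()
        ]
    else:
        out["genes"] = [set() for _ in range(len(out))]
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def call_dmrs(
    meta: MetaResult,
    annotation: pd.DataFrame,
    config: DmrConfig = DmrConfig(),
) -> pd.DataFrame:
    """End-to-end DMR calling from a meta-analysis result.

    Probes without genomic coordinates are excluded from region detection
    (they remain in the DMP-level tables).  Returns a frame with one row per
    emitted DMR: chrom, start, end (0-based half-open), n_cpgs, probe_ids,
    mean_b, direction, fisher_p, fisher_adj, stouffer_z, stouffer_p, hmfdr,
    n_hypo_members, n_hyper_members, genes.
    """
    t = meta.table.join(annotation[["chrom", "pos"]], how="inner")
    t = t[t["chrom"].notna() & np.isfinite(t["pos"])]
    order = np.lexsort((t["pos"].to_numpy(), t["chrom"].to_numpy()))
    t = t.iloc[order]
    positions = t["pos"].to_numpy(float)
    chroms = t["chrom"].to_numpy()
    z = t["z_meta"].to_numpy(float)
    smoothed = smooth_statistics(positions, chroms, z, config)
    member_sets = call_candidate_regions(smoothed, positions, chroms, config)
    rows = []
    for members in member_sets:
        sub = t.iloc[members]
        rs = region_statistics(
            sub["p_meta"].to_numpy(),
            sub["q_meta"].to_numpy(),
            sub["z_meta"].to_numpy(),
            sub["b_meta"].to_numpy(),
            sub["se_meta"].to_numpy(),
        )
        rows.append(
            {
                "chrom": chroms[members[0]],
                "start": int(positions[members[0]]),
                "end": int(positions[members[-1]]) + 1,
                "n_cpgs": len(members),
                "probe_ids": tuple(sub.index),
                "n_hypo_members": int((sub["b_meta"] < 0).sum()),
                "n_hyper_members": int((sub["b_meta"] >= 0).sum()),
                **rs,
            }
        )
    candidates = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_cpgs",
            "probe_ids",
            "n_hypo_members",
            "n_hyper_members",
            "fisher_p",
            "stouffer_z",
            "stouffer_p",
            "hmfdr",
            "mean_b",
            "direction",
        ],
    )
    return filter_and_annotate_dmrs(candidates, annotation, config)
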