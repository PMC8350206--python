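"""Fixed-effects inverse-variance meta-analysis across cohorts.

Per-cohort (effect, SE) pairs — already bias/inflation-corrected — are
combined per CpG with weights ``w_i = 1/se_i^2``.  Cochran's Q and I^2
quantify between-study heterogeneity (reported, never used to filter).
Only CpGs observed in a minimum number of cohorts enter the meta-analysis,
and Benjamini-Hochberg FDR is computed once over that coverage-filtered
probe universe; probes below the FDR threshold are the DMPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ewas import EwasResult

__all__ = [
    "MetaResult",
    "DmpCall",
    "filter_coverage",
    "ivw_meta",
    "heterogeneity",
    "bh_fdr",
    "run_meta_analysis",
    "call_dmps",
    "sensitivity_rerun",
]

MIN_COHORTS_DEFAULT = 6
DMP_FDR_DEFAULT = 0.005


@dataclass
class MetaResult:
    """Per-CpG meta-analytic effects over the coverage-filtered universe.

    ``table`` columns: k, b_meta, se_meta, z_meta, p_meta, q_meta, Q, I2,
    direction (one +/-/? character per cohort, in ``dataset_ids`` order).
    """

    table: pd.DataFrame
    dataset_ids: list[str]
    min_cohorts: int


@dataclass
class DmpCall:
    """DMP set at a meta-analysis FDR threshold, with direction summary."""

    probes: pd.Index
    q_threshold: float
    n_hypo: int
    n_hyper: int
    pct_hypo: float
    pct_hyper: float
    mean_pct_per_decade_hypo: float  # mean |change| at hypo-DMPs, % per decade
    mean_pct_per_decade_hyper: float


def filter_coverage(
    results: list[EwasResult], min_cohorts: int = MIN_COHORTS_DEFAULT
) -> pd.Index:
    """Probes with a finite corrected (effect, SE) in >= ``min_cohorts`` cohorts."""
    if min_cohorts < 1:
        raise ValueError("min_cohorts must be >= 1")
    counts: dict[str, int] = {}
    for res in results:
        ok = np.isfinite(res.table["b_corr"]) & np.isfinite(res.table["se_corr"]) & (
            res.table["se_corr"] > 0
        )
        for probe in res.table.index[ok]:
            counts[probe] = counts.get(probe, 0) + 1
    return pd.Index(sorted(p for p, k in counts.items() if k >= min_cohorts))


def ivw_meta(b: np.ndarray, se: np.ndarray) -> tuple[float, float, float, float]:
    """Inverse-variance weighted fixed-effects combination of one probe.

    Cohorts with ``se == 0`` are excluded.  Returns (b_meta, se_meta, z, p).
    """
    b = np.asarray(b, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(b) & np.isfinite(se) & (se > 0)
    b, se = b[ok], se[ok]
    if len(b) == 0:
        return np.nan, np.nan, np.nan, np.nan
    w = 1.0 / se**2
    b_meta = float(np.sum(w * b) / np.sum(w))
    se_meta = float(np.sum(w) ** -0.5)
    z = b_meta / se_meta
    p = 2 * stats.norm.sf(abs(z))
    return b_meta, se_meta, float(z), float(p)


def heterogeneity(b: np.ndarray, se: np.ndarray, b_meta: float) -> tuple[float, float]:
    """Cochran's Q and I^2 = max(0, (Q - (k-1)) / Q); zero when k = 1 or Q = 0."""
    b = np.asarray(b, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(b) & np.isfinite(se) & (se > 0)
    b, se = b[ok], se[ok]
    k = len(b)
    if k <= 1:
        return 0.0, 0.0
    w = 1.0 / se**2
    Q = float(np.sum(w * (b - b_meta) ** 2))
    if Q <= 0:
        return max(Q, 0.0), 0.0
    return Q, float(max(0.0, (Q - (k - 1)) / Q))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    out = np.full(len(p), np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def run_meta_analysis(
    results: list[EwasResult],
    min_cohorts: int = MIN_COHORTS_DEFAULT,
    exclude_datasets: set[str] | None = None,
) -> MetaResult:
    """IVW meta-analysis of all probes passing the coverage filter.

    Vectorized over the (probe x cohort) effect/SE matrices; probes a cohort
    did not assay contribute neither weight nor a direction character (``?``).
    """
    exclude = exclude_datasets or set()
    use = [r for r in results if r.dataset_id not in exclude]
    if not use:
        raise ValueError("no cohorts left after exclusion")
    dataset_ids = [r.dataset_id for r in use]
    probes = filter_coverage(use, min_cohorts)
    k_cohorts = len(use)
    B = np.full((len(probes), k_cohorts), np.nan)
    S = np.full((len(probes), k_cohorts), np.nan)
    for j, res in enumerate(use):
        sub = res.table.reindex(probes)
        b = sub["b_corr"].to_numpy(float)
        se = sub["se_corr"].to_numpy(float)
        bad = ~(np.isfinite(b) & np.isfinite(se) & (se > 0))
        b[bad] = np.nan
        se[bad] = np.nan
        B[:, j] = b
        S[:, j] = se
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(np.isfinite(S), 1.0 / S**2, 0.0)
        Bz = np.where(np.isfinite(B), B, 0.0)
        wsum = W.sum(axis=1)
        b_meta = (W * Bz).sum(axis=1) / wsum
        se_meta = wsum**-0.5
        z_meta = b_meta / se_meta
        p_meta = 2 * stats.norm.sf(np.abs(z_meta))
        Q = (W * (Bz - b_meta[:, None]) ** 2 * np.isfinite(B)).sum(axis=1)
        k = np.isfinite(B).sum(axis=1)
        with np.errstate(invalid="ignore"):
            I2 = np.where((k > 1) & (Q > 0), np.maximum(0.0, (Q - (k - 1)) / np.where(Q > 0, Q, 1.0)), 0.0)
    direction = np.where(np.isnan(B), "?", np.where(B < 0, "-", "+"))
    dir_str = ["".join(row) for row in direction]
    table = pd.DataFrame(
        {
            "k": k,
            "b_meta": b_meta,
            "se_meta": se_meta,
            "z_meta": z_meta,
            "p_meta": p_meta,
            "q_meta": bh_fdr(p_meta),
            "Q": Q,
            "I2": I2,
            "direction": dir_str,
        },
        index=probes,
    )
    return MetaResult(table=table, dataset_ids=dataset_ids, min_cohorts=min_cohorts)


def call_dmps(meta: MetaResult, q_threshold: float = DMP_FDR_DEFAULT) -> DmpCall:
    """DMPs at the meta-analysis FDR threshold, with the hypo/hyper summary.

    Direction comes from the sign of the meta effect; a zero effect (tie)
    counts as hyper.  Mean changes are reported as percent methylation per
    decade (|b_meta| * 10 * 100).
    """
    t = meta.table
    sig = t[t["q_meta"] < q_threshold]
    hypo = sig[sig["b_meta"] < 0]
    hyper = sig[sig["b_meta"] >= 0]
    n = len(sig)
    return DmpCall(
        probes=sig.index,
        q_threshold=q_threshold,
        n_hypo=len(hypo),
        n_hyper=len(hyper),
        pct_hypo=100.0 * len(hypo) / n if n else 0.0,
        pct_hyper=100.0 * len(hyper) / n if n else 0.0,
        mean_pct_per_decade_hypo=float(np.abs(hypo["b_meta"]).mean() * 1000) if len(hypo) else np.nan,
        mean_pct_per_decade_hyper=float(np.abs(hyper["b_meta"]).mean() * 1000) if len(hyper) else np.nan,
    )


def sensitivity_rerun(
    results: list[EwasResult],
    exclude_datasets: set[str],
    min_cohorts: int = MIN_COHORTS_DEFAULT,
    q_threshold: float = DMP_FDR_DEFAULT,
    reference: MetaResult | None = None,
) -> tuple[MetaResult, dict]:
    """Re-run the meta-analysis on a cohort subset and compare with the full run.

    Returns the subset MetaResult and a concordance report: Pearson r of
    b_meta over shared probes and the 2x2 cross-tab of DMP calls.
    """
    remaining = [r for r in results if r.dataset_id not in exclude_datasets]
    if len(remaining) < 2:
        raise ValueError("fewer than 2 cohorts remain after exclusion")
    full = reference if reference is not None else run_meta_analysis(results, min_cohorts)
    sub = run_meta_analysis(remaining, min_cohorts=min(min_cohorts, len(remaining)))
    shared = full.table.index.intersection(sub.table.index)
    b_full = full.table.loc[shared, "b_meta"]
    b_sub = sub.table.loc[shared, "b_meta"]
    r = float(np.corrcoef(b_full, b_sub)[0, 1]) if len(shared) > 1 else np.nan
    dmp_full = set(call_dmps(full, q_threshold).probes) & set(shared)
    dmp_sub = set(call_dmps(sub, q_threshold).probes) & set(shared)
    report = {
        "n_shared_probes": int(len(shared)),
        "b_meta_correlation": r,
        "dmp_both": len(dmp_full & dmp_sub),
        "dmp_full_only": len(dmp_full - dmp_sub),
        "dmp_subset_only": len(dmp_sub - dmp_full),
        "dmp_neither": int(len(shared)) - len(dmp_full | dmp_sub),
    }
    return sub, report
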