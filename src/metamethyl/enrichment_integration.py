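"""Genomic-context enrichment of DMRs and multi-omic integration.

Context enrichment compares the category distribution of CpGs inside
hypomethylated and hypermethylated DMRs against the remaining analyzed CpGs
with a Pearson chi-square test and per-cell residuals (O - E)/sqrt(E).
Gene-set enrichment corrects for the biased distribution of CpGs across
genes (genes with more probes are more likely to harbour a DMR by chance)
with a Wallenius noncentral hypergeometric test whose odds parameter is the
ratio of mean empirical selection weights inside versus outside the set.
Differentially methylated genes (DMGs: >= 1 annotated DMR) are intersected
with external transcriptome / proteome differential-expression lists via
2x2 chi-square overlap tests and a direction classification ("negative
relationship" = expression and methylation change in opposite directions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .meta_analysis import bh_fdr

__all__ = [
    "ContingencyResult",
    "OverlapResult",
    "context_enrichment",
    "geneset_enrichment",
    "define_dmgs",
    "omics_overlap",
    "classify_relationship",
    "candidate_report",
    "ACTIVE_TRANSCRIPTION_STATES",
]

ACTIVE_TRANSCRIPTION_STATES = frozenset({"Tx", "TxWk", "EnhG"})
SIGNIFICANCE_P = 0.005


@dataclass
class ContingencyResult:
    """Pearson chi-square on an observed r x c count table."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    residuals: pd.DataFrame  # (O - E) / sqrt(E)

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_P


@dataclass
class OverlapResult:
    """2x2 overlap between DMGs and a differential-expression gene list."""

    table: pd.DataFrame  # rows DMG/non-DMG, cols DE/non-DE
    chi2: float
    p: float
    odds_ratio: float
    pct_de_in_dmgs: float  # % of DE genes that are DMGs


def _pearson_chi2(observed: pd.DataFrame) -> ContingencyResult:
    """Shared chi-square kernel (no continuity correction) with residuals."""
    O = observed.to_numpy(float)
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    total = O.sum()
    if total <= 0 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("contingency table needs >=2 rows and columns with counts")
    E = row @ col / total
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (O - E) / np.sqrt(E)
    chi2 = float(np.nansum(resid**2))
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    wrap = lambda M: pd.DataFrame(M, index=observed.index, columns=observed.columns)
    return ContingencyResult(observed, wrap(E), chi2, df, p, wrap(resid))


def _probe_category(annotation: pd.DataFrame, category: str) -> pd.Series:
    if category == "island_context":
        return annotation["island_context"]
    if category == "chromatin_state":
        return annotation["chromatin_state"]
    if category == "tf_site":
        ctcf = annotation["ctcf"].astype(bool)
        ezh2 = annotation["ezh2"].astype(bool)
        out = pd.Series("none", index=annotation.index)
        out[ctcf & ~ezh2] = "CTCF"
        out[~ctcf & ezh2] = "EZH2"
        out[ctcf & ezh2] = "CTCF+EZH2"
        return out
    raise ValueError(f"unknown category {category!r}")


def context_enrichment(
    dmrs: pd.DataFrame,
    annotation: pd.DataFrame,
    universe: Sequence[str],
    category: str,
) -> ContingencyResult:
    """Chi-square comparison of DMR CpGs vs non-DMR CpGs across categories.

    The counting unit is the CpG: every analyzed probe (the coverage-filtered
    ``universe``) with genomic context is counted once, as a member of a
    hypo-DMR, of a hyper-DMR, or of neither.  Category levels whose expected
    count falls below 1 are pooled into "other".
    """
    universe = pd.Index(universe)
    ann = annotation.loc[annotation.index.intersection(universe)]
    ann = ann[ann["chrom"].notna()]
    cats = _probe_category(ann, category)
    membership = pd.Series("non-DMR", index=ann.index)
    for row in dmrs.itertuples():
        label = "hypo-DMR" if row.direction == "hypo" else "hyper-DMR"
        for p in row.probe_ids:
            if p in membership.index:
                membership[p] = label
    observed = pd.crosstab(membership, cats)
    observed = observed.reindex(
        [r for r in ("hypo-DMR", "hyper-DMR", "non-DMR") if r in observed.index]
    )
    # pool categories with tiny expected counts
    O = observed.to_numpy(float)
    E = O.sum(axis=1, keepdims=True) @ O.sum(axis=0, keepdims=True) / O.sum()
    small = (E < 1).any(axis=0)
    if small.any() and small.sum() < observed.shape[1]:
        pooled = observed.loc[:, small].sum(axis=1)
        observed = observed.loc[:, ~small]
        observed["other"] = pooled
    observed = observed.loc[(observed.sum(axis=1) > 0), (observed.sum(axis=0) > 0)]
    return _pearson_chi2(observed)


def geneset_enrichment(
    dmr_genes: Iterable[str],
    gene_cpg_counts: pd.Series,
    gene_sets: Mapping[str, Iterable[str]],
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """CpG-count-bias-corrected gene-set enrichment of the DMG list.

    The per-gene selection weight is the empirical probability of being a
    DMG as a function of CpG count (isotonic fit, so monotone in the count);
    each set's odds parameter is the ratio of mean weights inside versus
    outside, and the upper-tail p comes from the Wallenius noncentral
    hypergeometric distribution.  With equal weights this reduces exactly to
    the central hypergeometric tail.  Returns one row per set with BH FDR
    across sets.
    """
    if universe is None:
        universe = gene_cpg_counts.index
    universe = pd.Index(sorted(set(universe)))
    counts = gene_cpg_counts.reindex(universe)
    if counts.isna().any() or (counts < 1).any():
        raise ValueError("every universe gene needs a CpG count >= 1")
    selected = universe.isin(set(dmr_genes))
    n_selected = int(selected.sum())
    M = len(universe)

    # empirical probability-weighting: P(selected | CpG count), monotone
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    x = counts.to_numpy(float)
    w = iso.fit(x, selected.astype(float)).predict(x)
    w = np.clip(w, 1e-6, None)
    weights = pd.Series(w, index=universe)

    rows = []
    for set_id in sorted(gene_sets):
        members = universe.intersection(set(gene_sets[set_id]))
        n_set = len(members)
        if n_set == 0 or n_set == M:
            continue
        overlap = int(selected[universe.isin(members)].sum())
        w_in = float(weights[members].mean())
        w_out = float(weights[universe.difference(members)].mean())
        odds = w_in / w_out
        if abs(odds - 1.0) < 1e-12:
            p = float(stats.hypergeom.sf(overlap - 1, M, n_set, n_selected))
        else:
            p = float(
                stats.nchypergeom_wallenius.sf(overlap - 1, M, n_set, n_selected, odds)
            )
        rows.append(
            {
                "set_id": set_id,
                "n_set": n_set,
                "n_de_in_set": overlap,
                "odds": odds,
                "p": min(max(p, 0.0), 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["set_id", "n_set", "n_de_in_set", "odds", "p"])
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out.set_index("set_id")


def define_dmgs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene DMR counts and direction profile; DMG = at least one DMR."""
    profile: dict[str, dict] = {}
    for row in dmrs.itertuples():
        for g in row.genes:
            rec = profile.setdefault(g, {"n_dmrs": 0, "n_hypo": 0, "n_hyper": 0})
            rec["n_dmrs"] += 1
            if row.direction == "hypo":
                rec["n_hypo"] += 1
            else:
                rec["n_hyper"] += 1
    out = pd.DataFrame.from_dict(profile, orient="index").sort_index()
    if out.empty:
        out = pd.DataFrame(columns=["n_dmrs", "n_hypo", "n_hyper"], dtype=int)
    out.index.name = "gene"
    return out


def omics_overlap(
    dmgs: Iterable[str], de_list: Sequence[str], universe: Sequence[str]
) -> OverlapResult:
    """2x2 chi-square of DMG status against differential-expression status.

    DE genes outside the universe are dropped (logged via the returned
    counts); the odds ratio uses the Haldane 0.5 correction when a cell is
    empty.
    """
    universe = pd.Index(sorted(set(universe)))
    dmg = universe.isin(set(dmgs))
    de = universe.isin(set(de_list))
    obs = pd.DataFrame(
        [
            [int((dmg & de).sum()), int((dmg & ~de).sum())],
            [int((~dmg & de).sum()), int((~dmg & ~de).sum())],
        ],
        index=["DMG", "non-DMG"],
        columns=["DE", "non-DE"],
    )
    if int(de.sum()) == 0 or int(de.sum()) == len(universe):
        raise ValueError("degenerate overlap table: DE margin is empty or full")
    if int(dmg.sum()) == 0 or int(dmg.sum()) == len(universe):
        raise ValueError("degenerate overlap table: DMG margin is empty or full")
    res = _pearson_chi2(obs)
    a, b_, c, d = obs.to_numpy(float).ravel()
    if min(a, b_, c, d) == 0:
        a, b_, c, d = a + 0.5, b_ + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b_ * c)
    pct = 100.0 * obs.loc["DMG", "DE"] / obs["DE"].sum()
    return OverlapResult(
        table=obs, chi2=res.chi2, p=res.p, odds_ratio=float(odds_ratio), pct_de_in_dmgs=float(pct)
    )


def classify_relationship(
    dmrs: pd.DataFrame,
    de_list: pd.DataFrame,
    annotation: pd.DataFrame,
    active_states: frozenset[str] = ACTIVE_TRANSCRIPTION_STATES,
) -> pd.DataFrame:
    """Methylation-vs-expression direction classification, per DMR vote.

    For every (DMR, DE gene) pair the relationship is negative when the
    expression direction opposes the DMR direction (up-regulated with lower
    methylation, or down-regulated with higher methylation) and positive
    when they agree.  Votes are stratified by whether the majority of the
    DMR's member CpGs lie in a state of active transcription.  ``de_list``
    is indexed by gene with a ``direction`` column (+1 / -1).
    """
    rows = {
        ("active_transcription", "negative"): 0,
        ("active_transcription", "positive"): 0,
        ("other_region", "negative"): 0,
        ("other_region", "positive"): 0,
    }
    de_dir = de_list["direction"]
    for row in dmrs.itertuples():
        genes = set(row.genes) & set(de_dir.index)
        if not genes:
            continue
        states = annotation.loc[list(row.probe_ids), "chromatin_state"]
        active = (states.isin(active_states)).mean() > 0.5
        stratum = "active_transcription" if active else "other_region"
        meth_sign = -1 if row.direction == "hypo" else 1
        for g in genes:
            rel = "negative" if int(de_dir[g]) * meth_sign < 0 else "positive"
            rows[(stratum, rel)] += 1
    out = pd.DataFrame(
        [
            {"stratum": s, "relationship": r, "n": n}
            for (s, r), n in sorted(rows.items())
        ]
    ).set_index(["stratum", "relationship"])
    total = out["n"].sum()
    out["pct"] = 100.0 * out["n"] / total if total else 0.0
    return out


def candidate_report(
    candidates: Sequence[str],
    dmg_profile: pd.DataFrame,
    mrna_de: pd.DataFrame | None = None,
    protein_de: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Candidate-gene summary: DMR count, methylation direction, DE changes.

    Genes with no DMR appear with ``n_dmrs = 0`` and a blank direction;
    genes with DMRs in both directions read "Hypo and hypermethylation".
    """
    rows = []
    for gene in candidates:
        if gene in dmg_profile.index:
            rec = dmg_profile.loc[gene]
            n = int(rec["n_dmrs"])
            if rec["n_hypo"] > 0 and rec["n_hyper"] > 0:
                direction = "Hypo and hypermethylation"
            elif rec["n_hypo"] > 0:
                direction = "Hypomethylation"
            else:
                direction = "Hypermethylation"
        else:
            n, direction = 0, ""
        def _de_str(de):
            if de is None or gene not in de.index:
                return ""
            return "Increased" if int(de.loc[gene, "direction"]) > 0 else "Decreased"
        rows.append(
            {
                "gene": gene,
                "n_dmrs": n,
                "methylation_direction": direction,
                "mrna_change": _de_str(mrna_de),
                "protein_change": _de_str(protein_de),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
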