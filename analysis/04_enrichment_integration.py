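"""Genomic-context enrichment of DMRs and multi-omic integration.

From the seeded benchmark run: chi-square enrichment of DMR CpGs in
CpG-island contexts, chromatin states and TF binding sites; CpG-count-
bias-corrected gene-set enrichment against synthetic gene sets; overlap of
DMGs with simulated mRNA/protein differential-expression lists; direction
classification; and a candidate-gene report.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from metamethyl.annotation_io import write_outputs
from metamethyl.benchmarks import dmr_benchmark
from metamethyl.enrichment_integration import (
    candidate_report,
    classify_relationship,
    context_enrichment,
    define_dmgs,
    geneset_enrichment,
    omics_overlap,
)
from metamethyl.synthetic_data import simulate_de_lists


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    bench = dmr_benchmark(args.seed)
    result, truth, annotation = bench["result"], bench["truth"], bench["annotation"]
    dmrs = result.dmrs
    universe_probes = result.meta.table.index

    enrichments = {}
    for category in ("island_context", "chromatin_state", "tf_site"):
        res = context_enrichment(dmrs, annotation, universe_probes, category)
        enrichments[category] = res.residuals.assign(_chi2=res.chi2, _p=res.p)
        print(f"{category}: chi2={res.chi2:.1f} p={res.p:.3g}"
              + (" (significant)" if res.significant else ""))

    # gene universe = genes with >= 1 analyzed CpG; CpG counts for the bias
    ann_u = annotation.loc[universe_probes]
    counts: dict[str, int] = {}
    for genes in ann_u["genes"]:
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    import pandas as pd

    gene_cpg_counts = pd.Series(counts).sort_index()
    universe = list(gene_cpg_counts.index)
    dmgs = define_dmgs(dmrs)

    # synthetic gene sets: half tilted toward CpG-rich genes, half random
    rng = np.random.default_rng(args.seed)
    gene_sets = {}
    for j in range(40):
        tilt = rng.uniform(-1, 1)
        w = gene_cpg_counts.to_numpy(float) ** tilt
        members = rng.choice(universe, size=min(40, len(universe) // 4),
                             replace=False, p=w / w.sum())
        gene_sets[f"set{j:02d}"] = list(members)
    gs = geneset_enrichment(dmgs.index, gene_cpg_counts, gene_sets, universe)
    enrichments["gene_sets"] = gs
    print(f"gene sets: {int((gs['fdr'] < 0.005).sum())}/{len(gs)} significant "
          f"at FDR < 0.005 (bias-corrected)")

    mrna, protein = simulate_de_lists(
        truth, annotation, universe, odds=5.0,
        n_de_mrna=min(200, len(universe) // 3),
        n_de_protein=min(260, len(universe) // 3),
        seed=args.seed,
    )
    report = {}
    for name, de in (("mrna", mrna), ("protein", protein)):
        ov = omics_overlap(dmgs.index, de.index, universe)
        report[name] = {
            "pct_de_in_dmgs": ov.pct_de_in_dmgs,
            "chi2": ov.chi2,
            "p": ov.p,
            "odds_ratio": ov.odds_ratio,
        }
        print(f"{name}: {ov.pct_de_in_dmgs:.0f}% of DE genes are DMGs "
              f"(chi2={ov.chi2:.1f}, p={ov.p:.3g}, OR={ov.odds_ratio:.2f})")
    rel = classify_relationship(dmrs, mrna, annotation)
    neg_pct = float(
        100 * rel.xs("negative", level="relationship")["n"].sum() / max(rel["n"].sum(), 1)
    )
    report["pct_negative_relationship_mrna"] = neg_pct
    print(f"negative methylation-expression relationship in {neg_pct:.0f}% of votes")

    candidates = list(dmgs.sort_values("n_dmrs", ascending=False).head(10).index)
    cand = candidate_report(candidates, dmgs, mrna, protein)
    cand.to_csv(args.out_dir / "candidate_genes.tsv", sep="\t")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_outputs(args.out_dir, enrichments=enrichments)
    (args.out_dir / "integration_summary.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
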