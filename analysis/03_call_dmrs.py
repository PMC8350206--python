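"""Kernel-smoothed DMR calling on the meta-analysis statistics.

Re-runs the pipeline deterministically from --seed, smooths squared meta
z-scores with the 1000 bp Gaussian kernel, aggregates significant CpGs into
regions, applies the three region-level 0.005 thresholds, annotates genes,
and compares the emitted DMRs with the spiked truth blocks.
"""

import argparse
import json
from pathlib import Path

from metamethyl.annotation_io import write_outputs
from metamethyl.benchmarks import dmr_benchmark
from metamethyl.enrichment_integration import define_dmgs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    bench = dmr_benchmark(args.seed)
    dmrs = bench["result"].dmrs
    write_outputs(args.out_dir, dmrs=dmrs)
    dmgs = define_dmgs(dmrs)
    dmgs.to_csv(args.out_dir / "dmgs.tsv", sep="\t")

    summary = {
        "n_dmrs": int(len(dmrs)),
        "n_dmgs": int(len(dmgs)),
        "block_sensitivity": bench["sensitivity"],
        "false_dmrs": int(bench["false_dmrs"]),
        "direction_concordance": bench["direction_concordance"],
        "n_hypo_dmrs": int((dmrs["direction"] == "hypo").sum()),
        "n_hyper_dmrs": int((dmrs["direction"] == "hyper").sum()),
    }
    (args.out_dir / "dmr_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"{summary['n_dmrs']} DMRs ({summary['n_hypo_dmrs']} hypo / "
          f"{summary['n_hyper_dmrs']} hyper) spanning {summary['n_dmgs']} genes")
    print(f"recovered {bench['sensitivity']:.0%} of spiked blocks with "
          f"{bench['false_dmrs']} false regions; direction concordance "
          f"{bench['direction_concordance']:.0%}")


if __name__ == "__main__":
    main()
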