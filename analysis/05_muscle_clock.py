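"""Muscle epigenetic clock: train and evaluate by leave-one-dataset-out.

Simulates eight cohorts with ~300 true clock CpGs (0.1%/year) among 5000
probes, calibrates every dataset to the widest-age-range reference with the
beta-mixture quantile method, trains the elastic net on transformed age, and
reports per-dataset and aggregate LODO accuracy plus a pure-noise control.
"""

import argparse
import json
from pathlib import Path

from metamethyl.annotation_io import write_outputs
from metamethyl.benchmarks import clock_benchmark


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--skip-noise-control", action="store_true")
    args = ap.parse_args()

    bench = clock_benchmark(args.seed, with_noise_control=not args.skip_noise_control)
    ev = bench["evaluation"]
    args.out_dir.mkdir(parents=True, exist_ok=True)
    ev.per_dataset.to_csv(args.out_dir / "clock_lodo.tsv", sep="\t")
    write_outputs(args.out_dir, clock_model=bench["model"])

    summary = {
        "mean_r": bench["mean_r"],
        "median_abs_error_years": bench["median_error"],
        "n_clock_cpgs": bench["n_selected"],
        "selection_precision": bench["selection_precision"],
    }
    if "noise_mean_r" in bench:
        summary["noise_control_mean_r"] = bench["noise_mean_r"]
    (args.out_dir / "clock_summary.json").write_text(json.dumps(summary, indent=1))

    print(ev.per_dataset.round(3))
    print(f"LODO: mean r = {bench['mean_r']:.2f}, median error = "
          f"{bench['median_error']:.1f} years; final clock uses "
          f"{bench['n_selected']} CpGs ({bench['selection_precision']:.0%} "
          f"carrying true age signal)")
    if "noise_mean_r" in bench:
        print(f"pure-noise control: mean r = {bench['noise_mean_r']:.2f}")


if __name__ == "__main__":
    main()
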