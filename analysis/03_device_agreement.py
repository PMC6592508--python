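#!/usr/bin/env python
"""Quantify tracker-vs-reference agreement.

From the per-subject matrices of 02_transition_matrices.py: cell-wise
paired t tests of the transition probabilities, per-subject absolute
percent errors, and Bland-Altman bias with 1.96-SD limits of agreement
(x-axis = reference value).  Cells with |mean bias| <= 5 percentage points
count as free of systematic bias.  Writes paired_tests.csv, agreement.csv
and errors_long.csv under results/; Bland-Altman scatter PNGs go to
scratch/figures when --plots is given.
"""

import argparse
from pathlib import Path

import pandas as pd

from sleeptrans.agreement import plot_bland_altman
from sleeptrans.pipeline import analyze_pairs, load_manifest

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--plots", action="store_true")
    args = parser.parse_args()

    manifest = ROOT / "scratch" / "cohort" / "manifest.yaml"
    if not manifest.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    pairs, factors, _ = load_manifest(manifest)
    result = analyze_pairs(pairs, factors=factors)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    result.paired_tests.to_csv(results / "paired_tests.csv", index=False)
    result.agreement.to_csv(results / "agreement.csv", index=False)
    result.errors_long.to_csv(results / "errors_long.csv", index=False)
    if args.plots:
        paths = plot_bland_altman(result.agreement_results, ROOT / "scratch" / "figures")
        print(f"{len(paths)} Bland-Altman plots -> scratch/figures")

    sig = result.paired_tests[result.paired_tests["significant"]]
    print(f"{len(sig)} of 16 cells significantly different between devices (alpha 0.05):")
    for _, row in sig.iterrows():
        print(f"  s_{row['from']}->{row['to']}: tracker {row['mean_tracker']:.1f}% "
              f"vs reference {row['mean_reference']:.1f}% (p={row['p']:.3g})")
    acc = result.agreement
    free = acc[acc["acceptable"]]
    print(f"{len(free)} of 16 cells without systematic bias (|bias| <= 5 pp); "
          f"largest |bias| = {acc['bias'].abs().max():.1f} pp")


if __name__ == "__main__":
    main()
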