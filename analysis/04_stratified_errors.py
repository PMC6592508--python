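#!/usr/bin/env python
"""Stratify measurement errors by user-specific factors.

Splits the cohort at each factor's cut-off (age 25, PSQI 5, TST 360 min,
WASO 30 min, SOL 30 min, SE 90%, light 65%, SWS 20%, REM 20%, T_avg 90 min,
plus sex) and applies the exact rank-sum test to every transition cell's
per-subject absolute percent errors.  Also compares sleep patterns between
sexes and age groups with Welch t tests.  Writes stratification.csv and
demographics.csv under results/ and prints the significant strata.
"""

import argparse
from pathlib import Path

import pandas as pd

from sleeptrans.pipeline import analyze_pairs, load_manifest
from sleeptrans.stratify import compare_demographics

ROOT = Path(__file__).resolve().parents[1]

SLEEP_METRICS = ["tst", "waso", "sol", "se", "light_pct", "sws_pct", "rem_pct"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    args = parser.parse_args()

    manifest = ROOT / "scratch" / "cohort" / "manifest.yaml"
    if not manifest.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    pairs, factors, _ = load_manifest(manifest)
    result = analyze_pairs(pairs, factors=factors)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    report = result.stratification
    report.to_csv(results / "stratification.csv", index=False)

    demo_rows = []
    for by in ("sex", "age"):
        for metric in SLEEP_METRICS:
            res = compare_demographics(factors, metric, by=by)
            demo_rows.append({"grouping": by, "metric": metric,
                              "mean_low": res.mean_low, "mean_high": res.mean_high,
                              "t": res.t_stat, "p": res.p_value})
    demo = pd.DataFrame(demo_rows)
    demo.to_csv(results / "demographics.csv", index=False)

    sig = report[report["p"] < 0.05]
    print(f"{len(sig)} factor x cell strata with p < 0.05 (of {report['p'].notna().sum()} testable):")
    for _, row in sig.head(12).iterrows():
        print(f"  {row['factor']} (cutoff {row['cutoff']}) on e_{row['from']}->{row['to']}: "
              f"low {row['mean_low']:.1f}±{row['sd_low']:.1f}% vs "
              f"high {row['mean_high']:.1f}±{row['sd_high']:.1f}% (p={row['p']:.3f})")
    sig_demo = demo[demo["p"] < 0.05]
    print(f"{len(sig_demo)} demographic sleep-pattern differences with p < 0.05")
    if len(sig_demo):
        print(sig_demo.round(3).to_string(index=False))
    print("Under the epoch-iid misclassification channel, errors do not depend "
          "on the subject's covariates by construction, so significant strata "
          "here reflect the test's false-positive rate and any error-vs-sleep-"
          "architecture coupling induced by the channel itself.")


if __name__ == "__main__":
    main()
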