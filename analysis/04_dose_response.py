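#!/usr/bin/env python
"""Compare micro-lens transparency across drug doses.

Reads the per-lens measurements from step 03, groups them by dose and runs
pooled two-sample t-tests of each dose against the vehicle control (dose 0),
separately for the transmittance and focus ratios. Writes
results/optics/dose_response_<metric>.tsv and prints the comparison table.
"""
import argparse
from pathlib import Path

import pandas as pd

from microlens import dose_response_summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/optics"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/optics"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(args.in_dir / "measurements.tsv", sep="\t")
    for metric in ("transmittance_ratio", "focus_ratio"):
        groups = {dose: sub[metric].to_numpy()
                  for dose, sub in table.groupby("dose_ng_ml")}
        summary = dose_response_summary(groups, control_label=0.0, metric=metric)
        summary.to_csv(args.out_dir / f"dose_response_{metric}.tsv", sep="\t")
        print(f"\n{metric} vs dose (pooled t against vehicle control):")
        for dose, row in summary.iterrows():
            flag = " *" if row["p_vs_control"] < 0.05 else ""
            print(f"  {dose:7g} ng/ml  mean {row['mean']:.3f} +/- {row['sem']:.3f}"
                  f"  p={row['p_vs_control']:.2e}{flag}")


if __name__ == "__main__":
    main()
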