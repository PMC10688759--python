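#!/usr/bin/env python
"""Run the study's statistical procedure on the computed tables.

Per variable and group: Friedman screen across H0-H6; when it rejects,
Wilcoxon post-hocs of each hour against baseline; Mann-Whitney LPS vs
control at every hour; median(Q1;Q3) summaries.  Writes CSV reports and
formatted text tables (with '*' and '▲' significance marks) under
results/stats/.
"""

import argparse
from pathlib import Path

import pandas as pd

from fetalhrv.pipeline import run_stats

ROOT = Path(__file__).resolve().parent.parent


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--index-table", type=Path,
                        default=ROOT / "results" / "hrv_indices.csv")
    parser.add_argument("--physiology", type=Path,
                        default=ROOT / "results" / "cohort" / "physiology.csv")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "stats")
    args = parser.parse_args()
    table = pd.read_csv(args.index_table)
    phys = pd.read_csv(args.physiology)
    reports = run_stats(table, phys)
    for name, report in reports.items():
        report.to_csv(args.out / name)
        (args.out / f"{name}_table.txt").write_text(
            report.format_table() + "\n", encoding="utf-8")
    hrv = reports["hrv"]
    sig = hrv.friedman[hrv.friedman["p"] < 0.05]
    print(f"wrote reports to {args.out}")
    for group in ("LPS", "Control"):
        flagged = sorted(sig[sig.group == group]["variable"])
        print(f"{group}: Friedman-significant indices: "
              f"{', '.join(flagged) if flagged else 'none'}")
    wil = hrv.wilcoxon
    lps_sig = wil[(wil.group == "LPS") & wil.significant]
    for var in sorted(lps_sig["variable"].unique()):
        hours = ", ".join(lps_sig[lps_sig.variable == var]["timepoint"])
        print(f"  LPS {var} differs from baseline at: {hours}")


if __name__ == "__main__":
    main()
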