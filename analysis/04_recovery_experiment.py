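#!/usr/bin/env python
"""Multi-seed recovery of the built-in effect structure.

Regenerates the cohort under many master seeds and asks, for each seed:
does the statistical pipeline flag SDNN, LTV and SD2 as significantly
elevated — and DFA α1 as significantly decreased — within H2-H4 in the LPS
group, and how often does the stationary control group trip the same
criterion (pure type-I error)?  Writes per-seed flags and the summary
rates to results/.
"""

import argparse
from pathlib import Path

from fetalhrv.pipeline import flag_rates, pipeline_recovery

ROOT = Path(__file__).resolve().parent.parent


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-cohorts", type=int, default=10,
                        help="number of regenerated cohorts (seeds)")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    flags = pipeline_recovery(args.n_cohorts, master_seed=args.seed)
    rates = flag_rates(flags)
    args.out.mkdir(parents=True, exist_ok=True)
    flags.to_csv(args.out / "recovery_flags.csv", index=False)
    rates.to_csv(args.out / "recovery_rates.csv", index=False)
    print(f"flag rates over {args.n_cohorts} cohorts "
          f"(effect window H2-H4):")
    print(rates.pivot(index="variable", columns="group",
                      values="rate").round(2).to_string())


if __name__ == "__main__":
    main()
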