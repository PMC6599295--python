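#!/usr/bin/env python
"""Sequon occurrence rates with score confidence intervals.

Two parts: (1) score CIs recomputed from the published occurrence counts
(the N-~P-S/T rate among O-GlcNAc sites and the out-of-sample
misprediction rate), confirming the CI engine against the printed
intervals; (2) a full occurrence table for the candidate sequons on the
synthetic O-GlcNAc and O-GalNAc subsets, including the composite
consensus ~(W-S/T-W).
"""

import argparse
from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from oglyc_lpm.sequon_analysis import occurrence_table, score_ci
from oglyc_lpm.synthetic_data import sample_study

PATTERNS = ["N-P-S/T", "N-~P-S/T", "~N-X-S/T", "W-S/T-W", "~W-S/T-~W",
            "~W-S/T-W", "W-S/T-~W", "~(W-S/T-W)"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scale", type=float, default=0.5)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1] / "results")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for label, count, n in [("oos misprediction rate", 54, 259),
                            ("O-GlcNAc N-~P-S/T rate", 5, 411)]:
        s = score_ci(count, n, 0.95)
        rows.append({"quantity": label, "count": count, "n": n,
                     "rate_pct": round(100 * s.rate, 2),
                     "ci_low_pct": round(100 * s.ci_low, 2),
                     "ci_high_pct": round(100 * s.ci_high, 2)})
        print(f"{label}: {100 * s.rate:.2f}% "
              f"({100 * s.ci_low:.2f}%, {100 * s.ci_high:.2f}%)")
    pd.DataFrame(rows).to_csv(args.out / "published_count_cis.csv",
                              index=False)

    study = sample_study(seed=args.seed, scale=args.scale)
    tables = []
    for subset in ("oos_oglcnac", "ogal"):
        df = occurrence_table(PATTERNS, study[subset])
        df.insert(0, "subset", subset)
        tables.append(df)
        wstw = df[df.sequon == "W-S/T-W"]["rate_pct"].iloc[0]
        print(f"{subset}: W-S/T-W occurrence {wstw:.2f}% "
              f"(the composite consensus ~(W-S/T-W) holds when this is 0)")
    pd.concat(tables).to_csv(args.out / "sequon_occurrence.csv", index=False)
    print(f"wrote {args.out / 'sequon_occurrence.csv'}")


if __name__ == "__main__":
    main()
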