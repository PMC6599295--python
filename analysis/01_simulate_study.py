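#!/usr/bin/env python
"""Generate the synthetic study tables and write them under results/.

Produces every analysis subset the downstream scripts consume: the
structural estimation classes (O-GlcNAc positives vs multi-sugar N-glyc
negatives), the sequence-only classes, the out-of-sample O-GlcNAc and
O-GalNAc sets, and the W-S/T-W control set.
"""

import argparse
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from oglyc_lpm.study_io import write_study_table
from oglyc_lpm.synthetic_data import sample_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scale", type=float, default=0.5,
                    help="multiplier on the study sample sizes")
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1]
                    / "results" / "synthetic_study")
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    study = sample_study(seed=args.seed, scale=args.scale)
    for name, table in study.items():
        path = args.out / f"{name}.csv"
        write_study_table(table, path)
        print(f"{name}: {len(table)} records -> {path}")


if __name__ == "__main__":
    main()
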