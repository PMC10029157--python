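#!/usr/bin/env python
"""Assign every synthetic KRTAP to the O or M lineage and score recovery.

Searches the simulated proteome with the occludin-like and
metallothionein-like baits, applies the linked/similar harvest rules and
the two-round direct/indirect assignment, writes assignments.tsv, and
compares the labels with the generator's ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from krtap.linkage import assignments_frame
from krtap.synthetic import run_recovery_study

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--sub-rate", type=float, default=0.3)
    parser.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    study = run_recovery_study(args.sub_rate, seed=args.seed)
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    frame = assignments_frame(study["assignments"])
    frame.to_csv(out / "assignments.tsv", sep="\t", index=False)

    summary = pd.DataFrame([{
        "sub_rate": args.sub_rate,
        "seed": args.seed,
        "direct_recovery": study["direct_recovery"],
        "indirect_recovery": study["indirect_recovery"],
        "decoy_fpr": study["decoy_fpr"],
    }])
    summary.to_csv(out / "recovery_summary.tsv", sep="\t", index=False)

    counts = frame["label"].value_counts().to_dict()
    print(f"assigned {len(frame)} KRTAP-like proteins: {counts}")
    print(f"direct-lineage recovery {study['direct_recovery']:.1%}, "
          f"indirect {study['indirect_recovery']:.1%}, "
          f"decoy false linkage {study['decoy_fpr']:.2%} "
          f"-> {out / 'assignments.tsv'}")


if __name__ == "__main__":
    main()
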