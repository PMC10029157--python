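#!/usr/bin/env python
"""Generate the synthetic lineage study used by the downstream steps.

Writes the proteome FASTA (two ancestor baits, two evolved KRTAP-like
families with a second generation, 500 composition-matched decoys), the
KRTAP id list, the ground-truth table and a lineage-structured expression
table under results/study/.
"""

import argparse
from pathlib import Path

from krtap import write_fasta
from krtap.seqstore import SequenceStore
from krtap.synthetic import build_study, make_expression_table

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--sub-rate", type=float, default=0.3)
    parser.add_argument("--outdir", type=Path,
                        default=ROOT / "results" / "study")
    args = parser.parse_args()

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    study = build_study(args.sub_rate, seed=args.seed)
    write_fasta(study["db"], out / "proteome.fa")
    write_fasta(SequenceStore([study["o_bait"]]), out / "o_bait.fa")
    write_fasta(SequenceStore([study["m_bait"]]), out / "m_bait.fa")
    (out / "krtap_ids.txt").write_text(
        "\n".join(sorted(study["krtap_ids"])) + "\n")
    study["truth"].frame().to_csv(out / "truth.tsv", sep="\t", index=False)

    labels = {r.protein_id: r.lineage for r in study["truth"].rows
              if r.generation in ("direct", "indirect")}
    make_expression_table(labels, m_effect=26.0, seed=args.seed).to_csv(
        out / "expression.tsv", sep="\t")

    n = len(study["db"])
    print(f"simulated proteome of {n} records "
          f"({len(study['krtap_ids'])} KRTAP-like, seed {args.seed}, "
          f"substitution rate {args.sub_rate}) -> {out}")


if __name__ == "__main__":
    main()
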