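# krtap — tracing keratin-associated protein lineages

The human genome carries 93 keratin-associated protein (KRTAP) genes, the
small cysteine-rich or glycine/tyrosine-rich proteins that cross-link
trichocyte keratins in hair and wool fibres. Sequence similarity connects
these proteins to two far older molecules: a short glycine-tyrosine-rich
fragment of the tight-junction protein **occludin** and the cysteine-rich
metal-binding **metallothioneins**. This package implements, as a tested
and fully scripted pipeline, the homology-tracing procedure that splits a
KRTAP set into an occludin-derived (**O**) and a metallothionein-derived
(**M**) lineage, together with the sequence-feature diagnostics, distance
trees, and rank statistics used to characterise the two lineages. A
seeded synthetic-data generator stands in for the proteome, so every
stage runs on a desk with no download.

## What it computes

* **Local alignment with Expect values.** Exact Smith–Waterman dynamic
  programming under BLOSUM62 with affine gaps (existence 11, extension 1;
  a gap run of length *L* costs 11 + (*L* − 1)), no low-complexity
  masking and no compositional adjustment. Scores are calibrated by
  Karlin–Altschul statistics: bit score *S′* = (λ*S* − ln *K*)/ln 2 and
  Expect value *E* = *K m n* e^(−λ*S*) with λ = 0.267, *K* = 0.041 over
  the full *m*·*n* search space. An ungapped-λ solver (the unique
  positive root of Σᵢⱼ *p*ᵢ*p*ⱼ e^(λ*s*ᵢⱼ) = 1) sanity-checks the
  calibration.
* **Harvest rules and lineage assignment.** A bait search ranks the
  proteome by Expect value; the top-*n* hits are **linked** to the bait
  and hits with *E* ≤ 10⁻³ are **similar**. KRTAPs linked to exactly one
  of the two ancestor baits get a direct O/M label (linkage to both is
  surfaced as an error, since the procedure relies on the two direct
  sets being disjoint); the remainder are re-searched as baits and
  labelled O/M/dual-**indirect** by their sub-threshold hits to
  direct-labelled KRTAPs, or left unlinked.
* **Feature profiles.** Cysteine and Gly+Tyr fractions, GYG-triplet
  residue coverage with the ≥ 1/7 pass criterion, greedy non-overlapping
  counts of CC-prefixed 5-mer repeats, diagnostic motifs
  (CCCKPVCC/CCCKPMCC), the longest contiguous GY chain, and an
  UHS/HS/HGT sulphur-group classification.
* **Distance tree and the two-branch check.** A pairwise distance matrix
  from local-alignment identity (default: identities scaled by the
  shorter sequence length), classical neighbor joining, Newick output,
  and a bipartition-purity scan that makes the "O and M segregate into
  two main branches" claim testable.
* **Rank statistics.** Mann–Whitney rank-sum (exact by enumeration for
  small tie-free samples), Kruskal–Wallis, the pooled two-proportion
  z-test, median/IQR summaries, and a lineage-stratified expression
  comparison driver.
* **Synthetic data.** Seeded generators for the two ancestor archetypes,
  families evolved by whole-repeat-unit duplication/deletion plus
  BLOSUM62-conditional substitution, composition-matched decoy
  proteomes, and lognormal expression tables with a multiplicative
  M-lineage effect — with ground truth for recovery benchmarking.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1, substitution rate 0.3, 500 decoys):

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_classify_lineages.py --seed 1
python analysis/03_profile_features.py --seed 1
python analysis/04_tree_and_purity.py --seed 1
python analysis/05_lineage_statistics.py --seed 1
```

which prints, among other things:

```
assigned 40 KRTAP-like proteins: {'M_direct': 20, 'O_direct': 20}
direct-lineage recovery 100.0%, indirect 100.0%, decoy false linkage 0.20%
NJ tree over 40 leaves; best two-clade split purity 1.000 (side of 20)
length: M median 181 vs O median 70, rank-sum p = 5.31e-08
expression: M median 2219.3 vs O median 87.2, p = 6.80e-08
```

Read: every synthetic KRTAP was assigned its true lineage through the
bait searches; 1 of 500 unrelated decoys (0.2%) reached the *E* ≤ 10⁻³
similarity threshold by chance; the neighbor-joining tree splits
perfectly into an all-M and an all-O branch; and the M lineage is both
longer (tandem-repeat regions) and far more highly expressed than the O
lineage, each contrast highly significant by rank-sum test.

The same operations are exposed as a CLI (`krtap io-validate | align2 |
dotplot | classify | features | tree | stats | simulate | clades | full`)
for use on real FASTA/TSV inputs.

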