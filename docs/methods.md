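# Methods

This note records the models, algorithms, defaults and numerical choices
behind each analysis stage, plus known limitations.

## Gene model

A gene is an ordered list of exon *slots*. Each slot is one of:

- **constitutive** — always spliced in;
- **optional** — included or skipped;
- **cluster** — a mutually exclusive array; exactly one variant per
  mature transcript;
- **placeholder** — a slot whose exon could not be sequenced (counts
  toward the slot total but has no exon record and no sequence).

Pairwise **splice constraints** (`A implies B`, `A forbids B`) relate
exon identities. **Terminators** describe how translation can end: a
`stop_variant` (the stop lies inside a terminal cluster variant) or a
`retained_intron` after a boundary slot — the retained intron carries
its own stop codon and poly(A) signal and yields a truncated, secreted
("tail-less") protein.

Coordinates are GFF3-style (1-based, closed). Validation returns
violations as data, never exceptions; analyses that require a sound
model (census, counting, enumeration) refuse invalid input loudly.
Constraints joining slots on opposite sides of the retained-intron
boundary are rejected, because a truncated isoform could not evaluate
them consistently.

Serialization is FASTA (genome) + GFF3 (exon records) + YAML
(slots/constraints/terminators/curated peptides); `save_model` then
`load_model` is the identity on every field. Minus-strand exon sequences
are reverse-complemented on extraction.

## Isoform counting and enumeration

The isoform space is the set of valid selections: one variant per
cluster, an include/skip bit per optional exon, and a terminator class.
Counting is exact over Python integers:

- slots untouched by any constraint contribute closed-form factors
  (cluster arity; 2 per optional exon);
- slots connected by constraints are grouped (union-find) and each group
  is enumerated exhaustively.

A retained-intron terminator splits the gene at its boundary slot:
`n_membrane_bound = n_extracellular × n_tail`, and tail-less isoforms add
one per extracellular configuration. Enumeration is slot-major and
deterministic (skip before include; variants in declared order;
membrane-bound before tail-less) and raises `EnumerationTruncated`
rather than truncating silently. Tests verify counting, enumeration and
an independent Cartesian-product-plus-filter oracle agree on hundreds of
random constrained models.

## Translation and motifs

Splicing is concatenation of selected exon sequences in slot order (the
retained intron is appended for tail-less isoforms). Translation uses
the standard genetic code from position 1 and reports the first stop's
codon index and source segment; a stop spanning a splice junction is
attributed to the exon contributing its final base. This is how the
model expresses the terminal coupling in the reference gene: the last
optional exon ends in two dangling bases that complete a TAA stop with
the first base of terminal variant 44.1.

Motif scanning uses residue-class consensi (`X` = any residue,
`[...]` = class). ITAM (`YXXL`), ITIM (`[ISVL]XYXX[VL]`) and RGD are
curated patterns; SH2/SH3/polyproline/PDZ-ligand defaults are standard
literature classes and every report labels them as non-curated. All
overlapping hits are reported with 1-based spans.

## Evidence inference

Each cDNA contig contributes an ordered exon chain that only votes on
slots within its span, so partial contigs never misclassify uncovered
exons. Calls per slot: constitutive / optional / cluster / unobserved /
ambiguous (co-occurring variants, or a spanned slot whose exons are
never seen). `A implies B` is emitted when B appears in 100 % of the
A-carrying chains that span B's slot, with chain support attached;
rules with support below `min_support` (default 3) are withheld, and
rules whose endpoint is constitutive are suppressed as vacuous.

## Array discovery

Candidate internal exons are windows preceded by an AG acceptor and
followed by a GT donor, with lengths stepped by 3 inside a band of
±40 % around the profile's median nucleotide length (a relaxed ±80 %
band is still reported, flagged `abnormal_length`). Each in-frame,
stop-free window is translated and scored against the peptides of known
cluster members as `1 − edit_distance / max(length)` (best member wins;
alignment via edlib). Overlaps are resolved greedily by score; score
ties prefer the candidate whose length is closest to the profile median
(the scan's own length model), then the leftmost window. Survivors are
numbered in genomic order. Minus-strand scans work on the reverse
complement and map coordinates back. Default minimum similarity: 0.5.

Measured on seeded synthetic genomes (tandem arrays of five 40-residue
variants, canonical GT–AG introns): recovery of the exact planted
intervals has recall and precision 1.0 across 50 genomes at 0.8 planted
identity; at higher divergence recall degrades and is reported by the
test suite rather than asserted.

## Clone assignment

An amplicon clone spans one or more clusters. Each cluster vote aligns
every variant as an *infix* of the clone (edlib HW mode) and requires a
unique best hit with identity ≥ threshold (default 0.95): unique best →
assigned; tie → ambiguous; below threshold → unassigned. Tallies produce
a variants × tissues count matrix plus per-tissue and overall
undetected-variant lists; ambiguous/unassigned votes are counted
separately and never enter the matrix.

## Conservation logos and epitopes

Per-column conservation is information content IC = log₂ 20 − H (bits),
with H the Shannon entropy of residue frequencies; gaps are excluded
from frequencies and reported as occupancy. An optional small-sample
correction subtracts 19/(2 ln 2 · n), floored at 0. Closed forms used as
test oracles: invariant column → log₂ 20; 20 equiprobable residues → 0;
two equiprobable residues → log₂ 20 − 1.

Epitope windows are cut relative to conserved anchors: a fixed position
with an expected residue set (positions count non-empty alignment
columns, so gap-padding shifts windows consistently) or a short motif
located where it matches the most sequences. Anchors must resolve in
≥ 90 % of sequences (a failed sequence is flagged, never dropped; if the
expected residue is still the column's modal residue the extraction
proceeds with a warning). The packaged rules give 12- and 13-residue
windows around the invariant 16I/41V of the Ig2 cluster and 8-residue
windows around the 9K/R and LLC anchors of the Ig3 cluster.

## Synthetic data

All generators are deterministic functions of a seed and emit truth
records. `simulate_gene` plants cluster arrays (substitution mutants of
a random ancestor at a target identity, random synonymous codons,
canonical GT–AG introns). `simulate_transcripts` samples valid isoforms
by enumeration weight, which guarantees validity under any constraint
set (practical for small models only). `simulate_clone_survey` emits
individuals × clones × tissues amplicons (chosen variants joined by the
constitutive backbone between clusters) with substitution errors only —
no indels, chimeras or quality models. `encode_dual_frame` constructs a
nucleotide stretch encoding one peptide in frame 0 and a second peptide
at a shifted offset (positions past the first stop are treated as
3′UTR), via node-capped backtracking over synonymous codons.

## Reference fixture

The packaged PmDscam-like model has 44 slots: placeholder exon 1;
clusters at slots 4 (26), 6 (81), 15 (26), 32 (2) and 44 (2); optional
tail exons 34, 36, 37, 39, 41, 42, 43; the rest constitutive. The
cytoplasmic-tail peptides (exons 31–44) are curated sequences;
extracellular nucleotide sequences are deterministic synthetic stand-ins
flagged `synthetic` on each record, since the real sequences live in a
sequence-database accession. Terminal variants 44.1/44.2 overlap on the
genome in shifted frames; exon 43's junction stop and the retained
intron after exon 31 (stop + AATAAA) are encoded in actual nucleotides,
so the combinatorics, translation and evidence results all emerge from
sequence, not annotation.

## Limitations

- Counting assumes constraint groups small enough to enumerate; the
  component count is exact but worst-case exponential in the size of a
  single constraint-connected group.
- Enumeration-weighted transcript sampling enumerates the isoform list
  first and is therefore unsuitable for the full 21-million-isoform
  model (use sub-models).
- Array discovery assumes substitution-dominated divergence and
  canonical GT–AG boundaries; non-canonical splice sites and heavily
  indel-diverged variants are out of scope.
- Clone simulation models substitution errors only.
- Extracellular fixture sequences are stand-ins: analyses that depend on
  real extracellular nucleotides (e.g. real-data array discovery) are
  demonstrated on synthetic instances instead.
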