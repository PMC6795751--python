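# Methods

## Problem and model

Circular RNAs (circRNAs) are covalently closed transcripts produced by
back-splicing. Because a circRNA's sequence is a permutation of exonic
sequence already present in the linear transcriptome, the only read-level
evidence that distinguishes a circle is a read crossing its back-splice
junction — the point where the 3' end rejoins the 5' end. `ribocirc`
asks a narrower question than circRNA discovery: given candidate circRNA
sequences, which of them are *translated*? The evidence is ribosome
profiling (Ribo-seq): ~25-35 nt ribosome-protected fragments (RPFs) that
mark actively translated positions. A circRNA with RPFs across its
junction, in sufficient number, and with junction sequence that looks
like coding sequence, is called translated, and the peptide produced
across the junction is predicted.

The pipeline has five stages:

1. **Read preparation** (`readprep`). Adapter and quality trimming
   (leftmost adapter-prefix match of ≥7 nt with ≤1 mismatch; leading /
   trailing base quality trim; 4-nt sliding window with mean Phred < 15
   truncating at the window start; reads < 20 nt discarded; the step
   sequence is iterated to a fixpoint so trimming is idempotent). Reads
   aligning full-length to an rRNA reference with ≤2 substitutions on
   either strand are removed, then reads *perfectly* matching the linear
   genome (0 mismatches, either strand) are removed. What remains cannot
   be explained by the linear genome — the "final unique" reads.
2. **Pseudo-reference** (`pseudoref`). Each candidate circRNA sequence is
   duplicated in tandem so the back-splice junction sits exactly at the
   unit midpoint (`J = offset + L`); units are joined with 100-N spacers
   so that no RPF (< 50 nt) can align across two circRNAs. Coordinates
   are 0-based half-open everywhere; 1-based conversion happens only at
   the SAM/BED boundary.
3. **Junction mapping** (`junctionmap`). A gap-free seed-and-verify
   aligner with a pigeonhole completeness guarantee: a placement with ≤ m
   substitutions must contain one of m+1 disjoint exact chunks, so
   looking up each chunk's leading k-mer and verifying every candidate
   offset end-to-end finds *all* placements (reads too short for m+1
   chunks fall back to a vectorised full scan). Alignments may not touch
   an N, which confines them to one doubled unit. Reads hitting two
   units are discarded as ambiguous; the tandem-duplication shadow inside
   one unit is collapsed (junction-spanning placement preferred, else
   leftmost). Per circRNA, junction-spanning placements (≥1 nt on each
   side of J by default) are counted as NMJ; strictly more than 3 are
   required, and their union interval is the RMRJ (read-mapped region on
   the junction).
4. **Classification** (`netclassify`). Each RMRJ sequence is mapped to a
   word-adjacency network: nodes are its 3-mers, undirected edge weights
   count adjacent (step-1 overlapping) word pairs, self-loops excluded.
   Six global measures — mean degree, mean clustering, degree
   assortativity, mean normalised betweenness, mean shortest path over
   the largest component, edge/node ratio — are recomputed while edges
   with weight ≤ t are removed for t = 0…9, giving a 60-long feature
   vector. Degenerate cases (empty graph, undefined assortativity,
   single-node components) map to 0. Features are min-max scaled to the
   training bounds and classified by entropy-split (information-gain)
   decision trees — a single tree, or a forest (function default 25; the
   pipeline uses 100, which measurably stabilises decisions at these
   training sizes). A circRNA whose RMRJ is labelled coding is reported
   as translated. No ORF or start-codon logic enters the features, so
   non-AUG initiation is not penalised.
5. **Peptide prediction** (`peptides`). Because RPF coverage of circRNAs
   is too sparse for reliable initiation-site calling, peptides are
   called without a start codon: in each reading frame of the RMRJ, the
   maximal stop-free amino-acid runs are enumerated; runs that cover the
   junction (≥1 base on each side) and reach 10 aa are kept and the
   longest wins (ties: lowest frame, then leftmost). The call never
   contains a stop and its interval re-translates exactly to its peptide.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `spacer` | 100 nt | N run between doubled units; must exceed read length |
| `seed_len` (k) | 12 | index k-mer; capped at min(read)/(mismatches+1) |
| `max_mismatch` | 2 | substitution budget for virtual-genome mapping |
| `rrna_max_mismatch` | 2 | budget for rRNA depletion |
| `nmj_min` | 3 | RMRJ requires NMJ strictly greater than this |
| `min_overhang` | 1 nt | bases required on each side of the junction |
| `w` | 3 | network word length |
| `thresholds` (T) | 10 | edge-weight threshold iterations |
| `n_trees` | 100 (pipeline) | information-gain trees in the forest |
| `min_aa` | 10 | minimum peptide length |

## The synthetic generator

`simdata` emulates every input: a random linear genome and rRNA
reference; candidate circRNAs (200-800 nt) of which a chosen number are
translated; RPF reads (25-35 nt) with 3' adapter read-through, mild
quality decay, uniform substitution errors (0.2%), and rRNA / linear
genome contamination (10% each); coding and noncoding training sets; and
an order-k Markov null emulator with pseudo-count-1 smoothing whose
emitted ensemble reproduces the training composition (initial states and
lengths follow their empirical distributions) but none of its frame
structure.

**The coding model.** Synthetic coding sequence has two fixed layers,
both shipped in code: codon *usage* (one preferred codon per amino acid
carrying 80% of its amino acid's mass, amino-acid weights typical of
globular proteins) and codon *pair* structure — a first-order chain over
sense codons in which each codon has one favored successor carrying 90%
of the transition mass. The successor map contains eight disjoint
4-codon **guard cycles** A→B→C→D→A in which (A,B) reads a stop codon in
frame +1 and (C,D) in frame +2 (eight is the structural maximum: only
eight sense codons can precede a +1-frame stop). The pair layer is a
deliberately sharp caricature of natural codon-pair bias. It exists
because the fixed 6-measure × 10-threshold feature space is
statistically weak on 30-60 nt windows: with codon usage alone,
cross-validated separation from composition-matched Markov nulls is near
chance at RMRJ scale, whereas the 12-nt-periodic pair structure
concentrates word-adjacency weight strongly enough that junction windows
remain classifiable.

**Planting.** A translated circRNA carries a junction-crossing coding
run (60-300 nt, ≥18 nt on each side of the junction, flanked by in-frame
stop codons) built as guard-cycle repeats: one cycle left of the
junction, a different cycle right of it, with random phases. Guard
cycles make the planted frame decidable — both shifted frames hit a stop
within every 12 nt on either side of the junction, so the planted frame
is the unique junction-covering stop-free frame at window scale — while
keeping the junction region statistically identical to the rest of the
coding model. Junction (cycle, phase) configurations are dealt without
replacement across circRNAs, and simulated junction reads anchor ≥7 nt
on each side of the back-splice; both choices prevent reads on shared
periodic arms from aligning to more than one unit, which the ambiguity
rule would otherwise punish. Untranslated circRNAs are uniform random
sequence and receive only non-spanning reads plus two (sub-threshold)
junction reads.

**Training sets.** The classifier is trained on material shaped like
what it must classify: positives are junction windows (30-60 nt) cut
from translated-circRNA models, negatives are junction windows cut from
order-1 Markov null sources of candidate-circRNA length fitted to the
positives. Training on full-length transcripts instead transfers poorly
to RMRJ-scale windows, because all six measures scale with sequence
length.

**What the generator does not emulate.** Real codon-pair bias is far
weaker than the guard-cycle caricature; real ncRNA differs from mRNA in
more ways than composition; there is no 3-nt P-site periodicity, no
splice isoforms, no PCR duplicates, no indels, and circRNA sequences are
drawn independently of the simulated genome. Passing tests therefore
demonstrate that the machinery is correct and that the statistical
design behaves as intended under these conditions — not that the
classifier would reach the same accuracy on real Ribo-seq data.

## Validation experiments (`evaluation`)

*Null-model FDR.* Train on 500 coding junction fragments vs 500 Markov
negatives; fit an order-1 emulator to the positives; emit 10,000 null
candidate sequences (candidate-circRNA lengths); give each six
junction-spanning reads through the real aligner and RMRJ stage;
classify. The fraction called translated is the false-discovery
estimate; the acceptance script reports it.

*Depth titration.* One cohort (20 translated / 10 untranslated) is
generated at 16 junction reads per circRNA; shallower depths subsample
junction reads from the same FASTQ so all conditions share circRNAs,
contaminants and training data. Depth 2 sits below the NMJ cut by
construction; sensitivity is non-decreasing in depth.

## Numerical and design notes

- Trimming iterates to a fixpoint because a truncation can expose a new,
  shorter adapter overlap; a single pass is not idempotent.
- "Not perfectly aligned to the genome" is read literally: only reads
  with a 0-mismatch full-length genomic match are removed.
- NMJ counts both strands and does not deduplicate identical reads;
  flags (`plus_strand_only`, `dedup_junction_reads`) change both.
- The RMRJ, not the whole circRNA, is classified
  (`classify_full_sequence` switches).
- A read with placements in two units is discarded outright rather than
  assigned by score: with a doubled reference, multi-unit hits are
  almost always repeats, and a wrong junction assignment is worse than a
  lost read.
- Problem sizes in tests (10,000 nulls, 1,000 aligner instances, cohorts
  of 10-30 circRNAs) are the package's study conditions for desk-scale
  validation; genome-scale runs only change counts, not code paths.
- Model files are pickles with a self-describing header (format version,
  w, T, scaling bounds); identical training inputs and seed reproduce
  the file byte for byte.
- The junction BED records each junction as the 1-bp feature [J-1, J).
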