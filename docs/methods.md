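# Methods

This note documents the models and procedures behind each module, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Coordinate model

All coordinates are 1-based inclusive (the GFF3 convention); only BED
export converts to 0-based half-open. Gene order within a chromosome is a
stable sort on (start, end, gene_id), so ranks are deterministic even with
tied starts. Strand never enters interval arithmetic: cluster linkage, gap
search and centromere calling are strand-agnostic, since none of the
implemented rules has a strand condition. Overlapping genes are permitted
and recorded on the annotation (`overlapping_ids`) rather than rejected.

## CAZyme gene clusters

The membership rule — a cluster needs ≥3 CAZyme genes, or ≥2 CAZyme genes
plus ≥1 signature gene (transporter or transcription factor) — is applied
to connected components of a linkage graph. Two genes are linked when they
are within two intergenic distances of each other **and** at least one of
the pair is a CAZyme; signature genes never link to each other. Design
choices behind this:

* *"Two intergenic distances" is a rank distance.* The rule is
  interpreted as walking the gene order: gap ≤ 2 means at most one gene
  lies between the pair. A base-pair interpretation is available behind
  `max_gap_bp` for sensitivity analysis, but rank-based linkage matches
  the "intergenic" wording and what comparable cluster callers
  (e.g. CGC-style PUL finders) do. All annotated genes of any kind count
  toward ranks; only the signature table assigns roles.
* *Transitive closure.* A signature gene within two gaps of two CAZymes
  that are themselves four gaps apart bridges them into one cluster.
  Components, not windows, are reported.
* *Roles are exclusive.* A gene tagged both CAZyme and transporter counts
  as CAZyme only, so one gene can never satisfy both membership
  thresholds.
* *Determinism.* Clusters are reported in coordinate order with ids
  `<chrom>:CGC<ordinal>`; output is invariant under gene-id relabeling and
  chromosome reversal (ranks are recomputed from coordinates).

`cazgc_oracle` is a deliberately naive re-implementation (explicit sort,
pairwise linkage enumeration, closure by repeated set expansion) restricted
to ≤ 20 genes per chromosome. The suite checks set-equality of member
lists between caller and oracle on 1,000 random instances, and
`validate_cluster` re-checks every reported cluster's invariants
independently of the caller.

## Telomeres

`detect_telomeres` counts the longest run of back-to-back motif copies
(default TTAGGG) within a terminal window of 200 bp, scanning the 3′ end
for the motif and the 5′ end for its reverse complement. A terminus is
"present" at ≥ 3 tandem copies. The motif is part of the biology; the
window and copy threshold are package defaults (no published cutoff
exists) chosen so that a genuine telomeric tract of even three repeats is
called while isolated motif hits in random sequence (expected ≪ 1 per
window) are not. Reverse-complementing a chromosome swaps the two calls
exactly.

## Centromere candidates

Fungal centromeres in assemblies of this kind are operationally defined as
the longest ORF-free, retrotransposon-dominated, transcriptionally
depressed interval per chromosome. `find_centromere_candidate` takes the
longest gap between consecutive protein-coding genes (chromosome ends
included as boundaries by default, since telomere-adjacent gaps are
separately flagged by the telomere caller; ties break leftmost).
Non-coding genes (tRNA, rRNA, lncRNA) do not interrupt a candidate — the
"ORF-free" condition concerns protein-coding gene models only. The call
reports:

* `rt_fraction` — fraction of the interval covered by the union of
  (already confidence-filtered) repeat hits. "Mostly repeats" is reported,
  not thresholded; the conventional reading is rt_fraction ≥ 0.5.
* `expr_ratio` — mean windowed read depth inside the interval divided by
  the mean over two flanks. Flank length defaults to the candidate length
  per side (no published flank size exists), clipped at chromosome ends,
  and is configurable.

## Mitogenome comparison

`mito_compare` computes a global (Needleman–Wunsch-style) edit-distance
alignment via edlib, optionally banded (`band` caps the admissible edit
distance and must be at least the length difference; exceeding it raises).
Circular genomes are first co-rotated: the second sequence is rotated to
the shift minimizing Hamming mismatches against the first 1 kb of the
first sequence, ties toward zero shift. Differences are tallied from the
alignment as substitutions, insertions (bases only in the second
sequence) and deletions (bases only in the first), and

    per_base_rate = (subs + ins + dels) / max(len_a, len_b)

displayed to 3 significant digits, so one difference across a 115,207-bp
pair prints as 8.68e-06. The test oracle is an independent full-matrix
Levenshtein DP (vectorised row-by-row); it is run at 2–4 kb, where the
full matrix is cheap, alongside planted-truth recovery on generated pairs
whose edit sites are ≥ 30 bp apart (so the optimal alignment provably
recovers the planted breakdown).

## Repeat filtering and density

Both confidence thresholds (length ≥ 140 bp, Smith–Waterman score ≥ 450)
are conjunctive, order-stable and boundary-inclusive. Class assignment
keys on the RepeatMasker class/family string: LTR/LINE/SINE → class I
(retrotransposons), DNA → class II, anything else (simple repeats,
low-complexity, unknown, rolling-circle) → other. Density tracks are
per-window fractions of bases covered by the union of hits, so duplicated
or split hits never change a track.

## Expression statistics

* RPK divides the count by transcript length in **kilobases** (forced by
  the "per kilobase" naming); TPM rescales each sample's RPK vector to sum
  to 10⁶ (all-zero samples stay zero). FPKM uses the standard
  count·10⁹/(length·library size) definition.
* Per-gene p-values come from the two-sided Fisher exact test on the
  pooled 2×2 table (gene count vs rest of library, condition A vs B).
  Pooling discards replicate-level variance, which makes the test
  anticonservative under biological overdispersion; the fold-change and
  TPM-floor conditions are what keep the false-call rate at the nominal
  level in practice (verified by the planted-null simulation), and the
  test is pluggable (`test_fn`) so a negative-binomial test can be
  substituted. Multiplicity is controlled by Benjamini–Hochberg step-up
  FDR (the standard choice where no procedure is named).
* A gene is called *up* when fold change ≥ 3 on group-mean TPM, FDR
  < 0.05, and mean TPM > 0.5 in at least one group; *down* symmetrically
  at fold ≤ 1/3, so `call_deg(A,B)`'s up-set equals `call_deg(B,A)`'s
  down-set exactly. Zero-denominator fold changes map to +∞ (an optional
  TPM pseudocount is off by default); the TPM floor guards the resulting
  calls. The significance column can be switched to raw p (`use_raw_p`)
  where FDR is not wanted.
* FRG classification requires the *up* call in both contrasts (fruiting
  body vs monokaryotic mycelia AND vs dikaryotic mycelia); a flag selects
  either-contrast semantics. The orthology partition takes one hit table
  against the reference proteome plus the FBIG/FBDG id subsets, with FBIG
  taking precedence over FBDG so the four classes are disjoint and
  exhaustive.

## Filter cascades

The lncRNA cascade applies, in order: non-gene locus; length ≥ 200 nt;
FPKM > 1 (a transcript at exactly FPKM 1 is excluded); non-coding by all
coding-potential evaluators (configurable to majority); no Pfam domain;
predictor support ≥ 3. Length and FPKM are independent exclusions by
default: the literal conjunctive reading ("length < 200 **and** FPKM ≤ 1
excluded") would keep a 100-nt high-FPKM transcript, contradicting the
≥ 200 nt definition of a lncRNA; `literal_conjunction=True` restores the
literal rule. The predictor-support count is kept independent of the three
coding-potential evaluators, since the two criteria come from different
tool sets. Effector candidates require a signal peptide, zero
transmembrane domains, no GPI anchor and length strictly < 300 aa. Both
cascades count each rejected record at its first failing stage, so stage
tallies plus the accepted set always sum to the input size.

## Synthetic data: what it emulates, and what it does not

`generate_genome` builds, per chromosome: terminal telomere tracts with
known copy numbers (with a one-base guard so the tandem run count is exact
by construction), ~40 genes with uniform lengths/gaps, one 20-kb ORF-free
gap half-way along filled to a stated fraction (default 0.8) with
high-scoring class I hits, interspersed repeat hits whose lengths and
scores deliberately straddle the 140/450 thresholds (including exact
boundary values), planted cluster patterns (e.g. CAZyme triples,
CAZyme–transporter–CAZyme) separated by ≥ 4 plain genes, decoys violating
exactly one cluster rule, and a windowed depth track that is zero across
the centromere gap. Constructors validate that planted patterns satisfy —
and decoys violate — the cluster rules before any sequence is built.
Background sequence is i.i.d. uniform ACGT: repeat *coordinates*, not
repeat sequence content, carry the signal, because no downstream stage
reads repeat sequence. Consequently passing tests demonstrate correctness
of the interval/statistical logic, not robustness to sequence-level
artefacts (chimeric hits, nested repeats, GC bias).

`generate_counts` draws negative-binomial counts (per-gene dispersion 0.1,
the standard RNA-seq model) for three groups mirroring the sampled study
design — 3 fruiting-body, 4 monokaryotic-mycelium and 2 dikaryotic-mycelium
libraries — with log-normal baseline means, per-sample library factors in
[0.8, 1.25], and 100 of 2,000 genes induced 5-fold in fruiting bodies
(a realistic strong induction; the reference FB-initiation gene sets are
themselves defined by ≥ 4-fold changes). Dispersion 0 degenerates to
Poisson, which the law-of-large-numbers test uses. The generator does not
emulate batch effects, gene–gene correlation, or length-coupled counting
biases.

Under these conditions the analytic single-contrast sensitivity of the
DEG caller at the fold-3 threshold is ≈ 0.91 (the realized TPM fold of a
planted gene is ~5/1.2 ≈ 4.2 after compositional renormalization, and the
log-ratio SD from dispersion 0.1 at these group sizes is ≈ 0.24), with a
binomial SD of ≈ 0.03 at 100 planted genes. The suite therefore fixes the
recovery thresholds at sensitivity ≥ 0.80 per contrast and ≥ 0.75 for the
two-contrast FRG conjunction, with false-call rate ≤ 0.05 — bounds the
stated conditions meet with margin on every seed rather than on average.

## Test and acceptance scale

Problem sizes are chosen so the whole suite runs in well under a minute:
oracle equivalence at 1,000 random ≤ 20-gene chromosomes; Fisher-vs-
enumeration exhaustively for all 2×2 tables with margins ≤ 12 plus 200
random tables with margins ≤ 60 (the exact-rational oracle agrees with
the implementation to < 1e-15 on every table checked); the planted-null
false-call simulation at 20 seeds × 300 genes; the full-matrix edit-
distance oracle at 2–4 kb; synthetic genomes of 3 chromosomes × ~70 kb.
`scripts/acceptance.py` re-runs the same computations from scratch at a
user-supplied seed and reports the measured values as JSON.

## Known limitations

* The Fisher test on pooled counts is a fixed-margin approximation; with
  strong overdispersion and large replicate numbers an NB test (e.g.
  edgeR-style) should be plugged in via `test_fn`.
* The centromere heuristic returns exactly one candidate per chromosome
  and cannot represent diffuse or multiple repeat-rich gaps.
* Circular co-rotation assumes the two mitogenomes agree well over the
  probe kilobase; assemblies differing structurally at the origin need
  manual co-orientation.
* `cazgc_oracle` is intentionally exponential-ish and refuses chromosomes
  with more than 20 genes; it exists for verification only.
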