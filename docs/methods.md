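# Methods

This note documents the models and procedures implemented in histokit,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not
demonstrate. No empirical number appears here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Family and variant classification

Queries are scored by global Needleman–Wunsch alignment with BLOSUM62 and
affine gaps (a gap of length *L* costs `gap_open + gap_extend·L`, default
10 + 1·*L*) against a bundled ten-sequence reference set: the five human
canonical histones plus H3.3, H2A.X, H2A.Z, macroH2A and CENP-A. The
family of the best-scoring reference is accepted when alignment identity
(identical columns / alignment length) reaches `min_identity = 0.35`.
Histone cores are among the most conserved proteins known, so genuine
histones align far above this floor; composition-preserving shuffles of
the bundled H4 reach at most ≈ 0.27 identity (measured in the test
suite), so the floor separates signal from composition. Ties on score are
broken by family name and then reference id, making the call independent
of reference order.

Variant refinement is rule-based rather than phylogenetic (tree building
is deliberately out of scope):

* **H3.3 vs canonical H3** — five diagnostic sites on the canonical H3
  numbering: 31 (A→S), 87 (S→A), 89 (V→I), 90 (M→G), 96 (C→S/A). Sites
  are transferred through the alignment with the canonical reference; a
  gap at a site is reported as indeterminate and excluded. A query with
  ≥ 3 variant-state sites is called H3.3. Site 96 accepts either S or A
  as the variant state because the variant residue at this site is
  reported inconsistently in the literature; the observed residue is
  always recorded so the caller can audit the decision.
* **H2A.X** — the extreme C terminus matches S-Q-[E/D/I]-[Y/F/L]; a
  *near-match* (positions 1, 2, 4 fit, position 3 does not, e.g. SQAY) is
  also classified H2A.X, since an oocyte-restricted paralogue may carry a
  degenerate acidic position while retaining the phospho-acceptor serine.
* **macroH2A** — total length > 1.8× the canonical H2A reference. The
  true length ratio is ≈ 2.8, so 1.8 tolerates substantial truncation
  while rejecting tagged or extended conventional H2As.
* **CENP-A** — best-scoring reference is the CENP-A entry (an H3-derived
  fold with a long N-terminal tail); the N-terminal extension length is
  recorded as evidence.
* **sperm-type H2B** — an H2B-family protein with ≥ 2 SPKK/SPKK repeats
  in its N-terminal tail.

The bundled reference sequences are curated consensus reconstructions of
the human proteins (record headers state this). The macroH2A entry is a
synthetic stand-in — an H2A-like histone fold plus a basic linker plus a
composition-matched macro-domain-length filler — because only its length
and H2A-fold carry classification signal; it is labelled `_synthetic` in
the data file.

## Regulatory architecture and replication-dependency

Replication-dependent metazoan histone mRNAs are not polyadenylated; 3′
processing is directed by a conserved 16-nt stem-loop (6-bp stem, 4-nt
loop) shortly after the stop codon plus a purine-rich histone downstream
element (HDE) that base-pairs with U7 snRNA. The scanners:

* **TATA-box** — all TAWAAA (TA[A/T]AAA) matches, overlapping included,
  in a 120-nt window upstream of the start codon (no window is dictated
  by the biology; 120 nt covers core promoters of compact genomes).
* **Stem-loop** — 16-nt windows at offsets 0–40 after the stop (covering
  the 6–17-nt non-conserved spacer with slack). A window qualifies when
  (a) its stem forms ≥ `6 − max_mismatch` Watson–Crick/GU pairs
  (`max_mismatch = 3`) *and* (b) it lies within `max_consensus_distance =
  6` edits of a configurable consensus element (default a metazoan-type
  element, `GGCTCTTTTCAGAGCC`). The structural test alone is too
  permissive: a random 16-mer forms ≥ 3 stem pairs with appreciable
  probability, so a conserved-element class needs the similarity gate.
  Among qualifying windows the highest stability wins; ties go leftmost.
* **Stability** — additive stem score (GC = 3, AT = 2, GU = 1, mismatch =
  −2) in place of free-energy folding; no folding parameters are part of
  this pipeline's contract, and the additive score is monotone in the
  number of broken pairs, which is the property the downstream rule
  needs. The "unstable" threshold is 12 — the score of a perfect all-AT
  stem — so *any* broken pair drops an element below the weakest fully
  paired stem.
* **HDE** — best 10-nt window within 25 nt downstream of the stem-loop,
  reported when its purine (A/G) fraction ≥ 0.7; only sought after a
  stem-loop, since the element is defined relative to it.
* **polyA signal** — first AATAAA or ATTAAA in the 3′-UTR (the canonical
  hexamer plus its most common variant).

Dependency rules, applied in order to the per-gene feature set and the
per-stage expression table: (1) stable stem-loop + HDE + no polyA →
replication-dependent; (2) polyA + no stem-loop →
replication-independent; (3) stem-loop below the stability threshold + no
polyA + no expression in any stage → pseudogene candidate; (4) otherwise
ambiguous. Every verdict carries the fired rules as rationale. The
function is pure: identical inputs give identical verdicts.

## Copy-number estimation

Reads are decomposed into canonical 17-mers (lexicographic minimum of
forward and reverse complement; windows containing N are skipped; reads
are strand-collapsed because sequencing samples both strands). The
multiplicity histogram is smoothed with a width-3 moving average and its
mode above `min_multiplicity = 4` (excluding the sequencing-error peak;
ties to the lower multiplicity) is taken as the single-copy
("diploid-peak") coverage. The repeat unit's coverage is the *median*
multiplicity of its k-mers — robust to unique flanking k-mers and
repeat-edge effects — and

    copies_diploid = region_coverage / diploid_peak
    copies_per_haplotype = copies_diploid / 2.

This reproduces the conventional worked arithmetic exactly (28,000× /
20× = 1400 diploid = 700 per haplotype; 46,000× / 20× = 2300). Under the
alternative reading in which the single-copy peak already represents two
haplotype copies, every estimate would differ by a factor of 2; both
numbers are always reported so the ambiguity stays visible rather than
being resolved silently.

Desk-scale validation plants C ∈ {5, 50, 200} identical tandem copies of
a ~4.4-kb unit in a 50-kb background and simulates error-free 250-nt
reads at 20×; the estimator recovers C within 15% (typically within
5%). Note the k-mer multiplicity of single-copy sequence runs at
`coverage · (L − k + 1)/L` ≈ 0.94 × base coverage for L = 250, k = 17;
the unit/peak ratio divides this factor out, which is why the ratio — not
the peak itself — is the estimand.

## Alignment-free stem-loop comparison

Distances between 16-nt elements are Jaccard distances over k-mer sets
(k = 4, so an element contributes 13 k-mers). This is a proper metric
(verified on random triples in the suite) and is used instead of
mismatch-extended common-substring statistics because, at 16 nt,
set-based distances are well behaved and parameter-light; the distance
function is pluggable. Clustering is plain agglomerative (single or
UPGMA average linkage over the original distances) with deterministic
lexicographic tie-breaking, cross-checked against scipy's linkage
heights in the suite. The qualitative contract — a degenerate element
with 3 stem substitutions joins the dendrogram last among intact
elements — is the tested surface; exact distances depend on k and are
not meaningful beyond ordering.

## Synthetic data generator

The generator emulates the statistical structure of a compact, AT-rich
(GC = 0.35) hydrozoan genome carrying a full histone complement:

* a canonical cluster unit of five intron-less genes (H1, H2A, H2B, H3,
  H4), each with a planted TATA-box 25 nt upstream of the ATG, a perfect
  stem-loop 6–17 nt after the stop, and a pure-purine HDE, plus four
  small non-histone placeholder genes (5S rRNA, U1/U2 snRNA, Arg-tRNA)
  — repeated head-to-tail `cluster_copies` times;
* fourteen dispersed variant loci with introns (GT..AG boundaries,
  uniform positions; exon counts follow the tabulated complement:
  1 intron for H1.2/H2A.X.1/CENP-A/H3.3.2-less etc., 4 for
  H2A.X.2/H2A.Z, 7 for macroH2A) and polyA signals in place of
  stem-loops for the replication-independent set;
* five sperm-H2B analogues with 2/6/7/5/6 planted SPKK/SPKR repeats;
* one pseudogene analogue (H1.3): intact coding sequence, stem-loop with
  3 broken stem pairs, no HDE, no polyA, expressed in no stage;
* an H2A.X.2 analogue ending SQAY and two H3.3 analogues whose site-96
  change is reverted to the canonical C (the hydrozoan state, 4/5
  diagnostic sites).

Coding sequences are seeded from the bundled references:
reverse-translated with per-codon synonymous re-draws (rate 0.15) and
per-residue amino acid substitutions (rate 0.02) away from guarded
positions (diagnostic sites, C-terminal tetrad, SPKK blocks), so
classification runs against genuinely diverged sequences rather than
byte-identical copies. Every planted promoter/UTR is verified by running
the package's own scanners at generation time, resampling the random
spacers in the rare cases a spurious motif appears; the emitted truth is
therefore consistent with the emitted sequence by construction, which is
exactly the property a planted-truth benchmark must have.

Read simulation is uniform-start, strand-balanced, fixed-length, with
i.i.d. substitution errors (`ceil(coverage · G / L)` single-end reads;
paired mode uses a fixed insert). Defaults: 250-nt reads at 20×,
error-free — the regime in which copy-number recovery is benchmarked.

**What passing these tests does not show about real data:** the
background is i.i.d. (no repeat families competing with the cluster in
k-mer space), cluster copies are identical (no inter-copy divergence
flattening the region-coverage median), read errors are substitutions
only and coverage is uniform (no GC bias or fragmentation artefacts),
and the planted stem-loops are drawn from the same consensus the scanner
defaults to. On real genomes the consensus element should be re-derived
from the organism's own aligned UTRs and passed via `--consensus`, and
copy estimates should be read as order-of-magnitude lower bounds, not
counts.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; GFF3 output is standard
  1-based inclusive. FASTA/FASTQ round-trips preserve ids, residues and
  attribute maps byte-exactly (attribute values are percent-encoded).
* N (nucleotide) and X (protein) are accepted on input and excluded from
  k-mer and motif matching.
* Alignment tie-breaking takes the engine's first co-optimal alignment,
  which is deterministic for fixed inputs; the *score* is the tested
  contract (against exhaustive enumeration at small sizes).
* All randomness flows through a single seeded generator per entry
  point; identical (config, seed) pairs give byte-identical outputs.
* Report-time rounding only; all arithmetic identities
  (`copies_diploid · peak = region_coverage`) hold exactly beforehand.
* CLI exit codes: 0 success, 2 input error, 3 degenerate data (e.g. a
  k-mer histogram with no mass above the error peak).

## Known limitations

* The protamine screen is composition-only; a short basic tail on a long
  acidic protein dilutes below threshold (the windowed maximum is
  reported to make such cases visible but does not enter the call).
* CENP-A identification leans on the bundled reference; a highly
  diverged centromeric H3 with a short tail would be called canonical H3.
* The hairpin scorer is not a thermodynamic model; elements with
  non-canonical geometry (stems ≠ 6 bp, loops ≠ 4 nt) are rejected
  rather than scored.
* The copy estimator assumes the error peak and the single-copy peak are
  separated (`min_multiplicity` between them); at coverages below ~8×
  the two merge and the estimator correctly refuses rather than guesses.
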