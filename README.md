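# histokit

Annotation toolkit for histone gene complements, built around the kind of
analysis used to characterise the full histone inventory of a hydrozoan
genome: classify every histone protein into a family and variant, decide
from the gene's regulatory architecture whether it is expressed
replication-dependently, screen sperm histones for SPKK repeats and the
proteome for protamines, and estimate how many copies of the tandem
canonical histone cluster the genome carries — all runnable end-to-end on
synthetic data with planted ground truth.

## Who it is for

Genome annotators and chromatin biologists working on non-model animals
who have a draft genome, a set of candidate histone coding sequences and
(optionally) unassembled reads, and who want reproducible, rule-based
answers to four questions:

1. **Which histone is this?** Global alignment (Needleman–Wunsch, BLOSUM62,
   affine gaps: a gap of length *L* costs 10 + *L*) against a bundled
   reference set assigns the family (H1, H2A, H2B, H3, H4); residue-level
   diagnostics refine the variant. H3.3 is separated from canonical H3 at
   five sites of the canonical numbering — 31 (A→S), 87/89/90
   (SAVM→AAIG) and 96 (C→S/A); H2A.X by the C-terminal SQ[E/D/I][Y/F/L]
   tetrad; macroH2A by its macro-domain length extension (> 1.8× canonical
   H2A); CENP-A by its long N-terminal tail on an H3 fold; sperm-type H2B
   by ≥ 2 SPKK/SPKR repeats.
2. **Is it replication-dependent?** Replication-dependent histone mRNAs
   end in a conserved 16-nt stem-loop (6-bp stem, 4-nt loop) followed by a
   purine-rich histone downstream element (HDE) instead of a polyA signal.
   The scanner finds the hairpin within 40 nt of the stop codon, scores
   its stem additively (GC=3, AT=2, GU=1, mismatch=−2) and applies ordered
   rules: stable hairpin + HDE + no polyA → replication-dependent; polyA +
   no hairpin → replication-independent; degenerate hairpin + no polyA +
   no expression in any stage → pseudogene candidate.
3. **How many cluster copies?** From a canonical 17-mer multiplicity
   histogram of the reads: copies per diploid nucleus = (median k-mer
   coverage of the repeat unit) / (modal single-copy coverage), halved for
   per-haplotype. The printed worked example — a unit at 28,000× over a
   20× peak — gives 1400 diploid / 700 haploid copies.
4. **Are there protamines?** A composition screen (R+K fraction ≥ 0.45
   with R ≥ 0.25) that known protamines pass and all histones fail.

A Jaccard k-mer distance (k=4) with UPGMA clustering handles the
alignment-free comparison of the 16-nt stem-loop elements themselves,
e.g. showing that a pseudogene's degenerate element is the outgroup to
all intact ones.

## Worked example

Generate a synthetic complement (19 genes mirroring a hydrozoan histone
inventory, two cluster copies), annotate it, and estimate cluster copy
number from simulated reads:

```bash
histokit simulate --seed 11 --cluster-copies 50 --out-dir sim
histokit annotate --genome sim/genome.fasta --proteins sim/proteins.fasta \
    --genes sim/genes.gff3 --expression sim/expression.tsv --out-dir ann
histokit copynum --reads sim/reads.fastq --region sim/cluster_unit.fasta \
    --out-dir cn
```

The copy-number stage prints, for seed 11 with 50 planted copies:

```
region cluster_unit: coverage 934x, diploid peak 19x, copies (diploid) 49.1579, per haplotype 24.5789
```

i.e. the planted 50 copies are recovered within 2% (the modal single-copy
k-mer multiplicity sits slightly below the 20× base coverage because a
250-nt read contributes only 234 17-mers, and the unit/peak ratio divides
that factor out). The
annotation stage writes `classification.tsv` (19/19 correct family and
variant calls on the planted truth), `dependency.tsv` (11
replication-dependent, 7 replication-independent, 1 pseudogene candidate
— the linker-histone analogue whose stem-loop carries 3 mismatches and
which is expressed nowhere), `motifs.tsv` (SPKK counts 2/6/7/5/6 for the
five sperm-H2B analogues, no protamine-like sequence) and
`features.gff3`.

The desk arithmetic of the copy estimator is exposed directly:

```python
>>> from histokit.copynum import estimate_copies
>>> estimate_copies(28_000, 20).copies_diploid, estimate_copies(28_000, 20).copies_per_haplotype
(1400.0, 700.0)
>>> estimate_copies(46_000, 20).copies_diploid
2300.0
```

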