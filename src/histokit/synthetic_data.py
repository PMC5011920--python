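"""Synthetic genomes, gene sets and reads with planted ground truth.

The generator emulates the genomic architecture of a hydrozoan histone
complement so that every pipeline stage can be exercised against known
answers:

* a tandem-repeated canonical cluster unit carrying five intron-less
  histone genes (H1, H2A, H2B, H3, H4), each with an upstream TATA-box
  and a 3'-UTR stem-loop followed by a purine-rich HDE, plus small
  non-histone placeholder genes (5S rRNA, U1/U2 snRNA, Arg-tRNA) — the
  unit is repeated head-to-tail a configurable number of times;
* dispersed variant loci with introns (GT..AG boundaries) and polyA
  signals in place of the stem-loop;
* sperm-histone H2B variants whose N-terminal tails carry a configured
  number of SPKK/SPKR tetrapeptide repeats;
* one linker-histone pseudogene whose stem-loop carries three stem
  mismatches and which is expressed in no stage;
* uniform reads at configurable coverage and per-base substitution error.

Coding sequences are seeded from the bundled reference histones
(reverse-translated, codon-randomised, and lightly mutated at the amino
acid level away from diagnostic sites) so that classification against the
same reference set is exercised through genuine sequence divergence.
Every planted promoter/UTR is *verified at generation time* by running
the regulatory scanners and resampling the random spacers on the rare
occasions a spurious motif appears, so the emitted truth labels are
consistent with the emitted sequence by construction.

All outputs are byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable

from . import regulatory
from .classify import H3_DIAGNOSTIC_SITES, load_references
from .errors import InputError
from .seq_io import (
    NUCLEOTIDE,
    PROTEIN,
    ExpressionEvidence,
    GenomicFeature,
    SequenceRecord,
    reverse_complement,
    write_expression_table,
    write_fasta,
    write_fastq,
    write_gff3,
)

STAGES = ("larva", "feeding", "male", "female")
ALL_STAGES = STAGES
GENOME_ID = "synthetic_genome"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, tuple] = {}
for _codon, _aa in sorted(_STANDARD_TABLE.forward_table.items()):
    _AA_TO_CODONS.setdefault(_aa, ())
    _AA_TO_CODONS[_aa] += (_codon,)
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
STOP_CODON = "TAA"


@dataclass(frozen=True)
class GeneSpec:
    """Plan for one planted gene."""

    name: str
    family: str
    variant: str
    ref_id: str
    tata: bool = True
    stem_loop_mismatches: Optional[int] = 0  # None -> no stem-loop
    hde: bool = True
    polya: bool = False
    introns: int = 0
    spkk_repeats: int = 0
    expressed: tuple = ALL_STAGES
    protein_edits: tuple = ()  # (1-based position on the seeded protein, residue)

    def expected_verdict(self, stability_threshold: float = regulatory.DEFAULT_STABILITY_THRESHOLD) -> str:
        if (
            self.stem_loop_mismatches is not None
            and self.hde
            and not self.polya
        ):
            # a planted consensus element with m broken stem pairs
            element = _mutate_stem(regulatory.DEFAULT_STEM_LOOP_CONSENSUS, self.stem_loop_mismatches, np.random.default_rng(0))
            _, stability = regulatory.score_hairpin(element)
            if stability >= stability_threshold:
                return regulatory.REPLICATION_DEPENDENT
        if self.polya and self.stem_loop_mismatches is None:
            return regulatory.REPLICATION_INDEPENDENT
        if (
            self.stem_loop_mismatches is not None
            and not self.polya
            and not self.expressed
        ):
            return regulatory.PSEUDOGENE_CANDIDATE
        return regulatory.AMBIGUOUS


def default_cluster_unit() -> tuple:
    """The five-gene canonical repeat unit: intron-less, TATA + stem-loop + HDE."""
    canonical = dict(stem_loop_mismatches=0, hde=True, polya=False, introns=0)
    return (
        GeneSpec("H1.1", "H1", "canonical", "H1_canonical", **canonical),
        GeneSpec("H2A.1", "H2A", "canonical", "H2A_canonical", **canonical),
        GeneSpec("H2B.1", "H2B", "canonical", "H2B_canonical", **canonical),
        GeneSpec("H3.1", "H3", "canonical", "H3_canonical", **canonical),
        GeneSpec("H4.1", "H4", "canonical", "H4_canonical", **canonical),
    )


def default_variant_loci() -> tuple:
    """The fourteen dispersed loci: common variants, sperm H2Bs, pseudogene."""
    ri = dict(stem_loop_mismatches=None, hde=False, polya=True)
    rd = dict(stem_loop_mismatches=0, hde=True, polya=False)
    male = ("male",)
    return (
        GeneSpec("H1.2", "H1", "canonical", "H1_canonical", introns=1, **ri),
        GeneSpec(
            "H1.3", "H1", "canonical", "H1_canonical",
            stem_loop_mismatches=3, hde=False, polya=False, introns=0, expressed=(),
        ),
        GeneSpec("H2A.Z", "H2A", "H2A.Z", "H2AZ_variant", introns=4, **ri),
        GeneSpec("H2A.X.1", "H2A", "H2A.X", "H2AX_variant", introns=1, **ri),
        GeneSpec(
            "H2A.X.2", "H2A", "H2A.X", "H2AX_variant", introns=4,
            expressed=("female",), protein_edits=((141, "A"),), **ri,
        ),
        GeneSpec("macroH2A", "H2A", "macroH2A", "macroH2A_synthetic", introns=7, **ri),
        GeneSpec("H2B.2", "H2B", "sperm-H2B", "H2B_canonical", spkk_repeats=2, expressed=male, **rd),
        GeneSpec("H2B.3", "H2B", "sperm-H2B", "H2B_canonical", spkk_repeats=6, expressed=male, **rd),
        GeneSpec(
            "H2B.4", "H2B", "sperm-H2B", "H2B_canonical", spkk_repeats=7,
            expressed=("larva", "feeding", "male"), **rd,
        ),
        GeneSpec("H2B.5", "H2B", "sperm-H2B", "H2B_canonical", spkk_repeats=5, expressed=male, **rd),
        GeneSpec("H2B.6", "H2B", "sperm-H2B", "H2B_canonical", spkk_repeats=6, expressed=male, **rd),
        GeneSpec(
            "H3.3.1", "H3", "H3.3", "H33_variant", introns=1,
            protein_edits=((96, "C"),), **ri,
        ),
        GeneSpec(
            "H3.3.2", "H3", "H3.3", "H33_variant", introns=0,
            protein_edits=((96, "C"),), **rd,
        ),
        GeneSpec("CENP-A", "H3", "CENP-A", "CENPA_variant", introns=1, **ri),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    background_length: int = 60_000
    background_gc: float = 0.35  # hydrozoan genomes are AT-rich
    cluster_copies: int = 10
    cluster_unit: tuple = field(default_factory=default_cluster_unit)
    variant_loci: tuple = field(default_factory=default_variant_loci)
    read_length: int = 250
    coverage: float = 20.0
    error_rate: float = 0.0
    paired: bool = False
    codon_mutation_rate: float = 0.15  # synonymous codon re-draws per codon
    aa_mutation_rate: float = 0.02  # amino acid substitutions away from guarded sites
    upstream_pad: int = 150
    utr_len: int = 60
    downstream_pad: int = 20
    intergenic_spacer: int = 80

    def __post_init__(self) -> None:
        checks = {
            "background_gc": 0.0 <= self.background_gc <= 1.0,
            "error_rate": 0.0 <= self.error_rate <= 1.0,
            "coverage": self.coverage > 0,
            "cluster_copies": self.cluster_copies >= 0,
            "read_length": self.read_length >= 1,
            "background_length": self.background_length >= 1000,
            "codon_mutation_rate": 0.0 <= self.codon_mutation_rate <= 1.0,
            "aa_mutation_rate": 0.0 <= self.aa_mutation_rate <= 1.0,
            "utr_len": self.utr_len >= regulatory.ELEMENT_LEN,
        }
        for fname, ok in checks.items():
            if not ok:
                raise InputError(f"invalid config field {fname!r}")
        for spec in (*self.cluster_unit, *self.variant_loci):
            if spec.stem_loop_mismatches is not None and not (
                0 <= spec.stem_loop_mismatches <= regulatory.STEM_LEN
            ):
                raise InputError(f"invalid config field 'stem_loop_mismatches' for gene {spec.name!r}")
            if not (0 <= spec.spkk_repeats <= 10):
                raise InputError(f"invalid config field 'spkk_repeats' for gene {spec.name!r}")

    # ---- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["cluster_unit"] = [dataclasses.asdict(g) for g in self.cluster_unit]
        doc["variant_loci"] = [dataclasses.asdict(g) for g in self.variant_loci]
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise InputError(f"invalid config field {sorted(unknown)[0]!r}")
        for key in ("cluster_unit", "variant_loci"):
            if key in doc and doc[key] is not None:
                genes = []
                for g in doc[key]:
                    g = dict(g)
                    for tup in ("expressed", "protein_edits"):
                        if tup in g and g[tup] is not None:
                            g[tup] = tuple(tuple(x) if isinstance(x, list) else x for x in g[tup])
                    genes.append(GeneSpec(**g))
                doc[key] = tuple(genes)
        return cls(**doc)


@dataclass(frozen=True)
class GeneTruth:
    name: str
    family: str
    variant: str
    seq_id: str
    start: int  # representative instance, 0-based half-open, coding span
    end: int
    strand: str
    expected_verdict: str
    expected_spkk: int
    n_copies: int
    protein: str
    cds: str


@dataclass(frozen=True)
class SyntheticTruth:
    genes: tuple
    cluster_copies: int
    expression: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.name for g in self.genes],
                "family": [g.family for g in self.genes],
                "variant": [g.variant for g in self.genes],
                "seq_id": [g.seq_id for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "expected_verdict": [g.expected_verdict for g in self.genes],
                "expected_spkk": [g.expected_spkk for g in self.genes],
                "n_copies": [g.n_copies for g in self.genes],
            }
        )


@dataclass(frozen=True)
class SyntheticDataset:
    config: SimulationConfig
    genome: SequenceRecord
    features: tuple  # full truth annotation
    gene_models: tuple  # gene/exon/CDS subset (pipeline input)
    proteins: tuple
    cds: tuple
    cluster_unit_seq: str
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# sequence helpers

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_DNA, size=length, p=p).tobytes().decode("ascii")


def make_sperm_h2b(base_protein: str, n_repeats: int) -> str:
    """Prepend ``n_repeats`` SPKK/SPKR blocks (alternating K/R) to the tail."""
    if not 0 <= n_repeats <= 10:
        raise InputError("n_repeats must be in 0..10")
    blocks = "".join("SPKK" if i % 2 == 0 else "SPKR" for i in range(n_repeats))
    return blocks + base_protein


def _mutate_protein(
    protein: str, rate: float, rng: np.random.Generator, protected: frozenset
) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = list(protein)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in aas if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _reverse_translate(protein: str, codon_rate: float, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS[aa]
        if len(options) > 1 and rng.random() < codon_rate:
            codons.append(options[rng.integers(len(options))])
        else:
            codons.append(options[0])
    return "".join(codons)


def translate_cds(cds: str) -> str:
    protein = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in _STANDARD_TABLE.stop_codons:
            break
        protein.append(_CODON_TO_AA[codon])
    return "".join(protein)


def _mutate_stem(element: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Break ``n_mismatches`` stem pairs of a 16-nt hairpin element."""
    out = list(element)
    positions = rng.permutation(regulatory.STEM_LEN)[:n_mismatches]
    for i in sorted(int(p) for p in positions):
        partner = out[regulatory.ELEMENT_LEN - 1 - i]
        bad = [
            b
            for b in "ACGT"
            if regulatory.stem_pair_score(b, partner) == regulatory.MISMATCH_SCORE
            and b != out[i]
        ]
        out[i] = bad[rng.integers(len(bad))]
    return "".join(out)


# ---------------------------------------------------------------------------
# gene and genome assembly


@dataclass(frozen=True)
class _BuiltGene:
    spec: GeneSpec
    locus_seq: str
    features: tuple  # relative to locus start; gene/exon/CDS + signals
    coding_start: int  # relative coding span (ATG..stop inclusive)
    coding_end: int
    protein: str
    cds: str


def _protected_positions(spec: GeneSpec, protein: str) -> frozenset:
    protected = set()
    protected.update(4 * spec.spkk_repeats + i for i in range(4))  # motif boundary
    protected.update(range(4 * spec.spkk_repeats))
    if spec.family == "H3":
        # one leading Met is added at CDS level, not present here
        protected.update(p - 1 for p, _, _ in H3_DIAGNOSTIC_SITES)
    if spec.family == "H2A":
        protected.update(range(len(protein) - 4, len(protein)))
    protected.update(p - 1 for p, _ in spec.protein_edits)
    return frozenset(protected)


def _build_gene(spec: GeneSpec, refs, config: SimulationConfig, rng: np.random.Generator) -> _BuiltGene:
    base = next(r.record.residues for r in refs if r.record.id == spec.ref_id)
    for pos, residue in spec.protein_edits:
        if not 1 <= pos <= len(base):
            raise InputError(f"invalid config field 'protein_edits' for gene {spec.name!r}")
        base = base[: pos - 1] + residue + base[pos:]
    if spec.spkk_repeats:
        base = make_sperm_h2b(base, spec.spkk_repeats)
    mature = _mutate_protein(base, config.aa_mutation_rate, rng, _protected_positions(spec, base))
    protein = mature if mature.startswith("M") else "M" + mature
    cds = _reverse_translate(protein, config.codon_mutation_rate, rng) + STOP_CODON

    # introns with canonical GT..AG boundaries, uniform within the CDS
    cut_points = sorted(
        int(p) for p in rng.choice(np.arange(3, len(cds) - 3), size=spec.introns, replace=False)
    ) if spec.introns else []
    segments = []
    prev = 0
    coding_parts = []
    for cut in cut_points:
        coding_parts.append(cds[prev:cut])
        prev = cut
    coding_parts.append(cds[prev:])
    introns = [
        "GT" + _random_dna(rng, int(rng.integers(60, 150)), config.background_gc) + "AG"
        for _ in cut_points
    ]

    gc = config.background_gc
    for _attempt in range(60):
        # --- upstream with planted TATA ------------------------------------
        upstream = _random_dna(rng, config.upstream_pad, gc)
        tata_offset = config.upstream_pad - 31
        if spec.tata:
            upstream = upstream[:tata_offset] + "TATAAA" + upstream[tata_offset + 6 :]
        # --- 3'-UTR ---------------------------------------------------------
        if spec.stem_loop_mismatches is not None:
            spacer1 = _random_dna(rng, int(rng.integers(6, 18)), gc)
            element = _mutate_stem(
                regulatory.DEFAULT_STEM_LOOP_CONSENSUS, spec.stem_loop_mismatches, rng
            )
            parts = [spacer1, element, _random_dna(rng, 5, gc)]
            if spec.hde:
                hde_seq = rng.choice(
                    np.frombuffer(b"AG", dtype=np.uint8), size=10, p=[0.6, 0.4]
                ).tobytes().decode("ascii")
                parts.append(hde_seq)
            utr = "".join(parts)
            utr += _random_dna(rng, max(0, config.utr_len - len(utr)), gc)
            planted_sl_offset = len(spacer1)
        else:
            spacer = _random_dna(rng, 10, gc)
            utr = spacer + "AATAAA"
            utr += _random_dna(rng, max(0, config.utr_len - len(utr)), gc)
            planted_sl_offset = None

        found = regulatory.compute_utr_features(spec.name, upstream, utr)
        ok = True
        if spec.tata and not any(t == -31 for t in found.tata_hits):
            ok = False
        if planted_sl_offset is not None:
            ok = ok and (
                found.stem_loop is not None
                and found.stem_loop.offset_after_stop == planted_sl_offset
                and found.stem_loop.stem_mismatches == spec.stem_loop_mismatches
            )
            if spec.hde:
                ok = ok and found.hde is not None
        else:
            ok = ok and found.stem_loop is None and found.polyA == 10
        if not spec.polya and planted_sl_offset is not None:
            ok = ok and found.polyA is None
        if ok:
            break
    else:  # pragma: no cover - probability of 60 failures is negligible
        raise InputError(f"could not realise planted features for gene {spec.name!r}")

    # --- assemble the locus -------------------------------------------------
    pieces = [upstream]
    cursor = len(upstream)
    coding_start = cursor
    exon_spans = []
    for i, part in enumerate(coding_parts):
        pieces.append(part)
        exon_spans.append((cursor, cursor + len(part)))
        cursor += len(part)
        if i < len(introns):
            pieces.append(introns[i])
            cursor += len(introns[i])
    coding_end = cursor
    pieces.append(utr)
    utr_start = cursor
    cursor += len(utr)
    pieces.append(_random_dna(rng, config.downstream_pad, gc))
    cursor += config.downstream_pad

    attrs = {"ID": spec.name}
    feats = [
        GenomicFeature("_", coding_start, coding_end, "+", "gene", attrs),
    ]
    if spec.tata:
        feats.append(
            GenomicFeature("_", tata_offset, tata_offset + 6, "+", "TATA_box", {"Parent": spec.name})
        )
    for start, end in exon_spans:
        feats.append(GenomicFeature("_", start, end, "+", "exon", {"Parent": spec.name}))
        feats.append(GenomicFeature("_", start, end, "+", "CDS", {"Parent": spec.name}))
    if planted_sl_offset is not None:
        sl0 = utr_start + planted_sl_offset
        feats.append(
            GenomicFeature(
                "_", sl0, sl0 + regulatory.ELEMENT_LEN, "+", "stem_loop",
                {"Parent": spec.name, "stem_mismatches": str(spec.stem_loop_mismatches)},
            )
        )
        if found.hde is not None:
            h0 = utr_start + found.hde[0]
            feats.append(GenomicFeature("_", h0, h0 + 10, "+", "HDE", {"Parent": spec.name}))
    if found.polyA is not None:
        p0 = utr_start + found.polyA
        feats.append(GenomicFeature("_", p0, p0 + 6, "+", "polyA_signal", {"Parent": spec.name}))

    return _BuiltGene(
        spec=spec,
        locus_seq="".join(pieces),
        features=tuple(feats),
        coding_start=coding_start,
        coding_end=coding_end,
        protein=protein,
        cds=cds,
    )


def _shift(feats: Sequence[GenomicFeature], offset: int, copy: Optional[int]) -> list[GenomicFeature]:
    out = []
    for f in feats:
        attrs = f.attr
        if copy is not None:
            attrs["copy"] = str(copy)
        out.append(
            GenomicFeature(GENOME_ID, f.start + offset, f.end + offset, f.strand, f.ftype, attrs)
        )
    return out


def generate_genome(config: SimulationConfig) -> SyntheticDataset:
    """Build the genome, annotation, proteins and planted truth."""
    rng = np.random.default_rng(config.seed)
    refs = load_references()
    gc = config.background_gc

    cluster_genes = [_build_gene(s, refs, config, rng) for s in config.cluster_unit]
    variant_genes = [_build_gene(s, refs, config, rng) for s in config.variant_loci]

    # --- canonical repeat unit ---------------------------------------------
    unit_pieces: list[str] = []
    unit_feats: list[GenomicFeature] = []
    cursor = 0
    for built in cluster_genes:
        unit_feats.extend(
            GenomicFeature("_", f.start + cursor, f.end + cursor, f.strand, f.ftype, f.attr)
            for f in built.features
        )
        unit_pieces.append(built.locus_seq)
        cursor += len(built.locus_seq)
        spacer = _random_dna(rng, config.intergenic_spacer, gc)
        unit_pieces.append(spacer)
        cursor += len(spacer)
    for placeholder in ("5S_rRNA", "U1_snRNA", "U2_snRNA", "Arg_tRNA_GCA"):
        seq = _random_dna(rng, int(rng.integers(90, 130)), gc)
        unit_feats.append(
            GenomicFeature(
                "_", cursor, cursor + len(seq), "+", "gene",
                {"ID": placeholder, "gene_type": "non_histone"},
            )
        )
        unit_pieces.append(seq)
        cursor += len(seq)
        spacer = _random_dna(rng, 40, gc)
        unit_pieces.append(spacer)
        cursor += len(spacer)
    unit_seq = "".join(unit_pieces)

    # --- genome layout ------------------------------------------------------
    n_chunks = len(variant_genes) + 2
    chunk = config.background_length // n_chunks
    genome_pieces: list[str] = []
    features: list[GenomicFeature] = []
    pos = 0

    def emit_background(length: int) -> None:
        nonlocal pos
        genome_pieces.append(_random_dna(rng, length, gc))
        pos += length

    emit_background(chunk)
    cluster_start = pos
    for copy in range(config.cluster_copies):
        features.append(
            GenomicFeature(
                GENOME_ID, pos, pos + len(unit_seq), "+", "cluster_unit",
                {"ID": f"cluster_unit_{copy}", "copy": str(copy)},
            )
        )
        features.extend(_shift(unit_feats, pos, copy))
        genome_pieces.append(unit_seq)
        pos += len(unit_seq)
    variant_spans: dict[str, tuple] = {}
    for built in variant_genes:
        emit_background(chunk)
        features.extend(_shift(built.features, pos, None))
        variant_spans[built.spec.name] = (pos + built.coding_start, pos + built.coding_end)
        genome_pieces.append(built.locus_seq)
        pos += len(built.locus_seq)
    emit_background(chunk + config.background_length % n_chunks)

    genome_seq = "".join(genome_pieces)
    genome = SequenceRecord(GENOME_ID, genome_seq, NUCLEOTIDE, "synthetic histone-complement genome")

    # --- truth, proteins, expression ---------------------------------------
    truth_genes = []
    proteins = []
    cds_records = []
    expression = []
    for built in cluster_genes + variant_genes:
        spec = built.spec
        if spec in [b.spec for b in cluster_genes]:
            offset = cluster_start + sum(
                len(b.locus_seq) + config.intergenic_spacer
                for b in cluster_genes[: [b.spec for b in cluster_genes].index(spec)]
            )
            span = (offset + built.coding_start, offset + built.coding_end)
            n_copies = config.cluster_copies
        else:
            span = variant_spans[spec.name]
            n_copies = 1
        truth_genes.append(
            GeneTruth(
                name=spec.name,
                family=spec.family,
                variant=spec.variant,
                seq_id=GENOME_ID,
                start=span[0],
                end=span[1],
                strand="+",
                expected_verdict=spec.expected_verdict(),
                expected_spkk=spec.spkk_repeats,
                n_copies=n_copies,
                protein=built.protein,
                cds=built.cds,
            )
        )
        proteins.append(SequenceRecord(spec.name, built.protein, PROTEIN, f"family={spec.family}"))
        cds_records.append(SequenceRecord(spec.name, built.cds, NUCLEOTIDE, f"family={spec.family}"))
        for stage in STAGES:
            expression.append(ExpressionEvidence(spec.name, stage, stage in spec.expressed))

    gene_models = tuple(
        f
        for f in features
        if f.ftype in ("gene", "exon", "CDS") and f.attr.get("gene_type") != "non_histone"
    )
    truth = SyntheticTruth(
        genes=tuple(truth_genes), cluster_copies=config.cluster_copies, expression=tuple(expression)
    )
    return SyntheticDataset(
        config=config,
        genome=genome,
        features=tuple(features),
        gene_models=gene_models,
        proteins=tuple(proteins),
        cds=tuple(cds_records),
        cluster_unit_seq=unit_seq,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genome: str, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[SequenceRecord]:
    """Uniform reads at the configured coverage with substitution errors.

    Single-end by default: ceil(coverage x genome / read_length) reads with
    uniform start positions and random strand.  Paired mode emits mate
    pairs from fixed-insert fragments, halving the pair count.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    g = len(genome)
    if rl > g:
        raise InputError("read_length exceeds genome length")
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)

    def sample(n: int, starts: np.ndarray) -> np.ndarray:
        block = arr[starts[:, None] + np.arange(rl)[None, :]].copy()
        if config.error_rate > 0:
            mask = rng.random(block.shape) < config.error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()))
            code = _LUT_FWD[block[mask]]
            block[mask] = _DNA[(code + shift) % 4]
        flip = rng.random(n) < 0.5
        if flip.any():
            sub = block[flip]
            comp = _COMP_LUT[sub]
            block[flip] = comp[:, ::-1]
        return block

    reads: list[SequenceRecord] = []
    if config.paired:
        insert = 2 * rl + 100
        insert = min(insert, g)
        n_pairs = math.ceil(config.coverage * g / (2 * rl))
        starts = rng.integers(0, g - insert + 1, size=n_pairs)
        fwd = sample(n_pairs, starts)
        rev_starts = starts + insert - rl
        rev = sample(n_pairs, rev_starts)
        for i in range(n_pairs):
            reads.append(SequenceRecord(f"read{i:07d}/1", fwd[i].tobytes().decode(), NUCLEOTIDE))
            reads.append(SequenceRecord(f"read{i:07d}/2", rev[i].tobytes().decode(), NUCLEOTIDE))
    else:
        n = math.ceil(config.coverage * g / rl)
        starts = rng.integers(0, g - rl + 1, size=n)
        block = sample(n, starts)
        for i in range(n):
            reads.append(SequenceRecord(f"read{i:07d}", block[i].tobytes().decode(), NUCLEOTIDE))
    return reads


_LUT_FWD = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT_FWD[_b] = _i
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path, reads: bool = True) -> dict:
    """Write genome, annotation, proteins, truth and (optionally) reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "proteins": out / "proteins.fasta",
        "cds": out / "cds.fasta",
        "gene_models": out / "genes.gff3",
        "truth_gff3": out / "truth.gff3",
        "truth_tsv": out / "truth.tsv",
        "expression": out / "expression.tsv",
        "region": out / "cluster_unit.fasta",
        "config": out / "config.yaml",
    }
    write_fasta([dataset.genome], paths["genome"])
    write_fasta(dataset.proteins, paths["proteins"])
    write_fasta(dataset.cds, paths["cds"])
    lengths = {dataset.genome.id: len(dataset.genome)}
    write_gff3(dataset.gene_models, paths["gene_models"], seq_lengths=lengths)
    write_gff3(dataset.features, paths["truth_gff3"], seq_lengths=lengths)
    dataset.truth.to_frame().to_csv(paths["truth_tsv"], sep="\t", index=False, lineterminator="\n")
    write_expression_table(dataset.truth.expression, paths["expression"])
    write_fasta(
        [SequenceRecord("cluster_unit", dataset.cluster_unit_seq, NUCLEOTIDE)], paths["region"]
    )
    dataset.config.to_yaml(paths["config"])
    if reads:
        paths["reads"] = out / "reads.fastq"
        write_fastq(simulate_reads(dataset.genome.residues, dataset.config), paths["reads"])
    return {k: str(v) for k, v in paths.items()}
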