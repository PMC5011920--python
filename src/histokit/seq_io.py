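"""Sequence and feature I/O and the shared data model.

All downstream modules consume the types defined here; no other module
parses files itself.  Conventions:

* internal coordinates are 0-based half-open; GFF3 serialisation converts
  to the standard 1-based inclusive columns;
* residues are upper-cased on ingestion and validated against the declared
  alphabet ({A,C,G,T,N} for nucleotide, the 20 amino acids plus X for
  protein);
* FASTQ is accepted wherever FASTA reads are accepted, qualities are
  ignored (copy-number estimation uses counts only).
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import InputError

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

NUC_ALPHABET = frozenset("ACGTN")
PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

FEATURE_TYPES = frozenset(
    {
        "gene",
        "exon",
        "CDS",
        "TATA_box",
        "stem_loop",
        "HDE",
        "polyA_signal",
        "SPKK_repeat",
        "cluster_unit",
    }
)

_GFF_SOURCE = "histokit"


@dataclass(frozen=True)
class SequenceRecord:
    """A validated, case-normalised sequence with a declared molecule type."""

    id: str
    residues: str
    moltype: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.moltype not in (NUCLEOTIDE, PROTEIN):
            raise InputError(f"unknown moltype {self.moltype!r}")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise InputError(f"record {self.id!r}: empty sequence")
        alphabet = NUC_ALPHABET if self.moltype == NUCLEOTIDE else PROT_ALPHABET
        for pos, ch in enumerate(residues, start=1):
            if ch not in alphabet:
                raise InputError(
                    f"record {self.id!r}: residue {ch!r} at position {pos} "
                    f"is outside the {self.moltype} alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicFeature:
    """A located feature; coordinates 0-based half-open on ``seq_id``."""

    seq_id: str
    start: int
    end: int
    strand: str
    ftype: str
    attributes: tuple = ()  # sorted (key, value) pairs; dicts accepted in ctor

    def __post_init__(self) -> None:
        if isinstance(self.attributes, dict):
            object.__setattr__(
                self, "attributes", tuple(sorted(self.attributes.items()))
            )
        else:
            object.__setattr__(self, "attributes", tuple(sorted(self.attributes)))
        if self.start < 0 or self.end <= self.start:
            raise InputError(
                f"feature on {self.seq_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"feature on {self.seq_id}: strand must be '+' or '-'")
        if self.ftype not in FEATURE_TYPES:
            raise InputError(f"unknown feature type {self.ftype!r}")

    @property
    def attr(self) -> dict:
        return dict(self.attributes)


@dataclass(frozen=True)
class ExpressionEvidence:
    """Per-gene, per-stage expression detection flag (stand-in for RNA-seq)."""

    gene_id: str
    stage: str
    detected: bool


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _convert(bio_records: Iterable[_BioSeqRecord], moltype: str) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in bio_records:
        if rec.id in seen:
            raise InputError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), moltype=moltype, description=desc)
        )
    if not records:
        raise InputError("no records")
    return records


def read_fasta(path: str | Path, moltype: str) -> list[SequenceRecord]:
    """Read a FASTA file, preserving record order."""
    return _convert(SeqIO.parse(str(path), "fasta"), moltype)


def read_fastq(path: str | Path, moltype: str = NUCLEOTIDE) -> list[SequenceRecord]:
    """Read a FASTQ file; qualities are discarded."""
    return _convert(SeqIO.parse(str(path), "fastq"), moltype)


def read_sequences(path: str | Path, moltype: str) -> list[SequenceRecord]:
    """Read FASTA or FASTQ, sniffed from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                fmt = "fastq" if line.startswith("@") else "fasta"
                break
        else:
            raise InputError("no records")
    return _convert(SeqIO.parse(str(path), fmt), moltype)


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_fastq(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w", newline="\n") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.residues}\n+\n{'I' * len(r.residues)}\n")


# ---------------------------------------------------------------------------
# GFF3


def _quote(value: str) -> str:
    return urllib.parse.quote(str(value), safe="")


def write_gff3(
    features: Sequence[GenomicFeature],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
) -> None:
    """Serialise features as GFF3 (1-based inclusive coordinates).

    When ``seq_lengths`` is given, features extending past the end of their
    sequence raise :class:`InputError`.
    """
    if seq_lengths is not None:
        for f in features:
            if f.seq_id not in seq_lengths:
                raise InputError(f"feature references unknown sequence {f.seq_id!r}")
            if f.end > seq_lengths[f.seq_id]:
                raise InputError(
                    f"feature [{f.start}, {f.end}) out of bounds on {f.seq_id!r} "
                    f"(length {seq_lengths[f.seq_id]})"
                )
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{_quote(k)}={_quote(v)}" for k, v in f.attributes) or "."
            phase = "0" if f.ftype == "CDS" else "."
            fh.write(
                "\t".join(
                    (
                        f.seq_id,
                        _GFF_SOURCE,
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        phase,
                        attrs,
                    )
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GenomicFeature]:
    """Read a GFF3 file back into internal 0-based half-open features."""
    features: list[GenomicFeature] = []
    for f in gffutils.iterators.DataIterator(str(path)):
        attrs = {
            urllib.parse.unquote(k): urllib.parse.unquote(",".join(v))
            for k, v in f.attributes.items()
        }
        features.append(
            GenomicFeature(
                seq_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                ftype=f.featuretype,
                attributes=attrs,
            )
        )
    return features


# ---------------------------------------------------------------------------
# Expression evidence tables

_BOOL_MAP = {"0": False, "1": True, "true": True, "false": False}


def read_expression_table(path: str | Path) -> list[ExpressionEvidence]:
    """Read a TSV with columns gene_id, stage, detected ({0,1,true,false})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "stage", "detected"]
    if list(df.columns[:3]) != required:
        raise InputError(f"expression table must have columns {required}, got {list(df.columns)}")
    dup = df.duplicated(subset=["gene_id", "stage"])
    if dup.any():
        row = df[dup].iloc[0]
        raise InputError(f"duplicate expression entry for ({row.gene_id!r}, {row.stage!r})")
    evidence = []
    for _, row in df.iterrows():
        key = str(row.detected).strip().lower()
        if key not in _BOOL_MAP:
            raise InputError(f"cannot parse detected value {row.detected!r}")
        evidence.append(ExpressionEvidence(row.gene_id, row.stage, _BOOL_MAP[key]))
    return evidence


def write_expression_table(evidence: Sequence[ExpressionEvidence], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in evidence],
            "stage": [e.stage for e in evidence],
            "detected": [int(e.detected) for e in evidence],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]
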