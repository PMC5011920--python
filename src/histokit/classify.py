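"""Histone family and variant assignment.

Queries are scored by global (Needleman–Wunsch, affine-gap) alignment
against a small bundled reference set — the human canonical histones plus
the near-universal variants H3.3, H2A.X, H2A.Z, macroH2A and CENP-A — and
the family of the best-scoring reference is taken when the alignment
identity clears a noise floor calibrated against composition-preserving
shuffles.  The variant label is then refined by residue-level diagnostics:

* H3.3 is separated from canonical H3 at five positions of the canonical
  H3 numbering — 31 (A→S), 87/89/90 (SAVM→AAIG) and 96 (C→S/A);
* H2A.X carries the C-terminal SQ[E/D/I][Y/F/L] tetrad whose serine is
  the DNA-damage phospho-acceptor;
* macroH2A is recognised by its macro-domain length extension (total
  length > 1.8× canonical H2A);
* CENP-A is H3-derived with a long non-histone-fold N-terminal tail;
* sperm-specific H2B variants carry ≥ 2 SPKK/SPKR repeats in the
  N-terminal tail.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import motifs as _motifs
from .errors import InputError
from .seq_io import PROTEIN, SequenceRecord, read_fasta

FAMILIES = ("H1", "H2A", "H2B", "H3", "H4")
UNCLASSIFIED = "unclassified"

#: (position on canonical H3, canonical residue, H3.3-state residues).
#: Site 96 accepts S or A: the variant-state letter at this site is reported
#: inconsistently in the literature, so both are scored and the observed
#: residue is recorded in the report.
H3_DIAGNOSTIC_SITES = (
    (31, "A", ("S",)),
    (87, "S", ("A",)),
    (89, "V", ("I",)),
    (90, "M", ("G",)),
    (96, "C", ("S", "A")),
)

H2AX_POS3 = frozenset("EDI")
H2AX_POS4 = frozenset("YFL")

#: Family-level identity floor. Histone cores are deeply conserved;
#: composition-preserving shuffles of real histones align well below this.
DEFAULT_MIN_IDENTITY = 0.35

MACRO_LENGTH_FACTOR = 1.8
CENPA_TAIL_MIN = 20
SPERM_H2B_MIN_SPKK = 2


@dataclass(frozen=True)
class Reference:
    record: SequenceRecord
    family: str
    variant: str


@dataclass(frozen=True)
class ReferenceSet:
    references: tuple[Reference, ...]

    def __post_init__(self) -> None:
        present = {r.family for r in self.references}
        missing = set(FAMILIES) - present
        if missing:
            raise InputError(f"reference set incomplete, missing families {sorted(missing)}")

    def __iter__(self):
        return iter(self.references)

    def get(self, family: str, variant: str) -> Reference:
        for ref in self.references:
            if ref.family == family and ref.variant == variant:
                return ref
        raise KeyError((family, variant))


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_query: str
    aligned_target: str
    identity: float


@dataclass(frozen=True)
class DiagnosticReport:
    """Outcome of testing variant-diagnostic sites on a query protein."""

    positions_tested: tuple
    matches: int
    details: tuple  # (position, observed residue or '-' for indeterminate)

    def observed(self, position: int) -> str:
        return dict(self.details)[position]


@dataclass
class FamilyCall:
    query_id: str
    family: str
    variant: str
    score: float
    identity: float
    evidence: list[str] = field(default_factory=list)


def load_references() -> ReferenceSet:
    """Load the bundled reference FASTA.

    The bundled sequences are curated consensus reconstructions of the
    human canonical histones and common variants (see the data file
    headers); the macroH2A entry is a synthetic stand-in whose histone
    fold is H2A-like and whose macro-domain region is a composition-matched
    filler carrying only the length signal used by the classifier.
    """
    path = resources.files("histokit").joinpath("data/reference_histones.fasta")
    with resources.as_file(path) as p:
        records = read_fasta(p, PROTEIN)
    refs = []
    for rec in records:
        tokens = dict(
            t.split("=", 1) for t in rec.description.split() if "=" in t and t.count("=") == 1
        )
        try:
            refs.append(Reference(rec, tokens["family"], tokens["variant"]))
        except KeyError as exc:
            raise InputError(f"reference {rec.id!r} lacks family/variant tags") from exc
    return ReferenceSet(tuple(refs))


@functools.lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # A gap of length L costs gap_open + gap_extend * L.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment; gap of length L costs open + extend·L.

    The returned score is the optimum; among co-optimal alignments the
    engine's first enumeration is taken, which is deterministic for fixed
    inputs and parameters.
    """
    if not query or not target:
        raise InputError("cannot align empty sequence")
    aln = _aligner(matrix, gap_open, gap_extend).align(query.upper(), target.upper())[0]
    qrow, trow = aln[0], aln[1]
    matches = sum(a == b for a, b in zip(qrow, trow))
    return AlignmentResult(
        score=float(aln.score),
        aligned_query=qrow,
        aligned_target=trow,
        identity=matches / len(qrow),
    )


def h2ax_cterm_check(query: str) -> dict:
    """Test the extreme C terminus for the SQ[E/D/I][Y/F/L] tetrad.

    ``near_match`` is true when positions 1, 2 and 4 of the tetrad fit but
    position 3 does not (e.g. an SQAY ending).
    """
    if len(query) < 4:
        raise InputError("query shorter than the 4-residue tetrad")
    t = query[-4:].upper()
    frame = t[0] == "S" and t[1] == "Q" and t[3] in H2AX_POS4
    match = frame and t[2] in H2AX_POS3
    return {"match": match, "tetrad": t, "near_match": frame and not match}


def macro_length_check(
    query: str, canonical_h2a_length: int, factor: float = MACRO_LENGTH_FACTOR
) -> bool:
    """True when the query carries a macro-domain-scale length extension."""
    return len(query) > factor * canonical_h2a_length


def h3_variant_diagnostics(query: str, canonical_h3: str) -> DiagnosticReport:
    """Score the five H3.3-diagnostic sites of the canonical H3 numbering.

    Sites are transferred to the query through a global alignment with the
    canonical reference; a gap at a site makes it indeterminate (reported
    as '-') and it is excluded from the match count.
    """
    aln = global_align(query, canonical_h3)
    # Map canonical-H3 (1-based) positions to the query column.
    by_position: dict[int, str] = {}
    ref_pos = 0
    for qc, tc in zip(aln.aligned_query, aln.aligned_target):
        if tc != "-":
            ref_pos += 1
            by_position[ref_pos] = qc
    details = []
    matches = 0
    for pos, _canonical, variant_states in H3_DIAGNOSTIC_SITES:
        observed = by_position.get(pos, "-")
        details.append((pos, observed))
        if observed != "-" and observed in variant_states:
            matches += 1
    return DiagnosticReport(
        positions_tested=H3_DIAGNOSTIC_SITES, matches=matches, details=tuple(details)
    )


def _n_terminal_extension(aln: AlignmentResult) -> int:
    """Query residues aligned before the first target residue."""
    ext = 0
    for qc, tc in zip(aln.aligned_query, aln.aligned_target):
        if tc != "-":
            break
        if qc != "-":
            ext += 1
    return ext


def assign_family(
    query: SequenceRecord,
    refs: ReferenceSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> FamilyCall:
    """Assign family by best-scoring reference, then refine the variant.

    Deterministic: ties on score are broken by family name then reference
    id, both lexicographic, so reference order never changes the call.
    """
    scored = sorted(
        ((global_align(query.residues, ref.record.residues), ref) for ref in refs),
        key=lambda pair: (-pair[0].score, pair[1].family, pair[1].record.id),
    )
    best_aln, best_ref = scored[0]
    evidence = [
        f"best reference {best_ref.record.id} (family {best_ref.family}, "
        f"variant {best_ref.variant}), score {best_aln.score:.1f}, "
        f"identity {best_aln.identity:.3f}"
    ]
    if best_aln.identity < min_identity:
        evidence.append(f"identity below family floor {min_identity}")
        return FamilyCall(query.id, UNCLASSIFIED, "", best_aln.score, best_aln.identity, evidence)

    family = best_ref.family
    variant = best_ref.variant

    if family == "H3":
        canonical = refs.get("H3", "canonical").record.residues
        if best_ref.variant == "CENP-A":
            ext = _n_terminal_extension(global_align(query.residues, canonical))
            evidence.append(f"CENP-A reference preferred; N-terminal extension {ext} residues")
            variant = "CENP-A"
        else:
            report = h3_variant_diagnostics(query.residues, canonical)
            observed = ",".join(f"{p}{o}" for p, o in report.details)
            evidence.append(
                f"H3.3 diagnostic sites {report.matches}/{len(report.positions_tested)} ({observed})"
            )
            variant = "H3.3" if report.matches >= 3 else "canonical"
    elif family == "H2A":
        canonical_len = len(refs.get("H2A", "canonical").record.residues)
        if macro_length_check(query.residues, canonical_len):
            evidence.append(
                f"length {len(query.residues)} > {MACRO_LENGTH_FACTOR} x canonical H2A "
                f"({canonical_len}): macro-domain extension"
            )
            variant = "macroH2A"
        else:
            tetrad = h2ax_cterm_check(query.residues)
            if tetrad["match"] or tetrad["near_match"]:
                kind = "match" if tetrad["match"] else "near-match"
                evidence.append(f"C-terminal SQ tetrad {kind} ({tetrad['tetrad']})")
                variant = "H2A.X"
            elif best_ref.variant == "H2A.Z":
                variant = "H2A.Z"
            else:
                variant = "canonical"
    elif family == "H2B":
        spkk = _motifs.count_spkk(query.residues)
        if spkk.count >= SPERM_H2B_MIN_SPKK:
            evidence.append(f"{spkk.count} SPKK/SPKR repeats in the N-terminal tail")
            variant = "sperm-H2B"

    return FamilyCall(query.id, family, variant, best_aln.score, best_aln.identity, evidence)


def inventory(calls: Sequence[FamilyCall]) -> pd.DataFrame:
    """Counts per (family, variant); families with no calls appear with 0."""
    rows: dict[tuple[str, str], int] = {}
    for call in calls:
        key = (call.family, call.variant)
        rows[key] = rows.get(key, 0) + 1
    for family in FAMILIES:
        if not any(f == family for f, _ in rows):
            rows[(family, "")] = 0
    df = pd.DataFrame(
        [(f, v, n) for (f, v), n in sorted(rows.items())],
        columns=["family", "variant", "count"],
    )
    return df


def inventory_total(df: pd.DataFrame, classified_only: bool = True) -> int:
    if classified_only:
        df = df[df.family != UNCLASSIFIED]
    return int(df["count"].sum())


def classification_table(calls: Sequence[FamilyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query_id": [c.query_id for c in calls],
            "family": [c.family for c in calls],
            "variant": [c.variant for c in calls],
            "score": [c.score for c in calls],
            "identity": [round(c.identity, 4) for c in calls],
            "evidence": ["; ".join(c.evidence) for c in calls],
        }
    )
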