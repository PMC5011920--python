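"""Promoter and 3'-UTR element detection and replication-dependency calling.

Replication-dependent histone mRNAs are not polyadenylated; they end in a
conserved 16-nt hairpin (6-bp stem, 4-nt loop) a short distance after the
stop codon, followed by a purine-rich histone downstream element (HDE)
that base-pairs with U7 snRNA.  Replication-independent variants instead
carry a polyA signal and no hairpin.  A gene whose hairpin is degenerate
(mismatched stem, hence thermodynamically unstable), that lacks a polyA
signal and shows no expression in any stage is a pseudogene candidate.

Hairpin stability is scored additively over the six stem pairs (GC=3,
AT=2, GU wobble=1, mismatch=-2) rather than by free-energy folding; the
"unstable" threshold defaults to 12, the score of a perfect all-AT stem,
so any broken stem pair drops a hairpin below the weakest fully paired
one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .errors import InputError
from .seq_io import ExpressionEvidence

#: Metazoan-type histone stem-loop element used as the similarity anchor;
#: organism-specific consensus elements can be passed instead.
DEFAULT_STEM_LOOP_CONSENSUS = "GGCTCTTTTCAGAGCC"

STEM_LEN = 6
LOOP_LEN = 4
ELEMENT_LEN = 2 * STEM_LEN + LOOP_LEN

PAIR_SCORES = {
    ("G", "C"): 3,
    ("C", "G"): 3,
    ("A", "T"): 2,
    ("T", "A"): 2,
    ("G", "T"): 1,
    ("T", "G"): 1,
}
MISMATCH_SCORE = -2

#: Score of a perfect all-AT stem; hairpins below this are called unstable.
DEFAULT_STABILITY_THRESHOLD = 2 * STEM_LEN

TATA_PATTERN = re.compile(r"(?=TA[AT]AAA)")
DEFAULT_TATA_WINDOW = 120

DEFAULT_SEARCH_SPAN = 40
DEFAULT_MAX_MISMATCH = 3
DEFAULT_MAX_CONSENSUS_DISTANCE = 6

DEFAULT_HDE_WIDTH = 10
DEFAULT_HDE_RANGE = 25
DEFAULT_MIN_PURINE_FRACTION = 0.7

DEFAULT_POLYA_MOTIFS = ("AATAAA", "ATTAAA")

REPLICATION_DEPENDENT = "replication_dependent"
REPLICATION_INDEPENDENT = "replication_independent"
PSEUDOGENE_CANDIDATE = "pseudogene_candidate"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class StemLoopHit:
    offset_after_stop: int
    element_sequence: str
    stem_mismatches: int
    stability_score: float
    consensus_distance: int
    stem_len: int = STEM_LEN
    loop_len: int = LOOP_LEN


@dataclass(frozen=True)
class UtrFeatureSet:
    gene_id: str
    tata_hits: tuple = ()
    stem_loop: Optional[StemLoopHit] = None
    hde: Optional[tuple] = None  # (position within UTR, purine fraction)
    polyA: Optional[int] = None


@dataclass(frozen=True)
class DependencyCall:
    gene_id: str
    verdict: str
    rationale: tuple


def _check_dna(seq: str, where: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise InputError(f"{where}: nucleotide alphabet is DNA (ACGTN); found {sorted(bad)}")
    return seq


def scan_tata(upstream: str, window: int = DEFAULT_TATA_WINDOW) -> list[int]:
    """All TAWAAA (TA[A/T]AAA) start positions in the window nearest the ATG.

    Positions are reported relative to the start codon (negative offsets);
    overlapping occurrences are all reported.
    """
    upstream = _check_dna(upstream, "upstream")
    if window > len(upstream):
        window = len(upstream)
    region = upstream[len(upstream) - window :]
    base = len(upstream) - window
    return [base + m.start() - len(upstream) for m in TATA_PATTERN.finditer(region)]


def stem_pair_score(a: str, b: str) -> int:
    return PAIR_SCORES.get((a, b), MISMATCH_SCORE)


def score_hairpin(element: str) -> tuple[int, int]:
    """(stem mismatches, stability score) of a 16-nt element.

    Stem positions 1–6 pair antiparallel with 16–11; N never pairs.
    """
    if len(element) != ELEMENT_LEN:
        raise InputError(f"hairpin element must be {ELEMENT_LEN} nt")
    mismatches = 0
    score = 0
    for i in range(STEM_LEN):
        a, b = element[i], element[ELEMENT_LEN - 1 - i]
        s = MISMATCH_SCORE if "N" in (a, b) else stem_pair_score(a, b)
        score += s
        if s == MISMATCH_SCORE:
            mismatches += 1
    return mismatches, score


def find_stem_loop(
    utr: str,
    search_span: int = DEFAULT_SEARCH_SPAN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    consensus: str = DEFAULT_STEM_LOOP_CONSENSUS,
    max_consensus_distance: int = DEFAULT_MAX_CONSENSUS_DISTANCE,
) -> Optional[StemLoopHit]:
    """Best histone-type hairpin within ``search_span`` nt of the stop codon.

    A 16-nt window qualifies when its stem holds >= (6 - max_mismatch)
    Watson-Crick/GU pairs *and* it lies within ``max_consensus_distance``
    edits of the consensus element — structure alone is too permissive on
    random sequence for a conserved element class.  Among qualifying
    windows the highest stability score wins; ties go leftmost.
    """
    utr = _check_dna(utr, "3'-UTR")
    if len(utr) < ELEMENT_LEN:
        return None
    consensus = _check_dna(consensus, "consensus")
    best: Optional[StemLoopHit] = None
    last_offset = min(search_span, len(utr) - ELEMENT_LEN)
    for offset in range(last_offset + 1):
        element = utr[offset : offset + ELEMENT_LEN]
        mismatches, stability = score_hairpin(element)
        if mismatches > max_mismatch:
            continue
        dist = edlib.align(element, consensus, task="distance")["editDistance"]
        if dist > max_consensus_distance:
            continue
        if best is None or stability > best.stability_score:
            best = StemLoopHit(
                offset_after_stop=offset,
                element_sequence=element,
                stem_mismatches=mismatches,
                stability_score=float(stability),
                consensus_distance=dist,
            )
    return best


def scan_hde(
    downstream: str,
    width: int = DEFAULT_HDE_WIDTH,
    search_range: int = DEFAULT_HDE_RANGE,
    min_purine_fraction: float = DEFAULT_MIN_PURINE_FRACTION,
) -> Optional[tuple]:
    """Best purine-rich window downstream of the stem-loop.

    Returns (start position within ``downstream``, purine fraction) of the
    highest-fraction window (ties leftmost), or None below threshold.
    """
    downstream = _check_dna(downstream, "HDE region")
    if len(downstream) < width:
        return None
    best_pos, best_frac = None, -1.0
    for pos in range(min(search_range, len(downstream) - width) + 1):
        window = downstream[pos : pos + width]
        frac = sum(c in "AG" for c in window) / width
        if frac > best_frac:
            best_pos, best_frac = pos, frac
    if best_frac >= min_purine_fraction:
        return (best_pos, best_frac)
    return None


def scan_polyA(utr: str, motifs: Sequence[str] = DEFAULT_POLYA_MOTIFS) -> Optional[int]:
    """Position of the first polyadenylation signal in the 3'-UTR, if any."""
    utr = _check_dna(utr, "3'-UTR")
    hits = [utr.find(m) for m in motifs]
    hits = [h for h in hits if h >= 0]
    return min(hits) if hits else None


def compute_utr_features(
    gene_id: str,
    upstream: str,
    utr: str,
    tata_window: int = DEFAULT_TATA_WINDOW,
    search_span: int = DEFAULT_SEARCH_SPAN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    consensus: str = DEFAULT_STEM_LOOP_CONSENSUS,
    max_consensus_distance: int = DEFAULT_MAX_CONSENSUS_DISTANCE,
    hde_width: int = DEFAULT_HDE_WIDTH,
    hde_range: int = DEFAULT_HDE_RANGE,
    min_purine_fraction: float = DEFAULT_MIN_PURINE_FRACTION,
    polya_motifs: Sequence[str] = DEFAULT_POLYA_MOTIFS,
) -> UtrFeatureSet:
    """Run all scans for one gene; the HDE is only sought after a hairpin."""
    tata = scan_tata(upstream, tata_window) if upstream else []
    sl = find_stem_loop(utr, search_span, max_mismatch, consensus, max_consensus_distance)
    hde = None
    if sl is not None:
        tail_start = sl.offset_after_stop + ELEMENT_LEN
        found = scan_hde(utr[tail_start:], hde_width, hde_range, min_purine_fraction)
        if found is not None:
            hde = (tail_start + found[0], found[1])
    return UtrFeatureSet(
        gene_id=gene_id,
        tata_hits=tuple(tata),
        stem_loop=sl,
        hde=hde,
        polyA=scan_polyA(utr, polya_motifs),
    )


def call_dependency(
    features: UtrFeatureSet,
    expression: Sequence[ExpressionEvidence] = (),
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
) -> DependencyCall:
    """Apply the dependency rules, in order, to one gene's feature set.

    1. stable stem-loop + HDE + no polyA signal -> replication_dependent;
    2. polyA signal + no stem-loop -> replication_independent;
    3. unstable stem-loop + no polyA + no expression in any stage ->
       pseudogene_candidate;
    4. otherwise ambiguous.

    A pure function of its inputs; every verdict carries its rationale.
    """
    sl = features.stem_loop
    expressed = any(e.detected for e in expression if e.gene_id == features.gene_id)
    rationale: list[str] = []
    if sl is not None and sl.stability_score >= stability_threshold and features.hde and features.polyA is None:
        rationale.append(
            f"stable stem-loop at +{sl.offset_after_stop} "
            f"(stability {sl.stability_score:g} >= {stability_threshold:g})"
        )
        rationale.append(f"HDE at +{features.hde[0]} (purine fraction {features.hde[1]:.2f})")
        rationale.append("no polyA signal")
        return DependencyCall(features.gene_id, REPLICATION_DEPENDENT, tuple(rationale))
    if features.polyA is not None and sl is None:
        rationale.append(f"polyA signal at +{features.polyA}")
        rationale.append("no stem-loop")
        return DependencyCall(features.gene_id, REPLICATION_INDEPENDENT, tuple(rationale))
    if (
        sl is not None
        and sl.stability_score < stability_threshold
        and features.polyA is None
        and not expressed
    ):
        rationale.append(
            f"degenerate stem-loop ({sl.stem_mismatches} stem mismatches, "
            f"stability {sl.stability_score:g} < {stability_threshold:g})"
        )
        rationale.append("no polyA signal")
        rationale.append("no expression evidence in any stage")
        return DependencyCall(features.gene_id, PSEUDOGENE_CANDIDATE, tuple(rationale))
    rationale.append(
        "feature combination fits no rule: "
        f"stem_loop={'none' if sl is None else f'stability {sl.stability_score:g}'}, "
        f"hde={'present' if features.hde else 'none'}, "
        f"polyA={'none' if features.polyA is None else f'+{features.polyA}'}, "
        f"expressed={expressed}"
    )
    return DependencyCall(features.gene_id, AMBIGUOUS, tuple(rationale))
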