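"""SPKK repeat counting, tail basicity profiling and protamine screening.

Sperm-specific histones of several invertebrates carry tandem S-P-K-K/R
tetrapeptides in the N-terminal tail; the motif binds the minor groove of
linker DNA and compacts sperm chromatin where protamines are absent.
Protamines themselves are small, arginine-rich sperm nuclear basic
proteins (SNBPs, P-type; protamine-like PL-type proteins are somewhat less
arginine-biased).  The screen here is sequence-composition based: a
protein is protamine-like when its combined R+K fraction and its R
fraction alone both exceed calibrated thresholds that known protamines
pass and all histones fail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import InputError
from .seq_io import SequenceRecord

SPKK_PATTERN = re.compile(r"SPK[KR]")

DEFAULT_N_TERM_LEN = 60
DEFAULT_BASICITY_WINDOW = 30

#: Composition thresholds for the protamine screen (fractions of length).
DEFAULT_RK_THRESHOLD = 0.45
DEFAULT_R_THRESHOLD = 0.25
DEFAULT_P_TYPE_R = 0.45

TYPE_NONE = "none"
TYPE_PL = "PL-type-like"
TYPE_P = "P-type-like"


@dataclass(frozen=True)
class SpkkReport:
    protein_id: str
    region: tuple  # (start, end) of the scanned N-terminal segment
    count: int
    match_positions: tuple


@dataclass(frozen=True)
class BasicityProfile:
    protein_id: str
    fraction_R: float
    fraction_K: float
    fraction_RK: float
    windowed_max_RK: float
    protamine_like: bool
    protamine_type_hint: str


def count_spkk(
    protein: str, n_term_len: int = DEFAULT_N_TERM_LEN, protein_id: str = ""
) -> SpkkReport:
    """Non-overlapping, leftmost-first SPKK/SPKR matches in the N terminus.

    ``n_term_len`` bounds the scanned region (clamped to the protein
    length); leftmost-first non-overlap makes counts well defined on
    tandem arrays ("SPKKK" counts once).
    """
    if not protein:
        raise InputError("empty protein")
    protein = protein.upper()
    end = min(n_term_len, len(protein))
    region = protein[:end]
    positions = tuple(m.start() for m in SPKK_PATTERN.finditer(region))
    return SpkkReport(protein_id=protein_id, region=(0, end), count=len(positions), match_positions=positions)


def basicity_profile(
    protein: str,
    window: int = DEFAULT_BASICITY_WINDOW,
    protein_id: str = "",
    rk_threshold: float = DEFAULT_RK_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_type_r: float = DEFAULT_P_TYPE_R,
) -> BasicityProfile:
    """Global and max-windowed R/K composition plus the protamine call."""
    if not protein:
        raise InputError("empty protein")
    protein = protein.upper()
    n = len(protein)
    frac_r = protein.count("R") / n
    frac_k = protein.count("K") / n
    frac_rk = frac_r + frac_k
    w = min(window, n)
    windowed_max = max(
        (protein.count("R", i, i + w) + protein.count("K", i, i + w)) / w
        for i in range(n - w + 1)
    )
    protamine_like = frac_rk >= rk_threshold and frac_r >= r_threshold
    if protamine_like:
        hint = TYPE_P if frac_r >= p_type_r else TYPE_PL
    else:
        hint = TYPE_NONE
    return BasicityProfile(
        protein_id=protein_id,
        fraction_R=frac_r,
        fraction_K=frac_k,
        fraction_RK=frac_rk,
        windowed_max_RK=windowed_max,
        protamine_like=protamine_like,
        protamine_type_hint=hint,
    )


def protamine_screen(
    proteome: Sequence[SequenceRecord], **thresholds
) -> tuple[list[BasicityProfile], list[BasicityProfile]]:
    """Profile every protein; return (all profiles, protamine-like subset)."""
    profiles = [
        basicity_profile(rec.residues, protein_id=rec.id, **thresholds) for rec in proteome
    ]
    flagged = [p for p in profiles if p.protamine_like]
    return profiles, flagged


def motif_table(
    reports: Sequence[SpkkReport], profiles: Sequence[BasicityProfile]
) -> pd.DataFrame:
    by_id = {p.protein_id: p for p in profiles}
    rows = []
    for r in reports:
        p = by_id[r.protein_id]
        rows.append(
            {
                "protein_id": r.protein_id,
                "region_start": r.region[0],
                "region_end": r.region[1],
                "spkk_count": r.count,
                "match_positions": ",".join(map(str, r.match_positions)),
                "fraction_R": round(p.fraction_R, 4),
                "fraction_K": round(p.fraction_K, 4),
                "fraction_RK": round(p.fraction_RK, 4),
                "windowed_max_RK": round(p.windowed_max_RK, 4),
                "protamine_like": p.protamine_like,
                "type_hint": p.protamine_type_hint,
            }
        )
    return pd.DataFrame(rows)
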