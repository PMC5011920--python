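"""Tandem-repeat copy-number estimation from a k-mer depth histogram.

The procedure: count canonical (strand-collapsed) 17-mers in unassembled
reads, find the modal multiplicity of single-copy sequence (the "diploid
peak") in the multiplicity histogram after excluding the low-multiplicity
sequencing-error peak, measure the median multiplicity of the k-mers of a
repeat-unit sequence, and divide.  With the single-copy peak at 20x and a
repeat region at 28,000x this arithmetic yields 1400 copies per diploid
nucleus, i.e. 700 per haplotype.

The division is performed exactly as stated (region coverage / diploid
peak = copies in a diploid nucleus, halved for per-haplotype); under the
alternative reading in which the diploid peak already represents two
copies, all estimates would differ by a factor of 2.  Both numbers are
reported so the ambiguity stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError

DEFAULT_K = 17
DEFAULT_MIN_MULTIPLICITY = 4
DEFAULT_SMOOTH_WIDTH = 3

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """Bases to 2-bit codes; anything outside ACGT (e.g. N) becomes 255."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer integer codes of all valid windows (vectorised).

    Windows containing non-ACGT bases are dropped; each remaining k-mer is
    collapsed to min(forward, reverse-complement) so both strands count as
    one k-mer.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = (codes == 255).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    base = codes.astype(np.int64).copy()
    base[base == 255] = 0
    fwd = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | base[j : j + n]
    rc = np.zeros(n, dtype=np.int64)
    tmp = fwd.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    canon = np.minimum(fwd, rc)
    return canon[valid]


@dataclass(frozen=True)
class KmerCountTable:
    """Exact multiplicity table over canonical k-mers (codes sorted)."""

    k: int
    codes: np.ndarray
    counts: np.ndarray

    def multiplicities(self, seq: str) -> np.ndarray:
        """Multiplicity of every canonical k-mer of ``seq`` (absent -> 0)."""
        if len(seq) < self.k:
            raise InputError(f"region shorter than k={self.k}")
        query = _window_codes(_encode(seq), self.k)
        idx = np.searchsorted(self.codes, query)
        idx = np.clip(idx, 0, self.codes.size - 1)
        found = self.codes.size > 0
        hit = (self.codes[idx] == query) if found else np.zeros(query.size, dtype=bool)
        out = np.zeros(query.size, dtype=np.int64)
        out[hit] = self.counts[idx[hit]]
        return out


@dataclass(frozen=True)
class KmerHistogram:
    """Multiplicity -> number of distinct canonical k-mers at it."""

    k: int
    counts: dict

    @property
    def total_distinct(self) -> int:
        return int(sum(self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items())
        return pd.DataFrame(items, columns=["multiplicity", "distinct_kmers"])


@dataclass(frozen=True)
class CopyEstimate:
    region_id: str
    region_coverage: float
    diploid_peak: float
    copies_diploid: float
    copies_per_haplotype: float


def build_histogram(
    reads: Iterable[str], k: int = DEFAULT_K
) -> tuple[KmerCountTable, KmerHistogram]:
    """Exact canonical k-mer multiplicity table and its histogram.

    Invariant under read-order permutation and under reverse-complementing
    any subset of reads.  Raises when no read yields a single k-mer.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if 2 * k > 62:
        raise InputError("k too large for 64-bit packing (k <= 31)")
    # Reads are joined with an N separator so no window spans two reads.
    blob = "N".join(s.upper() for s in reads)
    if not blob:
        raise InputError("no reads")
    kmers = _window_codes(_encode(blob), k)
    if kmers.size == 0:
        raise InputError(f"all reads shorter than k={k} (or contain only N)")
    codes, counts = np.unique(kmers, return_counts=True)
    mult, n_distinct = np.unique(counts, return_counts=True)
    table = KmerCountTable(k=k, codes=codes, counts=counts)
    hist = KmerHistogram(k=k, counts={int(m): int(c) for m, c in zip(mult, n_distinct)})
    return table, hist


def find_diploid_peak(
    hist: KmerHistogram,
    min_multiplicity: int = DEFAULT_MIN_MULTIPLICITY,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
) -> int:
    """Modal multiplicity above the error peak, after moving-average smoothing.

    Multiplicities <= ``min_multiplicity`` (the sequencing-error peak) are
    excluded from the search.  Ties take the lower multiplicity.  A
    histogram with nothing above the floor, or one that is flat there,
    raises :class:`DegenerateDataError`.
    """
    if not hist.counts:
        raise DegenerateDataError("degenerate histogram: empty")
    mmax = max(hist.counts)
    dense = np.zeros(mmax + 1 + smooth_width, dtype=float)
    for mult, cnt in hist.counts.items():
        dense[mult] = cnt
    kernel = np.ones(smooth_width) / smooth_width
    smooth = np.convolve(dense, kernel, mode="same")
    lo = min_multiplicity + 1
    if lo > mmax:
        raise DegenerateDataError("degenerate histogram: no mass above the error-peak floor")
    raw = dense[lo : mmax + 1]
    present = raw[raw > 0]
    if present.size >= 3 and np.allclose(present, present[0]) and np.all(raw > 0):
        raise DegenerateDataError("degenerate histogram: flat above the error-peak floor")
    window = smooth[lo : mmax + 1]
    if window.size == 0 or np.allclose(window, window[0]):
        raise DegenerateDataError("degenerate histogram: flat above the error-peak floor")
    return lo + int(np.argmax(window))


def region_coverage(region: str, table: KmerCountTable) -> float:
    """Median multiplicity of the region's canonical k-mers (absent -> 0)."""
    mult = table.multiplicities(region)
    if mult.size == 0:
        raise InputError("region yields no k-mers (too short or all N)")
    return float(np.median(mult))


def estimate_copies(
    region_cov: float, diploid_peak: float, region_id: str = "region"
) -> CopyEstimate:
    """Copy counts from the fold-coverage ratio (exact before reporting)."""
    if diploid_peak <= 0:
        raise InputError("diploid peak must be positive")
    copies = region_cov / diploid_peak
    return CopyEstimate(
        region_id=region_id,
        region_coverage=float(region_cov),
        diploid_peak=float(diploid_peak),
        copies_diploid=copies,
        copies_per_haplotype=copies / 2.0,
    )


def estimate_from_reads(
    reads: Iterable[str],
    region: str,
    k: int = DEFAULT_K,
    min_multiplicity: int = DEFAULT_MIN_MULTIPLICITY,
    region_id: str = "region",
) -> tuple[CopyEstimate, KmerHistogram]:
    """End-to-end: histogram, peak, region coverage, copy estimate."""
    table, hist = build_histogram(reads, k=k)
    peak = find_diploid_peak(hist, min_multiplicity=min_multiplicity)
    cov = region_coverage(region, table)
    return estimate_copies(cov, peak, region_id=region_id), hist
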