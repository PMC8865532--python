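"""Repeat-hit confidence filtering and repeat-density tracks.

RepeatMasker hit tables are noisy; the pipeline keeps only hits that are at
least 140 bp long AND score at least 450 in the Smith-Waterman local
alignment (both thresholds conjunctive).  Class I elements (retrotransposons:
LTR, LINE, SINE) and class II elements (DNA transposons) are told apart from
the RepeatMasker class/family string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chromosome_features import CoverageTrack

#: default confidence thresholds
MIN_LENGTH = 140
MIN_SW_SCORE = 450


@dataclass(frozen=True)
class RepeatHit:
    """One RepeatMasker alignment row (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    sw_score: int
    family: str
    repeat_class: str  # "I", "II" or "other"
    class_family: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"repeat hit: invalid interval {self.start}..{self.end}")
        if self.sw_score < 0:
            raise ValueError("repeat hit: negative SW score")
        if self.repeat_class not in ("I", "II", "other"):
            raise ValueError(f"repeat hit: unknown class {self.repeat_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def classify_repeat_class(class_family: str) -> str:
    """Map a RepeatMasker class/family string to class I/II/other.

    LTR, LINE and SINE elements copy through an RNA intermediate (class I);
    DNA transposons move as DNA (class II); simple/low-complexity/unknown
    repeats are neither.
    """
    head = class_family.split("/")[0].strip().upper()
    if head in ("LTR", "LINE", "SINE"):
        return "I"
    if head == "DNA":
        return "II"
    return "other"


def filter_hits(
    hits: Sequence[RepeatHit],
    min_length: int = MIN_LENGTH,
    min_sw: int = MIN_SW_SCORE,
) -> list[RepeatHit]:
    """Keep hits with length >= min_length AND sw_score >= min_sw.

    Stable: input order is preserved.  Idempotent, and relaxing either
    threshold can only grow the kept set.
    """
    return [h for h in hits if h.length >= min_length and h.sw_score >= min_sw]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def repeat_density(
    hits: Sequence[RepeatHit], chrom_length: int, window: int, chrom: str = ""
) -> CoverageTrack:
    """Per-window fraction of bases covered by the union of hits.

    Overlapping hits are merged first (union semantics), so duplicating or
    splitting a hit never changes the track.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    for h in hits:
        if h.end > chrom_length:
            raise ValueError(
                f"hit {h.start}..{h.end} extends beyond chromosome end {chrom_length}"
            )
    n_windows = -(-chrom_length // window)
    covered = np.zeros(n_windows, dtype=float)
    for s, e in merge_intervals((h.start, h.end) for h in hits):
        first, last = (s - 1) // window, (e - 1) // window
        for w in range(first, last + 1):
            lo = max(s, w * window + 1)
            hi = min(e, (w + 1) * window)
            covered[w] += hi - lo + 1
    sizes = np.full(n_windows, window, dtype=float)
    if chrom_length % window:
        sizes[-1] = chrom_length % window
    return CoverageTrack(chrom=chrom, window=window, depths=covered / sizes)


def family_census(hits: Sequence[RepeatHit], family: str) -> int:
    """Number of hits whose family matches (case-insensitive substring)."""
    needle = family.lower()
    return sum(1 for h in hits if needle in h.family.lower())
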