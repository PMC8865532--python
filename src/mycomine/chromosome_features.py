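"""Chromosome-level feature heuristics.

* Telomeres: tandem copies of the telomeric motif (TTAGGG at the 3' end,
  its reverse complement CCCTAA at the 5' end) inside a terminal window.
* Centromere candidates: the longest interval on a chromosome free of
  protein-coding genes, reported with the fraction of the interval covered
  by (already filtered) repeat hits and the ratio of transcriptional
  activity inside the interval to its flanks.
* Mitogenome comparison: banded global edit-distance alignment of two
  near-identical circular genomes, with a per-base difference rate.
* Copy-ratio: relative read-mapping coverage of a target region (e.g. the
  45S rDNA array) versus single-copy regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np

from .core_io import ChromosomeRecord, GenomeAnnotation

TELOMERE_MOTIF = "TTAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Windowed per-base mean depth (or density) along one chromosome."""

    chrom: str
    window: int
    depths: np.ndarray

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise ValueError("negative depth")

    @property
    def n_windows(self) -> int:
        return len(self.depths)

    def mean_depth(self, start: int, end: int) -> float:
        """Mean depth over a 1-based inclusive interval, weighting each
        window by its overlap with the interval."""
        if start > end:
            raise ValueError("start > end")
        first = (start - 1) // self.window
        last = min((end - 1) // self.window, self.n_windows - 1)
        total = 0.0
        bases = 0
        for w in range(first, last + 1):
            lo = max(start, w * self.window + 1)
            hi = min(end, (w + 1) * self.window)
            if hi >= lo:
                total += self.depths[w] * (hi - lo + 1)
                bases += hi - lo + 1
        if bases == 0:
            raise ValueError("interval outside track")
        return total / bases


def read_depth_tsv(path: str | Path) -> dict[str, CoverageTrack]:
    """Read a depth TSV (chrom, window, window_index, mean_depth) into
    per-chromosome tracks."""
    rows: dict[str, dict[int, float]] = {}
    windows: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            chrom, window, idx, depth = line.rstrip("\n").split("\t")
            windows[chrom] = int(window)
            rows.setdefault(chrom, {})[int(idx)] = float(depth)
    tracks = {}
    for chrom, d in rows.items():
        depths = np.zeros(max(d) + 1)
        for i, v in d.items():
            depths[i] = v
        tracks[chrom] = CoverageTrack(chrom, windows[chrom], depths)
    return tracks


def write_depth_tsv(tracks: Mapping[str, CoverageTrack], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\twindow\twindow_index\tmean_depth\n")
        for chrom in tracks:
            t = tracks[chrom]
            for i, v in enumerate(t.depths):
                fh.write(f"{chrom}\t{t.window}\t{i}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Telomeres
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelomereCall:
    chrom: str
    terminus: str  # "5prime" | "3prime"
    motif: str
    tandem_copies: int
    present: bool


def _max_tandem_copies(window_seq: str, motif: str) -> int:
    """Longest run of back-to-back motif copies anywhere in the window."""
    best = 0
    m = len(motif)
    i = 0
    n = len(window_seq)
    while i < n:
        if window_seq.startswith(motif, i):
            run = 0
            j = i
            while window_seq.startswith(motif, j):
                run += 1
                j += m
            best = max(best, run)
            i = j
        else:
            i += 1
    return best


def detect_telomeres(
    chromosome: ChromosomeRecord,
    motif: str = TELOMERE_MOTIF,
    terminal_window: int = 200,
    min_copies: int = 3,
) -> tuple[TelomereCall, TelomereCall]:
    """Count maximal tandem motif copies at both termini.

    The 3' terminus is scanned for ``motif`` in the last ``terminal_window``
    bases; the 5' terminus for its reverse complement in the first window.
    A terminus is called present when the copy count reaches ``min_copies``.
    """
    if chromosome.sequence is None:
        raise ValueError(f"{chromosome.name}: sequence required")
    seq = chromosome.sequence
    if len(seq) < len(motif):
        raise ValueError(f"{chromosome.name}: sequence shorter than one motif copy")
    motif = motif.upper()
    rc = reverse_complement(motif)
    head = seq[:terminal_window]
    tail = seq[-terminal_window:]
    c5 = _max_tandem_copies(head, rc)
    c3 = _max_tandem_copies(tail, motif)
    return (
        TelomereCall(chromosome.name, "5prime", rc, c5, c5 >= min_copies),
        TelomereCall(chromosome.name, "3prime", motif, c3, c3 >= min_copies),
    )


# ---------------------------------------------------------------------------
# Centromere candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CentromereCall:
    chrom: str
    start: int
    end: int
    length: int
    rt_fraction: float
    expr_ratio: float
    orf_free: bool = True


def _union_overlap(intervals: Sequence[tuple[int, int]], start: int, end: int) -> int:
    """Bases of [start, end] covered by the union of intervals."""
    from .repeats import merge_intervals

    total = 0
    for s, e in merge_intervals(intervals):
        lo, hi = max(s, start), min(e, end)
        if hi >= lo:
            total += hi - lo + 1
    return total


def find_centromere_candidate(
    annotation: GenomeAnnotation,
    repeats: Sequence,
    expression_track: CoverageTrack | None,
    chrom: str,
    flank_length: int | None = None,
    include_terminal: bool = True,
) -> CentromereCall:
    """Longest interval on ``chrom`` free of protein-coding genes.

    Gaps are bounded by consecutive protein-coding genes, plus the two
    terminal gaps (before the first and after the last gene) unless
    ``include_terminal`` is off.  Ties break to the leftmost gap.
    ``rt_fraction`` is the fraction of the interval covered by the union of
    the supplied (pre-filtered) repeat hits; ``expr_ratio`` is the interval's
    mean depth divided by the mean of two equal-length flanks (default flank
    length = candidate length, clipped at the chromosome ends).
    """
    coding = annotation.genes_on(chrom, kind="protein_coding")
    if not coding:
        raise ValueError(f"{chrom}: no protein-coding gene")
    chrom_len = annotation.chromosome(chrom).length
    gaps: list[tuple[int, int]] = []
    if include_terminal and coding[0].start > 1:
        gaps.append((1, coding[0].start - 1))
    prev_end = coding[0].end
    for g in coding[1:]:
        if g.start > prev_end + 1:
            gaps.append((prev_end + 1, g.start - 1))
        prev_end = max(prev_end, g.end)
    if include_terminal and prev_end < chrom_len:
        gaps.append((prev_end + 1, chrom_len))
    if not gaps:
        raise ValueError(f"{chrom}: no gap between protein-coding genes")
    start, end = max(gaps, key=lambda iv: (iv[1] - iv[0] + 1, -iv[0]))
    length = end - start + 1

    chrom_hits = [(h.start, h.end) for h in repeats if h.chrom == chrom]
    rt_fraction = _union_overlap(chrom_hits, start, end) / length

    expr_ratio = float("nan")
    if expression_track is not None:
        flank = flank_length or length
        left_lo, left_hi = max(1, start - flank), start - 1
        right_lo, right_hi = end + 1, min(chrom_len, end + flank)
        flank_total, flank_bases = 0.0, 0
        for lo, hi in ((left_lo, left_hi), (right_lo, right_hi)):
            if hi >= lo:
                n = hi - lo + 1
                flank_total += expression_track.mean_depth(lo, hi) * n
                flank_bases += n
        inside = expression_track.mean_depth(start, end)
        if flank_bases == 0 or flank_total == 0:
            expr_ratio = float("inf") if inside > 0 else 0.0
        else:
            expr_ratio = inside / (flank_total / flank_bases)

    return CentromereCall(chrom, start, end, length, rt_fraction, expr_ratio)


def validate_centromere(call: CentromereCall, annotation: GenomeAnnotation) -> bool:
    """Check the call overlaps no protein-coding gene and is a maximal gap."""
    for g in annotation.genes_on(call.chrom, kind="protein_coding"):
        if g.start <= call.end and call.start <= g.end:
            return False
    return True


# ---------------------------------------------------------------------------
# Mitogenome comparison
# ---------------------------------------------------------------------------

def canonical_rotation(seq_a: str, seq_b: str, probe: int = 1000) -> str:
    """Rotate circular ``seq_b`` to the rotation minimizing Hamming mismatch
    against the first ``probe`` bases of ``seq_a`` (ties -> smallest shift)."""
    k = min(probe, len(seq_a), len(seq_b))
    a = np.frombuffer(seq_a[:k].encode(), dtype=np.uint8)
    doubled = np.frombuffer((seq_b + seq_b[: k - 1]).encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(doubled, k)[: len(seq_b)]
    mismatches = (windows != a).sum(axis=1)
    shift = int(np.argmin(mismatches))
    return seq_b[shift:] + seq_b[:shift]


def mito_compare(
    seq_a: str,
    seq_b: str,
    band: int | None = None,
    circular: bool = True,
) -> dict:
    """Globally align two near-identical genomes and tally differences.

    Returns substitutions, insertions (bases in ``seq_b`` absent from
    ``seq_a``), deletions (bases in ``seq_a`` absent from ``seq_b``), the
    alignment length, and ``per_base_rate`` = total differences divided by
    the longer sequence length.  ``band`` caps the alignment's edit distance
    (it must be at least the length difference); circular inputs are first
    co-rotated on the leading 1 kb.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if band is not None and band < abs(len(seq_a) - len(seq_b)):
        raise ValueError("band narrower than the sequence length difference")
    if circular and seq_a != seq_b:
        seq_b = canonical_rotation(seq_a, seq_b)
    result = edlib.align(seq_b, seq_a, mode="NW", task="path",
                         k=-1 if band is None else band)
    if result["editDistance"] < 0:
        raise ValueError(f"band {band} too narrow to align the sequences")
    nice = edlib.getNiceAlignment(result, seq_b, seq_a)
    target = nice["target_aligned"]   # seq_a
    query = nice["query_aligned"]     # seq_b
    subs = ins = dels = 0
    for qa, ta in zip(query, target):
        if qa == "-":
            dels += 1
        elif ta == "-":
            ins += 1
        elif qa != ta:
            subs += 1
    total = subs + ins + dels
    return {
        "substitutions": subs,
        "insertions": ins,
        "deletions": dels,
        "aligned_length": len(target),
        "edit_distance": result["editDistance"],
        "per_base_rate": total / max(len(seq_a), len(seq_b)),
    }


def format_rate(rate: float) -> str:
    """Display a per-base rate to 3 significant digits (scientific)."""
    return f"{rate:.2e}"


# ---------------------------------------------------------------------------
# Copy ratio
# ---------------------------------------------------------------------------

def copy_ratio(
    depth_tracks: Mapping[str, CoverageTrack] | CoverageTrack,
    target_intervals: Sequence[tuple],
    single_copy_intervals: Sequence[tuple],
) -> float:
    """(mean depth over targets) / (mean depth over single-copy regions).

    Intervals are (chrom, start, end); with a single track the chrom element
    may be omitted.  Invariant under uniform scaling of the whole track.
    """
    if not target_intervals or not single_copy_intervals:
        raise ValueError("interval lists must be non-empty")

    def _mean(intervals: Sequence[tuple]) -> float:
        total, bases = 0.0, 0
        for iv in intervals:
            if isinstance(depth_tracks, CoverageTrack):
                track = depth_tracks
                start, end = iv[-2], iv[-1]
            else:
                chrom, start, end = iv
                track = depth_tracks[chrom]
            n = end - start + 1
            total += track.mean_depth(start, end) * n
            bases += n
        return total / bases

    denom = _mean(single_copy_intervals)
    if denom == 0:
        raise ValueError("zero depth over single-copy intervals")
    return _mean(target_intervals) / denom
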