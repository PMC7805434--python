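"""Genomic interval primitives and exact interval algebra.

All coordinates are 0-based half-open (BED convention). Intervals carry no
strand: histone-mark peaks are unstranded, and every operation here is
strand-agnostic. The algebra matches BEDTools defaults, in particular
book-ended intervals (``a.end == b.start``) merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "PeakRecord",
    "TSSRecord",
    "RegionSetComparison",
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "coverage_segments",
    "total_length",
    "compare_region_sets",
    "nearest_gene",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Ordering is lexicographic by ``(chrom, start, end)`` and total, so lists
    of intervals sort into standard BED order.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap in bp between closest ends; 0 if overlapping or book-ended."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class PeakRecord:
    """One called ChIP-seq peak from an ENCODE narrowPeak/broadPeak file."""

    interval: GenomicInterval
    marker: str = ""
    peak_format: str = "narrow"
    neg_log10_p: float | None = None
    experiment_id: str = ""
    replicate_id: str = ""
    cell_line: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.neg_log10_p is not None and self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0 when present")


@dataclass(frozen=True)
class TSSRecord:
    """A scored single-base transcription start site annotation."""

    interval: GenomicInterval
    score: float
    gene: str = ""

    def __post_init__(self) -> None:
        if self.interval.end != self.interval.start + 1:
            raise ValueError("TSS interval must be exactly 1 bp wide")


@dataclass(frozen=True)
class RegionSetComparison:
    """Asymmetric region-set comparison statistics (all in [0, 1]).

    ``pct_a_overlapping_b``: fraction of A's regions with >=1 bp overlap in B.
    ``coverage_ratio_a``: bp covered by both / bp covered by A.
    ``jaccard``: bp(A and B) / bp(A or B).
    """

    pct_a_overlapping_b: float
    coverage_ratio_a: float
    jaccard: float
    degenerate: bool = field(default=False, compare=False)


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted disjoint set covering the same bases (book-ended merge)."""
    out: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        ivs = sorted(
            (iv for iv in intervals if iv.chrom == chrom),
            key=lambda iv: (iv.start, iv.end),
        )
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def coverage_segments(
    tracks: Sequence[Sequence[GenomicInterval]],
) -> list[tuple[GenomicInterval, int]]:
    """Partition covered bases into maximal segments of constant track coverage.

    Each track counts at most once per base (tracks are merged first). Returns
    ``(segment, n_tracks_covering)`` pairs sorted in BED order; segments where
    the coverage count changes are split even when book-ended.
    """
    merged = [merge_intervals(t) for t in tracks]
    events: dict[str, list[tuple[int, int]]] = {}
    for track in merged:
        for iv in track:
            events.setdefault(iv.chrom, []).append((iv.start, 1))
            events[iv.chrom].append((iv.end, -1))
    out: list[tuple[GenomicInterval, int]] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        prev_pos = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            if depth > 0 and prev_pos is not None and pos > prev_pos:
                out.append((GenomicInterval(chrom, prev_pos, pos), depth))
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            prev_pos = pos
    return out


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Exact basepair intersection of two interval sets, sorted and disjoint."""
    am = _by_chrom(merge_intervals(a))
    bm = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for chrom in sorted(set(am) & set(bm)):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of ``a`` not covered by ``b``, sorted and disjoint."""
    am = _by_chrom(merge_intervals(a))
    bm = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for chrom in sorted(am):
        cuts = bm.get(chrom, [])
        for iv in am[chrom]:
            pos = iv.start
            for cut in cuts:
                if cut.end <= pos or cut.start >= iv.end:
                    continue
                if cut.start > pos:
                    out.append(GenomicInterval(chrom, pos, cut.start))
                pos = max(pos, cut.end)
                if pos >= iv.end:
                    break
            if pos < iv.end:
                out.append(GenomicInterval(chrom, pos, iv.end))
    return out


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    """Number of distinct bases covered."""
    return sum(len(iv) for iv in merge_intervals(intervals)) if intervals else 0


def compare_region_sets(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> RegionSetComparison:
    """Asymmetric overlap statistics between region set A and region set B."""
    if not a:
        return RegionSetComparison(0.0, 0.0, 0.0, degenerate=True)
    bm = merge_intervals(b) if b else []
    b_by_chrom = _by_chrom(bm)
    n_overlap = 0
    for iv in a:
        cands = b_by_chrom.get(iv.chrom, ())
        if any(iv.start < c.end and c.start < iv.end for c in cands):
            n_overlap += 1
    inter_bp = total_length(intersect_intervals(a, b)) if b else 0
    a_bp = total_length(a)
    union_bp = total_length(list(a) + list(b))
    return RegionSetComparison(
        pct_a_overlapping_b=n_overlap / len(a),
        coverage_ratio_a=inter_bp / a_bp,
        jaccard=inter_bp / union_bp if union_bp else 0.0,
    )


def nearest_gene(
    cre: GenomicInterval,
    genes: Sequence[tuple[GenomicInterval, str]],
) -> tuple[str, int] | None:
    """Closest gene to a CRE by end-to-end gap (0 when overlapping).

    Ties break deterministically toward the gene with the smaller
    ``(chrom, start)``. Returns ``None`` when no gene lies on the CRE's
    chromosome.
    """
    best: tuple[int, GenomicInterval, str] | None = None
    for giv, name in genes:
        if giv.chrom != cre.chrom:
            continue
        d = cre.distance(giv)
        if best is None or d < best[0] or (d == best[0] and giv < best[1]):
            best = (d, giv, name)
    if best is None:
        return None
    return best[2], best[0]
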