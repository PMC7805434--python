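"""Consensus regulatory element (CRE) construction.

The workflow distils agreement across levels of evidence:

1. *Replicates* of one experiment are intersected (a base must be present in
   every replicate).
2. *Experiments* of one cell line are combined by keeping the merge of all
   bases covered by at least two experiments (one experiment passes through).
3. Per cell line, marker tracks classify elements: H3K4me3 near a TSS marks
   promoters; H3K4me1 depleted of H3K4me3 and >1 kb from every TSS marks
   enhancers; enhancers touched by H3K27ac are active enhancers.
4. *Tissue* and *global* consensuses keep regions overlapping in at least two
   cell lines, retaining the full-extent union of the overlapping regions.

Narrow- and broad-peak collections run through the pipeline separately, and
broad peaks are first filtered at reported p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .intervals import (
    GenomicInterval,
    PeakRecord,
    TSSRecord,
    coverage_segments,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
)

__all__ = [
    "ConsensusRegion",
    "MarkerTrack",
    "ConsensusConfig",
    "combine_replicates",
    "combine_experiments",
    "classify_cell_line_elements",
    "build_higher_consensus",
    "run_consensus_pipeline",
]

ELEMENT_CLASSES = ("promoter", "enhancer", "active_enhancer")
MARKERS = ("H3K4me1", "H3K4me3", "H3K27ac")


@dataclass(frozen=True)
class ConsensusRegion:
    """One CRE with its class, abstraction level and supporting evidence."""

    interval: GenomicInterval
    element_class: str
    level: str  # cell_line | tissue | global
    label: str  # cell line name, tissue name, or "global"
    peak_format: str
    n_support: int

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")
        floor = 1 if self.level == "cell_line" else 2
        if self.n_support < floor:
            raise ValueError(
                f"{self.level}-level region requires n_support >= {floor}"
            )


@dataclass(frozen=True)
class MarkerTrack:
    marker: str
    regions: tuple[GenomicInterval, ...]
    provenance: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConsensusConfig:
    """Tunable thresholds of the consensus pipeline (defaults per workflow)."""

    broad_pvalue_max: float = 0.01
    tss_min_score: float = 10.0
    tss_window: int = 1000
    min_experiments: int = 2
    min_cell_lines: int = 2
    #: tissue/global union semantics: full interval extents (default) or only
    #: the merged >=2-label overlap segments.
    higher_union_full_extent: bool = True


def combine_replicates(
    replicate_tracks: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Intersection of all replicate tracks (single replicate passes through)."""
    if not replicate_tracks:
        raise ValueError("at least one replicate track required")
    acc = merge_intervals(list(replicate_tracks[0]))
    for track in replicate_tracks[1:]:
        acc = intersect_intervals(acc, list(track))
    return acc


def combine_experiments(
    experiment_tracks: Sequence[Sequence[GenomicInterval]],
) -> list[tuple[GenomicInterval, int]]:
    """Merge of all bases present in >=2 experiments, with support counts.

    With a single experiment the track passes through with support 1
    ("at least two, when available"). The support count of an output region
    is the maximum number of distinct experiments covering any of its bases.
    """
    if not experiment_tracks:
        raise ValueError("at least one experiment track required")
    if len(experiment_tracks) == 1:
        return [(iv, 1) for iv in merge_intervals(list(experiment_tracks[0]))]
    segs = coverage_segments(experiment_tracks)
    seeds = [iv for iv, depth in segs if depth >= 2]
    merged = merge_intervals(seeds) if seeds else []
    out: list[tuple[GenomicInterval, int]] = []
    for region in merged:
        support = max(
            depth
            for iv, depth in segs
            if iv.chrom == region.chrom
            and iv.start < region.end
            and region.start < iv.end
        )
        out.append((region, support))
    return out


def _tss_windows(tss: Sequence[TSSRecord], window: int) -> list[GenomicInterval]:
    return [
        GenomicInterval(
            t.interval.chrom,
            max(0, t.interval.start - window),
            t.interval.start + window,
        )
        for t in tss
    ]


def classify_cell_line_elements(
    h3k4me3: Sequence[GenomicInterval] | None,
    h3k4me1: Sequence[GenomicInterval] | None,
    h3k27ac: Sequence[GenomicInterval] | None,
    tss: Sequence[TSSRecord],
    tss_min_score: float = 10.0,
    tss_window: int = 1000,
) -> dict[str, list[GenomicInterval]]:
    """Classify one cell line's consensus marker tracks into element classes.

    Promoters are whole H3K4me3 regions overlapping a ±``tss_window`` window
    around a retained TSS. Enhancers are H3K4me1 bases outside both all
    H3K4me3 regions and all TSS windows. Active enhancers are whole enhancer
    regions overlapped by >=1 bp of H3K27ac. A class is emitted only when its
    required marker(s) are available.
    """
    kept_tss = [t for t in tss if t.score >= tss_min_score]
    windows = merge_intervals(_tss_windows(kept_tss, tss_window)) if kept_tss else []
    out: dict[str, list[GenomicInterval]] = {}
    if h3k4me3 is None and h3k4me1 is None and h3k27ac is None:
        warnings.warn("no marker tracks available; no elements classified")
        return out
    if h3k4me3 is not None:
        me3 = merge_intervals(list(h3k4me3)) if h3k4me3 else []
        out["promoter"] = [
            iv
            for iv in me3
            if any(iv.overlaps(w) for w in windows if w.chrom == iv.chrom)
        ]
    if h3k4me1 is not None:
        enh = merge_intervals(list(h3k4me1)) if h3k4me1 else []
        if h3k4me3:
            enh = subtract_intervals(enh, list(h3k4me3))
        if windows:
            enh = subtract_intervals(enh, windows)
        out["enhancer"] = enh
        if h3k27ac is not None:
            ac = merge_intervals(list(h3k27ac)) if h3k27ac else []
            out["active_enhancer"] = [
                iv
                for iv in enh
                if any(iv.overlaps(a) for a in ac if a.chrom == iv.chrom)
            ]
    return out


def build_higher_consensus(
    per_label_tracks: Mapping[str, Sequence[GenomicInterval]],
    min_labels: int = 2,
    full_extent: bool = True,
) -> list[tuple[GenomicInterval, int]]:
    """Tissue/global consensus: regions overlapping in >= ``min_labels`` labels.

    Seed bases are those covered by at least ``min_labels`` distinct labels.
    With ``full_extent`` (default) every input interval containing a seed base
    contributes its full extent and the union is merged; otherwise only the
    merged seed segments are returned. Support is the number of distinct
    labels whose intervals touch the output region.
    """
    if not per_label_tracks:
        raise ValueError("at least one label required")
    tracks = {k: merge_intervals(list(v)) for k, v in per_label_tracks.items() if v}
    segs = coverage_segments(list(tracks.values()))
    seeds = merge_intervals([iv for iv, d in segs if d >= min_labels]) if segs else []
    if not seeds:
        return []
    if full_extent:
        contributing = [
            iv
            for track in tracks.values()
            for iv in track
            if any(iv.overlaps(s) for s in seeds)
        ]
        regions = merge_intervals(contributing)
    else:
        regions = seeds
    out: list[tuple[GenomicInterval, int]] = []
    for region in regions:
        support = sum(
            1
            for track in tracks.values()
            if any(region.overlaps(iv) for iv in track)
        )
        out.append((region, support))
    return out


TrackKey = tuple[str, str, str, str]  # (level, label, element_class, peak_format)


def run_consensus_pipeline(
    peaks: Sequence[PeakRecord],
    tss: Sequence[TSSRecord],
    config: ConsensusConfig | None = None,
) -> dict[TrackKey, list[ConsensusRegion]]:
    """Run the full consensus workflow on a set of annotated peak records.

    Peaks are grouped by (peak_format, cell_line, marker, experiment,
    replicate); narrow and broad collections are processed independently, the
    broad collection after p < ``broad_pvalue_max`` filtering. Returns one
    sorted, disjoint CRE track per (level, label, element class, format).
    """
    from .io import filter_peaks_by_pvalue

    cfg = config or ConsensusConfig()
    out: dict[TrackKey, list[ConsensusRegion]] = {}

    for fmt in ("narrow", "broad"):
        fmt_peaks = [p for p in peaks if p.peak_format == fmt]
        if fmt == "broad" and fmt_peaks:
            fmt_peaks = filter_peaks_by_pvalue(fmt_peaks, cfg.broad_pvalue_max)
        if not fmt_peaks:
            continue

        # cell line -> marker -> experiment -> replicate -> intervals
        nested: dict[str, dict[str, dict[str, dict[str, list[GenomicInterval]]]]] = {}
        cell_tissue: dict[str, str] = {}
        for p in fmt_peaks:
            nested.setdefault(p.cell_line, {}).setdefault(p.marker, {}).setdefault(
                p.experiment_id, {}
            ).setdefault(p.replicate_id, []).append(p.interval)
            cell_tissue[p.cell_line] = p.tissue

        # element class -> marker whose experiment support the CRE inherits
        defining_marker = {
            "promoter": "H3K4me3",
            "enhancer": "H3K4me1",
            "active_enhancer": "H3K4me1",
        }
        per_cell_elements: dict[str, dict[str, list[GenomicInterval]]] = {}
        for cell, markers in nested.items():
            marker_consensus: dict[str, list[GenomicInterval]] = {}
            marker_support: dict[str, list[tuple[GenomicInterval, int]]] = {}
            for marker, experiments in markers.items():
                exp_tracks = [
                    combine_replicates(list(reps.values()))
                    for reps in experiments.values()
                ]
                marker_support[marker] = combine_experiments(exp_tracks)
                marker_consensus[marker] = [iv for iv, _ in marker_support[marker]]
            elements = classify_cell_line_elements(
                marker_consensus.get("H3K4me3"),
                marker_consensus.get("H3K4me1"),
                marker_consensus.get("H3K27ac"),
                tss,
                tss_min_score=cfg.tss_min_score,
                tss_window=cfg.tss_window,
            )
            per_cell_elements[cell] = elements
            for cls, regions in elements.items():
                support_pairs = marker_support.get(defining_marker[cls], [])
                regs = []
                for iv in regions:
                    overlapping = [
                        n for siv, n in support_pairs if siv.overlaps(iv)
                    ]
                    regs.append(
                        ConsensusRegion(
                            iv, cls, "cell_line", cell, fmt,
                            max(overlapping, default=1),
                        )
                    )
                out[("cell_line", cell, cls, fmt)] = regs

        by_tissue: dict[str, list[str]] = {}
        for cell, tis in cell_tissue.items():
            by_tissue.setdefault(tis, []).append(cell)

        for cls in ELEMENT_CLASSES:
            for tissue, cells in sorted(by_tissue.items()):
                tracks = {
                    c: per_cell_elements.get(c, {}).get(cls, [])
                    for c in cells
                    if per_cell_elements.get(c, {}).get(cls)
                }
                if len(tracks) >= cfg.min_cell_lines:
                    regions = build_higher_consensus(
                        tracks,
                        min_labels=cfg.min_cell_lines,
                        full_extent=cfg.higher_union_full_extent,
                    )
                    if regions:
                        out[("tissue", tissue, cls, fmt)] = [
                            ConsensusRegion(iv, cls, "tissue", tissue, fmt, n)
                            for iv, n in regions
                        ]
            all_tracks = {
                c: els.get(cls, [])
                for c, els in per_cell_elements.items()
                if els.get(cls)
            }
            if len(all_tracks) >= cfg.min_cell_lines:
                regions = build_higher_consensus(
                    all_tracks,
                    min_labels=cfg.min_cell_lines,
                    full_extent=cfg.higher_union_full_extent,
                )
                if regions:
                    out[("global", "global", cls, fmt)] = [
                        ConsensusRegion(iv, cls, "global", "global", fmt, n)
                        for iv, n in regions
                    ]
    return out
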