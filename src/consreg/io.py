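"""Readers and writers for the BED-family formats used by the pipeline.

Supported inputs: BED3/BED6, ENCODE narrowPeak (BED6+4), ENCODE broadPeak
(BED6+3), scored BED for TSS, and a TSV sample sheet mapping peak files to
(marker, format, experiment, replicate, cell line, tissue). Output BED is
tab-separated, headerless, LF-terminated — byte-reproducible given the same
regions.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval, PeakRecord, TSSRecord

__all__ = [
    "PeakParseError",
    "read_peaks",
    "filter_peaks_by_pvalue",
    "read_tss",
    "read_bed",
    "write_bed",
    "SampleSheetRow",
    "read_sample_sheet",
]

#: 1-based column 8 of both narrowPeak and broadPeak is -log10(p); -1 means
#: "not reported" (ENCODE convention).
_PVAL_COL = 7

_N_COLS = {"narrow": 10, "broad": 9}


class PeakParseError(ValueError):
    """Malformed peak line; message carries the 1-based line number."""


def _parse_peak_line(
    fields: list[str], lineno: int, peak_format: str
) -> tuple[GenomicInterval, float | None]:
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
    except (IndexError, ValueError) as exc:
        raise PeakParseError(f"line {lineno}: malformed BED fields: {exc}") from exc
    if start >= end:
        raise PeakParseError(f"line {lineno}: start {start} >= end {end}")
    neg_log10_p: float | None = None
    if len(fields) > _PVAL_COL:
        try:
            raw = float(fields[_PVAL_COL])
        except ValueError as exc:
            raise PeakParseError(f"line {lineno}: bad p-value column: {exc}") from exc
        if raw != -1:
            neg_log10_p = raw
    return GenomicInterval(chrom, start, end), neg_log10_p


def read_peaks(
    path: str | Path,
    peak_format: str,
    *,
    marker: str = "",
    experiment_id: str = "",
    replicate_id: str = "",
    cell_line: str = "",
    tissue: str = "",
) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak or broadPeak file into sorted PeakRecords.

    Coordinates are preserved exactly; records are returned sorted by
    ``(chrom, start, end)``. Column 8 (−log10 p) maps to ``neg_log10_p``;
    the ENCODE sentinel −1 maps to ``None``.
    """
    if peak_format not in _N_COLS:
        raise ValueError(f"unknown peak format {peak_format!r}")
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            interval, nlp = _parse_peak_line(fields, lineno, peak_format)
            records.append(
                PeakRecord(
                    interval=interval,
                    marker=marker,
                    peak_format=peak_format,
                    neg_log10_p=nlp,
                    experiment_id=experiment_id,
                    replicate_id=replicate_id,
                    cell_line=cell_line,
                    tissue=tissue,
                )
            )
    records.sort(key=lambda r: r.interval)
    return records


def filter_peaks_by_pvalue(
    peaks: Sequence[PeakRecord], alpha: float
) -> list[PeakRecord]:
    """Retain peaks with reported p-value strictly below ``alpha``.

    ``p = 10**(-neg_log10_p)``; the boundary ``p == alpha`` is excluded.
    A peak with no reported p-value is an error: the caller asked for a
    p-value filter that cannot be evaluated.
    """
    if not (0 < alpha < 1 or alpha == 1.0):
        raise ValueError("alpha must be in (0, 1]")
    kept: list[PeakRecord] = []
    for peak in peaks:
        if peak.neg_log10_p is None:
            raise ValueError(
                f"peak {peak.interval.chrom}:{peak.interval.start}-"
                f"{peak.interval.end} has no reported p-value; cannot filter"
            )
        if 10.0 ** (-peak.neg_log10_p) < alpha:
            kept.append(peak)
    return kept


def read_tss(path: str | Path, min_score: float | None = None) -> list[TSSRecord]:
    """Read scored single-base TSS annotations from BED.

    BED rows wider than 1 bp are rejected. With ``min_score`` set, rows
    scoring below it are dropped (score >= min_score retained).
    """
    out: list[TSSRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                gene = fields[3] if len(fields) > 3 else ""
                score = float(fields[4]) if len(fields) > 4 else math.nan
            except (IndexError, ValueError) as exc:
                raise PeakParseError(f"line {lineno}: bad TSS row: {exc}") from exc
            rec = TSSRecord(interval=iv, score=score, gene=gene)
            if min_score is None or rec.score >= min_score:
                out.append(rec)
    out.sort(key=lambda r: r.interval)
    return out


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read the first three columns of a BED file."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except (IndexError, ValueError) as exc:
                raise PeakParseError(f"line {lineno}: bad BED row: {exc}") from exc
    out.sort()
    return out


def write_bed(
    path: str | Path,
    rows: Iterable[tuple],
) -> None:
    """Write tab-separated BED rows (interval first, then extra columns)."""
    with open(path, "w", newline="\n") as fh:
        for row in rows:
            iv = row[0]
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            cols.extend(str(x) for x in row[1:])
            fh.write("\t".join(cols) + "\n")


@dataclass(frozen=True)
class SampleSheetRow:
    path: str
    marker: str
    peak_format: str
    experiment_id: str
    replicate_id: str
    cell_line: str
    tissue: str


_SHEET_COLUMNS = (
    "path",
    "marker",
    "peak_format",
    "experiment_id",
    "replicate_id",
    "cell_line",
    "tissue",
)


def read_sample_sheet(path: str | Path) -> list[SampleSheetRow]:
    """Read the TSV sample sheet describing every peak file of a run."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_SHEET_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(
                "sample sheet missing column(s): " + ", ".join(sorted(missing))
            )
        return [
            SampleSheetRow(**{c: row[c] for c in _SHEET_COLUMNS}) for row in reader
        ]


def load_peaks_from_sheet(
    sheet: Sequence[SampleSheetRow], base_dir: str | Path | None = None
) -> list[PeakRecord]:
    """Read every peak file referenced by a sample sheet."""
    peaks: list[PeakRecord] = []
    for row in sheet:
        p = Path(row.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        peaks.extend(
            read_peaks(
                p,
                row.peak_format,
                marker=row.marker,
                experiment_id=row.experiment_id,
                replicate_id=row.replicate_id,
                cell_line=row.cell_line,
                tissue=row.tissue,
            )
        )
    return peaks
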