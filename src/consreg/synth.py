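"""Self-contained synthetic inputs with known ground truth.

Every generator is a pure function of (spec, seed): byte-identical outputs
across runs. The fixtures emulate the pipeline's real-world inputs — an
i.i.d.-composition genome with planted motif sites, per-replicate
narrowPeak/broadPeak files with optional boundary jitter and decoy peaks,
scored TSS BED, sharp JASPAR PFMs, and a phased diploid SNP VCF with planted
haplotype fractions — at desk scale. Ground-truth BED tracks are emitted
alongside the peaks so downstream tests assert recovery rather than
re-derivation. What the fixtures deliberately lack: read-level noise,
linkage disequilibrium beyond the planted fractions, and realistic peak
width/score distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, merge_intervals
from .io import write_bed
from .pfm import BASES, PFM, BackgroundModel, pfm_from_counts
from .tba import reverse_complement

__all__ = [
    "PlantedElement",
    "PlantedMotif",
    "PlantedSNP",
    "PeakNoise",
    "FixtureSpec",
    "make_genome",
    "make_sharp_pfm",
    "make_allele_sensitive_pfm",
    "write_jaspar",
    "make_tss",
    "make_peaks",
    "make_vcf",
    "default_fixture_spec",
]

_MARKERS_BY_CLASS = {
    "promoter": ("H3K4me3",),
    "enhancer": ("H3K4me1",),
    "active_enhancer": ("H3K4me1", "H3K27ac"),
}


@dataclass(frozen=True)
class PlantedElement:
    """A regulatory element planted in specific cell lines."""

    element_class: str
    interval: GenomicInterval
    cell_lines: tuple[str, ...]


@dataclass(frozen=True)
class PlantedMotif:
    """A motif consensus written into the reference at a fixed location."""

    pfm_id: str
    interval: GenomicInterval
    strand: str = "+"
    #: when set, the reference carries a broken site and a SNP restoring the
    #: consensus is planted on this fraction of haplotypes instead
    allele_fraction: float | None = None


@dataclass(frozen=True)
class PlantedSNP:
    chrom: str
    pos: int  # 0-based
    alt: str
    hap_fraction: float


@dataclass(frozen=True)
class PeakNoise:
    """Peak-file corruption rates (all zero = noiseless round trip)."""

    jitter: int = 0  # max +- bp shift of each boundary, per replicate
    dropout: float = 0.0  # probability a replicate misses a planted peak
    n_decoys_per_track: int = 0  # random peaks present in one experiment only


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of one synthetic study; reproducible from ``seed``."""

    chrom_lengths: Mapping[str, int]
    cell_line_tissue: Mapping[str, str]
    planted_elements: tuple[PlantedElement, ...] = ()
    planted_motifs: tuple[PlantedMotif, ...] = ()
    pfms: tuple[PFM, ...] = ()
    n_individuals: int = 50
    n_experiments: int = 2
    n_replicates: int = 2
    peak_format: str = "narrow"
    base_composition: BackgroundModel = field(default_factory=BackgroundModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for el in self.planted_elements:
            if el.interval.end > self.chrom_lengths.get(el.interval.chrom, 0):
                raise ValueError(f"planted element outside genome: {el}")
        for pm in self.planted_motifs:
            if pm.interval.end > self.chrom_lengths.get(pm.interval.chrom, 0):
                raise ValueError(f"planted motif outside genome: {pm}")


def make_sharp_pfm(
    motif_id: str,
    consensus: str,
    n_sites: int = 100,
    off_count: int = 1,
) -> PFM:
    """High-information PFM whose argmax sequence is ``consensus``.

    Each position gives ``n_sites - 3*off_count`` counts to the consensus
    base and ``off_count`` to each other base (~1.5 bits/position at the
    defaults, so an 8-mer exceeds 10 bits total).
    """
    counts = np.full((len(consensus), 4), float(off_count))
    for j, base in enumerate(consensus.upper()):
        counts[j, BASES.index(base)] = float(n_sites - 3 * off_count)
    return pfm_from_counts(motif_id, counts, pseudocount=1.0)


def make_allele_sensitive_pfm(motif_id: str, consensus: str) -> PFM:
    """PFM whose affinity hinges on its first position.

    Position 1 is ultra-sharp (mismatch costs ~1000x) while the remaining
    positions are moderately informative (~6x per mismatch). A single base
    change at position 1 therefore moves a site from far above to far below
    the genomic null tail, which makes allele-specific enrichment
    deterministic when that base is polymorphic: chance near-matches in a
    background genome sit orders of magnitude below the intact site but
    orders of magnitude above the broken one.
    """
    counts = np.full((len(consensus), 4), 5.0)
    counts[0, :] = 1.0
    for j, base in enumerate(consensus.upper()):
        counts[j, BASES.index(base)] = 2000.0 if j == 0 else 35.0
    return pfm_from_counts(motif_id, counts, pseudocount=1.0)


def write_jaspar(pfms_counts: Sequence[tuple[str, np.ndarray]], path: str | Path) -> None:
    """Write count matrices in JASPAR text format (one block per motif)."""
    with open(path, "w", newline="\n") as fh:
        for motif_id, counts in pfms_counts:
            fh.write(f">{motif_id} {motif_id}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{counts[j, bi]:.0f}" for j in range(counts.shape[0]))
                fh.write(f"{base} [ {row} ]\n")


def make_genome(spec: FixtureSpec) -> dict[str, str]:
    """I.i.d. genome from the base composition with planted motif sites.

    Motifs with an ``allele_fraction`` are *not* written: the reference keeps
    a broken site (first consensus base replaced by its complement) and the
    restoring SNP is planted by :func:`make_vcf`.
    """
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    pfm_by_id = {p.motif_id: p for p in spec.pfms}
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        if length < 1:
            raise ValueError(f"{chrom}: non-positive length")
        codes = rng.choice(4, size=length, p=spec.base_composition.probs)
        seq = np.array(list(BASES))[codes]
        occupied: list[tuple[int, int]] = []
        for pm in spec.planted_motifs:
            if pm.interval.chrom != chrom:
                continue
            for s, e in occupied:
                if pm.interval.start < e and s < pm.interval.end:
                    raise ValueError(f"overlapping planted motifs at {pm.interval}")
            occupied.append((pm.interval.start, pm.interval.end))
            site = pfm_by_id[pm.pfm_id].consensus()
            if pm.strand == "-":
                site = reverse_complement(site)
            if len(site) != len(pm.interval):
                raise ValueError(
                    f"motif {pm.pfm_id} length {len(site)} != interval "
                    f"{len(pm.interval)}"
                )
            site_arr = np.array(list(site))
            if pm.allele_fraction is not None:
                # break the site in the reference; make_vcf restores it
                site_arr[0] = reverse_complement(site[0])
            seq[pm.interval.start : pm.interval.end] = site_arr
        genome[chrom] = "".join(seq)
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_tss(
    spec: FixtureSpec, score: float = 20.0
) -> list[tuple[GenomicInterval, str, float]]:
    """One high-confidence TSS at the midpoint of every planted promoter."""
    out = []
    seen: set[tuple[str, int]] = set()
    idx = 0
    for el in spec.planted_elements:
        if el.element_class != "promoter":
            continue
        mid = (el.interval.start + el.interval.end) // 2
        key = (el.interval.chrom, mid)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            (
                GenomicInterval(el.interval.chrom, mid, mid + 1),
                f"GENE{idx}",
                score,
            )
        )
        idx += 1
    out.sort(key=lambda r: r[0])
    return out


def write_tss_bed(
    tss: Sequence[tuple[GenomicInterval, str, float]], path: str | Path
) -> None:
    write_bed(path, [(iv, gene, f"{score:g}") for iv, gene, score in tss])


def _truth_tracks(spec: FixtureSpec) -> dict[tuple[str, str, str], list[tuple[GenomicInterval, int]]]:
    """Expected consensus tracks (level, label, class) -> [(interval, support)].

    Noiseless expectation: replicates/experiments agree exactly, so cell-line
    tracks are the planted intervals; tissue/global tracks keep elements
    planted in >=2 cell lines of the scope, with support = number of carrier
    cell lines in scope.
    """
    truth: dict[tuple[str, str, str], list[tuple[GenomicInterval, int]]] = {}
    cells = sorted(spec.cell_line_tissue)
    exp_support = spec.n_experiments if spec.n_experiments > 1 else 1

    for cell in cells:
        for cls in ("promoter", "enhancer", "active_enhancer"):
            if cls == "enhancer":
                ivs = [
                    el.interval
                    for el in spec.planted_elements
                    if cell in el.cell_lines
                    and el.element_class in ("enhancer", "active_enhancer")
                ]
                # emitted only when the cell line has H3K4me1 at all
                if not ivs:
                    continue
            else:
                ivs = [
                    el.interval
                    for el in spec.planted_elements
                    if cell in el.cell_lines and el.element_class == cls
                ]
                if not ivs:
                    continue
            truth[("cell_line", cell, cls)] = [
                (iv, exp_support) for iv in sorted(merge_intervals(ivs))
            ]

    scopes: list[tuple[str, str, list[str]]] = [("global", "global", cells)]
    for tissue in sorted(set(spec.cell_line_tissue.values())):
        scopes.append(
            ("tissue", tissue, [c for c in cells if spec.cell_line_tissue[c] == tissue])
        )
    for level, label, scope_cells in scopes:
        for cls in ("promoter", "enhancer", "active_enhancer"):
            rows: list[tuple[GenomicInterval, int]] = []
            for el in spec.planted_elements:
                el_cls = el.element_class
                matches = (
                    el_cls == cls
                    or (cls == "enhancer" and el_cls == "active_enhancer")
                )
                if not matches:
                    continue
                carriers = [c for c in scope_cells if c in el.cell_lines]
                if len(carriers) >= 2:
                    rows.append((el.interval, len(carriers)))
            if rows:
                rows.sort(key=lambda r: r[0])
                truth[(level, label, cls)] = rows
    return truth


def make_peaks(
    spec: FixtureSpec,
    outdir: str | Path,
    noise: PeakNoise = PeakNoise(),
) -> Path:
    """Write per-replicate peak files, a sample sheet and ground-truth BEDs.

    Returns the path of the sample sheet. Decoy peaks (if requested) land in
    experiment 1 only, so the >=2-experiment rule must remove them whenever
    more than one experiment exists. Ground truth goes to ``truth/`` next to
    the peak files, one BED per nonempty (level, label, class) track with
    columns chrom, start, end, element class, support count.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    fmt = spec.peak_format
    suffix = "narrowPeak" if fmt == "narrow" else "broadPeak"
    chrom_bound = dict(spec.chrom_lengths)

    sheet_rows: list[tuple[str, ...]] = []
    for cell in sorted(spec.cell_line_tissue):
        tissue = spec.cell_line_tissue[cell]
        by_marker: dict[str, list[GenomicInterval]] = {}
        for el in spec.planted_elements:
            if cell not in el.cell_lines:
                continue
            for marker in _MARKERS_BY_CLASS[el.element_class]:
                by_marker.setdefault(marker, []).append(el.interval)
        for marker in sorted(by_marker):
            ivs = sorted(merge_intervals(by_marker[marker]))
            # decoys are known-negative ground truth: keep them clear of
            # every planted element (and its TSS window) so the only reason
            # they can survive is a pipeline defect
            exclusion = [
                GenomicInterval(
                    el.interval.chrom,
                    max(0, el.interval.start - 1200),
                    el.interval.end + 1200,
                )
                for el in spec.planted_elements
            ]
            decoys: list[GenomicInterval] = []
            for _ in range(noise.n_decoys_per_track):
                for _attempt in range(100):
                    chrom = sorted(chrom_bound)[int(rng.integers(len(chrom_bound)))]
                    width = int(rng.integers(200, 400))
                    start = int(rng.integers(chrom_bound[chrom] - width))
                    cand = GenomicInterval(chrom, start, start + width)
                    if not any(cand.overlaps(x) for x in exclusion):
                        decoys.append(cand)
                        break
                else:
                    raise RuntimeError("no free space for decoy peak")
            for exp in range(1, spec.n_experiments + 1):
                for rep in range(1, spec.n_replicates + 1):
                    rows = []
                    for iv in ivs:
                        if noise.dropout and rng.random() < noise.dropout:
                            continue
                        s, e = iv.start, iv.end
                        if noise.jitter:
                            s += int(rng.integers(-noise.jitter, noise.jitter + 1))
                            e += int(rng.integers(-noise.jitter, noise.jitter + 1))
                            s = max(0, s)
                            e = min(chrom_bound[iv.chrom], max(s + 1, e))
                        rows.append(GenomicInterval(iv.chrom, s, e))
                    if exp == 1:
                        rows.extend(decoys)
                    rows.sort()
                    fname = f"{cell}_{marker}_exp{exp}_rep{rep}.{suffix}"
                    _write_peak_file(outdir / fname, rows, fmt)
                    sheet_rows.append(
                        (
                            fname,
                            marker,
                            fmt,
                            f"exp{exp}",
                            f"rep{rep}",
                            cell,
                            tissue,
                        )
                    )

    sheet_path = outdir / "samples.tsv"
    header = "path\tmarker\tpeak_format\texperiment_id\treplicate_id\tcell_line\ttissue\n"
    with open(sheet_path, "w", newline="\n") as fh:
        fh.write(header)
        for row in sheet_rows:
            fh.write("\t".join(row) + "\n")

    for (level, label, cls), rows in sorted(_truth_tracks(spec).items()):
        path = outdir / "truth" / f"{level}_{label}_{cls}_{fmt}.bed"
        write_bed(path, [(iv, cls, n) for iv, n in rows])
    return sheet_path


def _write_peak_file(
    path: Path, intervals: Sequence[GenomicInterval], fmt: str
) -> None:
    # signalValue 5, -log10(p) 5 (p=1e-5, passes the broad p<0.01 filter),
    # -log10(q) 5; narrowPeak adds a summit offset column
    with open(path, "w", newline="\n") as fh:
        for i, iv in enumerate(intervals):
            cols = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                f"peak{i}",
                "0",
                ".",
                "5",
                "5",
                "5",
            ]
            if fmt == "narrow":
                cols.append(str(len(iv) // 2))
            fh.write("\t".join(cols) + "\n")


def make_vcf(
    spec: FixtureSpec,
    genome: Mapping[str, str],
    planted_snps: Sequence[PlantedSNP],
    path: str | Path,
) -> Path:
    """Write a phased diploid VCF with each SNP on an exact haplotype count.

    The carrier haplotypes of each SNP are a seeded random subset of size
    ``round(hap_fraction * 2N)``; a fraction that rounds to zero is an error.
    INFO/AC and INFO/AF record the planted counts.
    """
    path = Path(path)
    n_haps = 2 * spec.n_individuals
    rng = np.random.default_rng(spec.seed + 2)
    records = []
    # motif-restoring SNPs from allele-restricted planted motifs
    all_snps = list(planted_snps)
    pfm_by_id = {p.motif_id: p for p in spec.pfms}
    for pm in spec.planted_motifs:
        if pm.allele_fraction is None:
            continue
        site = pfm_by_id[pm.pfm_id].consensus()
        if pm.strand == "-":
            site = reverse_complement(site)
        all_snps.append(
            PlantedSNP(
                chrom=pm.interval.chrom,
                pos=pm.interval.start,
                alt=site[0],
                hap_fraction=pm.allele_fraction,
            )
        )
    for snp in sorted(all_snps, key=lambda s: (s.chrom, s.pos)):
        ref_base = genome[snp.chrom][snp.pos]
        if ref_base == snp.alt:
            raise ValueError(f"ALT equals reference at {snp.chrom}:{snp.pos}")
        ac = int(round(snp.hap_fraction * n_haps))
        if ac == 0:
            raise ValueError(
                f"hap_fraction {snp.hap_fraction} rounds to 0 of {n_haps} haplotypes"
            )
        carriers = set(rng.choice(n_haps, size=ac, replace=False).tolist())
        gts = []
        for ind in range(spec.n_individuals):
            a = 1 if 2 * ind in carriers else 0
            b = 1 if 2 * ind + 1 in carriers else 0
            gts.append(f"{a}|{b}")
        records.append((snp.chrom, snp.pos, ref_base, snp.alt, ac, gts))

    samples = [f"S{i:04d}" for i in range(spec.n_individuals)]
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(spec.chrom_lengths):
            fh.write(
                f"##contig=<ID={chrom},length={spec.chrom_lengths[chrom]}>\n"
            )
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, ac, gts in records:
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"AC={ac};AF={ac / n_haps:.6g}\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Desk-scale default study: 2 chromosomes x 500 kb, 3 cell lines in 2
    tissues, 2 experiments x 2 replicates, 5 sharp 10-mer PFMs, 50 diploid
    individuals."""
    chrom_lengths = {"chr1": 500_000, "chr2": 500_000}
    cell_line_tissue = {"cellA": "lung", "cellB": "lung", "cellC": "liver"}
    rng = np.random.default_rng(seed + 3)
    pfms = tuple(
        make_sharp_pfm(
            f"MOTIF{i}", "".join(BASES[b] for b in rng.choice(4, size=10))
        )
        for i in range(5)
    )
    elements = []
    # promoters / enhancers / active enhancers spaced 5 kb apart on chr1
    layout = [
        ("promoter", "chr1", 10_000, ("cellA", "cellB", "cellC")),
        ("promoter", "chr1", 15_000, ("cellA", "cellB")),
        ("promoter", "chr1", 20_000, ("cellA",)),
        ("enhancer", "chr1", 30_000, ("cellA", "cellB")),
        ("enhancer", "chr1", 35_000, ("cellB", "cellC")),
        ("active_enhancer", "chr1", 45_000, ("cellA", "cellB", "cellC")),
        ("active_enhancer", "chr2", 10_000, ("cellA", "cellB")),
        ("enhancer", "chr2", 20_000, ("cellC",)),
    ]
    for cls, chrom, start, cells in layout:
        elements.append(
            PlantedElement(cls, GenomicInterval(chrom, start, start + 600), cells)
        )
    motifs = (
        PlantedMotif("MOTIF0", GenomicInterval("chr1", 45_200, 45_210), "+"),
        PlantedMotif(
            "MOTIF1", GenomicInterval("chr1", 10_100, 10_110), "+", allele_fraction=0.5
        ),
    )
    return FixtureSpec(
        chrom_lengths=chrom_lengths,
        cell_line_tissue=cell_line_tissue,
        planted_elements=tuple(elements),
        planted_motifs=motifs,
        pfms=pfms,
        n_individuals=50,
        seed=seed,
    )
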