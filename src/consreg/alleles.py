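"""Haplotype-resolved CRE alleles and allele-aware TBA enrichment.

Each phased diploid sample contributes two haplotypes. A CRE *allele* is the
full haplotype sequence of the CRE (multi-SNP haplotypes form combined
alleles), obtained by substituting each haplotype's phased SNP alleles into
the reference sequence. Alleles are grouped by identity; the frequency
denominator is the haplotype count 2N. Only common alleles — frequency
strictly above the threshold (default 1%) — are retained, and the fraction
of common alleles whose normalized TBA is significant quantifies how broadly
the population supports a TF enrichment.

Only SNPs are substituted; indels and other variant classes are skipped and
counted. Because alleles differ from the reference by substitutions only,
all alleles share the reference length L and the same PFM-specific reference
distribution applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .pfm import PFM, BackgroundModel
from .tba import ReferenceDistribution, significance, tba_normalized

__all__ = ["AlleleSet", "AllelicEnrichment", "enumerate_alleles", "allelic_enrichment"]


@dataclass(frozen=True)
class Allele:
    sequence: str
    frequency: float
    n_haplotypes: int


@dataclass(frozen=True)
class AlleleSet:
    """Distinct haplotype sequences of one CRE with population frequencies."""

    cre_id: str
    alleles: tuple[Allele, ...]
    total_haplotypes: int
    n_skipped_variants: int = 0


@dataclass(frozen=True)
class AllelicEnrichment:
    """Fraction of a CRE's common alleles with significant TBA for one PFM."""

    cre_id: str
    pfm_id: str
    fraction_supporting: float
    cutoff: float
    n_common_alleles: int


def _is_snp(ref: str, alts: Sequence[str]) -> bool:
    return len(ref) == 1 and all(a is not None and len(a) == 1 for a in alts)


def enumerate_alleles(
    cre,
    genome: Mapping[str, str],
    vcf_path: str | Path,
    common_af_threshold: float = 0.01,
    on_unphased: str = "error",
) -> AlleleSet:
    """Enumerate the common haplotype alleles of a CRE from a phased VCF.

    Builds each haplotype's CRE sequence by substituting its phased SNP
    alleles into the reference, groups identical sequences, and retains
    alleles with frequency strictly above ``common_af_threshold``.
    Multi-allelic SNPs are handled per haplotype; indels/SVs are skipped and
    counted. Unphased genotypes raise by default (``on_unphased="skip"``
    drops the record with a warning).
    """
    import pysam

    iv = cre.interval if hasattr(cre, "interval") else cre
    ref_seq = str(genome[iv.chrom])[iv.start : iv.end].upper()
    cre_id = f"{iv.chrom}:{iv.start}-{iv.end}"

    n_skipped = 0
    substitutions: list[tuple[int, list[str]]] = []  # (offset, per-hap base)
    n_haps = None
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:  # sequential scan; inputs are desk-scale
            if rec.chrom != iv.chrom:
                continue
            pos0 = rec.pos - 1  # VCF is 1-based
            if not (iv.start <= pos0 < iv.end):
                continue
            alts = rec.alts or ()
            if not _is_snp(rec.ref, alts):
                n_skipped += 1
                continue
            alleles_here = (rec.ref,) + tuple(alts)
            hap_bases: list[str] = []
            ok = True
            for sample in rec.samples.values():
                if not sample.phased:
                    if on_unphased == "skip":
                        ok = False
                        break
                    raise ValueError(
                        f"unphased genotype at {rec.chrom}:{rec.pos} "
                        f"(sample {sample.name})"
                    )
                for gt in sample["GT"]:
                    if gt is None:
                        hap_bases.append(rec.ref)  # missing -> reference
                    else:
                        hap_bases.append(alleles_here[gt])
            if not ok:
                warnings.warn(f"skipping unphased record at {rec.chrom}:{rec.pos}")
                n_skipped += 1
                continue
            if n_haps is None:
                n_haps = len(hap_bases)
            elif n_haps != len(hap_bases):
                raise ValueError("inconsistent haplotype count across records")
            substitutions.append((pos0 - iv.start, hap_bases))

    if n_haps is None:
        # no usable variants: the reference is the only observed allele
        return AlleleSet(
            cre_id=cre_id,
            alleles=(Allele(ref_seq, 1.0, 0),),
            total_haplotypes=0,
            n_skipped_variants=n_skipped,
        )

    haplotypes = [list(ref_seq) for _ in range(n_haps)]
    for offset, hap_bases in substitutions:
        for h, base in enumerate(hap_bases):
            haplotypes[h][offset] = base.upper()

    counts: dict[str, int] = {}
    for h in haplotypes:
        s = "".join(h)
        counts[s] = counts.get(s, 0) + 1

    alleles = [
        Allele(seq, n / n_haps, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    common = tuple(a for a in alleles if a.frequency > common_af_threshold)
    return AlleleSet(
        cre_id=cre_id,
        alleles=common,
        total_haplotypes=n_haps,
        n_skipped_variants=n_skipped,
    )


def allelic_enrichment(
    allele_set: AlleleSet,
    pfm: PFM,
    ref: ReferenceDistribution,
    bg: BackgroundModel | None = None,
    cutoff: float = 1e-05,
) -> AllelicEnrichment:
    """Fraction of common alleles whose normalized TBA is significant.

    All alleles share the reference length (SNP substitutions only), so each
    is scored against the same PFM-specific reference distribution; an
    allele supports the enrichment when its significance bin is at least as
    stringent as ``cutoff``.
    """
    if not allele_set.alleles:
        raise ValueError(f"{allele_set.cre_id}: empty allele set")
    bg = bg or BackgroundModel()
    n_sig = 0
    for allele in allele_set.alleles:
        score = tba_normalized(allele.sequence, pfm, bg)
        sig = significance(score, ref)
        if sig != "ns" and sig <= cutoff:
            n_sig += 1
    return AllelicEnrichment(
        cre_id=allele_set.cre_id,
        pfm_id=pfm.motif_id,
        fraction_supporting=n_sig / len(allele_set.alleles),
        cutoff=cutoff,
        n_common_alleles=len(allele_set.alleles),
    )
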