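"""Total binding affinity (TBA) scoring with empirical significance.

The TBA of a sequence r (length L) for a motif w (length l) is

    a_rw = sum_{i=1..L-l+1} max( prod_j P(w_j, r_{i+j-1}) / P(b, r_{i+j-1}),
                                 prod_j P(w_{l-j+1}, r'_{i+j-1}) / P(b, r'_{i+j-1}) )

i.e. every window contributes the better of its two strand affinities,
expressed as a probability ratio against a background model b, with no site
cutoff — high- and low-affinity sites all contribute. TBA grows linearly
with L, so scores are compared after dividing by the window count L - l + 1;
significance comes from a PFM-specific empirical reference distribution of
normalized TBA over random genomic regions.

Numerics: each window's ratio product is accumulated in log space. The
per-window log-sum uses a symmetric pairwise fold (addends are paired
first-with-last), which makes the window score bit-identical under reversal
of the addend order; the sum over windows uses ``math.fsum`` (exactly
rounded, order-independent). Together these give exact strand symmetry:
``tba(s) == tba(revcomp(s))`` to the last bit. Unknown bases (N) contribute
a neutral ratio of 1 on both strands.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .pfm import PFM, BackgroundModel

__all__ = [
    "TBAResult",
    "ReferenceDistribution",
    "DEFAULT_CUTOFFS",
    "tba",
    "normalize_tba",
    "tba_normalized",
    "build_reference_distribution",
    "significance",
    "annotate_cres_with_tba",
]

#: p-value cutoffs at which significance bins are pre-computed, loosest first.
DEFAULT_CUTOFFS = (5e-02, 1e-02, 1e-03, 1e-04, 1e-05)

# sequence codes: A=0 C=1 G=2 T=3 N=4; complement swaps A<->T, C<->G, N->N
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = np.array([3, 2, 1, 0, 4])

_ENCODE_LUT = np.full(128, -1, dtype=np.int8)
for _b, _c in _CODE.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGTN string (case-insensitive) to integer codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if np.any(codes < 0):
        bad = chr(raw[int(np.argmax(codes < 0))])
        raise ValueError(f"non-ACGTN character {bad!r} in sequence")
    return codes.astype(np.intp)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


@dataclass(frozen=True)
class TBAResult:
    """Raw and length-normalized TBA of one sequence against one PFM."""

    raw_tba: float
    norm_tba: float
    seq_length: int
    pfm_id: str
    p_value_bin: float | str = "ns"


def _log_ratio_matrices(pfm: PFM, bg: BackgroundModel) -> tuple[np.ndarray, np.ndarray]:
    """(l x 5) log-ratio lookup tables for plus strand and reverse complement.

    Column 4 (N) is 0: an unknown base contributes ratio 1 on both strands.
    """
    lr = np.zeros((pfm.length, 5))
    lr[:, :4] = np.log(pfm.matrix) - np.log(bg.probs)[None, :]
    # reverse strand: position j reads motif position l-1-j at the complement
    lr_rc = lr[::-1][:, _COMP]
    return lr, lr_rc


def _symmetric_fold(addends: np.ndarray) -> np.ndarray:
    """Sum axis 1 by pairing column k with column -1-k, repeatedly.

    Float addition is commutative, so the result is bit-identical when the
    columns are given in reversed order — the property that makes TBA exactly
    strand-symmetric.
    """
    x = addends
    while x.shape[1] > 1:
        m = x.shape[1] // 2
        paired = x[:, :m] + x[:, ::-1][:, :m]
        if x.shape[1] % 2:
            x = np.concatenate([paired, x[:, m : m + 1]], axis=1)
        else:
            x = paired
    return x[:, 0]


def window_log_scores(codes: np.ndarray, pfm: PFM, bg: BackgroundModel) -> np.ndarray:
    """Best-of-two-strands log affinity ratio for each window of the sequence."""
    l = pfm.length
    if codes.shape[0] < l:
        raise ValueError(
            f"sequence length {codes.shape[0]} shorter than motif length {l}"
        )
    lr, lr_rc = _log_ratio_matrices(pfm, bg)
    windows = np.lib.stride_tricks.sliding_window_view(codes, l)
    j = np.arange(l)
    fwd = _symmetric_fold(lr[j, windows])
    rev = _symmetric_fold(lr_rc[j, windows])
    return np.maximum(fwd, rev)


def tba(seq: str, pfm: PFM, bg: BackgroundModel | None = None) -> float:
    """Raw TBA a_rw of a sequence for a PFM (natural scale, > 0)."""
    bg = bg or BackgroundModel()
    scores = window_log_scores(encode_sequence(seq), pfm, bg)
    return math.fsum(np.exp(scores))


def normalize_tba(raw: float, L: int, l: int) -> float:
    """Mean per-window affinity: raw / (L - l + 1)."""
    if L < l:
        raise ValueError(f"sequence length {L} < motif length {l}")
    return raw / (L - l + 1)


def tba_normalized(seq: str, pfm: PFM, bg: BackgroundModel | None = None) -> float:
    return normalize_tba(tba(seq, pfm, bg), len(seq), pfm.length)


@dataclass(frozen=True)
class ReferenceDistribution:
    """PFM-specific null distribution of normalized TBA over random regions.

    ``thresholds[alpha]`` is the upper order statistic x_(k) with
    k = ceil((n+1)(1-alpha)), so that a fresh null region exceeds it with
    probability <= alpha ((k+1)/(n+1) plotting convention). Cutoffs whose k
    exceeds the sample size get an infinite threshold: unreachable at that
    reference size.
    """

    pfm_id: str
    sample: np.ndarray  # sorted ascending
    thresholds: Mapping[float, float]
    n_regions: int
    rng_seed: int

    def threshold(self, alpha: float) -> float:
        return self.thresholds[alpha]


def _quantile_thresholds(
    sorted_sample: np.ndarray, cutoffs: Sequence[float]
) -> dict[float, float]:
    n = sorted_sample.shape[0]
    out: dict[float, float] = {}
    for alpha in cutoffs:
        k = math.ceil((n + 1) * (1.0 - alpha))
        out[alpha] = float(sorted_sample[k - 1]) if k <= n else math.inf
    return out


def build_reference_distribution(
    pfm: PFM,
    genome: Mapping[str, str],
    n_regions: int,
    length_sampler: Callable[[np.random.Generator], int] | Sequence[int],
    bg: BackgroundModel | None = None,
    seed: int = 0,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    max_n_fraction: float = 0.5,
    max_retries: int = 100,
) -> ReferenceDistribution:
    """Sample random genomic regions and build the normalized-TBA null.

    Regions are placed uniformly over genome positions (chromosomes weighted
    by length) with lengths drawn from ``length_sampler`` — either a callable
    on the RNG or a pool of lengths to resample from (e.g. the CRE length
    distribution). Regions that are mostly assembly gap (N fraction above
    ``max_n_fraction``) are resampled up to ``max_retries`` times.
    Deterministic given ``seed``.
    """
    bg = bg or BackgroundModel()
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    seqs = {c: str(genome[c]) for c in chroms}
    lengths = np.array([len(seqs[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    if callable(length_sampler):
        draw_length = length_sampler
    else:
        pool = np.asarray(list(length_sampler), dtype=int)
        if pool.size == 0:
            raise ValueError("empty length pool")
        draw_length = lambda r: int(pool[r.integers(pool.size)])

    values = np.empty(n_regions)
    for i in range(n_regions):
        for attempt in range(max_retries):
            region_len = max(draw_length(rng), pfm.length)
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            max_start = len(seqs[chrom]) - region_len
            if max_start < 0:
                continue
            start = int(rng.integers(max_start + 1))
            seq = seqs[chrom][start : start + region_len]
            n_frac = (seq.count("N") + seq.count("n")) / len(seq)
            if n_frac <= max_n_fraction:
                values[i] = tba_normalized(seq, pfm, bg)
                break
        else:
            raise RuntimeError(
                f"could not sample a usable region after {max_retries} tries"
            )
    values.sort()
    return ReferenceDistribution(
        pfm_id=pfm.motif_id,
        sample=values,
        thresholds=_quantile_thresholds(values, cutoffs),
        n_regions=n_regions,
        rng_seed=seed,
    )


def significance(
    norm_tba: float,
    ref: ReferenceDistribution,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    pfm_id: str | None = None,
) -> float | str:
    """Smallest cutoff whose threshold is <= the score, or ``"ns"``.

    The boundary is inclusive: a score exactly at threshold(alpha) is
    significant at alpha.
    """
    if pfm_id is not None and pfm_id != ref.pfm_id:
        raise ValueError(
            f"reference distribution is for {ref.pfm_id}, not {pfm_id}"
        )
    best: float | str = "ns"
    for alpha in sorted(cutoffs, reverse=True):  # loosest -> tightest
        if norm_tba >= ref.thresholds[alpha]:
            best = alpha
    return best


def empirical_pvalue(norm_tba: float, ref: ReferenceDistribution) -> float:
    """(k+1)/(n+1) upper empirical p-value of a score against the reference."""
    n = ref.sample.shape[0]
    k = n - bisect.bisect_left(ref.sample.tolist(), norm_tba)
    return (k + 1) / (n + 1)


def annotate_cres_with_tba(
    cres: Sequence,
    genome: Mapping[str, str],
    pfms: Sequence[PFM],
    refs: Mapping[str, ReferenceDistribution],
    bg: BackgroundModel | None = None,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    active_cutoff: float = 1e-05,
    pfm_min_sequences: int = 50,
    pfm_max_cre_fraction: float = 0.50,
):
    """Score every (CRE, PFM) pair and bin its significance.

    Quality filtering drops PFMs built from fewer than ``pfm_min_sequences``
    binding sites, and PFMs enriched (at ``active_cutoff``) in more than
    ``pfm_max_cre_fraction`` of the CRE set — recurrently-enriched
    low-information motifs carry no regional signal. Returns a pandas
    DataFrame with one row per retained (CRE, PFM) pair.
    """
    import pandas as pd

    bg = bg or BackgroundModel()
    kept_pfms = [p for p in pfms if p.n_sequences >= pfm_min_sequences]

    out_of_bounds = []
    for cre in cres:
        iv = cre.interval
        if iv.chrom not in genome or iv.end > len(genome[iv.chrom]):
            out_of_bounds.append(f"{iv.chrom}:{iv.start}-{iv.end}")
    if out_of_bounds:
        raise ValueError(
            "CRE(s) outside genome bounds: " + ", ".join(out_of_bounds)
        )

    rows = []
    enriched_frac: dict[str, float] = {}
    for pfm in kept_pfms:
        ref = refs[pfm.motif_id]
        n_enriched = 0
        pfm_rows = []
        for cre in cres:
            iv = cre.interval
            seq = str(genome[iv.chrom])[iv.start : iv.end]
            score = tba_normalized(seq, pfm, bg)
            sig = significance(score, ref, cutoffs)
            if sig != "ns" and sig <= active_cutoff:
                n_enriched += 1
            pfm_rows.append(
                {
                    "cre_id": f"{iv.chrom}:{iv.start}-{iv.end}",
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "element_class": cre.element_class,
                    "pfm_id": pfm.motif_id,
                    "norm_tba": score,
                    "p_value_bin": sig,
                }
            )
        frac = n_enriched / len(cres) if cres else 0.0
        enriched_frac[pfm.motif_id] = frac
        if frac <= pfm_max_cre_fraction:
            rows.extend(pfm_rows)

    df = pd.DataFrame(
        rows,
        columns=[
            "cre_id",
            "chrom",
            "start",
            "end",
            "element_class",
            "pfm_id",
            "norm_tba",
            "p_value_bin",
        ],
    )
    df.attrs["enriched_fraction"] = enriched_frac
    return df
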