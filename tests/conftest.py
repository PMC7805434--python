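"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own algorithms: interval
operations are checked against explicit per-base sets, and TBA against a
direct window-by-window product evaluation with no log space.
"""

from __future__ import annotations

import numpy as np
import pytest

from consreg.intervals import GenomicInterval
from consreg.pfm import BASES, PFM, BackgroundModel

# ---------------------------------------------------------------- intervals


def base_set(intervals) -> set[tuple[str, int]]:
    """Explicit set of (chrom, position) bases covered by intervals."""
    return {
        (iv.chrom, pos) for iv in intervals for pos in range(iv.start, iv.end)
    }


def assert_sorted_disjoint(intervals) -> None:
    for a, b in zip(intervals, intervals[1:]):
        assert (a.chrom, a.start, a.end) < (b.chrom, b.start, b.end)
        if a.chrom == b.chrom:
            assert a.end < b.start or (a.end <= b.start)


def random_track(rng: np.random.Generator, n_max: int = 8, coord_max: int = 10_000):
    """A random small interval list, possibly overlapping, 1-2 chromosomes."""
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        chrom = f"chr{int(rng.integers(1, 3))}"
        start = int(rng.integers(0, coord_max - 1))
        end = int(rng.integers(start + 1, min(start + 500, coord_max)))
        out.append(GenomicInterval(chrom, start, end))
    return out


# ---------------------------------------------------------------- TBA oracle

_COMP_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def tba_oracle(seq: str, pfm: PFM, bg: BackgroundModel | None = None) -> float:
    """Direct exhaustive-window product evaluation of total binding affinity."""
    bg = bg or BackgroundModel()
    seq = seq.upper()
    l = pfm.length
    bgp = {b: bg.probs[i] for i, b in enumerate(BASES)}

    def ratio(j: int, base: str) -> float:
        if base == "N":
            return 1.0
        return pfm.matrix[j, BASES.index(base)] / bgp[base]

    total = 0.0
    for i in range(len(seq) - l + 1):
        fwd = 1.0
        rev = 1.0
        for j in range(l):
            base = seq[i + j]
            fwd *= ratio(j, base)
            rev *= ratio(l - 1 - j, _COMP_BASE[base])
        total += max(fwd, rev)
    return total


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_pfm(rng: np.random.Generator, max_len: int = 12) -> PFM:
    l = int(rng.integers(1, max_len + 1))
    counts = rng.integers(0, 50, size=(l, 4)).astype(float)
    from consreg.pfm import pfm_from_counts

    return pfm_from_counts(f"rand{l}", counts, pseudocount=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
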