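"""Position frequency matrices and background nucleotide models.

JASPAR and TRANSFAC text dialects are parsed via :mod:`Bio.motifs`; count
matrices are converted to position probability matrices here, with a
pseudocount added to every cell before row normalization so that every entry
is strictly positive (the affinity ratio product requires it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

__all__ = ["PFM", "BackgroundModel", "parse_pfm", "uniform_background"]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PFM:
    """A TF binding motif as an l x 4 position probability matrix.

    ``matrix[j, n]`` is P(base n at motif position j); rows sum to 1 and,
    after pseudocount application, every entry is strictly positive.
    ``n_sequences`` is the number of binding sites the matrix was built from
    (used for quality filtering).
    """

    motif_id: str
    matrix: np.ndarray
    n_sequences: int = 0
    source_db: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PFM matrix must be l x 4 with l >= 1")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PFM {self.motif_id}: rows must sum to 1")
        if np.any(m <= 0):
            raise ValueError(
                f"PFM {self.motif_id}: zero/negative probabilities "
                "(apply a pseudocount)"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def consensus(self) -> str:
        """Most-probable base at each position (ties -> first in ACGT)."""
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    def information_content(self) -> float:
        """Total information content in bits against a uniform background."""
        m = self.matrix
        return float(np.sum(m * np.log2(m / 0.25)))


@dataclass(frozen=True)
class BackgroundModel:
    """Background nucleotide probabilities P(b, n) for n in ACGT."""

    probs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("background must have 4 probabilities (ACGT)")
        if not np.isclose(p.sum(), 1.0, atol=1e-9) or np.any(p <= 0):
            raise ValueError("background probabilities must be positive, sum 1")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_sequence(cls, seq: str, pseudocount: float = 1.0) -> "BackgroundModel":
        counts = np.array(
            [seq.count(b) + seq.count(b.lower()) for b in BASES], dtype=float
        )
        counts += pseudocount
        return cls(counts / counts.sum())


def uniform_background() -> BackgroundModel:
    return BackgroundModel()


def _counts_to_pfm(
    motif_id: str,
    counts: np.ndarray,
    pseudocount: float,
    source_db: str,
) -> PFM:
    counts = np.asarray(counts, dtype=float)
    row_sums = counts.sum(axis=1)
    if pseudocount <= 0 and np.any(np.all(counts == 0, axis=1)):
        raise ValueError(
            f"motif {motif_id}: row of zeros requires a positive pseudocount"
        )
    n_sequences = int(round(row_sums[0]))
    probs = (counts + pseudocount) / (row_sums + 4.0 * pseudocount)[:, None]
    return PFM(
        motif_id=motif_id,
        matrix=probs,
        n_sequences=n_sequences,
        source_db=source_db,
    )


def parse_pfm(
    path: str | Path,
    dialect: str,
    pseudocount: float = 1.0,
    source_db: str = "",
) -> list[PFM]:
    """Parse a JASPAR or TRANSFAC motif file into probability PFMs.

    Count matrices get ``pseudocount`` added to every cell before row
    normalization. A matrix whose rows already sum to 1 passes through
    unchanged when ``pseudocount`` is 0. ``n_sequences`` is the total count
    of the first matrix row before normalization, rounded.
    """
    if dialect not in ("jaspar", "transfac"):
        raise ValueError(f"unknown PFM dialect {dialect!r}")
    text = Path(path).read_text()
    if not text.strip():
        warnings.warn(f"empty PFM file {path}")
        return []
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, dialect)
        out: list[PFM] = []
        for m in parsed:
            counts = np.array(
                [[m.counts[b][j] for b in BASES] for j in range(m.length)],
                dtype=float,
            )
            motif_id = m.matrix_id if getattr(m, "matrix_id", None) else m.name
            out.append(
                _counts_to_pfm(
                    motif_id or "motif",
                    counts,
                    pseudocount,
                    source_db or dialect,
                )
            )
    return out


def pfm_from_counts(
    motif_id: str,
    counts: np.ndarray,
    pseudocount: float = 1.0,
    source_db: str = "",
) -> PFM:
    """Build a PFM directly from an l x 4 count matrix (ACGT column order)."""
    return _counts_to_pfm(motif_id, np.asarray(counts, float), pseudocount, source_db)
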