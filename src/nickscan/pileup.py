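"""Strand-specific per-position 5' end count profiles ("5' counts").

For every genomic position and each strand, the 5' count is the number of
read 5' ends mapping there: a forward (Watson) read contributes at its
leftmost aligned coordinate, a reverse (Crick) read at its rightmost aligned
coordinate (its biological 5' terminus).  Statistics downstream are computed
on the raw integer counts; counts-per-million normalization exists for track
export only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .reference import Genome
from .sonication import AlignedRead, ReadSet

__all__ = [
    "FivePrimeProfile",
    "filter_unique_mappers",
    "compute_five_prime_counts",
    "normalize_profile",
]


@dataclass
class FivePrimeProfile:
    """Per-strand 5' end counts over one chromosome.

    ``watson`` / ``crick`` are vectors of length equal to the chromosome;
    ``library_size`` is the number of reads counted.  When ``normalized`` is
    False the vectors are raw integers and sum to ``library_size``.
    """

    chrom: str
    watson: np.ndarray
    crick: np.ndarray
    library_size: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.watson = np.asarray(self.watson)
        self.crick = np.asarray(self.crick)
        if self.watson.shape != self.crick.shape or self.watson.ndim != 1:
            raise ValueError("watson and crick must be 1-D vectors of equal length")
        if (self.watson < 0).any() or (self.crick < 0).any():
            raise ValueError("5' counts cannot be negative")

    def __len__(self) -> int:
        return len(self.watson)

    def strand(self, strand: str) -> np.ndarray:
        if strand == "watson" or strand == "+":
            return self.watson
        if strand == "crick" or strand == "-":
            return self.crick
        raise ValueError(f"strand must be 'watson' or 'crick', got {strand!r}")


def _as_readset(reads) -> ReadSet:
    if isinstance(reads, ReadSet):
        return reads
    return ReadSet.from_reads(reads)


def filter_unique_mappers(reads, min_mapq: int = 10):
    """Drop multi-mapper reads (MAPQ below *min_mapq*), preserving order.

    The default threshold of 10 is the conventional samtools ``-q 10``
    unique-mapper cut.  Accepts a :class:`ReadSet` or a list of
    :class:`AlignedRead`; returns the same kind.
    """
    if isinstance(reads, ReadSet):
        return reads[reads.mapq >= min_mapq]
    return [r for r in reads if r.mapq >= min_mapq]


def compute_five_prime_counts(
    reads,
    genome: Genome | int,
    min_mapq: int | None = None,
) -> FivePrimeProfile:
    """Tally read 5' ends per position and strand.

    *genome* may be a :class:`Genome` or simply the chromosome length.
    With *min_mapq* set, multi-mappers are removed first (the removed reads
    do not count towards ``library_size``).
    """
    rs = _as_readset(reads)
    if min_mapq is not None:
        rs = filter_unique_mappers(rs, min_mapq)
    length = len(genome) if not isinstance(genome, int) else genome
    chrom = genome.name if isinstance(genome, Genome) else rs.chrom

    if len(rs) and (rs.start.min() < 0 or rs.end.max() > length):
        bad = int(np.flatnonzero((rs.start < 0) | (rs.end > length))[0])
        raise ValueError(f"read {rs[bad]} lies outside the genome (length {length})")

    fwd = rs.start[~rs.is_reverse]
    rev = rs.end[rs.is_reverse] - 1  # rightmost aligned base = 5' end
    watson = np.bincount(fwd, minlength=length).astype(np.int64)
    crick = np.bincount(rev, minlength=length).astype(np.int64)
    return FivePrimeProfile(chrom, watson, crick, library_size=len(rs))


def normalize_profile(profile: FivePrimeProfile) -> FivePrimeProfile:
    """Scale counts to counts-per-million of the library. Not idempotent:
    normalizing an already-normalized profile is an error."""
    if profile.normalized:
        raise ValueError("profile is already normalized")
    if profile.library_size <= 0:
        raise ValueError("cannot normalize an empty library")
    scale = 1e6 / profile.library_size
    return replace(
        profile,
        watson=profile.watson * scale,
        crick=profile.crick * scale,
        normalized=True,
    )
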