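"""Binned RPKM coverage tracks and IP/WCE enrichment ratios.

Standard ChIP-style display tracks: reads are assigned to the bin holding
their 5' end, counts are normalized to reads per kilobase per million mapped
reads (RPKM) with a fixed bin size (1 kb by default in the pipeline), and
enrichment is the element-wise ratio of an immunoprecipitate (IP) track to
its whole-cell-extract (WCE) input, stabilized with a pseudocount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .reference import Genome
from .sonication import ReadSet

__all__ = ["BinnedTrack", "rpkm_track", "enrichment_track"]


@dataclass
class BinnedTrack:
    chrom: str
    bin_size: int
    values: np.ndarray
    kind: str  # "rpkm" or "enrichment_ratio"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("track values cannot be negative")
        if self.kind not in ("rpkm", "enrichment_ratio"):
            raise ValueError(f"unknown track kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.values)


def rpkm_track(reads, genome: Genome | int, bin_size: int = 1000) -> BinnedTrack:
    """Per-bin read-start counts scaled to RPKM.

    Each read counts once, in the bin containing its 5' end; the value is
    ``count * 1e9 / (library_size * bin_size)``.
    """
    if bin_size < 10:
        raise ValueError("bin_size must be >= 10")
    rs = reads if isinstance(reads, ReadSet) else ReadSet.from_reads(reads)
    if len(rs) == 0:
        raise ValueError("cannot build an RPKM track from an empty library")
    length = len(genome) if isinstance(genome, Genome) else int(genome)
    chrom = genome.name if isinstance(genome, Genome) else rs.chrom
    n_bins = math.ceil(length / bin_size)
    five = np.where(rs.is_reverse, rs.end - 1, rs.start)
    counts = np.bincount(five // bin_size, minlength=n_bins).astype(float)
    values = counts * 1e9 / (len(rs) * bin_size)
    return BinnedTrack(chrom, bin_size, values, kind="rpkm")


def enrichment_track(ip: BinnedTrack, wce: BinnedTrack, pseudocount: float = 0.5) -> BinnedTrack:
    """Element-wise (IP + pseudocount) / (WCE + pseudocount) ratio track."""
    if ip.chrom != wce.chrom or ip.bin_size != wce.bin_size or len(ip) != len(wce):
        raise ValueError("IP and WCE tracks must share chromosome, bin size and shape")
    values = (ip.values + pseudocount) / (wce.values + pseudocount)
    return BinnedTrack(ip.chrom, ip.bin_size, values, kind="enrichment_ratio")
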