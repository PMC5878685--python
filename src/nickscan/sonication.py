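"""Sonication / end-blunting library simulator.

Models the physics behind nick detection: chromatin from a cell population
is sheared by sonication, fragment ends are blunted so that every fragment's
first 5' nucleotide is conserved, and single-end reads are sequenced from
those 5' ends.  A chromatid carrying a persistent single-strand break always
exposes a 5' end at the nick coordinate on the nicked strand, and the intact
strand opposite the nick is mechanically weakened over a short window and
preferentially breaks inside it — one position per molecule, drawn uniformly
(left of, across, or right of the nick).

Random double-strand sonication breaks are drawn as a Poisson process along
each molecule with rate ``1/mean_fragment_len``, giving approximately
exponential fragment lengths.  Each strand is then fragmented by the union
of the shared sonication cuts and its strand-specific breaks, and every
internal 5' end yields one read (``read_length`` nt, truncated at the
fragment's other end).  Molecule-terminal ends (coordinates 0 and L) are not
sequenced: they are artifacts of simulating a whole reference as a single
molecule, with no analogue at an interior locus of a real chromosome.

No aligner is run; reads carry their true coordinates, and mapping quality
is rule-based: a read whose interval lies inside a repeated block of the
genome is a multi-mapper (MAPQ 0), everything else maps uniquely (MAPQ 60).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .reference import Genome

__all__ = ["AlignedRead", "ReadSet", "SonicationParams", "simulate_library"]

UNIQUE_MAPQ = 60


class AlignedRead(NamedTuple):
    """One aligned single-end read (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' = forward/Watson, '-' = reverse/Crick
    mapq: int


@dataclass(frozen=True)
class SonicationParams:
    """Physical parameters of one simulated library.

    ``imprint_fraction`` is the fraction of molecules (chromatids) carrying
    the nick; ``weakened_window`` the width in nt of the preferential
    breakage zone on the strand opposite the nick, centered on it;
    ``opposite_break_prob`` the probability that a nicked molecule's intact
    strand breaks inside that zone.
    """

    n_molecules: int = 200_000
    imprint_fraction: float = 0.3
    mean_fragment_len: float = 300.0
    weakened_window: int = 20
    opposite_break_prob: float = 0.8
    read_length: int = 130
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.imprint_fraction <= 1.0:
            raise ValueError("imprint_fraction must be in [0, 1]")
        if self.weakened_window < 1:
            raise ValueError("weakened_window must be >= 1")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.mean_fragment_len <= self.read_length:
            raise ValueError("mean_fragment_len must exceed read_length")
        if not 0.0 <= self.opposite_break_prob <= 1.0:
            raise ValueError("opposite_break_prob must be in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


class ReadSet(Sequence):
    """Columnar container of aligned reads on one reference sequence.

    Behaves as a sequence of :class:`AlignedRead` while storing coordinates
    as numpy arrays, which keeps multi-million-read libraries cheap to
    filter and pile up.
    """

    __slots__ = ("chrom", "start", "end", "is_reverse", "mapq")

    def __init__(
        self,
        chrom: str,
        start: np.ndarray,
        end: np.ndarray,
        is_reverse: np.ndarray,
        mapq: np.ndarray,
    ) -> None:
        self.chrom = chrom
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.is_reverse = np.asarray(is_reverse, dtype=bool)
        self.mapq = np.asarray(mapq, dtype=np.int64)
        n = len(self.start)
        if not (len(self.end) == len(self.is_reverse) == len(self.mapq) == n):
            raise ValueError("column lengths differ")
        if n and (self.start >= self.end).any():
            raise ValueError("all reads must satisfy start < end")

    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead]) -> "ReadSet":
        reads = list(reads)
        chrom = reads[0].chrom if reads else "chr"
        if any(r.chrom != chrom for r in reads):
            raise ValueError("all reads must share one chromosome")
        return cls(
            chrom,
            np.array([r.start for r in reads], dtype=np.int64),
            np.array([r.end for r in reads], dtype=np.int64),
            np.array([r.strand == "-" for r in reads], dtype=bool),
            np.array([r.mapq for r in reads], dtype=np.int64),
        )

    def __len__(self) -> int:
        return len(self.start)

    def __getitem__(self, i):
        if isinstance(i, slice) or isinstance(i, np.ndarray):
            return ReadSet(self.chrom, self.start[i], self.end[i], self.is_reverse[i], self.mapq[i])
        return AlignedRead(
            self.chrom,
            int(self.start[i]),
            int(self.end[i]),
            "-" if self.is_reverse[i] else "+",
            int(self.mapq[i]),
        )

    def sorted_by_coordinate(self) -> "ReadSet":
        order = np.argsort(self.start, kind="stable")
        return self[order]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ReadSet {self.chrom}: {len(self)} reads>"


def _strand_breaks_to_reads(
    mol: np.ndarray,
    cut: np.ndarray,
    genome_len: int,
    read_length: int,
    reverse: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Turn per-molecule strand break coordinates into read intervals.

    A break at coordinate ``x`` severs the backbone between bases ``x-1``
    and ``x``: on the forward (Watson) strand it creates a new 5' end at
    ``x``; on the reverse (Crick) strand the upstream segment's 5' end is at
    ``x-1`` (segment end ``x``, half-open).  Reads run from the 5' end for
    ``read_length`` nt, truncated at the next break of the same strand (or
    the molecule end).
    """
    if len(cut) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    # sort by (molecule, coordinate) via a composite integer key; coincident
    # breaks (e.g. a sonication cut landing on the nick) collapse to a
    # single 5' end
    key = np.sort(mol * np.int64(genome_len + 1) + cut)
    if len(key) > 1:
        key = key[np.concatenate([[True], key[1:] != key[:-1]])]
    mol = key // (genome_len + 1)
    cut = key % (genome_len + 1)

    if not reverse:
        nxt = np.empty_like(cut)
        nxt[:-1] = np.where(mol[1:] == mol[:-1], cut[1:], genome_len)
        nxt[-1] = genome_len
        start = cut
        end = np.minimum(cut + read_length, nxt)
    else:
        prv = np.empty_like(cut)
        prv[1:] = np.where(mol[1:] == mol[:-1], cut[:-1], 0)
        prv[0] = 0
        end = cut
        start = np.maximum(cut - read_length, prv)
    return start, end


def simulate_library(genome: Genome, params: SonicationParams) -> ReadSet:
    """Simulate a sonicated, end-blunted single-end library.

    Returns a coordinate-sorted :class:`ReadSet`; one read per preserved
    internal 5' end on each strand.  Identical ``params.seed`` gives an
    identical read list.
    """
    for pos, _ in genome.nick_sites:
        if not 0 < pos < len(genome):
            raise ValueError(f"nick position {pos} outside genome {genome.name}")

    rng = np.random.default_rng(params.seed)
    L = len(genome)
    n = params.n_molecules

    # shared double-strand sonication cuts, Poisson process per molecule
    n_cuts = rng.poisson(L / params.mean_fragment_len, size=n)
    mol = np.repeat(np.arange(n, dtype=np.int64), n_cuts)
    cut = rng.integers(1, L, size=int(n_cuts.sum()), dtype=np.int64)

    imprinted = rng.random(n) < params.imprint_fraction
    imp_ids = np.flatnonzero(imprinted)

    watson_mol = [mol]
    watson_cut = [cut]
    crick_mol = [mol]
    crick_cut = [cut]
    for pos, strand in genome.nick_sites:
        # the nick itself: a 5' end always present on the nicked strand; a
        # break at coordinate x exposes a Watson 5' end at x but a Crick 5'
        # end at x-1, so a Crick nick at pos corresponds to the cut at pos+1
        nick_cut = pos if strand == "+" else pos + 1
        nick_target_mol = watson_mol if strand == "+" else crick_mol
        nick_target_cut = watson_cut if strand == "+" else crick_cut
        nick_target_mol.append(imp_ids)
        nick_target_cut.append(np.full(len(imp_ids), nick_cut, dtype=np.int64))
        # mechanically weakened zone on the opposite strand
        breaks = imp_ids[rng.random(len(imp_ids)) < params.opposite_break_prob]
        half = params.weakened_window // 2
        lo = max(1, pos - half)
        hi = min(L - 1, pos - half + params.weakened_window - 1)
        opp_pos = rng.integers(lo, hi + 1, size=len(breaks), dtype=np.int64)
        opp_target_mol = crick_mol if strand == "+" else watson_mol
        opp_target_cut = crick_cut if strand == "+" else watson_cut
        opp_target_mol.append(breaks)
        opp_target_cut.append(opp_pos)

    ws, we = _strand_breaks_to_reads(
        np.concatenate(watson_mol), np.concatenate(watson_cut), L, params.read_length, reverse=False
    )
    cs, ce = _strand_breaks_to_reads(
        np.concatenate(crick_mol), np.concatenate(crick_cut), L, params.read_length, reverse=True
    )

    start = np.concatenate([ws, cs])
    end = np.concatenate([we, ce])
    is_rev = np.concatenate([np.zeros(len(ws), dtype=bool), np.ones(len(cs), dtype=bool)])

    mapq = np.full(len(start), UNIQUE_MAPQ, dtype=np.int64)
    for b0, b1 in genome.repeat_blocks:
        contained = (start >= b0) & (end <= b1)
        mapq[contained] = 0

    return ReadSet(genome.name, start, end, is_rev, mapq).sorted_by_coordinate()
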