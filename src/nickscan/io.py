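"""Readers and writers for the standard formats the pipeline touches.

FASTA/BED for genomes, SAM (via pysam) and FASTQ for simulated libraries,
bedGraph and TSV for profiles and tracks.  All text; coordinates follow each
format's convention (BED/bedGraph 0-based half-open, TSV reports 1-based).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .pileup import FivePrimeProfile
from .reference import Genome
from .sonication import ReadSet
from .tracks import BinnedTrack

__all__ = [
    "write_genome_fasta",
    "write_genome_bed",
    "write_sam",
    "write_fastq",
    "read_sam",
    "write_profile_tsv",
    "write_profile_bedgraph",
    "write_track_bedgraph",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, len(genome), width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_genome_bed(genome: Genome, path: str | Path) -> None:
    """Features plus ground-truth nick sites (name ``nick``, strand set)."""
    with open(path, "w") as fh:
        for label, s, e in genome.features:
            fh.write(f"{genome.name}\t{s}\t{e}\t{label}\t0\t+\n")
        for pos, strand in genome.nick_sites:
            fh.write(f"{genome.name}\t{pos}\t{pos + 1}\tnick\t0\t{strand}\n")


def _sam_header(genome_or_name, length: int | None = None) -> pysam.AlignmentHeader:
    if isinstance(genome_or_name, Genome):
        name, length = genome_or_name.name, len(genome_or_name)
    else:
        name = genome_or_name
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": name, "LN": int(length)}]}
    )


def write_sam(reads: ReadSet, genome: Genome, path: str | Path) -> None:
    """Coordinate-sorted SAM with sequences taken from the reference."""
    header = _sam_header(genome)
    rs = reads.sorted_by_coordinate()
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i in range(len(rs)):
            s, e = int(rs.start[i]), int(rs.end[i])
            a = pysam.AlignedSegment(header)
            a.query_name = f"read{i}"
            a.reference_id = 0
            a.reference_start = s
            a.mapping_quality = int(rs.mapq[i])
            a.flag = 16 if rs.is_reverse[i] else 0
            seq = genome.sequence[s:e]
            a.query_sequence = _revcomp(seq) if rs.is_reverse[i] else seq
            a.cigarstring = f"{e - s}M"
            out.write(a)


def write_fastq(reads: ReadSet, genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(len(reads)):
            s, e = int(reads.start[i]), int(reads.end[i])
            seq = genome.sequence[s:e]
            if reads.is_reverse[i]:
                seq = _revcomp(seq)
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_sam(path: str | Path, chrom: str | None = None) -> ReadSet:
    """Load single-end alignments from SAM/BAM into a :class:`ReadSet`.

    The 5' position of a soft-clipped read is its first aligned reference
    base (pysam's ``reference_start`` / ``reference_end``), clips ignored.
    """
    starts, ends, revs, mapqs = [], [], [], []
    name = chrom
    with pysam.AlignmentFile(str(path)) as fh:
        for a in fh:
            if a.is_unmapped or (chrom is not None and a.reference_name != chrom):
                continue
            if name is None:
                name = a.reference_name
            elif a.reference_name != name:
                raise ValueError("multiple chromosomes in file; pass chrom= to select one")
            starts.append(a.reference_start)
            ends.append(a.reference_end)
            revs.append(a.is_reverse)
            mapqs.append(a.mapping_quality)
    return ReadSet(
        name or "chr",
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(revs, dtype=bool),
        np.array(mapqs, dtype=np.int64),
    )


def write_profile_tsv(profile: FivePrimeProfile, path: str | Path) -> None:
    """chrom, pos (1-based), watson, crick — one row per position."""
    df = pd.DataFrame(
        {
            "chrom": profile.chrom,
            "pos": np.arange(1, len(profile) + 1),
            "watson": profile.watson,
            "crick": profile.crick,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _write_bedgraph(chrom: str, values: np.ndarray, span: int, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if v != 0:
                fh.write(f"{chrom}\t{i * span}\t{i * span + span}\t{v:g}\n")


def write_profile_bedgraph(profile: FivePrimeProfile, prefix: str | Path) -> tuple[Path, Path]:
    """Two bedGraph tracks, ``<prefix>.watson.bedgraph`` / ``.crick.bedgraph``."""
    wpath = Path(f"{prefix}.watson.bedgraph")
    cpath = Path(f"{prefix}.crick.bedgraph")
    _write_bedgraph(profile.chrom, profile.watson, 1, wpath)
    _write_bedgraph(profile.chrom, profile.crick, 1, cpath)
    return wpath, cpath


def write_track_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    _write_bedgraph(track.chrom, track.values, track.bin_size, path)
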