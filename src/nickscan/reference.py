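"""Toy mating-type reference genomes with ground-truth nick sites.

The fission-yeast mating-type region is organised around three cassettes
(``mat1``, ``mat2P``, ``mat3M``) that share short homology boxes: H1 (59 bp,
centromere-distal side of each cassette), H2 (135 bp, centromere-proximal
side) and H3 (57 bp, present at the silent ``mat2``/``mat3`` cassettes only).
The imprint — a persistent single-strand break ("nick") on the Watson strand
— sits at the junction between the ``mat1`` allele and the H1 box, and its
position differs by exactly 3 nt between the M and P alleles.

The builders below reproduce that anatomy on a small synthetic sequence:
box and allele sequences are random stand-ins of the correct lengths (the
real locus sequence is not bundled), embedded in random flanks.  ``h90``
variants carry all three cassettes with verbatim-shared boxes, which creates
multi-mapping ambiguity by construction; "donor-less" variants carry only
``mat1`` and are fully alignable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genome",
    "build_mat_region",
    "H1_LEN",
    "H2_LEN",
    "H3_LEN",
    "VARIANTS",
]

H1_LEN = 59
H2_LEN = 135
H3_LEN = 57
ALLELE_M_LEN = 1100
ALLELE_P_LEN = ALLELE_M_LEN + 3  # shifts the allele/H1 junction by 3 nt

VARIANTS = ("h90_M", "h90_P", "M_donorless", "P_donorless", "nick_free")

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.36) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _fixed_parts() -> dict[str, str]:
    # Synthetic stand-ins for the shared boxes and allele cassettes; fixed
    # seeds so every genome built by this module shares the same parts.
    return {
        "H1": _random_seq(np.random.default_rng(101), H1_LEN),
        "H2": _random_seq(np.random.default_rng(102), H2_LEN),
        "H3": _random_seq(np.random.default_rng(103), H3_LEN),
        "alleleM": _random_seq(np.random.default_rng(104), ALLELE_M_LEN),
        "alleleP": _random_seq(np.random.default_rng(105), ALLELE_P_LEN),
    }


@dataclass
class Genome:
    """A reference sequence with annotated features and ground-truth nicks.

    Coordinates are 0-based half-open.  ``nick_sites`` holds
    ``(position, strand)`` pairs where *position* is the coordinate of the
    5' end created on the nicked strand and *strand* is ``'+'`` (Watson) or
    ``'-'`` (Crick).  ``repeat_blocks`` lists maximal intervals whose
    sequence occurs more than once in the genome; a read contained in one of
    them cannot be mapped uniquely.
    """

    name: str
    sequence: str
    features: list[tuple[str, int, int]] = field(default_factory=list)
    nick_sites: list[tuple[int, str]] = field(default_factory=list)
    repeat_blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for label, s, e in self.features:
            if not (0 <= s < e <= n):
                raise ValueError(f"feature {label!r} [{s}, {e}) outside genome of length {n}")
        for pos, strand in self.nick_sites:
            if not 0 <= pos < n:
                raise ValueError(f"nick position {pos} outside genome of length {n}")
            if strand not in "+-":
                raise ValueError(f"nick strand must be '+' or '-', got {strand!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_intervals(self, label: str) -> list[tuple[int, int]]:
        """All ``(start, end)`` intervals annotated with *label*."""
        return [(s, e) for lab, s, e in self.features if lab == label]


def _assemble(
    name: str,
    segments: list[tuple[str | None, str]],
    nick_segment_boundary: str | None,
) -> Genome:
    """Concatenate ``(label, seq)`` segments into a Genome.

    *nick_segment_boundary* names the labelled segment whose start coordinate
    becomes the nick position (the allele/H1 junction uses the H1 start).
    """
    seq_parts: list[str] = []
    features: list[tuple[str, int, int]] = []
    bounds: list[tuple[str | None, int, int]] = []
    pos = 0
    nick_pos: int | None = None
    for label, seg in segments:
        start, end = pos, pos + len(seg)
        seq_parts.append(seg)
        bounds.append((label, start, end))
        if label is not None:
            features.append((label, start, end))
        if label == nick_segment_boundary and nick_pos is None:
            nick_pos = start
        pos = end
    sequence = "".join(seq_parts)

    # Cassette-span features: one per group of consecutive labelled segments
    # belonging to the same cassette (labels look like "H1@mat1").
    spans: dict[str, list[int]] = {}
    for label, s, e in features:
        if "@" in label:
            cas = label.split("@", 1)[1]
            spans.setdefault(cas, []).extend((s, e))
    cassette_feats = [(cas, min(v), max(v)) for cas, v in spans.items()]

    repeat_blocks = _find_repeat_blocks(sequence, bounds)
    nicks = [] if nick_segment_boundary is None else [(int(nick_pos), "+")]
    return Genome(
        name=name,
        sequence=sequence,
        features=cassette_feats + features,
        nick_sites=nicks,
        repeat_blocks=repeat_blocks,
    )


def _find_repeat_blocks(
    sequence: str, bounds: list[tuple[str | None, int, int]]
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive construction segments whose concatenated
    sequence occurs more than once in the genome."""
    blocks: list[tuple[int, int]] = []
    n = len(bounds)
    i = 0
    while i < n:
        label, s0, _ = bounds[i]
        if label is None or sequence.count(sequence[s0 : bounds[i][2]]) < 2:
            i += 1
            continue
        # extend the run as far as the concatenation still repeats
        j = i
        while j + 1 < n and bounds[j + 1][0] is not None:
            cand = sequence[s0 : bounds[j + 1][2]]
            if sequence.count(cand) >= 2:
                j += 1
            else:
                break
        blocks.append((s0, bounds[j][2]))
        i += 1  # restart from the next segment: overlapping runs allowed
    # drop blocks contained in another block
    blocks = sorted(set(blocks))
    maximal = [
        b
        for b in blocks
        if not any(o != b and o[0] <= b[0] and b[1] <= o[1] for o in blocks)
    ]
    return maximal


def build_mat_region(variant: str, flank_len: int = 5000, seed: int = 0) -> Genome:
    """Build a synthetic mating-type region genome.

    Parameters
    ----------
    variant:
        One of ``h90_M``, ``h90_P`` (three cassettes, shared boxes verbatim),
        ``M_donorless``, ``P_donorless`` (mat1 only, unique sequence) or
        ``nick_free`` (mat1M anatomy, no nick — the low-imprint negative
        control).
    flank_len:
        Length of the random flank on each side; at least 1000 nt so that a
        ±1 kb scan window around the nick stays inside the genome.
    seed:
        Seed for the random flank/spacer sequence.  Box and allele sequences
        are fixed, so M and P variants built with the same seed differ only
        in the allele and their nick positions differ by exactly 3 nt.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if flank_len < 1000:
        raise ValueError("flank_len must be >= 1000")

    parts = _fixed_parts()
    rng = np.random.default_rng(seed)
    left = _random_seq(rng, flank_len)
    right = _random_seq(rng, flank_len)

    allele1 = "alleleP" if variant in ("h90_P", "P_donorless") else "alleleM"

    def mat1_segments() -> list[tuple[str | None, str]]:
        return [
            ("H2@mat1", parts["H2"]),
            (f"{allele1}@mat1", parts[allele1]),
            ("H1@mat1", parts["H1"]),
        ]

    if variant in ("M_donorless", "P_donorless", "nick_free"):
        segments = [(None, left), *mat1_segments(), (None, right)]
    else:
        spacer1 = _random_seq(rng, 2000)
        cenh = _random_seq(rng, 1500)
        segments = [
            (None, left),
            *mat1_segments(),
            (None, spacer1),
            ("H3@mat2", parts["H3"]),
            ("H2@mat2", parts["H2"]),
            ("alleleP@mat2", parts["alleleP"]),
            ("H1@mat2", parts["H1"]),
            (None, cenh),
            ("H3@mat3", parts["H3"]),
            ("H2@mat3", parts["H2"]),
            ("alleleM@mat3", parts["alleleM"]),
            ("H1@mat3", parts["H1"]),
            (None, right),
        ]

    nick_anchor = None if variant == "nick_free" else "H1@mat1"
    return _assemble(variant, segments, nick_anchor)
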