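"""Multi-scale sliding-window significance scan.

Slides windows of every size from 1 to ``max_size`` (step 1 by default)
across a region of one strand's 5' count profile, computing for each
(size, start) cell the window count sum (cumulative-sum arithmetic, exact in
integers) and its -log10 upper-tail p-value under the fitted count null.
Size-1 rows reduce exactly to single-position p-values.  The resulting
surface exposes the geometry of a persistent nick: a size-1 optimum at the
break on the nicked strand, and a short multi-nucleotide optimum facing it
on the opposite strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nullmodel import NullModel
from .pileup import FivePrimeProfile

__all__ = ["WindowHit", "ScanResult", "window_scan", "top_k", "best_window"]


@dataclass(frozen=True)
class WindowHit:
    """One scored window; ``offset_to_anchor`` is 0 when the window covers
    the anchor, positive when it starts right of it, negative when it ends
    left of it."""

    strand: str
    window_start: int
    window_size: int
    window_sum: int
    neglog10p: float
    offset_to_anchor: int | None = None


@dataclass
class ScanResult:
    """-log10(p) surface of a multi-scale window scan.

    ``neglog10p[i]`` and ``window_sums[i]`` are vectors over window starts
    for ``sizes[i]``; row ``i`` has ``region_length - sizes[i] + 1`` entries
    when step is 1.
    """

    chrom: str
    strand: str
    region: tuple[int, int]
    sizes: list[int]
    starts: list[np.ndarray]
    window_sums: list[np.ndarray]
    neglog10p: list[np.ndarray]
    model: NullModel
    step: int = 1
    anchor: int | None = field(default=None)

    def matrix(self, fill: float = np.nan) -> np.ndarray:
        """Rectangular (|sizes| x max starts) -log10(p) matrix, short rows
        padded with *fill* (useful for heatmaps)."""
        width = max(len(v) for v in self.neglog10p)
        out = np.full((len(self.sizes), width), fill)
        for i, row in enumerate(self.neglog10p):
            out[i, : len(row)] = row
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: strand, size, start, sum, neglog10p."""
        parts = [
            pd.DataFrame(
                {
                    "strand": self.strand,
                    "size": w,
                    "start": self.starts[i],
                    "sum": self.window_sums[i],
                    "neglog10p": self.neglog10p[i],
                }
            )
            for i, w in enumerate(self.sizes)
        ]
        return pd.concat(parts, ignore_index=True)


def window_scan(
    profile: FivePrimeProfile,
    strand: str,
    model: NullModel,
    region: tuple[int, int],
    max_size: int = 40,
    step: int = 1,
    anchor: int | None = None,
) -> ScanResult:
    """Scan all window sizes 1..*max_size* over *region* of one strand.

    Window sums use a cumulative sum over the region's raw counts; windows
    are confined to the region.  *step* subsamples window starts (the
    default 1 scores every start).
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    counts = profile.strand(strand)
    start, end = region
    if not (0 <= start < end <= len(counts)):
        raise ValueError(f"region [{start}, {end}) outside chromosome of length {len(counts)}")
    if end - start < max_size:
        raise ValueError(f"region of {end - start} nt shorter than max window size {max_size}")

    x = np.asarray(counts[start:end], dtype=np.int64)
    csum = np.concatenate([[0], np.cumsum(x)])

    sizes = list(range(1, max_size + 1))
    starts_l: list[np.ndarray] = []
    sums_l: list[np.ndarray] = []
    nlp_l: list[np.ndarray] = []
    for w in sizes:
        offs = np.arange(0, end - start - w + 1, step)
        sums = csum[offs + w] - csum[offs]
        starts_l.append(offs + start)
        sums_l.append(sums)
        nlp_l.append(model.neglog10_sf(sums, window_size=w))
    return ScanResult(
        chrom=profile.chrom,
        strand=strand,
        region=(start, end),
        sizes=sizes,
        starts=starts_l,
        window_sums=sums_l,
        neglog10p=nlp_l,
        model=model,
        step=step,
        anchor=anchor,
    )


def _offset(window_start: int, window_size: int, anchor: int) -> int:
    if window_start <= anchor < window_start + window_size:
        return 0
    if anchor < window_start:
        return window_start - anchor
    return (window_start + window_size - 1) - anchor


def top_k(result: ScanResult, k: int, anchor: int | None = None) -> list[WindowHit]:
    """The *k* most significant cells of the scan surface.

    Ties are broken deterministically: higher -log10(p) first, then smaller
    window size, then smaller start.  When *anchor* (or the scan's stored
    anchor) is given, each hit carries its signed offset to it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if anchor is None:
        anchor = result.anchor
    size_col = np.concatenate(
        [np.full(len(s), w) for w, s in zip(result.sizes, result.starts)]
    )
    start_col = np.concatenate(result.starts)
    sum_col = np.concatenate(result.window_sums)
    nlp_col = np.concatenate(result.neglog10p)
    order = np.lexsort((start_col, size_col, -nlp_col))
    hits = []
    for idx in order[: min(k, len(order))]:
        s, w = int(start_col[idx]), int(size_col[idx])
        hits.append(
            WindowHit(
                strand=result.strand,
                window_start=s,
                window_size=w,
                window_sum=int(sum_col[idx]),
                neglog10p=float(nlp_col[idx]),
                offset_to_anchor=None if anchor is None else _offset(s, w, anchor),
            )
        )
    return hits


def best_window(result: ScanResult, anchor: int | None = None) -> WindowHit:
    """The single most significant window of the scan."""
    return top_k(result, 1, anchor=anchor)[0]


def plot_surface(result: ScanResult, path=None, vmax: float | None = None):
    """Heatmap of the -log10(p) surface (window size x position).

    Requires matplotlib (the ``plot`` extra). Returns the figure; also
    saves it when *path* is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    mat = result.matrix()
    im = ax.imshow(
        mat,
        aspect="auto",
        origin="lower",
        interpolation="nearest",
        vmax=vmax,
        extent=(result.region[0], result.region[1], 0.5, len(result.sizes) + 0.5),
    )
    if result.anchor is not None:
        ax.axvline(result.anchor, color="w", lw=0.5, ls="--")
    ax.set_xlabel(f"position on {result.chrom}")
    ax.set_ylabel("window size (nt)")
    ax.set_title(f"{result.strand} strand")
    fig.colorbar(im, ax=ax, label="-log10 p")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
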