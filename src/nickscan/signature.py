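"""Genome-wide 5' count screen and the nick caller.

A persistent site- and strand-specific single-strand break leaves a
two-part molecular signature after sonication and 5'-conserving library
preparation: an exact single-nucleotide pileup of 5' ends on the nicked
strand, and a diffuse ~20-nt zone of elevated 5' ends on the opposite
strand where the intact strand is mechanically weakened and preferentially
breaks.  Repeat collapse and similar alignment artifacts instead inflate
both strands comparably, so the screen separates *strand-exclusive* from
*symmetric* enrichments, and the caller demands the full two-part geometry:
a strand-exclusive spike whose opposite strand carries a short, significant
best window overlapping it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nullmodel import NullModel, fit_null, pvalue_single
from .pileup import FivePrimeProfile
from .scan import WindowHit, best_window, window_scan

__all__ = ["EnrichedRegion", "ScreenResult", "NickCall", "genome_screen", "call_nicks"]


@dataclass(frozen=True)
class EnrichedRegion:
    """A run of Bonferroni-significant positions on one strand (merged
    within ``merge_dist``); ``symmetric`` marks comparable enrichment on the
    opposite strand (the repeat-artifact class)."""

    strand: str
    start: int
    end: int
    peak_pos: int
    peak_count: int
    min_p: float
    symmetric: bool


@dataclass
class ScreenResult:
    """Output of :func:`genome_screen`: per-strand significant positions and
    merged regions; ``threshold`` is the per-test Bonferroni p cutoff."""

    positions: dict[str, np.ndarray]
    regions: dict[str, list[EnrichedRegion]]
    threshold: float

    def exclusive_regions(self, strand: str | None = None) -> list[EnrichedRegion]:
        strands = [strand] if strand else ["watson", "crick"]
        return [r for s in strands for r in self.regions[s] if not r.symmetric]


@dataclass(frozen=True)
class NickCall:
    """A called persistent nick: the spike position and strand, its
    single-position p-value, and the supporting opposite-strand window."""

    chrom: str
    position: int
    nicked_strand: str
    single_p: float
    opposite_window: WindowHit
    asymmetric: bool = True


def _merge_runs(pos: np.ndarray, merge_dist: int) -> list[tuple[int, int]]:
    if len(pos) == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) > merge_dist)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(pos) - 1]])
    return [(int(pos[a]), int(pos[b]) + 1) for a, b in zip(starts, ends)]


def genome_screen(
    profile: FivePrimeProfile,
    model_watson: NullModel,
    model_crick: NullModel,
    alpha: float = 0.05,
    merge_dist: int = 50,
    symmetric_peak_ratio: float = 0.25,
) -> ScreenResult:
    """Screen both strands for positions with Bonferroni-significant 5' count.

    The family is every position on each strand (N = 2 x chromosome
    length); positions with upper-tail p below ``alpha / N`` are reported
    and merged into regions when within *merge_dist* nt of each other.  A
    region is labelled symmetric when the opposite strand has a significant
    region overlapping it (within *merge_dist*) whose per-position peak is
    at least *symmetric_peak_ratio* of its own peak — comparable two-strand
    enrichment, as produced by collapsed repeats — and strand-exclusive
    otherwise.
    """
    if profile.normalized:
        raise ValueError("screen raw counts: profile is normalized but the null is on integers")
    n_tests = 2 * len(profile)
    threshold = alpha / n_tests
    models = {"watson": model_watson, "crick": model_crick}

    positions: dict[str, np.ndarray] = {}
    for strand, model in models.items():
        counts = profile.strand(strand)
        # smallest count whose upper tail falls below the threshold
        kcrit = int(model._dist(1).isf(threshold)) + 1
        cand = np.flatnonzero(counts >= kcrit)
        sig = [p for p in cand if pvalue_single(int(counts[p]), model) < threshold]
        positions[strand] = np.asarray(sig, dtype=np.int64)

    raw_regions: dict[str, list[tuple[int, int]]] = {
        s: _merge_runs(positions[s], merge_dist) for s in ("watson", "crick")
    }

    regions: dict[str, list[EnrichedRegion]] = {"watson": [], "crick": []}
    for strand in ("watson", "crick"):
        other = "crick" if strand == "watson" else "watson"
        counts = profile.strand(strand)
        other_counts = profile.strand(other)
        for s, e in raw_regions[strand]:
            peak = s + int(np.argmax(counts[s:e]))
            peak_count = int(counts[peak])
            symmetric = False
            for os_, oe in raw_regions[other]:
                if os_ - merge_dist < e and s < oe + merge_dist:
                    opeak = int(other_counts[os_:oe].max())
                    if opeak >= symmetric_peak_ratio * peak_count:
                        symmetric = True
                        break
            regions[strand].append(
                EnrichedRegion(
                    strand=strand,
                    start=s,
                    end=e,
                    peak_pos=peak,
                    peak_count=peak_count,
                    min_p=pvalue_single(peak_count, models[strand]),
                    symmetric=symmetric,
                )
            )
    return ScreenResult(positions=positions, regions=regions, threshold=threshold)


def call_nicks(
    profile: FivePrimeProfile,
    model_watson: NullModel,
    model_crick: NullModel,
    alpha: float = 0.05,
    merge_dist: int = 50,
    flank: int = 1000,
    max_size: int = 40,
    min_opposite_size: int = 2,
    fit_flank: int = 5000,
    local_fit: bool = True,
) -> list[NickCall]:
    """Call persistent nicks by the two-strand sonication signature.

    For every strand-exclusive enriched region found by the genome screen,
    the opposite strand is scanned (sizes 1..*max_size*, ±*flank* nt around
    the spike) against a null refitted locally on ±*fit_flank* nt (or the
    given genome-wide model when *local_fit* is False).  A call is emitted
    when the opposite best window has size in [*min_opposite_size*,
    *max_size*], overlaps the spike ± its own size, and is Bonferroni
    significant across the scan's cells at *alpha*.  Calls are sorted by
    spike p-value.
    """
    screen = genome_screen(profile, model_watson, model_crick, alpha=alpha, merge_dist=merge_dist)
    L = len(profile)
    calls: list[NickCall] = []
    for region in screen.exclusive_regions():
        anchor = region.peak_pos
        opposite = "crick" if region.strand == "watson" else "watson"
        lo = max(0, anchor - flank)
        hi = min(L, anchor + flank + 1)
        if hi - lo < max_size:
            continue
        if local_fit:
            flo = max(0, anchor - fit_flank)
            fhi = min(L, anchor + fit_flank)
            model = fit_null(profile, opposite, region=(flo, fhi))
        else:
            model = model_crick if opposite == "crick" else model_watson
        result = window_scan(profile, opposite, model, region=(lo, hi), max_size=max_size, anchor=anchor)
        hit = best_window(result, anchor=anchor)
        n_cells = sum(len(v) for v in result.neglog10p)
        significant = hit.neglog10p > -np.log10(alpha / n_cells)
        faces_spike = (
            hit.window_start - hit.window_size <= anchor
            and anchor <= hit.window_start + 2 * hit.window_size - 1
        )
        if (
            min_opposite_size <= hit.window_size <= max_size
            and significant
            and faces_spike
        ):
            calls.append(
                NickCall(
                    chrom=profile.chrom,
                    position=anchor,
                    nicked_strand=region.strand,
                    single_p=region.min_p,
                    opposite_window=hit,
                    asymmetric=True,
                )
            )
    calls.sort(key=lambda c: (c.single_p, c.position))
    return calls
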