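"""Physics of the sonication / end-blunting simulator."""

import numpy as np
import pytest
from scipy import stats

from nickscan import Genome, SonicationParams, build_mat_region, compute_five_prime_counts, simulate_library


def _params(**kw):
    base = dict(n_molecules=2000, imprint_fraction=0.3, seed=5)
    base.update(kw)
    return SonicationParams(**base)


def test_identical_seed_identical_reads(m_genome):
    a = simulate_library(m_genome, _params())
    b = simulate_library(m_genome, _params())
    assert np.array_equal(a.start, b.start)
    assert np.array_equal(a.end, b.end)
    assert np.array_equal(a.is_reverse, b.is_reverse)
    c = simulate_library(m_genome, _params(seed=6))
    assert not np.array_equal(a.start, c.start)


def test_read_intervals_valid(nicked_run, m_genome):
    reads, _, params = nicked_run
    assert (reads.start < reads.end).all()
    assert (reads.end - reads.start <= params.read_length).all()
    assert reads.start.min() >= 0 and reads.end.max() <= len(m_genome)


def test_no_nick_gives_equal_strand_read_counts(nickfree_run):
    """Without strand-specific breaks both strands fragment at the shared
    sonication cuts, so read counts per strand are identical."""
    reads, _, _ = nickfree_run
    assert int(reads.is_reverse.sum()) * 2 == len(reads)


def test_strands_exchangeable_without_nick(nickfree_run):
    _, profile, _ = nickfree_run
    res = stats.mannwhitneyu(profile.watson[1:-1], profile.crick[1:-1])
    assert res.pvalue > 0.01


def test_no_single_position_spike_without_nick(nickfree_run):
    _, profile, _ = nickfree_run
    w = profile.watson[1:-1].astype(float)
    assert w.max() < 2.0 * np.quantile(w, 0.999)


def test_nick_creates_spike_above_noise(nicked_run, m_genome):
    _, profile, _ = nicked_run
    nick = m_genome.nick_sites[0][0]
    others = np.delete(profile.watson, nick)
    assert profile.watson[nick] > np.quantile(others[1:-1], 0.9999)


def test_empirical_mean_fragment_length(m_genome):
    """Fragments per molecule = internal cuts + 1; the read count per strand
    tallies the cuts, giving an independent estimate of the mean fragment
    length (finite molecules make it slightly shorter than the setting)."""
    params = SonicationParams(n_molecules=20_000, imprint_fraction=0.0, seed=3)
    reads = simulate_library(m_genome, params)
    n_cuts = len(reads) // 2
    est = len(m_genome) * params.n_molecules / (n_cuts + params.n_molecules)
    assert abs(est - params.mean_fragment_len) / params.mean_fragment_len < 0.05


def test_opposite_strand_breaks_confined_to_weakened_window(m_genome):
    """Crick 5' excess appears only inside the window centered on the nick."""
    params = SonicationParams(n_molecules=20_000, imprint_fraction=0.5, seed=9, weakened_window=20)
    profile = compute_five_prime_counts(simulate_library(m_genome, params), m_genome)
    nick = m_genome.nick_sites[0][0]
    zone = np.arange(nick - 11, nick + 9)
    background = np.delete(np.arange(1, len(m_genome) - 1), zone)
    bg_hi = np.quantile(profile.crick[background], 0.9999)
    assert (profile.crick[zone] > bg_hi).all()


def test_multimappers_flagged_inside_repeat_blocks():
    g = build_mat_region("h90_M")
    reads = simulate_library(g, _params(n_molecules=3000))
    contained = np.zeros(len(reads), dtype=bool)
    for b0, b1 in g.repeat_blocks:
        contained |= (reads.start >= b0) & (reads.end <= b1)
    assert (reads.mapq[contained] == 0).all()
    assert (reads.mapq[~contained] >= 30).all()


def test_nick_outside_genome_rejected():
    g = Genome("toy", "ACGT" * 500, nick_sites=[(0, "+")])
    with pytest.raises(ValueError):
        simulate_library(g, _params(n_molecules=10))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SonicationParams(imprint_fraction=1.5)
    with pytest.raises(ValueError):
        SonicationParams(mean_fragment_len=100.0, read_length=130)
    with pytest.raises(ValueError):
        SonicationParams(weakened_window=0)
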