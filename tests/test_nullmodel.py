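"""Negative-binomial null: fitting, tail p-values, deep-tail numerics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from nickscan import FivePrimeProfile, NullModel, fit_null, pvalue_single, pvalue_window


def _profile_from_counts(counts):
    counts = np.asarray(counts, dtype=int)
    zeros = np.zeros_like(counts)
    return FivePrimeProfile("c", counts, zeros, library_size=int(counts.sum()))


def test_nb_parameter_recovery():
    rng = np.random.default_rng(42)
    x = rng.negative_binomial(2, 0.5, size=100_000)  # mean 2.0
    m = fit_null(_profile_from_counts(x), "watson")
    assert m.family == "negative_binomial"
    assert abs(m.mean - 2.0) / 2.0 < 0.03
    assert abs(m.r - 2.0) / 2.0 < 0.10


def test_poisson_counts_fit_at_boundary():
    rng = np.random.default_rng(43)
    x = rng.poisson(1.0, size=100_000)
    m = fit_null(_profile_from_counts(x), "watson")
    assert 0.95 < m.variance / m.mean < 1.05


def test_constant_counts_fall_back_to_poisson():
    m = fit_null(_profile_from_counts(np.full(2000, 7)), "watson")
    assert m.family == "poisson" and m.mean == 7.0


def test_degenerate_fits_rejected():
    with pytest.raises(ValueError):
        fit_null(_profile_from_counts(np.zeros(2000, dtype=int)), "watson")
    with pytest.raises(ValueError):
        fit_null(_profile_from_counts(np.ones(500, dtype=int)), "watson")
    p = _profile_from_counts(np.ones(2000, dtype=int))
    from nickscan import normalize_profile

    with pytest.raises(ValueError):
        fit_null(normalize_profile(p), "watson")


def test_single_position_tail_against_direct_summation():
    """NB(r=2, p=0.5): P(X >= 10) has the closed form
    sum_{k>=10} (k+1) * 0.25 * 0.5^k = 6 * 0.5^10 = 0.005859375."""
    m = NullModel("negative_binomial", 2.0, 0.5, mean=2.0)
    assert pvalue_single(10, m) == pytest.approx(0.005859375, abs=1e-12)
    brute = float(stats.nbinom.pmf(np.arange(10, 400), 2, 0.5).sum())
    assert pvalue_single(10, m) == pytest.approx(brute, abs=1e-12)


def test_tail_basics_and_monotonicity():
    m = NullModel("negative_binomial", 2.0, 0.5, mean=2.0)
    assert pvalue_single(0, m) == 1.0
    ps = [pvalue_single(k, m) for k in range(50)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 200), st.integers(1, 8))
def test_window_tail_monotone_in_sum(total, w):
    m = NullModel("negative_binomial", 3.0, 0.4, mean=4.5)
    assert pvalue_window(total, w, m) >= pvalue_window(total + 1, w, m)
    assert pvalue_window(0, w, m) == 1.0


def test_window_size_one_reduces_to_single():
    m = NullModel("negative_binomial", 2.0, 0.5, mean=2.0)
    for k in range(0, 60, 3):
        assert pvalue_window(k, 1, m) == pytest.approx(pvalue_single(k, m), rel=1e-12)


@pytest.mark.parametrize("w", [2, 3, 4])
def test_window_sum_additivity_against_convolution(w):
    """The w-window null NB(w*r, p) equals the w-fold convolution of the
    single-position pmf."""
    m = NullModel("negative_binomial", 2.0, 0.5, mean=2.0)
    pmf = stats.nbinom.pmf(np.arange(0, 600), 2, 0.5)
    conv = pmf.copy()
    for _ in range(w - 1):
        conv = np.convolve(conv, pmf)[:600]
    for s in range(0, 51, 5):
        tail = 1.0 - conv[:s].sum()
        assert pvalue_window(s, w, m) == pytest.approx(tail, abs=1e-9)


def test_window_tail_against_monte_carlo():
    m = NullModel("negative_binomial", 2.0, 0.5, mean=2.0)
    rng = np.random.default_rng(77)
    sums = rng.negative_binomial(2, 0.5, size=(10**6, 5)).sum(axis=1)
    phat = float((sums >= 25).mean())
    se = math.sqrt(phat * (1 - phat) / 10**6)
    assert abs(pvalue_window(25, 5, m) - phat) < 3 * se


def test_deep_tail_log_path_matches_gamma_tail():
    """For a Poisson null the exact upper tail is the regularized upper
    incomplete gamma function; the log-space summation must agree with it
    well past where the plain survival function underflows."""
    m = NullModel("poisson", math.inf, 1.0, mean=5.0)
    for k in [232, 240]:  # sf ~ 1e-286 .. 1e-301: summation branch
        exact = float(special.gammainc(k, 5.0))  # P(X >= k) for Poisson(5)
        assert m.logsf(k) == pytest.approx(math.log(exact), rel=1e-8)
    # continuity across the direct/summation switch and beyond underflow
    nlp = m.neglog10_sf(np.arange(350, 600))
    assert (np.diff(nlp) > 0).all()
    assert nlp[-1] > 400  # far beyond the 1e-300 linear-scale floor


def test_pvalue_floor_on_linear_scale():
    m = NullModel("poisson", math.inf, 1.0, mean=5.0)
    assert pvalue_single(10_000, m) == 1e-300


def test_model_json_round_trip():
    m = NullModel("negative_binomial", 2.5, 0.4, mean=3.75, fit_region=("c", 0, 5000), n_positions_fit=5000)
    again = NullModel.from_json(m.to_json())
    assert again == m
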