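"""Overdispersed null model for per-position 5' counts.

Genomic 5' end counts are non-negative integers whose variance typically
exceeds their mean, so the null is a negative binomial NB(r, p) fitted by
maximum likelihood (moment-matched initialization) to the per-position
counts of one strand over a stated region, zeros included.  When the sample
variance does not exceed the mean, the fit falls back to the Poisson limit.

Upper-tail p-values are provided both for single positions and for sums over
windows of w positions, treated as sums of w i.i.d. draws: for NB(r, p) the
w-sum is NB(w*r, p), for Poisson(mu) it is Poisson(w*mu).  Tail probabilities
are evaluated in log space so that the -log10(p) surface stays exact far
beyond where double-precision survival functions underflow; the linear-scale
p-value accessors floor at 1e-300.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .pileup import FivePrimeProfile

__all__ = ["NullModel", "fit_null", "pvalue_single", "pvalue_window"]

P_FLOOR = 1e-300
# above this survival-function value scipy's direct computation is trusted
_SF_TRUST = 1e-280


@dataclass(frozen=True)
class NullModel:
    """Fitted count null: NB(r, p) with mean r(1-p)/p, or its Poisson limit.

    ``family`` is ``"negative_binomial"`` or ``"poisson"``; for the Poisson
    limit ``r`` is infinite and only ``mean`` is meaningful.
    """

    family: str
    r: float
    p: float
    mean: float
    fit_region: tuple[str, int, int] | None = None
    n_positions_fit: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mean <= 0:
            raise ValueError("model mean must be positive")

    @property
    def variance(self) -> float:
        if self.family == "poisson":
            return self.mean
        return self.r * (1 - self.p) / self.p**2

    def _dist(self, window_size: int = 1):
        if self.family == "poisson":
            return stats.poisson(window_size * self.mean)
        return stats.nbinom(window_size * self.r, self.p)

    def _logpmf(self, k: np.ndarray, window_size: int) -> np.ndarray:
        return self._dist(window_size).logpmf(k)

    def logsf(self, count: int, window_size: int = 1) -> float:
        """Natural log of P(S >= count) for the *window_size*-sum null.

        Falls back to log-space tail summation when the direct survival
        function underflows.
        """
        count = int(count)
        if count <= 0:
            return 0.0
        sf = float(self._dist(window_size).sf(count - 1))
        if sf > _SF_TRUST:
            return math.log(sf)
        # deep tail: sum pmf terms from `count` upwards in log space; in
        # this regime count >> mean, so terms decay geometrically
        total = -np.inf
        k0 = count
        block = 1024
        while True:
            ks = np.arange(k0, k0 + block)
            lp = self._logpmf(ks, window_size)
            chunk = special.logsumexp(lp)
            total = np.logaddexp(total, chunk)
            if lp[-1] < total - 40.0:
                # bound the remainder by a geometric series and stop
                ratio = lp[-1] - lp[-2]
                if ratio < -1e-12:
                    rem = lp[-1] + ratio - math.log1p(-math.exp(ratio))
                    total = np.logaddexp(total, rem)
                break
            k0 += block
            block = min(block * 2, 1 << 20)
        return float(total)

    def neglog10_sf(self, counts, window_size: int = 1) -> np.ndarray:
        """Vectorized -log10 P(S >= count); exact in the deep tail."""
        counts = np.asarray(counts, dtype=np.int64)
        dist = self._dist(window_size)
        sf = dist.sf(counts - 1)
        out = np.empty(counts.shape, dtype=float)
        ok = sf > _SF_TRUST
        with np.errstate(divide="ignore"):
            out[ok] = -np.log10(sf[ok])
        for idx in np.flatnonzero(~ok):
            out[idx] = -self.logsf(int(counts[idx]), window_size) / math.log(10)
        np.clip(out, 0.0, None, out=out)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "r": self.r,
                "p": self.p,
                "mean": self.mean,
                "fit_region": list(self.fit_region) if self.fit_region else None,
                "n_positions_fit": self.n_positions_fit,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "NullModel":
        d = json.loads(doc)
        region = tuple(d["fit_region"]) if d["fit_region"] else None
        return cls(d["family"], d["r"], d["p"], d["mean"], region, d["n_positions_fit"])


def _nb_profile_loglik(log_r: float, values: np.ndarray, weights: np.ndarray, mean: float) -> float:
    """NB log-likelihood profiled over the mean (MLE of the mean is the
    sample mean for any r), as a function of log r."""
    r = math.exp(log_r)
    p = r / (r + mean)
    ll = (
        special.gammaln(values + r)
        - special.gammaln(r)
        - special.gammaln(values + 1.0)
        + r * math.log(p)
        + values * math.log1p(-p)
    )
    return float(np.dot(weights, ll))


def fit_null(
    profile: FivePrimeProfile,
    strand: str,
    region: tuple[int, int] | None = None,
) -> NullModel:
    """Fit the count null to one strand of a profile over *region*.

    *region* is a 0-based half-open ``(start, end)`` interval; ``None``
    means the whole chromosome.  At least 1000 positions are required and
    the counts must be integers (fit before normalizing).
    """
    if profile.normalized:
        raise ValueError("fit the null on raw counts, not a normalized profile")
    counts = profile.strand(strand)
    start, end = (0, len(counts)) if region is None else region
    if not (0 <= start < end <= len(counts)):
        raise ValueError(f"region [{start}, {end}) outside profile of length {len(counts)}")
    x = np.asarray(counts[start:end], dtype=np.float64)
    n = len(x)
    if n < 1000:
        raise ValueError(f"fit region has {n} positions; need >= 1000")
    mean = float(x.mean())
    if mean == 0.0:
        raise ValueError("all counts in the fit region are zero")
    var = float(x.var())
    fit_region = (profile.chrom, start, end)

    if var <= mean:
        # at or below the Poisson boundary (includes constant counts)
        return NullModel("poisson", math.inf, 1.0, mean, fit_region, n)

    values, weights = np.unique(x, return_counts=True)
    r0 = mean * mean / (var - mean)
    res = optimize.minimize_scalar(
        lambda lr: -_nb_profile_loglik(lr, values, weights.astype(float), mean),
        bounds=(math.log(r0) - 12.0, math.log(1e9)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    r = float(math.exp(min(res.x, math.log(1e8))))
    if r >= 1e8:
        # indistinguishable from the Poisson limit at double precision
        return NullModel("poisson", math.inf, 1.0, mean, fit_region, n)
    p = r / (r + mean)
    return NullModel("negative_binomial", r, p, mean, fit_region, n)


def pvalue_single(count: int, model: NullModel) -> float:
    """Upper-tail p-value P(X >= count) of one position's 5' count.

    Floored at 1e-300; use :meth:`NullModel.logsf` for the exact log tail.
    """
    return max(math.exp(model.logsf(int(count), 1)), P_FLOOR)


def pvalue_window(window_sum: int, window_size: int, model: NullModel) -> float:
    """Upper-tail p-value of a window sum over *window_size* positions,
    P(S >= window_sum) with S a sum of i.i.d. draws from the null."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    return max(math.exp(model.logsf(int(window_sum), window_size)), P_FLOOR)
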