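"""Piecewise-linear empirical distributions for Monte Carlo sampling.

Strongly skewed biomarker data are often incompatible with any single
parametric family, so the population distribution of urinary levels is
represented non-parametrically: a piecewise-linear inverse CDF through the
empirical quantiles, sampled by inverse-transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurements import DEFAULT_QUANTILE_METHOD, quantile


@dataclass(frozen=True)
class QuantileDistribution:
    """Inverse CDF defined by (probability, value) knots.

    ``probs`` and ``values`` are equal-length nondecreasing sequences with
    ``inverse_cdf(probs[i]) == values[i]``; between knots the inverse CDF is
    linear.
    """

    probs: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if p.size != v.size or p.size < 2:
            raise ValueError("probs and values must have equal length >= 2")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probs must lie in [0, 1]")
        if np.any(np.diff(p) < 0) or np.any(np.diff(v) < 0):
            raise ValueError("probs and values must be nondecreasing")

    def inverse_cdf(self, p):
        """Evaluate the piecewise-linear inverse CDF at probability ``p``."""
        return np.interp(p, self.probs, self.values)


def fit_empirical_distribution(
    values, probs=None, method: str = DEFAULT_QUANTILE_METHOD
) -> QuantileDistribution:
    """Fit a :class:`QuantileDistribution` to observed (substituted) values.

    By default the knots are the order statistics themselves at plotting
    positions (k-1)/(n-1); a coarser probability grid can be supplied.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size < 2:
        raise ValueError("need at least two values to fit a distribution")
    if np.any(arr <= 0):
        raise ValueError("values must be positive (substitute below-LOQ records first)")
    if probs is None:
        p = np.arange(arr.size) / (arr.size - 1)
        return QuantileDistribution(tuple(p), tuple(arr))
    p = np.asarray(probs, dtype=float)
    q = quantile(arr, p, method)
    return QuantileDistribution(tuple(p), tuple(np.atleast_1d(q)))


def sample_distribution(
    dist: QuantileDistribution, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Inverse-transform sample ``n`` draws from the fitted distribution."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return dist.inverse_cdf(rng.random(n))
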