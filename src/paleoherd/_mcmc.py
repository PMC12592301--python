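"""Low-level MCMC primitives shared by the samplers.

Kept dependency-light and fast: the samplers call these inside tight Python
loops, so everything here avoids scipy.stats object overhead and works with
plain floats / small ndarrays.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtr, ndtri

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def slice_sample(x0: float, logf, w: float, rng: np.random.Generator, max_steps: int = 50) -> float:
    """One update of Neal's univariate slice sampler with stepping-out.

    ``logf`` is the (unnormalised) log density; ``w`` the initial bracket
    width. Returns a new point distributed according to exp(logf) given the
    current point ``x0``.
    """
    logy = logf(x0) + math.log(rng.random())
    u = rng.random()
    lo = x0 - w * u
    hi = lo + w
    steps = max_steps
    while steps > 0 and logf(lo) > logy:
        lo -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logf(hi) > logy:
        hi += w
        steps -= 1
    while True:
        x1 = lo + rng.random() * (hi - lo)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
        if hi - lo < 1e-300:  # numerically degenerate slice
            return x0


def truncnorm_rvs(
    mu: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """Draw from N(mu, sd^2) truncated to (lo, hi) by inverse-CDF."""
    a = ndtr((lo - mu) / sd)
    b = ndtr((hi - mu) / sd)
    if b - a < 1e-14:  # interval in an extreme tail or zero width
        return float(min(max(mu, lo), hi))
    u = a + rng.random() * (b - a)
    return float(mu + sd * ndtri(u))


def truncnorm_logpdf(x: float, mu: float, sd: float, lo: float, hi: float) -> float:
    """Log density of N(mu, sd^2) truncated to (lo, hi); -inf outside."""
    if not lo <= x <= hi:
        return -math.inf
    z = ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd)
    if z <= 0:
        # degenerate interval: treat as a point mass at the clipped value
        return 0.0 if abs(x - min(max(mu, lo), hi)) < 1e-12 else -math.inf
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd * _SQRT_2PI) - math.log(z)


def halfnormal_logpdf(x: float, sd: float) -> float:
    """Log density of N(0, sd^2) truncated to (0, inf); -inf for x <= 0."""
    if x <= 0:
        return -math.inf
    return -0.5 * (x / sd) ** 2 + math.log(2.0 / (sd * _SQRT_2PI))


def n_retained(iterations: int, burnin: int, thin: int, chains: int) -> int:
    """Number of posterior draws retained by a schedule: after discarding
    ``burnin`` iterations, every ``thin``-th of the remaining iterations is
    kept, per chain."""
    if burnin >= iterations:
        raise ValueError("burn-in must be smaller than the iteration count")
    if thin < 1:
        raise ValueError("thinning interval must be >= 1")
    return chains * ((iterations - burnin) // thin)
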