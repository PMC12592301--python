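"""Convergence and posterior-summary utilities.

Conventions are deliberately simple and classical: the Gelman-Rubin
potential scale reduction factor uses the two-variance (between/within)
decomposition without splitting or rank-normalisation, and HPD intervals
are the empirical shortest window over the sorted draws with ties broken
by the lowest start.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ChainSet:
    """Per-chain, per-parameter draws with schedule metadata."""

    draws: dict[str, np.ndarray]  # parameter -> (n_chains, n_draws)
    burnin: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError("all parameters must have equal (chains, draws) shapes")
        for v in self.draws.values():
            if v.ndim != 2:
                raise ValueError("draws must be 2-d (chains, iterations)")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)


def gelman_rubin(chains: ChainSet | np.ndarray, parameter: str | None = None) -> float:
    """Potential scale reduction factor (PSRF) for one parameter.

    ``chains`` is either a ChainSet (with ``parameter`` naming the entry) or
    a (n_chains, n_draws) array. Returns NaN with a warning when the
    within-chain variance is zero (degenerate chains).
    """
    if isinstance(chains, ChainSet):
        if parameter is None:
            raise ValueError("parameter name required with a ChainSet")
        x = chains.draws[parameter]
    else:
        x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    m, n = x.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    if w <= 0:
        warnings.warn("degenerate chains: zero within-chain variance", stacklevel=2)
        return float("nan")
    b = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def autocorrelation(chain: np.ndarray, lag: int) -> float:
    """Sample autocorrelation of a chain at the given lag.

    Returns NaN with a warning for a constant chain (undefined).
    """
    x = np.asarray(chain, dtype=float)
    if lag < 0 or lag >= len(x):
        raise ValueError("lag must satisfy 0 <= lag < len(chain)")
    if np.var(x) == 0:
        warnings.warn("autocorrelation undefined for a constant chain", stacklevel=2)
        return float("nan")
    if lag == 0:
        return 1.0
    a = x[:-lag]
    b = x[lag:]
    return float(np.corrcoef(a, b)[0, 1])


def hpd_interval(draws: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted
    draws; ties go to the lowest start."""
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 draws")
    k = int(math.ceil(mass * n))
    k = min(max(k, 1), n)
    if k == n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest start) tie
    return float(x[i]), float(x[i + k - 1])


def rolling_summary(chain: np.ndarray, window: int) -> pd.DataFrame:
    """Rolling mean and 2.5th/97.5th percentiles over trailing windows."""
    x = pd.Series(np.asarray(chain, dtype=float))
    if window > len(x):
        raise ValueError("window exceeds chain length")
    roll = x.rolling(window)
    out = pd.DataFrame(
        {
            "mean": roll.mean(),
            "q2.5": roll.quantile(0.025),
            "q97.5": roll.quantile(0.975),
        }
    ).dropna()
    out.index.name = "iteration"
    return out


def diagnostics_report(chains: ChainSet, lags: tuple[int, ...] = (1, 5, 10)) -> pd.DataFrame:
    """Per-parameter convergence table: PSRF plus pooled autocorrelations."""
    rows = []
    for name in chains.parameters:
        x = chains.draws[name]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            psrf = gelman_rubin(x)
            acs = {f"acf_lag{lag}": autocorrelation(x.reshape(-1), lag) for lag in lags}
        rows.append(dict(parameter=name, psrf=psrf, **acs))
    return pd.DataFrame(rows)
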