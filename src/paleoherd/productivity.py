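"""Growth curves, lifetime yields, feed costs and herd economics.

Live weight at age x months follows the saturating growth curve

    nu(x) = tau * exp( (a/b) * (1 - exp(-b x)) ),

with birth weight tau and rate/shape parameters a, b; the asymptotic adult
weight is tau * exp(a/b). Parameters are fitted by box-constrained least
squares (tau in [10, 30] kg, a and b in (0, 1]) from age/weight data.

Posterior survivorship (f, m per age class) is interpolated to a monthly
grid and combined with ethnographic constants to give, per animal born:
lifetime milk available for human consumption, meat-and-offal weight (MOW)
at slaughter, protein/fat/calorie totals, a feed-weight proxy for the cost
of keeping the animal, the herd growth rate (animals produced per animal
born), and the economic efficiency of calorie production (kcal per kg of
feed). Efficiency is meaningful only as a relative measure for comparing
kill-off strategies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .data import AgeClassSchema, ProductivityConstants
from .mortality import AncientPosterior

DAYS_PER_MONTH = 365.25 / 12.0


@dataclass(frozen=True)
class DerivedConstants:
    """Constants derived from the ethnographic inputs."""

    milk_per_cow_month: float  # kg, averaged over the calving cycle
    milk_available: float  # kg/month after calf consumption
    birth_prob: float  # per month, post age at first calving
    feed_monthly_fraction: float  # of live weight per month


def derive_constants(c: ProductivityConstants) -> DerivedConstants:
    """Derive cycle-averaged milk, available milk, monthly birth probability
    and the monthly feed fraction from the base constants."""
    milk_per_cow_month = c.milk_suckling * c.suckling_months / c.calving_interval
    return DerivedConstants(
        milk_per_cow_month=milk_per_cow_month,
        milk_available=milk_per_cow_month * (1.0 - c.calf_milk_fraction),
        birth_prob=1.0 / c.calving_interval,
        feed_monthly_fraction=c.feed_daily_fraction * DAYS_PER_MONTH,
    )


def growth_weight(tau: float, a: float, b: float, x: float | np.ndarray) -> float | np.ndarray:
    """Live weight (kg) at age x months: tau * exp((a/b)(1 - e^{-bx}))."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be non-negative")
    out = tau * np.exp((a / b) * (1.0 - np.exp(-b * x)))
    return float(out) if out.ndim == 0 else out


class GrowthCurve(BaseEstimator, RegressorMixin):
    """Box-constrained least-squares fit of the live-weight growth curve.

    Parameters
    ----------
    tau_bounds, a_bounds, b_bounds
        Box constraints; defaults tau in [10, 30] kg, a and b in (0, 1].
    n_grid
        Grid points per parameter for the deterministic multi-start.

    Attributes
    ----------
    tau_, a_, b_ : fitted parameters
    ss_ : residual sum of squares
    at_bounds_ : dict of parameters pinned at a box boundary
    """

    def __init__(
        self,
        tau_bounds: tuple[float, float] = (10.0, 30.0),
        a_bounds: tuple[float, float] = (1e-6, 1.0),
        b_bounds: tuple[float, float] = (1e-6, 1.0),
        n_grid: int = 4,
    ):
        self.tau_bounds = tau_bounds
        self.a_bounds = a_bounds
        self.b_bounds = b_bounds
        self.n_grid = n_grid

    def fit(self, X, y) -> "GrowthCurve":
        ages = np.asarray(X, dtype=float).reshape(-1)
        weights = np.asarray(y, dtype=float).reshape(-1)
        if len(ages) != len(weights) or len(ages) < 3:
            raise ValueError("need at least 3 (age, weight) points")
        if np.ptp(ages) < 12.0:
            raise ValueError("ages must span at least 12 months")
        lo = np.array([self.tau_bounds[0], self.a_bounds[0], self.b_bounds[0]])
        hi = np.array([self.tau_bounds[1], self.a_bounds[1], self.b_bounds[1]])

        def resid(p):
            return growth_weight(p[0], p[1], p[2], ages) - weights

        best = None
        # deterministic multi-start over a log-ish grid inside the box
        taus = np.linspace(lo[0], hi[0], self.n_grid)
        avals = np.geomspace(max(lo[1], 1e-3), hi[1], self.n_grid)
        bvals = np.geomspace(max(lo[2], 1e-3), hi[2], self.n_grid)
        for t0 in taus:
            for a0 in avals:
                for b0 in bvals:
                    try:
                        sol = least_squares(resid, x0=[t0, a0, b0], bounds=(lo, hi))
                    except Exception:
                        continue
                    ss = float(2 * sol.cost)
                    if best is None or ss < best[0] - 1e-12:
                        best = (ss, sol.x)
        if best is None:
            raise RuntimeError("growth-curve fit failed from every start")
        self.ss_, (self.tau_, self.a_, self.b_) = best[0], tuple(best[1])
        tol = 1e-6
        self.at_bounds_ = {
            name: val
            for name, val, (blo, bhi) in (
                ("tau", self.tau_, self.tau_bounds),
                ("a", self.a_, self.a_bounds),
                ("b", self.b_, self.b_bounds),
            )
            if val <= blo + tol or val >= bhi - tol
        }
        if self.at_bounds_:
            warnings.warn(
                f"growth-curve parameters pinned at a box boundary: {sorted(self.at_bounds_)}",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        return growth_weight(self.tau_, self.a_, self.b_, np.asarray(X, dtype=float).reshape(-1))

    @property
    def asymptote_(self) -> float:
        return self.tau_ * math.exp(self.a_ / self.b_)


def fit_growth_curve(ages, weights, **kwargs) -> GrowthCurve:
    """Fit the growth curve; returns the fitted :class:`GrowthCurve`."""
    return GrowthCurve(**kwargs).fit(ages, weights)


@dataclass(frozen=True)
class MonthlySurvival:
    """Per-sex survivorship on a monthly grid.

    ``s_f[x]`` (``s_m[x]``) is the probability that a random newborn is a
    female (male) alive at month x, for x = 0..terminal_cap. Survivorship
    attaches to the upper boundary of each age class and is linearly
    interpolated between boundaries.
    """

    s_f: np.ndarray
    s_m: np.ndarray

    def __post_init__(self) -> None:
        for s in (self.s_f, self.s_m):
            if np.any(np.diff(s) > 1e-12):
                raise ValueError("survivorship must be non-increasing")
            if abs(s[-1]) > 1e-12:
                raise ValueError("survivorship must reach 0 at the terminal cap")

    @property
    def months(self) -> int:
        return len(self.s_f) - 1


def monthly_survival(
    f: np.ndarray, m: np.ndarray, schema: AgeClassSchema, birth_male_fraction: float = 0.5
) -> MonthlySurvival:
    """Interpolate class-level survivorship (f, m of length T*-1) to integer
    months 0..terminal_cap, anchored at (0, 1/2) and forced to 0 at the cap."""
    bounds = schema.boundaries
    xs = np.arange(int(round(schema.terminal_cap)) + 1, dtype=float)
    pts_f = np.concatenate([[1.0 - birth_male_fraction], np.asarray(f, float), [0.0]])
    pts_m = np.concatenate([[birth_male_fraction], np.asarray(m, float), [0.0]])
    s_f = np.interp(xs, bounds, pts_f)
    s_m = np.interp(xs, bounds, pts_m)
    return MonthlySurvival(s_f=s_f, s_m=s_m)


@dataclass(frozen=True)
class YieldSummary:
    """Lifetime yields per animal born, plus feed cost and herd economics."""

    milk_kg: float
    milk_kcal: float
    mow_kg: float
    mow_kcal: float
    protein_kg: float
    fat_kg: float
    total_kcal: float
    feed_kg: float
    herd_growth: float  # animals produced per animal born
    efficiency: float  # kcal per kg feed; NaN when feed is zero

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def lifetime_yields(
    s: MonthlySurvival,
    growth: tuple[float, float, float] | GrowthCurve,
    c: ProductivityConstants | None = None,
) -> YieldSummary:
    """Sum monthly production over a lifetime, weighted by survivorship.

    Milk and births accrue from female survival in months
    [age_first_calving, terminal_cap); MOW accrues at the death month (the
    survival decrement s(x-1) - s(x)) at the weight-for-age then; feed
    accrues for every month an animal of either sex is alive.
    """
    c = c or ProductivityConstants()
    d = derive_constants(c)
    if isinstance(growth, GrowthCurve):
        tau, a, b = growth.tau_, growth.a_, growth.b_
    else:
        tau, a, b = growth
    cap = s.months
    x = np.arange(cap + 1)
    nu = growth_weight(tau, a, b, x)

    female_months = (x >= c.age_first_calving) & (x < cap)
    milk_kg = float(d.milk_available * s.s_f[female_months].sum())
    herd_growth = float(d.birth_prob * s.s_f[female_months].sum())

    d_f = -np.diff(s.s_f)  # deaths in month x = s(x-1) - s(x), x = 1..cap
    d_m = -np.diff(s.s_m)
    mow_kg = float(c.mow_fraction_of_liveweight * ((d_f + d_m) * nu[1:]).sum())
    feed_kg = float(d.feed_monthly_fraction * ((s.s_f[1:] + s.s_m[1:]) * nu[1:]).sum())

    milk_kcal = milk_kg * c.milk_kcal
    mow_kcal = mow_kg * c.mow_kcal
    total_kcal = milk_kcal + mow_kcal
    if feed_kg <= 0:
        warnings.warn("zero feed consumption: efficiency undefined", stacklevel=2)
        efficiency = float("nan")
    else:
        efficiency = total_kcal / feed_kg
    return YieldSummary(
        milk_kg=milk_kg,
        milk_kcal=milk_kcal,
        mow_kg=mow_kg,
        mow_kcal=mow_kcal,
        protein_kg=milk_kg * c.milk_protein + mow_kg * c.mow_protein,
        fat_kg=milk_kg * c.milk_fat + mow_kg * c.mow_fat,
        total_kcal=total_kcal,
        feed_kg=feed_kg,
        herd_growth=herd_growth,
        efficiency=efficiency,
    )


def yields_over_posterior(
    post: AncientPosterior,
    growth: tuple[float, float, float] | GrowthCurve,
    schema: AgeClassSchema,
    c: ProductivityConstants | None = None,
    site: str | None = None,
) -> pd.DataFrame:
    """One YieldSummary row per retained posterior draw for one site."""
    if post.n_draws == 0:
        raise ValueError("empty posterior")
    site = site or post.site_ids[0]
    f_draws = post.f[site]
    m_draws = post.m[site]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(f_draws.shape[0]):
            s = monthly_survival(f_draws[i], m_draws[i], schema)
            rows.append(lifetime_yields(s, growth, c).as_dict())
    return pd.DataFrame(rows)


def joint_mode(x: np.ndarray, y: np.ndarray, gridsize: int = 64) -> tuple[float, float]:
    """Posterior mode of a paired output via the peak of a 2-d Gaussian KDE
    evaluated on a regular grid over the draws."""
    from scipy.stats import gaussian_kde

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 and np.ptp(y) == 0:  # degenerate posterior
        return float(x[0]), float(y[0])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float(np.median(x)), float(np.median(y))
    kde = gaussian_kde(np.vstack([x, y]))
    gx = np.linspace(x.min(), x.max(), gridsize)
    gy = np.linspace(y.min(), y.max(), gridsize)
    gxx, gyy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([gxx.ravel(), gyy.ravel()]))
    i = int(np.argmax(dens))
    return float(gxx.ravel()[i]), float(gyy.ravel()[i])


def joint_summary(
    df: pd.DataFrame, xcol: str, ycol: str, mass: float = 0.95
) -> dict[str, float]:
    """Mode (2-d KDE peak) and per-axis HPD bounds for a paired output."""
    from .diagnostics import hpd_interval

    x = df[xcol].to_numpy()
    y = df[ycol].to_numpy()
    mx, my = joint_mode(x, y)
    if np.ptp(x) == 0:
        xlo = xhi = float(x[0])
    else:
        xlo, xhi = hpd_interval(x, mass)
    if np.ptp(y) == 0:
        ylo = yhi = float(y[0])
    else:
        ylo, yhi = hpd_interval(y, mass)
    return {
        f"{xcol}_mode": mx,
        f"{ycol}_mode": my,
        f"{xcol}_hpd_low": xlo,
        f"{xcol}_hpd_high": xhi,
        f"{ycol}_hpd_low": ylo,
        f"{ycol}_hpd_high": yhi,
    }
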