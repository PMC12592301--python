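"""Synthetic data, validation protocol, and kill-off-strategy search.

Three generators are provided:

* modern herd census tables drawn from the Poisson GLMM itself (herd random
  effects, sex-by-age interaction, log-population offset);
* simulated ancient kill-off datasets with known truths, for checking that
  HPD intervals of the refitted model cover the truth at their nominal rate;
* random kill-off strategies under a sex-asymmetric scenario (draws from the
  model's own generative process, so male-biased juvenile culls are common)
  and a sex-symmetric scenario (flat Dirichlet death proportions split
  equally between the sexes), scored by their lifetime-yield economics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mcmc import truncnorm_rvs
from .data import AgeClassSchema, KillOffProfile, ModernHerdTable, ProductivityConstants
from .mortality import AncientPosterior, MortalityModel
from .productivity import GrowthCurve, lifetime_yields, monthly_survival
from .sexratio import ModernPosterior

DEFAULT_SIZES = (10, 20, 50, 75, 100, 150, 200)
DEFAULT_GROWTH = (20.0, 0.132, 0.075)  # tau kg, a, b: unimproved-herd-like curve


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated kill-off profile with its known truth."""

    truth_theta: np.ndarray
    truth_f: np.ndarray
    truth_m: np.ndarray
    truth_r: np.ndarray
    counts: np.ndarray
    n_total: int
    seed: int
    scenario: str = "validation"

    def profile(self, schema: AgeClassSchema, site_id: str = "sim") -> KillOffProfile:
        return KillOffProfile(
            site_id=site_id, schema=schema, fixed_counts=self.counts.astype(np.int64)
        )


@dataclass(frozen=True)
class StrategyPoint:
    """A random kill-off strategy and its derived economics."""

    female_props: np.ndarray  # deaths per class, female share (sums with male to 1)
    male_props: np.ndarray
    milk_kcal: float
    mow_kcal: float
    total_kcal: float
    feed_kg: float
    herd_growth: float
    efficiency: float
    milk_efficiency: float
    mow_efficiency: float
    scenario: str


def generate_modern_synthetic(
    beta: tuple[float, float, float],
    omega: float,
    n_herds: int,
    schema: AgeClassSchema,
    population: int,
    seed: int | None = None,
    baseline: float = 0.0,
) -> ModernHerdTable:
    """Draw a modern herd census table from the GLMM's generative process.

    Survivor counts are Poisson with the model's linear predictor; draws
    exceeding the population offset are capped at it, with a warning giving
    the number of capped cells.

    ``baseline`` is a common log-rate offset added to every cell. The
    default 0 makes the expected count equal the population offset at age 0
    for an average herd; ``baseline=log(1/2)`` emulates a census in which
    each cell counts one sex out of a whole herd (each sex holds half the
    herd at birth), which keeps rates well below 1 so the Y <= PS cap
    almost never distorts the Poisson draw.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    rng = np.random.default_rng(seed)
    b1, b2, b3 = beta
    t = schema.midpoints
    eta = rng.normal(0.0, omega, size=n_herds) if omega > 0 else np.zeros(n_herds)
    mu = np.exp(
        eta[:, None, None]
        + baseline
        + math.log(population)
        + b1 * t[None, None, :]
        + b2 * np.array([0.0, 1.0])[None, :, None]
        + b3 * np.array([0.0, 1.0])[None, :, None] * t[None, None, :]
    )
    y = rng.poisson(mu)
    n_capped = int(np.sum(y > population))
    if n_capped:
        warnings.warn(f"{n_capped} survivor draws capped at the population size", stacklevel=2)
        y = np.minimum(y, population)
    pop = np.full((n_herds, schema.n_classes), population, dtype=np.int64)
    return ModernHerdTable(
        herd_ids=tuple(f"H{i + 1}" for i in range(n_herds)),
        survivors=y.astype(np.int64),
        population=pop,
        schema=schema,
    )


def _draw_truth(
    rng: np.random.Generator,
    schema: AgeClassSchema,
    pool: np.ndarray,
    f_link_sd: float = 0.1,
    truth_gamma: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One (theta, f, m, r) truth from the model's generative process:
    gamma from its half-normal prior (or a supplied pool of gamma draws),
    theta ~ Dirichlet(gamma), (beta2, beta3) from the modern pool, f from
    its truncated-normal link, m by accounting."""
    T = schema.n_classes
    if truth_gamma is None:
        gamma = np.abs(rng.normal(0.0, math.sqrt(1000.0), size=T))
        gamma = np.maximum(gamma, 1e-3)
    else:
        gamma = truth_gamma[rng.integers(truth_gamma.shape[0])]
    theta = rng.dirichlet(gamma)
    b2, b3 = pool[rng.integers(pool.shape[0])]
    t_mid = schema.midpoints[:-1]
    r = np.exp(b2 + b3 * t_mid)
    s = 1.0 - np.cumsum(theta)[:-1]
    f = np.empty(T - 1)
    m = np.empty(T - 1)
    f_prev, m_prev = 0.5, 0.5
    for j in range(T - 1):
        sj = max(s[j], 0.0)
        lo = max(0.0, sj - m_prev)
        hi = min(f_prev, sj)
        mu = sj / (1.0 + r[j])
        f[j] = truncnorm_rvs(mu, f_link_sd, lo, hi, rng) if hi > lo else lo
        m[j] = sj - f[j]
        f_prev, m_prev = f[j], m[j]
    return theta, f, m, r


def simulate_validation_suite(
    modern_fit: ModernPosterior,
    schema: AgeClassSchema,
    n_truths: int = 50,
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    seed: int | None = None,
    truth_gamma: np.ndarray | None = None,
) -> list[SimulatedDataset]:
    """Simulate kill-off profiles with known truths: ``n_truths`` generative
    truths, one multinomial count vector per sample size each (the default
    50 truths x 7 sizes gives 350 datasets)."""
    if modern_fit.n_draws == 0:
        raise ValueError("modern posterior is empty")
    rng = np.random.default_rng(seed)
    pool = np.column_stack([modern_fit.beta2, modern_fit.beta3])
    out = []
    for i in range(n_truths):
        theta, f, m, r = _draw_truth(rng, schema, pool, truth_gamma=truth_gamma)
        for n in sizes:
            counts = rng.multinomial(n, theta)
            out.append(
                SimulatedDataset(
                    truth_theta=theta,
                    truth_f=f,
                    truth_m=m,
                    truth_r=r,
                    counts=counts,
                    n_total=int(n),
                    seed=-1 if seed is None else int(seed),
                )
            )
    return out


def refit_suite(
    suite: list[SimulatedDataset],
    modern_fit: ModernPosterior,
    schema: AgeClassSchema,
    iterations: int = 11_000,
    burnin: int = 1_000,
    thin: int = 10,
    chains: int = 2,
    seed: int | None = None,
) -> list[AncientPosterior]:
    """Refit the mortality model to every simulated dataset (the scaled-down
    schedule default keeps a refit to a few seconds)."""
    ss = np.random.SeedSequence(seed)
    posts = []
    for ds, child in zip(suite, ss.spawn(len(suite))):
        model = MortalityModel(
            iterations=iterations,
            burnin=burnin,
            thin=thin,
            chains=chains,
            random_state=int(child.generate_state(1)[0] % (2**31)),
        )
        model.fit(ds.profile(schema), modern=modern_fit)
        posts.append(model.posterior_)
    return posts


def coverage_report(
    suite: list[SimulatedDataset],
    refits: list[AncientPosterior],
    levels: tuple[int, ...] = (95, 90, 80, 70, 60, 50, 40, 30, 20, 10),
) -> pd.DataFrame:
    """Empirical HPD coverage of the female survivorship truth.

    For each dataset, age class and nominal level, records whether the HPD
    interval of the refitted posterior of f_j contains the true f_j. Returns
    a long DataFrame (n_total, age_class, level, covered) that can be
    aggregated by size or class.
    """
    from .diagnostics import hpd_interval

    if len(suite) != len(refits):
        raise ValueError("one refit per simulated dataset required")
    rows = []
    for ds, post in zip(suite, refits):
        site = post.site_ids[0]
        f_draws = post.f[site]
        for j in range(f_draws.shape[1]):
            for level in levels:
                lo, hi = hpd_interval(f_draws[:, j], level / 100.0)
                rows.append(
                    dict(
                        n_total=ds.n_total,
                        age_class=j + 1,
                        level=level,
                        covered=bool(lo <= ds.truth_f[j] <= hi),
                    )
                )
    return pd.DataFrame(rows)


def coverage_table(report: pd.DataFrame, by: str = "n_total") -> pd.DataFrame:
    """Pivot a coverage report to empirical coverage proportions."""
    tab = report.groupby([by, "level"])["covered"].mean().unstack("level")
    return tab


def _strategy_from_survival(
    f: np.ndarray,
    m: np.ndarray,
    schema: AgeClassSchema,
    growth: tuple[float, float, float] | GrowthCurve,
    constants: ProductivityConstants | None,
    scenario: str,
) -> StrategyPoint:
    fb = np.concatenate([[0.5], f, [0.0]])
    mb = np.concatenate([[0.5], m, [0.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = monthly_survival(f, m, schema)
        ys = lifetime_yields(s, growth, constants)
    feed = ys.feed_kg
    return StrategyPoint(
        female_props=-np.diff(fb),
        male_props=-np.diff(mb),
        milk_kcal=ys.milk_kcal,
        mow_kcal=ys.mow_kcal,
        total_kcal=ys.total_kcal,
        feed_kg=feed,
        herd_growth=ys.herd_growth,
        efficiency=ys.efficiency,
        milk_efficiency=ys.milk_kcal / feed if feed > 0 else float("nan"),
        mow_efficiency=ys.mow_kcal / feed if feed > 0 else float("nan"),
        scenario=scenario,
    )


def simulate_strategy_sex_asymmetric(
    modern_fit: ModernPosterior,
    schema: AgeClassSchema,
    seed: int | None = None,
    growth: tuple[float, float, float] | GrowthCurve = DEFAULT_GROWTH,
    constants: ProductivityConstants | None = None,
) -> StrategyPoint:
    """One random sex-asymmetric strategy: survivorship drawn from the
    model's generative process (so the male kill tracks the modern sex-ratio
    decline), scored by its yields."""
    if modern_fit.n_draws == 0:
        raise ValueError("modern posterior is empty")
    rng = np.random.default_rng(seed)
    pool = np.column_stack([modern_fit.beta2, modern_fit.beta3])
    _, f, m, _ = _draw_truth(rng, schema, pool)
    return _strategy_from_survival(f, m, schema, growth, constants, "sex-asymmetric")


def simulate_strategy_sex_symmetric(
    schema: AgeClassSchema,
    seed: int | None = None,
    growth: tuple[float, float, float] | GrowthCurve = DEFAULT_GROWTH,
    constants: ProductivityConstants | None = None,
) -> StrategyPoint:
    """One random sex-symmetric strategy: death proportions psi ~ Dir(1)
    with each sex receiving psi/2, scored by its yields."""
    rng = np.random.default_rng(seed)
    psi = rng.dirichlet(np.ones(schema.n_classes))
    surv = 0.5 * (1.0 - np.cumsum(psi))[:-1]
    surv = np.clip(surv, 0.0, 0.5)
    return _strategy_from_survival(surv, surv.copy(), schema, growth, constants, "sex-symmetric")


def pareto_front(points: list[StrategyPoint]) -> list[StrategyPoint]:
    """Pareto-optimal subset maximising (efficiency, herd_growth)."""
    order = sorted(
        (p for p in points if np.isfinite(p.efficiency)),
        key=lambda p: (-p.efficiency, -p.herd_growth),
    )
    front: list[StrategyPoint] = []
    best_growth = -np.inf
    for p in order:
        if p.herd_growth > best_growth:
            front.append(p)
            best_growth = p.herd_growth
    return front


def search_strategies(
    n_sims: int,
    scenario: str,
    schema: AgeClassSchema,
    modern_fit: ModernPosterior | None = None,
    condition_growth_gt_1: bool = False,
    seed: int | None = None,
    growth: tuple[float, float, float] | GrowthCurve = DEFAULT_GROWTH,
    constants: ProductivityConstants | None = None,
) -> tuple[list[StrategyPoint], list[StrategyPoint]]:
    """Random search over kill-off strategies.

    Returns ``(points, front)`` where ``front`` is the Pareto-optimal subset
    on (efficiency, herd growth). With ``condition_growth_gt_1`` only
    herd-sustainable strategies (growth rate > 1) are kept.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if scenario not in ("sex-asymmetric", "sex-symmetric"):
        raise ValueError("scenario must be 'sex-asymmetric' or 'sex-symmetric'")
    if scenario == "sex-asymmetric" and modern_fit is None:
        raise ValueError("sex-asymmetric search needs a modern posterior")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sims)]
    points = []
    for s_i in seeds:
        if scenario == "sex-asymmetric":
            pt = simulate_strategy_sex_asymmetric(
                modern_fit, schema, seed=s_i, growth=growth, constants=constants
            )
        else:
            pt = simulate_strategy_sex_symmetric(
                schema, seed=s_i, growth=growth, constants=constants
            )
        points.append(pt)
    if condition_growth_gt_1:
        points = [p for p in points if p.herd_growth > 1.0]
    return points, pareto_front(points)


def strategy_frame(points: list[StrategyPoint]) -> pd.DataFrame:
    """Tabulate strategy points (one row each)."""
    rows = []
    for p in points:
        row = dict(
            scenario=p.scenario,
            milk_kcal=p.milk_kcal,
            mow_kcal=p.mow_kcal,
            total_kcal=p.total_kcal,
            feed_kg=p.feed_kg,
            herd_growth=p.herd_growth,
            efficiency=p.efficiency,
            milk_efficiency=p.milk_efficiency,
            mow_efficiency=p.mow_efficiency,
        )
        for j, (fp, mp) in enumerate(zip(p.female_props, p.male_props)):
            row[f"female_kill_{j + 1}"] = fp
            row[f"male_kill_{j + 1}"] = mp
        rows.append(row)
    return pd.DataFrame(rows)


def survival_family(lam: float, schema: AgeClassSchema) -> tuple[np.ndarray, np.ndarray]:
    """A one-parameter sex-symmetric survival family for sensitivity grids:
    deaths fall off geometrically across classes with ratio ``lam`` (small
    lam kills early, large lam kills late)."""
    T = schema.n_classes
    w = np.power(float(lam), np.arange(T))
    theta = w / w.sum()
    surv = 0.5 * (1.0 - np.cumsum(theta))[:-1]
    return np.clip(surv, 0.0, 0.5), np.clip(surv.copy(), 0.0, 0.5)
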