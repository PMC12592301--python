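"""Dirichlet-multinomial mortality model with sex partitioning.

Unsexed death counts N_kj for site k over T* ordered age classes are
modelled as multinomial with probabilities theta_k ~ Dirichlet(gamma);
integrating theta out gives the Dirichlet-multinomial (DM) likelihood used
for updating gamma, whose components carry iid half-normal TN(0, 1000; 0, inf)
priors. The population survival after class j is S_kj = 1 - sum_{l<=j}
theta_kl, which is split into female and male survivorship using the
age-dependent sex ratio r(t*) borrowed from the modern herd regression:

    f_kj ~ TN( S_kj / (1 + r(t*_j)), 0.01; lo, hi ),   m_kj = S_kj - f_kj,

with boundary values f_k0 = m_k0 = 1/2 (1:1 sex ratio at birth) and
f_kT* = m_kT* = 0. The truncation interval
(max(0, S_kj - m_k,j-1), min(f_k,j-1, S_kj)) enforces monotone
non-increasing survivorship for both sexes by construction. Individuals
whose age class is ambiguous are imputed from theta restricted to their
candidate classes at every iteration.

Inference is modular ("cut"): each iteration draws (beta2, beta3) from the
stored modern posterior pool instead of re-sampling them jointly, so small
ancient assemblages cannot distort the modern regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from ._mcmc import halfnormal_logpdf, n_retained, truncnorm_rvs
from .data import KillOffProfile
from .sexratio import ModernPosterior

_GAMMA_PRIOR_SD = math.sqrt(1000.0)
_F_LINK_SD = 0.1  # TN variance 0.01


def dm_log_pmf(n: np.ndarray, gamma: np.ndarray) -> float:
    """Log pmf of the Dirichlet-multinomial DM(gamma) at count vector ``n``.

    log [ Gamma(n_+ + 1) Gamma(g_+) / Gamma(n_+ + g_+)
          * prod_j Gamma(n_j + g_j) / (Gamma(g_j) Gamma(n_j + 1)) ]
    """
    n = np.asarray(n, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(n < 0) or not np.allclose(n, np.round(n)):
        raise ValueError("counts must be non-negative integers")
    if np.any(gamma <= 0):
        raise ValueError("all gamma components must be strictly positive")
    n_plus = n.sum()
    g_plus = gamma.sum()
    return float(
        gammaln(n_plus + 1.0)
        + gammaln(g_plus)
        - gammaln(n_plus + g_plus)
        + np.sum(gammaln(n + gamma) - gammaln(gamma) - gammaln(n + 1.0))
    )


def dm_variance_inflation(n_plus: int, gamma_plus: float) -> float:
    """Variance inflation of DM(gamma) counts relative to the multinomial:
    (n_+ + gamma_+) / (1 + gamma_+)."""
    if n_plus < 0:
        raise ValueError("n_plus must be non-negative")
    if gamma_plus <= 0:
        raise ValueError("gamma_plus must be positive")
    return (n_plus + gamma_plus) / (1.0 + gamma_plus)


def survival_from_theta(
    theta: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Central sex-specific survivorship implied by a death profile.

    Given theta on the simplex (length T*) and the sex ratio r_j at the
    midpoints of classes 1..T*-1, the population survival after class j is
    S_j = 1 - cumsum(theta)_j and the central split is f_j = S_j / (1 + r_j),
    m_j = S_j - f_j. The raw split can violate the monotonicity required of
    survivorship when r rises steeply; violations are clipped to the running
    minimum and flagged.

    Returns ``(f, m, clipped)`` with f, m of length T*-1.
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("sex ratio must be finite")
    if len(r) != len(theta) - 1:
        raise ValueError("need one sex-ratio value per non-terminal class")
    s = 1.0 - np.cumsum(theta)[:-1]
    s = np.clip(s, 0.0, None)
    f = s / (1.0 + r)
    m = s - f
    clipped = False
    f_mono = np.minimum.accumulate(np.minimum(f, 0.5))
    if not np.allclose(f_mono, f):
        clipped = True
    f = f_mono
    m = s - f
    m_mono = np.minimum.accumulate(np.minimum(m, 0.5))
    if not np.allclose(m_mono, m):
        clipped = True
        m = m_mono
        f = s - m
    return f, m, clipped


def male_excess_kill(f: np.ndarray, m: np.ndarray, j: int) -> float:
    """Proportion of males killed in class j beyond the female kill there:
    (m_{j-1} - m_j) - (f_{j-1} - f_j), with the 1/2 and 0 boundary values.

    ``f`` and ``m`` are the length-(T*-1) survivorship vectors; ``j`` is a
    1-based class index running to T*.
    """
    fb = np.concatenate([[0.5], f, [0.0]])
    mb = np.concatenate([[0.5], m, [0.0]])
    if not 1 <= j <= len(fb) - 1:
        raise ValueError("class index out of range")
    return float((mb[j - 1] - mb[j]) - (fb[j - 1] - fb[j]))


def impute_assignments(
    theta: np.ndarray, profile: KillOffProfile, rng: np.random.Generator
) -> np.ndarray:
    """Assign each ambiguous individual to one candidate class with
    probability proportional to theta on its candidate set; returns the
    effective count vector (fixed counts plus imputed assignments).

    A candidate set on which theta is entirely zero falls back to a uniform
    assignment (the limit of the proportional rule).
    """
    counts = np.asarray(profile.fixed_counts, dtype=np.int64).copy()
    for cand in profile.ambiguous:
        idx = np.asarray(sorted(cand))
        w = np.asarray(theta, dtype=float)[idx]
        tot = w.sum()
        if tot <= 0:
            w = np.ones(len(idx)) / len(idx)
        else:
            w = w / tot
        counts[idx[rng.choice(len(idx), p=w)]] += 1
    return counts


@dataclass(frozen=True)
class AncientPosterior:
    """Retained draws from the ancient mortality sampler.

    Arrays are stacked over retained iterations; site-indexed quantities are
    dictionaries keyed by site id.
    """

    site_ids: tuple[str, ...]
    gamma: np.ndarray  # (n_draws, T*)
    theta: dict[str, np.ndarray]  # site -> (n_draws, T*)
    f: dict[str, np.ndarray]  # site -> (n_draws, T*-1)
    m: dict[str, np.ndarray]  # site -> (n_draws, T*-1)
    male_excess: dict[str, np.ndarray]  # site -> (n_draws, T*)
    beta2: np.ndarray  # (n_draws,)
    beta3: np.ndarray  # (n_draws,)
    chain: np.ndarray  # (n_draws,)
    midpoints: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_draws(self) -> int:
        return self.gamma.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"chain": self.chain, "beta2": self.beta2, "beta3": self.beta3}
        for j in range(self.gamma.shape[1]):
            cols[f"gamma_{j + 1}"] = self.gamma[:, j]
        for site in self.site_ids:
            for j in range(self.theta[site].shape[1]):
                cols[f"theta_{site}_{j + 1}"] = self.theta[site][:, j]
            for j in range(self.f[site].shape[1]):
                cols[f"f_{site}_{j + 1}"] = self.f[site][:, j]
                cols[f"m_{site}_{j + 1}"] = self.m[site][:, j]
            for j in range(self.male_excess[site].shape[1]):
                cols[f"mxk_{site}_{j + 1}"] = self.male_excess[site][:, j]
        return pd.DataFrame(cols)

    def summary(self, hpd_mass: float = 0.95) -> pd.DataFrame:
        """Posterior mean/median/HPD per parameter."""
        from .diagnostics import hpd_interval

        rows = []
        df = self.to_frame().drop(columns=["chain"])
        for col in df.columns:
            x = df[col].to_numpy()
            lo, hi = hpd_interval(x, hpd_mass)
            rows.append(
                dict(parameter=col, mean=x.mean(), median=np.median(x), hpd_low=lo, hpd_high=hi)
            )
        return pd.DataFrame(rows)


class MortalityModel(BaseEstimator):
    """Gibbs/Metropolis sampler for sex-partitioned mortality profiles.

    Per iteration: (beta2, beta3) are drawn from the modern posterior pool;
    ambiguous individuals are re-imputed from theta; each log gamma_j takes a
    random-walk Metropolis step against the DM likelihood (summed over sites
    sharing gamma) times its half-normal prior; each theta_k is then drawn
    exactly from its collapsed conditional Dirichlet(gamma + n_k); finally
    each f_kj is drawn from its truncated-normal conditional given the new
    theta and m_kj set to S_kj - f_kj. Because the f-link density is
    normalised for every theta, f marginalises out of the gamma and theta
    updates, making the scan a valid partially collapsed Gibbs sampler (for
    a profile without ambiguous individuals it draws the joint posterior by
    exact composition).

    Parameters
    ----------
    iterations, burnin, thin, chains
        MCMC schedule (defaults mirror the production schedule: 2 x 110,000
        iterations, 10,000 burn-in, thinning 10 -> 20,000 retained draws).
    f_link_sd
        Standard deviation of the truncated-normal link between f and the
        central sex-ratio split (default 0.1, i.e. variance 0.01).
    birth_male_fraction
        Sex ratio at birth as the male fraction (default 0.5, i.e. 1:1;
        empirical estimates run 0.51-0.53).
    random_state
        Seed.

    Attributes
    ----------
    posterior_ : AncientPosterior
    chains_ : dict[str, np.ndarray] per-parameter (chains, draws) arrays for
        the shared parameters (gamma components).
    """

    def __init__(
        self,
        iterations: int = 110_000,
        burnin: int = 10_000,
        thin: int = 10,
        chains: int = 2,
        f_link_sd: float = _F_LINK_SD,
        birth_male_fraction: float = 0.5,
        random_state: int | None = None,
    ):
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.chains = chains
        self.f_link_sd = f_link_sd
        self.birth_male_fraction = birth_male_fraction
        self.random_state = random_state

    def fit(
        self,
        X: list[KillOffProfile] | KillOffProfile,
        y=None,
        modern: ModernPosterior | None = None,
        sex_ratio_pool: np.ndarray | None = None,
    ) -> "MortalityModel":
        """Sample the posterior for one or more kill-off profiles.

        ``modern`` supplies the (beta2, beta3) pool; alternatively
        ``sex_ratio_pool`` may give an explicit (n, 2) array of (beta2,
        beta3) pairs (a single pair fixes the sex ratio).
        """
        profiles = [X] if isinstance(X, KillOffProfile) else list(X)
        if not profiles:
            raise ValueError("no kill-off profiles given")
        schema = profiles[0].schema
        for p in profiles:
            if p.schema != schema:
                raise ValueError("all profiles in one fit must share an age-class schema")
        if modern is not None:
            pool = np.column_stack([modern.beta2, modern.beta3])
        elif sex_ratio_pool is not None:
            pool = np.atleast_2d(np.asarray(sex_ratio_pool, dtype=float))
        else:
            raise ValueError("either a modern posterior or a sex_ratio_pool is required")
        if pool.shape[0] < 1 or pool.shape[1] != 2:
            raise ValueError("sex-ratio pool must be a non-empty (n, 2) array")

        n_keep = n_retained(self.iterations, self.burnin, self.thin, 1)
        t_mid = schema.midpoints[:-1]  # r is needed for classes 1..T*-1
        ss = np.random.SeedSequence(self.random_state)
        results = []
        for c, child in enumerate(ss.spawn(self.chains)):
            rng = np.random.default_rng(child)
            results.append(self._run_chain(rng, profiles, pool, t_mid, n_keep))

        T = schema.n_classes
        self.chains_ = {
            f"gamma_{j + 1}": np.stack([res["gamma"][:, j] for res in results])
            for j in range(T)
        }
        self.posterior_ = AncientPosterior(
            site_ids=tuple(p.site_id for p in profiles),
            gamma=np.concatenate([res["gamma"] for res in results]),
            theta={
                p.site_id: np.concatenate([res["theta"][k] for res in results])
                for k, p in enumerate(profiles)
            },
            f={
                p.site_id: np.concatenate([res["f"][k] for res in results])
                for k, p in enumerate(profiles)
            },
            m={
                p.site_id: np.concatenate([res["m"][k] for res in results])
                for k, p in enumerate(profiles)
            },
            male_excess={
                p.site_id: np.concatenate([res["mxk"][k] for res in results])
                for k, p in enumerate(profiles)
            },
            beta2=np.concatenate([res["beta2"] for res in results]),
            beta3=np.concatenate([res["beta3"] for res in results]),
            chain=np.concatenate(
                [np.full(n_keep, c, dtype=int) for c in range(self.chains)]
            ),
            midpoints=schema.midpoints,
        )
        return self

    # ------------------------------------------------------------------
    def _run_chain(self, rng, profiles, pool, t_mid, n_keep):
        M = len(profiles)
        T = profiles[0].schema.n_classes
        p = T - 1
        sd = self.f_link_sd
        f0 = self.birth_male_fraction  # male share at birth
        female0 = 1.0 - f0

        # start gamma from its prior (overdispersed relative to any posterior)
        gamma = np.maximum(np.abs(rng.normal(0.0, _GAMMA_PRIOR_SD, size=T)), 1e-3)
        counts = [np.asarray(pr.fixed_counts, dtype=np.int64).copy() for pr in profiles]
        # start with uniform imputation of ambiguous individuals
        for k, pr in enumerate(profiles):
            for cand in pr.ambiguous:
                idx = sorted(cand)
                counts[k][idx[rng.integers(len(idx))]] += 1
        theta = [rng.dirichlet(gamma + counts[k]) for k in range(M)]
        f = [None] * M
        m = [None] * M

        step = np.full(T, 0.5)  # log-gamma RW step sizes, tuned in burn-in
        acc = np.zeros(T)
        tries = np.zeros(T)

        out = {
            "gamma": np.empty((n_keep, T)),
            "theta": [np.empty((n_keep, T)) for _ in range(M)],
            "f": [np.empty((n_keep, p)) for _ in range(M)],
            "m": [np.empty((n_keep, p)) for _ in range(M)],
            "mxk": [np.empty((n_keep, T)) for _ in range(M)],
            "beta2": np.empty(n_keep),
            "beta3": np.empty(n_keep),
        }

        kept = 0
        for it in range(self.iterations):
            # --- sex ratio draw from the modern pool (cut inference)
            b2, b3 = pool[rng.integers(pool.shape[0])]
            r = np.exp(b2 + b3 * t_mid)

            # --- impute ambiguous individuals given theta
            for k, pr in enumerate(profiles):
                if pr.ambiguous:
                    counts[k] = impute_assignments(theta[k], pr, rng)

            # --- gamma update: per-coordinate Metropolis against the
            #     collapsed (theta-marginalised) DM likelihood, alternating
            #     a log-scale random walk with an independence proposal from
            #     the half-normal prior (whose density cancels, leaving a
            #     pure likelihood ratio) to traverse the weakly identified
            #     direction/magnitude space quickly
            dm_cur = sum(dm_log_pmf(counts[k], gamma) for k in range(M))
            for j in range(T):
                prop = gamma.copy()
                if (it + j) % 2 == 0:
                    prop[j] = gamma[j] * math.exp(step[j] * rng.standard_normal())
                    dm_prop = sum(dm_log_pmf(counts[k], prop) for k in range(M))
                    logr = (
                        dm_prop
                        - dm_cur
                        + halfnormal_logpdf(prop[j], _GAMMA_PRIOR_SD)
                        - halfnormal_logpdf(gamma[j], _GAMMA_PRIOR_SD)
                        + math.log(prop[j])
                        - math.log(gamma[j])  # Jacobian of the log transform
                    )
                    tries[j] += 1
                    if math.log(rng.random()) < logr:
                        gamma = prop
                        dm_cur = dm_prop
                        acc[j] += 1
                else:
                    prop[j] = abs(rng.normal(0.0, _GAMMA_PRIOR_SD))
                    if prop[j] <= 0:
                        continue
                    dm_prop = sum(dm_log_pmf(counts[k], prop) for k in range(M))
                    if math.log(rng.random()) < dm_prop - dm_cur:
                        gamma = prop
                        dm_cur = dm_prop
            if it < self.burnin and (it + 1) % 200 == 0:
                rate = np.where(tries > 0, acc / np.maximum(tries, 1), 0.3)
                step *= np.exp(np.clip(rate - 0.3, -0.5, 0.5))
                acc[:] = 0
                tries[:] = 0

            # --- theta: exact collapsed conditional (f marginalises out)
            for k in range(M):
                theta[k] = rng.dirichlet(gamma + counts[k])

            # --- f: truncated-normal conditional given the new theta;
            #     m by the accounting identity m = S - f
            for k in range(M):
                s = 1.0 - np.cumsum(theta[k])
                fk = np.empty(p)
                mk = np.empty(p)
                f_prev, m_prev = female0, f0
                for j in range(p):
                    sj = max(s[j], 0.0)
                    lo = max(0.0, sj - m_prev)
                    hi = min(f_prev, sj)
                    mu = sj / (1.0 + r[j])
                    fk[j] = truncnorm_rvs(mu, sd, lo, hi, rng) if hi > lo else lo
                    mk[j] = sj - fk[j]
                    f_prev, m_prev = fk[j], mk[j]
                f[k], m[k] = fk, mk

            if it >= self.burnin and (it - self.burnin) % self.thin == 0 and kept < n_keep:
                out["gamma"][kept] = gamma
                out["beta2"][kept] = b2
                out["beta3"][kept] = b3
                for k in range(M):
                    out["theta"][k][kept] = theta[k]
                    out["f"][k][kept] = f[k]
                    out["m"][k][kept] = m[k]
                    fb = np.concatenate([[female0], f[k], [0.0]])
                    mb = np.concatenate([[f0], m[k], [0.0]])
                    out["mxk"][k][kept] = -np.diff(mb) + np.diff(fb)
                kept += 1
        return out


def fit_ancient(
    profiles: list[KillOffProfile] | KillOffProfile,
    modern: ModernPosterior | None = None,
    iterations: int = 110_000,
    burnin: int = 10_000,
    thin: int = 10,
    chains: int = 2,
    seed: int | None = None,
    **kwargs,
) -> AncientPosterior:
    """Fit the ancient mortality model; see :class:`MortalityModel`."""
    model = MortalityModel(
        iterations=iterations,
        burnin=burnin,
        thin=thin,
        chains=chains,
        random_state=seed,
        **{k: v for k, v in kwargs.items() if k in ("f_link_sd", "birth_male_fraction")},
    )
    model.fit(profiles, modern=modern, sex_ratio_pool=kwargs.get("sex_ratio_pool"))
    return model.posterior_
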