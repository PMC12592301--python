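"""Bayesian Poisson regression for the age-dependent sex ratio.

Modern unimproved herds record how many males and females are alive at each
age. Survivor counts are modelled as

    Y_sij ~ Poisson(mu_sij),
    log mu_sij = eta_i + log PS_ij + beta1 * t_j + beta2 * Sex_si
                 + beta3 * Sex_si * t_j,

with the log population size as an offset (coefficient fixed at 1), vague
N(0, 10000) priors on the regression coefficients, herd random effects
eta_i ~ N(0, omega^2) and omega ~ Uniform(0, 100). The fitted male main
effect and sex-by-age interaction give the sex ratio (males per female)

    r(t) = exp(beta2 + beta3 * t),

which is what the ancient mortality model borrows.

Posterior sampling is by single-site slice sampling for the log-concave
beta/eta conditionals and for omega.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._mcmc import n_retained, slice_sample
from .data import ModernHerdTable

_BETA_PRIOR_VAR = 10000.0
_OMEGA_UPPER = 100.0


@dataclass(frozen=True)
class ModernPosterior:
    """Retained MCMC draws from the modern sex-ratio regression."""

    beta1: np.ndarray  # (n_draws,) per-month log-rate slope (female baseline)
    beta2: np.ndarray  # (n_draws,) male main effect
    beta3: np.ndarray  # (n_draws,) sex-by-age interaction, per month
    eta: np.ndarray  # (n_draws, n_herds) herd random effects
    omega: np.ndarray  # (n_draws,) random-effect scale
    chain: np.ndarray  # (n_draws,) chain index of each draw
    herd_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.omega <= 0):
            raise ValueError("omega must be positive in every draw")

    @property
    def n_draws(self) -> int:
        return len(self.beta1)

    def sex_ratio(self, t: float | np.ndarray, idx: int | None = None) -> np.ndarray:
        """r(t) = exp(beta2 + beta3 t) per draw (or for one draw ``idx``)."""
        t = np.asarray(t, dtype=float)
        if idx is not None:
            return np.exp(self.beta2[idx] + self.beta3[idx] * t)
        return np.exp(self.beta2[:, None] + np.outer(self.beta3, t))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chain": self.chain, "beta1": self.beta1, "beta2": self.beta2, "beta3": self.beta3}
        )
        for h, hid in enumerate(self.herd_ids):
            df[f"eta_{hid}"] = self.eta[:, h]
        df["omega"] = self.omega
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ModernPosterior":
        eta_cols = [c for c in df.columns if c.startswith("eta_")]
        return cls(
            beta1=df["beta1"].to_numpy(float),
            beta2=df["beta2"].to_numpy(float),
            beta3=df["beta3"].to_numpy(float),
            eta=df[eta_cols].to_numpy(float),
            omega=df["omega"].to_numpy(float),
            chain=df["chain"].to_numpy(int) if "chain" in df else np.zeros(len(df), int),
            herd_ids=tuple(c[len("eta_") :] for c in eta_cols),
        )


def sex_ratio(beta2: float, beta3: float, t_star: float | np.ndarray) -> float | np.ndarray:
    """Sex ratio r(t*) = exp(beta2 + beta3 t*), males per female."""
    if np.any(np.asarray(t_star) < 0):
        raise ValueError("t_star must be non-negative")
    return np.exp(beta2 + beta3 * np.asarray(t_star, dtype=float))


def linear_predictor(
    table: ModernHerdTable,
    beta1: float,
    beta2: float,
    beta3: float,
    eta: np.ndarray,
    cell: tuple[int, int, int],
) -> float:
    """log mu for one (herd, sex, class) cell under given parameter values."""
    i, s, j = cell
    if s not in (0, 1):
        raise ValueError("sex must be 0 or 1")
    t = table.schema.midpoints[j]
    return float(
        eta[i] + math.log(table.population[i, j]) + beta1 * t + beta2 * s + beta3 * s * t
    )


class SexRatioGLMM(BaseEstimator):
    """Poisson GLMM for sex-by-age survivor counts with a log-population offset.

    Parameters
    ----------
    iterations, burnin, thin, chains
        MCMC schedule. The default mirrors the production schedule:
        2 chains x 110,000 iterations, 10,000 burn-in, thinning 10, which
        retains 20,000 draws. Tests and quick runs should scale this down.
    random_state
        Seed for the sampler.

    Attributes
    ----------
    posterior_ : ModernPosterior
        Retained draws of (beta1, beta2, beta3, eta, omega).
    chains_ : dict[str, np.ndarray]
        Per-parameter arrays of shape (chains, draws_per_chain) for
        convergence diagnostics.
    """

    def __init__(
        self,
        iterations: int = 110_000,
        burnin: int = 10_000,
        thin: int = 10,
        chains: int = 2,
        random_state: int | None = None,
    ):
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.chains = chains
        self.random_state = random_state

    def fit(self, X: ModernHerdTable, y=None) -> "SexRatioGLMM":
        table = X
        if table.n_herds < 2:
            import warnings

            warnings.warn(
                "omega (herd random-effect scale) is weakly identified with fewer than 2 herds",
                stacklevel=2,
            )
        n_keep = n_retained(self.iterations, self.burnin, self.thin, 1)

        # flatten cells once; the likelihood is a sum over all cells
        n_h, _, n_j = table.survivors.shape
        t = table.schema.midpoints
        herd_idx = np.repeat(np.arange(n_h), 2 * n_j)
        sex = np.tile(np.repeat([0.0, 1.0], n_j), n_h)
        tt = np.tile(t, 2 * n_h)
        y_obs = table.survivors.reshape(-1).astype(float)
        log_ps = np.log(table.population[:, None, :] * np.ones((1, 2, 1))).reshape(-1)
        if not np.all(np.isfinite(log_ps)):
            raise ValueError("non-finite offset: population sizes must be positive")
        sex_t = sex * tt
        herd_cells = [np.flatnonzero(herd_idx == h) for h in range(n_h)]

        ss = np.random.SeedSequence(self.random_state)
        child_seeds = ss.spawn(self.chains)
        keep: dict[str, list[np.ndarray]] = {k: [] for k in ("beta1", "beta2", "beta3", "omega")}
        keep_eta: list[np.ndarray] = []
        chain_ids: list[np.ndarray] = []

        for c in range(self.chains):
            rng = np.random.default_rng(child_seeds[c])
            res = self._run_chain(
                rng, n_keep, y_obs, log_ps, tt, sex, sex_t, herd_idx, herd_cells, n_h
            )
            for k in ("beta1", "beta2", "beta3", "omega"):
                keep[k].append(res[k])
            keep_eta.append(res["eta"])
            chain_ids.append(np.full(n_keep, c, dtype=int))

        self.chains_ = {k: np.stack(v) for k, v in keep.items()}
        self.posterior_ = ModernPosterior(
            beta1=np.concatenate(keep["beta1"]),
            beta2=np.concatenate(keep["beta2"]),
            beta3=np.concatenate(keep["beta3"]),
            eta=np.concatenate(keep_eta),
            omega=np.concatenate(keep["omega"]),
            chain=np.concatenate(chain_ids),
            herd_ids=table.herd_ids,
        )
        self.n_features_in_ = 3
        return self

    def _run_chain(
        self, rng, n_keep, y_obs, log_ps, tt, sex, sex_t, herd_idx, herd_cells, n_h
    ) -> dict[str, np.ndarray]:
        beta = np.zeros(3)
        eta = np.zeros(n_h)
        omega = 1.0

        def loglik_full(b1, b2, b3, eta_vec):
            lp = eta_vec[herd_idx] + log_ps + b1 * tt + b2 * sex + b3 * sex_t
            return float(y_obs @ lp - np.exp(lp).sum())

        out = {
            "beta1": np.empty(n_keep),
            "beta2": np.empty(n_keep),
            "beta3": np.empty(n_keep),
            "omega": np.empty(n_keep),
            "eta": np.empty((n_keep, n_h)),
        }
        kept = 0
        widths = (0.05, 0.5, 0.05)
        for it in range(self.iterations):
            for k in range(3):

                def logf(v, k=k):
                    b = beta.copy()
                    b[k] = v
                    return loglik_full(b[0], b[1], b[2], eta) - v * v / (2 * _BETA_PRIOR_VAR)

                beta[k] = slice_sample(beta[k], logf, widths[k], rng)

            for h in range(n_h):
                cells = herd_cells[h]
                base = log_ps[cells] + beta[0] * tt[cells] + beta[1] * sex[cells] + beta[2] * sex_t[cells]
                yh = y_obs[cells]
                ysum = float(yh.sum())

                def logf_eta(v):
                    return v * ysum - float(np.exp(base + v).sum()) - v * v / (2 * omega * omega)

                eta[h] = slice_sample(eta[h], logf_eta, 0.3, rng)

            sq = float(eta @ eta)

            def logf_omega(w):
                if not 0.0 < w < _OMEGA_UPPER:
                    return -math.inf
                return -n_h * math.log(w) - sq / (2 * w * w)

            omega = slice_sample(omega, logf_omega, 0.5, rng)

            if it >= self.burnin and (it - self.burnin) % self.thin == 0 and kept < n_keep:
                out["beta1"][kept] = beta[0]
                out["beta2"][kept] = beta[1]
                out["beta3"][kept] = beta[2]
                out["omega"][kept] = omega
                out["eta"][kept] = eta
                kept += 1
        return out

    def fitted_rates(self, table: ModernHerdTable) -> np.ndarray:
        """Posterior-mean survival rates mu/PS per cell (n_herds, 2, n_classes)."""
        post = self.posterior_
        t = table.schema.midpoints
        lp = (
            post.eta.mean(axis=0)[:, None, None]
            + post.beta1.mean() * t[None, None, :]
            + post.beta2.mean() * np.array([0.0, 1.0])[None, :, None]
            + post.beta3.mean() * np.array([0.0, 1.0])[None, :, None] * t[None, None, :]
        )
        return np.exp(lp)


def fit_modern(
    table: ModernHerdTable,
    iterations: int = 110_000,
    burnin: int = 10_000,
    thin: int = 10,
    chains: int = 2,
    seed: int | None = None,
) -> ModernPosterior:
    """Fit the modern sex-ratio GLMM and return its posterior draws."""
    model = SexRatioGLMM(
        iterations=iterations, burnin=burnin, thin=thin, chains=chains, random_state=seed
    )
    model.fit(table)
    return model.posterior_
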