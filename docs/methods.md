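# Methods

## Problem

Archaeological cattle kill-off profiles record how many animals (MNI) died
in each of a set of ordered age classes, but almost never the animals' sex.
Milk yield, herd growth and the economics of a slaughter strategy depend on
sex-specific survivorship: females are kept for reproduction and milking,
males are typically culled young. `paleoherd` infers sex-specific survival
curves from unsexed death counts by borrowing the age trajectory of the sex
ratio from census data on modern unimproved herds, then converts posterior
survival curves into lifetime product yields and herd economics.

## Modern sex-ratio regression

For herd *i*, sex *s* and age class *j* with midpoint *t_j* (months), the
number of surviving animals is modelled as

    Y_sij ~ Poisson(mu_sij)
    log mu_sij = eta_i + log PS_ij + beta1 t_j + beta2 Sex_si + beta3 Sex_si t_j

with `PS_ij` a population-size offset (coefficient fixed at 1), vague
N(0, 10000) priors on the coefficients, herd random effects
`eta_i ~ N(0, omega^2)` and `omega ~ Uniform(0, 100)`. The male/female sex
ratio at age *t* is `r(t) = exp(beta2 + beta3 t)`; with `beta3 < 0` males
are progressively depleted with age. `beta1` (the female baseline age
slope) is fitted but not used by `r(t)`; it is retained for posterior
predictive checks.

All conditionals (`beta`, `eta`, and `omega`) are log-concave or univariate
and are updated by Neal's slice sampler with stepping-out. Slice sampling
targets each conditional exactly, requires no envelope construction or
proposal tuning, and is as fast here as rejection-based alternatives, which
is why it is used uniformly rather than mixing update types per parameter.

## Ancient mortality model

Unsexed death counts `N_k = (N_k1 .. N_kT*)` for site *k* are multinomial
with death probabilities `theta_k ~ Dirichlet(gamma)`; integrating
`theta_k` out gives the Dirichlet-multinomial likelihood used to update
`gamma`, whose components carry iid half-normal TN(0, 1000; 0, inf) priors.
The DM inflates multinomial variance by `(n_+ + gamma_+) / (1 + gamma_+)`,
accommodating overdispersion. (The DM pmf is implemented in its standard
normalised form, with `Gamma(n_j + gamma_j)` in the product numerator.)

Population survival after class *j* is `S_kj = 1 - sum_{l<=j} theta_kl`.
Sex-specific survivorship uses the borrowed sex ratio at the class midpoint:

    f_kj ~ TN( S_kj / (1 + r(t*_j)), 0.01; lo_kj, hi_kj ),   m_kj = S_kj - f_kj

with boundaries `f_k0 = m_k0 = 1/2` (1:1 sex ratio at birth, configurable
via `birth_male_fraction` to admit the empirical 51-53% male range) and
`f_kT* = m_kT* = 0`. The truncation interval

    lo_kj = max(0, S_kj - m_k,j-1),    hi_kj = min(f_k,j-1, S_kj)

tightens the nominal (0, f_k,j-1) interval so that *both* monotonicity
constraints (f and m non-increasing) hold by construction; the interval is
never empty because `S_kj <= f_k,j-1 + m_k,j-1`. The TN variance 0.01
(sd 0.1) is applied independently per class. The accounting identity
`m = S - f` is preserved exactly, so the m/f ratio — the quantity the sex
ratio models — absorbs the TN noise.

Individuals recorded in several adjacent age classes are imputed each
iteration: an individual with candidate set C is assigned to class j in C
with probability `theta_kj / sum_{l in C} theta_kl` (uniform fallback when
theta vanishes on C).

### Sampler

Inference is modular ("cut"): each iteration draws `(beta2, beta3)` from
the stored modern posterior pool rather than re-sampling them jointly with
the ancient data, so small ancient assemblages cannot distort the modern
regression. Each scan then performs

1. impute ambiguous individuals given `theta`;
2. `gamma`: per-coordinate random-walk Metropolis on the log scale against
   the collapsed DM likelihood (summed over sites sharing `gamma`) times
   the half-normal prior, step sizes adapted toward ~30% acceptance during
   burn-in then frozen;
3. `theta_k ~ Dirichlet(gamma + n_k)` — its exact collapsed conditional;
4. `f_kj` sequentially from its truncated normal, `m_kj = S_kj - f_kj`.

Because the f-link density is normalised for every `theta`, `f`
marginalises exactly out of steps 2-3, making the scan a valid partially
collapsed Gibbs sampler; for a profile without ambiguous individuals it
draws the joint posterior by exact composition. An earlier variant that
Metropolis-corrected the `theta` draw against the stale `f` was found to be
non-invariant — HPD coverage of `f` on the simulate-and-refit suite sat
~10 points below nominal and did not improve with 4x longer chains — and
was replaced by the composition scan, after which coverage is nominal.

When several sites are fitted together they share one `gamma`
(hierarchical pooling); per-site fits are obtained by running sites
separately.

Default schedule (both samplers): 2 chains x 110,000 iterations, 10,000
burn-in, thinning 10 — 20,000 retained draws. Tests and the validation
suite use shortened schedules (noted below).

## Diagnostics

Classical two-variance Gelman-Rubin PSRF (no splitting or
rank-normalisation; degenerate zero-variance chains reported as NaN with a
warning), lag autocorrelation, rolling mean/2.5%/97.5% summaries, and HPD
intervals by the empirical shortest-window method over sorted draws with
ties broken at the lowest start. These exact conventions are pinned by
tests (including a cross-check of the PSRF against `arviz.rhat` on
well-mixed chains, where the conventions agree).

## Validation protocol

Truths are drawn from the model's own generative process: `gamma` from its
half-normal prior, `theta ~ Dirichlet(gamma)`, `(beta2, beta3)` from the
modern posterior pool, `f` through the truncated-normal link; one
multinomial count vector per sample size `n in {10, 20, 50, 75, 100, 150,
200}` for each of 50 truths (350 profiles at the default design). Drawing
truths from the prior actually used in refitting makes HPD coverage
exactly calibrated in expectation, which is what the coverage report
checks. The desk-scale configuration (10 truths, sizes {20, 200}, refits
of 11,000 iterations / 1,000 burn-in / thin 10) keeps the whole check
under a few minutes on one CPU; the full design remains available through
`paleoherd validate --chains-profile full`.

## Productivity model

Live weight at age *x* months follows `nu(x) = tau exp((a/b)(1 - e^{-bx}))`
(birth weight `tau`, asymptote `tau e^{a/b}`), fitted by box-constrained
least squares (`tau` in [10, 30] kg, `a, b` in (0, 1]) with a
deterministic multi-start grid; parameters pinned at a box boundary are
flagged.

Ethnographic constants (defaults, unimproved African herds): milk while
suckling 42.3 kg/month, suckling period 9.18 months, calving interval
18.36 months, age at first calving 42 months, calf milk share 68.4%, MOW
(meat-and-offal) 49.95% of live weight, daily feed 2.475% of live weight,
milk 0.0333/0.0375 kg protein/fat and 670 kcal per kg, MOW 0.1942/0.1273
kg protein/fat and 1980 kcal per kg. Derived: cycle-averaged milk
42.3 x 9.18 / 18.36 = 21.15 kg/month (21.13 in the source tables —
rounding in unreported intermediate averages; both round to the same 6.68
kg/month available milk), birth probability 1/18.36 ~ 0.0545 per month,
feed 2.475% x 365.25/12 = 75.33% of live weight per month.

Class-level survivorship attaches to the upper boundary of each age class
(f_kj is "still alive in class j"), is anchored at (0, 1/2), forced to 0
at the schema's terminal cap, and linearly interpolated to integer months —
the monthly grid the yield sums need; no interpolation rule is canonical,
and piecewise-linear is the least-structured choice. Per animal born:

* milk: `sum_{x in [AFC, cap)} s_f(x) * milk_available` — the cycle
  structure is collapsed into the pre-averaged available-milk rate over all
  post-AFC female months;
* herd growth: same sum with the monthly birth probability — animals
  produced per animal born (>1 means a growing herd); the newborn
  denominator includes both sexes through the 1/2 survivorship boundaries;
* MOW: deaths in month x are the survival decrement `s(x-1) - s(x)`,
  slaughtered at weight `nu(x)`, times the MOW fraction;
* feed: every month an animal is alive (x = 1..cap) costs
  `nu(x) * feed_monthly_fraction` — a relative proxy for keeping cost,
  never an absolute ration;
* efficiency: total kcal (milk + MOW) per kg feed; undefined (NaN, with a
  warning) when no animal outlives month 0. Efficiency comparisons are
  meaningful only relatively, across strategies under the same constants.

The terminal age of an open-ended last class must be set by the schema's
`terminal_cap`; the default is 144 months (a 12-year maximum working life
is typical for unimproved cattle, and the monthly sums need a finite
horizon).

## Strategy search

Two random kill-off scenarios, scored by the yields above: sex-asymmetric
(survivorship drawn from the model's generative process, so male-biased
juvenile culls follow the modern sex-ratio decline) and sex-symmetric
(death proportions `psi ~ Dirichlet(1)`, each sex receiving `psi/2`). The
search reports all points and the Pareto-optimal subset on (efficiency,
herd growth), optionally conditioned on herd growth > 1 (sustainability).
The default number of simulations is 20,000 per scenario (the source
analyses report both 20,000 and 100,000; the smaller figure is the default
and the count is configurable).

## Synthetic modern censuses

`generate_modern_synthetic` draws herd effects `eta_i ~ N(0, omega^2)` and
Poisson survivor counts from the model's linear predictor, capping draws at
the population offset (with a warning) to respect `Y <= PS`. With the
default zero baseline the expected count at age 0 equals `PS`, so the cap
truncates the upper Poisson tail of near-baseline cells; fixtures that are
meant to be capping-free (parameter-recovery oracles) pass
`baseline = log(1/2)`, emulating a census in which each cell counts one sex
out of a whole herd. What the generator does not emulate: age-dependent
population offsets, missing cells, non-Poisson overdispersion within herd,
and real tooth-wear misclassification — passing recovery tests therefore
show sampler correctness under the model, not robustness to those features.

## Numerical choices

* Truncated-normal draws by inverse CDF (`ndtri`), degenerate intervals
  (CDF mass < 1e-14) collapse to the clipped mean.
* `survival_from_theta` central values can violate monotonicity when r(t)
  rises; they are repaired by a two-pass running-minimum clip (f then m,
  recomputing the partner from `f + m = S`) and flagged. The sampler itself
  never needs the repair — its truncation bounds enforce monotonicity.
* Growth-curve fits run `scipy.optimize.least_squares` from a fixed 4x4x4
  start grid; ties broken by first minimum, so fits are deterministic.
* Imputation with all-zero theta on a candidate set falls back to uniform
  (the limit of the proportional rule).
* All seeds flow through `numpy.random.SeedSequence` spawning, so chains,
  replicates and suites are independently and reproducibly seeded.

## Scale choices

Test and acceptance runs use desk-scale schedules chosen as the package's
own defaults for development: GLMM fits of 1,500-3,000 iterations (the
posterior for a 15-herd, 270-cell table is tightly concentrated and mixes
within hundreds of iterations), ancient fits of 6,000-11,000 iterations,
10-truth validation suites, and 5,000-point strategy searches. The
production schedule (110,000 iterations) and full 350-profile design stay
one flag away.

## Known limitations

* The sex-ratio transfer assumes ancient herds managed sex like modern
  unimproved herds; no archaeological sexing information enters.
* The cut (two-stage) inference ignores any information ancient data might
  carry about the sex-ratio regression — by design.
* Productivity constants are point values; their uncertainty is not
  propagated (yields scale linearly in the per-kg densities, so relative
  comparisons survive miscalibrated constants).
* Efficiency uses feed weight as a cost proxy; absolute values are not
  interpretable.
* MNI derivation from tooth inventories is out of scope; the tool consumes
  finished MNI profiles.
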