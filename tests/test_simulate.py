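"""Synthetic generators, validation protocol and strategy search."""

import math

import numpy as np
import pytest

from paleoherd.mortality import AncientPosterior
from paleoherd.simulate import (
    coverage_report,
    generate_modern_synthetic,
    pareto_front,
    search_strategies,
    simulate_strategy_sex_asymmetric,
    simulate_strategy_sex_symmetric,
    simulate_validation_suite,
    survival_family,
)


class TestModernGenerator:
    def test_null_parameters_mean_equals_population(self, schema3):
        # beta = 0, omega = 0: mu = PS for every cell; with capping the
        # realised counts sit at/just under PS
        with pytest.warns(UserWarning, match="capped"):
            table = generate_modern_synthetic((0.0, 0.0, 0.0), 0.0, 5, schema3, 400, seed=0)
        assert np.all(table.survivors <= 400)
        # capping truncates the upper Poisson tail, costing ~sigma*phi(0)
        assert table.survivors.mean() == pytest.approx(400, rel=0.03)

    def test_same_seed_identical_table(self, schema3):
        a = generate_modern_synthetic((-0.02, -0.3, -0.01), 0.2, 4, schema3, 300, seed=9)
        b = generate_modern_synthetic((-0.02, -0.3, -0.01), 0.2, 4, schema3, 300, seed=9)
        assert np.array_equal(a.survivors, b.survivors)

    def test_negative_interaction_depletes_males_with_age(self, schema3):
        """With beta3 < 0 the male/female survivor ratio falls with age,
        averaged over many replicates."""
        ratios = []
        for rep in range(300):
            t = generate_modern_synthetic(
                (-0.01, 0.0, -0.03), 0.0, 1, schema3, 1000, seed=rep, baseline=math.log(0.4)
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios.append(t.survivors[0, 1, :] / t.survivors[0, 0, :])
        mean_ratio = np.nanmean(ratios, axis=0)
        assert mean_ratio[0] > mean_ratio[1] > mean_ratio[2]

    def test_nonpositive_population_rejected(self, schema3):
        with pytest.raises(ValueError):
            generate_modern_synthetic((0, 0, 0), 0.1, 2, schema3, 0)


class TestValidationSuite:
    def test_default_design_yields_350_datasets(self, modern_posterior, legge):
        suite = simulate_validation_suite(modern_posterior, legge, seed=0)
        assert len(suite) == 350

    def test_small_design_counts(self, modern_posterior, legge):
        suite = simulate_validation_suite(modern_posterior, legge, n_truths=3, sizes=(10,), seed=0)
        assert len(suite) == 3
        assert all(ds.counts.sum() == 10 for ds in suite)

    def test_truths_satisfy_survival_invariants(self, modern_posterior, legge):
        suite = simulate_validation_suite(modern_posterior, legge, n_truths=5, sizes=(50,), seed=1)
        for ds in suite:
            assert ds.truth_theta.sum() == pytest.approx(1.0)
            fb = np.concatenate([[0.5], ds.truth_f, [0.0]])
            mb = np.concatenate([[0.5], ds.truth_m, [0.0]])
            assert np.all(np.diff(fb) <= 1e-12)
            assert np.all(np.diff(mb) <= 1e-12)

    def test_reproducible_from_seed(self, modern_posterior, legge):
        a = simulate_validation_suite(modern_posterior, legge, n_truths=2, sizes=(20,), seed=3)
        b = simulate_validation_suite(modern_posterior, legge, n_truths=2, sizes=(20,), seed=3)
        assert np.array_equal(a[0].counts, b[0].counts)
        assert np.array_equal(a[1].truth_theta, b[1].truth_theta)


def _degenerate_posterior(ds, center, spread, site="sim"):
    n, p = 200, len(ds.truth_f)
    rng = np.random.default_rng(0)
    f = center[None, :] + spread * rng.standard_normal((n, p))
    T = p + 1
    return AncientPosterior(
        site_ids=(site,),
        gamma=np.ones((n, T)),
        theta={site: np.full((n, T), 1.0 / T)},
        f={site: f},
        m={site: f.copy()},
        male_excess={site: np.zeros((n, T))},
        beta2=np.zeros(n),
        beta3=np.zeros(n),
        chain=np.zeros(n, dtype=int),
    )


class TestCoverageReport:
    def test_posteriors_centred_on_truth_cover_everything(self, modern_posterior, legge):
        suite = simulate_validation_suite(modern_posterior, legge, n_truths=3, sizes=(20,), seed=0)
        refits = [_degenerate_posterior(ds, ds.truth_f, 1e-9) for ds in suite]
        rep = coverage_report(suite, refits, levels=(95, 50))
        assert rep["covered"].all()

    def test_posteriors_far_from_truth_cover_nothing(self, modern_posterior, legge):
        suite = simulate_validation_suite(modern_posterior, legge, n_truths=3, sizes=(20,), seed=0)
        refits = [_degenerate_posterior(ds, ds.truth_f + 10.0, 1e-9) for ds in suite]
        rep = coverage_report(suite, refits, levels=(95, 50))
        assert not rep["covered"].any()

    def test_coverage_monotone_in_level(self, modern_posterior, legge):
        suite = simulate_validation_suite(modern_posterior, legge, n_truths=4, sizes=(20,), seed=2)
        refits = [_degenerate_posterior(ds, ds.truth_f, 0.05) for ds in suite]
        rep = coverage_report(suite, refits, levels=(95, 80, 50, 20))
        pooled = rep.groupby("level")["covered"].mean()
        assert pooled.loc[20] <= pooled.loc[50] <= pooled.loc[80] <= pooled.loc[95]

    def test_mismatched_lengths_rejected(self, modern_posterior, legge):
        suite = simulate_validation_suite(modern_posterior, legge, n_truths=2, sizes=(20,), seed=0)
        with pytest.raises(ValueError):
            coverage_report(suite, [], levels=(95,))


class TestStrategies:
    def test_sex_symmetric_proportions(self, legge):
        pt = simulate_strategy_sex_symmetric(legge, seed=0)
        assert pt.female_props.sum() + pt.male_props.sum() == pytest.approx(1.0)
        assert pt.female_props.sum() == pytest.approx(0.5)
        assert np.allclose(pt.female_props, pt.male_props)

    def test_sex_symmetric_dirichlet_mean_uniform(self, legge):
        T = legge.n_classes
        tot = np.zeros(T)
        for s in range(3000):
            pt = simulate_strategy_sex_symmetric(legge, seed=s)
            tot += pt.female_props + pt.male_props
        assert np.allclose(tot / 3000, 1.0 / T, atol=0.02)

    def test_sex_asymmetric_monotone_survival(self, modern_posterior, legge):
        pt = simulate_strategy_sex_asymmetric(modern_posterior, legge, seed=1)
        assert np.all(pt.female_props >= -1e-12)
        assert np.all(pt.male_props >= -1e-12)
        assert pt.female_props.sum() + pt.male_props.sum() == pytest.approx(1.0)

    def test_same_seed_same_point(self, modern_posterior, legge):
        a = simulate_strategy_sex_asymmetric(modern_posterior, legge, seed=4)
        b = simulate_strategy_sex_asymmetric(modern_posterior, legge, seed=4)
        assert a.efficiency == b.efficiency
        assert np.array_equal(a.male_props, b.male_props)

    def test_early_male_kill_beats_symmetric_counterpart(self, modern_posterior, legge):
        """Killing males young (keeping females) is more calorie-efficient
        than spreading the same total kill evenly over the sexes."""
        from paleoherd.simulate import _strategy_from_survival

        # all males dead by ~26 months (class 4), females kept to old age
        f = np.array([0.5, 0.5, 0.45, 0.45, 0.45, 0.45, 0.4, 0.2])
        m = np.array([0.3, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        asym = _strategy_from_survival(f, m, legge, (20.0, 0.132, 0.075), None, "a")
        mid = (f + m) / 2.0
        sym = _strategy_from_survival(mid, mid.copy(), legge, (20.0, 0.132, 0.075), None, "s")
        assert asym.efficiency > sym.efficiency

    def test_search_counts_and_conditioning(self, modern_posterior, legge):
        pts, front = search_strategies(
            60, "sex-asymmetric", legge, modern_fit=modern_posterior, seed=0
        )
        assert len(pts) == 60
        cond, _ = search_strategies(
            60,
            "sex-asymmetric",
            legge,
            modern_fit=modern_posterior,
            condition_growth_gt_1=True,
            seed=0,
        )
        assert len(cond) <= len(pts)
        assert all(p.herd_growth > 1 for p in cond)

    def test_search_rejects_empty_request(self, legge):
        with pytest.raises(ValueError):
            search_strategies(0, "sex-symmetric", legge)

    def test_pareto_front_order_invariant(self, legge):
        pts = [simulate_strategy_sex_symmetric(legge, seed=s) for s in range(40)]
        a = pareto_front(pts)
        b = pareto_front(list(reversed(pts)))
        assert [(p.efficiency, p.herd_growth) for p in a] == [
            (p.efficiency, p.herd_growth) for p in b
        ]
        # no front point is dominated by any other point
        for fp in a:
            assert not any(
                (q.efficiency > fp.efficiency and q.herd_growth > fp.herd_growth) for q in pts
            )

    def test_survival_family_trades_milk_against_mow(self, legge):
        """Across a one-parameter kill-age family, milk and MOW efficiency
        are negatively associated."""
        from scipy.stats import spearmanr

        from paleoherd.simulate import _strategy_from_survival

        milk, mow = [], []
        for lam in np.geomspace(0.3, 3.0, 15):
            f, m = survival_family(lam, legge)
            pt = _strategy_from_survival(f, m, legge, (20.0, 0.132, 0.075), None, "fam")
            milk.append(pt.milk_efficiency)
            mow.append(pt.mow_efficiency)
        rho = spearmanr(milk, mow).statistic
        assert rho < 0
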