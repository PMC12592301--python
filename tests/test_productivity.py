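"""Growth curve, derived constants, monthly survival and lifetime yields."""

import math

import numpy as np
import pytest

from paleoherd.data import AgeClassSchema, ProductivityConstants
from paleoherd.productivity import (
    GrowthCurve,
    MonthlySurvival,
    derive_constants,
    fit_growth_curve,
    growth_weight,
    joint_mode,
    lifetime_yields,
    monthly_survival,
)


class TestGrowthWeight:
    def test_birth_weight_at_zero(self):
        assert growth_weight(22.0, 0.15, 0.08, 0.0) == pytest.approx(22.0)

    def test_asymptote(self):
        assert growth_weight(20.0, 0.1, 0.1, 1e6) == pytest.approx(20.0 * math.e)

    def test_point_value(self):
        expected = 20.0 * math.exp(1.0 - math.exp(-1.2))
        assert growth_weight(20.0, 0.1, 0.1, 12.0) == pytest.approx(expected)

    def test_strictly_increasing(self):
        x = np.linspace(0, 200, 100)
        assert np.all(np.diff(growth_weight(20.0, 0.1, 0.05, x)) > 0)


class TestGrowthCurveFit:
    def test_recovers_noiseless_parameters(self):
        ages = np.arange(0, 121, 6, dtype=float)
        true = (22.0, 0.15, 0.08)
        curve = fit_growth_curve(ages, growth_weight(*true, ages))
        assert curve.tau_ == pytest.approx(true[0], abs=1e-3)
        assert curve.a_ == pytest.approx(true[1], abs=1e-3)
        assert curve.b_ == pytest.approx(true[2], abs=1e-3)
        assert not curve.at_bounds_

    def test_constraint_binding_pins_and_flags(self):
        ages = np.arange(0, 121, 6, dtype=float)
        data = growth_weight(50.0, 0.15, 0.08, ages)  # demands tau = 50
        with pytest.warns(UserWarning, match="boundary"):
            curve = fit_growth_curve(ages, data)
        assert curve.tau_ == pytest.approx(30.0, abs=1e-6)
        assert "tau" in curve.at_bounds_

    def test_noise_raises_residual_ss(self):
        ages = np.arange(0, 121, 6, dtype=float)
        clean = growth_weight(22.0, 0.15, 0.08, ages)
        c0 = fit_growth_curve(ages, clean)
        c1 = fit_growth_curve(ages, clean + np.random.default_rng(0).normal(0, 1, len(ages)))
        assert c1.ss_ >= c0.ss_

    def test_degenerate_ages_rejected(self):
        with pytest.raises(ValueError, match="12 months"):
            fit_growth_curve([10.0, 10.0, 10.0], [20.0, 21.0, 22.0])

    def test_sklearn_interface(self):
        curve = GrowthCurve()
        params = curve.get_params()
        assert "tau_bounds" in params
        ages = np.arange(0, 61, 6, dtype=float)
        curve.fit(ages.reshape(-1, 1), growth_weight(20.0, 0.2, 0.1, ages))
        assert curve.predict([0.0])[0] == pytest.approx(curve.tau_)


class TestDerivedConstants:
    def test_reference_values(self):
        d = derive_constants(ProductivityConstants())
        assert round(d.birth_prob, 4) == 0.0545
        assert round(d.milk_available, 2) == 6.68
        assert round(100 * d.feed_monthly_fraction, 2) == 75.33
        assert d.milk_per_cow_month == pytest.approx(42.3 * 9.18 / 18.36)

    def test_milk_available_from_printed_average(self):
        # printed cycle-average of 21.13 kg/month with 68.4% calf share
        assert round(21.13 * (1 - 0.684), 2) == 6.68


class TestMonthlySurvival:
    def test_single_class_linear_interpolation(self):
        schema = AgeClassSchema.from_bounds([("a", 0, 5), ("b", 5, 10)])
        s = monthly_survival(np.array([0.0]), np.array([0.0]), schema)
        # f drops from 0.5 at month 0 to 0 at month 5, 0 thereafter
        assert s.s_f[0] == 0.5
        assert s.s_f[2] == pytest.approx(0.3)
        assert np.allclose(s.s_f[5:], 0.0)

    def test_flat_survival_drops_only_in_last_class(self):
        schema = AgeClassSchema.from_bounds([("a", 0, 40), ("b", 40, 80), ("c", 80, 120)])
        s = monthly_survival(np.array([0.5, 0.5]), np.array([0.0, 0.0]), schema)
        assert np.allclose(s.s_f[:81], 0.5)
        assert s.s_f[120] == 0.0

    def test_birth_value_is_half(self):
        schema = AgeClassSchema.from_bounds([("a", 0, 60), ("b", 60, 120)])
        s = monthly_survival(np.array([0.2]), np.array([0.1]), schema)
        assert s.s_f[0] == 0.5
        assert s.s_m[0] == 0.5

    def test_increasing_survivorship_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            MonthlySurvival(s_f=np.array([0.5, 0.6, 0.0]), s_m=np.array([0.5, 0.4, 0.0]))


def _flat_survival(cap=120, upper=(40, 80)):
    schema = AgeClassSchema.from_bounds(
        [("a", 0, upper[0]), ("b", upper[0], upper[1]), ("c", upper[1], cap)]
    )
    return schema


class TestLifetimeYields:
    def test_immediate_death_gives_no_milk_or_births(self):
        schema = _flat_survival()
        s = monthly_survival(np.array([0.0, 0.0]), np.array([0.0, 0.0]), schema)
        # all survival mass gone within the first class ramp; milk window empty
        with pytest.warns(UserWarning) if False else np.errstate():
            ys = lifetime_yields(s, (20.0, 0.132, 0.075))
        assert ys.milk_kg < 6.68 * 0.5  # essentially the interpolation ramp only
        assert ys.herd_growth == pytest.approx(0.0, abs=1e-12)

    def test_no_female_deaths_milk_and_growth_sums(self):
        schema = _flat_survival(cap=120)
        # females never die before the cap; males mirror them
        s = MonthlySurvival(
            s_f=np.concatenate([np.full(120, 0.5), [0.0]]),
            s_m=np.concatenate([np.full(120, 0.5), [0.0]]),
        )
        ys = lifetime_yields(s, (20.0, 0.132, 0.075))
        d = derive_constants(ProductivityConstants())
        assert ys.milk_kg == pytest.approx(0.5 * d.milk_available * 78)
        assert ys.herd_growth == pytest.approx(0.5 * d.birth_prob * 78)
        # printed-scale check: 0.5 * 6.68 * 78 = 260.52 kg, growth ~ 2.1255
        assert ys.milk_kg == pytest.approx(260.52, abs=0.6)
        assert ys.herd_growth == pytest.approx(2.1255, abs=0.01)

    def test_total_kcal_and_macronutrients_consistent(self, legge):
        s = monthly_survival(
            np.linspace(0.45, 0.05, 8), np.linspace(0.4, 0.01, 8), legge
        )
        c = ProductivityConstants()
        ys = lifetime_yields(s, (20.0, 0.132, 0.075), c)
        assert ys.total_kcal == pytest.approx(ys.milk_kcal + ys.mow_kcal)
        assert ys.protein_kg == pytest.approx(
            ys.milk_kg * c.milk_protein + ys.mow_kg * c.mow_protein
        )
        assert ys.efficiency == pytest.approx(ys.total_kcal / ys.feed_kg)

    def test_yields_scale_linearly_in_density_constants(self, legge):
        s = monthly_survival(np.linspace(0.45, 0.05, 8), np.linspace(0.4, 0.01, 8), legge)
        base = lifetime_yields(s, (20.0, 0.132, 0.075), ProductivityConstants())
        doubled = lifetime_yields(
            s, (20.0, 0.132, 0.075), ProductivityConstants(milk_kcal=2 * 670.0)
        )
        assert doubled.milk_kcal == pytest.approx(2 * base.milk_kcal)
        assert doubled.mow_kcal == pytest.approx(base.mow_kcal)

    def test_mow_bounded_by_asymptotic_weight(self, legge):
        s = monthly_survival(np.linspace(0.45, 0.05, 8), np.linspace(0.4, 0.01, 8), legge)
        c = ProductivityConstants()
        ys = lifetime_yields(s, (20.0, 0.132, 0.075), c)
        asym = 20.0 * math.exp(0.132 / 0.075)
        assert ys.mow_kg <= c.mow_fraction_of_liveweight * asym

    def test_herd_growth_monotone_in_female_survival(self, legge):
        lo = monthly_survival(np.linspace(0.3, 0.01, 8), np.linspace(0.3, 0.01, 8), legge)
        hi = monthly_survival(np.linspace(0.5, 0.2, 8), np.linspace(0.3, 0.01, 8), legge)
        g = (20.0, 0.132, 0.075)
        assert lifetime_yields(hi, g).herd_growth > lifetime_yields(lo, g).herd_growth

    def test_zero_feed_flags_undefined_efficiency(self):
        schema = _flat_survival()
        s = MonthlySurvival(s_f=np.zeros(121), s_m=np.zeros(121))
        # no one alive past month 0 (stillborn cohort)
        object.__setattr__(s, "s_f", np.concatenate([[0.0], np.zeros(120)]))
        with pytest.warns(UserWarning, match="feed"):
            ys = lifetime_yields(s, (20.0, 0.132, 0.075))
        assert math.isnan(ys.efficiency)


class TestJointMode:
    def test_degenerate_posterior(self):
        x = np.full(100, 2.0)
        y = np.full(100, 3.0)
        assert joint_mode(x, y) == (2.0, 3.0)

    def test_peak_near_sample_mode(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.3, 4000)
        y = rng.normal(-2.0, 0.5, 4000)
        mx, my = joint_mode(x, y)
        assert mx == pytest.approx(1.0, abs=0.15)
        assert my == pytest.approx(-2.0, abs=0.2)
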