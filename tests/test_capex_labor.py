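"""Power-law scaling fits, CapEx multipliers, depreciation, and labor cost."""

import math

import numpy as np
import pytest

from oleotec.assumptions import FeedstockProfile, PlantSpec, RegionProfile
from oleotec.capex_labor import (
    BuildRecord,
    ScalingModel,
    annual_depreciation,
    annual_labor_cost,
    fit_labor_model,
    fit_scaling_model,
    predict_capex,
    predict_ftes,
)


def _plant(capacity):
    return PlantSpec(fermentation_capacity_l=capacity)


def _feedstock(name="glucose", category="direct_sugar", mult=1.0):
    return FeedstockProfile(
        name=name,
        category=category,
        price_usd_per_mt={"USA": 1.0},
        capex_multiplier=mult,
        regions_available=["USA"],
    )


class TestFit:
    def test_noiseless_power_law_recovered(self):
        caps = np.logspace(np.log10(5e4), np.log10(1.5e7), 20)
        model = fit_scaling_model(
            [BuildRecord(capacity_l=c, capex_usd=3.0 * c**0.62) for c in caps]
        )
        assert model.exponent == pytest.approx(0.62, abs=1e-6)
        assert math.exp(model.log_intercept) == pytest.approx(3.0, rel=1e-6)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)
        assert model.n_points == 20

    def test_parameter_recovery_over_random_truths(self):
        # 100 random (intercept, exponent) pairs, noiseless: exact recovery
        rng = np.random.default_rng(42)
        caps = np.logspace(4.7, 7.2, 15)
        for _ in range(100):
            a = rng.uniform(0.5, 5000.0)
            b = rng.uniform(0.2, 1.0)
            model = fit_scaling_model(
                [BuildRecord(capacity_l=c, capex_usd=a * c**b) for c in caps]
            )
            assert model.exponent == pytest.approx(b, rel=1e-6)
            assert math.exp(model.log_intercept) == pytest.approx(a, rel=1e-6)
            assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_points_give_log_slope_and_perfect_fit(self):
        b1 = BuildRecord(capacity_l=1e5, capex_usd=2e6)
        b2 = BuildRecord(capacity_l=1e7, capex_usd=8e7)
        model = fit_scaling_model([b1, b2])
        slope = math.log(8e7 / 2e6) / math.log(1e7 / 1e5)
        assert model.exponent == pytest.approx(slope)
        assert model.r_squared == pytest.approx(1.0)

    def test_degenerate_capacities_rejected(self):
        builds = [BuildRecord(capacity_l=1e6, capex_usd=1e7)] * 3
        with pytest.raises(ValueError, match="degenerate"):
            fit_scaling_model(builds)
        with pytest.raises(ValueError, match="degenerate"):
            fit_scaling_model(builds[:1])


class TestPredictCapex:
    def test_feedstock_multipliers(self):
        model = ScalingModel(log_intercept=0.0, exponent=0.5, r_squared=1.0, n_points=2)
        plant = _plant(1e6)
        base = model.predict(1e6)
        assert predict_capex(model, plant, _feedstock(mult=0.86)) == pytest.approx(0.86 * base)
        assert predict_capex(model, plant, _feedstock("cassava", "simple_waste", 0.93)) == pytest.approx(0.93 * base)
        assert predict_capex(model, plant, _feedstock("corn_stover", "lignocellulosic", 1.0)) == pytest.approx(base)

    def test_monotone_in_capacity_and_homogeneous_in_multiplier(self):
        model = ScalingModel(log_intercept=3.0, exponent=0.8, r_squared=1.0, n_points=2)
        caps = [5e4, 5e5, 5e6, 1.5e7]
        preds = [predict_capex(model, _plant(c), _feedstock()) for c in caps]
        assert all(a < b for a, b in zip(preds, preds[1:]))
        half = predict_capex(model, _plant(1e6), _feedstock(mult=0.5))
        full = predict_capex(model, _plant(1e6), _feedstock(mult=1.0))
        assert half == pytest.approx(0.5 * full)

    def test_capex_per_liter_decreases_with_scale(self):
        model = ScalingModel(log_intercept=6.55, exponent=0.80, r_squared=1.0, n_points=2)
        caps = np.logspace(np.log10(5e4), np.log10(1.5e7), 10)
        per_l = [model.predict(c) / c for c in caps]
        assert all(a > b for a, b in zip(per_l, per_l[1:]))

    def test_out_of_range_capacity_warns_not_errors(self, caplog):
        model = ScalingModel(log_intercept=0.0, exponent=0.5, r_squared=1.0, n_points=2)
        with caplog.at_level("WARNING", logger="oleotec.capex_labor"):
            predict_capex(model, _plant(1e3), _feedstock())
        assert any("extrapolating" in rec.message for rec in caplog.records)


class TestDepreciation:
    def test_straight_line(self):
        assert annual_depreciation(100_000_000, 20) == 5_000_000

    def test_boundaries_rejected(self):
        with pytest.raises(ValueError):
            annual_depreciation(0, 20)
        with pytest.raises(ValueError):
            annual_depreciation(1e6, 0)

    def test_on_predicted_capex_matches_hand_computation(self):
        model = ScalingModel(
            log_intercept=math.log(3.0), exponent=0.62, r_squared=1.0, n_points=20
        )
        capex = predict_capex(model, _plant(1.5e7), _feedstock(mult=0.86))
        hand = 0.86 * 3.0 * 1.5e7**0.62 / 20
        assert annual_depreciation(capex, 20) == pytest.approx(hand)


class TestFtes:
    def test_noiseless_fte_power_law_recovered(self):
        caps = np.logspace(5, 7, 12)
        model = fit_labor_model(
            [BuildRecord(capacity_l=c, capex_usd=1.0, ftes=2.4 * c**0.35) for c in caps]
        )
        assert model.exponent == pytest.approx(0.35, abs=1e-6)
        assert predict_ftes(model, 1e6) == pytest.approx(2.4 * 1e6**0.35, rel=1e-6)

    def test_power_law_scaling_algebra(self):
        model = ScalingModel(
            log_intercept=math.log(2.4), exponent=0.35, r_squared=1.0, n_points=5
        )
        ratio = predict_ftes(model, 1e9) / predict_ftes(model, 1e6)
        assert ratio == pytest.approx(10 ** (3 * 0.35))

    def test_linear_degenerate_exponent(self):
        model = ScalingModel(log_intercept=0.0, exponent=1.0, r_squared=1.0, n_points=2)
        assert predict_ftes(model, 2e6) == pytest.approx(2 * predict_ftes(model, 1e6))

    def test_unfitted_model_rejected(self):
        model = ScalingModel(log_intercept=0.0, exponent=0.5, r_squared=0.0, n_points=0)
        with pytest.raises(ValueError, match="not fitted"):
            predict_ftes(model, 1e6)

    def test_predictions_not_rounded(self):
        model = ScalingModel(
            log_intercept=math.log(2.4), exponent=0.35, r_squared=1.0, n_points=5
        )
        assert predict_ftes(model, 1e6) % 1 != 0


class TestLaborCost:
    def test_forced_arithmetic(self):
        region = RegionProfile(
            name="USA", operator_salary_usd_per_year=40_000, corporate_tax_rate=0.2
        )
        assert annual_labor_cost(10, region) == 800_000
        assert annual_labor_cost(0, region) == 0

    def test_labor_per_kg_falls_with_scale_under_sublinear_ftes(self, default_set):
        # synthetic sweep: $/kg labor at 15M L far below 50k L
        region = default_set.region("USA")
        labor_model = default_set.labor_model_params
        per_kg = []
        for cap in (5e4, 1.5e7):
            ftes = predict_ftes(labor_model, cap)
            # output scales linearly with capacity, so $/kg ~ cost / capacity
            per_kg.append(annual_labor_cost(ftes, region) / cap)
        assert per_kg[1] < per_kg[0] / 10
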