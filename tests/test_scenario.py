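"""The scenario engine: invariants, calibration, counterfactuals,
decomposition and global aggregation."""

import dataclasses

import numpy as np
import pytest

from fooddemand import (
    WorldSpec, calibrate, counterfactual, decompose_growth, default_parameters,
    global_aggregate, make_drivers, make_observations, run_scenario,
)
from fooddemand.datamodel import AGE_COHORTS, DriverPanel
from fooddemand.parameters import SaturatingCurve
from fooddemand.scenario import CalibrationFactors


def constant_drivers(n_c=4, income=5000.0, years=range(1965, 2051, 5),
                     pop_scale=None):
    years = list(years)
    countries = [f"K{i}" for i in range(n_c)]
    inc = np.full((n_c, len(years)), income)
    pyramid = np.exp(-0.03 * np.arange(len(AGE_COHORTS)) * 5)
    pop = np.tile(pyramid[:, None, None, None] * 1e6 / 2,
                  (1, 2, n_c, len(years)))
    if pop_scale is not None:
        pop = pop * np.asarray(pop_scale)[None, None, :, None]
    return DriverPanel.from_arrays(countries, years, inc, pop)


class TestEngineInvariants:
    def test_run_completes_with_all_invariants(self, base_result):
        r = base_result
        np.testing.assert_allclose(
            r.bmi_adult.sum("bmi_class").values, 1.0, atol=1e-12)
        np.testing.assert_allclose(
            r.bmi_child.sum("bmi_class").values, 1.0, atol=1e-12)
        assert np.all(r.waste.values >= 0)
        assert np.all(r.height.values > 0)
        comp_sum = r.composition.sum("food_group").values
        np.testing.assert_allclose(comp_sum, r.demand.values,
                                   rtol=1e-12, atol=1e-9)
        assert np.all((r.pal.values >= 1.2) & (r.pal.values <= 2.5))

    def test_deterministic_bit_identical(self, small_world):
        spec, drivers, _ = small_world
        r1 = run_scenario(drivers, spec.truth)
        r2 = run_scenario(drivers, spec.truth)
        for name in ("height", "demand", "intake", "composition"):
            np.testing.assert_array_equal(getattr(r1, name).values,
                                          getattr(r2, name).values)

    def test_adult_cohort_height_carries_forward(self, base_result):
        h = base_result.height
        for year in (1990, 2020):
            np.testing.assert_array_equal(
                h.sel(age="20-24", year=year + 5).values,
                h.sel(age="15-19", year=year).values)

    def test_constant_drivers_reach_steady_state(self):
        drivers = constant_drivers()
        r = run_scenario(drivers, default_parameters())
        # with constant income the 15-19 height is constant from the start,
        # so all outputs are constant over time
        d = r.demand.values
        assert np.max(np.abs(d - d[:, :1]) / d[:, :1]) < 1e-9

    def test_population_doubling_leaves_per_capita_unchanged(self):
        a = run_scenario(constant_drivers(), default_parameters())
        b = run_scenario(constant_drivers(pop_scale=[2.0, 2.0, 2.0, 2.0]),
                         default_parameters())
        np.testing.assert_allclose(a.demand.values, b.demand.values,
                                   rtol=1e-12)
        np.testing.assert_allclose(a.intake.values, b.intake.values,
                                   rtol=1e-12)

    def test_missing_drivers_error_lists_gaps(self, small_world):
        _, drivers, _ = small_world
        broken = DriverPanel(income=drivers.income.where(
            drivers.income.coords["year"] != 1990),
            population=drivers.population)
        with pytest.raises(ValueError, match="incomplete drivers"):
            run_scenario(broken, default_parameters())


@pytest.fixture(scope="module")
def calibrated(small_world, base_result):
    spec, drivers, _ = small_world
    reported = make_observations(drivers, spec.truth, noise=1.0, seed=5)
    factors = calibrate(base_result, reported)
    result = run_scenario(drivers, spec.truth, calibration=factors)
    return reported, factors, result


class TestCalibration:
    def test_exact_at_reported_cells(self, calibrated):
        reported, _, result = calibrated
        modeled = result.to_observations()
        for name in ("height", "bmi_adult", "bmi_child", "demand",
                     "composition"):
            np.testing.assert_array_equal(getattr(modeled, name).values,
                                          getattr(reported, name).values)

    def test_no_spurious_cutoffs_on_clean_world(self, calibrated):
        _, _, result = calibrated
        assert result.clip_log == []

    def test_offsets_are_reported_minus_modeled(self, calibrated):
        """The demand offset equals reported minus the raw model demand of
        the calibrated pass (waste ratio times calibrated intake)."""
        reported, factors, result = calibrated
        raw = result.waste_ratio_model.values * result.intake.values
        expected = reported.demand.values - raw
        np.testing.assert_allclose(factors.offsets["demand"], expected,
                                   rtol=1e-9, atol=1e-9)

    def test_demand_cutoff_at_intake_is_logged(self, small_world,
                                               base_result):
        spec, drivers, _ = small_world
        reported = make_observations(drivers, spec.truth, noise=0)
        bad = reported.demand.copy(deep=True)
        bad[0, 5] = 100.0  # far below any plausible intake
        reported = dataclasses.replace(reported, demand=bad)
        factors = calibrate(base_result, reported)
        result = run_scenario(drivers, spec.truth, calibration=factors)
        assert any(entry[0] == "demand" for entry in result.clip_log)
        i_cell = result.intake.values[0, 5]
        assert result.demand.values[0, 5] == i_cell  # floored, waste >= 0

    def test_backfill_reuses_earliest_factors(self, small_world,
                                              base_result):
        """BMI factors for pre-data years equal the earliest derived ones."""
        spec, drivers, _ = small_world
        reported = make_observations(drivers, spec.truth, noise=1.0, seed=5)
        # pretend BMI data only starts in 1975
        ya = [int(y) for y in reported.bmi_adult.coords["year"].values]
        mask = [y < 1975 for y in ya]
        ba = reported.bmi_adult.copy(deep=True)
        ba[..., mask] = np.nan
        bc = reported.bmi_child.copy(deep=True)
        bc[..., mask] = np.nan
        reported = dataclasses.replace(reported, bmi_adult=ba, bmi_child=bc)
        factors = calibrate(base_result, reported, backfill=True)
        i1975 = ya.index(1975)
        for var in ("bmi_adult", "bmi_child"):
            off = factors.offsets[var]
            np.testing.assert_array_equal(off[..., 0], off[..., i1975])
            np.testing.assert_array_equal(off[..., 1], off[..., i1975])

    def test_factors_round_trip_through_csv(self, calibrated, tmp_path):
        reported, factors, result = calibrated
        factors.to_dir(tmp_path)
        back = CalibrationFactors.from_dir(tmp_path, factors.countries,
                                           factors.years)
        replay = run_scenario(result.drivers, result.params, calibration=back)
        np.testing.assert_allclose(replay.demand.values,
                                   result.demand.values, rtol=1e-12)


class TestCounterfactuals:
    def test_zero_waste_identity(self, base_result):
        change = counterfactual(base_result, "zero_waste", 2010)
        pop = base_result.drivers.population.sum(("age", "sex")).sel(
            year=2010).values
        x = base_result.waste.sel(year=2010).values
        d = base_result.demand.sel(year=2010).values
        assert change == pytest.approx(-100.0 * (x * pop).sum()
                                       / (d * pop).sum(), rel=1e-12)

    def test_sign_pattern_matches_behavioural_logic(self, base_result):
        """No-underweight raises demand, no-overweight and no-waste lower
        it, full activity raises it: the (+, -, +, -) pattern."""
        assert counterfactual(base_result, "underweight_to_normal", 2010) > 0
        assert counterfactual(base_result, "overweight_to_normal", 2010) < 0
        assert counterfactual(base_result, "inactive_to_moderate", 2010) > 0
        assert counterfactual(base_result, "zero_waste", 2010) < 0

    def test_no_underweight_world_is_a_noop(self):
        params = default_parameters()
        # move all underweight baseline/slope into the normal class
        new_shares = {}
        for stratum, curves in params.bmi_shares.items():
            curves = dict(curves)
            classes = list(curves)
            under, normal = classes[0], classes[2]
            u, n = curves[under], curves[normal]
            curves[normal] = SaturatingCurve(n.baseline + u.baseline,
                                             n.asymptote + u.asymptote,
                                             n.half_saturation)
            curves[under] = SaturatingCurve(0.0, 0.0, u.half_saturation)
            new_shares[stratum] = curves
        params = dataclasses.replace(params, bmi_shares=new_shares)
        r = run_scenario(constant_drivers(), params)
        assert counterfactual(r, "underweight_to_normal", 2010) == 0.0

    def test_unknown_switch_and_year_errors(self, base_result):
        with pytest.raises(ValueError, match="unknown"):
            counterfactual(base_result, "teleport_food", 2010)
        with pytest.raises(ValueError, match="year"):
            counterfactual(base_result, "zero_waste", 2012)


class TestDecomposition:
    def test_contributions_sum_to_net(self, base_result):
        dec = decompose_growth(base_result, 1975, 2050)
        for region, contrib in dec.contributions.items():
            total = sum(contrib.values())
            assert abs(total - dec.net[region]) <= 1e-9 * abs(dec.net[region])

    def test_reversed_order_also_additive(self, base_result):
        dec = decompose_growth(base_result, 1975, 2050)
        for region, contrib in dec.contributions_reversed.items():
            total = sum(contrib.values())
            assert abs(total - dec.net[region]) <= 1e-9 * abs(dec.net[region])

    def test_population_only_change_attributes_everything_to_population(self):
        growth = np.linspace(1.0, 2.0, 18)
        years = list(range(1965, 2051, 5))
        drivers = constant_drivers(n_c=1)
        pop = drivers.population.values * growth[None, None, None, :]
        drivers = DriverPanel.from_arrays(drivers.countries, years,
                                          drivers.income.values, pop)
        r = run_scenario(drivers, default_parameters())
        dec = decompose_growth(r, 1990, 2050)
        contrib = dec.contributions["World"]
        assert contrib["population"] == pytest.approx(dec.net["World"],
                                                      rel=1e-9)
        for factor in ("requirements", "bmi", "pal", "waste", "composition"):
            assert abs(contrib[factor]) <= 1e-9 * abs(dec.net["World"])

    def test_no_change_means_zero_contributions(self):
        r = run_scenario(constant_drivers(), default_parameters())
        dec = decompose_growth(r, 1990, 2050)
        for v in dec.contributions["World"].values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_animal_measure_includes_composition(self, base_result):
        dec = decompose_growth(base_result, 1975, 2050, measure="animal")
        assert dec.contributions["World"]["composition"] > 0
        total = sum(dec.contributions["World"].values())
        assert total == pytest.approx(dec.net["World"], rel=1e-9)

    def test_input_validation(self, base_result):
        with pytest.raises(ValueError, match="factors"):
            decompose_growth(base_result, 1975, 2050,
                             factors=("population", "magic"))
        with pytest.raises(ValueError, match="t0"):
            decompose_growth(base_result, 2050, 1975)
        with pytest.raises(ValueError, match="measure"):
            decompose_growth(base_result, 1975, 2050, measure="protein")


class TestGlobalAggregate:
    def test_billion_people_example(self):
        drivers = constant_drivers(n_c=1)
        r = run_scenario(drivers, default_parameters())
        agg = global_aggregate(r)
        d = float(r.demand.sel(year=2010).values[0])
        pop = float(r.drivers.population.sum(("age", "sex"))
                    .sel(year=2010).values[0])
        expect = d * pop * 365 * 4184 / 1e18
        assert float(agg.demand_ej.sel(region="World", year=2010)) == \
            pytest.approx(expect, rel=1e-12)

    def test_regional_totals_sum_to_world(self, base_result):
        countries = base_result.countries
        regions = ["ASI", "CHA", "GLN", "IND", "LAM", "MAF", "SSA"]
        mapping = {c: regions[i % 7] for i, c in enumerate(countries)}
        agg = global_aggregate(base_result, region_map=mapping)
        regional = agg.demand_ej.sel(region=regions).sum("region")
        world = agg.demand_ej.sel(region="World")
        np.testing.assert_allclose(regional.values, world.values, rtol=1e-12)

    def test_missing_mapping_entries_error(self, base_result):
        with pytest.raises(KeyError, match="missing"):
            global_aggregate(base_result, region_map={"C00": "ASI"})
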