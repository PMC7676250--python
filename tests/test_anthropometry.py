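"""Height projection, BMI-share curves and body weight."""

import numpy as np
import pytest
import xarray as xr

from fooddemand.anthropometry import (
    GrowthStandard, assemble_heights, body_weight, fit_bmi_shares,
    fit_height_regression, predict_bmi_shares, young_adult_height,
)
from fooddemand.datamodel import (
    ADULT_BMI_CLASSES, AGE_COHORTS, CHILD_BMI_CLASSES, SEXES,
)
from fooddemand.parameters import PowerLaw, SaturatingCurve


@pytest.fixture(scope="module")
def standard():
    return GrowthStandard.default()


class TestHeightRegression:
    def _panel(self, alpha, beta, years=range(1965, 2011, 5), n_c=6):
        countries = [f"C{i}" for i in range(n_c)]
        years = list(years)
        rng = np.random.default_rng(0)
        g = rng.uniform(200.0, 1200.0, size=(n_c, len(years)))
        g_da = xr.DataArray(g, dims=("country", "year"),
                            coords={"country": countries, "year": years})
        # heights generated with the engine's own lagging rule
        from fooddemand.anthropometry import lagged_mean_diet_quality

        g_by_year = {t: g[:, i] for i, t in enumerate(years)}
        h = np.empty((2, n_c, len(years)))
        for ti, t in enumerate(years):
            gbar = lagged_mean_diet_quality(g_by_year, t)
            if gbar is None:
                gbar = g_by_year[t]
            for si in range(2):
                h[si, :, ti] = alpha[si] * gbar ** beta[si]
        h_da = xr.DataArray(h, dims=("sex", "country", "year"),
                            coords={"sex": list(SEXES), "country": countries,
                                    "year": years})
        return h_da, g_da

    def test_noiseless_recovery(self):
        h, g = self._panel(alpha=(95.0, 90.0), beta=(0.06, 0.05))
        fitted = fit_height_regression(h, g)
        assert fitted["male"].scale == pytest.approx(95.0, rel=1e-6)
        assert fitted["male"].exponent == pytest.approx(0.06, rel=1e-6)
        assert fitted["female"].scale == pytest.approx(90.0, rel=1e-6)
        assert fitted["female"].exponent == pytest.approx(0.05, rel=1e-6)

    def test_constant_height_recovers_zero_exponent(self):
        h, g = self._panel(alpha=(170.0, 160.0), beta=(0.0, 0.0))
        fitted = fit_height_regression(h, g)
        assert fitted["male"].exponent == pytest.approx(0.0, abs=1e-10)
        assert fitted["male"].scale == pytest.approx(170.0, rel=1e-10)

    def test_single_g_value_is_degenerate(self):
        h, g = self._panel(alpha=(95.0, 90.0), beta=(0.06, 0.05))
        with pytest.raises(ValueError, match="degenerate"):
            fit_height_regression(h, xr.ones_like(g) * 600.0)

    def test_non_positive_height_errors(self):
        h, g = self._panel(alpha=(95.0, 90.0), beta=(0.06, 0.05))
        with pytest.raises(ValueError, match="positive"):
            fit_height_regression(h * 0.0, g)


class TestHeightAssembly:
    def test_child_heights_scale_with_divergence(self, standard):
        # a 170 cm cohort against a 176.5 cm reference scales a 137.8 cm
        # 10-year-old to 132.7 cm
        assert standard.adult_height("male") == pytest.approx(176.5)
        scaled = standard.height(10.0, "male") * 170.0 / 176.5
        assert scaled == pytest.approx(132.7, abs=0.05)

        h1519 = np.array([[170.0], [160.0]])
        H = assemble_heights(h1519, None, standard)
        expect = standard.height(12.5, "male") * 170.0 / 176.5
        assert H[2, 0, 0] == pytest.approx(expect, rel=1e-12)

    def test_child_heights_increase_with_age(self, standard):
        H = assemble_heights(np.array([[170.0], [160.0]]), None, standard)
        assert H[0, 0, 0] < H[1, 0, 0] < H[2, 0, 0] < H[3, 0, 0]

    def test_cohort_carrying(self, standard):
        prev = assemble_heights(np.array([[170.0], [160.0]]), None, standard)
        nxt = assemble_heights(np.array([[171.0], [161.0]]), prev, standard)
        # the 15-19 cohort of the previous step is now 20-24
        assert nxt[4, 0, 0] == 170.0
        # the open 100+ cohort absorbs the incoming 95-99 cohort
        assert nxt[-1, 0, 0] == prev[-2, 0, 0]

    def test_first_step_initializes_adults_at_young_adult_height(self,
                                                                 standard):
        H = assemble_heights(np.array([[170.0], [160.0]]), None, standard)
        assert np.all(H[3:, 0, :] == 170.0)
        assert np.all(H[3:, 1, :] == 160.0)

    def test_height_monotone_in_diet_quality(self):
        params = {"male": PowerLaw(116.0, 0.06), "female": PowerLaw(107.0, 0.06)}
        g = np.array([300.0, 600.0, 1200.0])
        h = young_adult_height(params, g)
        assert np.all(np.diff(h, axis=1) > 0)


class TestBodyWeight:
    @pytest.mark.parametrize("bmi,height,expected", [
        (22.5, 160.0, 57.6),
        (22.5, 157.0, 55.46025),
        (22.5, 0.0, 0.0),
    ])
    def test_weight_from_bmi_and_height(self, bmi, height, expected):
        assert body_weight(bmi, height) == pytest.approx(expected, rel=1e-12)

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            body_weight(-1.0, 170.0)
        with pytest.raises(ValueError):
            body_weight(22.5, -170.0)


class TestBmiShares:
    def _obs(self, truth_curves_adult, truth_curves_child, income):
        years = [int(y) for y in income.coords["year"].values]
        countries = [str(c) for c in income.coords["country"].values]
        y = income.values
        ad = np.stack([
            np.stack([
                np.stack([truth_curves_adult[c](y) for c in ADULT_BMI_CLASSES])
                for _ in SEXES], axis=1)
            for _ in ("15-59", "60+")], axis=1)
        ch = np.stack([
            np.stack([truth_curves_child[c](y) for c in CHILD_BMI_CLASSES])
            for _ in SEXES], axis=1)
        bmi_adult = xr.DataArray(ad, dims=("bmi_class", "age_group", "sex",
                                           "country", "year"),
                                 coords={"bmi_class": list(ADULT_BMI_CLASSES),
                                         "age_group": ["15-59", "60+"],
                                         "sex": list(SEXES),
                                         "country": countries, "year": years})
        bmi_child = xr.DataArray(ch, dims=("bmi_class", "sex", "country",
                                           "year"),
                                 coords={"bmi_class": list(CHILD_BMI_CLASSES),
                                         "sex": list(SEXES),
                                         "country": countries, "year": years})
        return bmi_adult, bmi_child

    def test_noiseless_share_recovery(self):
        income = xr.DataArray(
            np.linspace(500.0, 60000.0, 40).reshape(4, 10),
            dims=("country", "year"),
            coords={"country": list("ABCD"), "year": list(range(1965, 2015, 5))})
        adult = {c: SaturatingCurve(b, d, 10000.0) for c, b, d in zip(
            ADULT_BMI_CLASSES, [0.12, 0.16, 0.47, 0.15, 0.07, 0.03],
            [-0.09, -0.11, -0.20, 0.20, 0.13, 0.07])}
        child = {c: SaturatingCurve(b, d, 7000.0) for c, b, d in zip(
            CHILD_BMI_CLASSES, [0.16, 0.20, 0.52, 0.08, 0.04],
            [-0.12, -0.10, -0.06, 0.16, 0.12])}
        bmi_adult, bmi_child = self._obs(adult, child, income)
        fitted = fit_bmi_shares(bmi_adult, bmi_child, income)
        for cls_, curve in adult.items():
            est = fitted[("15-59", "male")][cls_]
            assert est.baseline == pytest.approx(curve.baseline, abs=1e-6)
            assert est.asymptote == pytest.approx(curve.asymptote, abs=1e-6)
            assert est.half_saturation == pytest.approx(
                curve.half_saturation, rel=1e-4)

    def test_flat_shares_fit_as_constants(self):
        income = xr.DataArray(
            np.linspace(500.0, 60000.0, 40).reshape(4, 10),
            dims=("country", "year"),
            coords={"country": list("ABCD"), "year": list(range(1965, 2015, 5))})
        adult = {c: SaturatingCurve(b, 0.0, 10000.0) for c, b in zip(
            ADULT_BMI_CLASSES, [0.12, 0.16, 0.47, 0.15, 0.07, 0.03])}
        child = {c: SaturatingCurve(b, 0.0, 7000.0) for c, b in zip(
            CHILD_BMI_CLASSES, [0.16, 0.20, 0.52, 0.08, 0.04])}
        bmi_adult, bmi_child = self._obs(adult, child, income)
        fitted = fit_bmi_shares(bmi_adult, bmi_child, income)
        est = fitted[("15-59", "male")]["20-25"]
        assert est(0.0) == pytest.approx(0.47, abs=1e-6)
        assert est(1e9) == pytest.approx(0.47, abs=1e-4)

    def test_obesity_share_rises_with_income(self, truth):
        curves = truth.bmi_shares[("15-59", "male")]
        lo = predict_bmi_shares(curves, 1000.0, classes=ADULT_BMI_CLASSES)
        hi = predict_bmi_shares(curves, 50000.0, classes=ADULT_BMI_CLASSES)
        obese = [ADULT_BMI_CLASSES.index(c) for c in ("30-35", ">=35")]
        under = ADULT_BMI_CLASSES.index("<18.5")
        assert hi[obese].sum() > lo[obese].sum()
        assert hi[under] < lo[under]


class TestPredictShares:
    def test_shares_sum_to_one(self, truth):
        curves = truth.bmi_shares[("15-59", "female")]
        y = np.array([0.0, 123.0, 9000.0, 1e7])
        s = predict_bmi_shares(curves, y, classes=ADULT_BMI_CLASSES)
        np.testing.assert_allclose(s.sum(axis=0), 1.0, atol=1e-12)

    def test_origin_gives_normalized_baselines(self, truth):
        curves = truth.bmi_shares[("0-14", "male")]
        s = predict_bmi_shares(curves, 0.0, classes=CHILD_BMI_CLASSES)
        base = np.array([curves[c].baseline for c in CHILD_BMI_CLASSES])
        np.testing.assert_allclose(s, base / base.sum(), rtol=1e-12)

    def test_half_saturation_property_of_curve(self):
        curve = SaturatingCurve(0.0, 0.4, 8000.0)
        assert curve(8000.0) == pytest.approx(0.2, rel=1e-12)

    def test_all_zero_shares_error(self):
        curves = {"a": SaturatingCurve(0.0, 0.5, 1000.0),
                  "b": SaturatingCurve(0.0, 0.5, 1000.0)}
        with pytest.raises(ValueError, match="normalize"):
            predict_bmi_shares(curves, 0.0)
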