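"""End-to-end parameter estimation from observation panels, and the
model-specific cross-validation harness.

The fitting order follows the model's causal chain: the diet tree and the
height regression use observed panels only; the BMI-share curves use
observed shares against income; the waste curve is fitted last, as the
ratio of observed demand to the intake the freshly fitted anthropometric
chain implies.  Activity (PAL) parameters and the pregnancy add-on are
configuration, not fitted, and are taken from a base parameter set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import xarray as xr

from .anthropometry import (
    GrowthStandard, assemble_heights, fit_bmi_shares, fit_height_regression,
    lagged_mean_diet_quality, young_adult_height,
)
from .datamodel import DriverPanel, ObservationPanels
from .energy import SchofieldCoeffs, intake_from_anthropometry, pal_state
from .fitting import CVReport, SaturatingRegressor, kfold_cv
from .parameters import ParameterSet, default_parameters
from .scenario import _predict_share_blocks, run_scenario


def modeled_intake(drivers: DriverPanel, params: ParameterSet,
                   g_obs: xr.DataArray, standard: GrowthStandard,
                   coeffs: SchofieldCoeffs) -> np.ndarray:
    """Per-capita intake (country, year) implied by the anthropometric chain
    when the diet-quality driver is taken from observed composition.

    Uses the same height lag-and-carry rules as the scenario engine, so on
    model-generated data this reproduces the engine's intake exactly without
    needing the (yet unfitted) waste parameters.
    """
    years = drivers.years
    income = drivers.income.values
    pop = drivers.population.values
    g_panel = g_obs.reindex(country=drivers.countries,
                            year=years).transpose("country", "year").values
    g_by_year = {t: g_panel[:, ti] for ti, t in enumerate(years)}

    out = np.empty((len(drivers.countries), len(years)))
    h_prev = None
    for ti, t in enumerate(years):
        g_bar = lagged_mean_diet_quality(g_by_year, t)
        if g_bar is None:
            g_bar = g_by_year[t]
        h1519 = young_adult_height(params.height, g_bar)
        H = assemble_heights(h1519, h_prev, standard)
        s_ad, s_ch = _predict_share_blocks(params, income[:, ti])
        A = pal_state(income[:, ti], params.pal)
        out[:, ti] = intake_from_anthropometry(H, s_ad, s_ch, A,
                                               pop[:, :, :, ti], params,
                                               standard, coeffs)
        h_prev = H
    return out


def _flat_xy(income: xr.DataArray, response: np.ndarray):
    x = income.transpose("country", "year").values.ravel()
    y = np.asarray(response, dtype=float).ravel()
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def fit_parameters(drivers: DriverPanel, observations: ObservationPanels,
                   base_params: ParameterSet | None = None,
                   standard: GrowthStandard | None = None,
                   coeffs: SchofieldCoeffs | None = None) -> ParameterSet:
    """Fit every behavioural parameter from observation panels.

    Returns a new parameter set with fitted height, BMI-share, diet-tree and
    waste curves; PAL and pregnancy settings are carried over from
    ``base_params`` (defaults when omitted).
    """
    base = base_params or default_parameters()
    standard = standard or GrowthStandard.default()
    coeffs = coeffs or SchofieldCoeffs.default()
    income = drivers.income.reindex(country=observations.countries,
                                    year=observations.years)

    g_obs = observations.diet_quality
    height = fit_height_regression(observations.height, g_obs)
    bmi = fit_bmi_shares(observations.bmi_adult, observations.bmi_child,
                         income)

    d = observations.demand.transpose("country", "year").values
    comp = observations.composition.transpose(
        "food_group", "country", "year").values
    with np.errstate(divide="ignore", invalid="ignore"):
        tree = np.stack([
            comp[0] / d,
            comp[1] / (d - comp[0]),
            comp[2] / (d - comp[0] - comp[1]),
        ])
    tree_curves = []
    for level, name in enumerate(("animal", "empty", "fvn")):
        x, y = _flat_xy(income, tree[level])
        est = SaturatingRegressor(fit_baseline=False,
                                  asymptote_bounds=(0.0, 1.0)).fit(x, y)
        tree_curves.append(est.curve_())

    interim = dataclasses.replace(base, height=height, bmi_shares=bmi,
                                  diet_animal=tree_curves[0],
                                  diet_empty=tree_curves[1],
                                  diet_fvn=tree_curves[2])
    intake = modeled_intake(drivers.subset(observations.countries), interim,
                            g_obs, standard, coeffs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = d / intake
    x, y = _flat_xy(income, ratio)
    waste_est = SaturatingRegressor(fit_baseline=False, offset=1.0,
                                    asymptote_bounds=(0.0, 5.0)).fit(x, y)
    return dataclasses.replace(interim, waste=waste_est.curve_())


# ---------------------------------------------------------------------------
# cross-validation harness


def model_fit_and_predict(drivers: DriverPanel,
                          observations: ObservationPanels,
                          evaluation_year: int = 2010,
                          base_params: ParameterSet | None = None):
    """Build the fit-and-predict procedure for country k-fold CV.

    For each fold, parameters are fitted on the training countries'
    observations; the full forward model is then run (uncalibrated) for the
    held-out countries and compared with their observations at the
    evaluation year, for four indicators: young-adult height, BMI-class
    shares, per-capita demand and dietary composition.
    """

    def fit_and_predict(train, test):
        params = fit_parameters(drivers.subset(train),
                                observations.subset(train),
                                base_params=base_params)
        result = run_scenario(drivers.subset(test), params)
        modeled = result.to_observations()
        held = observations.subset(test)
        out = {}
        pairs = {
            "height": (held.height, modeled.height),
            "bmi_shares": (
                np.concatenate([held.bmi_adult.sel(year=evaluation_year)
                                .values.ravel(),
                                held.bmi_child.sel(year=evaluation_year)
                                .values.ravel()]),
                np.concatenate([modeled.bmi_adult.sel(year=evaluation_year)
                                .values.ravel(),
                                modeled.bmi_child.sel(year=evaluation_year)
                                .values.ravel()])),
            "demand": (held.demand, modeled.demand),
            "composition": (held.composition, modeled.composition),
        }
        for name, (obs_da, pred_da) in pairs.items():
            if name == "bmi_shares":
                out[name] = (obs_da, pred_da)
                continue
            out[name] = (obs_da.sel(year=evaluation_year).values.ravel(),
                         pred_da.sel(year=evaluation_year).values.ravel())
        return out

    return fit_and_predict


def cross_validate(drivers: DriverPanel, observations: ObservationPanels,
                   k: int = 5, seed: int = 0, evaluation_year: int = 2010,
                   base_params: ParameterSet | None = None) -> CVReport:
    """Five-fold (by default) country cross-validation of the full model."""
    fap = model_fit_and_predict(drivers, observations, evaluation_year,
                                base_params)
    return kfold_cv(observations.countries, k, seed, fap)
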