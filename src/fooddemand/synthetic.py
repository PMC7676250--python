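"""Synthetic worlds: drivers and noisy "reported" panels from known
parameters, so fitting, calibration, validation and scenario machinery are
testable end to end without external data.

The generator targets statistical structure, not country realism: logistic
income growth between country-specific floors and ceilings spanning roughly
500-60,000 USD2005 PPP (wide enough to identify every half-saturation
constant), and a cohort-component population with income-declining fertility
and age-increasing mortality, which reproduces a demographic transition —
young pyramids early, ageing societies late.

Observation noise (all seeded): multiplicative log-normal on height and on
the household-waste margin (so reported demand never falls below intake),
additive Gaussian on logit shares (BMI classes and diet-tree shares) with
renormalization, keeping every generated panel consistent with the data
model's invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

from .datamodel import (
    AGE_COHORTS, FOOD_GROUPS, SEXES, YEARS, DriverPanel, ObservationPanels,
    cohort_midpoint, write_drivers, write_observations,
)
from .parameters import ParameterSet, default_parameters
from .scenario import run_scenario

DEFAULT_NOISE: dict[str, float] = {
    "height": 0.01,        # log-normal sigma on 15-19 height
    "bmi_shares": 0.03,    # gaussian sigma on share logits
    "waste": 0.05,         # log-normal sigma on the waste margin X
    "composition": 0.05,   # gaussian sigma on diet-tree share logits
}

_FERTILE_FEMALE = slice(3, 10)  # cohorts 15-19 .. 45-49


@dataclass
class WorldSpec:
    """Study conditions of a synthetic world; the seed fully determines
    drivers and observations."""

    n_countries: int = 30
    seed: int = 0
    start_year: int = 1965
    end_year: int = 2100
    income_floor: tuple[float, float] = (500.0, 2000.0)
    income_ceiling: tuple[float, float] = (5000.0, 60000.0)
    growth_rate: tuple[float, float] = (0.02, 0.08)       # 1/yr
    growth_midpoint: tuple[float, float] = (1980.0, 2060.0)
    initial_population: tuple[float, float] = (1e6, 1e8)  # persons
    pyramid_decay: tuple[float, float] = (0.02, 0.05)     # 1/yr of age
    fertility_max: float = 0.70    # births per woman 15-49 per 5 years
    fertility_min: float = 0.12
    fertility_half_saturation: float = 4000.0  # USD2005 PPP
    mortality_base: float = 0.001              # 1/yr
    mortality_scale: float = 2e-5
    mortality_slope: float = 0.085             # 1/yr of age
    truth: ParameterSet = field(default_factory=default_parameters)
    noise: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))


def _fertility(income, spec: WorldSpec):
    k = spec.fertility_half_saturation
    return spec.fertility_min + (spec.fertility_max - spec.fertility_min) * (
        k / (k + income))


def _survival(spec: WorldSpec) -> np.ndarray:
    """5-year cohort survival probabilities (Gompertz-type mortality)."""
    mids = np.array([cohort_midpoint(c) for c in AGE_COHORTS])
    hazard = spec.mortality_base + spec.mortality_scale * np.exp(
        spec.mortality_slope * mids)
    return np.exp(-5.0 * hazard)


def make_drivers(spec: WorldSpec) -> DriverPanel:
    """Generate income and population panels for a synthetic world."""
    rng = np.random.default_rng(spec.seed)
    years = np.array([y for y in YEARS
                      if spec.start_year <= y <= spec.end_year])
    n_c, n_t = spec.n_countries, years.size
    countries = [f"C{i:02d}" for i in range(n_c)]

    floor = rng.uniform(*spec.income_floor, n_c)
    ceiling = np.exp(rng.uniform(np.log(spec.income_ceiling[0]),
                                 np.log(spec.income_ceiling[1]), n_c))
    ceiling = np.maximum(ceiling, floor * 2.0)
    rate = rng.uniform(*spec.growth_rate, n_c)
    midpoint = rng.uniform(*spec.growth_midpoint, n_c)
    t = years[None, :]
    income = floor[:, None] + (ceiling - floor)[:, None] / (
        1.0 + np.exp(-rate[:, None] * (t - midpoint[:, None])))

    # initial age pyramid: geometric decline in age, even sex split
    decay = rng.uniform(*spec.pyramid_decay, n_c)
    mids = np.array([cohort_midpoint(c) for c in AGE_COHORTS])
    pyramid = np.exp(-decay[None, :] * mids[:, None])          # (age, country)
    totals = np.exp(rng.uniform(np.log(spec.initial_population[0]),
                                np.log(spec.initial_population[1]), n_c))
    pyramid = pyramid / pyramid.sum(axis=0, keepdims=True) * totals[None, :]

    pop = np.empty((len(AGE_COHORTS), 2, n_c, n_t))
    pop[:, 0, :, 0] = pyramid / 2.0
    pop[:, 1, :, 0] = pyramid / 2.0
    surv = _survival(spec)
    for ti in range(1, n_t):
        prev = pop[:, :, :, ti - 1]
        nxt = np.empty_like(prev)
        survived = prev * surv[:, None, None]
        nxt[1:] = survived[:-1]
        nxt[-1] += survived[-1]                                 # 100+ absorbs
        women = prev[_FERTILE_FEMALE, 1, :].sum(axis=0)
        births = _fertility(income[:, ti - 1], spec) * women
        nxt[0, 0, :] = births / 2.0
        nxt[0, 1, :] = births / 2.0
        pop[:, :, :, ti] = nxt

    return DriverPanel.from_arrays(countries, years, income, pop)


def _resolve_noise(noise) -> dict[str, float]:
    if noise is None:
        return dict(DEFAULT_NOISE)
    if np.isscalar(noise):
        return {k: float(noise) * v for k, v in DEFAULT_NOISE.items()}
    out = dict(DEFAULT_NOISE)
    out.update(noise)
    return out


def _logit_noise(shares: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Seeded Gaussian noise on logits, renormalized over the class axis
    (axis 0).  Raises if the noise destroys the share invariants."""
    if sigma == 0:
        return shares
    if np.any(shares <= 0) or np.any(shares >= 1):
        raise ValueError("logit noise requires shares strictly inside (0, 1)")
    logit = np.log(shares / (1.0 - shares))
    noisy = 1.0 / (1.0 + np.exp(-(logit + sigma * rng.standard_normal(
        shares.shape))))
    total = noisy.sum(axis=0)
    if not np.all(np.isfinite(total)) or np.any(total <= 0):
        raise ValueError("observation noise too large: share invariants broken")
    return noisy / total


def _lognormal(sigma: float, shape, rng) -> np.ndarray:
    """Mean-one multiplicative log-normal factors."""
    if sigma == 0:
        return np.ones(shape)
    return np.exp(sigma * rng.standard_normal(shape) - sigma ** 2 / 2.0)


def make_observations(drivers: DriverPanel, truth: ParameterSet,
                      noise=0.0, seed: int = 0, standard=None,
                      coeffs=None) -> ObservationPanels:
    """Forward-simulate with the truth parameters and perturb the outputs
    with seeded observation noise.  ``noise`` may be 0 (exact model output),
    a scalar multiplier on the default scales, or a per-variable dict.
    """
    result = run_scenario(drivers, truth, standard=standard, coeffs=coeffs)
    obs = result.to_observations()
    scales = _resolve_noise(noise if noise != 0.0 else
                            {k: 0.0 for k in DEFAULT_NOISE})
    if noise == 0.0 or all(v == 0 for v in scales.values()):
        return ObservationPanels(
            height=obs.height.copy(), bmi_adult=obs.bmi_adult.copy(),
            bmi_child=obs.bmi_child.copy(), demand=obs.demand.copy(),
            composition=obs.composition.copy())

    rng = np.random.default_rng(seed)
    height = obs.height.values * _lognormal(scales["height"],
                                            obs.height.shape, rng)
    bmi_adult = _logit_noise(obs.bmi_adult.values, scales["bmi_shares"], rng)
    bmi_child = _logit_noise(obs.bmi_child.values, scales["bmi_shares"], rng)

    intake = result.intake.values
    waste = result.waste.values
    demand = intake + waste * _lognormal(scales["waste"], waste.shape, rng)

    comp = result.composition.values
    d_model = result.demand.values
    with np.errstate(divide="ignore", invalid="ignore"):
        tree = np.stack([
            comp[0] / d_model,
            comp[1] / (d_model - comp[0]),
            comp[2] / (d_model - comp[0] - comp[1]),
        ])
    # per-level logit noise; no cross-level renormalization is needed since
    # the staple residual restores the exact sum
    noisy_tree = tree
    if scales["composition"] > 0:
        if np.any(tree <= 0) or np.any(tree >= 1):
            raise ValueError("tree shares outside (0,1); cannot apply noise")
        logit = np.log(tree / (1.0 - tree))
        noisy_tree = 1.0 / (1.0 + np.exp(-(logit + scales["composition"]
                                           * rng.standard_normal(tree.shape))))
    animal = noisy_tree[0] * demand
    empty = noisy_tree[1] * (demand - animal)
    fvn = noisy_tree[2] * (demand - animal - empty)
    staple = demand - animal - empty - fvn
    composition = np.stack([animal, empty, fvn, staple])

    cy = {"country": drivers.countries, "year": drivers.years}
    return ObservationPanels(
        height=xr.DataArray(height, dims=("sex", "country", "year"),
                            coords={"sex": list(SEXES), **cy}),
        bmi_adult=xr.DataArray(bmi_adult, dims=obs.bmi_adult.dims,
                               coords=obs.bmi_adult.coords),
        bmi_child=xr.DataArray(bmi_child, dims=obs.bmi_child.dims,
                               coords=obs.bmi_child.coords),
        demand=xr.DataArray(demand, dims=("country", "year"), coords=cy),
        composition=xr.DataArray(composition,
                                 dims=("food_group", "country", "year"),
                                 coords={"food_group": list(FOOD_GROUPS),
                                         **cy}),
    )


def make_world(spec: WorldSpec, noise=None
               ) -> tuple[DriverPanel, ObservationPanels, ParameterSet]:
    """Drivers, observations and the truth parameters in one call.

    Observation noise defaults to the spec's scales; pass ``noise=0`` for an
    exact (noiseless) world.  The observation seed is derived from the world
    seed so one integer pins everything down.
    """
    drivers = make_drivers(spec)
    if noise is None:
        noise = spec.noise
    obs = make_observations(drivers, spec.truth, noise=noise,
                            seed=(spec.seed + 1) % (2 ** 31))
    return drivers, obs, spec.truth


def write_world(spec: WorldSpec, directory: str | Path, noise=None) -> None:
    """Write a complete world (drivers + observations + truth JSON)."""
    directory = Path(directory)
    drivers, obs, truth = make_world(spec, noise=noise)
    write_drivers(drivers, directory)
    write_observations(obs, directory)
    truth.to_json(directory / "truth.json")
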