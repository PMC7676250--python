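"""Index conventions, typed panel containers, unit conversions and validation.

All panels share a common index vocabulary:

country
    opaque identifier (ISO3-style string for real data, ``C00``.. for
    synthetic worlds).
year
    representative year of a 5-year period, on the grid 1965, 1970, ..., 2100.
age
    one of 20 five-year cohorts ``0-4`` .. ``95-99`` plus the open cohort
    ``100+``.  Cohorts partition ages without overlap; ageing moves a cohort
    one class per timestep, the ``100+`` cohort absorbs.
sex
    ``male`` / ``female``.
bmi_class
    six adult classes on the kg/m^2 axis or five child classes in growth
    standard SD units.

Energy is kcal per capita per day everywhere internally; populations are in
persons.  Conversion to joules (1 kcal = 4184 J, thermochemical) happens only
at reporting boundaries.  Missing data is ``NaN``, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

# ---------------------------------------------------------------------------
# index vocabulary

YEARS: tuple[int, ...] = tuple(range(1965, 2101, 5))

AGE_COHORTS: tuple[str, ...] = tuple(
    f"{5 * i}-{5 * i + 4}" for i in range(20)
) + ("100+",)
CHILD_COHORTS: tuple[str, ...] = AGE_COHORTS[:3]   # 0-14 years
ADULT_COHORTS: tuple[str, ...] = AGE_COHORTS[3:]   # 15+ years

SEXES: tuple[str, str] = ("male", "female")

#: age groups used for BMI-share and activity regressions
AGE_GROUPS: tuple[str, str, str] = ("0-14", "15-59", "60+")
ADULT_AGE_GROUPS: tuple[str, str] = ("15-59", "60+")

ADULT_BMI_CLASSES: tuple[str, ...] = (
    "<18.5", "18.5-20", "20-25", "25-30", "30-35", ">=35"
)
#: class midpoints; open-ended classes use the midpoint of a 5-unit tail
ADULT_REPRESENTATIVE_BMI: tuple[float, ...] = (17.5, 19.25, 22.5, 27.5, 32.5, 37.5)

CHILD_BMI_CLASSES: tuple[str, ...] = (
    "<-2SD", "-2SD:-1SD", "-1SD:+1SD", "+1SD:+2SD", ">+2SD"
)
CHILD_REPRESENTATIVE_Z: tuple[float, ...] = (-2.5, -1.5, 0.0, 1.5, 2.5)

NORMAL_ADULT_CLASS = "20-25"
NORMAL_CHILD_CLASS = "-1SD:+1SD"
UNDERWEIGHT_ADULT_CLASSES: tuple[str, ...] = ("<18.5",)
UNDERWEIGHT_CHILD_CLASSES: tuple[str, ...] = ("<-2SD",)
OVERWEIGHT_ADULT_CLASSES: tuple[str, ...] = ("25-30", "30-35", ">=35")
OVERWEIGHT_CHILD_CLASSES: tuple[str, ...] = ("+1SD:+2SD", ">+2SD")

FOOD_GROUPS: tuple[str, ...] = ("animal", "empty", "fvn", "staple")

KCAL_TO_JOULES_FACTOR = 4184.0
DAYS_PER_YEAR = 365.0


def cohort_bounds(cohort: str) -> tuple[float, float]:
    """Closed-open age interval [lo, hi) covered by a cohort label."""
    if cohort == "100+":
        return (100.0, 105.0)
    lo, hi = cohort.split("-")
    return (float(lo), float(hi) + 1.0)


def cohort_midpoint(cohort: str) -> float:
    lo, hi = cohort_bounds(cohort)
    return 0.5 * (lo + hi)


def age_group_of(cohort: str) -> str:
    """Map a 5-year cohort to the 0-14 / 15-59 / 60+ regression group."""
    lo, _ = cohort_bounds(cohort)
    if lo < 15:
        return "0-14"
    if lo < 60:
        return "15-59"
    return "60+"


def kcal_to_joules(energy):
    """Convert kcal to joules (1 kcal = 4184 J, fixed convention)."""
    return np.asarray(energy, dtype=float) * KCAL_TO_JOULES_FACTOR


def annual_energy_ej(kcal_per_cap_day, population):
    """Total yearly food energy in EJ from a per-capita daily flow.

    ``kcal/cap/day * persons * 365 d/yr * 4184 J/kcal / 1e18``
    """
    kcal = np.asarray(kcal_per_cap_day, dtype=float)
    pop = np.asarray(population, dtype=float)
    return kcal * pop * DAYS_PER_YEAR * KCAL_TO_JOULES_FACTOR / 1e18


# ---------------------------------------------------------------------------
# containers


def _as_da(values, dims, coords, name):
    da = xr.DataArray(np.asarray(values, dtype=float), dims=dims,
                      coords=coords, name=name)
    return da


@dataclass
class DriverPanel:
    """Exogenous model drivers: income and population panels.

    income
        USD2005 PPP per capita per year, dims ``(country, year)``.
    population
        persons, dims ``(age, sex, country, year)``.
    """

    income: xr.DataArray
    population: xr.DataArray

    def __post_init__(self):
        self.income = self.income.transpose("country", "year")
        self.population = self.population.transpose("age", "sex", "country", "year")

    @classmethod
    def from_arrays(cls, countries: Sequence[str], years: Sequence[int],
                    income: np.ndarray, population: np.ndarray) -> "DriverPanel":
        countries = list(countries)
        years = [int(y) for y in years]
        inc = _as_da(income, ("country", "year"),
                     {"country": countries, "year": years}, "income")
        pop = _as_da(population, ("age", "sex", "country", "year"),
                     {"age": list(AGE_COHORTS), "sex": list(SEXES),
                      "country": countries, "year": years}, "population")
        return cls(income=inc, population=pop)

    @property
    def countries(self) -> list[str]:
        return [str(c) for c in self.income.coords["country"].values]

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.income.coords["year"].values]

    def subset(self, countries: Iterable[str]) -> "DriverPanel":
        countries = list(countries)
        return DriverPanel(income=self.income.sel(country=countries),
                           population=self.population.sel(country=countries))


@dataclass
class ObservationPanels:
    """Reported panels consumed by fitting and calibration.

    All arrays may contain NaN where a country-year was not observed.

    height
        15-19 cohort body height, cm, dims ``(sex, country, year)``.
    bmi_adult / bmi_child
        population shares per BMI class, dims
        ``(bmi_class, age_group, sex, country, year)`` /
        ``(bmi_class, sex, country, year)``.
    demand
        per-capita food availability, kcal/cap/day, dims ``(country, year)``.
    composition
        four-group calories, kcal/cap/day, dims ``(food_group, country, year)``.
    """

    height: xr.DataArray
    bmi_adult: xr.DataArray
    bmi_child: xr.DataArray
    demand: xr.DataArray
    composition: xr.DataArray

    @property
    def countries(self) -> list[str]:
        return [str(c) for c in self.demand.coords["country"].values]

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.demand.coords["year"].values]

    def subset(self, countries: Iterable[str]) -> "ObservationPanels":
        countries = list(countries)
        return ObservationPanels(
            height=self.height.sel(country=countries),
            bmi_adult=self.bmi_adult.sel(country=countries),
            bmi_child=self.bmi_child.sel(country=countries),
            demand=self.demand.sel(country=countries),
            composition=self.composition.sel(country=countries),
        )

    @property
    def diet_quality(self) -> xr.DataArray:
        """Observed diet-quality driver G: animal + empty calories."""
        return (self.composition.sel(food_group="animal")
                + self.composition.sel(food_group="empty"))


@dataclass
class EnergyState:
    """Per-capita energy accounting: intake I, demand D, waste X = D - I."""

    intake: np.ndarray
    demand: np.ndarray
    waste: np.ndarray

    def __post_init__(self):
        self.intake = np.asarray(self.intake, dtype=float)
        self.demand = np.asarray(self.demand, dtype=float)
        self.waste = np.asarray(self.waste, dtype=float)
        if not np.allclose(self.waste, self.demand - self.intake,
                           rtol=1e-12, atol=1e-9):
            raise ValueError("waste must equal demand - intake")
        if np.any(self.waste < -1e-9):
            raise ValueError("demand below intake (negative waste)")


# ---------------------------------------------------------------------------
# validation

SHARE_TOL = 1e-6


@dataclass(frozen=True)
class Violation:
    panel: str
    index: tuple
    message: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.panel}{self.index}: {self.message}"


def _check_year_grid(da: xr.DataArray, name: str, out: list[Violation]) -> None:
    for y in np.atleast_1d(da.coords["year"].values):
        if int(y) not in YEARS:
            out.append(Violation(name, (int(y),), "year off the 5-year grid"))


def _check_nonneg_finite(da: xr.DataArray, name: str, out: list[Violation],
                         allow_nan: bool = False) -> None:
    vals = da.values
    bad_nan = np.isnan(vals)
    if not allow_nan and bad_nan.any():
        for idx in zip(*np.nonzero(bad_nan)):
            out.append(Violation(name, _coord_tuple(da, idx), "missing value"))
            if len(out) > 200:
                return
    neg = vals < 0
    if neg.any():
        for idx in zip(*np.nonzero(neg)):
            out.append(Violation(name, _coord_tuple(da, idx), "negative value"))
            if len(out) > 200:
                return
    inf = np.isinf(vals)
    if inf.any():
        for idx in zip(*np.nonzero(inf)):
            out.append(Violation(name, _coord_tuple(da, idx), "non-finite value"))


def _coord_tuple(da: xr.DataArray, idx: tuple) -> tuple:
    return tuple(da.coords[d].values[i] for d, i in zip(da.dims, idx))


def _check_share_sums(da: xr.DataArray, name: str, out: list[Violation]) -> None:
    total = da.sum("bmi_class", skipna=False)
    bad = np.abs(total.values - 1.0) > SHARE_TOL
    bad &= ~np.isnan(total.values)
    if bad.any():
        for idx in zip(*np.nonzero(bad)):
            out.append(Violation(name, _coord_tuple(total, idx),
                                 f"shares sum to {total.values[idx]:.6f}, not 1"))
            if len(out) > 200:
                return


_KNOWN_DIMS = {"country", "year", "age", "sex", "bmi_class", "age_group",
               "food_group"}


def validate_panel(panel) -> list[Violation]:
    """Validate a panel container; an empty report means valid.

    Checks missing cells, negative values, non-finite values, BMI-share
    normalization and off-grid timesteps.  Side-effect free and idempotent.
    """
    out: list[Violation] = []
    if isinstance(panel, DriverPanel):
        _check_year_grid(panel.income, "income", out)
        _check_nonneg_finite(panel.income, "income", out)
        _check_nonneg_finite(panel.population, "population", out)
        return out
    if isinstance(panel, ObservationPanels):
        for name in ("height", "demand", "composition"):
            da = getattr(panel, name)
            _check_year_grid(da, name, out)
            _check_nonneg_finite(da, name, out, allow_nan=True)
        for name in ("bmi_adult", "bmi_child"):
            da = getattr(panel, name)
            _check_nonneg_finite(da, name, out, allow_nan=True)
            over = da.values > 1 + SHARE_TOL
            if over.any():
                for idx in zip(*np.nonzero(over)):
                    out.append(Violation(name, _coord_tuple(da, idx),
                                         "share above one"))
            _check_share_sums(da, name, out)
        return out
    if isinstance(panel, xr.DataArray):
        unknown = set(panel.dims) - _KNOWN_DIMS
        if unknown:
            raise TypeError(f"unknown index dimension(s): {sorted(unknown)}")
        name = panel.name or "panel"
        if "year" in panel.dims:
            _check_year_grid(panel, name, out)
        _check_nonneg_finite(panel, name, out, allow_nan=True)
        if "bmi_class" in panel.dims:
            _check_share_sums(panel, name, out)
        return out
    raise TypeError(f"cannot validate object of type {type(panel).__name__}")


# ---------------------------------------------------------------------------
# long-format CSV I/O

LONG_COLUMNS = ("country", "year", "age", "sex", "bmi_class", "variable", "value")


def array_to_long(da: xr.DataArray, variable: str) -> pd.DataFrame:
    """Flatten a panel to the long CSV schema, omitting unused index columns."""
    df = da.to_dataframe(name="value").reset_index()
    df = df.rename(columns={"age_group": "age", "food_group": "bmi_class"})
    df["variable"] = variable
    cols = [c for c in LONG_COLUMNS if c in df.columns]
    return df[cols]


def long_to_array(df: pd.DataFrame, dims: Sequence[str]) -> xr.DataArray:
    """Rebuild a panel from long CSV rows; ``dims`` fixes the dim order."""
    index_cols = [c for c in dims]
    wide = df.set_index(index_cols)["value"]
    da = xr.DataArray.from_series(wide)
    return da.transpose(*dims)


def write_long_csv(da: xr.DataArray, variable: str, path: str | Path) -> None:
    array_to_long(da, variable).to_csv(path, index=False, float_format="%.17g")


# -- driver panel files ------------------------------------------------------

def write_drivers(drivers: DriverPanel, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    p = directory / "drivers_income.csv"
    drivers.income.to_dataframe(name="income").reset_index().to_csv(
        p, index=False, float_format="%.17g")
    paths.append(p)
    p = directory / "drivers_population.csv"
    (drivers.population.to_dataframe(name="population").reset_index()
     .to_csv(p, index=False, float_format="%.17g"))
    paths.append(p)
    return paths


def read_drivers(directory: str | Path) -> DriverPanel:
    directory = Path(directory)
    inc = pd.read_csv(directory / "drivers_income.csv",
                      float_precision="round_trip")
    pop = pd.read_csv(directory / "drivers_population.csv",
                      float_precision="round_trip")
    income = xr.DataArray.from_series(
        inc.set_index(["country", "year"])["income"])
    population = xr.DataArray.from_series(
        pop.set_index(["age", "sex", "country", "year"])["population"])
    # restore canonical (non-alphabetical) cohort order
    population = population.reindex(age=list(AGE_COHORTS), sex=list(SEXES))
    return DriverPanel(income=income, population=population)


# -- observation panel files -------------------------------------------------

def write_observations(obs: ObservationPanels, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []

    h = obs.height.to_dataframe(name="height_cm").reset_index()
    h["age"] = "15-19"
    p = directory / "obs_height.csv"
    h[["country", "year", "age", "sex", "height_cm"]].to_csv(
        p, index=False, float_format="%.17g")
    paths.append(p)

    ad = obs.bmi_adult.to_dataframe(name="share").reset_index()
    ad = ad.rename(columns={"age_group": "agegroup"})
    ch = obs.bmi_child.to_dataframe(name="share").reset_index()
    ch["agegroup"] = "0-14"
    bmi = pd.concat([ad, ch], ignore_index=True)
    p = directory / "obs_bmi_shares.csv"
    bmi[["country", "year", "agegroup", "sex", "bmi_class", "share"]].to_csv(
        p, index=False, float_format="%.17g")
    paths.append(p)

    d = obs.demand.to_dataframe(name="demand_kcal").reset_index()
    p = directory / "obs_demand.csv"
    d[["country", "year", "demand_kcal"]].to_csv(p, index=False,
                                                 float_format="%.17g")
    paths.append(p)

    comp = obs.composition.to_dataset("food_group").to_dataframe().reset_index()
    comp = comp.rename(columns={g: f"{g}_kcal" for g in FOOD_GROUPS})
    comp["total_kcal"] = sum(comp[f"{g}_kcal"] for g in FOOD_GROUPS)
    p = directory / "obs_composition.csv"
    comp[["country", "year"] + [f"{g}_kcal" for g in FOOD_GROUPS]
         + ["total_kcal"]].to_csv(p, index=False, float_format="%.17g")
    paths.append(p)
    return paths


def read_observations(directory: str | Path) -> ObservationPanels:
    directory = Path(directory)
    h = pd.read_csv(directory / "obs_height.csv",
                    float_precision="round_trip")
    height = xr.DataArray.from_series(
        h.set_index(["sex", "country", "year"])["height_cm"])
    height = height.reindex(sex=list(SEXES))

    bmi = pd.read_csv(directory / "obs_bmi_shares.csv",
                      float_precision="round_trip")
    ad = bmi[bmi["agegroup"] != "0-14"].rename(columns={"agegroup": "age_group"})
    bmi_adult = xr.DataArray.from_series(
        ad.set_index(["bmi_class", "age_group", "sex", "country", "year"])["share"])
    bmi_adult = bmi_adult.reindex(bmi_class=list(ADULT_BMI_CLASSES),
                                  age_group=list(ADULT_AGE_GROUPS),
                                  sex=list(SEXES))
    ch = bmi[bmi["agegroup"] == "0-14"]
    bmi_child = xr.DataArray.from_series(
        ch.set_index(["bmi_class", "sex", "country", "year"])["share"])
    bmi_child = bmi_child.reindex(bmi_class=list(CHILD_BMI_CLASSES),
                                  sex=list(SEXES))

    d = pd.read_csv(directory / "obs_demand.csv",
                    float_precision="round_trip")
    demand = xr.DataArray.from_series(
        d.set_index(["country", "year"])["demand_kcal"])

    comp = pd.read_csv(directory / "obs_composition.csv",
                       float_precision="round_trip")
    comp = comp.melt(id_vars=["country", "year"],
                     value_vars=[f"{g}_kcal" for g in FOOD_GROUPS],
                     var_name="food_group", value_name="value")
    comp["food_group"] = comp["food_group"].str.removesuffix("_kcal")
    composition = xr.DataArray.from_series(
        comp.set_index(["food_group", "country", "year"])["value"])
    composition = composition.reindex(food_group=list(FOOD_GROUPS))

    return ObservationPanels(height=height.transpose("sex", "country", "year"),
                             bmi_adult=bmi_adult.transpose(
                                 "bmi_class", "age_group", "sex", "country", "year"),
                             bmi_child=bmi_child.transpose(
                                 "bmi_class", "sex", "country", "year"),
                             demand=demand.transpose("country", "year"),
                             composition=composition.transpose(
                                 "food_group", "country", "year"))
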