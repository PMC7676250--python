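"""Body height projection, BMI-class population shares and body weight.

Height of the 15-19 cohort follows a power law in the diet-quality driver G
(animal-source plus empty calories, averaged over the three preceding 5-year
timesteps).  Adult cohorts keep the height estimated when they reached adult
age; child heights are the growth-standard curve scaled by the factor by
which the current 15-19 cohort diverges from the standard at age 18.

BMI-class shares are saturating functions of per-capita income, fitted per
(class, age group, sex) stratum, then clipped to [0, 1] and renormalized so
the shares form a proper distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .datamodel import (
    ADULT_AGE_GROUPS, ADULT_BMI_CLASSES, ADULT_REPRESENTATIVE_BMI,
    AGE_COHORTS, CHILD_BMI_CLASSES, CHILD_COHORTS, CHILD_REPRESENTATIVE_Z,
    SEXES, cohort_midpoint,
)
from .fitting import PowerLawRegressor, SaturatingRegressor
from .parameters import PowerLaw, SaturatingCurve

CHILD_MIDPOINT_AGES = tuple(cohort_midpoint(c) for c in CHILD_COHORTS)
REFERENCE_ADULT_AGE = 18.0


# ---------------------------------------------------------------------------
# growth standard


@dataclass
class GrowthStandard:
    """Reference height and median BMI by age and sex.

    The bundled table (``growth_standard_synthetic.csv``) is a stylized,
    synthetic stand-in for the WHO growth-standard tables, smooth in age and
    pinned to plausible magnitudes; users may supply official tables in the
    same CSV schema (``age,sex,height_cm,median_bmi,bmi_sd``).
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"age", "sex", "height_cm", "median_bmi", "bmi_sd"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"growth standard table lacks columns {missing}")
        self.table = self.table.sort_values(["sex", "age"]).reset_index(drop=True)
        if (self.table["height_cm"] <= 0).any():
            raise ValueError("growth standard heights must be positive")

    @classmethod
    def default(cls) -> "GrowthStandard":
        path = resources.files("fooddemand") / "data/growth_standard_synthetic.csv"
        with resources.as_file(path) as p:
            return cls(pd.read_csv(p))

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthStandard":
        return cls(pd.read_csv(path))

    def _interp(self, column: str, age, sex: str):
        sub = self.table[self.table["sex"] == sex]
        return np.interp(np.asarray(age, dtype=float),
                         sub["age"].to_numpy(), sub[column].to_numpy())

    def height(self, age, sex: str):
        return self._interp("height_cm", age, sex)

    def median_bmi(self, age, sex: str):
        return self._interp("median_bmi", age, sex)

    def bmi_sd(self, age, sex: str):
        return self._interp("bmi_sd", age, sex)

    def adult_height(self, sex: str) -> float:
        return float(self.height(REFERENCE_ADULT_AGE, sex))


def child_representative_bmi(standard: GrowthStandard) -> np.ndarray:
    """Representative BMI per (child class, child cohort, sex).

    Class-representative z-scores are mapped to BMI as
    ``median_bmi + z * bmi_sd`` at the cohort midpoint age.
    """
    out = np.empty((len(CHILD_BMI_CLASSES), len(CHILD_COHORTS), len(SEXES)))
    for si, sex in enumerate(SEXES):
        med = standard.median_bmi(CHILD_MIDPOINT_AGES, sex)
        sd = standard.bmi_sd(CHILD_MIDPOINT_AGES, sex)
        for zi, z in enumerate(CHILD_REPRESENTATIVE_Z):
            out[zi, :, si] = med + z * sd
    if np.any(out <= 0):
        raise ValueError("non-positive representative child BMI")
    return out


# ---------------------------------------------------------------------------
# height


def lagged_mean_diet_quality(g_by_year: dict[int, np.ndarray],
                             year: int) -> np.ndarray | None:
    """Mean of G over the preceding three 5-year timesteps.

    Uses whatever subset of {t-15, t-10, t-5} is available; returns None when
    no history exists (the model start, where the engine falls back to the
    contemporaneous, self-consistent G).
    """
    hist = [g_by_year[t] for t in (year - 15, year - 10, year - 5)
            if t in g_by_year]
    if not hist:
        return None
    return np.mean(hist, axis=0)


def young_adult_height(height_params: dict[str, PowerLaw],
                       g_bar: np.ndarray) -> np.ndarray:
    """15-19 cohort height (cm) per sex from the diet-quality power law.

    Returns an array of shape ``(sex, country)``.
    """
    g_bar = np.asarray(g_bar, dtype=float)
    if np.any(g_bar < 0):
        raise ValueError("diet quality G must be non-negative")
    return np.stack([height_params[s](g_bar) for s in SEXES])


def assemble_heights(h1519: np.ndarray, previous: np.ndarray | None,
                     standard: GrowthStandard) -> np.ndarray:
    """Full height panel ``(age, sex, country)`` for one timestep.

    Children are the growth standard scaled by the 15-19 divergence factor;
    adult cohorts age forward unchanged (the 100+ cohort absorbs); at the
    first timestep all adult cohorts start at the 15-19 value for their sex.
    """
    n_age, n_sex = len(AGE_COHORTS), len(SEXES)
    n_c = h1519.shape[1]
    H = np.empty((n_age, n_sex, n_c))
    for si, sex in enumerate(SEXES):
        factor = h1519[si] / standard.adult_height(sex)  # (country,)
        for ci, age in enumerate(CHILD_MIDPOINT_AGES):
            H[ci, si] = standard.height(age, sex) * factor
    H[3] = h1519
    if previous is None:
        H[4:] = h1519[None, :, :]
    else:
        H[4:] = previous[3:-1]
    if np.any(H <= 0):
        raise ValueError("non-positive height")
    return H


def project_height(height_params: dict[str, PowerLaw],
                   g_by_year: dict[int, np.ndarray], year: int,
                   previous: np.ndarray | None,
                   standard: GrowthStandard) -> np.ndarray:
    """One height-projection step: Eq.-style power law for the 15-19 cohort,
    growth-standard scaling for children, cohort carrying for adults."""
    g_bar = lagged_mean_diet_quality(g_by_year, year)
    if g_bar is None:
        raise ValueError(f"no diet-quality history before {year}; "
                         "the scenario engine bootstraps the first timestep")
    h1519 = young_adult_height(height_params, g_bar)
    return assemble_heights(h1519, previous, standard)


def fit_height_regression(height_obs: xr.DataArray,
                          g_obs: xr.DataArray) -> dict[str, PowerLaw]:
    """Per-sex power-law fit of observed 15-19 height against lagged G.

    ``height_obs`` has dims (sex, country, year); ``g_obs`` (country, year).
    Height at t is paired with the mean of G over {t-15, t-10, t-5} (with the
    same fallback rule as the scenario engine).  Non-positive values in the
    fitting set raise, as the log transform is undefined.
    """
    years = [int(y) for y in g_obs.coords["year"].values]
    g_by_year = {t: g_obs.sel(year=t).values for t in years}
    out: dict[str, PowerLaw] = {}
    for sex in SEXES:
        xs, ys = [], []
        for t in [int(y) for y in height_obs.coords["year"].values]:
            gbar = lagged_mean_diet_quality(g_by_year, t)
            if gbar is None:
                gbar = g_by_year.get(t)
                if gbar is None:
                    continue
            h = height_obs.sel(sex=sex, year=t).values
            keep = np.isfinite(h) & np.isfinite(gbar)
            xs.append(np.asarray(gbar)[keep])
            ys.append(h[keep])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.size < 3:
            raise ValueError(f"need at least 3 observations to fit height "
                             f"for sex={sex}")
        est = PowerLawRegressor().fit(x, y)
        out[sex] = est.curve_()
    return out


# ---------------------------------------------------------------------------
# body weight


def body_weight(representative_bmi, height_cm):
    """``W = B * (H/100)**2`` in kg; heights are cm, BMI kg/m^2."""
    b = np.asarray(representative_bmi, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if np.any(b < 0) or np.any(h < 0):
        raise ValueError("negative BMI or height")
    return b * (h / 100.0) ** 2


def adult_representative_bmi() -> np.ndarray:
    return np.asarray(ADULT_REPRESENTATIVE_BMI, dtype=float)


# ---------------------------------------------------------------------------
# BMI-class shares


def fit_bmi_shares(bmi_adult: xr.DataArray, bmi_child: xr.DataArray,
                   income: xr.DataArray
                   ) -> dict[tuple[str, str], dict[str, SaturatingCurve]]:
    """Fit the saturating share curve per (class, age group, sex) stratum.

    Observed shares are pooled over countries and years against per-capita
    income.  Non-convergence raises an error naming the stratum.
    """
    y_flat = income.transpose("country", "year").values.ravel()
    out: dict[tuple[str, str], dict[str, SaturatingCurve]] = {}

    def fit_one(share_values, label):
        keep = np.isfinite(share_values)
        x, y = y_flat[keep], share_values[keep]
        if np.unique(x).size < 4:
            raise ValueError(f"stratum {label}: need >= 4 income levels")
        try:
            est = SaturatingRegressor(fit_baseline=True).fit(x, y)
        except RuntimeError as exc:
            raise RuntimeError(f"BMI-share fit failed for stratum {label}: "
                               f"{exc}") from exc
        return est.curve_()

    for group in ADULT_AGE_GROUPS:
        for sex in SEXES:
            curves = {}
            for cls_ in ADULT_BMI_CLASSES:
                vals = (bmi_adult.sel(bmi_class=cls_, age_group=group, sex=sex)
                        .transpose("country", "year").values.ravel())
                curves[cls_] = fit_one(vals, (cls_, group, sex))
            out[(group, sex)] = curves
    for sex in SEXES:
        curves = {}
        for cls_ in CHILD_BMI_CLASSES:
            vals = (bmi_child.sel(bmi_class=cls_, sex=sex)
                    .transpose("country", "year").values.ravel())
            curves[cls_] = fit_one(vals, (cls_, "0-14", sex))
        out[("0-14", sex)] = curves
    return out


def predict_bmi_shares(curves: dict[str, SaturatingCurve], income,
                       classes: tuple[str, ...] | None = None) -> np.ndarray:
    """Evaluate the per-class curves, clip to [0, 1] and renormalize.

    Returns an array of shape ``(n_classes,) + income.shape`` whose class
    axis sums to one everywhere.
    """
    y = np.asarray(income, dtype=float)
    if np.any(y < 0):
        raise ValueError("income must be non-negative")
    if classes is None:
        classes = tuple(curves.keys())
    raw = np.stack([np.clip(curves[c](y), 0.0, 1.0) for c in classes])
    total = raw.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("all BMI-class shares are zero; cannot normalize")
    return raw / total
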