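"""Basal metabolic rate (Schofield equations), physical activity levels and
aggregation of per-class intake to country-level per-capita intake.

BMR is linear in body weight per Schofield age bracket and sex
(``kcal/day = gamma * W + delta``); total energy expenditure — and, in
steady state, food intake — is BMR times the physical activity level (PAL)
multiplier.  The PAL is a population mix of a sedentary and an active
multiplier weighted by an income-dependent inactivity share.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import anthropometry
from .datamodel import (
    ADULT_AGE_GROUPS, AGE_COHORTS, AGE_GROUPS, CHILD_COHORTS, SEXES,
    age_group_of, cohort_midpoint,
)
from .parameters import PALParams, ParameterSet

SCHOFIELD_BRACKETS = ("0-3", "3-10", "10-18", "18-30", "30-60", "60+")


def schofield_bracket_for_age(age: float) -> str:
    """Bracket containing an age in years (upper bounds exclusive)."""
    for upper, bracket in ((3, "0-3"), (10, "3-10"), (18, "10-18"),
                           (30, "18-30"), (60, "30-60")):
        if age < upper:
            return bracket
    return "60+"


@dataclass
class SchofieldCoeffs:
    """Weight-based BMR coefficients per Schofield bracket and sex.

    The bundled table is the standard FAO/WHO/UNU weight-based coefficient
    set expressed in kcal/day (converted from MJ/day at 4.184 kJ/kcal).
    Alternative equation sets (height-inclusive, temperature-dependent) can
    be supplied as a table in the same schema.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"bracket", "sex", "gamma_kcal_per_kg", "delta_kcal"}
        if required - set(self.table.columns):
            raise ValueError("Schofield table lacks required columns")
        if (self.table["gamma_kcal_per_kg"] <= 0).any():
            raise ValueError("gamma must be positive in every bracket")
        self._lookup = {
            (r.bracket, r.sex): (float(r.gamma_kcal_per_kg), float(r.delta_kcal))
            for r in self.table.itertuples()
        }
        missing = {(b, s) for b in SCHOFIELD_BRACKETS for s in SEXES} - set(self._lookup)
        if missing:
            raise ValueError(f"Schofield table misses brackets {sorted(missing)}")

    @classmethod
    def default(cls) -> "SchofieldCoeffs":
        path = resources.files("fooddemand") / "data/schofield_coefficients.csv"
        with resources.as_file(path) as p:
            return cls(pd.read_csv(p))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SchofieldCoeffs":
        return cls(pd.read_csv(path))

    def coefficients(self, bracket: str, sex: str) -> tuple[float, float]:
        try:
            return self._lookup[(bracket, sex)]
        except KeyError:
            raise KeyError(f"no Schofield coefficients for ({bracket}, {sex})")

    def cohort_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(gamma, delta) arrays of shape (age_cohort, sex), mapping each
        5-year cohort to the bracket containing its midpoint age."""
        gamma = np.empty((len(AGE_COHORTS), len(SEXES)))
        delta = np.empty_like(gamma)
        for ai, cohort in enumerate(AGE_COHORTS):
            bracket = schofield_bracket_for_age(cohort_midpoint(cohort))
            for si, sex in enumerate(SEXES):
                gamma[ai, si], delta[ai, si] = self.coefficients(bracket, sex)
        return gamma, delta


def bmr(weight, age_cohort: str, sex: str,
        coeffs: SchofieldCoeffs | None = None):
    """Basal metabolic rate in kcal/day: ``gamma * W + delta``."""
    coeffs = coeffs or SchofieldCoeffs.default()
    if age_cohort not in AGE_COHORTS:
        raise KeyError(f"unknown age cohort {age_cohort!r}")
    w = np.asarray(weight, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative body weight")
    bracket = schofield_bracket_for_age(cohort_midpoint(age_cohort))
    gamma, delta = coeffs.coefficients(bracket, sex)
    return gamma * w + delta


def pal(income, age_group: str, sex: str, params: PALParams):
    """Activity multiplier ``A = p*sedentary + (1-p)*active`` where p is the
    income-dependent inactivity share (clipped to [0, 1])."""
    y = np.asarray(income, dtype=float)
    if np.any(y < 0):
        raise ValueError("income must be non-negative")
    p = np.clip(params.inactivity[(age_group, sex)](y), 0.0, 1.0)
    return p * params.sedentary + (1.0 - p) * params.active


def pal_state(income: np.ndarray, params: PALParams) -> np.ndarray:
    """PAL panel of shape ``(age_group, sex, country)`` for one timestep."""
    return np.stack([
        np.stack([pal(income, g, s, params) for s in SEXES])
        for g in AGE_GROUPS
    ])


def intake_per_class(weight, pal_multiplier, gamma, delta):
    """Elementwise steady-state intake ``(gamma*W + delta) * A`` kcal/day."""
    w = np.asarray(weight, dtype=float)
    return (np.asarray(gamma, dtype=float) * w
            + np.asarray(delta, dtype=float)) * np.asarray(pal_multiplier,
                                                           dtype=float)


def aggregate_intake(intake, shares, population, pregnancy_kcal=0.0):
    """Population- and share-weighted per-capita intake plus pregnancy term.

    ``intake`` and ``shares`` have shape (bmi_class, age_cohort, sex);
    ``population`` (age_cohort, sex).  The pregnancy add-on distributes
    ``N * P_{0-4} / 5`` over the whole population (the /5 converts the
    5-year birth cohort to annual births).
    """
    intake = np.asarray(intake, dtype=float)
    shares = np.asarray(shares, dtype=float)
    pop = np.asarray(population, dtype=float)
    total = pop.sum()
    if total <= 0:
        raise ValueError("total population must be positive")
    per_cohort = (intake * shares).sum(axis=0)          # (age, sex)
    base = (per_cohort * pop).sum() / total
    newborn = pop[0, :].sum()
    return base + pregnancy_kcal * newborn / 5.0 / total


# ---------------------------------------------------------------------------
# vectorized engine kernel

_CHILD_GROUP_INDEX = 0
_ADULT_GROUP_INDEX = np.array(
    [0 if age_group_of(c) == "15-59" else 1 for c in AGE_COHORTS[3:]])
_COHORT_GROUP_INDEX = np.array(
    [AGE_GROUPS.index(age_group_of(c)) for c in AGE_COHORTS])


def intake_from_anthropometry(height: np.ndarray, s_adult: np.ndarray,
                              s_child: np.ndarray, pal_panel: np.ndarray,
                              population: np.ndarray, params: ParameterSet,
                              standard, coeffs: SchofieldCoeffs) -> np.ndarray:
    """Country per-capita intake (kcal/cap/day) for one timestep.

    Shapes: height (21, 2, C); s_adult (6, 2, 2, C) over (class, adult age
    group, sex); s_child (5, 2, C); pal_panel (3, 2, C) over the three
    regression age groups; population (21, 2, C).
    """
    gamma, delta = coeffs.cohort_arrays()
    n_c = height.shape[-1]
    totals = population.sum(axis=(0, 1))
    if np.any(totals <= 0):
        raise ValueError("zero total population in at least one country")

    mean_intake = np.empty((len(AGE_COHORTS), len(SEXES), n_c))

    # children: class axis is the 5 growth-standard z-classes
    b_child = anthropometry.child_representative_bmi(standard)  # (5, 3, 2)
    h_child = height[:3]                                        # (3, 2, C)
    w = b_child[:, :, :, None] * (h_child[None] / 100.0) ** 2   # (5,3,2,C)
    a_child = pal_panel[_CHILD_GROUP_INDEX][None, None]         # (1,1,2,C)
    i_cls = (gamma[None, :3, :, None] * w
             + delta[None, :3, :, None]) * a_child
    mean_intake[:3] = (i_cls * s_child[:, None, :, :]).sum(axis=0)

    # adults: class axis is the 6 absolute-BMI classes
    b_adult = anthropometry.adult_representative_bmi()          # (6,)
    h_adult = height[3:]                                        # (18, 2, C)
    w = b_adult[:, None, None, None] * (h_adult[None] / 100.0) ** 2
    a_adult = pal_panel[_COHORT_GROUP_INDEX[3:]][None]          # (1,18,2,C)
    i_cls = (gamma[None, 3:, :, None] * w
             + delta[None, 3:, :, None]) * a_adult
    s_sel = s_adult[:, _ADULT_GROUP_INDEX, :, :]                # (6,18,2,C)
    mean_intake[3:] = (i_cls * s_sel).sum(axis=0)

    base = (mean_intake * population).sum(axis=(0, 1)) / totals
    newborn = population[0].sum(axis=0)
    return base + params.pregnancy_kcal * newborn / 5.0 / totals
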