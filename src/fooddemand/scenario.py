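"""The time-stepping engine: run simulations on the 5-year grid, apply
additive calibration, compute counterfactuals and decompose demand growth.

Within a timestep the estimation sequence is: height -> body weight -> PAL
-> intake per BMI class -> BMI-class shares -> aggregate intake -> waste and
demand -> dietary composition.  The diet-quality driver G (animal + empty
calories) feeds back into height with a three-timestep lag; at the first
simulated year, where no history exists, the engine solves the within-year
fixed point (G equals the composition the model itself produces) by
deterministic iteration.

Calibration is additive: offsets are derived as reported minus raw model
value, variable by variable in pipeline order within a calibrated pass, so
that at every reported cell the calibrated output equals the reported value
exactly.  Calibrated values are cut off below zero, share estimates above
one; cutoff events are logged.  Offsets are held constant (forward-filled)
beyond the last reported year; backfilling into the pre-data period (the
convention used for early BMI data) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import demand as demand_mod
from .anthropometry import (
    GrowthStandard, assemble_heights, lagged_mean_diet_quality,
    young_adult_height,
)
from .datamodel import (
    ADULT_AGE_GROUPS, ADULT_BMI_CLASSES, AGE_COHORTS, AGE_GROUPS,
    CHILD_BMI_CLASSES, FOOD_GROUPS, NORMAL_ADULT_CLASS, NORMAL_CHILD_CLASS,
    OVERWEIGHT_ADULT_CLASSES, OVERWEIGHT_CHILD_CLASSES, SEXES,
    UNDERWEIGHT_ADULT_CLASSES, UNDERWEIGHT_CHILD_CLASSES, YEARS,
    DriverPanel, ObservationPanels, annual_energy_ej,
)
from .energy import SchofieldCoeffs, intake_from_anthropometry, pal_state
from .parameters import ParameterSet

logger = logging.getLogger(__name__)

COUNTERFACTUAL_SWITCHES = ("underweight_to_normal", "overweight_to_normal",
                           "inactive_to_moderate", "zero_waste")
DEFAULT_FACTOR_ORDER = ("population", "requirements", "bmi", "pal", "waste",
                        "composition")

_SHARE_SUM_TOL = 1e-12


# ---------------------------------------------------------------------------
# calibration factors


@dataclass
class CalibrationFactors:
    """Additive calibration offsets per variable, country (and stratum).

    ``offsets[var]`` holds the additive factor on the full year grid of the
    run; ``reported[var]`` holds the reported value at cells where a factor
    was derived (NaN elsewhere).  At derived cells the calibrated value is
    the reported value itself — the bitwise-exact form of raw + (reported -
    raw) — and elsewhere raw + offset, clipped at physical bounds.
    """

    countries: list[str]
    years: list[int]
    offsets: dict[str, np.ndarray]
    reported: dict[str, np.ndarray]

    _SHAPES = {
        "height": ("sex", "country", "year"),
        "bmi_adult": ("bmi_class", "age_group", "sex", "country", "year"),
        "bmi_child": ("bmi_class", "sex", "country", "year"),
        "demand": ("country", "year"),
        "diet": ("tree_level", "country", "year"),
        "composition": ("tree_level", "country", "year"),
    }

    def backfill(self) -> "CalibrationFactors":
        """Copy each variable's first derived offsets backwards into years
        before any reported data (e.g. reusing the earliest BMI factors for
        the pre-data period).  The backfilled pre-period is approximate: its
        offsets were derived downstream of a slightly different trajectory.
        """
        new_off = {}
        new_rep = {k: v.copy() for k, v in self.reported.items()}
        for var, off in self.offsets.items():
            off = off.copy()
            derived_any = np.isfinite(self.reported[var]).any(
                axis=tuple(range(self.reported[var].ndim - 1)))
            idx = np.nonzero(derived_any)[0]
            if idx.size:
                first = idx[0]
                off[..., :first] = off[..., first:first + 1]
            new_off[var] = off
        return CalibrationFactors(self.countries, self.years, new_off, new_rep)

    # -- text serialization --------------------------------------------------

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for kind, table in (("offsets", self.offsets),
                            ("reported", self.reported)):
            for var, arr in table.items():
                dims = self._SHAPES[var][:arr.ndim]
                da = xr.DataArray(arr, dims=dims,
                                  coords=self._coords(var, dims))
                df = da.to_dataframe(name="value").reset_index()
                df.to_csv(directory / f"calib_{kind}_{var}.csv", index=False,
                          float_format="%.17g")

    def _coords(self, var, dims):
        coords = {}
        for d in dims:
            if d == "country":
                coords[d] = self.countries
            elif d == "year":
                coords[d] = self.years
            elif d == "sex":
                coords[d] = list(SEXES)
            elif d == "age_group":
                coords[d] = list(ADULT_AGE_GROUPS)
            elif d == "tree_level":
                coords[d] = ["animal", "empty", "fvn"]
            elif d == "bmi_class":
                coords[d] = (list(ADULT_BMI_CLASSES) if var == "bmi_adult"
                             else list(CHILD_BMI_CLASSES))
        return coords

    @classmethod
    def from_dir(cls, directory: str | Path, countries, years
                 ) -> "CalibrationFactors":
        directory = Path(directory)
        offsets, reported = {}, {}
        for kind, table in (("offsets", offsets), ("reported", reported)):
            for var, dims in cls._SHAPES.items():
                path = directory / f"calib_{kind}_{var}.csv"
                if not path.exists():
                    continue
                df = pd.read_csv(path, float_precision="round_trip")
                dims_present = [d for d in dims if d in df.columns]
                da = xr.DataArray.from_series(
                    df.set_index(dims_present)["value"])
                dummy = cls(list(countries), [int(y) for y in years], {}, {})
                da = da.reindex(**dummy._coords(var, dims_present))
                table[var] = da.transpose(*dims_present).values
        return cls([str(c) for c in countries], [int(y) for y in years],
                   offsets, reported)


class _CalibState:
    """Per-run calibration bookkeeping for one of three modes:

    off     no calibration;
    derive  compute offsets against reported panels while applying them;
    apply   replay stored factors.
    """

    def __init__(self, countries, years, factors: CalibrationFactors | None,
                 reported: ObservationPanels | None, max_year: int | None):
        self.countries = countries
        self.years = years
        n_c, n_t = len(countries), len(years)
        self.clip_log: list[tuple] = []
        shapes = {
            "height": (2, n_c, n_t),
            "bmi_adult": (6, 2, 2, n_c, n_t),
            "bmi_child": (5, 2, n_c, n_t),
            "demand": (n_c, n_t),
            "diet": (3, n_c, n_t),
            "composition": (3, n_c, n_t),
        }
        if reported is not None:
            self.mode = "derive"
            self.offsets = {k: np.zeros(s) for k, s in shapes.items()}
            self.reported = {k: np.full(s, np.nan) for k, s in shapes.items()}
            self._rep_src = self._align_reported(reported, max_year)
            self._last = {k: np.zeros(s[:-1]) for k, s in shapes.items()}
        elif factors is not None:
            self.mode = "apply"
            self.offsets = factors.offsets
            self.reported = factors.reported
        else:
            self.mode = "off"

    def _align_reported(self, obs: ObservationPanels, max_year):
        sel = dict(country=self.countries)
        ys = [int(y) for y in self.years]

        def get(da, dims):
            da = da.reindex(country=self.countries, year=ys).transpose(*dims)
            vals = da.values.astype(float).copy()
            if max_year is not None:
                mask = np.array(ys) > max_year
                vals[..., mask] = np.nan
            return vals

        comp = get(obs.composition, ("food_group", "country", "year"))
        return {
            "height": get(obs.height, ("sex", "country", "year")),
            "bmi_adult": get(obs.bmi_adult,
                             ("bmi_class", "age_group", "sex", "country",
                              "year")),
            "bmi_child": get(obs.bmi_child,
                             ("bmi_class", "sex", "country", "year")),
            "demand": get(obs.demand, ("country", "year")),
            "composition": comp[:3],  # animal, empty, fvn; staple is residual
        }

    def _log_clips(self, var, ti, mask, note):
        if mask.any():
            n = int(mask.sum())
            self.clip_log.append((var, self.years[ti], n, note))
            logger.info("calibration cutoff: %s year=%s cells=%d (%s)",
                        var, self.years[ti], n, note)

    def value(self, var, ti, raw, lo=None, hi=None):
        """Calibrated value for one timestep (raw shape = stored[..., ti])."""
        if self.mode == "off":
            return raw
        if self.mode == "derive":
            rep = self._rep_src[var][..., ti] if var in self._rep_src else \
                np.full_like(raw, np.nan)
            have = np.isfinite(rep)
            off = self._last[var]
            out = raw + off
            out[have] = rep[have]
            new_off = np.where(have, rep - raw, off)
            self._last[var] = new_off
            self.offsets[var][..., ti] = new_off
            self.reported[var][..., ti] = np.where(have, rep, np.nan)
        else:
            rep = self.reported.get(var)
            off = self.offsets.get(var)
            out = raw + (off[..., ti] if off is not None else 0.0)
            if rep is not None:
                have = np.isfinite(rep[..., ti])
                out[have] = rep[..., ti][have]
        if lo is not None:
            low = out < lo
            self._log_clips(var, ti, low, f"below {np.min(lo) if np.ndim(lo) else lo}")
            out = np.maximum(out, lo)
        if hi is not None:
            high = out > hi
            self._log_clips(var, ti, high, "above bound")
            out = np.minimum(out, hi)
        return out

    def shares(self, var, ti, raw):
        """Calibrate a share block (class axis first) and re-normalize only
        when cutoffs pushed the sum away from one."""
        out = self.value(var, ti, raw.copy(), lo=0.0, hi=1.0)
        if self.mode == "off":
            return out
        total = out.sum(axis=0)
        bad = np.abs(total - 1.0) > _SHARE_SUM_TOL
        if bad.any():
            self._log_clips(var, ti, bad, "renormalized share sum")
            out[:, bad] = out[:, bad] / total[bad]
        return out

    def composition(self, var, ti, raw_levels, demand_c):
        """Substitute reported animal/empty/fvn calories where available;
        record the implied tree-share offsets for projection years."""
        if self.mode == "off":
            return None
        if self.mode == "apply":
            rep = self.reported.get("composition")
            if rep is None:
                return None
            out = rep[..., ti].copy()
            return out
        rep = self._rep_src["composition"][..., ti]
        self.reported["composition"][..., ti] = rep
        return rep.copy()


# ---------------------------------------------------------------------------
# scenario result


@dataclass
class ScenarioResult:
    """Full model trajectory plus the inputs needed to re-run it.

    Panels: ``height`` (age, sex, country, year); ``bmi_adult`` /
    ``bmi_child`` share panels; ``pal``; per-capita energy flows ``intake``,
    ``demand``, ``waste`` and the four-group ``composition`` in
    kcal/cap/day; the model waste ratio and the diet-quality driver G.
    """

    drivers: DriverPanel
    params: ParameterSet
    standard: GrowthStandard
    coeffs: SchofieldCoeffs
    calibration: CalibrationFactors | None
    height: xr.DataArray
    bmi_adult: xr.DataArray
    bmi_child: xr.DataArray
    pal: xr.DataArray
    intake: xr.DataArray
    demand: xr.DataArray
    waste: xr.DataArray
    waste_ratio_model: xr.DataArray
    composition: xr.DataArray
    diet_quality: xr.DataArray
    clip_log: list = field(default_factory=list)

    @property
    def countries(self) -> list[str]:
        return self.drivers.countries

    @property
    def years(self) -> list[int]:
        return self.drivers.years

    def to_observations(self) -> ObservationPanels:
        """Modeled panels in the schema of reported observations."""
        return ObservationPanels(
            height=self.height.sel(age="15-19").transpose(
                "sex", "country", "year"),
            bmi_adult=self.bmi_adult,
            bmi_child=self.bmi_child,
            demand=self.demand,
            composition=self.composition,
        )


# ---------------------------------------------------------------------------
# the engine


def _check_drivers(drivers: DriverPanel) -> None:
    gaps = []
    years = drivers.years
    for y in years:
        if y not in YEARS:
            gaps.append(f"year {y} off the 5-year grid")
    if sorted(years) != list(range(min(years), max(years) + 1, 5)):
        gaps.append("year coverage is not a contiguous 5-year range")
    if np.isnan(drivers.income.values).any():
        bad = np.argwhere(np.isnan(drivers.income.values))
        for c_i, t_i in bad[:10]:
            gaps.append(f"income missing for {drivers.countries[c_i]}, "
                        f"{years[t_i]}")
    if np.isnan(drivers.population.values).any():
        gaps.append("population panel has missing cells")
    if gaps:
        raise ValueError("incomplete drivers: " + "; ".join(gaps))


def _predict_share_blocks(params: ParameterSet, income: np.ndarray):
    from .anthropometry import predict_bmi_shares

    s_ad = np.empty((len(ADULT_BMI_CLASSES), len(ADULT_AGE_GROUPS),
                     len(SEXES), income.size))
    for gi, group in enumerate(ADULT_AGE_GROUPS):
        for si, sex in enumerate(SEXES):
            s_ad[:, gi, si, :] = predict_bmi_shares(
                params.bmi_shares[(group, sex)], income,
                classes=ADULT_BMI_CLASSES)
    s_ch = np.empty((len(CHILD_BMI_CLASSES), len(SEXES), income.size))
    for si, sex in enumerate(SEXES):
        s_ch[:, si, :] = predict_bmi_shares(
            params.bmi_shares[("0-14", sex)], income,
            classes=CHILD_BMI_CLASSES)
    return s_ad, s_ch


def _step(Y, pop_t, g_bar, h_prev, ti, params, standard, coeffs, cal,
          first_year_bootstrap_h1519=None):
    """All within-timestep estimations for one year, vectorized over
    countries.  Returns a dict of state arrays."""
    if first_year_bootstrap_h1519 is not None:
        h1519_raw = first_year_bootstrap_h1519
    else:
        h1519_raw = young_adult_height(params.height, g_bar)
    h1519 = cal.value("height", ti, h1519_raw.copy(), lo=0.0)
    H = assemble_heights(h1519, h_prev, standard)

    s_ad_raw, s_ch_raw = _predict_share_blocks(params, Y)
    s_ad = cal.shares("bmi_adult", ti, s_ad_raw)
    s_ch = cal.shares("bmi_child", ti, s_ch_raw)

    A = pal_state(Y, params.pal)
    intake = intake_from_anthropometry(H, s_ad, s_ch, A, pop_t, params,
                                       standard, coeffs)
    w = demand_mod.waste_ratio(Y, params)
    d = cal.value("demand", ti, (w * intake).copy(), lo=intake)
    x = d - intake

    raw_shares = demand_mod.diet_tree_shares(Y, params)
    shares = cal.value("diet", ti, np.stack(raw_shares), lo=0.0, hi=1.0)
    comp = demand_mod.split_diet(d, Y, params,
                                 shares=(shares[0], shares[1], shares[2]))
    rep = cal.composition("composition", ti, shares, d)
    if rep is not None:
        for li, grp in enumerate(("animal", "empty", "fvn")):
            have = np.isfinite(rep[li])
            comp[grp] = np.where(have, rep[li], comp[grp])
        # enforce the nesting bounds, then rebuild the staple residual
        comp["animal"] = np.clip(comp["animal"], 0.0, d)
        comp["empty"] = np.clip(comp["empty"], 0.0, d - comp["animal"])
        comp["fvn"] = np.clip(comp["fvn"], 0.0,
                              d - comp["animal"] - comp["empty"])
        comp["staple"] = d - comp["animal"] - comp["empty"] - comp["fvn"]
        # implied tree-share offsets for projection years
        if cal.mode == "derive":
            with np.errstate(divide="ignore", invalid="ignore"):
                imp = np.stack([
                    comp["animal"] / d,
                    comp["empty"] / np.maximum(d - comp["animal"], 1e-300),
                    comp["fvn"] / np.maximum(
                        d - comp["animal"] - comp["empty"], 1e-300),
                ])
            have = np.isfinite(rep)
            off = np.where(have, imp - np.stack(raw_shares),
                           cal._last["diet"])
            cal._last["diet"] = off
            cal.offsets["diet"][..., ti] = off
    g = comp["animal"] + comp["empty"]
    return {"h1519": h1519, "H": H, "s_ad": s_ad, "s_ch": s_ch, "A": A,
            "I": intake, "w": w, "D": d, "X": x, "comp": comp, "G": g}


def _simulate(drivers: DriverPanel, params: ParameterSet,
              standard: GrowthStandard | None,
              coeffs: SchofieldCoeffs | None,
              calibration: CalibrationFactors | None = None,
              reported: ObservationPanels | None = None,
              max_reported_year: int | None = None):
    _check_drivers(drivers)
    standard = standard or GrowthStandard.default()
    coeffs = coeffs or SchofieldCoeffs.default()
    countries, years = drivers.countries, drivers.years
    n_c, n_t = len(countries), len(years)
    income = drivers.income.values
    pop = drivers.population.values

    cal = _CalibState(countries, years, calibration, reported,
                      max_reported_year)

    out = {
        "height": np.empty((len(AGE_COHORTS), 2, n_c, n_t)),
        "s_ad": np.empty((6, 2, 2, n_c, n_t)),
        "s_ch": np.empty((5, 2, n_c, n_t)),
        "A": np.empty((len(AGE_GROUPS), 2, n_c, n_t)),
        "I": np.empty((n_c, n_t)), "D": np.empty((n_c, n_t)),
        "X": np.empty((n_c, n_t)), "w": np.empty((n_c, n_t)),
        "comp": np.empty((4, n_c, n_t)), "G": np.empty((n_c, n_t)),
    }
    g_by_year: dict[int, np.ndarray] = {}
    h_prev = None
    for ti, t in enumerate(years):
        Y = income[:, ti]
        pop_t = pop[:, :, :, ti]
        g_bar = lagged_mean_diet_quality(g_by_year, t)
        if g_bar is None:
            # model start: no diet-quality history; solve the within-year
            # fixed point G = composition(G) starting from standard heights
            boot = np.stack([np.full(n_c, standard.adult_height(s))
                             for s in SEXES])
            state = _step(Y, pop_t, None, h_prev, ti, params, standard,
                          coeffs, cal, first_year_bootstrap_h1519=boot)
            for _ in range(60):
                g_cur = state["G"]
                state = _step(Y, pop_t, g_cur, h_prev, ti, params, standard,
                              coeffs, cal)
                if np.max(np.abs(state["G"] - g_cur) / (1.0 + g_cur)) < 1e-13:
                    break
            logger.info("bootstrapped diet-quality driver at model start %s", t)
        else:
            state = _step(Y, pop_t, g_bar, h_prev, ti, params, standard,
                          coeffs, cal)
        out["height"][..., ti] = state["H"]
        out["s_ad"][..., ti] = state["s_ad"]
        out["s_ch"][..., ti] = state["s_ch"]
        out["A"][..., ti] = state["A"]
        out["I"][:, ti] = state["I"]
        out["D"][:, ti] = state["D"]
        out["X"][:, ti] = state["X"]
        out["w"][:, ti] = state["w"]
        for gi, grp in enumerate(FOOD_GROUPS):
            out["comp"][gi, :, ti] = state["comp"][grp]
        out["G"][:, ti] = state["G"]
        g_by_year[t] = state["G"]
        h_prev = state["H"]

    cy = {"country": countries, "year": years}
    result = ScenarioResult(
        drivers=drivers, params=params, standard=standard, coeffs=coeffs,
        calibration=calibration,
        height=xr.DataArray(out["height"],
                            dims=("age", "sex", "country", "year"),
                            coords={"age": list(AGE_COHORTS),
                                    "sex": list(SEXES), **cy}),
        bmi_adult=xr.DataArray(out["s_ad"],
                               dims=("bmi_class", "age_group", "sex",
                                     "country", "year"),
                               coords={"bmi_class": list(ADULT_BMI_CLASSES),
                                       "age_group": list(ADULT_AGE_GROUPS),
                                       "sex": list(SEXES), **cy}),
        bmi_child=xr.DataArray(out["s_ch"],
                               dims=("bmi_class", "sex", "country", "year"),
                               coords={"bmi_class": list(CHILD_BMI_CLASSES),
                                       "sex": list(SEXES), **cy}),
        pal=xr.DataArray(out["A"], dims=("age_group", "sex", "country",
                                         "year"),
                         coords={"age_group": list(AGE_GROUPS),
                                 "sex": list(SEXES), **cy}),
        intake=xr.DataArray(out["I"], dims=("country", "year"), coords=cy),
        demand=xr.DataArray(out["D"], dims=("country", "year"), coords=cy),
        waste=xr.DataArray(out["X"], dims=("country", "year"), coords=cy),
        waste_ratio_model=xr.DataArray(out["w"], dims=("country", "year"),
                                       coords=cy),
        composition=xr.DataArray(out["comp"],
                                 dims=("food_group", "country", "year"),
                                 coords={"food_group": list(FOOD_GROUPS),
                                         **cy}),
        diet_quality=xr.DataArray(out["G"], dims=("country", "year"),
                                  coords=cy),
        clip_log=cal.clip_log,
    )
    factors = None
    if cal.mode == "derive":
        factors = CalibrationFactors(countries, years, cal.offsets,
                                     cal.reported)
        result.calibration = factors
    return result, factors


def run_scenario(drivers: DriverPanel, params: ParameterSet,
                 calibration: CalibrationFactors | None = None,
                 standard: GrowthStandard | None = None,
                 coeffs: SchofieldCoeffs | None = None) -> ScenarioResult:
    """Run the full pipeline over the drivers' year range; deterministic."""
    result, _ = _simulate(drivers, params, standard, coeffs,
                          calibration=calibration)
    return result


def calibrate(modeled: ScenarioResult, reported: ObservationPanels,
              year: int | None = None,
              backfill: bool = False) -> CalibrationFactors:
    """Derive additive calibration factors against reported panels.

    Offsets are derived at every reported cell up to ``year`` (all reported
    years when None) within a calibrated pass re-run from the modeled
    result's own drivers and parameters; they are held constant beyond the
    last derived year.  ``backfill=True`` additionally reuses each
    variable's earliest factors for pre-data years.
    """
    _, factors = _simulate(modeled.drivers, modeled.params, modeled.standard,
                           modeled.coeffs, reported=reported,
                           max_reported_year=year)
    if backfill:
        factors = factors.backfill()
    return factors


# ---------------------------------------------------------------------------
# counterfactuals


def _move_share_mass(arr, classes, class_axis_labels, target):
    """Move all share mass from ``classes`` into ``target`` (in place)."""
    labels = list(class_axis_labels)
    tgt = labels.index(target)
    for cls_ in classes:
        i = labels.index(cls_)
        arr[tgt] += arr[i]
        arr[i] = 0.0
    return arr


def counterfactual(base: ScenarioResult, switch: str, year: int) -> float:
    """Percent change in global demand when one behavioural switch is
    applied at ``year``: underweight or overweight population moved to the
    normal-weight class, the inactive population raised to active PALs, or
    household waste removed (demand set to intake).
    """
    if switch not in COUNTERFACTUAL_SWITCHES:
        raise ValueError(f"unknown counterfactual switch {switch!r}; "
                         f"expected one of {COUNTERFACTUAL_SWITCHES}")
    if year not in base.years:
        raise ValueError(f"year {year} not in the base scenario")
    ti = base.years.index(year)
    pop_t = base.drivers.population.values[:, :, :, ti]
    pop_total = pop_t.sum(axis=(0, 1))
    D = base.demand.values[:, ti]
    I = base.intake.values[:, ti]

    if switch == "zero_waste":
        d_new = I
    else:
        s_ad = base.bmi_adult.values[..., ti].copy()
        s_ch = base.bmi_child.values[..., ti].copy()
        A = base.pal.values[..., ti].copy()
        if switch == "underweight_to_normal":
            _move_share_mass(s_ad, UNDERWEIGHT_ADULT_CLASSES,
                             ADULT_BMI_CLASSES, NORMAL_ADULT_CLASS)
            _move_share_mass(s_ch, UNDERWEIGHT_CHILD_CLASSES,
                             CHILD_BMI_CLASSES, NORMAL_CHILD_CLASS)
        elif switch == "overweight_to_normal":
            _move_share_mass(s_ad, OVERWEIGHT_ADULT_CLASSES,
                             ADULT_BMI_CLASSES, NORMAL_ADULT_CLASS)
            _move_share_mass(s_ch, OVERWEIGHT_CHILD_CLASSES,
                             CHILD_BMI_CLASSES, NORMAL_CHILD_CLASS)
        elif switch == "inactive_to_moderate":
            A[:] = base.params.pal.active
        H = base.height.values[..., ti]
        i_new = intake_from_anthropometry(H, s_ad, s_ch, A, pop_t,
                                          base.params, base.standard,
                                          base.coeffs)
        w = base.waste_ratio_model.values[:, ti]
        # keep any additive demand calibration: shift demand by the modeled
        # waste response to the intake change
        d_new = np.maximum(D + w * (i_new - I), i_new)

    before = float((D * pop_total).sum())
    after = float((d_new * pop_total).sum())
    return 100.0 * (after - before) / before


# ---------------------------------------------------------------------------
# growth decomposition


@dataclass
class DecompositionResult:
    """Chained growth contributions per region, in EJ/yr.

    Contributions sum to net growth exactly by the telescoping construction;
    ``contributions_reversed`` quantifies order dependence.
    """

    measure: str
    t0: int
    t1: int
    factors: tuple[str, ...]
    contributions: dict[str, dict[str, float]]
    net: dict[str, float]
    contributions_reversed: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region, contrib in self.contributions.items():
            row = {"region": region, **contrib, "net": self.net[region]}
            rows.append(row)
        return pd.DataFrame(rows)


def _snapshot(base: ScenarioResult, year: int):
    ti = base.years.index(year)
    pop = base.drivers.population.values[:, :, :, ti]
    total = pop.sum(axis=(0, 1))
    D = base.demand.values[:, ti]
    I = base.intake.values[:, ti]
    comp = base.composition.values[:, :, ti]
    with np.errstate(divide="ignore", invalid="ignore"):
        w_eff = np.where(I > 0, D / I, 1.0)
        animal_eff = np.where(D > 0, comp[0] / D, 0.0)
    return {
        "pop_total": total,
        "structure": pop / total[None, None, :],
        "height": base.height.values[..., ti],
        "s_ad": base.bmi_adult.values[..., ti],
        "s_ch": base.bmi_child.values[..., ti],
        "pal": base.pal.values[..., ti],
        "waste": w_eff,
        "animal_share": animal_eff,
    }


def _evaluate(snaps, sel: dict[str, str], base: ScenarioResult,
              measure: str) -> np.ndarray:
    """Per-country total EJ/yr for a mixed-vintage component selection."""
    s = {f: snaps[v] for f, v in sel.items()}
    pop_total = s["population"]["pop_total"]
    structure = s["requirements"]["structure"]
    height = s["requirements"]["height"]
    pop = structure * pop_total[None, None, :]
    intake = intake_from_anthropometry(
        height, s["bmi"]["s_ad"], s["bmi"]["s_ch"], s["pal"]["pal"], pop,
        base.params, base.standard, base.coeffs)
    d = s["waste"]["waste"] * intake
    if measure == "animal":
        d = d * s["composition"]["animal_share"]
    return annual_energy_ej(d, pop_total)


def decompose_growth(base: ScenarioResult, t0: int, t1: int,
                     factors: tuple[str, ...] = DEFAULT_FACTOR_ORDER,
                     measure: str = "demand",
                     region_map: dict[str, str] | None = None
                     ) -> DecompositionResult:
    """Chained (sequential-substitution) decomposition of total demand (or
    animal-source demand) growth between two timesteps.

    The contribution of factor i is the growth when factors 1..i are at
    their ``t1`` state minus the growth when factors 1..i-1 are; the
    contributions therefore sum to net growth exactly.
    """
    if t0 not in base.years or t1 not in base.years:
        raise ValueError("t0 and t1 must both be simulated timesteps")
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    unknown = set(factors) - set(DEFAULT_FACTOR_ORDER)
    if unknown:
        raise ValueError(f"unrecognized factors: {sorted(unknown)}")
    if measure not in ("demand", "animal"):
        raise ValueError("measure must be 'demand' or 'animal'")

    snaps = {"t0": _snapshot(base, t0), "t1": _snapshot(base, t1)}
    countries = np.array(base.countries)
    if region_map is None:
        groups = {"World": np.ones(len(countries), dtype=bool)}
    else:
        missing = [c for c in countries if c not in region_map]
        if missing:
            raise KeyError(f"countries missing from region mapping: {missing}")
        groups = {r: np.array([region_map[c] == r for c in countries])
                  for r in sorted(set(region_map[c] for c in countries))}

    def chained(order):
        sel = {f: "t0" for f in DEFAULT_FACTOR_ORDER}
        prev = _evaluate(snaps, sel, base, measure)
        contrib = {r: {} for r in groups}
        for f in order:
            sel[f] = "t1"
            cur = _evaluate(snaps, sel, base, measure)
            for r, mask in groups.items():
                contrib[r][f] = float((cur - prev)[mask].sum())
            prev = cur
        # factors outside `order` stay at t0; close the telescoping with
        # a final full-t1 evaluation so contributions still sum to net
        return contrib

    order = tuple(factors)
    contributions = chained(order)
    contributions_rev = chained(tuple(reversed(order)))

    start = _evaluate(snaps, {f: "t0" for f in DEFAULT_FACTOR_ORDER}, base,
                      measure)
    sel_end = {f: "t0" for f in DEFAULT_FACTOR_ORDER}
    for f in order:
        sel_end[f] = "t1"
    end = _evaluate(snaps, sel_end, base, measure)
    net = {r: float((end - start)[mask].sum()) for r, mask in groups.items()}
    return DecompositionResult(measure=measure, t0=t0, t1=t1, factors=order,
                               contributions=contributions, net=net,
                               contributions_reversed=contributions_rev)


# ---------------------------------------------------------------------------
# global aggregates


def global_aggregate(result: ScenarioResult,
                     region_map: dict[str, str] | None = None) -> xr.Dataset:
    """Annual energy totals in EJ/yr per region and year (plus 'World').

    Total demand is ``sum_c D_c * P_c * 365 * 4184 / 1e18``; the same
    conversion applies to intake, waste and the four food groups.
    """
    countries = result.countries
    if region_map is not None:
        missing = [c for c in countries if c not in region_map]
        if missing:
            raise KeyError(f"countries missing from region mapping: {missing}")
        regions = sorted(set(region_map[c] for c in countries))
        membership = {r: [c for c in countries if region_map[c] == r]
                      for r in regions}
    else:
        membership = {}
    membership["World"] = countries

    pop_total = result.drivers.population.sum(("age", "sex"))
    data = {}
    flows = {"demand": result.demand, "intake": result.intake,
             "waste": result.waste}
    for gi, grp in enumerate(FOOD_GROUPS):
        flows[grp] = result.composition.sel(food_group=grp)

    region_names = list(membership)
    years = result.years
    for name, da in flows.items():
        vals = np.empty((len(region_names), len(years)))
        ej = annual_energy_ej(da.values, pop_total.values)
        for ri, r in enumerate(region_names):
            idx = [countries.index(c) for c in membership[r]]
            vals[ri] = ej[idx].sum(axis=0)
        data[f"{name}_ej"] = (("region", "year"), vals)
    popv = np.empty((len(region_names), len(years)))
    for ri, r in enumerate(region_names):
        idx = [countries.index(c) for c in membership[r]]
        popv[ri] = pop_total.values[idx].sum(axis=0)
    data["population"] = (("region", "year"), popv)
    return xr.Dataset(data, coords={"region": region_names, "year": years})
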