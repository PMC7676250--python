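"""Model parameter containers and the default (synthetic-truth) parameter set.

Every behavioural relation in the model is one of two saturating families:

* ``SaturatingCurve``: ``f(Y) = baseline + asymptote * Y / (half_saturation + Y)``
  used for BMI-class shares, the waste ratio (plus a fixed offset of 1), the
  three diet-tree shares and the physical-inactivity share.
* ``PowerLaw``: ``H = scale * G**exponent`` for young-adult body height as a
  function of the diet-quality driver G.

Parameters are plain frozen dataclasses with JSON round-tripping so fitted
sets can be shipped between pipeline stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .datamodel import (
    ADULT_AGE_GROUPS, ADULT_BMI_CLASSES, AGE_GROUPS, CHILD_BMI_CLASSES, SEXES,
)


@dataclass(frozen=True)
class SaturatingCurve:
    """``f(Y) = baseline + asymptote * Y / (half_saturation + Y)``.

    The asymptote may be negative for shares that shrink with income; the
    half-saturation must be positive.
    """

    baseline: float = 0.0
    asymptote: float = 0.0
    half_saturation: float = 1.0

    def __post_init__(self):
        if self.half_saturation <= 0:
            raise ValueError("half_saturation must be positive")

    def __call__(self, y):
        y = np.asarray(y, dtype=float)
        return self.baseline + self.asymptote * y / (self.half_saturation + y)


@dataclass(frozen=True)
class PowerLaw:
    """``f(g) = scale * g**exponent`` with scale > 0."""

    scale: float
    exponent: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def __call__(self, g):
        g = np.asarray(g, dtype=float)
        return self.scale * np.power(g, self.exponent)


@dataclass
class PALParams:
    """Physical-activity-level construction.

    The inactivity share p(Y) follows a saturating curve per age group and
    sex; the PAL multiplier is the population mix
    ``A = p * sedentary + (1 - p) * active``.  Default multipliers are the
    FAO/WHO/UNU category midpoints (sedentary 1.53, active 1.76).
    """

    inactivity: dict[tuple[str, str], SaturatingCurve]
    sedentary: float = 1.53
    active: float = 1.76

    def __post_init__(self):
        if not (1.2 <= self.sedentary < self.active <= 2.5):
            raise ValueError("need 1.2 <= sedentary < active <= 2.5")


@dataclass
class ParameterSet:
    """All fitted constants of the demand model.

    height
        per-sex power law for the 15-19 cohort height vs diet quality G.
    bmi_shares
        per (age_group, sex) stratum: per-class saturating share curves.
    waste
        the excess ratio D/I - 1 as a saturating curve in income
        (asymptote = epsilon, half_saturation = zeta).
    diet_animal / diet_empty / diet_fvn
        the nested diet-tree shares (eta, theta), (iota, kappa), (lambda, mu).
    pal
        the activity construction.
    pregnancy_kcal
        additional kcal/day sustained for one year per newborn.
    """

    height: dict[str, PowerLaw]
    bmi_shares: dict[tuple[str, str], dict[str, SaturatingCurve]]
    waste: SaturatingCurve
    diet_animal: SaturatingCurve
    diet_empty: SaturatingCurve
    diet_fvn: SaturatingCurve
    pal: PALParams
    pregnancy_kcal: float = 460.0

    # convenience accessors for the waste parameters' conventional names
    @property
    def epsilon(self) -> float:
        return self.waste.asymptote

    @property
    def zeta(self) -> float:
        return self.waste.half_saturation

    def classes_for(self, age_group: str) -> tuple[str, ...]:
        return CHILD_BMI_CLASSES if age_group == "0-14" else ADULT_BMI_CLASSES

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "height": {s: asdict(p) for s, p in self.height.items()},
            "bmi_shares": {
                f"{g}|{s}": {cls: asdict(c) for cls, c in curves.items()}
                for (g, s), curves in self.bmi_shares.items()
            },
            "waste": asdict(self.waste),
            "diet_animal": asdict(self.diet_animal),
            "diet_empty": asdict(self.diet_empty),
            "diet_fvn": asdict(self.diet_fvn),
            "pal": {
                "inactivity": {f"{g}|{s}": asdict(c)
                               for (g, s), c in self.pal.inactivity.items()},
                "sedentary": self.pal.sedentary,
                "active": self.pal.active,
            },
            "pregnancy_kcal": self.pregnancy_kcal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        def key(k):
            g, s = k.split("|")
            return (g, s)

        return cls(
            height={s: PowerLaw(**p) for s, p in d["height"].items()},
            bmi_shares={key(k): {cls_: SaturatingCurve(**c)
                                 for cls_, c in curves.items()}
                        for k, curves in d["bmi_shares"].items()},
            waste=SaturatingCurve(**d["waste"]),
            diet_animal=SaturatingCurve(**d["diet_animal"]),
            diet_empty=SaturatingCurve(**d["diet_empty"]),
            diet_fvn=SaturatingCurve(**d["diet_fvn"]),
            pal=PALParams(
                inactivity={key(k): SaturatingCurve(**c)
                            for k, c in d["pal"]["inactivity"].items()},
                sedentary=d["pal"]["sedentary"],
                active=d["pal"]["active"],
            ),
            pregnancy_kcal=d["pregnancy_kcal"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def flat(self) -> dict[str, float]:
        """Flatten every scalar parameter to ``name -> value`` (for reports
        and recovery checks)."""
        out: dict[str, float] = {}
        for s, p in self.height.items():
            out[f"height.{s}.scale"] = p.scale
            out[f"height.{s}.exponent"] = p.exponent
        for (g, s), curves in self.bmi_shares.items():
            for cls_, c in curves.items():
                out[f"bmi.{g}.{s}.{cls_}.baseline"] = c.baseline
                out[f"bmi.{g}.{s}.{cls_}.asymptote"] = c.asymptote
                out[f"bmi.{g}.{s}.{cls_}.half_saturation"] = c.half_saturation
        out["waste.epsilon"] = self.waste.asymptote
        out["waste.zeta"] = self.waste.half_saturation
        for name, c in (("animal", self.diet_animal), ("empty", self.diet_empty),
                        ("fvn", self.diet_fvn)):
            out[f"diet.{name}.asymptote"] = c.asymptote
            out[f"diet.{name}.half_saturation"] = c.half_saturation
        return out


def default_parameters() -> ParameterSet:
    """The reference parameter set.

    Doubles as the synthetic-truth parameter set of the world generator.
    Values are chosen so the synthetic nutrition transition is realistic in
    magnitude: adult heights around 155-180 cm, waste ratios saturating at
    1.5, an animal-calorie share saturating at 35%, BMI-share curves whose
    raw per-stratum sums are exactly 1 at every income (so clipping and
    renormalization are no-ops on clean data).
    """
    bmi = {}

    def stratum(classes, baselines, deltas, k):
        assert abs(sum(baselines) - 1.0) < 1e-12
        assert abs(sum(deltas)) < 1e-12
        return {cls_: SaturatingCurve(c, d, k)
                for cls_, c, d in zip(classes, baselines, deltas)}

    bmi[("15-59", "male")] = stratum(
        ADULT_BMI_CLASSES,
        [0.12, 0.16, 0.47, 0.15, 0.07, 0.03],
        [-0.09, -0.11, -0.20, 0.20, 0.13, 0.07], 10000.0)
    bmi[("15-59", "female")] = stratum(
        ADULT_BMI_CLASSES,
        [0.14, 0.16, 0.45, 0.14, 0.07, 0.04],
        [-0.11, -0.10, -0.17, 0.15, 0.14, 0.09], 9000.0)
    bmi[("60+", "male")] = stratum(
        ADULT_BMI_CLASSES,
        [0.15, 0.17, 0.43, 0.15, 0.07, 0.03],
        [-0.12, -0.12, -0.14, 0.18, 0.12, 0.08], 8000.0)
    bmi[("60+", "female")] = stratum(
        ADULT_BMI_CLASSES,
        [0.16, 0.16, 0.42, 0.15, 0.08, 0.03],
        [-0.13, -0.11, -0.13, 0.15, 0.13, 0.09], 8500.0)
    bmi[("0-14", "male")] = stratum(
        CHILD_BMI_CLASSES,
        [0.16, 0.20, 0.52, 0.08, 0.04],
        [-0.12, -0.10, -0.06, 0.16, 0.12], 7000.0)
    bmi[("0-14", "female")] = stratum(
        CHILD_BMI_CLASSES,
        [0.15, 0.19, 0.54, 0.08, 0.04],
        [-0.11, -0.09, -0.07, 0.15, 0.12], 7500.0)

    pal = PALParams(inactivity={
        ("0-14", "male"): SaturatingCurve(0.20, 0.0, 10000.0),
        ("0-14", "female"): SaturatingCurve(0.20, 0.0, 10000.0),
        ("15-59", "male"): SaturatingCurve(0.10, 0.35, 15000.0),
        ("15-59", "female"): SaturatingCurve(0.15, 0.35, 15000.0),
        ("60+", "male"): SaturatingCurve(0.25, 0.45, 15000.0),
        ("60+", "female"): SaturatingCurve(0.30, 0.40, 15000.0),
    })

    return ParameterSet(
        height={"male": PowerLaw(116.0, 0.06),
                "female": PowerLaw(107.0, 0.06)},
        bmi_shares=bmi,
        waste=SaturatingCurve(0.0, 0.5, 10000.0),
        diet_animal=SaturatingCurve(0.0, 0.35, 10000.0),
        diet_empty=SaturatingCurve(0.0, 0.35, 8000.0),
        diet_fvn=SaturatingCurve(0.0, 0.25, 6000.0),
        pal=pal,
        pregnancy_kcal=460.0,
    )
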