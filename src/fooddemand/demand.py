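"""Food demand from intake via the income-dependent waste ratio, and the
nested four-group dietary composition tree.

Demand D (FAOSTAT-style availability) exceeds intake I by the household
waste X; the ratio D/I saturates in income.  Composition is split after
demand in a fixed nesting — animal calories first, then empty calories from
the plant remainder, then fruits/vegetables/nuts, with staples as the
residual — which guarantees the four groups sum to total demand exactly.
"""

from __future__ import annotations

import numpy as np

from .datamodel import EnergyState
from .parameters import ParameterSet, SaturatingCurve


def waste_ratio(income, params: SaturatingCurve | ParameterSet):
    """Demand/intake ratio ``1 + eps*Y/(zeta+Y)`` (1 at Y=0, 1+eps at inf)."""
    curve = params.waste if isinstance(params, ParameterSet) else params
    y = np.asarray(income, dtype=float)
    if np.any(y < 0):
        raise ValueError("income must be non-negative")
    return 1.0 + curve(y)


def demand_from_intake(intake, ratio) -> EnergyState:
    """``D = ratio * I``, ``X = D - I``; a ratio below 1 is a data error
    (intake exceeding availability) and is surfaced, not clipped."""
    i = np.asarray(intake, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if np.any(i < 0):
        raise ValueError("intake must be non-negative")
    if np.any(r < 1):
        raise ValueError("demand/intake ratio below 1")
    d = r * i
    return EnergyState(intake=i, demand=d, waste=d - i)


def diet_tree_shares(income, params: ParameterSet):
    """The three nested shares (animal of D, empty of D-L, fvn of D-L-E)."""
    y = np.asarray(income, dtype=float)
    return (np.clip(params.diet_animal(y), 0.0, 1.0),
            np.clip(params.diet_empty(y), 0.0, 1.0),
            np.clip(params.diet_fvn(y), 0.0, 1.0))


def split_diet(demand_kcal, income, params: ParameterSet,
               shares: tuple | None = None) -> dict[str, np.ndarray]:
    """Split total demand into animal L, empty E, fruit/veg/nut V and the
    staple residual R = D - L - E - V.  Non-negativity follows from the
    share bounds; the components sum to D by construction.
    """
    d = np.asarray(demand_kcal, dtype=float)
    if np.any(d < 0):
        raise ValueError("demand must be non-negative")
    if shares is None:
        shares = diet_tree_shares(income, params)
    s_animal, s_empty, s_fvn = shares
    animal = s_animal * d
    empty = s_empty * (d - animal)
    fvn = s_fvn * (d - animal - empty)
    staple = d - animal - empty - fvn
    return {"animal": animal, "empty": empty, "fvn": fvn, "staple": staple}


def animal_share(composition: dict[str, np.ndarray]) -> np.ndarray:
    """Share of animal-source calories in total demand, L/D."""
    total = sum(composition[g] for g in ("animal", "empty", "fvn", "staple"))
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total demand must be positive")
    return np.asarray(composition["animal"], dtype=float) / total
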