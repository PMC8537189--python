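"""Retention efficiency at leaf, tree, and green-area scales.

Only the surface (rain-removable) PM pool enters the efficiency accounting:
in-wax PM cannot be removed by rainfall or wind, so it represents a
saturating stock rather than a renewable flux.  Three scales:

* ``AE_leaf`` (mg m^-2 d^-1): deposition density divided by exposure time.
* ``AE_plant`` (mg d^-1): AE_leaf times the total leaf area of one plant,
  LA = LAI x (pi/4) D^2, with D the crown diameter.
* ``AE_land`` (mg m^-2 d^-1): AE_leaf times LAI — deposition per unit of
  greened ground, the scale most relevant for planting decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import ValidationError

#: Fractions of the surface (water-wash) pool, in reporting order.
SPM_FRACTIONS = ("DPM", "PM_0.1-2.5", "PM_2.5-10", "PM_>10")
#: The derived wash total.
SPM_TOTAL = "SPM"
SCALES = ("leaf", "plant", "land")

FractionMap = dict[str, float]


def ae_leaf(density_mg_per_m2: Mapping[str, float], exposure_days: float) -> FractionMap:
    """Per-leaf-area retention efficiency (mg m^-2 d^-1) per SPM fraction.

    Input keys must be SPM-side fractions only; the derived SPM total is
    appended.  Passing in-wax (chloroform) fractions is an error because
    efficiency is defined for the rain-removable pool only.
    """
    if exposure_days <= 0:
        raise ValidationError("exposure_days must be > 0")
    bad = [k for k in density_mg_per_m2 if k not in SPM_FRACTIONS]
    if bad:
        raise ValidationError(
            f"efficiency is defined for surface-PM fractions {SPM_FRACTIONS} only; "
            f"got {bad}"
        )
    missing = [k for k in SPM_FRACTIONS if k not in density_mg_per_m2]
    if missing:
        raise ValidationError(f"missing SPM fractions {missing}")
    out = {k: density_mg_per_m2[k] / exposure_days for k in SPM_FRACTIONS}
    out[SPM_TOTAL] = sum(out.values())
    return out


def total_leaf_area(lai: float, crown_diameter_m: float) -> float:
    """Total leaf area LA (m^2) of one plant: LAI x D^2 x pi/4."""
    if lai <= 0 or crown_diameter_m <= 0:
        raise ValidationError("LAI and crown diameter must be > 0")
    return lai * crown_diameter_m**2 * math.pi / 4.0


def ae_plant(ae_leaf_map: Mapping[str, float], leaf_area_m2: float) -> FractionMap:
    """Whole-plant retention efficiency (mg d^-1): AE_leaf x LA, elementwise."""
    if leaf_area_m2 <= 0:
        raise ValidationError("total leaf area must be > 0")
    return {k: v * leaf_area_m2 for k, v in ae_leaf_map.items()}


def ae_land(ae_leaf_map: Mapping[str, float], lai: float) -> FractionMap:
    """Green-area retention efficiency (mg m^-2 d^-1): AE_leaf x LAI."""
    if lai <= 0:
        raise ValidationError("LAI must be > 0")
    return {k: v * lai for k, v in ae_leaf_map.items()}


@dataclass(frozen=True)
class Ranking:
    """Descending ranking of species by one efficiency value."""

    ordered: tuple[tuple[str, float], ...]  # (species_id, value), descending

    @property
    def max_species(self) -> str:
        return self.ordered[0][0]

    @property
    def max_value(self) -> float:
        return self.ordered[0][1]

    @property
    def min_species(self) -> str:
        return self.ordered[-1][0]

    @property
    def min_value(self) -> float:
        return self.ordered[-1][1]


def rank_species(values: Mapping[str, float]) -> Ranking:
    """Rank species by a scalar efficiency, descending; ties break alphabetically."""
    if not values:
        raise ValidationError("cannot rank an empty set of species")
    ordered = tuple(sorted(values.items(), key=lambda kv: (-kv[1], kv[0])))
    return Ranking(ordered=ordered)
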