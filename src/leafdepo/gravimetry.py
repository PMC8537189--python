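"""Raw measurements to masses and areas.

Three primitive quantities feed the PM inventory:

* **Insoluble PM on a filter** — each microporous membrane is weighed before
  (tare) and after (loaded) filtration, several times each to damp balance
  noise; the PM mass is the difference of the replicate means.
* **Soluble PM in the filtrate** — whatever passes the finest (0.1 um)
  membrane is quantified as total dissolved solids: concentration (mg/L,
  conductivity meter) times eluate volume (L).
* **Needle surface area** — conifer needle batches are not scanned; their
  total surface area follows from mean needle length, needle count, and
  mean displaced volume, treating each needle as a cylinder-like solid:

      A = 2 L (1 + pi/n) sqrt(n V' / (pi L))

All masses are in mg, areas in m^2, volumes of liquid in L and of needles
in m^3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .errors import MeasurementError, ValidationError

#: Default tolerance (mg) below which a negative loaded-minus-tare difference
#: is attributed to balance noise and clamped to zero.  Matches the precision
#: class of a 0.1 mg analytical balance.
DEFAULT_QC_TOLERANCE_MG = 0.05

WASH_STEPS = ("water", "chloroform")
PORE_SIZES_UM = (10.0, 2.5, 0.1)


@dataclass(frozen=True)
class FilterWeighing:
    """Tare/loaded weighings for one membrane in the filtration cascade."""

    batch_id: str
    wash_step: str  # "water" or "chloroform"
    pore_um: float  # 10, 2.5 or 0.1
    tare_mg: tuple[float, ...]
    loaded_mg: tuple[float, ...]

    def __post_init__(self):
        if self.wash_step not in WASH_STEPS:
            raise ValidationError(
                f"wash_step must be one of {WASH_STEPS}, got {self.wash_step!r}"
            )
        if self.pore_um not in PORE_SIZES_UM:
            raise ValidationError(
                f"pore_um must be one of {PORE_SIZES_UM}, got {self.pore_um!r}"
            )
        if not self.tare_mg or not self.loaded_mg:
            raise ValidationError("at least one tare and one loaded replicate required")
        if any(m <= 0 for m in self.tare_mg) or any(m <= 0 for m in self.loaded_mg):
            raise ValidationError("filter masses must be positive")


@dataclass(frozen=True)
class TDSReading:
    """Total-dissolved-solids reading for the filtrate of one wash step."""

    batch_id: str
    wash_step: str
    concentration_mg_per_l: float
    volume_l: float

    def __post_init__(self):
        if self.wash_step not in WASH_STEPS:
            raise ValidationError(
                f"wash_step must be one of {WASH_STEPS}, got {self.wash_step!r}"
            )
        if self.concentration_mg_per_l < 0:
            raise ValidationError("TDS concentration must be >= 0")
        if self.volume_l <= 0:
            raise ValidationError("eluate volume must be > 0")


@dataclass(frozen=True)
class NeedleDims:
    """Mean length (m), count, and mean displaced volume (m^3) of needles."""

    length_m: float
    count: float
    volume_m3: float

    def __post_init__(self):
        if self.length_m <= 0 or self.count <= 0 or self.volume_m3 <= 0:
            raise ValidationError("needle length, count and volume must be > 0")


def filter_pm_mass(
    w: FilterWeighing, qc_tolerance_mg: float = DEFAULT_QC_TOLERANCE_MG
) -> float:
    """PM mass (mg) intercepted by one membrane: mean(loaded) - mean(tare).

    A small negative difference (|diff| <= ``qc_tolerance_mg``) is treated as
    balance noise and clamped to 0.0 with a warning; a larger negative
    difference indicates a data error and raises :class:`MeasurementError`.
    """
    diff = _mean(w.loaded_mg) - _mean(w.tare_mg)
    if diff < 0:
        if -diff <= qc_tolerance_mg:
            warnings.warn(
                f"batch {w.batch_id} ({w.wash_step}, {w.pore_um} um): "
                f"negative mass difference {diff:.4f} mg within QC tolerance, "
                "clamped to 0",
                stacklevel=2,
            )
            return 0.0
        raise MeasurementError(
            f"batch {w.batch_id} ({w.wash_step}, {w.pore_um} um): loaded mean "
            f"below tare mean by {-diff:.4f} mg, beyond QC tolerance "
            f"{qc_tolerance_mg} mg"
        )
    return diff


def soluble_mass(r: TDSReading) -> float:
    """Soluble PM mass (mg) = TDS concentration x eluate volume.

    This is the water-soluble fraction (DPM) for the water wash and the
    organic-soluble fraction (OPM) for the chloroform wash.
    """
    return r.concentration_mg_per_l * r.volume_l


def needle_area(d: NeedleDims) -> float:
    """Total surface area (m^2) of a batch of conifer needles.

    A = 2 L (1 + pi/n) sqrt(n V' / (pi L)), from mean length L, count n and
    mean displaced volume V'.  Dimensional check: sqrt(m^3 / m) = m, times
    the length factor gives m^2.
    """
    a = (
        2.0
        * d.length_m
        * (1.0 + math.pi / d.count)
        * math.sqrt(d.count * d.volume_m3 / (math.pi * d.length_m))
    )
    if not math.isfinite(a):
        raise ValidationError(f"needle area is not finite for {d}")
    return a


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs)
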