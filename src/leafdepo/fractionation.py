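"""Per-batch PM inventories, mass proportions, and leaf-area densities.

Each leaf batch is eluted in two wash steps — water + brushing (surface PM,
SPM, the rain-removable pool) then chloroform (in-wax PM, WPM) — and each
eluate is pumped through a 10 um, 2.5 um, 0.1 um membrane cascade.  That
yields, per wash step, three insoluble size fractions (>10, 2.5-10,
0.1-2.5 um) plus a soluble fraction (TDS of the final filtrate: DPM for
water, OPM for chloroform): an eight-cell mass inventory per batch.  Wash
totals (SPM, WPM) are always derived sums, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ValidationError
from .gravimetry import (
    DEFAULT_QC_TOLERANCE_MG,
    FilterWeighing,
    TDSReading,
    filter_pm_mass,
    soluble_mass,
)

#: Insoluble size-fraction labels, finest to coarsest.
SIZE_FRACTIONS = ("PM_0.1-2.5", "PM_2.5-10", "PM_>10")
#: Soluble-fraction label per wash step.
SOLUBLE_FRACTION = {"water": "DPM", "chloroform": "OPM"}
#: Cascade semantics: membrane pore size (um) -> size-fraction label.
PORE_TO_FRACTION = {10.0: "PM_>10", 2.5: "PM_2.5-10", 0.1: "PM_0.1-2.5"}
WASH_STEPS = ("water", "chloroform")

#: All 8 inventory cells in canonical order: (wash_step, fraction).
INVENTORY_CELLS: tuple[tuple[str, str], ...] = tuple(
    (step, frac)
    for step in WASH_STEPS
    for frac in (SOLUBLE_FRACTION[step],) + SIZE_FRACTIONS
)

Cell = tuple[str, str]


@dataclass(frozen=True)
class PMInventory:
    """Eight-cell PM mass map (mg) for one batch, plus its leaf area (m^2)."""

    batch_id: str
    masses: Mapping[Cell, float]
    leaf_area_m2: float

    def __post_init__(self):
        missing = [c for c in INVENTORY_CELLS if c not in self.masses]
        if missing:
            raise ValidationError(f"batch {self.batch_id}: missing cells {missing}")
        extra = [c for c in self.masses if c not in INVENTORY_CELLS]
        if extra:
            raise ValidationError(f"batch {self.batch_id}: unknown cells {extra}")
        if any(m < 0 for m in self.masses.values()):
            raise ValidationError(f"batch {self.batch_id}: negative mass")
        if self.leaf_area_m2 <= 0:
            raise ValidationError(f"batch {self.batch_id}: leaf area must be > 0")

    def wash_total(self, step: str) -> float:
        """Derived SPM (water) or WPM (chloroform) total, mg."""
        return sum(v for (s, _), v in self.masses.items() if s == step)

    @property
    def spm_total(self) -> float:
        return self.wash_total("water")

    @property
    def wpm_total(self) -> float:
        return self.wash_total("chloroform")

    @property
    def total(self) -> float:
        return self.spm_total + self.wpm_total


def assemble_inventory(
    batch_id: str,
    weighings: Iterable[FilterWeighing],
    tds: Iterable[TDSReading],
    leaf_area_m2: float,
    qc_tolerance_mg: float = DEFAULT_QC_TOLERANCE_MG,
) -> PMInventory:
    """Build the 8-cell inventory of one batch from its raw measurements.

    Requires exactly three filter weighings (one per pore size) and one TDS
    reading per wash step; duplicates or missing cells raise with the cell
    named.
    """
    masses: dict[Cell, float] = {}
    for w in weighings:
        if w.batch_id != batch_id:
            raise ValidationError(
                f"weighing for batch {w.batch_id} passed to batch {batch_id}"
            )
        cell = (w.wash_step, PORE_TO_FRACTION[w.pore_um])
        if cell in masses:
            raise ValidationError(f"batch {batch_id}: duplicate weighing for {cell}")
        masses[cell] = filter_pm_mass(w, qc_tolerance_mg=qc_tolerance_mg)
    for r in tds:
        if r.batch_id != batch_id:
            raise ValidationError(
                f"TDS reading for batch {r.batch_id} passed to batch {batch_id}"
            )
        cell = (r.wash_step, SOLUBLE_FRACTION[r.wash_step])
        if cell in masses:
            raise ValidationError(f"batch {batch_id}: duplicate TDS reading for {cell}")
        masses[cell] = soluble_mass(r)

    missing = [c for c in INVENTORY_CELLS if c not in masses]
    if missing:
        raise ValidationError(f"batch {batch_id}: missing measurement for {missing}")
    return PMInventory(batch_id=batch_id, masses=masses, leaf_area_m2=leaf_area_m2)


def mass_proportions(inv: PMInventory) -> dict[Cell, float]:
    """Percent of total PM in each of the 8 cells; sums to 100."""
    total = inv.total
    if total <= 0:
        raise ValidationError(
            f"batch {inv.batch_id}: total PM is zero, proportions undefined"
        )
    return {cell: 100.0 * m / total for cell, m in inv.masses.items()}


def density_per_leaf_area(inv: PMInventory) -> dict[Cell, float]:
    """Mass per unit leaf area (mg/m^2) for each inventory cell."""
    return {cell: m / inv.leaf_area_m2 for cell, m in inv.masses.items()}


def species_mean_densities(
    inventories: Iterable[PMInventory],
) -> dict[Cell, float]:
    """Unweighted mean of per-batch densities — the species-level estimate.

    The batches of a species differ in leaf count and area, so each batch is
    first normalised to mg/m^2 and the batch densities are then averaged
    with equal weight.
    """
    invs = list(inventories)
    if not invs:
        raise ValidationError("no inventories to aggregate")
    acc = {cell: 0.0 for cell in INVENTORY_CELLS}
    for inv in invs:
        for cell, d in density_per_leaf_area(inv).items():
            acc[cell] += d
    return {cell: v / len(invs) for cell, v in acc.items()}
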