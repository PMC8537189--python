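"""Built-in reference dataset: twenty temperate evergreen species.

Ships the published per-species summary tables from the winter field
campaign this pipeline is modelled on (Xi'an, China; 7-day exposure,
2-4 individuals per species, three leaf batches each):

* ``load_efficiency()`` — retention efficiency of the surface-PM pool per
  species, fraction (DPM, PM 0.1-2.5, 2.5-10, >10 um, SPM total) and scale
  (per leaf area mg m^-2 d^-1, per plant mg d^-1, per green area
  mg m^-2 d^-1).
* ``load_wettability()`` — mean +/- SD adaxial contact angles for water and
  diiodomethane, and the reported Owens-Wendt surface free energy
  components (mJ/m^2).
* ``load_species()`` — taxonomy, life form, leaf texture and the reported
  capacity cluster (1 = smallest deposited PM, 3 = largest).

Code caveat: the efficiency table labels *Phyllostachys viridis* ``PhSu``
while the species table defines ``PhVi`` (and no ``PhSu``).  Both codes are
shipped verbatim; :func:`code_mismatches` reports the discrepancy and the
loaders emit a warning so downstream joins do not silently drop the
species.  ``CODE_ALIASES`` maps the orphan code to its presumed partner
for callers who choose to reconcile.
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

#: Orphan species code in the efficiency table -> presumed species-table code.
CODE_ALIASES = {"PhSu": "PhVi"}

#: Species whose reported polar component is not reproducible from its mean
#: angles: the unconstrained polar root is marginally negative and clamps to
#: zero, while the published table prints 0.1 mJ/m^2.
DEGENERATE_SFE_SPECIES = ("TrRe",)


def _read(name: str) -> pd.DataFrame:
    with resources.files("leafdepo.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_efficiency() -> pd.DataFrame:
    """Long table: species_id, scale {leaf,plant,land}, fraction, value."""
    df = _read("reference_efficiency.csv")
    _warn_on_mismatch(df["species_id"])
    return df


def load_wettability() -> pd.DataFrame:
    """Per-species contact angles (deg) and surface free energy (mJ/m^2)."""
    return _read("reference_wettability.csv")


def load_species() -> pd.DataFrame:
    """Species metadata and reported capacity cluster."""
    return _read("reference_species.csv")


def efficiency_wide(scale: str) -> pd.DataFrame:
    """Efficiency at one scale, species x fraction (columns incl. SPM)."""
    df = load_efficiency()
    sub = df[df["scale"] == scale]
    return sub.pivot(index="species_id", columns="fraction", values="value")


def code_mismatches() -> dict[str, str]:
    """Species codes present in the efficiency table but absent from the
    species table, mapped to their presumed alias (empty string if none)."""
    eff = set(_read("reference_efficiency.csv")["species_id"])
    spp = set(_read("reference_species.csv")["species_id"])
    return {code: CODE_ALIASES.get(code, "") for code in sorted(eff - spp)}


def _warn_on_mismatch(codes: pd.Series) -> None:
    spp = set(_read("reference_species.csv")["species_id"])
    orphans = sorted(set(codes) - spp)
    if orphans:
        warnings.warn(
            f"reference efficiency table uses species codes {orphans} that the "
            f"species table does not define (known aliases: {CODE_ALIASES})",
            stacklevel=3,
        )
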