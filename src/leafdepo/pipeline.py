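"""End-to-end analysis: study bundle -> quantities, statistics, report tables.

Stages (each failure is wrapped in :class:`~leafdepo.errors.StageError`
naming the stage and the offending record):

1. ``gravimetry``      raw weighings/TDS -> per-batch 8-cell inventories
2. ``fractionation``   inventories -> densities (mg/m^2), species means,
                       mass proportions (%)
3. ``surface_energy``  contact angles -> wettability summary + Owens-Wendt SFE
4. ``efficiency``      SPM densities + morphometrics -> AE at leaf/plant/land
5. ``stats``           ANOVA/Tukey across species, PM vs surface-property
                       correlations, K-means capacity clusters
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import fractionation as frac
from . import stats as st
from .efficiency import (
    SPM_FRACTIONS,
    SPM_TOTAL,
    ae_land,
    ae_leaf,
    ae_plant,
    total_leaf_area,
)
from .errors import LeafDepoError, StageError
from .gravimetry import DEFAULT_QC_TOLERANCE_MG, FilterWeighing, TDSReading
from .io import StudyBundle
from .surface_energy import owens_wendt_solve, summarize_wettability


@dataclass
class RunConfig:
    """Tunables of one analysis run (all stages; no hidden defaults)."""

    qc_tolerance_mg: float = DEFAULT_QC_TOLERANCE_MG
    alpha: float = 0.05
    k_clusters: int = 3
    seed: int = st.DEFAULT_SEED
    n_restarts: int = st.DEFAULT_RESTARTS
    report_precision: int = 1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise LeafDepoError("alpha must be in (0, 1)")
        if self.k_clusters < 2:
            raise LeafDepoError("k_clusters must be >= 2")


@dataclass
class StudyResults:
    """All tables produced by :func:`quantify`."""

    inventories: dict[str, frac.PMInventory]          # batch_id -> inventory
    densities: pd.DataFrame        # species x 8 cells + totals, mg/m^2
    proportions: pd.DataFrame      # species x 8 cells, % of total PM
    wettability: pd.DataFrame      # species: mean/sd angle per liquid, class
    surface_energy: pd.DataFrame   # species: gamma_p, gamma_d, gamma, clamped
    efficiency: pd.DataFrame       # long: species, scale, fraction, value
    anova: pd.DataFrame            # outcome, F, p, dfs
    correlations: pd.DataFrame     # x, y, r, p, slope, n
    clusters: pd.DataFrame         # species, cluster
    log: list[str] = field(default_factory=list)

    def report_tables(self) -> dict[str, pd.DataFrame]:
        return {
            "densities": self.densities,
            "proportions": self.proportions,
            "wettability": self.wettability,
            "surface_energy": self.surface_energy,
            "efficiency": self.efficiency,
            "anova": self.anova,
            "correlations": self.correlations,
            "clusters": self.clusters,
        }


def _cell_col(cell: tuple[str, str]) -> str:
    return f"{cell[0]}:{cell[1]}"


def build_inventories(
    bundle: StudyBundle, qc_tolerance_mg: float = DEFAULT_QC_TOLERANCE_MG
) -> dict[str, frac.PMInventory]:
    """Stage 1: group raw rows per batch and assemble the 8-cell inventories."""
    inventories: dict[str, frac.PMInventory] = {}
    areas = bundle.batches.set_index("batch_id")["leaf_area_m2"]
    wg = bundle.weighings.groupby(["batch_id", "wash_step", "pore_um"], sort=True)
    per_batch_weighings: dict[str, list[FilterWeighing]] = {}
    for (batch_id, step, pore), g in wg:
        per_batch_weighings.setdefault(batch_id, []).append(
            FilterWeighing(
                batch_id=batch_id,
                wash_step=step,
                pore_um=float(pore),
                tare_mg=tuple(g["tare_mg"]),
                loaded_mg=tuple(g["loaded_mg"]),
            )
        )
    per_batch_tds: dict[str, list[TDSReading]] = {}
    for row in bundle.tds.itertuples():
        per_batch_tds.setdefault(row.batch_id, []).append(
            TDSReading(
                batch_id=row.batch_id,
                wash_step=row.wash_step,
                concentration_mg_per_l=float(row.concentration_mg_per_l),
                volume_l=float(row.volume_l),
            )
        )
    for batch_id in bundle.batches["batch_id"]:
        try:
            inventories[batch_id] = frac.assemble_inventory(
                batch_id,
                per_batch_weighings.get(batch_id, []),
                per_batch_tds.get(batch_id, []),
                leaf_area_m2=float(areas[batch_id]),
                qc_tolerance_mg=qc_tolerance_mg,
            )
        except LeafDepoError as e:
            raise StageError("gravimetry", str(e), record_id=batch_id) from e
    return inventories


def quantify(bundle: StudyBundle, config: RunConfig | None = None) -> StudyResults:
    """Run the full analysis on a validated study bundle."""
    cfg = config or RunConfig()
    log: list[str] = []

    inventories = build_inventories(bundle, cfg.qc_tolerance_mg)
    log.append(f"gravimetry: {len(inventories)} batch inventories from "
               f"{len(bundle.weighings)} weighing rows, {len(bundle.tds)} TDS rows")

    # Stage 2: densities and proportions at the species level.
    batch_species = bundle.batches.set_index("batch_id")["species_id"]
    species_order = list(bundle.species["species_id"])
    try:
        by_species: dict[str, list[frac.PMInventory]] = {}
        for batch_id, inv in inventories.items():
            by_species.setdefault(batch_species[batch_id], []).append(inv)
        dens_rows, prop_rows, batch_dens_rows = {}, {}, []
        for sp in species_order:
            means = frac.species_mean_densities(by_species[sp])
            dens_rows[sp] = {_cell_col(c): v for c, v in means.items()}
            total = sum(means.values())
            prop_rows[sp] = {_cell_col(c): 100.0 * v / total for c, v in means.items()}
            for inv in by_species[sp]:
                row = {"species_id": sp, "batch_id": inv.batch_id}
                row.update({_cell_col(c): v for c, v in
                            frac.density_per_leaf_area(inv).items()})
                batch_dens_rows.append(row)
    except LeafDepoError as e:
        raise StageError("fractionation", str(e)) from e
    densities = pd.DataFrame.from_dict(dens_rows, orient="index")
    densities.index.name = "species_id"
    densities["SPM"] = densities[[c for c in densities if c.startswith("water:")]].sum(axis=1)
    densities["WPM"] = densities[[c for c in densities if c.startswith("chloroform:")]].sum(axis=1)
    densities["total_pm"] = densities["SPM"] + densities["WPM"]
    proportions = pd.DataFrame.from_dict(prop_rows, orient="index")
    proportions.index.name = "species_id"
    batch_densities = pd.DataFrame(batch_dens_rows)
    log.append(f"fractionation: densities for {len(densities)} species "
               f"({len(batch_densities)} batch rows)")

    # Stage 3: wettability and surface free energy per species.
    try:
        wet_rows, sfe_rows = [], []
        for sp, g in bundle.contact_angles.groupby("species_id", sort=False):
            summaries = {}
            for liquid, gl in g.groupby("liquid"):
                summaries[liquid] = summarize_wettability(list(gl["angle_deg"]))
            w = summaries["water"]
            d = summaries["diiodomethane"]
            wet_rows.append(
                dict(
                    species_id=sp,
                    theta_water_deg=w.mean_deg, theta_water_sd=w.sd_deg,
                    theta_diiodomethane_deg=d.mean_deg, theta_diiodomethane_sd=d.sd_deg,
                    wettability_class=w.wettability_class,
                )
            )
            sfe = owens_wendt_solve(w.mean_deg, d.mean_deg)
            sfe_rows.append(
                dict(
                    species_id=sp,
                    gamma_polar=sfe.gamma_polar,
                    gamma_dispersive=sfe.gamma_dispersive,
                    gamma_total=sfe.gamma_total,
                    clamped=";".join(sfe.clamped),
                )
            )
    except (LeafDepoError, KeyError) as e:
        raise StageError("surface_energy", str(e)) from e
    wettability = pd.DataFrame(wet_rows).set_index("species_id").loc[species_order].reset_index()
    sfe_table = pd.DataFrame(sfe_rows).set_index("species_id").loc[species_order].reset_index()
    log.append(f"surface_energy: {len(sfe_table)} species solved")

    # Stage 4: retention efficiency of the surface pool at three scales.
    morpho = bundle.morphometrics.set_index("species_id")
    exposure = bundle.batches.groupby("species_id")["exposure_days"].mean()
    eff_rows = []
    try:
        for sp in species_order:
            spm_dens = {f: float(densities.loc[sp, f"water:{f}"]) for f in SPM_FRACTIONS}
            leaf = ae_leaf(spm_dens, float(exposure[sp]))
            la = total_leaf_area(float(morpho.loc[sp, "lai"]),
                                 float(morpho.loc[sp, "crown_diameter_m"]))
            plant = ae_plant(leaf, la)
            land = ae_land(leaf, float(morpho.loc[sp, "lai"]))
            for scale, m in (("leaf", leaf), ("plant", plant), ("land", land)):
                for fr in SPM_FRACTIONS + (SPM_TOTAL,):
                    eff_rows.append(dict(species_id=sp, scale=scale,
                                         fraction=fr, value=m[fr]))
    except LeafDepoError as e:
        raise StageError("efficiency", str(e)) from e
    efficiency = pd.DataFrame(eff_rows)
    log.append(f"efficiency: {len(efficiency)} records "
               f"({len(species_order)} species x 3 scales x 5 fractions)")

    # Stage 5: statistics across species.
    try:
        anova_rows, corr_rows = [], []
        multi_batch = bundle.batches.groupby("species_id").size().ge(2).all() \
            and len(species_order) >= 2
        if multi_batch:
            for outcome, col in [("SPM density", None), ("total PM density", "total")]:
                groups = {}
                for sp in species_order:
                    sub = batch_densities[batch_densities["species_id"] == sp]
                    water_cols = [c for c in sub.columns if c.startswith("water:")]
                    chloro_cols = [c for c in sub.columns if c.startswith("chloroform:")]
                    vals = sub[water_cols].sum(axis=1) if col is None else \
                        sub[water_cols + chloro_cols].sum(axis=1)
                    groups[sp] = list(vals)
                a = st.one_way_anova(groups)
                anova_rows.append(dict(outcome=outcome, F=a.f, p=a.p,
                                       df_between=a.df_between, df_within=a.df_within))
        sfe_idx = sfe_table.set_index("species_id")
        wet_idx = wettability.set_index("species_id")
        for xname, xvals in [
            ("theta_water_deg", wet_idx["theta_water_deg"]),
            ("gamma_total", sfe_idx["gamma_total"]),
            ("gamma_polar", sfe_idx["gamma_polar"]),
            ("gamma_dispersive", sfe_idx["gamma_dispersive"]),
        ]:
            if len(species_order) >= 3:
                c = st.correlate(
                    [float(xvals[sp]) for sp in species_order],
                    [float(densities.loc[sp, "total_pm"]) for sp in species_order],
                )
                corr_rows.append(dict(x=xname, y="total_pm", r=c.r, p=c.p,
                                      slope=c.slope, n=c.n))
        feature_cols = [c for c in densities.columns if ":" in c] + ["total_pm"]
        if len(species_order) >= cfg.k_clusters:
            cl = st.kmeans_capacity_clusters(
                densities[feature_cols],
                totals=densities["total_pm"].to_numpy(),
                k=cfg.k_clusters, seed=cfg.seed, n_restarts=cfg.n_restarts,
            )
            clusters = pd.DataFrame(
                {"species_id": species_order,
                 "cluster": [cl.labels[sp] for sp in species_order]}
            )
        else:
            clusters = pd.DataFrame({"species_id": species_order,
                                     "cluster": [1] * len(species_order)})
    except LeafDepoError as e:
        raise StageError("stats", str(e)) from e
    anova = pd.DataFrame(anova_rows, columns=["outcome", "F", "p", "df_between", "df_within"])
    correlations = pd.DataFrame(corr_rows, columns=["x", "y", "r", "p", "slope", "n"])
    log.append(f"stats: {len(anova)} ANOVA outcomes, {len(correlations)} correlations, "
               f"{clusters['cluster'].nunique()} clusters")

    return StudyResults(
        inventories=inventories,
        densities=densities,
        proportions=proportions,
        wettability=wettability,
        surface_energy=sfe_table,
        efficiency=efficiency,
        anova=anova,
        correlations=correlations,
        clusters=clusters,
        log=log,
    )
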