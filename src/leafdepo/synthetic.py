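"""Forward simulation of a complete retention study from known ground truth.

The generator inverts the measurement protocol: it draws per-species true
deposition densities and surface energies, converts them to the raw records
a field/lab campaign would produce — filter tare/loaded weighings, TDS
readings, contact-angle droplets, batch leaf areas, morphometrics — and
packs them into the same :class:`~leafdepo.io.StudyBundle` the analysis
pipeline consumes.  With all noise standard deviations at zero the pipeline
recovers the truth exactly, which anchors every downstream recovery test.

Default study conditions mirror the reference campaign: 20 species x 3
batches, 7-day exposure, three weighing replicates per filter side, fifteen
contact-angle droplets per liquid, 0.05 mg balance noise, 5 deg droplet
noise.  Composition shares are drawn from the campaign's reported ranges
(surface PM 44.9-66.9% of total, water-soluble 12.9-22.1%, etc.).  Species
capacities come in three tiers (low/mid/high total PM) whose means are
separated by five within-tier standard deviations, giving a clusterable
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import StudyBundle, validate_bundle
from .surface_energy import (
    DIIODOMETHANE,
    WATER,
    SurfaceEnergy,
    forward_contact_angles,
)

TIERS = ("low", "mid", "high")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the simulator.  Units: mg, m, m^2, m^2/m^2, L, deg, d."""

    n_species: int = 20
    n_batches: int = 3
    leaf_area_range_m2: tuple[float, float] = (0.04, 0.12)
    exposure_days: float = 7.0

    # Composition shares of total PM (fractions of 1); the >10 um share of
    # each wash step is the remainder, keeping shares summing to 1.
    spm_share_range: tuple[float, float] = (0.449, 0.669)
    dpm_share_range: tuple[float, float] = (0.129, 0.221)
    spm_fine_share_range: tuple[float, float] = (0.014, 0.038)   # 0.1-2.5 um
    spm_mid_share_range: tuple[float, float] = (0.036, 0.093)    # 2.5-10 um
    opm_share_range: tuple[float, float] = (0.012, 0.088)
    wpm_fine_share_range: tuple[float, float] = (0.007, 0.038)
    wpm_mid_share_range: tuple[float, float] = (0.021, 0.071)

    # Capacity tiers: total PM density (mg/m^2) ~ N(tier mean, tier sd),
    # means separated by 5 sd so the tier structure is recoverable.
    tier_means_mg_m2: tuple[float, float, float] = (500.0, 1200.0, 1900.0)
    tier_sd_mg_m2: float = 140.0

    # Surface energy (mJ/m^2): baseline +/- a component that tracks total PM
    # (capacity and surface energy are positively coupled in the field).
    sfe_polar_base: float = 12.0
    sfe_polar_pm_coupling: float = 7.0
    sfe_polar_sd: float = 1.5
    sfe_dispersive_base: float = 25.0
    sfe_dispersive_pm_coupling: float = 3.0
    sfe_dispersive_sd: float = 1.0

    # Morphometrics.
    lai_range: tuple[float, float] = (1.3, 4.5)
    crown_diameter_range_m: tuple[float, float] = (1.0, 8.0)

    # Measurement noise.
    weighing_sd_mg: float = 0.05
    ca_sd_deg: float = 5.0
    tds_rel_sd: float = 0.0
    n_weighing_replicates: int = 3
    n_ca_replicates: int = 15

    # Protocol constants.
    filter_tare_range_mg: tuple[float, float] = (100.0, 150.0)
    water_volume_l: float = 0.35
    chloroform_volume_l: float = 0.15

    def __post_init__(self):
        for name in ("weighing_sd_mg", "ca_sd_deg", "tds_rel_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        # Worst-case sub-shares must leave a positive >10 um remainder.
        if self.dpm_share_range[1] + self.spm_fine_share_range[1] + \
           self.spm_mid_share_range[1] >= self.spm_share_range[0]:
            raise ValidationError("surface sub-shares can exceed the surface total share")
        wpm_min = 1.0 - self.spm_share_range[1]
        if self.opm_share_range[1] + self.wpm_fine_share_range[1] + \
           self.wpm_mid_share_range[1] >= wpm_min:
            raise ValidationError("in-wax sub-shares can exceed the in-wax total share")
        if self.n_species < 1 or self.n_batches < 1:
            raise ValidationError("n_species and n_batches must be >= 1")


#: Inventory cell order used for truth arrays (matches fractionation).
TRUTH_CELLS = (
    ("water", "DPM"),
    ("water", "PM_0.1-2.5"),
    ("water", "PM_2.5-10"),
    ("water", "PM_>10"),
    ("chloroform", "OPM"),
    ("chloroform", "PM_0.1-2.5"),
    ("chloroform", "PM_2.5-10"),
    ("chloroform", "PM_>10"),
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind one simulated study."""

    species_ids: tuple[str, ...]
    tiers: tuple[str, ...]
    densities_mg_m2: pd.DataFrame  # species x 8 cells (column = "step:fraction")
    surface_energies: tuple[SurfaceEnergy, ...]
    lai: tuple[float, ...]
    crown_diameter_m: tuple[float, ...]

    def density(self, species_id: str, cell: tuple[str, str]) -> float:
        return float(self.densities_mg_m2.loc[species_id, f"{cell[0]}:{cell[1]}"])


def generate_truth(cfg: GeneratorConfig, seed: int) -> SyntheticTruth:
    """Draw per-species ground truth: capacities, composition, SFE, morphometrics."""
    rng = np.random.default_rng(seed)
    n = cfg.n_species
    species_ids = tuple(f"sp{i+1:02d}" for i in range(n))
    tiers = tuple(TIERS[i % 3] for i in range(n))

    tier_mean = {t: m for t, m in zip(TIERS, cfg.tier_means_mg_m2)}
    total = np.array(
        [max(rng.normal(tier_mean[t], cfg.tier_sd_mg_m2), 50.0) for t in tiers]
    )

    u = lambda lohi, size: rng.uniform(*lohi, size)
    spm = u(cfg.spm_share_range, n)
    dpm = u(cfg.dpm_share_range, n)
    s_fine = u(cfg.spm_fine_share_range, n)
    s_mid = u(cfg.spm_mid_share_range, n)
    s_coarse = spm - dpm - s_fine - s_mid
    opm = u(cfg.opm_share_range, n)
    w_fine = u(cfg.wpm_fine_share_range, n)
    w_mid = u(cfg.wpm_mid_share_range, n)
    w_coarse = (1.0 - spm) - opm - w_fine - w_mid
    shares = np.column_stack([dpm, s_fine, s_mid, s_coarse, opm, w_fine, w_mid, w_coarse])
    dens = shares * total[:, None]
    densities = pd.DataFrame(
        dens,
        index=pd.Index(species_ids, name="species_id"),
        columns=[f"{s}:{f}" for s, f in TRUTH_CELLS],
    )

    mid = cfg.tier_means_mg_m2[1]
    span = (cfg.tier_means_mg_m2[2] - cfg.tier_means_mg_m2[0]) / 2.0
    z = (total - mid) / span
    gp = np.clip(
        cfg.sfe_polar_base + cfg.sfe_polar_pm_coupling * z
        + rng.normal(0, cfg.sfe_polar_sd, n), 0.5, 45.0,
    )
    gd = np.clip(
        cfg.sfe_dispersive_base + cfg.sfe_dispersive_pm_coupling * z
        + rng.normal(0, cfg.sfe_dispersive_sd, n), 5.0, 45.0,
    )
    sfes = tuple(SurfaceEnergy(float(p), float(d)) for p, d in zip(gp, gd))

    lai = tuple(float(x) for x in u(cfg.lai_range, n))
    crown = tuple(float(x) for x in u(cfg.crown_diameter_range_m, n))
    return SyntheticTruth(
        species_ids=species_ids,
        tiers=tiers,
        densities_mg_m2=densities,
        surface_energies=sfes,
        lai=lai,
        crown_diameter_m=crown,
    )


def simulate_measurements(
    truth: SyntheticTruth, cfg: GeneratorConfig, seed: int
) -> StudyBundle:
    """Generate the raw measurement record implied by ``truth``.

    Densities become per-batch masses (density x batch leaf area); insoluble
    masses become tare/loaded weighing replicates with Gaussian balance
    noise; soluble masses become TDS concentrations at the protocol volumes;
    surface energies become contact-angle droplets via the forward
    Owens-Wendt relation plus angular noise (truncated to (0, 180), redrawn
    when outside).
    """
    rng = np.random.default_rng(seed)
    life_forms = ("tree", "shrub", "herb", "tree-dwelling")

    species_rows, morpho_rows, batch_rows = [], [], []
    weigh_rows, tds_rows, ca_rows = [], [], []

    for i, sp in enumerate(truth.species_ids):
        species_rows.append(
            dict(
                species_id=sp,
                binomial=f"Synthetica speciosa {i+1}",
                life_form=life_forms[i % len(life_forms)],
                leaf_habit="evergreen",
            )
        )
        morpho_rows.append(
            dict(species_id=sp, lai=truth.lai[i], crown_diameter_m=truth.crown_diameter_m[i])
        )

        for b in range(cfg.n_batches):
            batch_id = f"{sp}_b{b+1}"
            area = rng.uniform(*cfg.leaf_area_range_m2)
            batch_rows.append(
                dict(
                    batch_id=batch_id,
                    species_id=sp,
                    leaf_area_m2=area,
                    n_leaves=int(rng.integers(8, 41)),
                    exposure_days=cfg.exposure_days,
                )
            )
            for step, fraction in TRUTH_CELLS:
                mass = truth.density(sp, (step, fraction)) * area
                if fraction in ("DPM", "OPM"):
                    vol = cfg.water_volume_l if step == "water" else cfg.chloroform_volume_l
                    conc = mass / vol
                    if cfg.tds_rel_sd > 0:
                        conc = max(conc * (1.0 + rng.normal(0, cfg.tds_rel_sd)), 0.0)
                    tds_rows.append(
                        dict(
                            batch_id=batch_id,
                            wash_step=step,
                            concentration_mg_per_l=conc,
                            volume_l=vol,
                        )
                    )
                else:
                    pore = {"PM_>10": 10.0, "PM_2.5-10": 2.5, "PM_0.1-2.5": 0.1}[fraction]
                    tare_true = rng.uniform(*cfg.filter_tare_range_mg)
                    for rep in range(cfg.n_weighing_replicates):
                        weigh_rows.append(
                            dict(
                                batch_id=batch_id,
                                wash_step=step,
                                pore_um=pore,
                                replicate=rep + 1,
                                tare_mg=tare_true + rng.normal(0, cfg.weighing_sd_mg)
                                if cfg.weighing_sd_mg > 0 else tare_true,
                                loaded_mg=tare_true + mass
                                + (rng.normal(0, cfg.weighing_sd_mg)
                                   if cfg.weighing_sd_mg > 0 else 0.0),
                            )
                        )

        for liquid in (WATER, DIIODOMETHANE):
            theta = forward_contact_angles(truth.surface_energies[i], liquid)
            for rep in range(cfg.n_ca_replicates):
                angle = theta + (rng.normal(0, cfg.ca_sd_deg) if cfg.ca_sd_deg > 0 else 0.0)
                tries = 0
                while not 0.0 < angle < 180.0:
                    tries += 1
                    if tries > 100:
                        raise ValidationError(
                            f"{sp}: cannot draw a physical contact angle around {theta:.1f} deg"
                        )
                    angle = theta + rng.normal(0, cfg.ca_sd_deg)
                ca_rows.append(
                    dict(species_id=sp, liquid=liquid.name, replicate=rep + 1, angle_deg=angle)
                )

    bundle = StudyBundle(
        species=pd.DataFrame(species_rows),
        morphometrics=pd.DataFrame(morpho_rows),
        batches=pd.DataFrame(batch_rows),
        weighings=pd.DataFrame(weigh_rows),
        tds=pd.DataFrame(tds_rows),
        contact_angles=pd.DataFrame(ca_rows),
    )
    validate_bundle(bundle)
    return bundle


def simulate_study(
    cfg: GeneratorConfig, seed: int
) -> tuple[SyntheticTruth, StudyBundle]:
    """Convenience: truth plus measurements from one seed.

    Truth and measurement noise use distinct child seeds of ``seed`` so the
    same truth can be re-measured independently.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    truth = generate_truth(cfg, seed=int(ss[0].generate_state(1)[0] % 2**31))
    bundle = simulate_measurements(
        truth, cfg, seed=int(ss[1].generate_state(1)[0] % 2**31)
    )
    return truth, bundle
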