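"""Leaf surface free energy from two-liquid contact angles (Owens-Wendt).

A sessile droplet of a probe liquid with known surface tension components
meets the leaf at contact angle theta.  Combining Young's equation with the
Owens-Wendt geometric-mean decomposition of interfacial energy gives, per
liquid,

    gamma_l (1 + cos theta) = 2 ( sqrt(gamma_l^p gamma_s^p)
                                + sqrt(gamma_l^d gamma_s^d) )

which is linear in (a, b) = (sqrt(gamma_s^p), sqrt(gamma_s^d)).  Two probe
liquids with distinct polar/dispersive ratios (here distilled water and
diiodomethane) determine the leaf's polar and dispersive components; their
sum is the total surface free energy.  All energies are in mJ/m^2, angles
in degrees at the API boundary (radians internally).

A solved root may come out slightly negative when the surface is nearly
apolar at the edge of the physical domain; the component is then clamped to
zero and flagged rather than fitted under constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev

import numpy as np

from .errors import ValidationError

__all__ = [
    "LiquidProperties",
    "SurfaceEnergy",
    "WettabilitySummary",
    "WATER",
    "DIIODOMETHANE",
    "LIQUIDS",
    "owens_wendt_solve",
    "forward_contact_angles",
    "summarize_wettability",
    "classify_wettability",
]


@dataclass(frozen=True)
class LiquidProperties:
    """Surface tension of a probe liquid, split into polar and dispersive parts."""

    name: str
    gamma_total: float
    gamma_polar: float
    gamma_dispersive: float

    def __post_init__(self):
        if min(self.gamma_total, self.gamma_polar, self.gamma_dispersive) < 0:
            raise ValidationError(f"{self.name}: surface tension components must be >= 0")
        if abs(self.gamma_polar + self.gamma_dispersive - self.gamma_total) > 1e-9:
            raise ValidationError(
                f"{self.name}: polar + dispersive must equal total "
                f"({self.gamma_polar} + {self.gamma_dispersive} != {self.gamma_total})"
            )


#: Standard probe-liquid constants (mJ/m^2): total, polar, dispersive.
WATER = LiquidProperties("water", 72.8, 51.0, 21.8)
DIIODOMETHANE = LiquidProperties("diiodomethane", 50.8, 2.3, 48.5)

LIQUIDS: dict[str, LiquidProperties] = {
    WATER.name: WATER,
    DIIODOMETHANE.name: DIIODOMETHANE,
}


@dataclass(frozen=True)
class SurfaceEnergy:
    """Polar/dispersive decomposition of a solid surface free energy (mJ/m^2).

    ``clamped`` names the components whose unconstrained root was negative
    and was clamped to zero.
    """

    gamma_polar: float
    gamma_dispersive: float
    clamped: tuple[str, ...] = ()

    @property
    def gamma_total(self) -> float:
        return self.gamma_polar + self.gamma_dispersive

    def __post_init__(self):
        if self.gamma_polar < 0 or self.gamma_dispersive < 0:
            raise ValidationError("surface energy components must be >= 0")


def owens_wendt_solve(
    theta_water_deg: float,
    theta_diiodomethane_deg: float,
    liquids: tuple[LiquidProperties, LiquidProperties] = (WATER, DIIODOMETHANE),
) -> SurfaceEnergy:
    """Solve the two-liquid Owens-Wendt system for the leaf surface energy.

    Parameters
    ----------
    theta_water_deg, theta_diiodomethane_deg
        Mean contact angles (degrees, in (0, 180)) of the first and second
        liquid in ``liquids``.
    liquids
        The two probe liquids; they must have distinct polar/dispersive
        ratios or the 2x2 system is singular.

    Returns
    -------
    SurfaceEnergy
        Squared roots of the linear solve; a negative root is clamped to 0
        and recorded in ``clamped``.
    """
    angles = (theta_water_deg, theta_diiodomethane_deg)
    for th in angles:
        if not 0.0 < th < 180.0:
            raise ValidationError(f"contact angle must be in (0, 180) deg, got {th}")

    coeff = np.array(
        [[math.sqrt(liq.gamma_polar), math.sqrt(liq.gamma_dispersive)] for liq in liquids]
    )
    rhs = np.array(
        [
            liq.gamma_total * (1.0 + math.cos(math.radians(th))) / 2.0
            for liq, th in zip(liquids, angles)
        ]
    )
    if abs(np.linalg.det(coeff)) < 1e-9:
        raise ValidationError(
            "probe liquids have proportional polar/dispersive vectors; "
            "the Owens-Wendt system is singular"
        )
    a, b = np.linalg.solve(coeff, rhs)

    clamped = []
    if a < 0:
        a, clamped = 0.0, clamped + ["polar"]
    if b < 0:
        b, clamped = 0.0, clamped + ["dispersive"]
    return SurfaceEnergy(
        gamma_polar=a * a, gamma_dispersive=b * b, clamped=tuple(clamped)
    )


def forward_contact_angles(
    surface: SurfaceEnergy, liquid: LiquidProperties
) -> float:
    """Predicted contact angle (degrees) of ``liquid`` on ``surface``.

    Inverts the Owens-Wendt relation:
    cos theta = 2 (sqrt(g_l^p g_s^p) + sqrt(g_l^d g_s^d)) / g_l - 1.
    Raises if the implied cosine leaves [-1, 1] (complete wetting or
    complete non-wetting; no finite angle exists).
    """
    work = 2.0 * (
        math.sqrt(liquid.gamma_polar * surface.gamma_polar)
        + math.sqrt(liquid.gamma_dispersive * surface.gamma_dispersive)
    )
    cos_theta = work / liquid.gamma_total - 1.0
    if not -1.0 <= cos_theta <= 1.0:
        raise ValidationError(
            f"non-physical combination: cos(theta) = {cos_theta:.4f} for "
            f"{liquid.name} on surface {surface}"
        )
    return math.degrees(math.acos(cos_theta))


@dataclass(frozen=True)
class WettabilitySummary:
    mean_deg: float
    sd_deg: float
    n: int
    wettability_class: str


def classify_wettability(theta_deg: float) -> str:
    """Wettability class from a mean contact angle.

    <90 deg wettable; 90-130 deg non-wettable; >130 deg highly non-wettable.
    """
    if theta_deg < 90.0:
        return "wettable"
    if theta_deg <= 130.0:
        return "non-wettable"
    return "highly non-wettable"


def summarize_wettability(angles_deg: list[float]) -> WettabilitySummary:
    """Mean, sample SD and wettability class of replicate contact angles."""
    if len(angles_deg) < 2:
        raise ValidationError("at least 2 replicate angles required")
    for th in angles_deg:
        if not 0.0 < th < 180.0:
            raise ValidationError(f"contact angle must be in (0, 180) deg, got {th}")
    m = mean(angles_deg)
    return WettabilitySummary(
        mean_deg=m,
        sd_deg=stdev(angles_deg),
        n=len(angles_deg),
        wettability_class=classify_wettability(m),
    )
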