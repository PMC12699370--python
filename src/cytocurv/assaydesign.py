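"""Closed-form calculators for curved-membrane bead (SSLB) assay design.

Membrane curvature of a spherical bead is 1/radius = 2/diameter.  For
uniform spheres of equal material density the total surface area per unit
mass scales as 1/diameter, so equal total surface area across bead sizes
requires mass proportional to diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from cytocurv.exceptions import ParameterError

__all__ = [
    "BeadSpec",
    "sphere_curvature",
    "equal_area_mass",
    "lipid_mix_masses",
    "design_table",
]

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class BeadSpec:
    """A bead preparation: diameter and total mass (density assumed shared)."""

    diameter_nm: float
    mass_ug: float
    material_density: float = 1.0  # relative units, equal across sizes

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0 or self.mass_ug <= 0:
            raise ParameterError("bead diameter and mass must be positive")


def sphere_curvature(diameter_nm: float) -> float:
    """Curvature 1/radius of a sphere, in µm^-1, from its diameter in nm.

    Raises
    ------
    ParameterError
        If the diameter is not positive.
    """
    if diameter_nm <= 0:
        raise ParameterError(f"diameter must be positive, got {diameter_nm}")
    return 2.0 / (diameter_nm / NM_PER_UM)


def equal_area_mass(ref: BeadSpec, target_diameter_nm: float) -> float:
    """Mass of target-diameter beads with the same total surface area as ``ref``.

    mass = ref.mass * target_diameter / ref.diameter (equal density,
    uniform spheres).

    Raises
    ------
    ParameterError
        If the target diameter is not positive.
    """
    if target_diameter_nm <= 0:
        raise ParameterError(
            f"target diameter must be positive, got {target_diameter_nm}"
        )
    return ref.mass_ug * target_diameter_nm / ref.diameter_nm


def lipid_mix_masses(
    total_mass_ug: float,
    molar_ratio: dict[str, float],
    molar_masses: dict[str, float],
) -> dict[str, float]:
    """Per-component masses for a lipid mix of given molar ratio and total mass.

    mass_i is proportional to ratio_i * molar_mass_i, normalized to the
    requested total.

    Raises
    ------
    ParameterError
        On empty mappings, missing molar masses or non-positive values.
    """
    if total_mass_ug <= 0:
        raise ParameterError("total mass must be positive")
    if not molar_ratio:
        raise ParameterError("molar ratio mapping is empty")
    missing = set(molar_ratio) - set(molar_masses)
    if missing:
        raise ParameterError(f"missing molar masses for {sorted(missing)}")
    weights = {}
    for name, ratio in molar_ratio.items():
        m = molar_masses[name]
        if ratio <= 0 or m <= 0:
            raise ParameterError(f"non-positive ratio or molar mass for {name!r}")
        weights[name] = ratio * m
    total_weight = sum(weights.values())
    return {name: total_mass_ug * w / total_weight for name, w in weights.items()}


def design_table(
    diameters_nm: list[float],
    ref: BeadSpec = BeadSpec(diameter_nm=1000.0, mass_ug=2000.0),
) -> pd.DataFrame:
    """Design table: per diameter, equal-surface-area mass and curvature."""
    rows = [
        {
            "diameter_nm": d,
            "mass_ug": equal_area_mass(ref, d),
            "kappa_per_um": sphere_curvature(d),
        }
        for d in diameters_nm
    ]
    return pd.DataFrame(rows)
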