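"""Sedimentation-derived hydrodynamic quantities.

Small calculator for the downstream arithmetic of sedimentation-velocity
experiments: oligomeric stoichiometry from measured vs monomer mass,
hydrodynamic radius from mass + frictional ratio, standardization of
sedimentation coefficients to water at 20 °C, and the Stokes-Einstein
size-scaling factor for diffusion.

Units at the interface: kDa, Svedberg, cP, g/ml, ml/g, nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Avogadro constant (1/mol)
N_AVOGADRO = 6.02214076e23

# Water at 20 degC
WATER20_VISCOSITY_CP = 1.002
WATER20_DENSITY_G_ML = 0.99823

#: Conventional partial specific volume for proteins when no
#: sequence-computed value is available (ml/g). An explicit input is
#: always preferred.
DEFAULT_VBAR_ML_G = 0.73


class FlotationError(ValueError):
    """Raised when the buoyancy term is non-positive (flotation regime)."""


@dataclass(frozen=True)
class HydroParams:
    """Scalar inputs for the sedimentation calculators.

    All quantities must be positive; ``f_ratio`` >= 1 and ``vbar`` in the
    physically plausible protein range (0.5, 1.0) ml/g.
    """

    monomer_mass_kda: float
    measured_mass_kda: float
    s_obs_svedberg: float
    f_ratio: float
    vbar_ml_g: float = DEFAULT_VBAR_ML_G
    buffer_viscosity_cp: float = WATER20_VISCOSITY_CP
    buffer_density_g_ml: float = WATER20_DENSITY_G_ML
    water20_viscosity_cp: float = WATER20_VISCOSITY_CP
    water20_density_g_ml: float = WATER20_DENSITY_G_ML

    def __post_init__(self) -> None:
        for name in (
            "monomer_mass_kda",
            "measured_mass_kda",
            "s_obs_svedberg",
            "f_ratio",
            "vbar_ml_g",
            "buffer_viscosity_cp",
            "buffer_density_g_ml",
            "water20_viscosity_cp",
            "water20_density_g_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.f_ratio < 1.0:
            raise ValueError("f_ratio must be >= 1 (sphere limit)")
        if not (0.5 < self.vbar_ml_g < 1.0):
            raise ValueError("vbar_ml_g outside plausible protein range (0.5, 1.0)")


def oligomer_ratio(
    measured_mass_kda: float,
    monomer_mass_kda: float,
    *,
    ambiguity_tol: float = 0.15,
) -> tuple[float, int, bool]:
    """Mass ratio, nearest integer stoichiometry, and an ambiguity flag.

    The flag is True when the ratio deviates from the nearest integer by
    more than ``ambiguity_tol``, i.e. the stoichiometry call is unsafe.
    """
    if measured_mass_kda <= 0 or monomer_mass_kda <= 0:
        raise ValueError("masses must be positive")
    ratio = measured_mass_kda / monomer_mass_kda
    stoich = max(1, round(ratio))
    ambiguous = abs(ratio - stoich) > ambiguity_tol
    return ratio, stoich, ambiguous


def hydrodynamic_radius(mass_kda: float, f_ratio: float, vbar_ml_g: float) -> float:
    """Hydrodynamic (Stokes) radius in nm.

    R_h = (f/f0) * (3 M vbar / (4 pi N_A))^(1/3)

    where the second factor is the radius of the anhydrous sphere of equal
    mass and partial specific volume.
    """
    if mass_kda <= 0 or f_ratio <= 0 or vbar_ml_g <= 0:
        raise ValueError("mass, frictional ratio and vbar must be positive")
    mass_g_mol = mass_kda * 1000.0
    volume_cm3 = mass_g_mol * vbar_ml_g / N_AVOGADRO  # per molecule
    r0_cm = (3.0 * volume_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return f_ratio * r0_cm * 1e7  # cm -> nm


def s20w_correct(
    s_obs_svedberg: float,
    *,
    vbar_ml_g: float,
    buffer_viscosity_cp: float,
    buffer_density_g_ml: float,
    water20_viscosity_cp: float = WATER20_VISCOSITY_CP,
    water20_density_g_ml: float = WATER20_DENSITY_G_ML,
) -> float:
    """Standardize an observed sedimentation coefficient to water at 20 °C.

    s20,w = s_obs * (eta_b / eta_20w) * (1 - vbar*rho_20w) / (1 - vbar*rho_b)
    """
    if s_obs_svedberg <= 0:
        raise ValueError("s_obs must be positive")
    if min(vbar_ml_g, buffer_viscosity_cp, buffer_density_g_ml) <= 0:
        raise ValueError("vbar, viscosity and density must be positive")
    buoyancy_buffer = 1.0 - vbar_ml_g * buffer_density_g_ml
    if buoyancy_buffer <= 0:
        raise FlotationError(
            "flotation regime: 1 - vbar*rho_buffer <= 0, particle does not sediment"
        )
    buoyancy_water = 1.0 - vbar_ml_g * water20_density_g_ml
    return (
        s_obs_svedberg
        * (buffer_viscosity_cp / water20_viscosity_cp)
        * (buoyancy_water / buoyancy_buffer)
    )


def size_scaling_factor(mass_ratio: float) -> float:
    """Stokes-Einstein factor by which diffusion slows for a mass increase.

    At equal shape and density, R_h scales as mass^(1/3), so D drops by
    mass_ratio^(1/3).
    """
    if mass_ratio <= 0:
        raise ValueError("mass_ratio must be positive")
    return mass_ratio ** (1.0 / 3.0)
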