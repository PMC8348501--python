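"""Extruder geometry, volumetric flux, and pore pressure–tension relations.

All quantities are SI internally (m, Pa, N·m⁻¹, m·s⁻¹).  Laboratory
conventions — flux in mL·min⁻¹·cm⁻², diameters in nm — are handled by the
unit helpers at the bottom of the module.

The physics implemented here is elementary but load-bearing: the volumetric
flux through the filter follows from piston kinematics,

    J_V = R_S² · v_p / R_F²,

and the effective lateral tension sustained by a bilayer spanning a
cylindrical pore of radius R_p under a transmembrane pressure difference ΔP
follows the Laplace-type relation

    ΔP ≈ 2 σ_m / R_p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, InvalidGeometryError

__all__ = [
    "ExtruderGeometry",
    "FlowSetting",
    "PressureTension",
    "volumetric_flux",
    "force_to_pressure",
    "tension_from_pressure",
    "pressure_from_tension",
    "flux_si_to_ml_min_cm2",
    "flux_ml_min_cm2_to_si",
]

# 1 mL·min⁻¹·cm⁻² expressed in SI flux units (m³·s⁻¹·m⁻² ≡ m·s⁻¹)
_ML_MIN_CM2 = 1e-6 / (60.0 * 1e-4)


@dataclass(frozen=True)
class ExtruderGeometry:
    """Geometry of the syringe–filter extrusion train.

    Parameters
    ----------
    syringe_radius_m :
        Inner radius of the driving syringe, R_S (m).
    filter_radius_m :
        Radius of the exposed filter disc, R_F (m).
    pore_radius_m :
        Radius of a single extrusion pore, R_p (m).
    pore_length_m :
        Pore length (m); carried for provenance, unused by the flux and
        tension relations, which reduce the geometry to the pore radius.
    pore_count :
        Number of pores in the filter; informational only.
    """

    syringe_radius_m: float
    filter_radius_m: float
    pore_radius_m: float
    pore_length_m: float = 10e-6
    pore_count: int = 1

    def __post_init__(self) -> None:
        for name in ("syringe_radius_m", "filter_radius_m", "pore_radius_m", "pore_length_m"):
            if not (getattr(self, name) > 0.0) or not math.isfinite(getattr(self, name)):
                raise InvalidGeometryError(f"{name} must be positive and finite")
        if self.pore_radius_m >= self.filter_radius_m:
            raise InvalidGeometryError("pore_radius_m must be smaller than filter_radius_m")
        if self.pore_count < 1:
            raise InvalidGeometryError("pore_count must be a positive integer")


@dataclass(frozen=True)
class FlowSetting:
    """Flow set-point of a run: piston velocity, resulting flux, temperature."""

    piston_velocity_m_s: float
    volumetric_flux_si: float
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.piston_velocity_m_s < 0.0:
            raise DomainError("piston velocity must be >= 0")
        if self.volumetric_flux_si < 0.0:
            raise DomainError("volumetric flux must be >= 0")
        if not self.temperature_K > 0.0:
            raise DomainError("temperature must be > 0 K")

    @property
    def volumetric_flux_ml_min_cm2(self) -> float:
        return flux_si_to_ml_min_cm2(self.volumetric_flux_si)


@dataclass(frozen=True)
class PressureTension:
    """Paired transmembrane pressure difference and lateral membrane tension."""

    pressure_difference_Pa: float
    lateral_tension_N_m: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pressure_difference_Pa) and math.isfinite(self.lateral_tension_N_m)):
            raise DomainError("pressure and tension must be finite")


def volumetric_flux(geometry: ExtruderGeometry, piston_velocity: float) -> float:
    """Volumetric flux across the filter, J_V = R_S²·v_p / R_F².

    Units follow the inputs: with SI metres and m·s⁻¹ the result is
    m³·s⁻¹·m⁻² (numerically m·s⁻¹).
    """
    if piston_velocity < 0.0:
        raise DomainError("piston velocity must be >= 0")
    return (geometry.syringe_radius_m ** 2) * piston_velocity / (geometry.filter_radius_m ** 2)


def force_to_pressure(force_N: float, geometry: ExtruderGeometry) -> float:
    """Convert piston force to hydrostatic pressure difference, ΔP = F/(π·R_S²).

    The conversion uses the piston cross-section; seal friction beyond the
    measured no-lipid device baseline is not modelled (the baseline
    subtraction in :mod:`extrumech.traces` accounts for it).
    """
    if force_N < 0.0:
        raise DomainError("force must be >= 0")
    return force_N / (math.pi * geometry.syringe_radius_m ** 2)


def tension_from_pressure(pressure_Pa: float, pore_radius_m: float) -> float:
    """Lateral membrane tension at the pore, σ_m = ΔP·R_p/2."""
    if pore_radius_m <= 0.0:
        raise InvalidGeometryError("pore radius must be > 0")
    if pressure_Pa < 0.0:
        raise DomainError("pressure difference must be >= 0")
    return 0.5 * pressure_Pa * pore_radius_m


def pressure_from_tension(tension_N_m: float, pore_radius_m: float) -> float:
    """Pressure difference sustaining a tension σ_m at the pore, ΔP = 2σ_m/R_p."""
    if pore_radius_m <= 0.0:
        raise InvalidGeometryError("pore radius must be > 0")
    if tension_N_m < 0.0:
        raise DomainError("tension must be >= 0")
    return 2.0 * tension_N_m / pore_radius_m


def flux_si_to_ml_min_cm2(flux_si: float) -> float:
    """Render an SI flux (m³·s⁻¹·m⁻²) in the laboratory unit mL·min⁻¹·cm⁻²."""
    return flux_si / _ML_MIN_CM2


def flux_ml_min_cm2_to_si(flux_lab: float) -> float:
    """Parse a laboratory flux (mL·min⁻¹·cm⁻²) into SI (m³·s⁻¹·m⁻²)."""
    return flux_lab * _ML_MIN_CM2
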