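"""Bilayer continuum mechanics and force-based calibrations.

Two energy densities describe the bilayer response during extrusion:

* stretching, ``E_exp = ½·K_A·((A − A0)/A0)²`` with area compression
  modulus K_A (N·m⁻¹);
* bending, the Helfrich form
  ``E_bend = ½·κ_b·(C1 + C2 − C0)² + κ_G·C1·C2`` with bending rigidity κ_b,
  Gaussian modulus κ_G and spontaneous curvature C0.

For a closed sphere with C0 = 0, the integrated bending energy is the
classic scale-invariant 8π·κ_b + 4π·κ_G.

The extrusion force itself is calibrated against literature mechanical
parameters: the stabilised (≈ sixth-cycle) force tracks the bending
rigidity, while the first-cycle force (or the cycle-1 minus stabilised
difference) tracks the tensile strength.  Both calibrations are ordinary
least-squares lines through user-supplied anchor points; extrapolation
beyond the anchor range is refused unless overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError, ExtrapolationError, RankDeficiencyError
from .traces import ForceDecomposition

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ElasticParameters",
    "StretchState",
    "CurvatureState",
    "MembraneComposition",
    "LinearFit",
    "MechanicsCalibration",
    "stretching_energy",
    "bending_energy_density",
    "sphere_bending_energy",
    "fit_force_vs_composition",
    "calibrate_mechanics",
    "read_calibration_anchors",
    "estimate_bending_rigidity",
    "estimate_tensile_strength",
    "joules_to_kbt",
]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class ElasticParameters:
    """Phenomenological elastic constants of a lipid bilayer."""

    bending_rigidity_J: float
    gaussian_modulus_J: float = 0.0
    spontaneous_curvature_per_m: float = 0.0
    compression_modulus_N_m: float = 0.24  # typical PC bilayer K_A

    def __post_init__(self) -> None:
        if not self.bending_rigidity_J > 0.0:
            raise DomainError("bending rigidity must be > 0")
        if not self.compression_modulus_N_m > 0.0:
            raise DomainError("compression modulus must be > 0")

    def bending_rigidity_kbt(self, temperature_K: float = 298.15) -> float:
        return self.bending_rigidity_J / (BOLTZMANN_J_PER_K * temperature_K)


@dataclass(frozen=True)
class StretchState:
    """Relaxed and stressed membrane areas."""

    relaxed_area_m2: float
    stressed_area_m2: float

    def __post_init__(self) -> None:
        if self.relaxed_area_m2 <= 0.0:
            raise DomainError("relaxed area must be > 0")
        if self.stressed_area_m2 < 0.0:
            raise DomainError("stressed area must be >= 0")


@dataclass(frozen=True)
class CurvatureState:
    """The two principal local curvatures of a membrane patch."""

    c1_per_m: float
    c2_per_m: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c1_per_m) and math.isfinite(self.c2_per_m)):
            raise DomainError("curvatures must be finite")


@dataclass(frozen=True)
class MembraneComposition:
    """Host lipid plus cholesterol mole fraction."""

    cholesterol_fraction: float
    host_lipid: str = "POPC"

    def __post_init__(self) -> None:
        if not 0.0 <= self.cholesterol_fraction <= 1.0:
            raise DomainError("cholesterol fraction must lie in [0, 1]")


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line with diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    residuals: np.ndarray
    x_min: float
    x_max: float

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class MechanicsCalibration:
    """Force → mechanical-parameter calibration line.

    ``target`` names the calibrated property; ``mode`` records which force
    the anchors refer to (stabilised cycle force for bending rigidity,
    first-cycle or formation-difference force for tensile strength).
    """

    target: Literal["bending_rigidity", "tensile_strength"]
    mode: Literal["stabilized", "first_cycle", "difference"]
    fit: LinearFit
    provenance: str = "user-supplied literature anchors"


def stretching_energy(compression_modulus_N_m: float, state: StretchState) -> float:
    """Stretching elastic energy per unit area, ½·K_A·((A−A0)/A0)² (N·m⁻¹)."""
    if compression_modulus_N_m <= 0.0:
        raise DomainError("compression modulus must be > 0")
    strain = (state.stressed_area_m2 - state.relaxed_area_m2) / state.relaxed_area_m2
    return 0.5 * compression_modulus_N_m * strain * strain


def bending_energy_density(params: ElasticParameters, curv: CurvatureState) -> float:
    """Helfrich bending energy per unit area (J·m⁻²)."""
    mean_term = curv.c1_per_m + curv.c2_per_m - params.spontaneous_curvature_per_m
    return (0.5 * params.bending_rigidity_J * mean_term * mean_term
            + params.gaussian_modulus_J * curv.c1_per_m * curv.c2_per_m)


def sphere_bending_energy(params: ElasticParameters, radius_m: float) -> float:
    """Total bending energy of a closed sphere of the given radius (J).

    For zero spontaneous curvature the result is 8π·κ_b + 4π·κ_G,
    independent of the radius.
    """
    if radius_m <= 0.0:
        raise DomainError("radius must be > 0")
    c = 1.0 / radius_m
    area = 4.0 * math.pi * radius_m * radius_m
    return area * bending_energy_density(params, CurvatureState(c, c))


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    if np.unique(x).size < 2:
        raise RankDeficiencyError("need >= 2 distinct x values for a line")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    # constant-y data: no variance to explain, report R² = 0 by convention
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        slope_se=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        intercept_se=float(res.intercept_stderr) if np.isfinite(res.intercept_stderr) else 0.0,
        residuals=y - pred,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def fit_force_vs_composition(points: Sequence[tuple[float, float]]) -> LinearFit:
    """OLS fit of extrusion force against cholesterol mole fraction.

    Expects ``(cholesterol_fraction, force_N)`` pairs spanning at least two
    distinct fractions; the slope sign is of direct interest (cholesterol
    stiffens PC bilayers, so a positive slope is the expected outcome for
    both the first-cycle and stabilised forces).
    """
    if len(points) < 3:
        raise DomainError("need >= 3 (fraction, force) points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    return _ols(x, y)


def calibrate_mechanics(
    anchor_points: Sequence[tuple[float, float]],
    target: Literal["bending_rigidity", "tensile_strength"],
    mode: Literal["stabilized", "first_cycle", "difference"] | None = None,
    provenance: str = "user-supplied literature anchors",
) -> MechanicsCalibration:
    """Least-squares line through ``(force_N, literature value)`` anchors.

    Anchor forces must be baseline-corrected and taken from the cycle the
    calibration mode designates.  With exactly two anchors the line
    interpolates them exactly (R² = 1 by construction).
    """
    if len(anchor_points) < 2:
        raise RankDeficiencyError("need >= 2 anchor points")
    if mode is None:
        mode = "stabilized" if target == "bending_rigidity" else "first_cycle"
    if target == "bending_rigidity" and mode != "stabilized":
        raise ConfigurationError("bending rigidity is calibrated against the stabilised force")
    if target == "tensile_strength" and mode == "stabilized":
        raise ConfigurationError("tensile strength is calibrated against F1 or the difference")
    x = np.array([p[0] for p in anchor_points], dtype=float)
    y = np.array([p[1] for p in anchor_points], dtype=float)
    return MechanicsCalibration(target=target, mode=mode, fit=_ols(x, y), provenance=provenance)


def read_calibration_anchors(
    path, property_name: Literal["bending_rigidity", "tensile_strength"],
) -> list[tuple[float, float]]:
    """Read ``(force_N, value)`` anchor pairs for one property from a CSV.

    Expected header: ``cholesterol_fraction,force_N,property,value,units``.
    Anchor values are user-supplied from the literature; the template
    shipped with the package contains synthetic placeholders only.
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = {"force_N", "property", "value"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"{path}: expected columns {sorted(required)}")
    rows = df[df["property"] == property_name]
    if len(rows) < 2:
        raise RankDeficiencyError(
            f"{path}: fewer than 2 anchors for property {property_name!r}")
    return list(zip(rows["force_N"].astype(float), rows["value"].astype(float)))


def _apply_calibration(force: float, cal: MechanicsCalibration,
                       allow_extrapolation: bool) -> tuple[float, float]:
    fit = cal.fit
    if not allow_extrapolation and not (fit.x_min <= force <= fit.x_max):
        raise ExtrapolationError(
            f"force {force:.3g} N outside anchor range [{fit.x_min:.3g}, {fit.x_max:.3g}] N; "
            "pass allow_extrapolation=True to override")
    value = fit.predict(force)
    se = math.hypot(fit.slope_se * force, fit.intercept_se)
    return value, se


def estimate_bending_rigidity(
    stabilized_force_N: float,
    cal: MechanicsCalibration,
    allow_extrapolation: bool = False,
) -> tuple[float, float]:
    """Bending rigidity (in the calibration's units) from the stabilised force.

    Returns ``(value, standard_error)``; the standard error is propagated
    from the calibration line's parameter uncertainties and is zero for an
    exactly-determined two-anchor line.
    """
    if cal.target != "bending_rigidity":
        raise ConfigurationError("calibration was not fitted for bending rigidity")
    return _apply_calibration(stabilized_force_N, cal, allow_extrapolation)


def estimate_tensile_strength(
    decomp: ForceDecomposition,
    cal: MechanicsCalibration,
    mode: Literal["first_cycle", "difference"] = "first_cycle",
    allow_extrapolation: bool = False,
) -> dict:
    """Tensile strength from a force decomposition via a fitted calibration.

    ``first_cycle`` maps F1; ``difference`` maps F1 − F∞ and carries a
    caveat flag: the formation-force difference has been observed to
    *decrease* with cholesterol content, opposite to the tensile-strength
    trend established on giant unilamellar vesicles, so difference-mode
    estimates should be treated as exploratory.
    """
    if cal.target != "tensile_strength":
        raise ConfigurationError("calibration was not fitted for tensile strength")
    if cal.mode != mode:
        raise ConfigurationError(f"calibration mode {cal.mode!r} does not match requested {mode!r}")
    force = decomp.first_cycle_force_N if mode == "first_cycle" else decomp.formation_force_N
    value, se = _apply_calibration(force, cal, allow_extrapolation)
    return {
        "value": value,
        "standard_error": se,
        "mode": mode,
        "caveat_anomalous_trend": mode == "difference",
    }


def joules_to_kbt(energy_J: float, temperature_K: float = 298.15) -> float:
    """Express an energy in units of k_B·T at the given temperature."""
    if temperature_K <= 0.0:
        raise DomainError("temperature must be > 0 K")
    return energy_J / (BOLTZMANN_J_PER_K * temperature_K)
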