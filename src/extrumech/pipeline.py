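"""End-to-end orchestration: config validation, staged runs, JSON reports.

A run wires the modules together in the order the experiment happens:
synthesize or load a force trace → segment cycles → baseline-correct →
decompose forces → (optionally) calibrate to mechanical parameters;
synthesize or load vesicle populations → histogram → mixture fits →
homogeneity verdict → DLS/TEM comparison; synthesize or load spectra →
FRET mixing verdict.  Stages are independent where possible: a failure is
recorded per stage and the remaining independent stages still run.

Configuration is a JSON file validated by a pydantic model; all lengths
are SI metres internally, with the volumetric-flux set-point accepted and
re-serialized in the laboratory unit mL·min⁻¹·cm⁻².
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .errors import ConfigurationError
from .fret import FretControls, StewartCalibration, evaluate_mixing, fret_ratio
from .geometry import (ExtruderGeometry, FlowSetting, flux_ml_min_cm2_to_si,
                       flux_si_to_ml_min_cm2, force_to_pressure, tension_from_pressure,
                       volumetric_flux)
from .mechanics import calibrate_mechanics, estimate_bending_rigidity, estimate_tensile_strength
from .populations import build_histogram, classify_histogram, compare_dls_tem, dls_summary
from .synth import (PopulationSpec, ScenarioModel, SpectrumSpec, TraceSpec,
                    generate_force_trace, generate_population, simulate_fret_spectrum,
                    simulate_recalibration)
from .traces import DeviceBaseline, correct_baseline, decompose_forces, summarize_cycles

logger = logging.getLogger("extrumech")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    syringe_radius_m: float = Field(4.85e-3, gt=0)
    filter_radius_m: float = Field(9.5e-3, gt=0)
    pore_radius_m: float = Field(50e-9, gt=0)
    pore_length_m: float = Field(10e-6, gt=0)
    pore_count: int = Field(1, ge=1)

    def to_geometry(self) -> ExtruderGeometry:
        return ExtruderGeometry(self.syringe_radius_m, self.filter_radius_m,
                                self.pore_radius_m, self.pore_length_m, self.pore_count)


class FlowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    piston_velocity_m_s: float = Field(0.0, ge=0)
    volumetric_flux_ml_min_cm2: float = Field(0.48, ge=0)
    temperature_K: float = Field(298.15, gt=0)


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gap_threshold_N: float = Field(1.0, gt=0)
    min_duration_s: float = Field(0.5, gt=0)
    plateau_fraction: float = Field(0.5, gt=0, le=1)
    stable_tol: float = Field(0.05, gt=0, lt=1)
    delta: float = Field(0.02, ge=0, lt=1)
    adequacy: float = Field(0.98, gt=0, le=1)
    mixing_threshold: float = Field(0.1, ge=0, le=1)


class CalibrationAnchor(BaseModel):
    model_config = ConfigDict(extra="forbid")
    force_N: float
    value: float


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bending_rigidity_anchors: list[CalibrationAnchor] = Field(default_factory=list)
    tensile_strength_anchors: list[CalibrationAnchor] = Field(default_factory=list)
    tensile_mode: Literal["first_cycle", "difference"] = "first_cycle"


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration with SI-normalized units."""

    model_config = ConfigDict(extra="forbid")
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    flow: FlowConfig = Field(default_factory=FlowConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    calibration: CalibrationConfig | None = None
    composition: str = "POPC"
    scenario: Literal["A", "B", "C"] = "A"
    recalibration_pore_diameter_nm: float = Field(50.0, gt=0)
    seed: int = 0
    output_dir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(path: str | Path | None = None,
                    data: dict[str, Any] | None = None) -> RunConfig:
    """Load, schema-check and default-fill a JSON pipeline configuration."""
    if (path is None) == (data is None):
        raise ConfigurationError("provide exactly one of path or data")
    if path is not None:
        with open(path) as fh:
            data = json.load(fh)
    try:
        cfg = RunConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError carries itemized errors
        raise ConfigurationError(str(exc)) from exc
    return cfg


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute a full synthetic end-to-end run and return the report dict.

    Deterministic for a fixed config and seed.  Each stage records either
    its result or its error; dependent stages are skipped with a notice
    when an upstream stage fails, independent ones still run.
    """
    rng = np.random.default_rng(config.seed)
    report: dict[str, Any] = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
        },
        "stages": {},
        "warnings": [],
    }
    th = config.thresholds

    # ---- force-trace stage ------------------------------------------------
    decomp = None
    try:
        trace_spec = TraceSpec(seed=config.seed)
        trace, truth = generate_force_trace(trace_spec, rng)
        summaries = summarize_cycles(trace, th.gap_threshold_N, th.min_duration_s,
                                     th.plateau_fraction)
        baseline = DeviceBaseline(trace_spec.baseline_force_N)
        corrected = [correct_baseline(s, baseline) for s in summaries]
        decomp = decompose_forces(corrected, th.stable_tol)
        decomp_raw = decompose_forces(summaries, th.stable_tol)
        report["stages"]["trace"] = {
            "n_cycles": len(summaries),
            "per_cycle_force_N": [round(s.plateau_force_N, 4) for s in corrected],
            "per_cycle_force_raw_N": [round(s.plateau_force_N, 4) for s in summaries],
            "decomposition": {
                "first_cycle_force_N": decomp.first_cycle_force_N,
                "stabilized_force_N": decomp.stabilized_force_N,
                "formation_force_N": decomp.formation_force_N,
                "convergence_cycle": decomp.convergence_cycle,
            },
            "decomposition_uncorrected": {
                "first_cycle_force_N": decomp_raw.first_cycle_force_N,
                "stabilized_force_N": decomp_raw.stabilized_force_N,
                "formation_force_N": decomp_raw.formation_force_N,
            },
        }
    except Exception as exc:
        logger.exception("trace stage failed")
        report["stages"]["trace"] = {"error": f"{type(exc).__name__}: {exc}"}

    # ---- pore pressure / tension -----------------------------------------
    try:
        geom = config.geometry.to_geometry()
        flux_si = flux_ml_min_cm2_to_si(config.flow.volumetric_flux_ml_min_cm2)
        v_p = config.flow.piston_velocity_m_s or (
            flux_si * geom.filter_radius_m ** 2 / geom.syringe_radius_m ** 2)
        flow = FlowSetting(v_p, volumetric_flux(geom, v_p), config.flow.temperature_K)
        stage: dict[str, Any] = {
            "volumetric_flux_ml_min_cm2": flux_si_to_ml_min_cm2(flow.volumetric_flux_si),
            "piston_velocity_m_s": flow.piston_velocity_m_s,
        }
        if decomp is not None:
            dp = force_to_pressure(decomp.stabilized_force_N, geom)
            stage["stabilized_pressure_Pa"] = dp
            stage["stabilized_lateral_tension_N_m"] = tension_from_pressure(dp, geom.pore_radius_m)
        report["stages"]["flux_tension"] = stage
    except Exception as exc:
        logger.exception("flux stage failed")
        report["stages"]["flux_tension"] = {"error": f"{type(exc).__name__}: {exc}"}

    # ---- mechanics calibration -------------------------------------------
    if config.calibration is None:
        report["stages"]["mechanics"] = {"skipped": "no calibration anchors configured"}
        report["warnings"].append("mechanics stage skipped: no calibration supplied")
    elif decomp is None:
        report["stages"]["mechanics"] = {"skipped": "trace stage failed upstream"}
    else:
        try:
            stage = {}
            cal_cfg = config.calibration
            if len(cal_cfg.bending_rigidity_anchors) >= 2:
                cal = calibrate_mechanics(
                    [(a.force_N, a.value) for a in cal_cfg.bending_rigidity_anchors],
                    target="bending_rigidity")
                kb, kb_se = estimate_bending_rigidity(decomp.stabilized_force_N, cal,
                                                      allow_extrapolation=True)
                stage["bending_rigidity"] = {"value": kb, "standard_error": kb_se,
                                             "units": "calibration anchor units",
                                             "r_squared": cal.fit.r_squared}
            if len(cal_cfg.tensile_strength_anchors) >= 2:
                cal = calibrate_mechanics(
                    [(a.force_N, a.value) for a in cal_cfg.tensile_strength_anchors],
                    target="tensile_strength", mode=cal_cfg.tensile_mode)
                stage["tensile_strength"] = estimate_tensile_strength(
                    decomp, cal, mode=cal_cfg.tensile_mode, allow_extrapolation=True)
            report["stages"]["mechanics"] = stage or {"skipped": "fewer than 2 anchors per property"}
        except Exception as exc:
            logger.exception("mechanics stage failed")
            report["stages"]["mechanics"] = {"error": f"{type(exc).__name__}: {exc}"}

    # ---- population stage -------------------------------------------------
    try:
        pop_spec = PopulationSpec(seed=config.seed)
        extruded = generate_population(pop_spec, rng)
        verdict_ex, fit1_ex, fit2_ex = classify_histogram(
            build_histogram(extruded), delta=th.delta, adequacy=th.adequacy, seed=config.seed)
        model = ScenarioModel(config.scenario, config.recalibration_pore_diameter_nm,
                              seed=config.seed)
        recal = simulate_recalibration(extruded, model, rng)
        verdict_re, fit1_re, fit2_re = classify_histogram(
            build_histogram(recal), delta=th.delta, adequacy=th.adequacy, seed=config.seed)
        dls = dls_summary(recal)
        report["stages"]["population"] = {
            "extruded": {"verdict": verdict_ex.verdict,
                         "r_squared": [verdict_ex.r_squared_one, verdict_ex.r_squared_two]},
            "recalibrated": {"scenario": config.scenario,
                             "verdict": verdict_re.verdict,
                             "r_squared": [verdict_re.r_squared_one, verdict_re.r_squared_two]},
            "dls_vs_tem": compare_dls_tem(dls, recal.number_mean_nm()),
        }
    except Exception as exc:
        logger.exception("population stage failed")
        report["stages"]["population"] = {"error": f"{type(exc).__name__}: {exc}"}

    # ---- FRET stage ---------------------------------------------------------
    try:
        spec = SpectrumSpec(seed=config.seed)
        labelled = PopulationSpec(
            seed=config.seed,
            label_fractions={"donor": 0.5, "acceptor": 0.5, "dual": 0.0, "none": 0.0})
        donors_acceptors = generate_population(labelled, rng)
        model = ScenarioModel(config.scenario, config.recalibration_pore_diameter_nm,
                              seed=config.seed)
        co_recal = simulate_recalibration(donors_acceptors, model, rng)
        negative = fret_ratio(simulate_fret_spectrum(donors_acceptors, spec, rng))
        positive_pop = generate_population(
            PopulationSpec(seed=config.seed,
                           label_fractions={"donor": 0.0, "acceptor": 0.0, "dual": 1.0,
                                            "none": 0.0}), rng)
        positive = fret_ratio(simulate_fret_spectrum(positive_pop, spec, rng))
        sample = fret_ratio(simulate_fret_spectrum(co_recal, spec, rng))
        result = evaluate_mixing(sample, FretControls(negative, positive), th.mixing_threshold)
        report["stages"]["fret"] = {
            "scenario": config.scenario,
            "fret_ratio": result.fret_ratio,
            "mixing_index": result.mixing_index,
            "verdict": result.verdict,
            "controls": {"negative": negative, "positive": positive},
        }
    except Exception as exc:
        logger.exception("fret stage failed")
        report["stages"]["fret"] = {"error": f"{type(exc).__name__}: {exc}"}

    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Serialize a report to JSON (creating parent directories)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
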