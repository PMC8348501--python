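"""FRET lipid-mixing quantification and Stewart lipid assay.

Lipid mixing between co-extruded vesicle populations is detected by
resonance energy transfer between an NBD donor (excitation 467 nm, emission
peak 531 nm) and a rhodamine-B acceptor (emission peak 589 nm): when both
dyes reside in the same bilayer, donor emission is quenched and the
acceptor band grows.  A sample spectrum is reduced to the acceptor/donor
band-integral ratio, normalised between a negative control (single-dye
populations mixed without fusing) and a positive control (dual-labelled
vesicles) to give a mixing index in [0, 1].

Total lipid is quantified by the Stewart ammonium-ferrothiocyanate assay:
absorbance is linear in phospholipid concentration, so concentration is
recovered by inverting a user-calibrated line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidControlsError, UndefinedRatioError

__all__ = [
    "DONOR_EMISSION_PEAK_NM",
    "ACCEPTOR_EMISSION_PEAK_NM",
    "EXCITATION_NM",
    "EmissionSpectrum",
    "FretControls",
    "MixingResult",
    "StewartCalibration",
    "read_spectrum",
    "fret_ratio",
    "mixing_index",
    "classify_mixing",
    "evaluate_mixing",
    "concentration_from_absorbance",
]

EXCITATION_NM = 467.0
DONOR_EMISSION_PEAK_NM = 531.0
ACCEPTOR_EMISSION_PEAK_NM = 589.0


@dataclass(frozen=True)
class EmissionSpectrum:
    """Donor-excited emission spectrum over (at least) 520–630 nm."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_nm: float = EXCITATION_NM

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)
        if wl.ndim != 1 or it.shape != wl.shape or wl.size < 2:
            raise DomainError("spectrum needs aligned 1-D wavelength/intensity arrays")
        if not np.all(np.diff(wl) > 0):
            raise DomainError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise DomainError("intensities must be finite")
        if np.any(it < 0):
            raise DomainError("intensities must be >= 0")
        if wl[0] > DONOR_EMISSION_PEAK_NM - 5 or wl[-1] < ACCEPTOR_EMISSION_PEAK_NM + 5:
            raise DomainError("spectrum must cover the 531 nm and 589 nm bands")


@dataclass(frozen=True)
class FretControls:
    """Acceptor/donor ratios of the negative and positive control samples."""

    negative_ratio: float
    positive_ratio: float

    def __post_init__(self) -> None:
        if not self.positive_ratio > self.negative_ratio:
            raise InvalidControlsError("positive control ratio must exceed the negative")


@dataclass(frozen=True)
class MixingResult:
    """Mixing verdict with the quantities that produced it."""

    fret_ratio: float
    mixing_index: float
    verdict: Literal["mixed", "not_mixed"]
    threshold: float


@dataclass(frozen=True)
class StewartCalibration:
    """Linear absorbance-vs-concentration calibration of the Stewart assay."""

    slope_per_mg_ml: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope_per_mg_ml > 0.0:
            raise DomainError("Stewart calibration slope must be > 0")


def read_spectrum(path: str | Path) -> EmissionSpectrum:
    """Read a two-column delimited spectrum with header ``wavelength_nm,intensity``."""
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"wavelength_nm", "intensity"} <= set(df.columns):
        raise DomainError(f"{path}: expected columns wavelength_nm,intensity")
    return EmissionSpectrum(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())


def _band_integral(spec: EmissionSpectrum, center_nm: float, half_width_nm: float) -> float:
    mask = np.abs(spec.wavelength_nm - center_nm) <= half_width_nm
    if mask.sum() < 2:
        raise DomainError(f"spectrum does not resolve the {center_nm} nm band")
    return float(np.trapezoid(spec.intensity[mask], spec.wavelength_nm[mask]))


def fret_ratio(
    spec: EmissionSpectrum,
    donor_band_nm: tuple[float, float] = (DONOR_EMISSION_PEAK_NM, 5.0),
    acceptor_band_nm: tuple[float, float] = (ACCEPTOR_EMISSION_PEAK_NM, 5.0),
) -> float:
    """Acceptor/donor band-integral ratio of a donor-excited spectrum.

    Bands are (center, half-width) windows; integrals rather than peak
    heights make the ratio robust to the sampling grid and invariant under
    uniform intensity rescaling.
    """
    donor = _band_integral(spec, *donor_band_nm)
    acceptor = _band_integral(spec, *acceptor_band_nm)
    if donor <= 0.0:
        raise UndefinedRatioError("donor band integral is zero")
    return acceptor / donor


def mixing_index(sample_ratio: float, controls: FretControls) -> float:
    """Sample ratio normalised between the controls, clipped to [0, 1]."""
    span = controls.positive_ratio - controls.negative_ratio
    raw = (sample_ratio - controls.negative_ratio) / span
    return float(np.clip(raw, 0.0, 1.0))


def classify_mixing(index: float, threshold: float = 0.1) -> MixingResult:
    """Binary mixing verdict: mixed iff the index exceeds the threshold.

    The threshold is a fraction of the control span; the underlying
    experiment reports a detected/not-detected outcome, so the default is a
    conservative 10% of the dynamic range.
    """
    if not 0.0 <= index <= 1.0:
        raise DomainError("mixing index must lie in [0, 1]")
    return MixingResult(
        fret_ratio=float("nan"),
        mixing_index=index,
        verdict="mixed" if index > threshold else "not_mixed",
        threshold=threshold,
    )


def evaluate_mixing(sample_ratio: float, controls: FretControls,
                    threshold: float = 0.1) -> MixingResult:
    """Full chain: ratio → index → verdict, retaining the raw ratio."""
    idx = mixing_index(sample_ratio, controls)
    res = classify_mixing(idx, threshold)
    return MixingResult(fret_ratio=sample_ratio, mixing_index=idx,
                        verdict=res.verdict, threshold=threshold)


def concentration_from_absorbance(absorbance: float, cal: StewartCalibration) -> float:
    """Invert the Stewart calibration line to a lipid concentration (mg·mL⁻¹).

    Absorbances below the calibration intercept are clipped to zero
    concentration with a warning (blank drift), never reported negative.
    """
    if absorbance < cal.intercept:
        warnings.warn("absorbance below calibration intercept; clipping concentration to 0",
                      stacklevel=2)
        return 0.0
    return (absorbance - cal.intercept) / cal.slope_per_mg_ml
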