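"""Segmentation and per-cycle analysis of multi-cycle extrusion force traces.

A run consists of several passes ("cycles") of the liposome suspension
through the filter.  Within each cycle the force rises rapidly and then
plateaus while flow is constant; between cycles the syringe is reversed and
the force falls back to the device baseline.  Across cycles the plateau
force declines monotonically as multilamellar vesicles are converted to
unilamellar ones, stabilising around the sixth cycle.  The first-cycle and
stabilised plateau forces separate the irreversible contribution (vesicle
formation, F1 − F∞) from the reversible one (bilayer deformation plus
device resistance, F∞).

Plateau statistics are robust (median / scaled MAD) to tolerate the
pressure spikes that accompany cycle starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyTraceError, InsufficientPlateauError

__all__ = [
    "ForceTrace",
    "CycleSummary",
    "DeviceBaseline",
    "ForceDecomposition",
    "read_force_trace",
    "segment_cycles",
    "plateau_force",
    "summarize_cycles",
    "correct_baseline",
    "decompose_forces",
    "transmitted_lipid_fraction",
]

# scale factor making the median absolute deviation a consistent estimator
# of the Gaussian standard deviation
_MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class ForceTrace:
    """Time-stamped extrusion force record for one multi-cycle run."""

    time_s: np.ndarray
    force_N: np.ndarray
    run_id: str = ""
    composition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.force_N, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "force_N", f)
        if t.ndim != 1 or f.shape != t.shape or t.size < 2:
            raise DomainError("trace needs >= 2 aligned (time, force) samples")
        if not np.all(np.isfinite(f)) or not np.all(np.isfinite(t)):
            raise DomainError("trace samples must be finite")
        if not np.all(np.diff(t) > 0.0):
            raise DomainError("time must be strictly increasing")


@dataclass(frozen=True)
class CycleSummary:
    """Plateau force and quality metrics for one extrusion cycle."""

    cycle_index: int  # 1-based
    plateau_force_N: float
    plateau_sd_N: float
    rise_duration_s: float
    n_plateau_samples: int
    baseline_corrected: bool = False
    clipped: bool = False


@dataclass(frozen=True)
class DeviceBaseline:
    """Intrinsic device resistance from a no-lipid control run."""

    baseline_force_N: float
    baseline_sd_N: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_force_N < 0.0:
            raise DomainError("baseline force must be >= 0")


@dataclass(frozen=True)
class ForceDecomposition:
    """First-cycle vs stabilised force split of a multi-cycle run.

    ``formation_force_N`` (F1 − F∞) is the irreversible, vesicle-formation
    contribution; the stabilised force carries the reversible deformation
    work plus whatever device resistance was not subtracted.
    """

    first_cycle_force_N: float
    stabilized_force_N: float
    formation_force_N: float
    convergence_cycle: int
    converged: bool = True

    def __post_init__(self) -> None:
        if abs(self.formation_force_N - (self.first_cycle_force_N - self.stabilized_force_N)) > 1e-9:
            raise DomainError("formation force must equal F1 - F_stabilized")
        if self.convergence_cycle < 1:
            raise DomainError("convergence cycle must be >= 1")


def read_force_trace(path: str | Path, run_id: str = "", composition: str = "") -> ForceTrace:
    """Read a two-column delimited trace file with header ``time_s,force_N``."""
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"time_s", "force_N"} <= set(df.columns):
        raise DomainError(f"{path}: expected columns time_s,force_N")
    return ForceTrace(df["time_s"].to_numpy(), df["force_N"].to_numpy(),
                      run_id=run_id or str(path), composition=composition)


@dataclass(frozen=True)
class _Segment:
    """A contiguous slice of a trace attributed to one cycle."""

    time_s: np.ndarray
    force_N: np.ndarray
    start_index: int
    stop_index: int  # exclusive


def segment_cycles(
    trace: ForceTrace,
    gap_threshold_N: float = 1.0,
    min_duration_s: float = 0.5,
    merge_gap_s: float = 1.0,
    smooth_window_s: float = 0.5,
) -> list[_Segment]:
    """Locate extrusion cycles as contiguous runs of supra-threshold force.

    A cycle is a maximal contiguous region where the force exceeds
    ``gap_threshold_N`` for at least ``min_duration_s``.  Thresholding is
    applied to a running-median-smoothed copy of the force (window
    ``smooth_window_s``) so single noisy samples neither create nor split
    cycles; a running median leaves step edges in place, so noiseless
    boundaries stay exact.  Runs separated by sub-threshold dips shorter
    than ``merge_gap_s`` are additionally merged: true inter-cycle gaps are
    much longer.  Segments are non-overlapping and ordered in time.
    """
    force = trace.force_N
    dt = float(np.median(np.diff(trace.time_s)))
    k = int(round(smooth_window_s / dt)) | 1 if dt > 0 else 1
    if k >= 3 and force.size > k:
        from scipy.ndimage import median_filter
        force = median_filter(force, size=k, mode="nearest")
    above = force > gap_threshold_N
    if not above.any():
        raise EmptyTraceError("no samples exceed the gap threshold")
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(trace.force_N.size)
    runs: list[list[int]] = []
    for i0, i1 in zip(starts, stops):
        if runs and trace.time_s[i0] - trace.time_s[runs[-1][1] - 1] < merge_gap_s:
            runs[-1][1] = i1
        else:
            runs.append([i0, i1])
    segments: list[_Segment] = []
    for i0, i1 in runs:
        if trace.time_s[i1 - 1] - trace.time_s[i0] >= min_duration_s:
            segments.append(_Segment(trace.time_s[i0:i1], trace.force_N[i0:i1], i0, i1))
    if not segments:
        raise EmptyTraceError("no supra-threshold region satisfies the minimum duration")
    return segments


def plateau_force(segment: _Segment, plateau_fraction: float = 0.5) -> tuple[float, float]:
    """Robust plateau level of one cycle segment.

    The rise is excluded by dropping all samples before the force first
    reaches 90% of the segment's robust maximum (98th percentile); the
    plateau window is the trailing ``plateau_fraction`` of the remaining
    samples.  Returns (median, scaled-MAD sd).
    """
    f = segment.force_N
    if f.size < 10:
        raise InsufficientPlateauError("segment has fewer than 10 samples")
    if not 0.0 < plateau_fraction <= 1.0:
        raise DomainError("plateau_fraction must lie in (0, 1]")
    robust_max = np.percentile(f, 98)
    risen = np.flatnonzero(f >= 0.9 * robust_max)
    post_rise = f[risen[0]:]
    n_win = max(int(round(plateau_fraction * post_rise.size)), 1)
    window = post_rise[-n_win:]
    if window.size < 5:
        raise InsufficientPlateauError(
            f"plateau window has {window.size} samples (< 5); lower plateau_fraction or resample")
    med = float(np.median(window))
    sd = float(_MAD_TO_SD * np.median(np.abs(window - med)))
    return med, sd


def summarize_cycles(
    trace: ForceTrace,
    gap_threshold_N: float = 1.0,
    min_duration_s: float = 0.5,
    plateau_fraction: float = 0.5,
) -> list[CycleSummary]:
    """Segment a trace and compute a :class:`CycleSummary` per cycle."""
    summaries = []
    for i, seg in enumerate(segment_cycles(trace, gap_threshold_N, min_duration_s), start=1):
        med, sd = plateau_force(seg, plateau_fraction)
        robust_max = np.percentile(seg.force_N, 98)
        first_at_level = np.flatnonzero(seg.force_N >= 0.9 * robust_max)[0]
        rise = float(seg.time_s[first_at_level] - seg.time_s[0])
        n_win = max(int(round(plateau_fraction * (seg.force_N.size - first_at_level))), 1)
        summaries.append(CycleSummary(i, med, sd, rise, n_win))
    return summaries


def correct_baseline(summary: CycleSummary, baseline: DeviceBaseline | None) -> CycleSummary:
    """Subtract the no-lipid device baseline from a cycle's plateau force.

    Negative corrected forces are clipped to zero and flagged.  A missing
    baseline produces an explicit warning and returns the summary unchanged
    (marked uncorrected) rather than failing silently.
    """
    if baseline is None:
        warnings.warn("no device baseline supplied; plateau forces left uncorrected",
                      stacklevel=2)
        return summary
    corrected = summary.plateau_force_N - baseline.baseline_force_N
    clipped = corrected <= 0.0
    if clipped:
        warnings.warn(
            f"cycle {summary.cycle_index}: baseline >= plateau; clipping to 0 N",
            stacklevel=2)
    return replace(summary, plateau_force_N=max(corrected, 0.0),
                   baseline_corrected=True, clipped=clipped)


def decompose_forces(
    summaries: Sequence[CycleSummary],
    stable_tol: float = 0.05,
) -> ForceDecomposition:
    """Split a cycle series into formation and deformation contributions.

    The convergence cycle is the first cycle whose plateau force differs
    from the previous cycle's by less than ``stable_tol`` (relative).  The
    stabilised force F∞ is the plateau at that cycle; the formation force is
    F1 − F∞.  A series that never stabilises returns the last cycle with
    ``converged=False``.
    """
    if len(summaries) < 2:
        raise DomainError("need >= 2 cycles to decompose forces")
    forces = np.array([s.plateau_force_N for s in summaries], dtype=float)
    f1 = float(forces[0])
    convergence = None
    for i in range(1, forces.size):
        prev = forces[i - 1]
        rel = abs(forces[i] - prev) / prev if prev > 0 else abs(forces[i] - prev)
        if rel < stable_tol:
            convergence = i  # 0-based index of converged cycle
            break
    converged = convergence is not None
    if not converged:
        convergence = forces.size - 1
    f_inf = float(forces[convergence])
    return ForceDecomposition(
        first_cycle_force_N=f1,
        stabilized_force_N=f_inf,
        formation_force_N=f1 - f_inf,
        convergence_cycle=int(convergence) + 1,
        converged=converged,
    )


def transmitted_lipid_fraction(
    concentrations_per_cycle: Sequence[float],
    input_concentration: float,
) -> list[float]:
    """Per-cycle fraction of the input lipid found on the trans side.

    Fractions slightly above 1 can occur through assay noise; values above
    1.05 trigger a measurement-inconsistency warning but are reported as
    measured.  Monotone saturation is expected, not enforced.
    """
    if input_concentration <= 0.0:
        raise DomainError("input concentration must be > 0")
    fractions = [c / input_concentration for c in concentrations_per_cycle]
    if any(f > 1.05 for f in fractions):
        warnings.warn("transmitted fraction exceeds 1.05: check Stewart assay consistency",
                      stacklevel=2)
    return fractions
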