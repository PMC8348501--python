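"""Seeded generators emulating the extrusion instrument and its assays.

Everything the analysis modules consume can be generated here with known
ground truth: multi-cycle force traces, vesicle populations, the three
mechanistic recalibration scenarios, donor-excited FRET spectra, and
Stewart-assay absorbances.

Mechanistic scenarios for how unilamellar vesicles form at a pore:

* **A** — vesicles split at the pore *entrance*: each oversized vesicle
  sheds one pore-sized daughter, the left-over lipid closes into a second,
  smaller vesicle.  Labels never mix; the output size distribution is
  bimodal.
* **B** — lipid from several co-transiting vesicles fuses into an
  elongated structure inside the pore and daughters bud at the *exit*,
  slightly larger than the pore.  Labels mix; output is unimodal.
* **C** — as B, but budding happens *inside* the pore, so daughters do not
  exceed the pore diameter.  Labels mix; output is unimodal at/below pore
  size.

Membrane area (∝ lamellarity·d²) is conserved exactly in every split, and
dye bookkeeping is done on area fractions so label redistribution never
creates dye.  All randomness flows through an explicitly passed
``numpy.random.Generator`` (or the seed stored in each spec); there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import DomainError
from .fret import EmissionSpectrum, StewartCalibration
from .populations import VesiclePopulation
from .traces import ForceTrace

__all__ = [
    "TraceSpec",
    "TraceGroundTruth",
    "PopulationSpec",
    "ScenarioModel",
    "SpectrumSpec",
    "CycleTrajectory",
    "generate_force_trace",
    "generate_population",
    "simulate_extrusion_cycles",
    "simulate_recalibration",
    "simulate_fret_spectrum",
    "generate_stewart_absorbance",
]

_MIN_DIAMETER_NM = 20.0


def _rng_from(seed_or_rng: int | np.random.Generator | None, default_seed: int) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    if seed_or_rng is None:
        return np.random.default_rng(default_seed)
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------------------
# force traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    """Parameters of a synthetic multi-cycle force trace.

    Defaults reproduce the canonical POPC run: 7 cycles declining from a
    16.4 N first-cycle plateau to a 6.7 N stabilised plateau, the decline
    saturating near the sixth cycle (decline constant 1.2 cycles).
    """

    n_cycles: int = 7
    first_cycle_force_N: float = 16.4
    stabilized_force_N: float = 6.7
    decline_constant_cycles: float = 1.2
    rise_time_s: float = 1.5
    plateau_duration_s: float = 30.0
    gap_duration_s: float = 8.0
    noise_sd_N: float = 0.12
    baseline_force_N: float = 0.5
    sampling_rate_hz: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.first_cycle_force_N >= self.stabilized_force_N >= 0.0:
            raise DomainError("need first_cycle_force >= stabilized_force >= 0")
        if self.n_cycles < 1 or self.sampling_rate_hz <= 0 or self.plateau_duration_s <= 0:
            raise DomainError("invalid trace spec")
        if self.decline_constant_cycles < 0 or self.rise_time_s < 0 or self.noise_sd_N < 0:
            raise DomainError("invalid trace spec")

    def plateau_level(self, cycle_index: int) -> float:
        """Ground-truth total plateau force of a 1-based cycle (incl. baseline)."""
        f1, finf, lam = self.first_cycle_force_N, self.stabilized_force_N, self.decline_constant_cycles
        if lam == 0:
            decline = f1 - finf if cycle_index == 1 else 0.0
        else:
            decline = (f1 - finf) * np.exp(-(cycle_index - 1) / lam)
        return finf + decline + self.baseline_force_N


@dataclass(frozen=True)
class TraceGroundTruth:
    """What the generator actually put into a trace."""

    plateau_forces_N: np.ndarray  # total per-cycle plateau incl. device baseline
    cycle_bounds: tuple[tuple[int, int], ...]  # (start, stop) sample indices per cycle
    baseline_force_N: float


def generate_force_trace(
    spec: TraceSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ForceTrace, TraceGroundTruth]:
    """Synthesize a multi-cycle extrusion force trace plus its ground truth.

    Each cycle rises exponentially (time constant ``rise_time_s``) from the
    device baseline to its plateau and holds it for ``plateau_duration_s``;
    cycles are separated by baseline-level gaps.  Gaussian noise of
    ``noise_sd_N`` is added throughout.
    """
    rng = _rng_from(rng, spec.seed)
    dt = 1.0 / spec.sampling_rate_hz
    n_gap = max(int(round(spec.gap_duration_s * spec.sampling_rate_hz)), 1)
    n_act = max(int(round(spec.plateau_duration_s * spec.sampling_rate_hz)), 10)

    chunks: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    plateaus: list[float] = []
    pos = 0

    def gap() -> None:
        nonlocal pos
        chunks.append(np.full(n_gap, spec.baseline_force_N))
        pos += n_gap

    gap()
    for i in range(1, spec.n_cycles + 1):
        p_i = spec.plateau_level(i)
        plateaus.append(p_i)
        t_local = np.arange(n_act) * dt
        if spec.rise_time_s > 0:
            profile = spec.baseline_force_N + (p_i - spec.baseline_force_N) * (
                1.0 - np.exp(-t_local / spec.rise_time_s))
        else:
            profile = np.full(n_act, p_i)
        chunks.append(profile)
        bounds.append((pos, pos + n_act))
        pos += n_act
        gap()

    force = np.concatenate(chunks)
    if spec.noise_sd_N > 0:
        force = force + rng.normal(0.0, spec.noise_sd_N, size=force.size)
    force = np.maximum(force, 0.0)
    time = np.arange(force.size) * dt
    trace = ForceTrace(time, force, run_id=f"synthetic seed={spec.seed}")
    truth = TraceGroundTruth(np.array(plateaus), tuple(bounds), spec.baseline_force_N)
    return trace, truth


# --------------------------------------------------------------------------
# vesicle populations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """Gaussian-mixture vesicle population with labels and lamellarity.

    Defaults produce an extruded, unilamellar, unlabelled suspension with
    the canonical 100 nm-pore outcome (mean 137 nm).  ``label_fractions``
    assigns {donor, acceptor, dual, none} tags; ``lamellarity_choices`` /
    ``lamellarity_probs`` draw per-vesicle lamellarity.
    """

    n_vesicles: int = 1000
    size_means_nm: tuple[float, ...] = (137.0,)
    size_sds_nm: tuple[float, ...] = (15.0,)
    weights: tuple[float, ...] = (1.0,)
    lamellarity_choices: tuple[int, ...] = (1,)
    lamellarity_probs: tuple[float, ...] = (1.0,)
    label_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"donor": 0.0, "acceptor": 0.0, "dual": 0.0, "none": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vesicles < 0:
            raise DomainError("n_vesicles must be >= 0")
        if not (len(self.size_means_nm) == len(self.size_sds_nm) == len(self.weights)):
            raise DomainError("size_means, size_sds and weights must align")
        if any(m <= 0 for m in self.size_means_nm) or any(s <= 0 for s in self.size_sds_nm):
            raise DomainError("component means and sds must be > 0")
        if abs(sum(self.weights) - 1.0) > 1e-9 or any(w < 0 for w in self.weights):
            raise DomainError("weights must be a simplex")
        if abs(sum(self.label_fractions.values()) - 1.0) > 1e-9:
            raise DomainError("label fractions must sum to 1")
        if abs(sum(self.lamellarity_probs) - 1.0) > 1e-9:
            raise DomainError("lamellarity probabilities must sum to 1")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int,
                      lower: float = _MIN_DIAMETER_NM,
                      upper: float = np.inf) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out <= lower) | (out > upper)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= lower) | (out > upper)
    return out


def generate_population(
    spec: PopulationSpec,
    rng: np.random.Generator | None = None,
) -> VesiclePopulation:
    """Draw a vesicle population from the spec's Gaussian mixture.

    Diameters are truncated at 20 nm (smaller vesicles are neither physical
    nor resolvable); labels and lamellarity are assigned independently of
    size.
    """
    rng = _rng_from(rng, spec.seed)
    n = spec.n_vesicles
    comp = rng.choice(len(spec.weights), size=n, p=np.asarray(spec.weights))
    d = np.empty(n)
    for j in range(len(spec.weights)):
        mask = comp == j
        d[mask] = _truncated_normal(rng, spec.size_means_nm[j], spec.size_sds_nm[j],
                                    int(mask.sum()))
    lam = rng.choice(np.asarray(spec.lamellarity_choices), size=n,
                     p=np.asarray(spec.lamellarity_probs))
    label_names = ("donor", "acceptor", "dual", "none")
    probs = np.array([spec.label_fractions.get(k, 0.0) for k in label_names])
    tags = rng.choice(4, size=n, p=probs)
    donor = np.where((tags == 0) | (tags == 2), 1.0, 0.0)
    acceptor = np.where((tags == 1) | (tags == 2), 1.0, 0.0)
    return VesiclePopulation(d, lamellarity=lam, donor_frac=donor, acceptor_frac=acceptor,
                             source=f"synthetic seed={spec.seed}")


# --------------------------------------------------------------------------
# mechanistic scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioModel:
    """Which mechanism produces daughters at the pore, and with what sizes.

    ``daughter_mean_factor`` g scales the pore diameter to the daughter
    mean: g ≥ 1 for entrance/exit budding (daughters slightly exceed the
    pore) and g ≤ 1 for in-pore budding.  ``None`` picks the scenario
    default (1.2 for A/B, 0.8 for C).
    """

    scenario: Literal["A", "B", "C"]
    pore_diameter_nm: float
    daughter_mean_factor: float | None = None
    daughter_sd_nm: float = 8.0
    group_size: int = 10  # co-transit pooling size for scenarios B/C
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B", "C"):
            raise DomainError("scenario must be A, B or C")
        if self.pore_diameter_nm <= 0 or self.daughter_sd_nm <= 0 or self.group_size < 1:
            raise DomainError("invalid scenario model")
        if self.daughter_mean_factor is None:
            object.__setattr__(self, "daughter_mean_factor",
                               0.8 if self.scenario == "C" else 1.2)
        if not self.daughter_mean_factor > 0:
            raise DomainError("daughter_mean_factor must be > 0")
        if self.scenario == "C" and self.daughter_mean_factor > 1.0:
            raise DomainError("scenario C daughters cannot exceed the pore diameter (g <= 1)")

    @property
    def daughter_mean_nm(self) -> float:
        return self.daughter_mean_factor * self.pore_diameter_nm


@dataclass(frozen=True)
class CycleTrajectory:
    """Per-cycle observables exposed alongside simulated cycle populations."""

    transmitted_fraction: np.ndarray  # unilamellar (finished) membrane-area fraction
    mean_diameter_nm: np.ndarray
    pdi_analog: np.ndarray  # intensity-weighted relative variance


def _scenario_a_split(d: float, model: ScenarioModel,
                      rng: np.random.Generator) -> tuple[float, float]:
    """One area-conserving entrance split: (daughter, leftover) diameters."""
    hi = np.sqrt(max(d * d - _MIN_DIAMETER_NM ** 2, 0.0))
    if hi <= _MIN_DIAMETER_NM:
        return d, 0.0  # too small to split meaningfully; passes intact
    for _ in range(1000):
        dd = rng.normal(model.daughter_mean_nm, model.daughter_sd_nm)
        if _MIN_DIAMETER_NM < dd < hi:
            return dd, float(np.sqrt(d * d - dd * dd))
    # pathological model (daughter mean far above parent): deterministic fallback
    dd = 0.5 * (hi + _MIN_DIAMETER_NM)
    return dd, float(np.sqrt(d * d - dd * dd))


def _emit_daughters(area: float, model: ScenarioModel,
                    rng: np.random.Generator) -> list[float]:
    """Bud daughters from a pooled membrane area, conserving it exactly.

    Scenario C daughters are additionally capped at the pore diameter —
    in-pore budding cannot produce vesicles larger than the pore.  The
    sub-resolvable area remainder is redistributed multiplicatively over
    the emitted daughters (a < 0.1% diameter shift) so conservation is
    exact.
    """
    cap = model.pore_diameter_nm if model.scenario == "C" else np.inf
    daughters: list[float] = []
    remaining = area
    min_area = _MIN_DIAMETER_NM ** 2
    while remaining > min_area:
        dd = float(_truncated_normal(rng, model.daughter_mean_nm, model.daughter_sd_nm, 1,
                                     upper=cap)[0])
        if dd * dd > remaining:
            dd = float(np.sqrt(remaining))
        daughters.append(dd)
        remaining -= dd * dd
    if remaining > 0.0:
        if daughters:
            scale = float(np.sqrt(area / (area - remaining)))
            daughters = [d * scale for d in daughters]
        else:
            daughters.append(float(np.sqrt(remaining)))
    return daughters


def simulate_recalibration(
    pop: VesiclePopulation,
    model: ScenarioModel,
    rng: np.random.Generator | None = None,
) -> VesiclePopulation:
    """One pass of a preformed unilamellar suspension through smaller pores.

    Scenario A splits every oversized vesicle once (daughter + left-over,
    labels inherited, never mixed).  Scenarios B and C pool membrane area
    within random co-transit groups and bud daughters from the pool, mixing
    labels within each group.  Vesicles at or below the pore diameter pass
    unchanged in every scenario.
    """
    if np.any(pop.lamellarity > 1):
        raise DomainError("recalibration input must be unilamellar")
    if len(pop) and model.pore_diameter_nm >= pop.number_mean_nm():
        raise DomainError("recalibration requires pore diameter below the population mean")
    rng = _rng_from(rng, model.seed)

    d_out: list[float] = []
    don_out: list[float] = []
    acc_out: list[float] = []

    oversized = pop.diameters_nm > model.pore_diameter_nm
    # untouched passthrough
    for i in np.flatnonzero(~oversized):
        d_out.append(float(pop.diameters_nm[i]))
        don_out.append(float(pop.donor_frac[i]))
        acc_out.append(float(pop.acceptor_frac[i]))

    idx = np.flatnonzero(oversized)
    if model.scenario == "A":
        for i in idx:
            d = float(pop.diameters_nm[i])
            dd, leftover = _scenario_a_split(d, model, rng)
            for new_d in (dd, leftover):
                if new_d > 0.0:
                    d_out.append(new_d)
                    don_out.append(float(pop.donor_frac[i]))
                    acc_out.append(float(pop.acceptor_frac[i]))
    else:
        perm = rng.permutation(idx)
        for g0 in range(0, perm.size, model.group_size):
            group = perm[g0:g0 + model.group_size]
            areas = pop.diameters_nm[group] ** 2
            pool = float(areas.sum())
            don_pool = float(np.sum(areas * pop.donor_frac[group])) / pool
            acc_pool = float(np.sum(areas * pop.acceptor_frac[group])) / pool
            for dd in _emit_daughters(pool, model, rng):
                d_out.append(dd)
                don_out.append(don_pool)
                acc_out.append(acc_pool)

    return VesiclePopulation(np.array(d_out), donor_frac=np.array(don_out),
                             acceptor_frac=np.array(acc_out),
                             source=f"recalibrated scenario {model.scenario}")


def _pdi_analog(d: np.ndarray) -> float:
    w = (d / d.max()) ** 6
    z = float(np.sum(w * d) / np.sum(w))
    var = float(np.sum(w * (d - z) ** 2) / np.sum(w))
    return var / (z * z)


def simulate_extrusion_cycles(
    pop: VesiclePopulation,
    model: ScenarioModel,
    n_cycles: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[VesiclePopulation], CycleTrajectory]:
    """Multi-cycle extrusion of a (possibly multilamellar) suspension.

    Per cycle, every multilamellar vesicle sheds its outermost lamella
    (area d²) into unilamellar daughters following the scenario rule, and
    keeps (lamellarity − 1) layers at the same diameter; unilamellar
    vesicles much larger than the pore (> 1.5×) are reprocessed by the
    scenario rule, while pore-sized unilamellar vesicles pass unchanged.
    Membrane area is conserved exactly within each cycle.

    Returns one population per cycle and the per-cycle trajectory of
    transmitted (finished unilamellar) area fraction, number-mean diameter
    and an intensity-weighted polydispersity analog.
    """
    rng = _rng_from(rng, model.seed)
    reprocess = 1.5 * model.pore_diameter_nm
    current = pop
    out: list[VesiclePopulation] = []
    transmitted, means, pdis = [], [], []

    for _ in range(n_cycles):
        d_new: list[float] = []
        lam_new: list[int] = []
        don_new: list[float] = []
        acc_new: list[float] = []

        pooled_area = 0.0
        pooled_don = 0.0
        pooled_acc = 0.0

        for i in range(len(current)):
            d = float(current.diameters_nm[i])
            L = int(current.lamellarity[i])
            don = float(current.donor_frac[i])
            acc = float(current.acceptor_frac[i])
            if L > 1:
                # peel the outer lamella into the budding pool; keep the core
                peeled = d * d
                d_new.append(d)
                lam_new.append(L - 1)
                don_new.append(don)
                acc_new.append(acc)
            elif d > reprocess:
                peeled = d * d
            else:
                d_new.append(d)
                lam_new.append(1)
                don_new.append(don)
                acc_new.append(acc)
                continue

            if model.scenario == "A":
                # no pooling: bud daughters from this vesicle's lipid only
                for dd in _emit_daughters(peeled, model, rng):
                    d_new.append(dd)
                    lam_new.append(1)
                    don_new.append(don)
                    acc_new.append(acc)
            else:
                pooled_area += peeled
                pooled_don += peeled * don
                pooled_acc += peeled * acc

        if pooled_area > 0.0:
            don_pool = pooled_don / pooled_area
            acc_pool = pooled_acc / pooled_area
            for dd in _emit_daughters(pooled_area, model, rng):
                d_new.append(dd)
                lam_new.append(1)
                don_new.append(don_pool)
                acc_new.append(acc_pool)

        current = VesiclePopulation(
            np.array(d_new), lamellarity=np.array(lam_new, dtype=int),
            donor_frac=np.array(don_new), acceptor_frac=np.array(acc_new),
            source=f"extrusion cycle, scenario {model.scenario}")
        out.append(current)

        area = current.membrane_area
        finished = (current.lamellarity == 1) & (current.diameters_nm <= reprocess)
        transmitted.append(float(area[finished].sum() / area.sum()))
        means.append(current.number_mean_nm())
        pdis.append(_pdi_analog(current.diameters_nm))

    return out, CycleTrajectory(np.array(transmitted), np.array(means), np.array(pdis))


# --------------------------------------------------------------------------
# FRET spectra and Stewart assay
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumSpec:
    """Two-peak emission model for the donor/acceptor pair.

    The donor peak (531 nm) loses the transferred fraction of its
    amplitude; the acceptor peak (589 nm) gains it, on top of a small
    constant leak from direct acceptor excitation at 467 nm that gives the
    negative control its realistic nonzero acceptor band.
    """

    donor_peak_nm: float = 531.0
    acceptor_peak_nm: float = 589.0
    peak_width_nm: float = 12.0
    transfer_efficiency: float = 0.8
    acceptor_leak: float = 0.05
    intensity_scale: float = 1000.0
    noise_sd: float = 2.0
    wavelength_start_nm: float = 520.0
    wavelength_stop_nm: float = 630.0
    wavelength_step_nm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfer_efficiency <= 1.0:
            raise DomainError("transfer efficiency must lie in [0, 1]")
        if not 0.0 <= self.acceptor_leak < 1.0:
            raise DomainError("acceptor leak must lie in [0, 1)")
        for peak in (self.donor_peak_nm, self.acceptor_peak_nm):
            if not self.wavelength_start_nm <= peak <= self.wavelength_stop_nm:
                raise DomainError("peaks must lie inside the acquired wavelength range")
        if self.peak_width_nm <= 0 or self.intensity_scale <= 0 or self.noise_sd < 0:
            raise DomainError("invalid spectrum spec")


def dual_label_fraction(pop: VesiclePopulation) -> float:
    """Fraction of labelled vesicles carrying both dyes."""
    labels = pop.labels
    labelled = np.isin(labels, ("donor", "acceptor", "dual"))
    if not labelled.any():
        return 0.0
    return float(np.mean(labels[labelled] == "dual"))


def simulate_fret_spectrum(
    pop: VesiclePopulation,
    spec: SpectrumSpec,
    rng: np.random.Generator | None = None,
) -> EmissionSpectrum:
    """Donor-excited emission spectrum of a labelled vesicle suspension.

    The effective transfer efficiency is the spec's per-vesicle transfer
    efficiency scaled by the dual-labelled vesicle fraction (donor-only
    vesicles cannot transfer; spontaneous inter-vesicle probe exchange is
    taken as zero because both probes partition too strongly into the
    bilayer to hop between vesicles).
    """
    import warnings

    rng = _rng_from(rng, spec.seed)
    labels = pop.labels
    donor_present = bool(np.isin(labels, ("donor", "dual")).any())
    if not donor_present:
        warnings.warn("population carries no donor-labelled vesicles; "
                      "returning leak-only spectrum", stacklevel=2)
    e_eff = spec.transfer_efficiency * dual_label_fraction(pop)
    wl = np.arange(spec.wavelength_start_nm, spec.wavelength_stop_nm + 0.5 * spec.wavelength_step_nm,
                   spec.wavelength_step_nm)

    def peak(center: float) -> np.ndarray:
        return np.exp(-0.5 * ((wl - center) / spec.peak_width_nm) ** 2)

    donor_amp = (1.0 - e_eff) if donor_present else 0.0
    intensity = spec.intensity_scale * (
        donor_amp * peak(spec.donor_peak_nm)
        + (e_eff + spec.acceptor_leak) * peak(spec.acceptor_peak_nm))
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=wl.size)
    return EmissionSpectrum(wl, np.maximum(intensity, 0.0))


def expected_band_ratio(spec: SpectrumSpec, dual_fraction: float) -> float:
    """Closed-form acceptor/donor band ratio of the noiseless two-peak model.

    Because both peaks share a width and the ±5 nm integration windows are
    symmetric about each peak, the band integrals are proportional to the
    peak amplitudes, so the ratio is (E_eff + leak)/(1 − E_eff).
    """
    e_eff = spec.transfer_efficiency * dual_fraction
    if e_eff >= 1.0:
        raise DomainError("donor amplitude vanishes; ratio undefined")
    return (e_eff + spec.acceptor_leak) / (1.0 - e_eff)


def generate_stewart_absorbance(
    concentration_mg_ml: float,
    cal: StewartCalibration,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Forward Stewart model: absorbance = slope·c + intercept (+ noise)."""
    if concentration_mg_ml < 0.0:
        raise DomainError("concentration must be >= 0")
    rng = _rng_from(rng, 0)
    value = cal.slope_per_mg_ml * concentration_mg_ml + cal.intercept
    if noise_sd > 0:
        value += rng.normal(0.0, noise_sd)
    return float(value)
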