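"""Vesicle population statistics: histograms, mixture fits, homogeneity.

After extrusion a liposome suspension should be a single, roughly Gaussian
size population; after recalibration through substantially smaller pores it
may split into two (a pore-sized daughter population plus larger
"left-over" vesicles).  The discrimination used here mirrors how size
histograms measured from micrographs are analysed in practice:

1. bin the measured diameters (Freedman–Diaconis by default),
2. fit the binned counts with one and with two Gaussian components,
3. call the population *heterogeneous* when the two-component fit improves
   R² materially **and** the one-component fit is inadequate.

A dynamic-light-scattering summary (z-average, PDI) is emulated from the
same diameters using Rayleigh d⁶ intensity weighting, which is what makes
DLS systematically overshoot a number-weighted microscopy mean on bimodal
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigurationError, DomainError, FitFailureError, InsufficientSampleError

__all__ = [
    "VesiclePopulation",
    "Histogram",
    "MixtureFit",
    "PopulationVerdict",
    "DlsResult",
    "read_diameters",
    "build_histogram",
    "fit_gaussian_mixture",
    "classify_population",
    "classify_histogram",
    "dls_summary",
    "compare_dls_tem",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))
_MIN_DIAMETER_NM = 20.0  # physical floor; also keeps d⁶ weights finite


@dataclass
class VesiclePopulation:
    """Vesicle diameters with lamellarity and fluorescent-label bookkeeping.

    ``donor_frac`` / ``acceptor_frac`` give, per vesicle, the fraction of
    its membrane area carrying the respective dye; the categorical ``labels``
    view (donor/acceptor/dual/none) is derived from them.
    """

    diameters_nm: np.ndarray
    lamellarity: np.ndarray | None = None
    donor_frac: np.ndarray | None = None
    acceptor_frac: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_nm, dtype=float)
        self.diameters_nm = d
        if d.ndim != 1:
            raise DomainError("diameters must be a 1-D array")
        if d.size and not np.all(d > 0.0):
            raise DomainError("all diameters must be positive")
        n = d.size
        if self.lamellarity is None:
            self.lamellarity = np.ones(n, dtype=int)
        else:
            self.lamellarity = np.asarray(self.lamellarity, dtype=int)
        if self.donor_frac is None:
            self.donor_frac = np.zeros(n)
        else:
            self.donor_frac = np.asarray(self.donor_frac, dtype=float)
        if self.acceptor_frac is None:
            self.acceptor_frac = np.zeros(n)
        else:
            self.acceptor_frac = np.asarray(self.acceptor_frac, dtype=float)
        for arr, name in ((self.lamellarity, "lamellarity"),
                          (self.donor_frac, "donor_frac"),
                          (self.acceptor_frac, "acceptor_frac")):
            if arr.shape != d.shape:
                raise DomainError(f"{name} length must match diameters")
        if np.any(self.lamellarity < 1):
            raise DomainError("lamellarity must be >= 1")

    def __len__(self) -> int:
        return self.diameters_nm.size

    @property
    def labels(self) -> np.ndarray:
        """Categorical label per vesicle: donor, acceptor, dual or none."""
        has_d = self.donor_frac > 0.0
        has_a = self.acceptor_frac > 0.0
        out = np.full(len(self), "none", dtype=object)
        out[has_d & ~has_a] = "donor"
        out[~has_d & has_a] = "acceptor"
        out[has_d & has_a] = "dual"
        return out

    @property
    def membrane_area(self) -> np.ndarray:
        """Per-vesicle membrane area in units of nm² (∝ lamellarity·d²)."""
        return self.lamellarity * self.diameters_nm ** 2

    def number_mean_nm(self) -> float:
        if len(self) == 0:
            raise InsufficientSampleError("empty population")
        return float(self.diameters_nm.mean())


@dataclass(frozen=True)
class Histogram:
    """Binned diameter counts (uniform bins)."""

    bin_edges_nm: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_nm, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges_nm", edges)
        object.__setattr__(self, "counts", counts)
        if counts.size != edges.size - 1:
            raise DomainError("len(counts) must equal len(bin_edges) - 1")
        if not np.all(np.diff(edges) > 0):
            raise DomainError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise DomainError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_nm[:-1] + self.bin_edges_nm[1:])

    @property
    def bin_width(self) -> float:
        return float(np.mean(np.diff(self.bin_edges_nm)))

    @property
    def total_area(self) -> float:
        """Σ counts·Δbin — the area every mixture fit is constrained to."""
        return float(np.sum(self.counts * np.diff(self.bin_edges_nm)))

    def signature(self) -> tuple:
        return (self.bin_edges_nm.tobytes(), self.counts.tobytes())


@dataclass(frozen=True)
class MixtureFit:
    """One- or two-Gaussian description of a diameter histogram.

    ``components`` are (mean_nm, sd_nm, weight) triples ordered by mean;
    weights are component areas in count·nm units and sum to the
    histogram's total area by construction of the fit.
    """

    k: int
    components: tuple[tuple[float, float, float], ...]
    r_squared: float
    ss_res: float
    hist_signature: tuple = field(repr=False, default=())

    @property
    def means(self) -> tuple[float, ...]:
        return tuple(c[0] for c in self.components)


@dataclass(frozen=True)
class PopulationVerdict:
    """Homogeneity call with the two fit qualities it was based on."""

    verdict: Literal["homogeneous", "heterogeneous"]
    r_squared_one: float
    r_squared_two: float
    delta: float
    adequacy: float


@dataclass(frozen=True)
class DlsResult:
    """Intensity-weighted size summary in the style of a DLS instrument."""

    z_average_nm: float
    pdi: float

    def __post_init__(self) -> None:
        if self.z_average_nm <= 0.0 or self.pdi < 0.0:
            raise DomainError("z-average must be > 0 and PDI >= 0")


def read_diameters(path: str | Path, source: str = "") -> VesiclePopulation:
    """Read a one-column delimited diameter list with header ``diameter_nm``."""
    df = pd.read_csv(path)
    if "diameter_nm" not in df.columns:  # tab-separated fallback
        df = pd.read_csv(path, sep="\t")
    if "diameter_nm" not in df.columns:
        raise DomainError(f"{path}: expected a diameter_nm column")
    return VesiclePopulation(df["diameter_nm"].to_numpy(dtype=float), source=source or str(path))


def build_histogram(pop: VesiclePopulation, binning_rule: str | int = "fd") -> Histogram:
    """Bin a diameter sample (Freedman–Diaconis by default, uniform bins)."""
    if len(pop) < 30:
        raise InsufficientSampleError(f"need >= 30 diameters, got {len(pop)}")
    counts, edges = np.histogram(pop.diameters_nm, bins=binning_rule)
    return Histogram(edges, counts)


def _mixture_counts(centers: np.ndarray, total_area: float,
                    params: np.ndarray, k: int) -> np.ndarray:
    """Predicted bin counts of a k-component Gaussian mixture.

    Total area is fixed to the histogram's, so count conservation is built
    into the model rather than asked of the optimizer.
    """
    if k == 1:
        mu, sd = params
        areas = np.array([total_area])
        mus, sds = np.array([mu]), np.array([sd])
    else:
        mu1, sd1, mu2, sd2, w = params
        areas = total_area * np.array([w, 1.0 - w])
        mus, sds = np.array([mu1, mu2]), np.array([sd1, sd2])
    out = np.zeros_like(centers)
    for a, m, s in zip(areas, mus, sds):
        out += a / (s * _SQRT_2PI) * np.exp(-0.5 * ((centers - m) / s) ** 2)
    return out


def _fit_once(hist: Histogram, k: int, x0: np.ndarray) -> tuple[np.ndarray, float]:
    centers = hist.centers
    lo_edge, hi_edge = hist.bin_edges_nm[0], hist.bin_edges_nm[-1]
    span = hi_edge - lo_edge
    sd_lo, sd_hi = hist.bin_width / 4.0, 2.0 * span
    if k == 1:
        lb = [lo_edge - span, sd_lo]
        ub = [hi_edge + span, sd_hi]
    else:
        lb = [lo_edge - span, sd_lo, lo_edge - span, sd_lo, 1e-6]
        ub = [hi_edge + span, sd_hi, hi_edge + span, sd_hi, 1.0 - 1e-6]
    x0 = np.clip(x0, lb, ub)

    def resid(p: np.ndarray) -> np.ndarray:
        return _mixture_counts(centers, hist.total_area, p, k) - hist.counts

    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", max_nfev=2000)
    return sol.x, float(np.sum(sol.fun ** 2))


def _starts_k1(hist: Histogram) -> list[np.ndarray]:
    c, w = hist.centers, hist.counts.astype(float)
    total = w.sum()
    mu = float(np.sum(c * w) / total)
    sd = float(np.sqrt(np.sum(w * (c - mu) ** 2) / total)) or hist.bin_width
    return [np.array([mu, sd]),
            np.array([c[np.argmax(w)], max(sd / 2.0, hist.bin_width)])]


def _starts_k2(hist: Histogram, k1_params: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    c, w = hist.centers, hist.counts.astype(float)
    total = w.sum()
    mu, sd = k1_params
    starts = [np.array([mu, sd, mu + sd, sd, 0.99])]  # nested: reproduces k=1
    # k-means-style split of bin centers weighted by counts
    med = float(np.interp(0.5, np.cumsum(w) / total, c))
    lo, hi = c <= med, c > med
    for mask_pair in ((lo, hi),):
        m_lo, m_hi = mask_pair
        if w[m_lo].sum() > 0 and w[m_hi].sum() > 0:
            mu1 = float(np.sum(c[m_lo] * w[m_lo]) / w[m_lo].sum())
            mu2 = float(np.sum(c[m_hi] * w[m_hi]) / w[m_hi].sum())
            s1 = float(np.sqrt(np.sum(w[m_lo] * (c[m_lo] - mu1) ** 2) / w[m_lo].sum())) or hist.bin_width
            s2 = float(np.sqrt(np.sum(w[m_hi] * (c[m_hi] - mu2) ** 2) / w[m_hi].sum())) or hist.bin_width
            frac = float(w[m_lo].sum() / total)
            starts.append(np.array([mu1, s1, mu2, s2, min(max(frac, 0.05), 0.95)]))
    span = c[-1] - c[0]
    while len(starts) < 10:
        mus = np.sort(rng.uniform(c[0], c[-1], size=2))
        starts.append(np.array([mus[0], span / rng.uniform(4, 12),
                                mus[1], span / rng.uniform(4, 12),
                                rng.uniform(0.2, 0.8)]))
    return starts


def fit_gaussian_mixture(hist: Histogram, k: int, seed: int = 0) -> MixtureFit:
    """Nonlinear least-squares fit of k Gaussian components to bin counts.

    Uses multistart initialisation (moment start, count-weighted split of
    the bin centers, nested k=1 solution, random restarts; best of 10 by
    residual sum of squares).  R² is computed on the bin counts.  The
    nested initialisation guarantees SS_res(k=2) ≤ SS_res(k=1) on the same
    histogram.
    """
    if k not in (1, 2):
        raise DomainError("k must be 1 or 2")
    occupied = int(np.count_nonzero(hist.counts))
    if k == 1 and occupied < 6:
        raise InsufficientSampleError("need >= 6 occupied bins for a 1-component fit")
    if k == 2 and occupied < 10:
        raise InsufficientSampleError("need >= 10 occupied bins for a 2-component fit")
    rng = np.random.default_rng(seed)

    best: tuple[np.ndarray, float] | None = None
    k1_best: np.ndarray | None = None
    for x0 in _starts_k1(hist):
        p, ss = _fit_once(hist, 1, x0)
        if k1_best is None or ss < best_k1_ss:  # noqa: F821 — assigned below on first pass
            k1_best, best_k1_ss = p, ss
    if k == 1:
        best = (k1_best, best_k1_ss)
    else:
        for x0 in _starts_k2(hist, k1_best, rng):
            p, ss = _fit_once(hist, 2, x0)
            if best is None or ss < best[1]:
                best = (p, ss)
    if best is None or not np.all(np.isfinite(best[0])):
        raise FitFailureError(f"{k}-component fit failed to converge")

    params, ss_res = best
    y = hist.counts.astype(float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if k == 1:
        comps = [(float(params[0]), float(params[1]), hist.total_area)]
    else:
        mu1, sd1, mu2, sd2, w = params
        comps = [(float(mu1), float(sd1), float(w) * hist.total_area),
                 (float(mu2), float(sd2), (1.0 - float(w)) * hist.total_area)]
        comps.sort(key=lambda c: c[0])
    return MixtureFit(k=k, components=tuple(comps), r_squared=r2, ss_res=ss_res,
                      hist_signature=hist.signature())


def classify_population(
    fit1: MixtureFit,
    fit2: MixtureFit,
    delta: float = 0.02,
    adequacy: float = 0.98,
) -> PopulationVerdict:
    """Homogeneity verdict from the paired 1- and 2-component fit qualities.

    Heterogeneous iff the two-component fit improves R² by more than
    ``delta`` **and** the one-component fit is below the ``adequacy``
    threshold; otherwise homogeneous.
    """
    if fit1.k != 1 or fit2.k != 2:
        raise ConfigurationError("expected a k=1 fit and a k=2 fit, in that order")
    if fit1.hist_signature and fit2.hist_signature and fit1.hist_signature != fit2.hist_signature:
        raise ConfigurationError("fits were computed on different histograms")
    heterogeneous = (fit2.r_squared - fit1.r_squared > delta) and (fit1.r_squared < adequacy)
    return PopulationVerdict(
        verdict="heterogeneous" if heterogeneous else "homogeneous",
        r_squared_one=fit1.r_squared,
        r_squared_two=fit2.r_squared,
        delta=delta,
        adequacy=adequacy,
    )


def classify_histogram(hist: Histogram, delta: float = 0.02, adequacy: float = 0.98,
                       seed: int = 0) -> tuple[PopulationVerdict, MixtureFit, MixtureFit]:
    """Convenience wrapper: fit k=1 and k=2 on one histogram and classify."""
    fit1 = fit_gaussian_mixture(hist, 1, seed=seed)
    fit2 = fit_gaussian_mixture(hist, 2, seed=seed)
    return classify_population(fit1, fit2, delta=delta, adequacy=adequacy), fit1, fit2


def dls_summary(pop: VesiclePopulation) -> DlsResult:
    """Rayleigh-weighted (d⁶) size summary emulating a DLS instrument report.

    z_average = Σ w·d / Σ w with w ∝ d⁶; PDI is the intensity-weighted
    relative variance, zero for a monodisperse sample.
    """
    if len(pop) < 30:
        raise InsufficientSampleError(f"need >= 30 diameters, got {len(pop)}")
    d = pop.diameters_nm
    w = (d / d.max()) ** 6  # normalised to avoid overflow at large d in nm⁶
    z = float(np.sum(w * d) / np.sum(w))
    var = float(np.sum(w * (d - z) ** 2) / np.sum(w))
    return DlsResult(z_average_nm=z, pdi=var / (z * z))


def compare_dls_tem(dls: DlsResult, tem_mean_nm: float,
                    flag_ratio: float = 1.15) -> dict:
    """Discrepancy report between a DLS z-average and a microscopy number mean.

    A ratio above ``flag_ratio`` flags the kind of intensity-weighting
    bias expected when a nominally homogeneous sample hides a second, larger
    population.
    """
    if tem_mean_nm <= 0.0:
        raise DomainError("TEM mean must be > 0")
    ratio = dls.z_average_nm / tem_mean_nm
    return {
        "dls_z_average_nm": dls.z_average_nm,
        "tem_mean_nm": tem_mean_nm,
        "ratio": ratio,
        "difference_nm": dls.z_average_nm - tem_mean_nm,
        "flagged": ratio > flag_ratio,
    }
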