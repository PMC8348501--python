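# Methods

This note records the models, parameter choices and known limitations of
the package, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic tests do and do not establish
about real data.

## Extruder geometry, flux and pore tension

All internal quantities are SI; converters render the laboratory units
(mL·min⁻¹·cm⁻² for flux, nm for diameters, N for forces).

The volumetric flux is purely kinematic, `J_V = R_S² v_p / R_F²`. The
force → pressure conversion uses the piston cross-section,
`ΔP = F / (π R_S²)`. This is a deliberate modelling choice: seal friction
and other device losses are not modelled mechanistically but subtracted as
a scalar baseline measured in a no-lipid control run. The default syringe
radius (4.85 mm) is the scale of a 2.5 mL laboratory syringe; it is a
configuration value, not a measured constant, and should be set per
instrument. Pore length and pore count are carried in the geometry for
provenance but enter no formula — the pressure–tension relation
`ΔP ≈ 2 σ_m / R_p` reduces the pore geometry to its radius. Pore size is
configured per run rather than fixed, since nominally identical
protocols are run with 0.05–0.2 µm filters.

## Force-trace analysis

A multi-cycle trace is segmented by thresholding a running-median-smoothed
copy of the force (default window 0.5 s): a cycle is a maximal
supra-threshold run lasting at least `min_duration_s` (default 0.5 s),
with sub-threshold dips shorter than `merge_gap_s` (default 1 s) merged.
The median filter suppresses isolated noise samples without displacing
step edges, so segment boundaries of clean traces are exact. The gap
threshold (default 1 N) must be placed between the device baseline and the
lowest plateau; with noisy traces a higher threshold (e.g. 3 N) is the
right choice and is exposed as a parameter.

The plateau of a cycle is summarized robustly: samples before the force
first reaches 90% of the segment's robust maximum (98th percentile) are
discarded as rise, and the plateau statistic is the median of the trailing
50% of what remains, with a scaled-MAD spread. Median/MAD are used instead
of mean/sd to tolerate the pressure spikes that accompany cycle starts.

Convergence of the per-cycle plateau series is declared at the first cycle
whose force differs from the previous one by less than `stable_tol`
(default 5% relative); with the default decline law this lands on cycle 6.
The decomposition reports F₁, F∞ = F(convergence), and the formation force
F₁ − F∞, both baseline-corrected and raw — whether published plateau
values include the device resistance is ambiguous in general, so both are
carried. Baseline correction subtracts a scalar; corrected values at or
below zero are clipped to 0 and flagged. The formation force is invariant
under any constant offset applied to both trace and baseline.

## Membrane mechanics

The stretching energy density `½ K_A ε²` and Helfrich bending density
`½ κ_b (C₁+C₂−C₀)² + κ_G C₁C₂` are evaluated directly; the closed-sphere
bending energy `4πR² E(1/R, 1/R)` reduces to `8πκ_b + 4πκ_G` for C₀ = 0
and is used as an analytic self-check.

Forces map to mechanical parameters by ordinary least-squares lines
through user-supplied anchor points (literature κ_b or tensile strength at
known compositions with their measured forces). Unweighted OLS is used
because the calibrations are simple linear correlations with few points;
fits carry R², residuals and parameter standard errors, and estimates
propagate the calibration covariance. Querying a calibration outside its
anchor range raises by default (flagged override available) — these lines
have no physical reason to extrapolate. The bending-rigidity calibration
uses the stabilised (deformation-only) force; tensile strength uses the
first-cycle force by default. A difference-mode (F₁ − F∞) tensile estimate
is available but carries a caveat flag: the formation-force difference has
been observed to *decrease* with cholesterol content, opposite to the
tensile-strength trend measured on giant unilamellar vesicles, so
difference-mode estimates are exploratory. κ_b is reported in joules and
in k_BT at the configured temperature (default 298.15 K), the unit
literature anchors are usually quoted in. The shipped anchor template
contains synthetic placeholder numbers and must be edited with real
literature values before scientific use.

The tensile (stretching) and bending contributions are kept as two
independent estimates; no joint functional form is imposed.

## Population analysis

Diameter samples (≥ 30) are binned with the Freedman–Diaconis rule by
default. One- and two-component Gaussian curves are fitted to the bin
counts by bounded nonlinear least squares with the **total area
constrained to the histogram area**, so count conservation is built into
the model and component weights always sum to the histogram area. The
two-component fit uses multistart initialisation (moment start,
count-weighted median split of the bin centers, the nested one-component
solution with a vanishing second component, and random restarts; best of
10 by residual sum of squares, fixed seed). The nested start guarantees
R²(k=2) ≥ R²(k=1) on every histogram.

R² is computed on bin counts (not frequency densities or CDFs), matching
how micrograph-derived size histograms are usually assessed. The
homogeneity rule is: *heterogeneous* iff the two-component fit improves R²
by more than `delta` = 0.02 **and** the one-component fit is below
`adequacy` = 0.98. The adequacy guard keeps noise-level improvements on an
already-excellent single-Gaussian fit from flipping the verdict. Applied
to published fit-quality pairs for extruded (R²₁ ≈ 0.999) versus
recalibrated (R²₁ as low as 0.34) suspensions, the rule reproduces the
expected pattern exactly.

Sensitivity: on ideal single-Gaussian samples of n = 1000 with FD binning,
Poisson bin noise leaves the one-component fit at R² ≈ 0.95–0.98, and the
two-component fit captures enough of that noise to cross the 0.02 margin
in roughly 5% of seeds. The false-heterogeneity rate of the default rule
at these conditions is therefore about 5%; the false-homogeneity rate on
entrance-split bimodal samples is 0% in 100 seeded replicates. Coarser
binning or larger samples push the false-positive rate down quickly.

The DLS emulation weights diameters by d⁶ (Rayleigh scattering
approximation for particles well below the wavelength):
`z = Σ w d / Σ w`, `PDI = Σ w (d − z)² / (Σ w z²)`. This is a moment-based
emulation of the instrument's output, not a simulation of autocorrelation
decays or a cumulant inversion. Its purpose is directional: on bimodal
samples the intensity weighting drags the z-average far above the
number-weighted microscopy mean (ratio ≈ 1.5 for the default
entrance-split recalibration), which is exactly the DLS/TEM discrepancy
pattern that flags hidden heterogeneity. A ratio above 1.15 is flagged.
No truncation correction is applied for diameters near the pore size;
distributions are fitted as observed.

## FRET mixing assay and Stewart assay

Spectra are reduced to the ratio of band-integrated acceptor (589 ± 5 nm)
to donor (531 ± 5 nm) intensity. Band integrals rather than peak heights
make the ratio robust to the sampling grid and exactly invariant under
uniform intensity rescaling. The mixing index normalises a sample ratio
between a negative control (single-labelled populations mixed without
fusing) and a positive control (dual-labelled vesicles), clipped to
[0, 1]; the verdict threshold is 0.1 of the control span, a conservative
choice for an assay whose published outcome is binary
(detected / not detected). Spontaneous inter-vesicle probe transfer is set
to zero in the forward model — both probes partition far too strongly into
the bilayer (high logP) to hop between vesicles on experimental
timescales.

The Stewart (ammonium-ferrothiocyanate) assay is a linear calibration;
concentration is recovered by inverting the line, with below-intercept
absorbances clipped to zero concentration and warned.

## Synthetic generators

The generators define the study conditions; their defaults are fixed once:

* **Force traces** — 7 cycles; first-cycle plateau 16.4 N; stabilised
  plateau 6.7 N; exponential decline constant 1.2 cycles (a single
  exponential with floor is the simplest shape matching a rapid decrease
  followed by a slower decline, saturating near cycle 6); exponential
  within-cycle rise (τ = 1.5 s) to the plateau, 30 s plateaus, 8 s
  baseline gaps, device baseline 0.5 N, Gaussian noise 0.12 N, 20 Hz
  sampling. Ground truth (per-cycle plateau levels, cycle boundaries) is
  returned alongside every trace.
* **Populations** — Gaussian-mixture diameters truncated at 20 nm
  (smaller vesicles are neither physical nor resolvable, and the floor
  keeps d⁶ weights finite); default a single 137 ± 15 nm component with
  n = 1000 vesicles, the scale of a 100 nm-pore extrusion measured by
  electron microscopy. Labels (donor/acceptor/dual/none) and lamellarity
  are assigned independently of size. Dye bookkeeping is per-vesicle area
  fractions, so label redistribution can never create dye.
* **Scenarios** — daughter diameters are Normal(g·pore, 8 nm) with
  g = 1.2 for entrance/exit budding (A/B; extruded vesicles typically
  exceed the pore diameter) and g = 0.8 with a hard cap at the pore
  diameter for in-pore budding (C). Scenario A splits each oversized
  vesicle once per pass into a daughter plus an area-conserving leftover
  (`d_left = √(d² − d_daughter²)`), labels inherited; the leftover
  re-splits only on subsequent passes. The size distribution of
  leftovers is this construction's, not a measured one. Scenarios B/C
  pool membrane area within random co-transit groups (default 10
  vesicles) and emit daughters until the pool is exhausted, mixing labels
  within each group; the sub-resolvable remainder is redistributed
  multiplicatively (< 0.1% diameter shift), so membrane area is conserved
  exactly in every scenario. Multi-cycle extrusion peels one lamella per
  pass from each multilamellar vesicle into the scenario's budding rule
  and reprocesses unilamellar vesicles larger than 1.5× the pore, which
  reproduces the saturating transmitted-lipid fraction and the declining
  mean size and polydispersity across cycles.
* **Spectra** — two unit-height Gaussian peaks (531/589 nm, width 12 nm);
  the donor peak loses the transferred amplitude fraction and the
  acceptor gains it; effective transfer efficiency is the per-vesicle
  efficiency (0.8) times the dual-labelled vesicle fraction; a constant
  5% leak from direct acceptor excitation gives the negative control its
  realistic nonzero acceptor band; additive noise 2 a.u. on a
  1000 a.u. scale.

All randomness funnels through one explicitly passed seeded generator; no
global state. Identical seeds give bit-identical outputs.

### What the synthetic tests do not show

The generators emulate the *statistical signatures* of the instrument and
assays, not their physics: there is no hydrodynamics inside the pore, no
membrane-rupture kinetics, no photophysics (Förster radius, orientation
factors, quenching), and no DLS autocorrelation inversion. Passing tests
establish that the analysis chain recovers what the forward models put in
and discriminates the mechanistic scenarios under realistic noise — they
do not validate the forward models against real instruments. Absolute R²
values of real micrograph histograms depend on image segmentation and
binning choices outside this package's scope, so published R² values are
treated as classification inputs, not as reproduction targets.

## Numerical choices and degenerate inputs

* Segmentation: median smoothing window 0.5 s; threshold crossings of the
  smoothed trace; exact on noiseless steps.
* Plateau windows with fewer than 5 samples raise instead of returning a
  meaningless statistic; traces with no supra-threshold run raise an
  empty-trace error.
* Mixture fits require ≥ 6 occupied bins (k = 1) or ≥ 10 (k = 2);
  histograms require ≥ 30 diameters; DLS summaries likewise.
* OLS on constant responses reports slope 0 with R² = 0 (no variance to
  explain); fewer than two distinct abscissae raise a rank-deficiency
  error.
* Two-anchor calibrations interpolate exactly and report zero parameter
  standard errors (no residual degrees of freedom).
* A never-converging cycle series returns the last cycle flagged
  non-converged rather than raising.
* Problem sizes in the test suite and acceptance script (100 seeded
  replicates for rate estimates, n = 1000 populations, 200 plateau
  segments) were chosen as the smallest sizes at which the rates and
  recovery tolerances are statistically meaningful.
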