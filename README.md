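# extrumech

Quantitative analysis of **liposome extrusion** experiments: from raw
extrusion force–time traces, vesicle diameter lists and donor-excited
emission spectra to lipid-bilayer mechanical parameters, population
homogeneity verdicts and lipid-mixing verdicts.

## Who this is for

Extrusion — forcing a lipid suspension through cylindrical nanopores in a
polycarbonate filter — is the standard way to produce size-controlled
unilamellar liposomes (LUVs). An instrumented extruder that holds the
volumetric flux constant while recording the piston force turns this
routine preparation step into a measurement: the force needed to sustain
flow carries information about the mechanics of the bilayer being pushed
through the pores. This package implements the analysis chain for such
measurements, plus seeded synthetic generators that emulate the instrument
and the accompanying assays, so the whole pipeline runs and is testable
without external data.

## The model in brief

**Flux and tension.** The volumetric flux across the filter follows from
piston kinematics, `J_V = R_S² v_p / R_F²` (syringe radius R_S, filter
radius R_F, piston speed v_p). The transmembrane pressure difference
relates to the effective lateral tension of a bilayer spanning a pore of
radius R_p by the Laplace-type relation `ΔP ≈ 2 σ_m / R_p`.

**Bilayer energetics.** Stretching costs
`E_exp = ½ K_A ((A − A₀)/A₀)²` per unit area (area compression modulus
K_A); bending follows the Helfrich form
`E_bend = ½ κ_b (C₁ + C₂ − C₀)² + κ_G C₁C₂` (bending rigidity κ_b,
Gaussian modulus κ_G, spontaneous curvature C₀). For a closed sphere with
C₀ = 0 the integrated bending energy is the scale-invariant
`8π κ_b + 4π κ_G`.

**Force decomposition.** Across repeated extrusion cycles the plateau
force declines from a first-cycle value F₁ (multilamellar vesicles must be
ruptured *and* deformed) to a stabilised value F∞ around the sixth cycle
(only deformation remains). The difference F₁ − F∞ is the irreversible
vesicle-*formation* contribution; F∞ tracks the bending rigidity, F₁ (or
the difference) the tensile strength, each via a linear calibration
against literature anchor values.

**Population and mixing discriminants.** Three mechanistic scenarios for
vesicle formation at a pore make distinct, testable predictions when a
preformed LUV suspension is *recalibrated* through smaller pores:
entrance splitting (A) produces a **bimodal** size distribution with **no
lipid mixing**; pooled budding at the pore exit (B) or inside the pore (C)
produces a **unimodal** distribution with **extensive mixing**. Homogeneity
is judged by comparing one- vs two-Gaussian fits of the diameter histogram
(R² on bin counts); mixing is quantified by the NBD→rhodamine FRET
acceptor/donor band ratio normalised between negative and positive
controls.

## Worked example

```bash
extrumech run --seed 0 --out report.json
```

runs the full synthetic pipeline. Key numbers from the report (seed 0):

```
per-cycle force (baseline-corrected, N):
  [16.40, 10.92, 8.55, 7.49, 7.03, 6.85, 6.77]
decomposition:
  first_cycle_force_N   16.40
  stabilized_force_N     6.85
  formation_force_N      9.55
  convergence_cycle      6
population:
  extruded      homogeneous   (R² one/two: 0.971 / 0.982)
  recalibrated  heterogeneous (R² one/two: 0.239 / 0.996)
  DLS z-average 136.0 nm vs number mean 91.4 nm  (ratio 1.49, flagged)
fret (scenario A):
  mixing_index 0.00  ->  not_mixed
```

Reading: the 7-cycle force trace declines from 16.4 N to a stabilised
6.85 N, so ~9.6 N of the first-cycle force is spent irreversibly forming
unilamellar vesicles. The freshly extruded population is a single Gaussian
(homogeneous); after recalibration through 50 nm pores under entrance
splitting it is clearly bimodal — and because intensity-weighted light
scattering (∝ d⁶) is dominated by the larger mode, the emulated DLS
z-average (136 nm) far exceeds the microscopy-style number mean (91 nm).
No FRET develops between co-extruded donor-only and acceptor-only
vesicles, the signature that vesicles split at the pore entrance without
exchanging lipids.

The same analyses are available per stage (`extrumech trace analyze`,
`extrumech population analyze`, `extrumech fret classify`) on delimited
text files, and as plain library functions.

## Layout

```
src/extrumech/
  geometry.py     flux, force->pressure, pore pressure<->tension
  traces.py       cycle segmentation, plateau forces, decomposition
  mechanics.py    stretching/bending energies, force calibrations
  populations.py  histograms, 1/2-Gaussian fits, homogeneity, DLS
  fret.py         FRET band ratios, mixing index, Stewart assay
  synth.py        seeded generators: traces, populations, scenarios, spectra
  pipeline.py     config validation and staged end-to-end runs
  cli.py          command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
examples/         editable calibration-anchor template (placeholders)
```
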