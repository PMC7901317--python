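# Methods

## Problem and scope

Continuous-wave broadband NIRS measures light attenuation at several
source–detector separations on the tissue surface.  In the 650–900 nm
window absorption is dominated by oxy- and deoxyhaemoglobin (plus water),
so the spectral shape of the absorption coefficient carries the tissue
oxygen saturation StO2 = c_HbO2/(c_HbO2 + c_HHb).  The package implements
three published inversion strategies (BRUNO, BF, SRS), a data-quality
score for derivative slope spectra, and the synthetic forward models
needed to benchmark all three at desk scale.  Everything runs on analytic
diffusion solutions for semi-infinite (and two-layer) homogeneous media;
finite-element light transport on anatomical meshes, time-resolved
fitting, and clinical data are out of scope, so heterogeneous-mesh
benchmark numbers are reproduced only as bounds and orderings, never as
exact values.

## Conventions

* µ_a and µ_s′ in natural-log mm⁻¹; attenuation A = −log10(I/I₀) in
  optical density.  The ln 10 factors in the slope model are exactly this
  conversion.
* Water fraction WF is a fraction in [0, 1] internally; configuration
  tables and printed output use percent.
* Wavelengths in nm; grids need not be uniform.  Chromophore tables are
  resampled (linear interpolation, no extrapolation) onto the data grid,
  never the data onto the table.

## Chromophore data

`data/hb_water_extinction_synthetic.tsv` holds specific absorption of
HbO2 and HHb (mm⁻¹ µM⁻¹) and pure-water absorption (mm⁻¹) at 1 nm
spacing over 650–1000 nm.  It is a monotone-cubic (PCHIP) interpolation
through anchor values recalled from the standard published compilations
of haemoglobin molar extinction and water absorption — hence *synthetic*:
it reproduces the features the algorithms key on (the 760 nm HHb band,
the isosbestic point near 800 nm, the HbO2 rise through 800–900 nm, and
water bands near 740 and 836 nm) but is not a verbatim copy of any
measured dataset.  Because every benchmark in this package generates its
synthetic measurements from the same table it inverts with, results are
self-consistent by construction; absolute StO2 on real instrument data
would inherit whatever extinction compilation the instrument pipeline
uses.

## Forward models

**ZBC (zero boundary conditions).**  `zbc_reflectance` is the far-field
form of the ZBC dipole solution, R(ρ) = z₀ µ_eff e^(−µ_eff r)/(2π r²)
with z₀ = 1/µ_s′, r = √(ρ² + z₀²) and µ_eff = √(3 µ_a µ_s′)
(scattering-only diffusion coefficient D = 1/(3µ_s′)).  Its attenuation
gradient over the 15–30 mm window equals the analytic slope model

    ∂A/∂ρ = (1/ln 10)(√(3 µ_a µ_s′) + 2 ln(d_L/d_S)/(d_L − d_S))

to better than 1% across µ_a ∈ [0.005, 0.03] mm⁻¹ and
µ_s′ ∈ [0.5, 1.5] mm⁻¹, which makes it the natural generator for
slope-based inversions.  The full flux-form dipole solution carries an
extra 1/(µ_eff r² + r) term in the log-derivative that breaks this
asymptote by up to 8% at short separations; we deliberately use the
far-field form so that generator and slope model describe the same
physics.

**EBC (extrapolated boundary conditions).**  `ebc_reflectance` is the
standard image-dipole solution with the extrapolated boundary at
z = −z_b, z_b = 2AD, D = 1/(3(µ_a + µ_s′)), and A from the polynomial
fit to the Fresnel-integral internal reflection coefficient (default
relative refractive index n = 1.4, configurable).  The absolute EBC and
ZBC reflectances differ by a factor ≈ 2.5–3 (the image amplitude), but
on the measurement scale — optical density and especially its distance
gradient — the two agree within 8% and 2% respectively at 15–30 mm,
which is why a ZBC slope model suffices for multidistance work.

**Two-layer medium.**  `two_layer_reflectance` solves the layered
diffusion Green's function in the spatial-frequency domain (overflow-safe
closed form with the source at depth z₀ inside the top layer and an
extrapolated boundary) and inverts the Hankel transform with a fixed
composite Gauss–Legendre quadrature over s ∈ [0, 64] mm⁻¹ (panel widths
0.25–2 mm⁻¹, 48 nodes each, ≈ 10 Bessel oscillation periods per panel at
ρ = 30 mm).  Truncation is monitored with an extension band
s ∈ [64, 80] mm⁻¹ compared against the peak reflectance (tolerance
1e-5): a band-vs-pointwise-total criterion would be wrong here because
the truncation error is absolute while the reconstructed value is
exponentially smaller than the spectrum bands.  Equal layers reproduce
the homogeneous EBC closed form to ~1e-11 relative; a 60 mm top layer
matches the top-homogeneous limit to ~1e-7.  The top layer must be at
least one transport mean free path thick (else the isotropic source
would sit in the bottom layer and the solver raises).  Note the
thickness interpolation between the two homogeneous limits is not
guaranteed monotone when absorption and scattering contrasts pull in
opposite directions; it is monotone for matched scattering.

## Synthetic measurements

`simulate_multidistance` sets intensity equal to model reflectance
(I₀ = 1, arbitrary units — all algorithms are invariant to a
distance-independent scale) and adds, per replicate, uniform noise on
±1% of the per-detector spectral maximum, independently per
(distance, wavelength) pair; "maximal amplitude" is read as a bounded
distribution, with Gaussian available as an alternative reading but
uniform the default.  Draws that would make intensity non-positive are
redrawn and counted.  Noise level, the 15/20/25/30 mm geometry, the
704–911 nm 1-nm grid and the 50-replicate design are the study
conditions of the benchmark; they are fixed defaults, not tuning knobs.
The phantom generator sweeps saturation through
oxygenation–deoxygenation cycles (exponential approach, plateaus at 0
and 100%) at constant total haemoglobin, WF = 0.98 and intralipid-like
scattering (a = 1.0, b = 1.2), emulating a stirred blood–yeast liquid
phantom.

What the generator does *not* emulate: anatomical layering beyond two
homogeneous slabs, partial-volume averaging of a probe on a curved head,
CSF light channelling, instrument drift, dark noise, or wavelength
miscalibration.  Passing benchmarks therefore demonstrate correctness of
the inversions against their own model class under measurement noise,
not clinical accuracy.

## Algorithms

**Slope estimation** is an ordinary least-squares fit of A against ρ per
wavelength across all detectors (the two-detector case degenerates to a
difference quotient).  A distance-independent coupling offset leaves the
slope unchanged.

**SRS** inverts the slope model per wavelength under µ_s′ = k(1 − hλ),
h = 0.00063 mm⁻¹ nm⁻¹, giving kµ_a(λ), then solves the overdetermined
linear system over the whole grid (a generalisation of the classic
two-wavelength inversion; discrete-wavelength device emulation is
available via the `wavelengths` argument).  Wavelengths where the
pre-square bracket is negative are flagged, as are negative recovered
scaled concentrations.  Water is not modelled by default, matching the
published method; an optional third column adds it.

**BF** smooths the measured single-distance reflectance with a 5-point
moving average, differentiates twice (central differences on the native
grid; endpoints one-sided and excluded from the residual window), and
fits the EBC model pushed through the identical pipeline over
710–850 nm.  The unknown multiplicative source-coupling factor is
profiled out in closed form at every objective evaluation (clipped
positive).  First- and second-derivative SSE terms are each normalised
by the variance of the corresponding measured derivative so that both
scales contribute; the combination is configurable since the published
description fixes only that both derivatives are used.

**BRUNO** applies the same smooth-and-differentiate pipeline to the
measured attenuation slope and to the ZBC slope model over 710–900 nm
and minimises the derivative SSE over θ = (WF, c_HbO2, c_HHb, a, b).

**Bounded simplex.**  Both fits use Nelder–Mead with the sinusoidal
variable transformation x = lb + (sin y + 1)/2 · (ub − lb) (the
classic bounded-fminsearch device), tolerances 1e-6 on argument and
objective, iteration cap 2000 per free parameter, and one restart from
the best point on non-convergence.  Parameters with lb = ub are frozen
(used to pin WF at 0 for waterless media, following the published
bound-table footnote).  A concentration that lands on a bound is
flagged, not discarded.

**Identifiability.**  The slope model constrains µ_a·µ_s′ only, so the
parameter vector has an exact flat direction: scaling all concentrations
and WF by s while scaling the scattering amplitude by 1/s leaves the
objective unchanged.  StO2 and the WF:c_THb ratio are invariant along
it; absolute concentrations and absolute WF are anchored only by the
optimizer's start point and bounds, which is why recovered WF scatters
around the truth by a few percentage points even on noiseless data and
why a coupling error on the slope amplitude moves the recovered
µ_a·µ_s′ product rather than StO2.  BF does not share this degeneracy
(the reflectance shape depends on µ_a and µ_s′ separately), which is
why it recovers absolute parameters on clean data.

## Quality score

The fitted model derivative and the measured derivative are z-scored
over the fit range; squared residuals are summed over 750–770 nm (HHb
band) and 825–840 nm (water feature), multiplied, and divided by the
range (max − min) of the normalised model.  Scores below the threshold
(default 2, an operating point carried over from clinical broadband
data) mark a spectrum as suitable; the score is advisory and nothing is
auto-dropped.  On the homogeneous benchmark at 1% noise all replicates
score well below 2 (mean ≈ 0.3–0.4); the low-haemoglobin phantom
configuration (c_THb 30 µM) produces weaker spectral features and
correspondingly higher advisory scores at saturation extremes.

## Benchmark studies

* **Homogeneous accuracy** (`run_homogeneous_benchmark`): 50 noisy
  replicates of grey-matter properties; BRUNO and SRS read ZBC-generated
  multidistance attenuation, BF reads EBC-generated 30 mm reflectance,
  so each inversion faces the forward physics of its own model class.
  Summaries report the median, quartiles, the median of absolute
  per-replicate errors, and the error of the median.  The headline
  accuracy statistic is the error of the median recovery, which is how
  the published benchmark figures (0.4/4.2/9.5 pp for BRUNO/BF/SRS) are
  defined.
* **Two-layer sweep** (`run_layer_sweep`): 23 conditions (8 superficial,
  8 deep, 7 joint saturation steps over 10–90%, the non-swept layer held
  at 60%), superficial layer 4 mm thick (a neonatal scalp+skull+CSF
  surrogate), layer properties from the published two-layer design at
  constant per-layer total haemoglobin.  The recovered StO2 series is
  summarised by the multilinear regression
  StO2 = constant + x₁·Brain + x₂·ECT; a small |x₂| means little
  superficial contamination.
* **Phantom cycles** (`run_phantom_experiment`): four full cycles,
  phantom bound set (WF 97–100%, concentrations ≤ 40 µM); recovered
  series smoothed with a 5-step moving average before computing each
  algorithm's dynamic range and Spearman rank correlation (average ranks
  on ties) against the truth.

Problem sizes (50 replicates, 23 sweep conditions, 80 phantom time
points, 1 nm grid over 704–911 nm) are the package's benchmark design
throughout.

## Known limitations

* Self-consistency: benchmarks invert data generated by the package's
  own forward models; accuracy numbers measure algorithmic fidelity, not
  instrument accuracy on tissue.
* The vendored chromophore table is a synthetic reconstruction; swap in
  an instrument-specific compilation via `load_table` for real data.
* The two-layer solver requires the superficial layer to exceed one
  transport mean free path and is CW-only.
* SRS overshoot above 100% (negative recovered scaled HHb) can occur at
  full oxygenation when water absorption, unmodelled by SRS, is present;
  results are flagged rather than clipped.
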