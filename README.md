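# brunox — broadband multidistance NIRS tissue oximetry

`brunox` implements and benchmarks three algorithms that recover absolute
tissue oxygen saturation (StO2) from continuous-wave broadband
near-infrared spectra, aimed at cerebral oximetry in neonates:

* **BRUNO** (broadband multidistance oximetry) — fits the zero-boundary
  (ZBC) diffusion model of the attenuation slope,

      ∂A/∂ρ = (1/ln 10) · ( √(3 μₐ μₛ′) + 2 ln(d_L/d_S)/(d_L − d_S) ),

  to the measured multidistance slope spectrum in first spectral
  derivative space (710–900 nm), searching over the tissue parameter
  vector θ = (WF, c_HbO2, c_HHb, a, b) with a bounded Nelder–Mead
  simplex, where

      μₐ(λ)  = c_HbO2 α_HbO2(λ) + c_HHb α_HHb(λ) + WF μ_a,H2O(λ),
      μₛ′(λ) = a (λ/1000)^(−b),

  and reports StO2 = 100 · c_HbO2 / (c_HbO2 + c_HHb).
* **BF** (broadband fitting) — fits the extrapolated-boundary (EBC)
  diffusion reflectance of a semi-infinite medium to a single-distance
  spectrum in first- and second-derivative space (710–850 nm) over the
  same parameter vector.
* **SRS** (spatially resolved spectroscopy) — converts the attenuation
  slope into a scaled absorption spectrum under the linear scattering
  approximation μₛ′ = k(1 − hλ), h = 0.00063 mm⁻¹ nm⁻¹, and solves a
  linear two-chromophore system; the unknown k cancels in StO2.

The package also provides the analytic diffusion forward models (ZBC,
EBC, and a two-layer medium solved in the Hankel domain) used to
generate synthetic benchmark measurements at the standard 15/20/25/30 mm
source–detector separations, an automated data-quality score for
derivative slope spectra, and scripted benchmark studies (homogeneous
accuracy, two-layer contamination sweep, oxygenation-cycle phantom).

A synthetic 1-nm reconstruction of the HbO2/HHb/water absorption
compilations ships with the package (natural-log mm⁻¹ convention;
attenuation in base-10 optical density; WF stored as a fraction
internally, printed as percent at the I/O boundary).

## Worked example

Simulate one noisy broadband multidistance measurement of grey-matter
tissue (c_HbO2 = 55 µM, c_HHb = 29.5 µM, no water, a = 0.5 mm⁻¹,
b = 1.7; true StO2 = 65.1%) and invert it:

```python
import numpy as np
from brunox import (load_default_table, resample, TissueParams,
                    simulate_multidistance, attenuation_slope, bruno_fit,
                    srs_fit, standard_bounds)
from brunox.experiments import DEFAULT_GRID

table = load_default_table()
tissue = TissueParams(c_hbo2=55.0, c_hhb=29.5, wf=0.0, a=0.5, b=1.7)
meas = simulate_multidistance(tissue, table, DEFAULT_GRID,
                              noise_fraction=0.01, seed=1)[0]
slope = attenuation_slope(meas)
tab = resample(table, meas.wavelength)
fit = bruno_fit(slope, tab, standard_bounds("simulation", water=False))
print(f"BRUNO StO2: {fit.sto2:.1f}%  (truth 65.1%)")
print(f"converged: {fit.converged}  objective: {fit.objective:.3e}")
print(f"quality score: {fit.quality.score:.3f}  (pass: {fit.quality.passed})")
print(f"SRS StO2:   {srs_fit(slope, tab).sto2:.1f}%")
```

prints

```
BRUNO StO2: 65.9%  (truth 65.1%)
converged: True  objective: 5.408e-07
quality score: 0.278  (pass: True)
SRS StO2:   58.1%
```

BRUNO lands within a percentage point of the truth on this noisy
replicate and the quality score is far below the advisory threshold
of 2.  SRS underestimates by about 7 points: the medium's power-law
scattering decays faster with wavelength than SRS's fixed linear
approximation, which down-weights the red (HbO2-dominated) end of the
scaled absorption spectrum.

The same studies are available from the shell:

```sh
brunox simulate --model 1 --n 50 --seed 7 --out-dir spectra
brunox fit --algorithm bruno --input spectra/model1_rep000.tsv
brunox benchmark --model 1 --n 50 --seed 7
brunox sweep --seed 7
brunox phantom --cycles 4 --seed 7
```

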