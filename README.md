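# geldose

3D polymer-gel dosimetry analysis for ⁹⁰Y selective internal radiation
therapy (SIRT), stereotactic body radiation therapy (SBRT), and their
combination.

## The problem

Combining ⁹⁰Y-SIRT with an SBRT boost requires verifying the *cumulative*
3D absorbed-dose distribution, but no routine dosimeter integrates dose
across both irradiation types. A polymer gel dosimeter does: radiation
polymerizes monomers in the gel in proportion to absorbed dose, raising
the transverse MR relaxation rate R2 = 1/T2. Reading the gel out with a
multi-spin-echo MR sequence therefore yields a high-resolution 3D dose
map that can be compared against PET-based ⁹⁰Y dosimetry and the
treatment-planning-system (TPS) dose.

`geldose` implements that full analysis chain for medical physicists:

- **Relaxometry** — voxel-wise mono-exponential fits
  `S(TE) = S₀·exp(−R2·TE)` over a 16-echo train (22.5–360 ms), with
  optional first-echo exclusion, producing R2 maps (1/s).
- **Calibration** — dose–response tables from calibration vials (with
  wall-margin exclusion of the oxygen-inhibited rim), linear/quadratic
  fits of `R2(D) = R2₀ + s·D`, linear-range (saturation-onset) detection,
  AIC + F-test model comparison, and curve inversion R2 → dose.
- **MIRD dosimetry** — for ⁹⁰Y (T½ = 64.1 h, DCF = 49.77 J/GBq):
  `D = DCF · A₀/M · (1 − e^{−λT})`, decay correction, activity→dose map
  conversion with self-calibration, and PET-vs-dose-calibrator checks.
- **Dose metrics** — per-VOI statistics, cumulative DVHs, D₂/D₅₀/D₉₈,
  heterogeneity index HI = (D₂% − D₉₈%)/D₅₀%, CV = σ/μ, line profiles,
  isodose masks, dose-map summation, and a gamma index (3%/3 mm default).
- **Synthetic phantom** — a digital twin of the physical phantom (80 mm
  cylinder "liver" enclosing a 27 mm sphere "tumor") generating
  ground-truth activity/dose/R2 fields, Rician multi-echo MR series and
  PSF-blurred PET, so every stage is testable without scanner data.
- **Pipeline + CLI** — `geldose simulate | calibrate | dose-map | metrics | report`.

## Worked example

```python
import numpy as np
from geldose import phantom, pipeline
from geldose.phantom import GelResponseModel

# synthetic EBRT calibration set: 8 vials, 0-21 Gy in 3 Gy steps,
# planted sensitivity 0.380 1/s/Gy, Rician noise
model = GelResponseModel(r2_0=3.0, sensitivity=0.380, d_sat=1e6,
                         rim_mm=2.0, noise_model="gaussian",
                         noise_sigma=0.5, seed=17)
vials = phantom.make_vial_set(np.arange(0, 22, 3), model)
result = pipeline.run_calibration_workflow(vials, noise_floor=1.5)
print(f"sensitivity {result.sensitivity:.4f} 1/s/Gy, "
      f"linear range 0-{result.d_max:g} Gy")
```

prints

```
sensitivity 0.3799 1/s/Gy, linear range 0-21 Gy
```

i.e. the pipeline recovers the planted gel sensitivity to 0.03% from noisy
synthetic vials and finds no saturation within the irradiated range. The
same workflow on a ladder extending past the gel's saturation onset
(plateau planted at 16.75 Gy, doses up to 44.66 Gy) reports
`linear range 0-16.75 Gy`.

From a shell, the full synthetic workflow runs as

```bash
geldose simulate  --out run/sim --seed 1
geldose calibrate --out run/cal --seed 1
geldose report    --inputs run/sim --curve run/cal/calibration_linear.json \
                  --out run/report --seed 1
```

writing per-VOI dose tables (MRI-gel, PET-MIRD, TPS, PET+TPS), HI/CV
tables, DVHs, a line profile and gamma pass rates to `run/report/`.

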