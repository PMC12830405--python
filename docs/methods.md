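# Methods

This note documents the models, conventions and numerical choices behind
`geldose`, and what the synthetic phantom does and does not emulate.

## Coordinate and unit conventions

Volumes are axis-aligned voxel grids with 0-based indices; the physical
position of voxel `i` is `origin + i·spacing` (voxel-center convention,
mm). Echo times are stored in seconds and R2 in 1/s internally;
milliseconds appear only at the I/O boundary (sidecar files), matching
how acquisition protocols are written. Activity concentrations are
MBq/mL, densities g/mL, doses Gy. Registration is *not* performed: the
pipeline applies user-supplied rigid transforms (alignment of such phantoms is done manually
in an external viewer), and always resamples PET and TPS volumes onto the MRI grid,
which serves as the reference frame. Voxels mapping outside a moving
volume become 0 (background for dose/activity semantics) and are
counted rather than raised as errors, since the phantom sits well inside
every field of view.

## Relaxometry

The multi-spin-echo signal is modeled as a mono-exponential,
`S(TE) = S₀·exp(−R2·TE)`. Fitting is nonlinear least squares on the
exponential — a vectorized damped Gauss–Newton across voxels, solving
the 2×2 normal equations in closed form with step halving — initialized
from the ordinary log-linear regression of ln S on TE over strictly
positive signals. The log-linear start lands in the correct basin
(noiseless data converges to machine precision), while the NLS
refinement avoids the noise-variance distortion of fitting in the log
domain. Iterations stop when no voxel's residual sum of squares improves
by more than 1 part in 10¹².

Choices that matter:

- **First-echo exclusion** defaults to on (the first echo is most
  affected by B1 inhomogeneity and imperfect refocusing) but is a flag;
  neither setting is asserted correct.
- **R2 bounds** [0, 200] 1/s keep background voxels from running away;
  gel R2 values are an order of magnitude below the cap.
- **Magnitude noise floor**: echoes whose signal falls below a
  configurable floor (typically 3× the background noise sd) are
  zero-weighted, because Rician magnitude statistics bias low-signal
  tails upward (the floor of a pure-noise magnitude voxel is
  σ·√(π/2)). At least two echoes are always retained per voxel.
- Invalid voxels (all-non-positive signal, or no convergence) are set to
  0 and flagged in a companion validity mask rather than raising.

## Calibration

Per-vial dose–response points are the mean ± sd of valid R2 voxels after
eroding a wall margin (default 2 voxels, Chebyshev metric): oxygen
penetrating from walls and lids inhibits polymerization, so peripheral
voxels under-respond. Fits are **unweighted OLS** on the vial means; the
per-point sd is diagnostic only (no weighting scheme is implied by the
data model, and vial voxel counts are similar).

- **Linear-range detection** is a greedy prefix rule: starting from the
  4 lowest doses, the prefix grows while the line fitted to it predicts
  every included point within a tolerance fraction (default 5%) of the
  included response span. The rule is monotone in the tolerance and
  reproducible, replacing by-eye identification of the saturation onset.
- **Model comparison** uses AIC = n·ln(RSS/n) + 2k (k = 2 linear, 3
  quadratic) and the nested F-test with (1, n−3) degrees of freedom; the
  quadratic model is preferred only when AIC favors it *and* p < α
  (default 0.05). The AIC variant is documented rather than asserted to
  match any external value.
- **Inversion**: linear curves invert exactly; quadratic curves take the
  root on the ascending branch below the vertex (the physical response
  is monotone within the calibrated range). Voxels below baseline clamp
  to 0 Gy, voxels above the valid range clamp to its top and are flagged
  saturated; reports include saturated voxels at the clamped value with
  their count, since tumor means in practice include saturated cores.

## MIRD dosimetry for ⁹⁰Y

Defaults: half-life 64.1 h, DCF 49.77 J/GBq (decay to infinity), gel
density 1.03 g/mL (configurable per call). A finite readout horizon T
scales the dose by the cumulated-activity fraction
`AUC(T) = 1 − e^{−λT}`; the horizon is always an explicit parameter
(the default workflows use 68 h for vials and 69 h for the phantom).
MBq/mL over g/mL is numerically GBq/kg, so
`D = DCF · C/ρ · AUC(T)` with C in MBq/mL.

Only **local energy deposition** is modeled — each voxel's dose comes
from its own activity, with no beta dose-point-kernel convolution and no
bremsstrahlung photon dose. This mirrors routine clinical ⁹⁰Y voxel
dosimetry; it under-represents cross-voxel dose at sharp activity
gradients. PET self-calibration is a single global rescale making the
summed activity (concentration × voxel volume over the phantom mask)
match an independently measured total.

## Dose metrics

- **D_x%** uses descending-rank linear interpolation (the linearly
  interpolated (100−x)th percentile); a brute-force sorted-array oracle
  enforces the convention in the tests.
- **Standard deviations are population** (no Bessel correction),
  consistent with CV = σ/μ over large VOIs.
- **DVHs** are cumulative (fraction of VOI ≥ dose), with edges from 0 to
  one bin past the VOI maximum.
- **Gamma index**: per reference voxel, the minimum over evaluated
  voxels of `√((ΔD/dose_tol)² + (r/DTA)²)`, evaluated at voxel centers
  (no sub-voxel interpolation), with global normalization (reference max
  or a prescribed dose) and a low-dose cutoff (default 10%). Defaults
  3%/3 mm follow common radiotherapy QA practice; the search visits
  integer shifts in order of increasing physical distance and stops once
  the distance term alone exceeds every voxel's current best, which is
  provably identical to exhaustive search. An optional cap
  (`max_gamma_search`) bounds the search radius; pass/fail is exact for
  any cap ≥ 1, only gamma values above the cap can be overestimated. The
  pipeline caps at 2 to keep large-map comparisons fast.
- **Isodose output is a voxel level-set mask** (dose ≥ level); contours
  are a rendering concern.

## The synthetic phantom

The generator emulates the physical measurement objects: a PMMA cylinder
(inner ⌀ 80 mm, height 100 mm, 5 mm wall) of gel as "normal liver"
enclosing a 27 mm inner-⌀ gel sphere as "tumor", sphere rim 62 mm below
the lid. Default grid spacing is 2 mm (the protocol slice thickness);
geometry tests refine to 1 and 0.5 mm to check discretization
convergence.

- **Activity**: piecewise-constant per compartment (defaults 0.388 and
  0.019 MBq/mL — the default combination fill), optionally multiplied
  by a mean-one correlated lognormal field (smoothed white noise,
  default correlation length 6 mm, log-sd 0.5) emulating the colloidal,
  non-uniform behavior of ⁹⁰Y-citrate. The lognormal parameters are
  free: no quantitative heterogeneity model exists for this system, only
  the evidence that PET-dose CV far exceeds TPS-dose CV.
- **SBRT dose**: the prescription is flat over the sphere and rolls off
  outside it through a Gaussian penumbra (the 50% level sits 2.5σ
  outside the sphere surface), so the PTV mean holds the prescription to
  well under 1% for realistic penumbras; σ → 0 degenerates to the binary
  sphere.
- **Gel response truth**: `R2 = R2₀ + s·min(D, d_sat)` — a hard plateau
  at the saturation onset (default 16.75 Gy, the detected linear-range
  limit) — with an oxygen-inhibited rim of configurable thickness
  responding as dose 0. The monomer-diffusion under-response annulus
  around saturated cores is *not* modeled (described only qualitatively
  in the literature).
- **MR synthesis**: per echo `S = S₀·e^{−R2·TE}` plus Gaussian noise or
  Rician magnitude noise `√((S+n₁)² + n₂²)`; Rician is the realistic
  default, Gaussian exists for analytic tests.
- **PET synthesis**: Gaussian PSF blur (default FWHM 6 mm) conserving
  total activity, then multiplicative noise of a given CV. No
  tomographic projection/reconstruction, no decay during acquisition,
  no scanner calibration error.

Because the generator shares the analysis pipeline's forward model,
noiseless closed-loop tests are *identities* (generate → relaxometry →
calibration reproduces the planted dose map to ≤1e-6 Gy outside rim and
plateau). Passing them demonstrates internal consistency and correct
inversion arithmetic — not that real gel, with chemistry drift,
temperature sensitivity, B1 artifacts and registration error, behaves
this way. The experimental signatures the synthetic phantom *does* reproduce
are structural: saturation makes the gel-reported tumor mean fall
strictly below the PET+TPS sum, and colloidal heterogeneity makes the
PET-dose CV far exceed the TPS-dose CV.

## Problem sizes and statistical checks

Monte-Carlo sensitivity recovery runs 500 independent synthetic vial
experiments per planted slope (0.380, 0.758, 0.487 1/s/Gy) on compact
vials (16 mm ⌀ × 24 mm at 2 mm spacing) with Rician noise at 1% of the
signal amplitude — small enough to keep the full loop fast, large enough
that the mean slope estimate's Monte-Carlo error is a fraction of the 2%
acceptance band. The residual ~1% downward bias is the expected Rician
magnitude-floor effect on the highest-dose vials. Relaxometry exactness
is checked on up to 96³ voxel grids; metric oracles run exhaustively on
≤16³ volumes.

## Known limitations

- No multi-exponential or stretched-exponential relaxometry, no
  B1/stimulated-echo (EPG) correction.
- No automatic or deformable registration; transforms are inputs.
- No beta-range kernel, bremsstrahlung or annihilation-photon dose; the
  cylinder over-response reported for real gel (which records *all*
  deposited energy) is therefore outside the synthetic model.
- No gel batch-to-batch sensitivity harmonization or temporal-stability
  modeling; sensitivities are per-experiment.
- The recorded vial measurements ship as data (a CSV of dose-calibrator
  and PET readings); they are inputs to cross-checks, not quantities the
  arithmetic force-reproduces: several recorded activity→dose pairs are
  mutually inconsistent at the 2–10% level.
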