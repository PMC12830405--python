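"""Digital phantom and simulated-measurement generators.

The physical phantom the generators emulate is a gel-filled PMMA cylinder
(inner diameter 80 mm, inner height 100 mm, 5 mm walls) representing
normal liver, enclosing a 27 mm inner-diameter sphere representing a
tumor, with the sphere rim 62 mm below the lid. The generators produce:

- compartment masks (sphere, cylinder-excluding-sphere, wall, background);
- a Y-90 activity-concentration field, optionally with correlated
  lognormal heterogeneity emulating the colloidal, non-uniform behavior
  of Y-90 citrate in gel;
- an SBRT-like dose field: flat prescription over the sphere with a
  Gaussian penumbra falling off outside it;
- the gel's R2 response to a dose field: linear with a hard saturation
  plateau at ``d_sat`` and an oxygen-inhibited non-responding rim along
  gel/container boundaries;
- simulated multi-echo MR magnitude series (Gaussian or Rician noise) and
  a PET measurement (Gaussian PSF blur + multiplicative noise).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from . import mird
from .volumes import MultiEchoSeries, ScalarVolume, VOIMask, VolumeError, VoxelGrid

#: Echo times of the reference multi-spin-echo protocol: 16 echoes at
#: 22.5 ms spacing (22.5 ... 360 ms), in seconds.
DEFAULT_ECHO_TIMES_S = 0.0225 * np.arange(1, 17)


def default_phantom_grid(spacing_mm: float = 2.0) -> VoxelGrid:
    """A centered grid comfortably containing the phantom (origin at center)."""
    extent = np.array([104.0, 104.0, 124.0])  # mm; cylinder + wall + margin
    shape = tuple(int(np.ceil(e / spacing_mm)) for e in extent)
    origin = tuple(-(n - 1) * spacing_mm / 2.0 for n in shape)
    return VoxelGrid(shape, (spacing_mm,) * 3, origin)


@dataclass(frozen=True)
class PhantomSpec:
    """Cylinder-with-sphere phantom geometry (mm).

    ``sphere_center_below_lid_mm`` locates the sphere center below the
    interior top of the cylinder; the default places the sphere rim 62 mm
    below the lid (62 + radius).
    """

    cylinder_inner_diameter_mm: float = 80.0
    cylinder_inner_height_mm: float = 100.0
    wall_mm: float = 5.0
    sphere_inner_diameter_mm: float = 27.0
    sphere_center_below_lid_mm: float = 62.0 + 13.5
    grid: VoxelGrid = field(default_factory=default_phantom_grid)

    def __post_init__(self):
        r_cyl = self.cylinder_inner_diameter_mm / 2.0
        r_sph = self.sphere_inner_diameter_mm / 2.0
        if min(self.cylinder_inner_diameter_mm, self.cylinder_inner_height_mm,
               self.wall_mm, self.sphere_inner_diameter_mm) <= 0:
            raise VolumeError("all phantom dimensions must be positive")
        if r_sph >= r_cyl:
            raise VolumeError("sphere must fit strictly inside the cylinder")
        if not (r_sph < self.sphere_center_below_lid_mm <
                self.cylinder_inner_height_mm - r_sph):
            raise VolumeError("sphere must sit strictly inside the cylinder height")

    @property
    def sphere_center_mm(self) -> tuple[float, float, float]:
        # cylinder interior spans z in [-H/2, +H/2] around the grid center
        z = self.cylinder_inner_height_mm / 2.0 - self.sphere_center_below_lid_mm
        return (0.0, 0.0, z)


@dataclass(frozen=True)
class GelResponseModel:
    """Ground-truth gel dose response used to synthesize R2 and MR data.

    R2(D) = r2_0 + sensitivity * min(D, d_sat); voxels within ``rim_mm``
    of a gel/container or gel/air boundary respond as dose 0 (oxygen
    inhibition). ``s0`` is the MR signal amplitude; noise is Gaussian or
    Rician with standard deviation ``noise_sigma`` per channel.
    """

    r2_0: float = 3.0
    sensitivity: float = 0.38
    d_sat: float = 16.75
    rim_mm: float = 0.0
    s0: float = 100.0
    noise_model: str = "rician"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sensitivity <= 0 or self.d_sat <= 0:
            raise VolumeError("sensitivity and d_sat must be positive")
        if self.rim_mm < 0 or self.noise_sigma < 0:
            raise VolumeError("rim and noise sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise VolumeError("noise_model must be 'gaussian' or 'rician'")


@dataclass(frozen=True)
class ActivityFieldSpec:
    """Per-compartment Y-90 activity concentrations with optional heterogeneity.

    The defaults are the combination-phantom fill: 0.388 MBq/mL in the
    sphere and 0.019 MBq/mL in the cylinder. ``lognormal`` heterogeneity
    multiplies by a mean-one correlated lognormal field with log-domain
    standard deviation ``log_sigma`` and the stated correlation length.
    """

    sphere_conc_mbq_ml: float = 0.388
    cylinder_conc_mbq_ml: float = 0.019
    heterogeneity: str = "none"
    log_sigma: float = 0.0
    correlation_length_mm: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.sphere_conc_mbq_ml < 0 or self.cylinder_conc_mbq_ml < 0:
            raise VolumeError("activity concentrations must be >= 0")
        if self.heterogeneity not in ("none", "lognormal"):
            raise VolumeError("heterogeneity must be 'none' or 'lognormal'")
        if self.log_sigma < 0:
            raise VolumeError("log_sigma must be >= 0")
        if self.heterogeneity == "lognormal" and self.correlation_length_mm <= 0:
            raise VolumeError("correlation length must be positive")


def make_phantom_masks(spec: PhantomSpec) -> dict[str, VOIMask]:
    """Mutually exclusive compartment masks on the spec's grid.

    Returns ``sphere``, ``cylinder_excl_sphere`` (gel outside the sphere),
    ``wall`` (PMMA shell, sides/bottom/top) and ``background``.
    """
    grid = spec.grid
    ax = grid.coordinate_axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r_cyl = spec.cylinder_inner_diameter_mm / 2.0
    h = spec.cylinder_inner_height_mm
    w = spec.wall_mm
    rho = np.sqrt(X**2 + Y**2)
    interior = (rho <= r_cyl) & (np.abs(Z) <= h / 2.0)
    outer = (rho <= r_cyl + w) & (np.abs(Z) <= h / 2.0 + w)
    wall = outer & ~interior
    cx, cy, cz = spec.sphere_center_mm
    r_sph = spec.sphere_inner_diameter_mm / 2.0
    sphere = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r_sph**2
    sphere &= interior
    cyl_excl = interior & ~sphere
    background = ~outer
    return {
        "sphere": VOIMask(grid, sphere, "sphere"),
        "cylinder_excl_sphere": VOIMask(grid, cyl_excl, "cylinder_excl_sphere"),
        "wall": VOIMask(grid, wall, "wall"),
        "background": VOIMask(grid, background, "background"),
    }


def _correlated_lognormal(shape, spacing_mm, log_sigma, corr_mm, rng) -> np.ndarray:
    """Mean-one lognormal multiplier exp(G - var(G)/2), G smooth Gaussian."""
    white = rng.standard_normal(shape)
    sigma_vox = np.asarray(corr_mm) / np.asarray(spacing_mm)
    g = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = g.std()
    if sd > 0:
        g = g / sd * log_sigma
    return np.exp(g - log_sigma**2 / 2.0)


def make_activity_field(masks: dict[str, VOIMask], spec: ActivityFieldSpec) -> ScalarVolume:
    """Piecewise-constant activity field, optionally modulated by a mean-one
    correlated lognormal multiplier emulating colloidal non-uniformity."""
    grid = masks["sphere"].grid
    conc = np.zeros(grid.shape)
    conc[masks["sphere"].membership] = spec.sphere_conc_mbq_ml
    conc[masks["cylinder_excl_sphere"].membership] = spec.cylinder_conc_mbq_ml
    if spec.heterogeneity == "lognormal" and spec.log_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        mult = _correlated_lognormal(
            grid.shape, grid.spacing, spec.log_sigma, spec.correlation_length_mm, rng
        )
        conc = conc * mult
    return ScalarVolume(grid, conc, "MBq/mL")


def _signed_distance_to_sphere(grid: VoxelGrid, sphere: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the sphere surface (mm, negative inside)."""
    sp = grid.spacing
    outside = ndimage.distance_transform_edt(~sphere, sampling=sp)
    inside = ndimage.distance_transform_edt(sphere, sampling=sp)
    return outside - inside


def make_sbrt_dose(
    masks: dict[str, VOIMask],
    prescribed_gy: float = 10.0,
    penumbra_sigma_mm: float = 2.0,
) -> ScalarVolume:
    """SBRT-like dose field: flat prescription covering the sphere (PTV),
    rolling off outside it with a Gaussian penumbra.

    The 50% dose level sits ``2.5 * penumbra_sigma_mm`` outside the sphere
    surface, so the full prescription covers the PTV (sphere mean within
    1% of the prescription for penumbra well below the sphere radius). A
    zero penumbra yields the binary sphere field.
    """
    if prescribed_gy < 0:
        raise VolumeError("prescribed dose must be >= 0")
    grid = masks["sphere"].grid
    sphere = masks["sphere"].membership
    if prescribed_gy == 0:
        return ScalarVolume(grid, np.zeros(grid.shape), "Gy")
    if penumbra_sigma_mm <= 0:
        return ScalarVolume(grid, np.where(sphere, prescribed_gy, 0.0), "Gy")
    d = _signed_distance_to_sphere(grid, sphere)
    margin = 2.5 * penumbra_sigma_mm
    dose = prescribed_gy * ndtr((margin - d) / penumbra_sigma_mm)
    return ScalarVolume(grid, dose, "Gy")


def truth_dose_from_activity(
    activity: ScalarVolume,
    horizon_h: float = 69.0,
    density_g_per_ml: float = mird.GEL_DENSITY_G_PER_ML,
    spec: mird.RadionuclideSpec = mird.Y90,
) -> ScalarVolume:
    """Ground-truth absorbed dose delivered by the activity field over the
    integration horizon (local energy deposition, voxel by voxel)."""
    dose = mird.absorbed_dose_gy(activity.values, horizon_h, density_g_per_ml, spec)
    return ScalarVolume(activity.grid, dose, "Gy")


def gel_mask(masks: dict[str, VOIMask]) -> np.ndarray:
    return masks["sphere"].membership | masks["cylinder_excl_sphere"].membership


def oxygen_rim_mask(masks: dict[str, VOIMask], rim_mm: float) -> np.ndarray:
    """Gel voxels within ``rim_mm`` of any gel/container or gel/air boundary."""
    gel = gel_mask(masks)
    if rim_mm <= 0:
        return np.zeros(gel.shape, bool)
    grid = masks["sphere"].grid
    dist_to_nongel = ndimage.distance_transform_edt(gel, sampling=grid.spacing)
    return gel & (dist_to_nongel <= rim_mm)


def gel_r2_truth(
    dose: ScalarVolume,
    model: GelResponseModel,
    masks: dict[str, VOIMask],
) -> ScalarVolume:
    """Ground-truth R2 response of the gel to a dose field.

    Piecewise-linear with a hard plateau: R2 = r2_0 + s * min(D, d_sat).
    Oxygen-inhibited rim voxels (within ``model.rim_mm`` of a gel
    boundary) respond as dose 0; non-gel voxels carry r2_0.
    """
    effective = np.minimum(dose.values, model.d_sat)
    rim = oxygen_rim_mask(masks, model.rim_mm)
    effective = np.where(rim, 0.0, effective)
    gel = gel_mask(masks)
    r2 = np.where(gel, model.r2_0 + model.sensitivity * effective, model.r2_0)
    return ScalarVolume(dose.grid, r2, "1/s")


def synthesize_multiecho(
    r2_truth: ScalarVolume,
    model: GelResponseModel,
    echo_times_s: np.ndarray = DEFAULT_ECHO_TIMES_S,
    signal_mask: np.ndarray | None = None,
) -> MultiEchoSeries:
    """Simulate the multi-spin-echo magnitude series of an R2 field.

    Per echo, S = s0 exp(-R2 TE) plus noise: ``gaussian`` adds N(0, sigma);
    ``rician`` returns sqrt((S + n1)^2 + n2^2) with independent N(0, sigma)
    draws, the magnitude statistics of complex MR data. ``signal_mask``
    optionally zeroes the amplitude outside the gel (air/container
    background). Deterministic under the model's seed.
    """
    te = np.asarray(echo_times_s, dtype=float)
    if np.any(np.diff(te) <= 0):
        raise VolumeError("echo times must be strictly increasing")
    rng = np.random.default_rng(model.seed)
    s0 = np.full(r2_truth.grid.shape, model.s0)
    if signal_mask is not None:
        s0 = np.where(signal_mask, model.s0, 0.0)
    echoes = []
    for t in te:
        clean = s0 * np.exp(-r2_truth.values * t)
        if model.noise_sigma > 0:
            if model.noise_model == "gaussian":
                sig = clean + rng.normal(0.0, model.noise_sigma, clean.shape)
            else:
                n1 = rng.normal(0.0, model.noise_sigma, clean.shape)
                n2 = rng.normal(0.0, model.noise_sigma, clean.shape)
                sig = np.sqrt((clean + n1) ** 2 + n2**2)
        else:
            sig = clean
        echoes.append(ScalarVolume(r2_truth.grid, sig, "a.u."))
    return MultiEchoSeries(r2_truth.grid, echoes, te)


def synthesize_pet(
    activity_truth: ScalarVolume,
    psf_fwhm_mm: float = 6.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> ScalarVolume:
    """Simulate a PET measurement: Gaussian PSF blur (partial-volume
    effect) followed by multiplicative noise of the given coefficient of
    variation. The blur conserves total activity in the interior."""
    if psf_fwhm_mm < 0 or noise_cv < 0:
        raise VolumeError("PSF width and noise CV must be >= 0")
    vals = activity_truth.values
    if psf_fwhm_mm > 0:
        sigma_vox = psf_fwhm_mm / 2.3548200450309493 / np.asarray(activity_truth.grid.spacing)
        vals = ndimage.gaussian_filter(vals, sigma=sigma_vox, mode="constant")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        vals = vals * (1.0 + noise_cv * rng.standard_normal(vals.shape))
    return ScalarVolume(activity_truth.grid, np.maximum(vals, 0.0), "MBq/mL")


# ---------------------------------------------------------------------------
# Calibration vials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VialGeometry:
    """A cylindrical calibration vial on its own small grid."""

    inner_diameter_mm: float = 24.0
    inner_height_mm: float = 40.0
    spacing_mm: float = 2.0

    def build(self) -> tuple[VoxelGrid, np.ndarray]:
        margin = 2 * self.spacing_mm
        nx = int(np.ceil((self.inner_diameter_mm + 2 * margin) / self.spacing_mm))
        nz = int(np.ceil((self.inner_height_mm + 2 * margin) / self.spacing_mm))
        shape = (nx, nx, nz)
        origin = tuple(-(n - 1) * self.spacing_mm / 2.0 for n in shape)
        grid = VoxelGrid(shape, (self.spacing_mm,) * 3, origin)
        X, Y, Z = np.meshgrid(*grid.coordinate_axes(), indexing="ij")
        interior = (
            (X**2 + Y**2 <= (self.inner_diameter_mm / 2.0) ** 2)
            & (np.abs(Z) <= self.inner_height_mm / 2.0)
        )
        return grid, interior


def make_vial_set(
    doses_gy,
    model: GelResponseModel,
    geometry: VialGeometry = VialGeometry(),
    echo_times_s: np.ndarray = DEFAULT_ECHO_TIMES_S,
) -> list[tuple[MultiEchoSeries, VOIMask, float]]:
    """One synthetic calibration vial per dose.

    Each vial carries a uniform interior dose, the model's oxygen rim and
    noise, and returns (series, interior mask, dose). Noise seeds derive
    from the model seed and the vial index, so a vial set is reproducible
    as a whole.
    """
    doses = np.asarray(doses_gy, dtype=float)
    if np.any(doses < 0):
        raise VolumeError("vial doses must be >= 0")
    grid, interior = geometry.build()
    # reuse the phantom response machinery with a vial-shaped "gel" compartment
    empty = np.zeros(grid.shape, bool)
    masks = {
        "sphere": VOIMask(grid, empty, "sphere"),
        "cylinder_excl_sphere": VOIMask(grid, interior, "vial_interior"),
        "wall": VOIMask(grid, empty, "wall"),
        "background": VOIMask(grid, ~interior, "background"),
    }
    out = []
    for k, d in enumerate(doses):
        dose_vol = ScalarVolume(grid, np.where(interior, d, 0.0), "Gy")
        r2 = gel_r2_truth(dose_vol, model, masks)
        vial_model = GelResponseModel(
            r2_0=model.r2_0, sensitivity=model.sensitivity, d_sat=model.d_sat,
            rim_mm=model.rim_mm, s0=model.s0, noise_model=model.noise_model,
            noise_sigma=model.noise_sigma, seed=int(model.seed + 7919 * k) % (2**31),
        )
        series = synthesize_multiecho(r2, vial_model, echo_times_s, signal_mask=interior)
        out.append((series, VOIMask(grid, interior.copy(), f"vial_{k}"), float(d)))
    return out
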