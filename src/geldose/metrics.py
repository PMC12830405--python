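"""Dose-distribution evaluation metrics.

Per-VOI statistics, cumulative dose-volume histograms, dose percentiles
D_x% (the dose received by at least x% of the volume), heterogeneity
index HI = (D2% - D98%)/D50%, coefficient of variation CV = sigma/mu,
line profiles, isodose level sets, dose-map summation, and the gamma
index for comparing two dose distributions.

Conventions fixed here and enforced by brute-force oracles in the tests:
- D_x% uses descending-rank linear interpolation on the sorted voxel
  doses (equivalently the (100-x)th linear-interpolated percentile).
- Standard deviations are population (no Bessel correction); VOI voxel
  counts are large.
- Gamma is evaluated at voxel centers (no sub-voxel interpolation), with
  a global dose normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import ScalarVolume, VOIMask, VolumeError, require_same_grid


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the VOI receiving at least each dose edge."""

    dose_edges: np.ndarray
    cum_volume_fraction: np.ndarray


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-index acceptance criteria.

    ``dose_tol_percent`` of the normalization dose, distance-to-agreement
    in mm, and a low-dose cutoff below which reference voxels are not
    evaluated. Defaults are the common radiotherapy QA choice of
    3%/3 mm with a 10% cutoff and global-max normalization.
    """

    dose_tol_percent: float = 3.0
    dta_mm: float = 3.0
    low_dose_cutoff_fraction: float = 0.1
    normalization: str = "global_max"
    prescribed_dose_gy: float | None = None
    #: cap the spatial search at ``max_gamma_search * dta_mm``; gamma values
    #: above the cap may be overestimated but pass/fail (gamma <= 1) stays
    #: exact for any cap >= 1. None searches until provably exhaustive.
    max_gamma_search: float | None = None

    def __post_init__(self):
        if self.dose_tol_percent <= 0 or self.dta_mm <= 0:
            raise VolumeError("gamma criteria must be strictly positive")
        if self.max_gamma_search is not None and self.max_gamma_search < 1:
            raise VolumeError("max_gamma_search must be >= 1")
        if not (0 <= self.low_dose_cutoff_fraction < 1):
            raise VolumeError("low-dose cutoff must be in [0, 1)")
        if self.normalization not in ("global_max", "prescribed"):
            raise VolumeError("normalization must be 'global_max' or 'prescribed'")


def voi_stats(dose: ScalarVolume, mask: VOIMask) -> dict:
    """Mean, population sd, min, max and voxel count over a VOI."""
    require_same_grid(dose, mask)
    if mask.voxel_count == 0:
        raise VolumeError(f"empty mask {mask.label!r}")
    v = dose.values[mask.membership]
    return {
        "mean": float(v.mean()),
        "sd": float(v.std()),
        "min": float(v.min()),
        "max": float(v.max()),
        "voxel_count": int(v.size),
    }


def dvh(dose: ScalarVolume, mask: VOIMask, bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH with edges from 0 to one bin beyond the VOI maximum."""
    require_same_grid(dose, mask)
    if bin_width_gy <= 0:
        raise VolumeError("DVH bin width must be > 0")
    if mask.voxel_count == 0:
        raise VolumeError("empty mask")
    v = dose.values[mask.membership]
    top = float(v.max())
    n_bins = int(np.ceil(top / bin_width_gy)) + 1 if top > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width_gy
    frac = (v[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(edges, frac)


def dose_percentile(dose: ScalarVolume, mask: VOIMask, x_percent: float) -> float:
    """D_x%: the dose received by at least x% of the VOI.

    Descending-rank linear interpolation: with voxel doses sorted in
    descending order d_0 >= ... >= d_{n-1}, D_x sits at fractional rank
    (x/100)(n-1). Equivalent to the linear-interpolated (100-x)th
    percentile of the dose distribution.
    """
    require_same_grid(dose, mask)
    if not (0 < x_percent < 100):
        raise VolumeError("x must be in (0, 100)")
    if mask.voxel_count == 0:
        raise VolumeError("empty mask")
    v = dose.values[mask.membership]
    return float(np.percentile(v, 100.0 - x_percent))


def heterogeneity_index(dose: ScalarVolume, mask: VOIMask) -> float:
    """HI = (D2% - D98%)/D50%; 0 for a perfectly uniform VOI."""
    d50 = dose_percentile(dose, mask, 50.0)
    if d50 <= 0:
        raise VolumeError("HI undefined: median VOI dose is not positive")
    return (dose_percentile(dose, mask, 2.0) - dose_percentile(dose, mask, 98.0)) / d50


def coefficient_of_variation(dose: ScalarVolume, mask: VOIMask) -> float:
    """CV = sigma/mu over the VOI (population sd)."""
    s = voi_stats(dose, mask)
    if s["mean"] <= 0:
        raise VolumeError("CV undefined: mean VOI dose is not positive")
    return s["sd"] / s["mean"]


def line_profile(
    dose: ScalarVolume,
    p0_mm,
    p1_mm,
    step_mm: float = 0.5,
    interpolation: str = "trilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the dose along a segment at uniform arc-length spacing.

    Returns (distance from p0 in mm, dose in Gy). Endpoints must lie
    within the voxel-center bounding box of the volume.
    """
    orders = {"nearest": 0, "trilinear": 1}
    if interpolation not in orders:
        raise VolumeError(f"interpolation must be one of {sorted(orders)}")
    if step_mm <= 0:
        raise VolumeError("step must be > 0")
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    upper = np.asarray(dose.grid.shape) - 1
    for p in (p0, p1):
        idx = dose.grid.physical_to_index(p)
        if np.any(idx < -1e-9) or np.any(idx > upper + 1e-9):
            raise VolumeError(f"profile endpoint {p} lies outside the volume")
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.floor(length / step_mm + 1e-9)), 0)
    dist = np.arange(n + 1) * step_mm
    if length > 0 and dist[-1] < length - 1e-9:
        dist = np.append(dist, length)
    pts = p0[None, :] + (dist[:, None] / length if length > 0 else 0.0) * (p1 - p0)[None, :]
    idx = dose.grid.physical_to_index(pts).T
    vals = ndimage.map_coordinates(dose.values, idx, order=orders[interpolation], mode="nearest")
    return dist, vals


def isodose_mask(dose: ScalarVolume, level_gy: float) -> VOIMask:
    """Level set of the dose map: voxels receiving at least ``level_gy``."""
    if level_gy < 0:
        raise VolumeError("isodose level must be >= 0")
    return VOIMask(dose.grid, dose.values >= level_gy, f">={level_gy:g}Gy")


def sum_dose_maps(maps: list[ScalarVolume]) -> ScalarVolume:
    """Voxelwise sum of dose maps sharing one grid."""
    if not maps:
        raise VolumeError("need at least one dose map")
    grid = require_same_grid(*maps)
    for m in maps:
        if m.unit != "Gy":
            raise VolumeError("can only sum Gy maps")
    total = np.sum([m.values for m in maps], axis=0)
    return ScalarVolume(grid, total, "Gy")


def gamma_index(
    reference: ScalarVolume,
    evaluated: ScalarVolume,
    criteria: GammaCriteria = GammaCriteria(),
) -> tuple[np.ndarray, float]:
    """Gamma map and pass rate for an evaluated dose map against a reference.

    Per reference voxel r, gamma(r) is the minimum over evaluated voxels e of

        sqrt( ((D_e - D_r)/dose_tol)^2 + (|x_e - x_r|/dta)^2 )

    with dose_tol = tol% of the normalization dose. Reference voxels below
    the low-dose cutoff are excluded (NaN in the map). The search visits
    integer voxel shifts in order of increasing physical distance and
    stops once the distance term alone exceeds every voxel's current best
    gamma, which is exact (identical to exhaustive search).
    """
    grid = require_same_grid(reference, evaluated)
    ref = reference.values
    ev = evaluated.values
    if criteria.normalization == "prescribed":
        if not criteria.prescribed_dose_gy or criteria.prescribed_dose_gy <= 0:
            raise VolumeError("prescribed normalization requires a positive dose")
        norm = float(criteria.prescribed_dose_gy)
    else:
        norm = float(ref.max())
        if norm <= 0:
            raise VolumeError("reference maximum dose is not positive")
    dose_tol = criteria.dose_tol_percent / 100.0 * norm
    dta = criteria.dta_mm
    evaluable = ref >= criteria.low_dose_cutoff_fraction * norm
    if not evaluable.any():
        raise VolumeError("no reference voxels above the low-dose cutoff")

    spacing = np.asarray(grid.spacing)
    # zero-shift term bounds the search radius
    best_sq = ((ev - ref) / dose_tol) ** 2
    r_needed = dta * np.sqrt(best_sq[evaluable].max())
    if criteria.max_gamma_search is not None:
        r_needed = min(r_needed, dta * criteria.max_gamma_search)
    max_shift = np.minimum(
        np.ceil(r_needed / spacing).astype(int), np.asarray(ref.shape) - 1
    )
    shifts = []
    for dx in range(-max_shift[0], max_shift[0] + 1):
        for dy in range(-max_shift[1], max_shift[1] + 1):
            for dz in range(-max_shift[2], max_shift[2] + 1):
                if dx == dy == dz == 0:
                    continue
                d_mm2 = ((np.array([dx, dy, dz]) * spacing) ** 2).sum()
                if d_mm2 <= r_needed**2:
                    shifts.append((d_mm2, dx, dy, dz))
    shifts.sort()

    for d_mm2, dx, dy, dz in shifts:
        dist_term = d_mm2 / dta**2
        if dist_term >= best_sq[evaluable].max():
            break
        # overlapping slices of reference and shifted evaluated volume
        src = tuple(
            slice(max(0, -d), ref.shape[a] - max(0, d)) for a, d in enumerate((dx, dy, dz))
        )
        dst = tuple(
            slice(max(0, d), ref.shape[a] + min(0, d)) for a, d in enumerate((dx, dy, dz))
        )
        cand = ((ev[src] - ref[dst]) / dose_tol) ** 2 + dist_term
        np.minimum(best_sq[dst], cand, out=best_sq[dst])

    gamma = np.sqrt(best_sq)
    gamma[~evaluable] = np.nan
    passed = gamma[evaluable] <= 1.0 + 1e-12
    pass_rate = float(100.0 * passed.mean())
    return gamma, pass_rate
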