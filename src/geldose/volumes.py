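"""Voxel-grid data model and on-disk I/O for dose/activity/R2 volumes.

Volumes are axis-aligned 3D grids with voxel-center physical coordinates:
the position of voxel index ``i`` is ``origin + i * spacing`` (mm, 0-based).
On disk, volumes are NIfTI-1 files with a JSON sidecar carrying the unit
tag, echo-time list (ms) for multi-echo series, and acquisition timestamp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Recognized physical unit tags.
UNITS = ("a.u.", "1/s", "Gy", "MBq/mL")


class VolumeError(ValueError):
    """Raised on inconsistent grids, units, or degenerate masks."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: shape (nx, ny, nz), spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise VolumeError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"grid spacing must be 3 positive numbers, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinates along each axis (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 affine mapping voxel index to mm."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def close_to(self, other: "VoxelGrid", tol_mm: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol_mm)
            and np.allclose(self.origin, other.origin, atol=tol_mm)
        )


@dataclass
class ScalarVolume:
    """One scalar physical quantity on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray
    unit: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise VolumeError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.unit not in UNITS:
            raise VolumeError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        if self.unit in ("Gy", "MBq/mL") and np.any(self.values < 0):
            raise VolumeError(f"{self.unit} volume must be non-negative everywhere")

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ScalarVolume":
        return ScalarVolume(self.grid, values, unit or self.unit)


@dataclass
class VOIMask:
    """Boolean volume-of-interest membership on a voxel grid."""

    grid: VoxelGrid
    membership: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.grid.shape:
            raise VolumeError(
                f"mask shape {self.membership.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.membership.sum())


@dataclass
class MultiEchoSeries:
    """Co-registered echo volumes of a multi-spin-echo acquisition.

    ``echo_times`` are in seconds and strictly increasing; all echoes share
    one grid. The raw magnitude images carry arbitrary units (a.u.).
    """

    grid: VoxelGrid
    echoes: list[ScalarVolume]
    echo_times: np.ndarray
    acquisition_time: str | None = None

    def __post_init__(self):
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if len(self.echoes) != len(self.echo_times):
            raise VolumeError(
                f"{len(self.echoes)} echo volumes but {len(self.echo_times)} echo times"
            )
        if len(self.echoes) < 3:
            raise VolumeError("a multi-echo series needs at least 3 echoes")
        if np.any(np.diff(self.echo_times) <= 0):
            raise VolumeError("echo times must be strictly increasing")
        for e in self.echoes:
            if not e.grid.close_to(self.grid):
                raise VolumeError("all echoes must share the series grid")

    @property
    def n_echoes(self) -> int:
        return len(self.echoes)

    def signal_array(self) -> np.ndarray:
        """Stack echoes into a (n_echoes, nx, ny, nz) array."""
        return np.stack([e.values for e in self.echoes], axis=0)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map from moving-volume physical coordinates into reference coordinates.

    ``p_ref = rotation @ p_moving + translation`` (mm).
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise VolumeError("rotation must be a 3x3 orthonormal matrix")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise VolumeError("rotation must be proper (determinant +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of physical points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix_file(cls, path) -> "RigidTransform":
        """Read a plain-text row-major 4x4 homogeneous matrix (mm)."""
        m = np.loadtxt(path).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_matrix_file(self, path) -> None:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        np.savetxt(path, m)


# ---------------------------------------------------------------------------
# NIfTI + JSON-sidecar I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> VoxelGrid:
    lin = affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
        raise VolumeError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = np.diag(lin)
    if np.any(spacing <= 0):
        raise VolumeError("NIfTI affine must have positive diagonal spacings")
    return VoxelGrid(tuple(shape[:3]), tuple(spacing), tuple(affine[:3, 3]))


def write_volume(vol: ScalarVolume, path, acquisition_time: str | None = None) -> None:
    """Write a ScalarVolume as NIfTI plus a JSON sidecar with the unit tag."""
    path = Path(path)
    img = nib.Nifti1Image(vol.values.astype(np.float64), vol.grid.affine())
    nib.save(img, str(path))
    meta = {"unit": vol.unit}
    if acquisition_time is not None:
        meta["acquisition_time"] = acquisition_time
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path, expected_unit: str | None = None) -> ScalarVolume:
    """Read a NIfTI volume; the unit comes from the sidecar or the caller.

    Raises on a missing file, a non-axis-aligned affine, an unknown unit
    tag, or a sidecar/caller unit disagreement.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise VolumeError(f"expected a 3D volume, got shape {data.shape}")
    grid = _grid_from_affine(img.affine, data.shape)
    sidecar = _sidecar_path(path)
    unit = None
    if sidecar.exists():
        unit = json.loads(sidecar.read_text()).get("unit")
    if expected_unit is not None:
        if unit is not None and unit != expected_unit:
            raise VolumeError(f"sidecar unit {unit!r} != expected {expected_unit!r}")
        unit = expected_unit
    if unit is None:
        raise VolumeError(f"no unit tag in sidecar for {path} and none provided")
    return ScalarVolume(grid, data, unit)


def write_mask(mask: VOIMask, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(mask.membership.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


def read_mask(path, label: str = "") -> VOIMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = _grid_from_affine(img.affine, data.shape)
    return VOIMask(grid, data > 0, label or path.stem)


def write_multiecho(series: MultiEchoSeries, path) -> None:
    """Write a multi-echo series as a 4D NIfTI (last axis = echo) + sidecar.

    Echo times go to the sidecar in milliseconds, the unit the protocol
    sheet uses; in memory they are seconds.
    """
    path = Path(path)
    stack = np.moveaxis(series.signal_array(), 0, -1)
    img = nib.Nifti1Image(stack.astype(np.float64), series.grid.affine())
    nib.save(img, str(path))
    meta = {"unit": "a.u.", "echo_times_ms": (series.echo_times * 1e3).tolist()}
    if series.acquisition_time is not None:
        meta["acquisition_time"] = series.acquisition_time
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_multiecho(path) -> MultiEchoSeries:
    """Read a 4D multi-echo NIfTI whose sidecar lists one echo time (ms) per echo."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise VolumeError(f"expected a 4D multi-echo volume, got shape {data.shape}")
    grid = _grid_from_affine(img.affine, data.shape)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VolumeError(f"multi-echo series {path} requires a sidecar with echo_times_ms")
    meta = json.loads(sidecar.read_text())
    te_ms = meta.get("echo_times_ms")
    if te_ms is None:
        raise VolumeError("sidecar lacks echo_times_ms")
    if len(te_ms) != data.shape[3]:
        raise VolumeError(
            f"sidecar lists {len(te_ms)} echo times but file holds {data.shape[3]} echoes"
        )
    echoes = [ScalarVolume(grid, data[..., k], "a.u.") for k in range(data.shape[3])]
    return MultiEchoSeries(
        grid, echoes, np.asarray(te_ms, dtype=float) / 1e3,
        acquisition_time=meta.get("acquisition_time"),
    )


# ---------------------------------------------------------------------------
# Geometry operations
# ---------------------------------------------------------------------------


def resample_to_reference(
    vol: ScalarVolume,
    xform: RigidTransform,
    ref: VoxelGrid,
    interpolation: str = "trilinear",
) -> tuple[ScalarVolume, int]:
    """Resample ``vol`` onto ``ref`` through a rigid transform.

    ``xform`` maps moving (``vol``) physical coordinates into reference
    coordinates. Reference voxels that map outside the moving volume are
    set to 0 (background for dose/activity semantics); the second return
    value counts them.
    """
    orders = {"nearest": 0, "trilinear": 1}
    if interpolation not in orders:
        raise VolumeError(f"interpolation must be one of {sorted(orders)}")
    if not np.all(np.isfinite(vol.values)):
        raise VolumeError("moving volume contains non-finite values")
    inv = xform.inverse()
    axes = ref.coordinate_axes()
    ref_pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)  # (nx,ny,nz,3)
    moving_pts = inv.apply(ref_pts.reshape(-1, 3))
    idx = vol.grid.physical_to_index(moving_pts).T  # (3, N)
    sampled = ndimage.map_coordinates(
        vol.values, idx, order=orders[interpolation], mode="constant", cval=np.nan
    )
    # map_coordinates' cval only covers samples fully outside; clamp the
    # outside test to the voxel-center bounding box explicitly.
    upper = np.asarray(vol.grid.shape) - 1
    outside = np.any((idx < -1e-9) | (idx > upper[:, None] + 1e-9), axis=0)
    sampled[outside | ~np.isfinite(sampled)] = 0.0
    out = ScalarVolume(ref, sampled.reshape(ref.shape), vol.unit)
    return out, int(np.count_nonzero(outside))


def erode_mask(mask: VOIMask, margin_voxels: int) -> VOIMask:
    """Shrink a mask so every retained voxel sits >= margin voxels
    (Chebyshev distance, in-plane and through-plane) from any non-mask voxel.

    The eroded mask going empty is an error: statistics on it would be
    undefined. Margin 0 is the identity.
    """
    if margin_voxels < 0:
        raise VolumeError("erosion margin must be >= 0")
    if margin_voxels == 0:
        return VOIMask(mask.grid, mask.membership.copy(), mask.label)
    eroded = ndimage.binary_erosion(
        mask.membership, structure=np.ones((3, 3, 3), bool),
        iterations=margin_voxels, border_value=0,
    )
    if not eroded.any():
        raise VolumeError(
            f"mask {mask.label!r} is empty after eroding {margin_voxels} voxels"
        )
    return VOIMask(mask.grid, eroded, mask.label)


def require_same_grid(*items) -> VoxelGrid:
    """Assert that volumes/masks share one grid and return it."""
    grid = items[0].grid
    for it in items[1:]:
        if not it.grid.close_to(grid):
            raise VolumeError("inputs do not share a common voxel grid")
    return grid
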