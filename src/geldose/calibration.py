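"""Dose-response calibration of the polymer gel.

R2 rises with absorbed dose; over the gel's working range the relation is
linear, ``R2(D) = R2_0 + s * D`` with sensitivity ``s`` (1/s/Gy) the slope
of the calibration curve. At high dose the response saturates (monomer
depletion), so calibration includes an explicit linear-range detector and
an optional quadratic model compared against the linear one by AIC and a
nested F-test.

Vial means are fitted by unweighted ordinary least squares; the per-vial
standard deviations are retained for diagnostics only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import ScalarVolume, VOIMask, VolumeError, erode_mask, require_same_grid


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class DoseResponsePoint:
    """Mean +/- sd of valid R2 voxels in one calibration vial at a known dose."""

    dose_gy: float
    mean_r2: float
    sd_r2: float
    n_voxels: int

    def __post_init__(self):
        if self.dose_gy < 0 or self.sd_r2 < 0 or self.n_voxels < 1:
            raise CalibrationError(f"invalid dose-response point {self}")


@dataclass
class CalibrationCurve:
    """Fitted dose-response model R2(D) = r2_0 + sensitivity*D [+ quad*D^2].

    ``valid_range`` is (0, d_max) in Gy; inverting the curve outside it
    flags voxels as saturated.
    """

    model: str                     # "linear" or "quadratic"
    r2_0: float                    # intercept, 1/s
    sensitivity: float             # slope, 1/s/Gy
    quad: float = 0.0              # quadratic coefficient, 1/s/Gy^2 (0 for linear)
    valid_range: tuple[float, float] = (0.0, np.inf)
    fit: dict = field(default_factory=dict)

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        return self.r2_0 + self.sensitivity * dose + self.quad * dose**2

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        d["valid_range"] = tuple(d["valid_range"])
        return cls(**d)


@dataclass
class ModelComparison:
    """Linear vs quadratic response model: AIC and nested F-test."""

    aic_linear: float
    aic_quadratic: float
    f_statistic: float
    p_value: float
    preferred: str


@dataclass
class CalibrationFlags:
    """Per-voxel bookkeeping from inverting the calibration curve."""

    below_baseline: np.ndarray
    saturated: np.ndarray
    invalid: np.ndarray


def build_dose_response(
    r2_map: ScalarVolume,
    vial_masks: Sequence[tuple[VOIMask, float]],
    wall_margin_voxels: int = 2,
    validity: VOIMask | None = None,
) -> list[DoseResponsePoint]:
    """Average R2 inside each (wall-eroded) vial mask at its known dose.

    A margin of voxels next to the vial wall is excluded before averaging:
    oxygen penetrating from the walls and lid inhibits polymerization, so
    peripheral voxels under-respond. Voxels flagged invalid by the R2 fit
    are excluded when a validity mask is supplied.
    """
    points = []
    for mask, dose in vial_masks:
        require_same_grid(r2_map, mask)
        core = erode_mask(mask, wall_margin_voxels)
        sel = core.membership
        if validity is not None:
            sel = sel & validity.membership
        if not sel.any():
            raise CalibrationError(
                f"no valid voxels left in vial {mask.label!r} after wall exclusion"
            )
        vals = r2_map.values[sel]
        points.append(
            DoseResponsePoint(float(dose), float(vals.mean()), float(vals.std()), int(sel.sum()))
        )
    return sorted(points, key=lambda p: p.dose_gy)


def points_to_table(points: Iterable[DoseResponsePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.dose_gy, p.mean_r2, p.sd_r2, p.n_voxels) for p in points],
        columns=["dose_gy", "mean_r2", "sd_r2", "n_voxels"],
    )


def table_to_points(df: pd.DataFrame) -> list[DoseResponsePoint]:
    return [
        DoseResponsePoint(r.dose_gy, r.mean_r2, r.sd_r2, int(r.n_voxels))
        for r in df.itertuples()
    ]


def _design(doses: np.ndarray, model: str) -> np.ndarray:
    cols = [np.ones_like(doses), doses]
    if model == "quadratic":
        cols.append(doses**2)
    return np.column_stack(cols)


def _ols(x: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    return beta, rss


def fit_calibration(
    points: Sequence[DoseResponsePoint],
    model: str = "linear",
    d_max: float | None = None,
) -> CalibrationCurve:
    """OLS fit of mean R2 on dose (and dose^2 for the quadratic model).

    Only points with dose <= d_max enter the fit; d_max becomes the upper
    end of the curve's valid range (default: the largest fitted dose).
    """
    if model not in ("linear", "quadratic"):
        raise CalibrationError(f"unknown model {model!r}")
    pts = sorted(points, key=lambda p: p.dose_gy)
    if d_max is not None:
        pts = [p for p in pts if p.dose_gy <= d_max + 1e-12]
    k = 2 if model == "linear" else 3
    if len(pts) < k + 1:
        raise CalibrationError(f"{model} fit needs at least {k + 1} points, got {len(pts)}")
    doses = np.array([p.dose_gy for p in pts])
    y = np.array([p.mean_r2 for p in pts])
    if np.ptp(doses) == 0:
        raise CalibrationError("degenerate design: all doses equal")
    X = _design(doses, model)
    beta, rss = _ols(X, y)
    n = len(pts)
    tss = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else float("nan")
    dof = n - k
    sigma2 = rss / dof if dof > 0 else float("nan")
    try:
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov)).tolist()
    except np.linalg.LinAlgError:
        se = [float("nan")] * k
    top = float(doses.max()) if d_max is None else float(d_max)
    return CalibrationCurve(
        model=model,
        r2_0=float(beta[0]),
        sensitivity=float(beta[1]),
        quad=float(beta[2]) if model == "quadratic" else 0.0,
        valid_range=(0.0, top),
        fit={"rss": rss, "n": n, "r_squared": r_squared, "se": se},
    )


def compare_models(
    points: Sequence[DoseResponsePoint],
    d_max: float | None = None,
    alpha: float = 0.05,
) -> ModelComparison:
    """AIC and nested F-test of the quadratic term against the linear model.

    AIC = n ln(RSS/n) + 2k with k the number of regression coefficients
    (2 linear, 3 quadratic). The F statistic for the added quadratic term
    has (1, n-3) degrees of freedom. The quadratic model is preferred only
    when both the AIC favors it and the F-test is significant at ``alpha``.
    """
    pts = sorted(points, key=lambda p: p.dose_gy)
    if d_max is not None:
        pts = [p for p in pts if p.dose_gy <= d_max + 1e-12]
    n = len(pts)
    if n < 5:
        raise CalibrationError("model comparison needs at least 5 points")
    doses = np.array([p.dose_gy for p in pts])
    y = np.array([p.mean_r2 for p in pts])
    _, rss_lin = _ols(_design(doses, "linear"), y)
    _, rss_quad = _ols(_design(doses, "quadratic"), y)

    def aic(rss, k):
        return n * np.log(max(rss, 1e-300) / n) + 2 * k

    aic_l, aic_q = aic(rss_lin, 2), aic(rss_quad, 3)
    # nested OLS guarantees rss_quad <= rss_lin up to floating-point noise
    if rss_lin - rss_quad <= 1e-10 * rss_lin + 1e-25:
        f, p = 0.0, 1.0
    elif rss_quad == 0.0:
        f, p = float("inf"), 0.0
    else:
        f = (rss_lin - rss_quad) / (rss_quad / (n - 3))
        p = float(stats.f.sf(f, 1, n - 3))
    preferred = "quadratic" if (aic_q < aic_l and p < alpha) else "linear"
    return ModelComparison(float(aic_l), float(aic_q), float(f), float(p), preferred)


def detect_linear_range(
    points: Sequence[DoseResponsePoint],
    tolerance_fraction: float = 0.05,
) -> float:
    """Largest dose up to which the response is consistent with a straight line.

    Grows a prefix greedily from the 4 lowest-dose points. A prefix is
    accepted while the line fitted to it predicts every included point
    within ``tolerance_fraction`` of the included response span
    (max |residual| <= tol * (max mean_r2 - min mean_r2)). Returns the
    largest accepted dose; points beyond it are in the saturation regime.
    """
    pts = sorted(points, key=lambda p: p.dose_gy)
    if len(pts) < 4:
        raise CalibrationError("linear-range detection needs at least 4 points")
    doses = np.array([p.dose_gy for p in pts])
    y = np.array([p.mean_r2 for p in pts])

    def prefix_ok(k):
        d, r = doses[:k], y[:k]
        span = np.ptp(r)
        if span <= 0:
            raise CalibrationError("degenerate response: no slope over candidate range")
        beta, _ = _ols(_design(d, "linear"), r)
        resid = r - (beta[0] + beta[1] * d)
        return np.max(np.abs(resid)) <= tolerance_fraction * span

    if not prefix_ok(4):
        raise CalibrationError("no linear prefix satisfies the tolerance")
    k = 4
    while k < len(pts) and prefix_ok(k + 1):
        k += 1
    return float(doses[k - 1])


def apply_calibration(
    r2_map: ScalarVolume,
    curve: CalibrationCurve,
) -> tuple[ScalarVolume, CalibrationFlags]:
    """Invert the calibration curve to turn an R2 map into a dose map (Gy).

    Linear model: D = (R2 - R2_0)/s. Quadratic: the root on the ascending
    branch of the parabola (the physical response is monotone within the
    calibrated range). Voxels below baseline (R2 < R2_0) clamp to 0;
    voxels mapping above the valid range clamp to d_max and are flagged
    saturated; quadratic voxels with no real root are flagged invalid.
    """
    if curve.sensitivity <= 0:
        raise CalibrationError("calibration sensitivity must be positive")
    r2 = r2_map.values
    d_max = curve.valid_range[1]
    if curve.model == "linear" or curve.quad == 0.0:
        dose = (r2 - curve.r2_0) / curve.sensitivity
        invalid = np.zeros(r2.shape, bool)
    else:
        disc = curve.sensitivity**2 + 4.0 * curve.quad * (r2 - curve.r2_0)
        invalid = disc < 0
        disc_safe = np.where(invalid, 0.0, disc)
        dose = (-curve.sensitivity + np.sqrt(disc_safe)) / (2.0 * curve.quad)
        dose = np.where(invalid, 0.0, dose)
    below = (dose < 0) & ~invalid
    dose = np.where(below, 0.0, dose)
    saturated = (dose > d_max) & ~invalid
    dose = np.where(saturated, d_max, dose)
    out = ScalarVolume(r2_map.grid, dose, "Gy")
    return out, CalibrationFlags(below, saturated, invalid)
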