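"""Voxel-wise mono-exponential T2 decay fitting (R2 mapping).

The MR signal of a multi-spin-echo acquisition decays as
``S(TE) = S0 * exp(-R2 * TE)`` with R2 = 1/T2 the transverse relaxation
rate (1/s). In polymer gel dosimetry R2 increases with radiation-induced
polymerization, so the R2 map is the raw dosimetric readout.

The first echo is commonly discarded before fitting: it is the echo most
affected by B1 inhomogeneity and imperfect refocusing pulses. Both
settings are supported (``discard_first``); neither is asserted correct.

Fitting is nonlinear least squares on the exponential, initialized from
the log-linear regression of ln S on TE; the log-linear start lands in the
right basin and the NLS refinement avoids the noise bias of fitting in the
log domain. Fits are bounded to R2 in [0, 200] 1/s, a generous physical
range for gels, which keeps background voxels from running away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .volumes import MultiEchoSeries, ScalarVolume, VOIMask, VolumeError, require_same_grid

#: Upper bound on fitted R2 (1/s); physical plausibility for gel dosimeters.
R2_MAX = 200.0


@dataclass
class R2FitResult:
    """Per-voxel fit: amplitude S0 (a.u.), rate R2 (1/s), residual sum of squares."""

    s0: float
    r2: float
    rss: float
    valid: bool
    reason: str = ""
    n_echoes_used: int = 0


@dataclass
class R2MapResult:
    """R2 map plus validity mask and fit bookkeeping."""

    r2: ScalarVolume
    s0: np.ndarray
    valid: VOIMask
    n_echoes_used: int


def _loglinear(te: np.ndarray, signal: np.ndarray) -> tuple[float, float] | None:
    """OLS of ln S on TE over strictly positive signals; (s0, r2) or None."""
    pos = signal > 0
    if pos.sum() < 2:
        return None
    t, y = te[pos], np.log(signal[pos])
    slope, intercept = np.polyfit(t, y, 1)
    return float(np.exp(intercept)), float(-slope)


def fit_monoexponential(
    signal: np.ndarray,
    echo_times: np.ndarray,
    discard_first: bool = True,
    max_iter: int = 200,
) -> R2FitResult:
    """Fit S(TE) = S0 exp(-R2 TE) to one voxel's echo train.

    Parameters
    ----------
    signal : array of MR magnitudes (a.u.), one per echo.
    echo_times : strictly increasing echo times in seconds.
    discard_first : drop the earliest echo before fitting.
    """
    signal = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if signal.shape != te.shape:
        raise VolumeError("signal and echo_times must have equal length")
    if np.any(np.diff(te) <= 0):
        raise VolumeError("echo times must be strictly increasing")
    if discard_first:
        signal, te = signal[1:], te[1:]
    if len(te) < 2:
        raise VolumeError("need at least 2 usable echoes after first-echo exclusion")
    n_used = len(te)

    if np.all(signal <= 0):
        return R2FitResult(0.0, 0.0, float("nan"), False, "non-positive", n_used)

    start = _loglinear(te, signal)
    if start is None:
        return R2FitResult(0.0, 0.0, float("nan"), False, "non-positive", n_used)
    s0_init = max(start[0], 1e-12)
    r2_init = min(max(start[1], 0.0), R2_MAX)

    def model(t, s0, r2):
        return s0 * np.exp(-r2 * t)

    try:
        popt, _ = curve_fit(
            model, te, signal,
            p0=[s0_init, r2_init],
            bounds=([0.0, 0.0], [np.inf, R2_MAX]),
            maxfev=max_iter * 10,
        )
    except RuntimeError:
        return R2FitResult(0.0, 0.0, float("nan"), False, "non-convergence", n_used)
    s0, r2 = float(popt[0]), float(popt[1])
    rss = float(np.sum((model(te, s0, r2) - signal) ** 2))
    if s0 <= 0:
        return R2FitResult(s0, r2, rss, False, "non-positive", n_used)
    return R2FitResult(s0, r2, rss, True, "", n_used)


def _gauss_newton_map(te: np.ndarray, sig: np.ndarray, s0: np.ndarray, r2: np.ndarray,
                      w: np.ndarray | None = None, n_iter: int = 40, tol: float = 1e-12):
    """Damped Gauss-Newton refinement of (S0, R2) across many voxels at once.

    ``sig`` is (n_echo, n_vox); ``w`` an optional 0/1 echo weight of the
    same shape. The 2x2 normal equations are solved in closed form per
    voxel; steps that fail to reduce the residual are halved (simple
    backtracking), and R2 is clamped to [0, R2_MAX].
    """
    te = te[:, None]
    if w is None:
        w = np.ones_like(sig)

    def rss_of(s0v, r2v):
        return np.sum(w * (s0v[None] * np.exp(-r2v[None] * te) - sig) ** 2, axis=0)

    rss = rss_of(s0, r2)
    for _ in range(n_iter):
        e = np.exp(-r2[None] * te)
        pred = s0[None] * e
        res = w * (sig - pred)
        j1 = w * e                 # d pred / d s0
        j2 = w * (-te * pred)      # d pred / d r2
        a11 = np.sum(j1 * j1, axis=0)
        a12 = np.sum(j1 * j2, axis=0)
        a22 = np.sum(j2 * j2, axis=0)
        b1 = np.sum(j1 * res, axis=0)
        b2 = np.sum(j2 * res, axis=0)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, np.inf, det)
        d_s0 = (a22 * b1 - a12 * b2) / det
        d_r2 = (a11 * b2 - a12 * b1) / det
        prev_rss = rss
        step = np.ones_like(s0)
        improved = np.zeros_like(s0, dtype=bool)
        new_s0, new_r2 = s0.copy(), r2.copy()
        for _half in range(8):
            trial_s0 = np.where(improved, new_s0, np.maximum(s0 + step * d_s0, 1e-12))
            trial_r2 = np.where(improved, new_r2, np.clip(r2 + step * d_r2, 0.0, R2_MAX))
            trial_rss = rss_of(trial_s0, trial_r2)
            better = ~improved & (trial_rss < rss)
            new_s0 = np.where(better, trial_s0, new_s0)
            new_r2 = np.where(better, trial_r2, new_r2)
            rss = np.where(better, trial_rss, rss)
            improved |= better
            if improved.all():
                break
            step *= 0.5
        s0, r2 = new_s0, new_r2
        if np.all(prev_rss - rss <= tol * prev_rss + 1e-30):
            break
    return s0, r2, rss


def compute_r2_map(
    series: MultiEchoSeries,
    mask: VOIMask | None = None,
    discard_first: bool = True,
    noise_floor: float | None = None,
) -> R2MapResult:
    """Fit the mono-exponential decay in every (masked) voxel of a series.

    Invalid voxels (all-non-positive signal, or no convergence) are set to
    0 in the map and flagged false in the returned validity mask.

    ``noise_floor`` optionally zero-weights echoes whose signal falls below
    the given magnitude floor (e.g. 3x the background standard deviation),
    guarding against the Rician bias of low-signal tails.
    """
    if mask is not None:
        require_same_grid(series.echoes[0], mask)
    te = series.echo_times.copy()
    sig4d = series.signal_array()
    if discard_first:
        te, sig4d = te[1:], sig4d[1:]
    if len(te) < 2:
        raise VolumeError("need at least 2 usable echoes")

    sel = mask.membership if mask is not None else np.ones(series.grid.shape, bool)
    sig = sig4d[:, sel]  # (n_echo, n_vox)
    w = np.ones_like(sig)
    if noise_floor is not None:
        # zero-weight echoes below the magnitude floor (Rician bias guard),
        # keeping at least 2 echoes per voxel
        w = (sig >= noise_floor).astype(float)
        too_few = w.sum(axis=0) < 2
        w[:, too_few] = 1.0

    n_echo, n_vox = sig.shape
    pos = (sig > 0) & (w > 0)
    usable = pos.sum(axis=0) >= 2

    # Vectorized log-linear start over positive echoes only.
    logs = np.where(pos, np.log(np.where(pos, sig, 1.0)), 0.0)
    wp = pos.astype(float)
    n = wp.sum(axis=0)
    n_safe = np.where(n > 0, n, 1)
    st = (wp * te[:, None]).sum(axis=0) / n_safe
    sy = logs.sum(axis=0) / n_safe
    stt = (wp * (te[:, None] - st[None]) ** 2).sum(axis=0)
    sty = (wp * (te[:, None] - st[None]) * (logs - sy[None])).sum(axis=0)
    slope = np.where(stt > 0, sty / np.where(stt > 0, stt, 1.0), 0.0)
    s0 = np.where(usable, np.exp(sy - slope * st), 1.0)
    r2 = np.where(usable, np.clip(-slope, 0.0, R2_MAX), 0.0)

    s0, r2, rss = _gauss_newton_map(te, sig, np.maximum(s0, 1e-12), r2, w=w)
    valid = usable & (s0 > 0) & np.isfinite(r2)

    r2_map = np.zeros(series.grid.shape)
    s0_map = np.zeros(series.grid.shape)
    valid_map = np.zeros(series.grid.shape, bool)
    r2_map[sel] = np.where(valid, r2, 0.0)
    s0_map[sel] = np.where(valid, s0, 0.0)
    valid_map[sel] = valid
    return R2MapResult(
        r2=ScalarVolume(series.grid, r2_map, "1/s"),
        s0=s0_map,
        valid=VOIMask(series.grid, valid_map, "r2-fit-valid"),
        n_echoes_used=len(te),
    )
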