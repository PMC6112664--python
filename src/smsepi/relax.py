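"""Voxel-wise mono-exponential T2* relaxometry.

Separates multi-echo magnitude signals into S0 (the TE = 0
extrapolation, predominantly T1-weighted) and T2* via
``S(TE) = S0 * exp(-TE / T2*)``: a log-linear regression provides the
starting point, refined by Levenberg–Marquardt with an analytic
Jacobian.  Fits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "EchoSeries",
    "RelaxFitResult",
    "loglinear_init",
    "fit_monoexp",
    "fit_volume_dynamic",
    "roi_timecourse",
    "T2S_BOUNDS",
]

T2S_BOUNDS = (0.1, 2000.0)  # ms


@dataclass
class EchoSeries:
    """Multi-echo magnitude data.

    ``signals`` has shape (n_frames, n_echoes, ...spatial); ``te_list``
    in ms, ``frame_times`` in s.
    """

    te_list: np.ndarray
    signals: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.te_list = np.asarray(self.te_list, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.te_list.size < 2:
            raise ValueError("need at least two echoes")
        if np.any(np.diff(self.te_list) <= 0):
            raise ValueError("te_list must be strictly increasing")
        if self.signals.shape[1] != self.te_list.size:
            raise ValueError("signals axis 1 must match number of echoes")
        if np.any(self.signals < 0):
            raise ValueError("magnitude signals must be >= 0")


@dataclass
class RelaxFitResult:
    s0: float
    t2s: float
    residual: float
    converged: bool
    method: str  # "log-linear" | "lm"
    clipped: bool = False


def loglinear_init(te_list, signals, t2s_bounds=T2S_BOUNDS):
    """Log-linear starting estimate: OLS of ln(S) on TE.

    Non-positive signals are excluded echo-wise; with fewer than two
    usable echoes the fit fails (``ok=False``).  A non-negative slope
    (no decay) caps T2* at the upper bound.  Returns
    ``(s0, t2s, ok, capped)``.
    """
    te = np.asarray(te_list, dtype=float)
    s = np.asarray(signals, dtype=float)
    use = s > 0
    if use.sum() < 2:
        return float("nan"), float("nan"), False, False
    te_u, s_u = te[use], s[use]
    slope, intercept = np.polyfit(te_u, np.log(s_u), 1)
    s0 = float(np.exp(intercept))
    if slope >= 0:
        return s0, t2s_bounds[1], True, True
    t2s = float(-1.0 / slope)
    capped = False
    if t2s < t2s_bounds[0] or t2s > t2s_bounds[1]:
        t2s = float(np.clip(t2s, *t2s_bounds))
        capped = True
    return s0, t2s, True, capped


def _residual_and_jac(params, te, s):
    s0, t2s = params
    e = np.exp(-te / t2s)
    r = s0 * e - s
    jac = np.stack([e, s0 * e * te / t2s**2], axis=1)
    return r, jac


def fit_monoexp(te_list, signals, t2s_bounds=T2S_BOUNDS, tol: float = 1e-10,
                max_iter: int = 50) -> RelaxFitResult:
    """Levenberg–Marquardt mono-exponential fit of one voxel.

    Starts from :func:`loglinear_init`; falls back to the initializer if
    LM fails to improve the cost.  Out-of-bound optima are clipped and
    flagged.
    """
    te = np.asarray(te_list, dtype=float)
    s = np.asarray(signals, dtype=float)
    s0_i, t2s_i, ok, capped = loglinear_init(te, s, t2s_bounds)
    if not ok:
        return RelaxFitResult(float("nan"), float("nan"), float("nan"),
                              converged=False, method="log-linear")
    use = s > 0
    te_u, s_u = te[use], s[use]

    def fun(p):
        return _residual_and_jac(p, te_u, s_u)[0]

    def jac(p):
        return _residual_and_jac(p, te_u, s_u)[1]

    init_res = float(np.sum(fun([s0_i, t2s_i]) ** 2))
    try:
        sol = least_squares(fun, [s0_i, t2s_i], jac=jac, method="lm",
                            ftol=tol, xtol=tol, gtol=tol, max_nfev=10 * max_iter)
    except Exception:
        sol = None
    if sol is None or not sol.success or 2 * sol.cost > init_res + 1e-30:
        return RelaxFitResult(s0_i, t2s_i, init_res, converged=False,
                              method="log-linear", clipped=capped)
    s0, t2s = float(sol.x[0]), float(sol.x[1])
    clipped = False
    if t2s < t2s_bounds[0] or t2s > t2s_bounds[1]:
        t2s = float(np.clip(t2s, *t2s_bounds))
        clipped = True
    if s0 < 0:
        s0, clipped = 0.0, True
    res = float(np.sum((s0 * np.exp(-te_u / t2s) - s_u) ** 2))
    return RelaxFitResult(s0, t2s, res, converged=True, method="lm", clipped=clipped)


def fit_volume_dynamic(series: EchoSeries, mask: np.ndarray | None = None,
                       t2s_bounds=T2S_BOUNDS, snr_floor: float = 3.0):
    """Fit every masked voxel of every frame.

    Returns ``(s0_maps, t2s_maps, info)`` with map shape
    (n_frames, ...spatial); voxels outside the mask are NaN.  ``info``
    counts non-converged and low-SNR voxels (mean signal below
    ``snr_floor`` times the background noise estimate).
    """
    sig = series.signals
    n_frames = sig.shape[0]
    spatial = sig.shape[2:]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask shape does not match spatial grid")
    s0_maps = np.full((n_frames,) + spatial, np.nan)
    t2s_maps = np.full((n_frames,) + spatial, np.nan)
    n_fallback = 0
    coords = np.argwhere(mask)
    # background noise level from unmasked voxels (for the SNR flag)
    bg = sig[:, :, ~mask]
    noise = float(bg.mean()) if bg.size else 0.0
    n_low_snr = 0
    for fr in range(n_frames):
        for c in coords:
            voxel = sig[(fr, slice(None)) + tuple(c)]
            fit = fit_monoexp(series.te_list, voxel, t2s_bounds=t2s_bounds)
            s0_maps[(fr,) + tuple(c)] = fit.s0
            t2s_maps[(fr,) + tuple(c)] = fit.t2s
            if not fit.converged:
                n_fallback += 1
            if noise > 0 and voxel.mean() < snr_floor * noise:
                n_low_snr += 1
    info = {"n_fallback": n_fallback, "n_low_snr": n_low_snr,
            "n_fits": int(n_frames * len(coords))}
    return s0_maps, t2s_maps, info


def roi_timecourse(maps: np.ndarray, roi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise mean and standard deviation over an ROI.

    ``maps``: (n_frames, ...spatial); ``roi``: boolean spatial mask (or
    voxel index tuple array).  NaN voxels are ignored.
    """
    maps = np.asarray(maps, dtype=float)
    roi = np.asarray(roi)
    if roi.dtype != bool:
        m = np.zeros(maps.shape[1:], dtype=bool)
        m[tuple(roi.T)] = True
        roi = m
    if not roi.any():
        raise ValueError("empty ROI")
    vals = maps[:, roi]
    return np.nanmean(vals, axis=1), np.nanstd(vals, axis=1)
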