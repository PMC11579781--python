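"""Orientational autocorrelation of O-H bond vectors and correlation times.

The observable is the first-rank (P1) autocorrelation of the O->H unit
vector, C(t) = <u(t0) . u(t0+t)> averaged over all time origins and all
groups, fitted with a single exponential exp(-t/tau).  For isotropic
rotational diffusion with coefficient D_r this decays as exp(-2 D_r t),
so the fitted correlation time is 1/(2 D_r) — the e-fold time of the
decay, which is how the "time to rotate by one radian" reading is made
operational here.  Both the rank choice and the fit window are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import Trajectory, minimum_image
from .errors import GeometryError, SugarglassError

__all__ = [
    "OrientationSeries",
    "CorrelationFit",
    "oh_orientation_series",
    "autocorrelation",
    "fit_correlation_time",
]


@dataclass
class OrientationSeries:
    """Unit vectors per group per frame on a shared time grid (ps)."""

    times: np.ndarray           # (T,)
    vectors: np.ndarray         # (T, n_groups, 3), unit norm

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (T, n_groups, 3)")
        norms = np.linalg.norm(self.vectors, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("orientation vectors must be unit norm (1e-6)")


@dataclass
class CorrelationFit:
    """Exponential fit of an orientational autocorrelation function."""

    lags: np.ndarray
    c: np.ndarray
    tau: float | None           # ps; None when the fit did not converge
    fit_window: tuple[int, int]  # [lo, hi) lag-index window used
    residual_rms: float
    converged: bool


def oh_orientation_series(trajectory: Trajectory,
                          oh_groups: list[tuple[int, int]]) -> OrientationSeries:
    """Minimum-image O->H unit vectors for each (O, H) pair per frame."""
    if not oh_groups:
        raise SugarglassError("no O-H groups supplied")
    o_idx = np.asarray([o for o, _ in oh_groups])
    h_idx = np.asarray([h for _, h in oh_groups])
    out = np.empty((trajectory.n_frames, len(oh_groups), 3))
    for t, fr in enumerate(trajectory.frames):
        v = minimum_image(fr.positions[h_idx] - fr.positions[o_idx], fr.cell)
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        if np.any(norms < 1e-12):
            bad = int(np.argmin(norms))
            raise GeometryError(f"zero-length O-H bond {oh_groups[bad]} in frame {t}")
        out[t] = v / norms
    return OrientationSeries(times=trajectory.times, vectors=out)


def autocorrelation(series: OrientationSeries,
                    max_lag_fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """FFT-based C(t) over all time origins and groups; C(0) = 1 exactly.

    Requests beyond the series length are truncated with a warning.
    """
    u = series.vectors
    n_t = u.shape[0]
    if n_t < 10:
        raise SugarglassError(f"need at least 10 frames, got {n_t}")
    max_lag = int(round(max_lag_fraction * (n_t - 1)))
    if max_lag > n_t - 1:
        import warnings
        warnings.warn("max_lag beyond series length; truncating")
        max_lag = n_t - 1

    # sum_{t0} u(t0).u(t0+t), via FFT per group and component
    n_fft = 1 << int(np.ceil(np.log2(2 * n_t)))
    fu = np.fft.rfft(u, n=n_fft, axis=0)
    corr = np.fft.irfft((fu * np.conj(fu)).real.sum(axis=2), n=n_fft, axis=0)[:n_t]
    counts = n_t - np.arange(n_t)
    c = corr.mean(axis=1) / counts
    c = c[:max_lag + 1] / c[0]  # unit vectors: c[0] = 1 up to rounding
    dt = series.times[1] - series.times[0] if n_t > 1 else 1.0
    lags = np.arange(max_lag + 1) * dt
    return lags, c


def fit_correlation_time(lags: np.ndarray, c: np.ndarray,
                         floor: float = 0.05) -> CorrelationFit:
    """Fit exp(-t/tau) to C(t) over the window where C stays above ``floor``.

    The linearised log-least-squares estimate (weights C^2) seeds one
    nonlinear refinement pass.  A C(t) that never decays below 1/e within
    the window is reported as non-converged rather than raising.
    """
    lags = np.asarray(lags, float)
    c = np.asarray(c, float)
    # contiguous window from t=0 until C first drops to the floor
    below = np.flatnonzero(c <= floor)
    hi = int(below[0]) if below.size else len(c)
    window = (0, hi)
    cw, tw = c[:hi], lags[:hi]
    if hi < 3 or cw.min() > np.exp(-1.0):
        return CorrelationFit(lags=lags, c=c, tau=None, fit_window=window,
                              residual_rms=float("nan"), converged=False)
    pos = cw > 0
    # weighted linear fit of ln C = -t/tau: weights w = C^2
    w = cw[pos] ** 2
    slope = -(w * tw[pos] * np.log(cw[pos])).sum() / (w * tw[pos] ** 2).sum()
    tau0 = 1.0 / max(slope, 1e-12)
    try:
        (tau,), _ = curve_fit(lambda t, tau: np.exp(-t / tau), tw, cw,
                              p0=[tau0], maxfev=2000)
    except RuntimeError:
        tau = tau0
    resid = cw - np.exp(-tw / tau)
    return CorrelationFit(lags=lags, c=c, tau=float(tau), fit_window=window,
                          residual_rms=float(np.sqrt(np.mean(resid**2))),
                          converged=True)
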