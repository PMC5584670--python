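"""Contrast-based autofocus.

The focal plane is swept over a region of interest; the contrast-focus
score of the tracked object is recorded at each plane and a Gaussian
(amplitude * exp(-(z - peak)^2 / (2 w^2)) + offset) is least-squares
fitted to the score-versus-z samples.  The best focal distance is the
fitted peak; if the fit is rejected the argmax sample is used instead.
Sweeps are centred and bidirectional.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = ["FocusSweep", "FocusFit", "AutofocusParams", "sweep_focus",
           "fit_focus_gaussian", "autofocus_target"]


@dataclass
class FocusFit:
    amplitude: float
    peak_z: float
    width: float
    offset: float
    residual_norm: float
    accepted: bool


@dataclass
class FocusSweep:
    z_samples: np.ndarray
    scores: np.ndarray
    roi: tuple                   # (x, y, radius) um used for matching
    fit: FocusFit = None
    target_lost: bool = False
    low_confidence: bool = False
    best_z: float = None


@dataclass
class AutofocusParams:
    half_range: float = 10.0       # um
    step: float = 2.0              # um
    min_usable_points: int = 4
    max_residual_fraction: float = 0.5   # of the score range
    widen_factor: float = 2.0      # one retry with doubled half_range


def _gauss(z, a, mu, w, c):
    return a * np.exp(-(z - mu) ** 2 / (2.0 * w ** 2)) + c


def sweep_focus(acquire, roi, z_center: float, half_range: float = 10.0,
                step: float = 2.0, segment=None) -> FocusSweep:
    """Sweep the focal plane across ``z_center +- half_range``.

    ``acquire(z)`` must return a frame at plane ``z``; ``segment(frame)``
    must return ``(detections, geometry)``.  At each plane the detection
    whose centroid (in um) is nearest to the roi centre and within the roi
    radius contributes its CFS; a missing object scores 0.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    n = int(round(half_range / step))
    zs = z_center + step * np.arange(-n, n + 1)
    if zs.size < 5:
        zs = z_center + step * np.arange(-2, 3)
    x0, y0, radius = roi
    scores = np.zeros(zs.size)
    for i, z in enumerate(zs):
        frame = acquire(float(z))
        detections, geom = segment(frame)
        best = None
        for det in detections:
            if not det.cfs_usable:
                continue
            x, y = geom.pixel_to_um(det.centroid[0], det.centroid[1])
            d = float(np.hypot(x - x0, y - y0))
            if d <= radius and (best is None or d < best[0]):
                best = (d, det.cfs)
        scores[i] = best[1] if best is not None else 0.0
    sweep = FocusSweep(z_samples=zs, scores=scores, roi=tuple(roi))
    if not np.any(scores > 0):
        sweep.target_lost = True
    return sweep


def fit_focus_gaussian(sweep: FocusSweep, params: AutofocusParams = None) -> float:
    """Fit the Gaussian and return the best focal z.

    Rejects the fit (falling back to the argmax sample) when the peak lies
    outside the sweep range, the width collapses below the step, or the
    residual norm exceeds the configured fraction of the score range.
    Fewer than ``min_usable_points`` non-zero scores also falls back, with
    the low-confidence flag set.  The fit is performed in z-centred
    coordinates, so it is translation-equivariant.
    """
    params = params or AutofocusParams()
    z = np.asarray(sweep.z_samples, dtype=float)
    y = np.asarray(sweep.scores, dtype=float)
    step = float(np.min(np.diff(z))) if z.size > 1 else 1.0
    argmax_z = float(z[int(np.argmax(y))])
    usable = int(np.count_nonzero(y))
    if usable < params.min_usable_points:
        sweep.low_confidence = True
        sweep.best_z = argmax_z
        return argmax_z
    # fit the peak region only: far tails of the focus curve are not
    # Gaussian (detection cutoffs) and would bias the peak estimate
    keep = y >= y.min() + 0.15 * (y.max() - y.min())
    if keep.sum() < max(5, params.min_usable_points):
        keep = np.ones_like(keep, dtype=bool)
    zf, yf = z[keep], y[keep]
    zm = float(zf.mean())
    zc = zf - zm
    p0 = [float(yf.max() - yf.min()), float(zc[int(np.argmax(yf))]),
          2.0 * step, float(yf.min())]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_gauss, zc, yf, p0=p0, maxfev=2000)
    except RuntimeError:
        sweep.low_confidence = True
        sweep.best_z = argmax_z
        return argmax_z
    a, mu, w, c = popt
    w = abs(float(w))
    peak = float(mu) + zm
    resid = float(np.linalg.norm(yf - _gauss(zc, *popt)))
    score_range = float(yf.max() - yf.min()) or 1.0
    accepted = (z.min() <= peak <= z.max() and w >= step
                and resid <= params.max_residual_fraction * score_range
                and a > 0)
    sweep.fit = FocusFit(float(a), peak, w, float(c), resid, accepted)
    sweep.best_z = peak if accepted else argmax_z
    return sweep.best_z


def sweep_table(sweep: FocusSweep):
    """Sweep record as a DataFrame (z, cfs, fitted curve) for CSV export."""
    import pandas as pd

    fitted = np.full(sweep.z_samples.size, np.nan)
    if sweep.fit is not None:
        f = sweep.fit
        fitted = _gauss(np.asarray(sweep.z_samples, dtype=float),
                        f.amplitude, f.peak_z, f.width, f.offset)
    return pd.DataFrame({"z_um": sweep.z_samples, "cfs": sweep.scores,
                         "fitted": fitted})


def autofocus_target(track, objective, acquire, segment,
                     params: AutofocusParams = None):
    """Re-find the focal plane that maximizes the target's CFS.

    Sweeps about the track's last z; on a lost sweep, widens the range once
    (doubling) before reporting loss.  On success the virtual objective is
    moved to the fitted peak and the sweep is returned.
    """
    params = params or AutofocusParams()
    z_last = track.last_position()[2]
    roi = (track.last_position()[0], track.last_position()[1], track.search_radius)
    sweep = sweep_focus(acquire, roi, z_last, params.half_range, params.step,
                        segment=segment)
    if sweep.target_lost:
        sweep = sweep_focus(acquire, roi, z_last,
                            params.half_range * params.widen_factor,
                            params.step, segment=segment)
        if sweep.target_lost:
            return sweep
    best_z = fit_focus_gaussian(sweep, params)
    objective.move(best_z)
    return sweep
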