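"""Pupil ellipse fitting, saccade amplitude and trial filtering.

Trials from lit contexts are discarded when the maximal pupil-center
displacement during the 2 s of stimulation exceeds the mouse visual acuity
of 2 degrees — 57.6 um of arc on a 1.65 mm-radius eye.  Dark-context trials
are never filtered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

from .datatypes import PupilTrack, validate_trial_table

DEFAULT_EYE_RADIUS_MM = 1.65
DEFAULT_ACUITY_DEG = 2.0
STIM_WINDOW_S = (0.0, 2.0)  # relative to stimulus onset
UNFILTERED_CONTEXTS = ("dark",)


@dataclass
class EllipseFit:
    """Axis-aligned ellipse: center, semi-major radius, eccentricity."""

    cx: float
    cy: float
    radius: float
    eccentricity: float
    success: bool = True
    objective: float = np.nan


def _ellipse_objective(image: np.ndarray, params, grads, lam: float = 1.0,
                       softness: float = 0.05) -> float:
    """J = (mean outside - mean inside) + lam * mean outward normal gradient.

    Large J for a dark ellipse on a lighter background whose boundary sits
    on the luminance edge.  Pixel membership is softened near the boundary
    so the objective is smooth in the parameters.
    """
    cx, cy, r, ecc = params
    h, w = image.shape
    a = r
    b = r * np.sqrt(max(1.0 - ecc**2, 1e-9))
    yy, xx = np.mgrid[0:h, 0:w]
    q = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
    w_in = np.clip((1.0 + softness - q) / (2 * softness), 0.0, 1.0)
    n_in = w_in.sum()
    if n_in < 1.0 or n_in > image.size - 1.0:
        return -np.inf
    mean_in = (image * w_in).sum() / n_in
    mean_out = (image * (1.0 - w_in)).sum() / (image.size - n_in)

    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    bx = cx + a * np.cos(theta)
    by = cy + b * np.sin(theta)
    gy, gx = grads
    ix = np.clip(np.round(bx).astype(int), 0, w - 1)
    iy = np.clip(np.round(by).astype(int), 0, h - 1)
    # outward normal of an axis-aligned ellipse
    nx = np.cos(theta) / a
    ny = np.sin(theta) / b
    nn = np.hypot(nx, ny)
    grad = (gx[iy, ix] * nx + gy[iy, ix] * ny) / nn
    return (mean_out - mean_in) + lam * grad.mean()


def fit_pupil_ellipse(
    image: np.ndarray,
    init,
    bounds=None,
    lam: float = 1.0,
) -> EllipseFit:
    """Fit an axis-aligned ellipse to a dark pupil by derivative-free search.

    ``init`` is (cx, cy, radius, eccentricity).  A flat (no-contrast) image
    returns the init with ``success=False``.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    init = np.asarray(init, dtype=float)
    if np.ptp(image) < 1e-12:
        return EllipseFit(*init, success=False)

    if bounds is None:
        h, w = image.shape
        bounds = [(0, w - 1), (0, h - 1), (2.0, min(h, w) / 2), (0.0, 0.95)]

    grads = np.gradient(image)

    def neg_j(p):
        for v, (lo, hi) in zip(p, bounds):
            if not lo <= v <= hi:
                return 1e6
        return -_ellipse_objective(image, p, grads, lam)

    # restarted Nelder-Mead: a fresh simplex around the current best escapes
    # the premature shrinkage this landscape induces
    best_x = np.asarray(init, dtype=float)
    best_f = neg_j(best_x)
    steps = np.array([4.0, 4.0, 4.0, 0.15])
    for _ in range(6):
        simplex = np.vstack([best_x] + [best_x + np.eye(4)[i] * steps[i]
                                        for i in range(4)])
        res = minimize(neg_j, best_x, method="Nelder-Mead",
                       options=dict(xatol=0.02, fatol=1e-10, maxiter=4000,
                                    initial_simplex=simplex))
        if res.fun < best_f - 1e-9:
            best_x, best_f = res.x, res.fun
            steps = np.maximum(steps * 0.5, [0.5, 0.5, 0.5, 0.05])
        else:
            break
    ok = np.isfinite(best_f) and best_f < 1e6
    params = best_x if ok else init
    return EllipseFit(*params, success=bool(ok), objective=-best_f)


def saccade_amplitude(track: PupilTrack, window) -> float:
    """Max pairwise Euclidean distance between pupil centers in a time window.

    Brute-force over all sample pairs (t, t') in ``window = (t0, t1)``.
    """
    t0, t1 = window
    sel = (track.t >= t0) & (track.t <= t1)
    if sel.sum() < 2:
        raise ValueError("need at least 2 samples in window")
    pts = np.column_stack([track.x_um[sel], track.y_um[sel]])
    return float(pdist(pts).max())


def um_to_deg(d_um: float, eye_radius_mm: float = DEFAULT_EYE_RADIUS_MM) -> float:
    """Arc length on the eyeball to visual angle (degrees)."""
    if eye_radius_mm <= 0:
        raise ValueError("eye_radius_mm must be positive")
    d_um = np.asarray(d_um, dtype=float)
    if np.any(d_um < 0):
        raise ValueError("displacement must be non-negative")
    return float(d_um / (eye_radius_mm * 1000.0) * 180.0 / np.pi)


def deg_to_um(deg: float, eye_radius_mm: float = DEFAULT_EYE_RADIUS_MM) -> float:
    """Visual angle (degrees) to arc length on the eyeball (um)."""
    if eye_radius_mm <= 0:
        raise ValueError("eye_radius_mm must be positive")
    return float(deg * np.pi / 180.0 * eye_radius_mm * 1000.0)


def filter_trials(
    trials: pd.DataFrame,
    track: PupilTrack,
    frame_rate: float,
    threshold_deg: float = DEFAULT_ACUITY_DEG,
    eye_radius_mm: float = DEFAULT_EYE_RADIUS_MM,
    window_s=STIM_WINDOW_S,
):
    """Flag trials whose gaze change exceeds the acuity threshold.

    Saccade amplitude is evaluated over ``window_s`` relative to stimulus
    onset.  Trials in ``UNFILTERED_CONTEXTS`` (dark) are always kept.
    Trials without tracking coverage are marked invalid with reason
    ``no_tracking``.

    Returns ``(trials_with_flags, summary)`` where summary maps context to
    the kept fraction.
    """
    validate_trial_table(trials)
    threshold_um = deg_to_um(threshold_deg, eye_radius_mm)

    out = trials.copy()
    amps = np.full(len(out), np.nan)
    keep = np.ones(len(out), dtype=bool)
    valid = out["valid"].astype(bool).to_numpy()
    reasons = out["reason"].astype(object).to_numpy() if "reason" in out else np.full(len(out), "", dtype=object)

    t_end = track.t[-1]
    for i, (_, tr) in enumerate(out.iterrows()):
        onset_t = tr.onset_sample / frame_rate
        w = (onset_t + window_s[0], onset_t + window_s[1])
        if w[0] < track.t[0] or w[1] > t_end:
            valid[i] = False
            reasons[i] = "no_tracking"
            keep[i] = False
            continue
        amps[i] = saccade_amplitude(track, w)
        if tr.context not in UNFILTERED_CONTEXTS and amps[i] > threshold_um:
            keep[i] = False

    out["max_displacement_um"] = amps
    out["max_displacement_deg"] = [
        um_to_deg(a, eye_radius_mm) if np.isfinite(a) else np.nan for a in amps
    ]
    out["keep"] = keep
    out["valid"] = valid & keep
    out["reason"] = reasons

    summary = {
        ctx: float(sub["keep"].mean())
        for ctx, sub in out.groupby("context", sort=False)
    }
    return out, summary
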