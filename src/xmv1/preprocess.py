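"""Fluorescence preprocessing: neuropil subtraction, baseline, dF/F,
temporal deconvolution, smoothing and trial epoching.

The deconvolution inverts the indicator's exponential decay:

    r(t) = f'(t) + f(t) / tau

with f'(t) a forward difference at one-frame lag (~30 ms at 31.5 Hz) and
tau = 2 s.  Negative rate estimates are retained by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .datatypes import DeconvolvedTraces, RoiTraceSet, validate_trial_table

DEFAULT_TAU = 2.0            # s, indicator decay
DEFAULT_SMOOTH_WINDOW = 0.190  # s, sliding boxcar
DEFAULT_BASELINE_SIGMA = 1.0   # s, Gaussian prefilter for baseline
BLOCK_LEN_S = 5.0
BASELINE_NEIGHBORHOOD = 5      # blocks


def subtract_neuropil(traces: RoiTraceSet, weight: float = 0.7) -> np.ndarray:
    """F_c = F - weight * F_np, elementwise."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    return traces.F - weight * traces.F_np


def estimate_baseline(
    F_c: np.ndarray,
    frame_rate: float,
    block_len: float = BLOCK_LEN_S,
    n_blocks: int = BASELINE_NEIGHBORHOOD,
    gaussian_sigma: float = DEFAULT_BASELINE_SIGMA,
):
    """Per-ROI per-block baseline.

    For each 5 s block, the baseline is the minimum of the Gaussian-filtered
    trace over that block's ``n_blocks``-wide neighborhood (the block and its
    two neighbors on each side for n_blocks=5); edge blocks use truncated
    neighborhoods.

    Returns ``(F_c0, flagged)`` where F_c0 has shape (n_roi, n_total_blocks)
    and ``flagged`` lists ROI indices with a non-positive baseline anywhere.
    """
    F_c = np.atleast_2d(F_c)
    samples_per_block = int(round(block_len * frame_rate))
    n_total = F_c.shape[1] // samples_per_block
    if n_total < 1:
        raise ValueError("recording shorter than one block")

    smoothed = gaussian_filter1d(F_c, sigma=gaussian_sigma * frame_rate, axis=1)
    block_min = np.stack(
        [
            smoothed[:, b * samples_per_block : (b + 1) * samples_per_block].min(axis=1)
            for b in range(n_total)
        ],
        axis=1,
    )
    half = n_blocks // 2
    F_c0 = np.empty_like(block_min)
    for b in range(n_total):
        lo, hi = max(0, b - half), min(n_total, b + half + 1)
        F_c0[:, b] = block_min[:, lo:hi].min(axis=1)

    flagged = sorted(set(np.where(F_c0 <= 0)[0].tolist()))
    return F_c0, flagged


def expand_baseline(F_c0: np.ndarray, n_samples: int, frame_rate: float,
                    block_len: float = BLOCK_LEN_S) -> np.ndarray:
    """Broadcast per-block baselines to per-sample (last block padded out)."""
    samples_per_block = int(round(block_len * frame_rate))
    reps = np.repeat(F_c0, samples_per_block, axis=1)
    if reps.shape[1] < n_samples:
        pad = np.tile(reps[:, -1:], (1, n_samples - reps.shape[1]))
        reps = np.concatenate([reps, pad], axis=1)
    return reps[:, :n_samples]


def dff(F_c: np.ndarray, F_c0: np.ndarray) -> np.ndarray:
    """f = (F_c - F_c0) / F_c0. F_c0 may be per-sample or per-ROI scalar."""
    F_c0 = np.asarray(F_c0, dtype=float)
    if np.any(F_c0 <= 0):
        bad = sorted(set(np.where(np.atleast_2d(F_c0) <= 0)[0].tolist()))
        raise ValueError(f"non-positive baseline for ROI(s) {bad}")
    return (F_c - F_c0) / F_c0


def deconvolve(f: np.ndarray, tau: float = DEFAULT_TAU,
               frame_rate: float = 31.5) -> np.ndarray:
    """r = f' + f/tau, forward difference at one-frame lag.

    The last sample's derivative is set to zero (no future frame), which
    keeps constants mapping to c/tau at every sample.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    f = np.atleast_2d(f)
    dt = 1.0 / frame_rate
    fprime = np.diff(f, axis=1, append=f[:, -1:]) / dt
    return fprime + f / tau


def smooth(r: np.ndarray, window: float = DEFAULT_SMOOTH_WINDOW,
           frame_rate: float = 31.5) -> np.ndarray:
    """Centered moving average; edges renormalised over the truncated window."""
    r = np.atleast_2d(r)
    w = int(round(window * frame_rate))
    if w < 1:
        raise ValueError("window shorter than one frame")
    if w == 1:
        return r.copy()
    kernel = np.ones(w)
    norm = np.convolve(np.ones(r.shape[1]), kernel, mode="same")
    out = np.empty_like(r, dtype=float)
    for i in range(r.shape[0]):
        out[i] = np.convolve(r[i], kernel, mode="same") / norm
    return out


@dataclass
class ResponseProfiles:
    """Trial-averaged, baseline- and blank-subtracted responses.

    ``profiles[stimulus]`` is an (n_roi, block_samples) matrix; stimuli with
    zero valid trials appear in ``missing`` instead.
    """

    profiles: dict
    n_trials_used: dict
    missing: list = field(default_factory=list)
    frame_rate: float = 31.5

    def concatenate(self, stimuli=None) -> np.ndarray:
        keys = list(self.profiles) if stimuli is None else list(stimuli)
        return np.concatenate([self.profiles[k] for k in keys], axis=1)


def epoch_and_average(
    r: np.ndarray,
    trials: pd.DataFrame,
    frame_rate: float,
    baseline_window: float = 0.5,
    subtract_blank: bool = True,
    blank_stimulus: str = "blank",
) -> ResponseProfiles:
    """Average deconvolved responses over valid trials per stimulus.

    Each trial's block (starting ``baseline_window`` before onset) has its
    pre-onset mean subtracted; stimulus averages then subtract the average
    blank profile computed the same way.
    """
    validate_trial_table(trials)
    r = np.atleast_2d(r)
    n_roi, n_t = r.shape
    pre = int(round(baseline_window * frame_rate))

    def trial_stack(sub: pd.DataFrame) -> np.ndarray:
        blocks = []
        for _, tr in sub.iterrows():
            start = int(tr.onset_sample) - pre
            stop = start + int(tr.n_samples)
            if start < 0 or stop > n_t:
                continue
            seg = r[:, start:stop]
            base = seg[:, :pre].mean(axis=1, keepdims=True)
            blocks.append(seg - base)
        return np.stack(blocks) if blocks else None

    valid = trials[trials["valid"].astype(bool)]
    profiles, n_used, missing = {}, {}, []

    blank_profile = None
    if subtract_blank:
        stack = trial_stack(valid[valid["stimulus"] == blank_stimulus])
        if stack is not None:
            blank_profile = stack.mean(axis=0)

    for stim, sub in valid.groupby("stimulus", sort=False):
        stack = trial_stack(sub)
        if stack is None:
            missing.append(stim)
            continue
        prof = stack.mean(axis=0)
        if subtract_blank and blank_profile is not None:
            prof = prof - blank_profile
        profiles[stim] = prof
        n_used[stim] = stack.shape[0]

    for stim in trials["stimulus"].unique():
        if stim not in profiles and stim not in missing:
            missing.append(stim)

    return ResponseProfiles(profiles=profiles, n_trials_used=n_used,
                            missing=missing, frame_rate=frame_rate)


def run(
    traces: RoiTraceSet,
    neuropil_weight: float = 0.7,
    tau: float = DEFAULT_TAU,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    baseline_sigma: float = DEFAULT_BASELINE_SIGMA,
) -> DeconvolvedTraces:
    """Full chain: subtract neuropil, baseline, dF/F, deconvolve, smooth."""
    F_c = subtract_neuropil(traces, neuropil_weight)
    F_c0, flagged = estimate_baseline(F_c, traces.frame_rate,
                                      gaussian_sigma=baseline_sigma)
    base = expand_baseline(F_c0, traces.n_samples, traces.frame_rate)
    keep = np.ones(traces.n_roi, dtype=bool)
    keep[flagged] = False
    f = np.zeros_like(F_c)
    f[keep] = dff(F_c[keep], base[keep])
    r = smooth(deconvolve(f, tau, traces.frame_rate),
               smooth_window, traces.frame_rate)
    return DeconvolvedTraces(r=r, f=f, F_c0=F_c0, tau=tau,
                             smoothing_window=smooth_window,
                             frame_rate=traces.frame_rate,
                             excluded_rois=list(flagged))
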