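"""Shared container types for the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default two-photon acquisition rate (Hz).
DEFAULT_FRAME_RATE = 31.5

#: Default pupil-camera sampling rate (Hz).
PUPIL_SAMPLE_RATE = 50.0

#: Columns required in a trial table.
TRIAL_COLUMNS = ("trial_id", "stimulus", "context", "onset_sample", "n_samples", "valid")


@dataclass
class RoiTraceSet:
    """Raw ROI fluorescence with matched neuropil traces.

    Attributes
    ----------
    F : ndarray, shape (n_roi, n_samples)
        Mean ROI fluorescence, arbitrary units.
    F_np : ndarray, shape (n_roi, n_samples)
        Local neuropil fluorescence per ROI, same units.
    frame_rate : float
        Acquisition rate in Hz.
    """

    F: np.ndarray
    F_np: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.F_np = np.asarray(self.F_np, dtype=float)
        if self.F.shape != self.F_np.shape:
            raise ValueError(
                f"F and F_np shape mismatch: {self.F.shape} vs {self.F_np.shape}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (np.isfinite(self.F).all() and np.isfinite(self.F_np).all()):
            raise ValueError("trace values must be finite")

    @property
    def n_roi(self) -> int:
        return self.F.shape[0]

    @property
    def n_samples(self) -> int:
        return self.F.shape[1]


@dataclass
class DeconvolvedTraces:
    """Rate estimates and intermediates from the preprocessing chain."""

    r: np.ndarray
    f: np.ndarray
    F_c0: np.ndarray  # baseline, (n_roi, n_blocks)
    tau: float
    smoothing_window: float
    frame_rate: float = DEFAULT_FRAME_RATE
    excluded_rois: list = field(default_factory=list)


@dataclass
class PupilTrack:
    """Pupil-center trajectory on the eye surface (micrometres)."""

    t: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    diameter_um: np.ndarray
    sample_rate: float = PUPIL_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x_um": self.x_um, "y_um": self.y_um,
             "diameter_um": self.diameter_um}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_rate: float = PUPIL_SAMPLE_RATE) -> "PupilTrack":
        return cls(
            t=df["t"].to_numpy(), x_um=df["x_um"].to_numpy(),
            y_um=df["y_um"].to_numpy(), diameter_um=df["diameter_um"].to_numpy(),
            sample_rate=sample_rate,
        )


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table for the required columns; returns the table."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return trials
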