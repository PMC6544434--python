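"""File layouts: HDF5 trace container, CSV trial/pupil tables, TIFF stacks.

HDF5 layout::

    /traces/F      (n_roi, n_samples) float
    /traces/Fnp    (n_roi, n_samples) float
    /truth/rates   optional
    /truth/labels  optional, fixed-length bytes
    attrs: frame_rate, seed
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datatypes import PupilTrack, RoiTraceSet, validate_trial_table


def save_dataset_h5(path, traces: RoiTraceSet, truth_rates=None,
                    truth_labels=None, seed: int = None) -> None:
    with h5py.File(path, "w") as h5:
        g = h5.create_group("traces")
        g.create_dataset("F", data=traces.F)
        g.create_dataset("Fnp", data=traces.F_np)
        h5.attrs["frame_rate"] = traces.frame_rate
        if seed is not None:
            h5.attrs["seed"] = seed
        if truth_rates is not None or truth_labels is not None:
            t = h5.create_group("truth")
            if truth_rates is not None:
                t.create_dataset("rates", data=truth_rates)
            if truth_labels is not None:
                t.create_dataset(
                    "labels", data=np.array([str(l) for l in truth_labels], dtype="S32")
                )


def load_dataset_h5(path):
    """Returns (RoiTraceSet, truth_rates or None, truth_labels or None)."""
    with h5py.File(path, "r") as h5:
        traces = RoiTraceSet(
            F=h5["traces/F"][()], F_np=h5["traces/Fnp"][()],
            frame_rate=float(h5.attrs["frame_rate"]),
        )
        rates = h5["truth/rates"][()] if "truth" in h5 and "rates" in h5["truth"] else None
        labels = (
            [s.decode() for s in h5["truth/labels"][()]]
            if "truth" in h5 and "labels" in h5["truth"] else None
        )
    return traces, rates, labels


def save_trials_csv(path, trials: pd.DataFrame) -> None:
    validate_trial_table(trials).to_csv(path, index=False)


def load_trials_csv(path) -> pd.DataFrame:
    return validate_trial_table(pd.read_csv(path))


def save_pupil_csv(path, track: PupilTrack) -> None:
    track.to_frame().to_csv(path, index=False)


def load_pupil_csv(path, sample_rate: float = 50.0) -> PupilTrack:
    return PupilTrack.from_frame(pd.read_csv(path), sample_rate=sample_rate)


def save_stack_tiff(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def load_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(path)
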