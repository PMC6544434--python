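"""Ground-truth synthetic datasets for the analysis pipeline.

Emulates 31.5 Hz fluorescence recordings organised in 5 s stimulus blocks
separated by 3 s gaps, with slow-indicator kinetics (decay tau = 2 s),
shared neuropil contamination mixed at exactly 0.7 so the downstream
subtraction is an identity in expectation, 50 Hz pupil trajectories with
injected saccades, and periodic-sweep movies for phase mapping.

All stochastic draws are driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DEFAULT_FRAME_RATE, PUPIL_SAMPLE_RATE, PupilTrack, RoiTraceSet

# ---------------------------------------------------------------------------
# stimulus / block geometry
# ---------------------------------------------------------------------------

BLOCK_S = 5.0          # imaging block duration
GAP_S = 3.0            # inter-block interval
ONSET_S = 0.5          # stimulus onset within block (leaves a baseline window)
STIM_S = 2.0           # stimulus duration

SOUND_STIMULI = ("up_ramp", "down_ramp")
VISUAL_STIMULI = ("looming", "receding")
DEFAULT_STIMULI = ("up_ramp", "down_ramp", "looming", "receding", "blank")

CELL_TYPES = (
    "loud_ON", "quiet_ON", "ON_mixed", "loud_OFF",
    "quiet_tonic", "loud_tonic", "tonic_plus_loudOFF", "nonresponsive",
)

TAU_DECAY_S = 2.0      # indicator decay
TAU_RISE_S = 0.18      # chosen rise constant (slow-rise indicator)
NEUROPIL_WEIGHT = 0.7  # exact mixing coefficient, matches subtraction default


class UnknownStimulusError(ValueError):
    """Raised for stimulus descriptors outside the supported set."""


@dataclass
class CellTypeSpec:
    """Functional cell type: rate templates plus variability parameters."""

    label: str
    rate_template: dict  # stimulus -> ndarray (Hz) over one block
    trial_gain_cv: float = 0.2
    context_modulation: float = 0.0  # additive Hz in light vs dark


@dataclass
class SyntheticDataset:
    """A complete ground-truth recording."""

    traces: RoiTraceSet
    trials: pd.DataFrame
    truth_labels: list
    truth_rates: np.ndarray
    pupil: PupilTrack
    seed: int
    truth_signal: np.ndarray = None  # pre-mixing fluorescence per ROI
    saccade_truth: pd.DataFrame = None


def _bump(t: np.ndarray, t0: float, tau_r: float = 0.10) -> np.ndarray:
    """Alpha-shaped transient peaking tau_r after t0, unit peak."""
    x = t - t0
    out = np.where(x >= 0, (x / tau_r) * np.exp(1.0 - x / tau_r), 0.0)
    return out


def _plateau(t: np.ndarray, t0: float, t1: float, ramp: float = 0.05) -> np.ndarray:
    """Smoothed rectangular window [t0, t1], unit height."""
    rise = np.clip((t - t0) / ramp, 0.0, 1.0)
    fall = np.clip((t1 - t) / ramp, 0.0, 1.0)
    return rise * fall


def make_rate_templates(
    stimulus_set=DEFAULT_STIMULI,
    frame_rate: float = DEFAULT_FRAME_RATE,
    peak_hz: float = 20.0,
) -> dict:
    """Build firing-rate templates (Hz) over one 5 s block for every cell type.

    Sound stimuli ramp between quiet and loud over the 2 s stimulation window.
    ON types emit a transient when their preferred intensity is present at
    (or reached during) the stimulus; OFF types respond after stimulus end;
    tonic types sustain during their preferred-intensity epoch.  Visual and
    blank stimuli yield zero templates for these auditory types.

    Returns ``{type_label: {stimulus: template}}``.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    for s in stimulus_set:
        if s not in DEFAULT_STIMULI:
            raise UnknownStimulusError(f"unknown stimulus descriptor: {s!r}")

    n = int(round(BLOCK_S * frame_rate))
    t = np.arange(n) / frame_rate
    on, off = ONSET_S, ONSET_S + STIM_S
    zero = np.zeros(n)

    # loud intensity epoch within the stimulation window, per sound stimulus:
    #   down_ramp starts loud and decays; up_ramp reaches loud near the end.
    loud_reach = {"down_ramp": on, "up_ramp": off - 0.2}
    quiet_reach = {"up_ramp": on, "down_ramp": off - 0.2}

    def sound_only(build) -> dict:
        tmpl = {}
        for s in stimulus_set:
            tmpl[s] = build(s) if s in SOUND_STIMULI else zero.copy()
        return tmpl

    def loud_on(s):
        amp = 1.0 if s == "down_ramp" else 0.35
        return peak_hz * amp * _bump(t, loud_reach[s])

    def quiet_on(s):
        amp = 1.0 if s == "up_ramp" else 0.35
        return peak_hz * amp * _bump(t, quiet_reach[s])

    def on_mixed(s):
        return peak_hz * 0.8 * _bump(t, on)

    def loud_off(s):
        # offset transient for every sound, stronger when the sound ends loud
        amp = 1.0 if s == "up_ramp" else 0.35
        return peak_hz * amp * _bump(t, off + 0.05)

    def quiet_tonic(s):
        # sustained during the quiet half of the ramp
        win = (on, on + 1.2) if s == "up_ramp" else (off - 1.2, off)
        return peak_hz * 0.5 * _plateau(t, *win)

    def loud_tonic(s):
        win = (on, on + 1.2) if s == "down_ramp" else (off - 1.2, off)
        return peak_hz * 0.5 * _plateau(t, *win)

    def tonic_plus_loudoff(s):
        return 0.7 * loud_tonic(s) + 0.7 * loud_off(s)

    builders = {
        "loud_ON": loud_on,
        "quiet_ON": quiet_on,
        "ON_mixed": on_mixed,
        "loud_OFF": loud_off,
        "quiet_tonic": quiet_tonic,
        "loud_tonic": loud_tonic,
        "tonic_plus_loudOFF": tonic_plus_loudoff,
    }

    templates = {label: sound_only(b) for label, b in builders.items()}
    templates["nonresponsive"] = {s: zero.copy() for s in stimulus_set}
    return templates


def calcium_kernel(
    frame_rate: float,
    tau_decay: float = TAU_DECAY_S,
    tau_rise: float = 0.0,
    duration_s: float = 12.0,
) -> np.ndarray:
    """Peak-normalised difference-of-exponentials indicator kernel."""
    if not tau_decay > tau_rise >= 0:
        raise ValueError("require tau_decay > tau_rise >= 0")
    t = np.arange(int(round(duration_s * frame_rate))) / frame_rate
    k = np.exp(-t / tau_decay)
    if tau_rise > 0:
        k = k - np.exp(-t / tau_rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def rates_to_fluorescence(
    rates: np.ndarray,
    tau_decay: float = TAU_DECAY_S,
    tau_rise: float = 0.0,
    neuropil_weight: float = NEUROPIL_WEIGHT,
    noise_sd: float = 0.0,
    baseline: float = 100.0,
    seed: int = 0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    dff_per_spike: float = 0.1,
    neuropil_amp: float = 0.0,
    return_signal: bool = False,
):
    """Forward model: firing rates -> raw + neuropil fluorescence.

    F_cell = baseline * (1 + A * (rates (*) kernel) * dt) + baseline * noise
    F      = F_cell + neuropil_weight * F_np

    with kernel a peak-normalised difference of exponentials.  F_np is a
    slow random-walk contaminant shared across ROIs, so subtracting
    ``neuropil_weight * F_np`` downstream recovers F_cell exactly.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if not np.isfinite(rates).all():
        raise ValueError("rates must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_roi, n_t = rates.shape
    dt = 1.0 / frame_rate
    kern = calcium_kernel(frame_rate, tau_decay, tau_rise)

    rng = np.random.default_rng(seed)
    f_sig = np.empty_like(rates)
    for i in range(n_roi):
        f_sig[i] = np.convolve(rates[i] * dt * dff_per_spike, kern)[:n_t]

    F_cell = baseline * (1.0 + f_sig)
    if noise_sd > 0:
        F_cell = F_cell + baseline * noise_sd * rng.standard_normal((n_roi, n_t))

    # shared slow contaminant: low-passed random walk, strictly positive
    if neuropil_amp > 0:
        walk = np.cumsum(rng.standard_normal(n_t))
        win = max(int(round(2.0 * frame_rate)), 1)
        walk = np.convolve(walk, np.ones(win) / win, mode="same")
        walk = walk - walk.min()
        scale = walk.max() if walk.max() > 0 else 1.0
        F_np_row = baseline * neuropil_amp * (0.5 + walk / scale)
    else:
        F_np_row = np.zeros(n_t)
    F_np = np.tile(F_np_row, (n_roi, 1))

    traces = RoiTraceSet(F=F_cell + neuropil_weight * F_np, F_np=F_np,
                         frame_rate=frame_rate)
    if return_signal:
        return traces, F_cell
    return traces


def make_trial_table(
    stimuli=DEFAULT_STIMULI,
    n_repetitions: int = 20,
    contexts=("dark",),
    frame_rate: float = DEFAULT_FRAME_RATE,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomised block design: one stimulus per 5 s block, 3 s gaps.

    Contexts are run as consecutive sessions; within each context every
    stimulus repeats ``n_repetitions`` times in shuffled order.
    """
    rng = np.random.default_rng(seed)
    period = int(round((BLOCK_S + GAP_S) * frame_rate))
    n_block = int(round(BLOCK_S * frame_rate))
    onset_in_block = int(round(ONSET_S * frame_rate))

    rows = []
    block_idx = 0
    for context in contexts:
        order = np.repeat(np.arange(len(stimuli)), n_repetitions)
        rng.shuffle(order)
        for si in order:
            start = block_idx * period + int(round(GAP_S * frame_rate))
            rows.append(
                dict(
                    trial_id=block_idx,
                    stimulus=stimuli[si],
                    context=context,
                    onset_sample=start + onset_in_block,
                    n_samples=n_block,
                    valid=True,
                )
            )
            block_idx += 1
    return pd.DataFrame(rows)


def rates_from_trials(
    trials: pd.DataFrame,
    labels,
    templates: dict,
    frame_rate: float = DEFAULT_FRAME_RATE,
    trial_gain_cv: float = 0.2,
    context_modulation: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Assemble the noiseless population rate matrix from templates.

    Each trial scales the cell's template by a lognormal gain with unit mean
    and the given CV.  ``context_modulation`` adds (light) / subtracts (dark)
    a constant rate during sound stimulation, clipped at zero.
    """
    rng = np.random.default_rng(seed)
    n_roi = len(labels)
    period = int(round((BLOCK_S + GAP_S) * frame_rate))
    n_t = int(trials["onset_sample"].max()) + int(trials["n_samples"].max()) + period
    rates = np.zeros((n_roi, n_t))
    onset_in_block = int(round(ONSET_S * frame_rate))
    stim_n = int(round(STIM_S * frame_rate))

    sigma = np.sqrt(np.log(1.0 + trial_gain_cv**2)) if trial_gain_cv > 0 else 0.0
    for _, tr in trials.iterrows():
        start = int(tr.onset_sample) - onset_in_block
        stop = start + int(tr.n_samples)
        gains = (
            rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_roi)
            if sigma > 0 else np.ones(n_roi)
        )
        ctx_sign = {"dark": -1.0, "light": +1.0, "dim_light": +1.0, "bimodal": +1.0}.get(
            tr.context, 0.0
        )
        for i, lab in enumerate(labels):
            tmpl = templates[lab][tr.stimulus]
            seg = tmpl[: stop - start] * gains[i]
            if context_modulation != 0.0 and tr.stimulus in SOUND_STIMULI and lab != "nonresponsive":
                mod = np.zeros_like(seg)
                mod[onset_in_block : onset_in_block + stim_n] = ctx_sign * context_modulation
                seg = seg + mod
            rates[i, start:stop] += seg
    return np.clip(rates, 0.0, None)


def make_pupil_track(
    duration: float,
    sample_rate: float = PUPIL_SAMPLE_RATE,
    saccade_rate: float = 0.0,
    saccade_amp_um: float = 100.0,
    seed: int = 0,
    jitter_um: float = 2.0,
    trial_onsets_s=None,
):
    """Piecewise-constant pupil trajectory with optional per-trial saccades.

    If ``trial_onsets_s`` is given, each trial independently receives a
    saccade (a step in position of size ``saccade_amp_um`` in a random
    direction) with probability ``saccade_rate``, placed inside the first
    2 s of stimulation.  Gaussian jitter of SD ``jitter_um`` is added
    throughout.

    Returns ``(PupilTrack, saccade_truth)`` where saccade_truth is a
    DataFrame (trial index, time, amplitude).
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    y = np.zeros(n)

    events = []
    if trial_onsets_s is not None and saccade_rate > 0:
        for k, onset in enumerate(np.asarray(trial_onsets_s, dtype=float)):
            if rng.random() < saccade_rate:
                t_sacc = onset + rng.uniform(0.1, 1.9)
                idx = int(round(t_sacc * sample_rate))
                if idx >= n:
                    continue
                theta = rng.uniform(0, 2 * np.pi)
                x[idx:] += saccade_amp_um * np.cos(theta)
                y[idx:] += saccade_amp_um * np.sin(theta)
                events.append(dict(trial=k, t=t_sacc, amplitude_um=saccade_amp_um))

    x = x + jitter_um * rng.standard_normal(n)
    y = y + jitter_um * rng.standard_normal(n)
    diameter = 400.0 + 20.0 * np.sin(2 * np.pi * 0.05 * t)

    track = PupilTrack(t=t, x_um=x, y_um=y, diameter_um=diameter, sample_rate=sample_rate)
    truth = pd.DataFrame(events, columns=["trial", "t", "amplitude_um"])
    return track, truth


def make_retinotopy_movie(
    width: int,
    height: int,
    n_cycles: int = 10,
    stim_freq: float = 0.1,
    phase_map: np.ndarray = None,
    delay: float = 0.0,
    amplitude_mask: np.ndarray = None,
    noise_sd: float = 0.0,
    frame_rate: float = 15.0,
    seed: int = 0,
):
    """Bidirectional periodic-sweep movies with a known phase map.

    Pixel time course (direction d = +1 forward, -1 reverse):

        amplitude_mask[i,j] * sin(2*pi*stim_freq*t + d*phase_map[i,j] + delay) + noise

    The retinotopic phase flips with sweep direction while the hemodynamic
    delay does not, so the half-difference / half-sum combination recovers
    (phase_map, delay).

    Returns ``(movie_fwd, movie_rev)`` as float32 T x H x W stacks.
    """
    if n_cycles < 2:
        raise ValueError("need at least 2 stimulus cycles")
    if stim_freq <= 0:
        raise ValueError("stim_freq must be positive")
    if phase_map is None:
        phase_map = np.zeros((height, width))
    if amplitude_mask is None:
        amplitude_mask = np.ones((height, width))
    phase_map = np.asarray(phase_map, dtype=float)
    amplitude_mask = np.asarray(amplitude_mask, dtype=float)

    n_frames = int(round(n_cycles / stim_freq * frame_rate))
    t = np.arange(n_frames) / frame_rate
    rng = np.random.default_rng(seed)

    movies = []
    for direction in (+1, -1):
        arg = (2 * np.pi * stim_freq * t[:, None, None]
               + direction * phase_map[None, :, :] + delay)
        mov = amplitude_mask[None, :, :] * np.sin(arg)
        if noise_sd > 0:
            mov = mov + noise_sd * rng.standard_normal(mov.shape)
        movies.append(mov.astype(np.float32))
    return movies[0], movies[1]


# ---------------------------------------------------------------------------
# top-level dataset assembly
# ---------------------------------------------------------------------------

DEFAULT_TYPE_PROPORTIONS = {
    "loud_ON": 0.25,
    "quiet_ON": 0.10,
    "ON_mixed": 0.08,
    "loud_OFF": 0.10,
    "quiet_tonic": 0.08,
    "loud_tonic": 0.08,
    "tonic_plus_loudOFF": 0.08,
    "nonresponsive": 0.23,
}


def make_dataset(
    n_neurons: int = 300,
    n_repetitions: int = 20,
    stimuli=DEFAULT_STIMULI,
    contexts=("dark",),
    type_proportions: dict = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    noise_sd: float = 0.03,
    trial_gain_cv: float = 0.2,
    context_modulation: float = 0.0,
    neuropil_amp: float = 0.1,
    tau_rise: float = 0.0,
    saccade_rate: float = 0.0,
    saccade_amp_um: float = 100.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a full ground-truth recording: traces, trials, pupil, labels."""
    props = dict(DEFAULT_TYPE_PROPORTIONS if type_proportions is None else type_proportions)
    rng = np.random.default_rng(seed)

    labels_pool = list(props)
    counts = np.floor(np.array([props[k] for k in labels_pool]) * n_neurons).astype(int)
    while counts.sum() < n_neurons:
        counts[int(rng.integers(len(counts)))] += 1
    labels = [lab for lab, c in zip(labels_pool, counts) for _ in range(c)]
    rng.shuffle(labels)

    trials = make_trial_table(stimuli, n_repetitions, contexts, frame_rate,
                              seed=seed + 1)
    templates = make_rate_templates(stimuli, frame_rate)
    rates = rates_from_trials(
        trials, labels, templates, frame_rate,
        trial_gain_cv=trial_gain_cv, context_modulation=context_modulation,
        seed=seed + 2,
    )
    traces, signal = rates_to_fluorescence(
        rates, tau_rise=tau_rise, noise_sd=noise_sd, seed=seed + 3,
        frame_rate=frame_rate, neuropil_amp=neuropil_amp, return_signal=True,
    )

    duration = traces.n_samples / frame_rate
    onsets_s = trials["onset_sample"].to_numpy() / frame_rate
    pupil, sacc = make_pupil_track(
        duration, saccade_rate=saccade_rate, saccade_amp_um=saccade_amp_um,
        seed=seed + 4, trial_onsets_s=onsets_s,
    )
    return SyntheticDataset(
        traces=traces, trials=trials, truth_labels=labels, truth_rates=rates,
        pupil=pupil, seed=seed, truth_signal=signal, saccade_truth=sacc,
    )
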