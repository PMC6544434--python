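"""Threshold-linear rate network for context-dependent sound responses.

Populations update synchronously:

    r_i(t) = f_i( b_context_i + g_aud_i * s_aud(t) + g_vis_i * s_vis(t)
                  + sum_j W[i, j] * r_j(t-1) )

where f_i is a continuous two-segment piecewise-linear function with a low
sub-threshold gain (not constant zero: background inputs let the cell fire
below its mean threshold) and a higher supra-threshold gain.

When the inhibitory population sits close to its threshold in the dark, a
sound transient recruits strong disynaptic inhibition and the excitatory
population's sound response is negative; in the light the inhibitory
population operates in its shallow segment and direct excitation wins,
flipping the response sign.  With a visual drive placing E near/above its
own threshold, the same auditory input is amplified supra-linearly
(bimodal boosting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DT = 0.02  # s per update step
TAU_AUD = 0.3  # s, decay of the auditory input transient


@dataclass
class Nonlinearity:
    """Two-segment threshold-linear function, continuous at the threshold."""

    theta: float = 1.0
    k_lo: float = 0.1
    k_hi: float = 2.0
    offset: float = 0.1

    def __call__(self, x):
        return f_piecewise(x, self.theta, self.k_lo, self.k_hi, self.offset)


def f_piecewise(x, theta: float, k_lo: float, k_hi: float, offset: float):
    """f(x) = max(0, offset + k_lo*x) for x <= theta, then continues with
    slope k_hi above theta."""
    x = np.asarray(x, dtype=float)
    low = np.maximum(0.0, offset + k_lo * x)
    f_theta = max(0.0, offset + k_lo * theta)
    high = f_theta + k_hi * (x - theta)
    out = np.where(x <= theta, low, high)
    return out if out.ndim else float(out)


@dataclass
class RateModelSpec:
    """Populations, gains, context baselines and nonlinearities.

    ``W[i, j]`` is the gain from population j onto population i.
    """

    populations: tuple = ("I", "E")
    b_context: dict = field(default_factory=lambda: {
        "dark": {"I": 0.95, "E": 0.30},
        "light": {"I": 0.10, "E": 0.60},
    })
    g_auditory: dict = field(default_factory=lambda: {"I": 1.0, "E": 0.6})
    g_visual: dict = field(default_factory=lambda: {"I": 0.0, "E": 1.0})
    W: np.ndarray = None
    nonlinearity: dict = field(default_factory=lambda: {
        "I": Nonlinearity(theta=1.0, k_lo=0.1, k_hi=2.0, offset=0.1),
        "E": Nonlinearity(theta=1.0, k_lo=0.2, k_hi=2.0, offset=0.05),
    })

    def __post_init__(self):
        if self.W is None:
            # I -> E inhibitory, weak E -> I feedback, zero diagonal
            self.W = np.zeros((len(self.populations), len(self.populations)))
            idx = {p: i for i, p in enumerate(self.populations)}
            if "I" in idx and "E" in idx:
                self.W[idx["E"], idx["I"]] = -1.2
                self.W[idx["I"], idx["E"]] = 0.3
        self.W = np.asarray(self.W, dtype=float)

    @classmethod
    def from_yaml(cls, path) -> "RateModelSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        nl = {
            p: Nonlinearity(**params) for p, params in d["nonlinearity"].items()
        }
        return cls(
            populations=tuple(d["populations"]),
            b_context={c: dict(v) for c, v in d["b_context"].items()},
            g_auditory=dict(d["g_auditory"]),
            g_visual=dict(d["g_visual"]),
            W=np.asarray(d["W"], dtype=float),
            nonlinearity=nl,
        )

    def to_yaml(self, path) -> None:
        d = dict(
            populations=list(self.populations),
            b_context={c: dict(v) for c, v in self.b_context.items()},
            g_auditory=dict(self.g_auditory),
            g_visual=dict(self.g_visual),
            W=self.W.tolist(),
            nonlinearity={
                p: dict(theta=nl.theta, k_lo=nl.k_lo, k_hi=nl.k_hi,
                        offset=nl.offset)
                for p, nl in self.nonlinearity.items()
            },
        )
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


@dataclass
class StimulusInputs:
    """Auditory transient (exponential decay) and visual plateau (step)."""

    s_auditory: np.ndarray
    s_visual: np.ndarray
    dt: float = DT

    @classmethod
    def make(cls, T: int, dt: float = DT, sound_onset: int = 20,
             sound_amp: float = 0.5, tau_aud: float = TAU_AUD,
             visual_onset: int = 10, visual_amp: float = 0.0) -> "StimulusInputs":
        t = np.arange(T)
        s_aud = np.where(
            t >= sound_onset,
            sound_amp * np.exp(-(t - sound_onset) * dt / tau_aud), 0.0
        )
        s_vis = np.where(t >= visual_onset, visual_amp, 0.0)
        return cls(s_auditory=s_aud, s_visual=s_vis, dt=dt)


def baseline_fixed_point(spec: RateModelSpec, context: str,
                         tol: float = 1e-10, max_iter: int = 10_000,
                         damping: float = 0.5) -> np.ndarray:
    """No-stimulus steady state by damped iteration of the update map."""
    pops = spec.populations
    b = np.array([spec.b_context[context][p] for p in pops])
    r = np.zeros(len(pops))
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(max_iter):
            drive = b + spec.W @ r
            r_new = np.array(
                [spec.nonlinearity[p](drive[i]) for i, p in enumerate(pops)])
            step = r_new - r
            if not np.isfinite(step).all():
                break
            r = r + damping * step
            if np.abs(step).max() < tol:
                return r
    raise RuntimeError(
        f"baseline fixed point did not converge in context {context!r}; "
        f"residual {np.abs(step).max():.3g}"
    )


def simulate(spec: RateModelSpec, inputs: StimulusInputs, context: str,
             T: int = None) -> np.ndarray:
    """Synchronous trajectory; initial state is the baseline fixed point.

    Returns rates of shape (n_populations, T).
    """
    pops = spec.populations
    n = len(pops)
    if T is None:
        T = len(inputs.s_auditory)
    b = np.array([spec.b_context[context][p] for p in pops])
    ga = np.array([spec.g_auditory[p] for p in pops])
    gv = np.array([spec.g_visual[p] for p in pops])

    r = baseline_fixed_point(spec, context)
    out = np.empty((n, T))
    for t in range(T):
        drive = b + ga * inputs.s_auditory[t] + gv * inputs.s_visual[t] + spec.W @ r
        r = np.array([spec.nonlinearity[p](drive[i]) for i, p in enumerate(pops)])
        out[:, t] = r
    return out


def response(spec: RateModelSpec, inputs: StimulusInputs, context: str,
             population: str = "E") -> np.ndarray:
    """Baseline-subtracted trajectory of one population."""
    rates = simulate(spec, inputs, context)
    base = baseline_fixed_point(spec, context)
    i = spec.populations.index(population)
    return rates[i] - base[i]


def context_experiment(spec: RateModelSpec = None, T: int = 150,
                       sound_amp: float = 0.5) -> dict:
    """Mean sound-evoked E response (baseline-subtracted) per context."""
    if spec is None:
        spec = RateModelSpec()
    inputs = StimulusInputs.make(T, sound_amp=sound_amp)
    out = {}
    for context in spec.b_context:
        resp = response(spec, inputs, context)
        out[context] = float(resp[20:100].mean())
    return out


def bimodal_experiment(spec: RateModelSpec = None, T: int = 150,
                       sound_amp: float = 0.5,
                       visual_levels: dict = None,
                       context: str = "light") -> dict:
    """Boosting table: bimodal minus (visual + auditory-alone) per level.

    ``visual_levels`` maps level name to visual input amplitude; defaults
    are none / nonpreferred (keeps E below threshold) / preferred (drives E
    near threshold).
    """
    if spec is None:
        spec = RateModelSpec()
    if visual_levels is None:
        visual_levels = {"none": 0.0, "nonpreferred": 0.3, "preferred": 1.0}

    def windowed(resp):
        return float(resp[20:100].mean())

    aud_only = windowed(response(
        spec, StimulusInputs.make(T, sound_amp=sound_amp), context))

    table = {}
    for level, v_amp in visual_levels.items():
        vis = StimulusInputs.make(T, sound_amp=0.0, visual_amp=v_amp)
        both = StimulusInputs.make(T, sound_amp=sound_amp, visual_amp=v_amp)
        r_vis = windowed(response(spec, vis, context))
        r_both = windowed(response(spec, both, context))
        table[level] = dict(
            visual=r_vis, bimodal=r_both, auditory_alone=aud_only,
            boost=r_both - r_vis - aud_only,
        )
    return table


def affine_spec(k: float = 0.5, offset: float = 10.0) -> RateModelSpec:
    """Spec whose nonlinearities are all affine (k_lo = k_hi, far from the
    zero clip) — superposition holds exactly, so boosting vanishes."""
    spec = RateModelSpec()
    spec.nonlinearity = {
        p: Nonlinearity(theta=1.0, k_lo=k, k_hi=k, offset=offset)
        for p in spec.populations
    }
    return spec
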