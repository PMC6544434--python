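"""Pipeline orchestration: config validation, staged execution, manifest,
human-readable report.

Stages run in fixed order (synth, preprocess, filter_trials, cluster,
stats, model); each writes its outputs under ``output_dir`` and records a
checksum in the run manifest.  Deterministic stages reproduce identical
checksums for the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, eyetrack, io, preprocess, rate_model, stats, synthetic

STAGE_ORDER = ("synth", "preprocess", "filter_trials", "cluster", "stats", "model")

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "run_out",
    "stages": list(STAGE_ORDER),
    "synth": {
        "n_neurons": 120,
        "n_repetitions": 20,
        "contexts": ["dark"],
        "noise_sd": 0.03,
        "saccade_rate": 0.0,
    },
    "preprocess": {
        "neuropil_weight": 0.7,
        "tau": 2.0,
        "smooth_window": 0.190,
    },
    "filter_trials": {
        "threshold_deg": 2.0,
        "eye_radius_mm": 1.65,
    },
    "cluster": {
        "n_over": 25,
        "hom_threshold": 0.4,
        "reagg_threshold": 0.4,
    },
    "stats": {
        "alpha": 0.01,
        "mask_pct": 1.0,
        "response_window": [0.2, 1.0],
    },
    "model": {
        "spec_yaml": None,  # default in-code spec when None
    },
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for k, v in override.items():
        if k not in defaults:
            raise ConfigError(f"unknown config key: {path}{k}")
        if isinstance(defaults[k], dict) and isinstance(v, dict):
            out[k] = _merge(defaults[k], v, path=f"{path}{k}.")
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict = None) -> dict:
    """Load + validate a YAML config; unknown keys are rejected."""
    cfg = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, cfg)
    if overrides:
        cfg = _merge(cfg, overrides)
    unknown = [s for s in cfg["stages"] if s not in STAGE_ORDER]
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute enabled stages in order; returns the run manifest."""
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    enabled = [s for s in STAGE_ORDER if s in config["stages"]]

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "stages": {},
        "warnings": [],
    }
    state = {}

    def record(stage: str, outputs: dict, t0: float) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 3),
            "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
            "paths": {name: str(p) for name, p in outputs.items()},
        }

    for stage in enabled:
        t0 = time.time()
        try:
            if stage == "synth":
                sc = config["synth"]
                ds = synthetic.make_dataset(
                    n_neurons=sc["n_neurons"], n_repetitions=sc["n_repetitions"],
                    contexts=tuple(sc["contexts"]), noise_sd=sc["noise_sd"],
                    saccade_rate=sc["saccade_rate"], seed=seed,
                )
                h5 = out_dir / "dataset.h5"
                trials_csv = out_dir / "trials.csv"
                pupil_csv = out_dir / "pupil.csv"
                io.save_dataset_h5(h5, ds.traces, ds.truth_rates, ds.truth_labels, seed)
                io.save_trials_csv(trials_csv, ds.trials)
                io.save_pupil_csv(pupil_csv, ds.pupil)
                state["dataset"] = ds
                record(stage, {"dataset": h5, "trials": trials_csv, "pupil": pupil_csv}, t0)

            elif stage == "preprocess":
                if "dataset" not in state:
                    raise StageError(stage, "missing upstream output; run 'synth' first")
                pc = config["preprocess"]
                dec = preprocess.run(
                    state["dataset"].traces,
                    neuropil_weight=pc["neuropil_weight"], tau=pc["tau"],
                    smooth_window=pc["smooth_window"],
                )
                state["deconvolved"] = dec
                npz = out_dir / "deconvolved.npz"
                np.savez(npz, r=dec.r, f=dec.f, F_c0=dec.F_c0)
                record(stage, {"deconvolved": npz}, t0)

            elif stage == "filter_trials":
                if "dataset" not in state:
                    raise StageError(stage, "missing upstream output; run 'synth' first")
                fc = config["filter_trials"]
                ds = state["dataset"]
                trials, summary = eyetrack.filter_trials(
                    ds.trials, ds.pupil, ds.traces.frame_rate,
                    threshold_deg=fc["threshold_deg"],
                    eye_radius_mm=fc["eye_radius_mm"],
                )
                state["trials"] = trials
                csv = out_dir / "trials_filtered.csv"
                trials.to_csv(csv, index=False)
                record(stage, {"trials_filtered": csv}, t0)
                manifest["stages"][stage]["kept_fraction"] = summary

            elif stage == "cluster":
                if "deconvolved" not in state:
                    raise StageError(stage, "missing upstream output; run 'preprocess' first")
                cc = config["cluster"]
                ds = state["dataset"]
                trials = state.get("trials", ds.trials)
                prof = preprocess.epoch_and_average(
                    state["deconvolved"].r, trials, ds.traces.frame_rate
                )
                X = prof.concatenate(sorted(prof.profiles))
                model = clustering.fit(
                    X, n_over=cc["n_over"], hom_threshold=cc["hom_threshold"],
                    reagg_threshold=cc["reagg_threshold"],
                )
                state["profiles"] = prof
                state["cluster_model"] = model
                labels_csv = out_dir / "cluster_labels.csv"
                pd.DataFrame({"neuron": np.arange(len(model.labels)),
                              "cluster": model.labels,
                              "truth": ds.truth_labels}).to_csv(labels_csv, index=False)
                rep = {
                    "n_kept_clusters": len(model.kept_labels),
                    "homogeneity": model.homogeneity,
                    "explained_variance_pct": clustering.explained_variance(X, model),
                    "best_match_accuracy": clustering.best_match_accuracy(
                        ds.truth_labels, model.labels),
                }
                rep_json = out_dir / "cluster_report.json"
                rep_json.write_text(json.dumps(rep, indent=2))
                record(stage, {"labels": labels_csv, "report": rep_json}, t0)

            elif stage == "stats":
                if "deconvolved" not in state:
                    raise StageError(stage, "missing upstream output; run 'preprocess' first")
                sc = config["stats"]
                ds = state["dataset"]
                trials = state.get("trials", ds.trials)
                fr = ds.traces.frame_rate
                w0, w1 = sc["response_window"]
                res = _responder_fractions(
                    state["deconvolved"].r, trials, fr, (w0, w1),
                    alpha=sc["alpha"], mask_pct=sc["mask_pct"],
                )
                res["seed"] = seed
                js = out_dir / "responders.json"
                js.write_text(json.dumps(res, indent=2))
                state["stats"] = res
                record(stage, {"responders": js}, t0)

            elif stage == "model":
                mc = config["model"]
                spec = (rate_model.RateModelSpec.from_yaml(mc["spec_yaml"])
                        if mc["spec_yaml"] else rate_model.RateModelSpec())
                ctx = rate_model.context_experiment(spec)
                boost = rate_model.bimodal_experiment(spec)
                res = {"context_response": ctx,
                       "boost_table": boost,
                       "signs": {c: ("+" if v > 0 else "-") for c, v in ctx.items()}}
                js = out_dir / "model.json"
                js.write_text(json.dumps(res, indent=2))
                state["model"] = res
                record(stage, {"model": js}, t0)

        except StageError:
            raise
        except Exception as exc:  # fail fast with stage-named error
            raise StageError(stage, str(exc)) from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _responder_fractions(r, trials, frame_rate, window, alpha, mask_pct):
    """Per-stimulus excited/inhibited fractions vs blank trials."""
    valid = trials[trials["valid"].astype(bool)]
    pre = int(round(0.5 * frame_rate))
    i0 = int(round(window[0] * frame_rate))
    i1 = int(round(window[1] * frame_rate))

    def trial_means(sub):
        vals = []
        for _, tr in sub.iterrows():
            on = int(tr.onset_sample)
            if on - pre < 0 or on + i1 > r.shape[1]:
                continue
            base = r[:, on - pre:on].mean(axis=1)
            vals.append(r[:, on + i0:on + i1].mean(axis=1) - base)
        return np.stack(vals, axis=1) if vals else None

    blank = trial_means(valid[valid["stimulus"] == "blank"])
    out = {"alpha": alpha, "mask_pct": mask_pct, "fractions": {}}
    if blank is None:
        return out
    for stim, sub in valid.groupby("stimulus", sort=False):
        if stim == "blank":
            continue
        sm = trial_means(sub)
        if sm is None or sm.shape[1] < 3:
            continue
        p, direction = stats.detect_responders_matrix(sm, blank, alpha)
        n = len(p)
        for d in ("excited", "inhibited"):
            raw = 100.0 * float(np.sum(direction == d)) / n
            out["fractions"].setdefault(stim, {})[d] = {
                "raw_pct": raw,
                "displayed_pct": stats.masked_fraction(raw, mask_pct),
            }
    return out


def report(manifest: dict, output_dir) -> str:
    """Markdown summary of a completed run."""
    out_dir = Path(output_dir)
    lines = ["# Run report", "",
             f"- config hash: `{manifest['config_hash']}`",
             f"- seed: {manifest['seed']}", ""]
    for stage in STAGE_ORDER:
        info = manifest["stages"].get(stage)
        if info is None:
            lines += [f"## {stage}", "", "_skipped_", ""]
            continue
        lines += [f"## {stage}", "", f"- status: {info['status']} "
                  f"({info['seconds']} s)"]
        if stage == "filter_trials" and "kept_fraction" in info:
            for ctx, frac in info["kept_fraction"].items():
                lines.append(f"- kept fraction [{ctx}]: {frac:.3f}")
        if stage == "cluster":
            rep = json.loads((out_dir / "cluster_report.json").read_text())
            lines.append(f"- kept clusters: {rep['n_kept_clusters']}")
            lines.append(f"- explained variance: {rep['explained_variance_pct']:.1f}%")
            lines.append(f"- best-match accuracy: {rep['best_match_accuracy']:.3f}")
        if stage == "stats" and (out_dir / "responders.json").exists():
            rep = json.loads((out_dir / "responders.json").read_text())
            for stim, dirs in rep.get("fractions", {}).items():
                for d, v in dirs.items():
                    lines.append(
                        f"- {stim} {d}: raw {v['raw_pct']:.1f}%, "
                        f"displayed {v['displayed_pct']:.1f}%")
        if stage == "model" and (out_dir / "model.json").exists():
            rep = json.loads((out_dir / "model.json").read_text())
            ctx = rep["context_response"]
            verdict = ("dark-negative/light-positive"
                       if ctx.get("dark", 0) < 0 < ctx.get("light", 0)
                       else "signs not reproduced")
            lines.append(f"- context signs: {verdict}")
            boost = rep["boost_table"]
            if "preferred" in boost:
                lines.append(f"- boost(preferred): {boost['preferred']['boost']:.4f}")
                lines.append(f"- boost(nonpreferred): {boost['nonpreferred']['boost']:.4f}")
        lines.append("")
    return "\n".join(lines)
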