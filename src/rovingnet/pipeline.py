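"""End-to-end orchestration: synthesize -> analyse -> train -> perturb -> report.

A single YAML-configurable, seeded run executes the full study at desk
scale: synthetic control- and case-group sensor epochs; preprocessing,
evoked averaging, peak metrics, the cluster permutation test and the
mismatch score per group; label construction from the control group's
cluster average; network training and evaluation; the three perturbation
experiments over the eight-level ladder with latent-stability metrics; and
a machine-readable summary.  Stages write their artefacts into the run
directory and can be re-run individually; every stage derives its own
child seed deterministically from the global seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, meg_analysis, meg_synth, perturb_lab, rnn_core

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_stage", "make_report", "STAGES"]

logger = logging.getLogger("rovingnet.pipeline")

STAGES = ("simulate", "analyse", "train", "perturb", "report")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Group parameter blocks accept any :class:`~rovingnet.meg_synth.GroupAEFParams`
    field; unspecified fields fall back to the control/case defaults.
    """

    seed: int = 0
    out_dir: str = "rovingnet_run"
    control: dict = field(default_factory=dict)
    case: dict = field(default_factory=dict)
    n_trials_per_condition: int = 150
    n_channels: int = 64
    noise_sd_ft: float = 100.0
    cluster_threshold: float = 3.3
    n_permutations: int = 1000
    alpha: float = 0.05
    n_labels_per_condition: int = 1200
    label_noise_sd: float = 0.6
    train: dict = field(default_factory=dict)
    levels: tuple = perturb_lab.DEFAULT_LEVELS
    random_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        ss = np.random.SeedSequence([self.seed, sum(map(ord, stage))])
        return int(ss.generate_state(1)[0] % (2**31))

    def group_params(self, group: str) -> meg_synth.GroupAEFParams:
        base = meg_synth.CONTROL_PARAMS if group == "control" else meg_synth.CASE_PARAMS
        overrides = dict(self.control if group == "control" else self.case)
        if "frequency_latency_offsets_ms" in overrides:
            overrides["frequency_latency_offsets_ms"] = {
                float(k): float(v)
                for k, v in overrides["frequency_latency_offsets_ms"].items()
            }
        if "deviant_window_ms" in overrides:
            overrides["deviant_window_ms"] = tuple(overrides["deviant_window_ms"])
        return (
            base
            if not overrides
            else meg_synth.GroupAEFParams(**{**asdict(base), **overrides})
        )


def _stage_simulate(config: RunConfig, out: Path) -> None:
    seed = config.child_seed("simulate")
    for i, group in enumerate(("control", "case")):
        epochs = meg_synth.generate_synthetic_epochs(
            config.group_params(group),
            n_trials_per_condition=config.n_trials_per_condition,
            n_channels=config.n_channels,
            noise_sd=config.noise_sd_ft,
            seed=seed + i,
        )
        meg_synth.save_epochs(epochs, out / f"epochs_{group}.npz")
        meg_synth.channel_table(epochs).to_csv(
            out / f"channels_{group}.csv", index=False
        )


def _stage_analyse(config: RunConfig, out: Path) -> dict:
    summary = {}
    for group in ("control", "case"):
        path = out / f"epochs_{group}.npz"
        if not path.exists():
            raise PipelineError("analyse", f"missing artefact {path.name}; run simulate")
        epochs = meg_synth.load_epochs(path)
        clean = meg_analysis.preprocess_epochs(epochs)
        aef_s = meg_analysis.compute_aef(clean, "S")
        aef_d = meg_analysis.compute_aef(clean, "D")
        # group peak metrics from the standard-evoked average: deviants are
        # rare in the emulated recordings but half the synthetic trials, so
        # a pooled average would over-weight the deviant enhancement
        peak = meg_analysis.detect_peak(aef_s)
        adjacency = meg_synth.grid_adjacency(epochs.channel_positions)
        clusters = meg_analysis.cluster_permutation_test(
            clean.select("S"),
            clean.select("D"),
            adjacency,
            cluster_threshold=config.cluster_threshold,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=config.child_seed("analyse"),
        )
        meg_analysis.cluster_table(clusters).to_csv(
            out / f"clusters_{group}.csv", index=False
        )
        significant = [c for c in clusters if c.significant]
        if significant:
            top = significant[0]
            mmn_channels = list(top.channel_set)
            mmn_window = top.time_window_ms
        else:  # fall back to the generator's planted window
            params = config.group_params(group)
            gains = meg_synth.dipolar_gains(meg_synth.sensor_grid(
                int(round(np.sqrt(config.n_channels)))))
            mmn_channels = list(
                meg_synth.default_cluster_channels(epochs.channel_positions, gains)
            )
            mmn_window = params.deviant_window_ms
        mmn_wave, mmn_score = meg_analysis.compute_mmn(
            aef_s, aef_d, mmn_channels, mmn_window
        )
        cluster_mean = {
            "S": aef_s.data[mmn_channels].mean(axis=0),
            "D": aef_d.data[mmn_channels].mean(axis=0),
        }
        np.savez(
            out / f"aef_{group}.npz",
            aef_s=aef_s.data,
            aef_d=aef_d.data,
            cluster_mean_s=cluster_mean["S"],
            cluster_mean_d=cluster_mean["D"],
            mmn_waveform=mmn_wave.samples,
            t0_ms=aef_s.t0_ms,
            sampling_rate_hz=aef_s.sampling_rate_hz,
            mmn_channels=np.array(mmn_channels),
        )
        summary[group] = {
            "peak_latency_ms": peak.latency_ms,
            "peak_amplitude_ft": abs(peak.amplitude),
            "peak_channel": peak.channel,
            "n_rejected_trials": clean.n_rejected,
            "n_significant_clusters": len(significant),
            "top_cluster_p": significant[0].p_value if significant else None,
            "mmn_score_ft": mmn_score,
        }
    return summary


def _post_trigger_labels(out: Path, group: str) -> tuple:
    """Cluster-averaged per-condition AEFs on the 138-sample label grid."""
    with np.load(out / f"aef_{group}.npz") as f:
        t0 = float(f["t0_ms"])
        rate = float(f["sampling_rate_hz"])
        times = t0 + np.arange(f["cluster_mean_s"].shape[-1]) * 1000.0 / rate
        post = times >= -1e-9
        s = f["cluster_mean_s"][post][: rnn_core.N_FRAMES]
        d = f["cluster_mean_d"][post][: rnn_core.N_FRAMES]
    return (
        meg_synth.EvokedWaveform(s, 0.0, rate),
        meg_synth.EvokedWaveform(d, 0.0, rate),
    )


def _stage_train(config: RunConfig, out: Path) -> dict:
    if not (out / "aef_control.npz").exists():
        raise PipelineError("train", "missing control AEF artefact; run analyse")
    aef_s, aef_d = _post_trigger_labels(out, "control")
    seed = config.child_seed("train")
    labels = rnn_core.make_labels(
        aef_s,
        aef_d,
        n_per_condition=config.n_labels_per_condition,
        noise_sd=config.label_noise_sd,
        seed=seed,
    )
    train_cfg = rnn_core.TrainConfig(seed=seed + 3, **config.train)
    dataset = rnn_core.make_dataset(labels, seed=seed + 1, split=train_cfg.split)
    model0 = rnn_core.init_model(seed=seed + 2, dropout_rate=train_cfg.dropout)
    model, history = rnn_core.train(model0, dataset, train_cfg)
    history.to_csv(out / "loss_history.csv", index=False)
    rnn_core.save_model(model, out / "model.npz")
    np.savez(
        out / "labels.npz",
        clean_s=labels.clean_s,
        clean_d=labels.clean_d,
        center=labels.center,
        scale=labels.scale,
        flip=labels.flip,
        noise_sd=labels.noise_sd,
    )
    x_test, y_test, _ = dataset.block("test")
    test_mse = rnn_core.evaluate(model, x_test, y_test)
    pos, neg, ratio = perturb_lab.ei_ratio(model)
    return {
        "test_mse": test_mse,
        "final_train_mse": float(history.train_mse.iloc[-1]),
        "final_val_mse": float(history.val_mse.iloc[-1]),
        "ei_positive": pos,
        "ei_negative": neg,
        "ei_ratio": ratio,
    }


def _rebuild_dataset(config: RunConfig, out: Path) -> rnn_core.Dataset:
    """Reconstruct the training dataset from persisted label artefacts."""
    with np.load(out / "labels.npz") as f:
        aef_s = meg_synth.EvokedWaveform(
            f["clean_s"] * float(f["flip"]) * float(f["scale"]) + float(f["center"])
        )
        aef_d = meg_synth.EvokedWaveform(
            f["clean_d"] * float(f["flip"]) * float(f["scale"]) + float(f["center"])
        )
        noise_sd = float(f["noise_sd"])
    seed = config.child_seed("train")
    labels = rnn_core.make_labels(
        aef_s,
        aef_d,
        n_per_condition=config.n_labels_per_condition,
        noise_sd=noise_sd,
        seed=seed,
    )
    train_cfg = rnn_core.TrainConfig(seed=seed + 3, **config.train)
    return rnn_core.make_dataset(labels, seed=seed + 1, split=train_cfg.split)


def _stage_perturb(config: RunConfig, out: Path) -> dict:
    if not (out / "model.npz").exists():
        raise PipelineError("perturb", "missing model artefact; run train")
    model = rnn_core.load_model(out / "model.npz")
    dataset = _rebuild_dataset(config, out)
    baseline = rnn_core.mean_condition_predictions(model, dataset)
    base_metrics = perturb_lab.prediction_metrics(
        baseline["S"], baseline["D"], baseline["S"], baseline["D"]
    )
    tables = []
    for experiment in ("negative", "positive", "random"):
        results = perturb_lab.run_experiment(
            model,
            experiment,
            dataset,
            levels=config.levels,
            random_fraction=config.random_fraction,
            seed=config.child_seed("perturb"),
            baseline=baseline,
        )
        tables.append(perturb_lab.results_table(results))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "perturbation_results.csv", index=False)
    mse_table = table.pivot(index="experiment", columns="level", values="test_mse")
    mse_table.to_csv(out / "mse_by_level.csv")
    np.savez(out / "baseline_predictions.npz", pred_s=baseline["S"], pred_d=baseline["D"])
    return {
        "baseline": {
            k: float(v) for k, v in base_metrics.items() if not k.startswith("relative")
        },
        "n_levels": len(tuple(config.levels)),
    }


def run_stage(config: RunConfig, stage: str) -> dict:
    """Execute one pipeline stage; returns its summary fragment."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    logger.info("stage %s starting (seed %d)", stage, config.child_seed(stage))
    try:
        if stage == "simulate":
            fragment = _stage_simulate(config, out) or {}
        elif stage == "analyse":
            fragment = _stage_analyse(config, out)
        elif stage == "train":
            fragment = _stage_train(config, out)
        elif stage == "perturb":
            fragment = _stage_perturb(config, out)
        elif stage == "report":
            fragment = {"report": make_report(out)}
        else:
            raise ValueError(f"unknown stage {stage!r}")
    except PipelineError:
        raise
    except Exception as exc:  # surface the failing stage
        raise PipelineError(stage, str(exc)) from exc
    logger.info("stage %s done in %.1f s", stage, time.time() - t0)
    return fragment


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in order and write a summary JSON."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_path = out / "summary.json"
    summary = (
        json.loads(summary_path.read_text()) if summary_path.exists() else {}
    )
    summary["version"] = __version__
    summary["seed"] = config.seed
    for stage in stages:
        fragment = run_stage(config, stage)
        if fragment:
            summary[stage] = fragment
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def make_report(run_dir) -> str:
    """Human-readable summary of a (possibly partial) run directory."""
    run_dir = Path(run_dir)
    lines = [f"rovingnet run report: {run_dir}"]
    summary_path = run_dir / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        for group in ("control", "case"):
            g = summary.get("analyse", {}).get(group)
            if g:
                lines.append(
                    f"  {group}: peak {g['peak_amplitude_ft']:.0f} fT at "
                    f"{g['peak_latency_ms']:.0f} ms post-trigger, "
                    f"{g['n_significant_clusters']} significant cluster(s), "
                    f"mMMN {g['mmn_score_ft']:.1f} fT"
                )
        t = summary.get("train")
        if t:
            lines.append(
                f"  model: test MSE {t['test_mse']:.3f}, "
                f"E:I ratio {t['ei_ratio']:.3f} "
                f"({t['ei_positive']}:{t['ei_negative']})"
            )
    else:
        lines.append("  summary.json absent")
    perturb_path = run_dir / "perturbation_results.csv"
    if perturb_path.exists():
        table = pd.read_csv(perturb_path)
        for experiment, block in table.groupby("experiment"):
            levels = ", ".join(f"{v:.2f}" for v in block.test_mse)
            lines.append(
                f"  {experiment} perturbation MSE over "
                f"{len(block)} levels: {levels}"
            )
    else:
        lines.append("  perturbation stage absent")
    missing = [
        name
        for name in ("epochs_control.npz", "model.npz", "perturbation_results.csv")
        if not (run_dir / name).exists()
    ]
    if missing:
        lines.append(f"  missing artefacts: {', '.join(missing)}")
    return "\n".join(lines)
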