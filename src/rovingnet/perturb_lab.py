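"""Graded weight-perturbation experiments on the trained network.

After training, the hidden layers' recurrent weights are partitioned by
sign into excitatory (positive) and inhibitory (negative) connections.
Three experiments scale them multiplicatively at eight graded levels
(0.5% .. 4%), each applied to the pristine trained model:

* ``negative`` — every negative recurrent weight w -> w (1 - lambda):
  graded inhibition reduction (the hypothesised reduced-inhibition
  phenotype);
* ``positive`` — every positive recurrent weight w -> w (1 + lambda):
  graded excitation increase (runaway-excitation control);
* ``random``   — a seeded random half of the recurrent weights, positives
  increased and negatives reduced: balanced control.

Per level the battery records the test loss, peak amplitude/latency of the
mean standard- and deviant-input predictions, the prediction mismatch score
(mean |D - S|), and the stability of the fourth hidden layer's latent
trajectory (top-2 principal components): start-to-end distance and
convex-hull area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

from .meg_synth import EvokedWaveform
from .meg_analysis import detect_peak
from .rnn_core import (
    HIDDEN_LAYERS,
    N_FRAMES,
    Dataset,
    RNNModel,
    Spectrogram,
    evaluate,
    forward,
    mean_condition_predictions,
)

__all__ = [
    "DEFAULT_LEVELS",
    "PerturbationSpec",
    "PerturbationResult",
    "LatentTrajectory",
    "ei_ratio",
    "perturb_weights",
    "prediction_metrics",
    "extract_latents",
    "pca_project",
    "stability_metrics",
    "run_experiment",
    "results_table",
]

#: the eight-level perturbation ladder: 0.5% .. 4%
DEFAULT_LEVELS: tuple[float, ...] = tuple(0.005 * k for k in range(1, 9))

_EXPERIMENTS = ("negative", "positive", "random")


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation: which experiment, how strong, which random subset."""

    experiment: str
    level: float
    random_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {_EXPERIMENTS}"
            )
        if not 0.0 <= self.level < 1.0:
            raise ValueError("perturbation level must be in [0, 1)")
        if not 0.0 < self.random_fraction <= 1.0:
            raise ValueError("random_fraction must be in (0, 1]")


@dataclass(frozen=True)
class LatentTrajectory:
    """Top principal-component scores of a latent activation matrix."""

    scores: np.ndarray  # (2, 138)
    explained_variance_ratio: np.ndarray


@dataclass(frozen=True)
class PerturbationResult:
    experiment: str
    level: float
    test_mse: float
    peak_amplitude_s: float
    peak_latency_s_ms: float
    peak_amplitude_d: float
    peak_latency_d_ms: float
    mmn: float
    relative_increase_s: float
    relative_increase_d: float
    latent_start_end_distance: float
    latent_area: float


def ei_ratio(model: RNNModel) -> tuple[int, int, float]:
    """Excitatory:inhibitory synapse accounting on the recurrent weights.

    Counts strictly positive and strictly negative entries of the four
    hidden layers' recurrent matrices; ratio = positive / negative (inf if
    there are no negative weights).
    """
    pos = sum(int((model.W_hh[l] > 0).sum()) for l in HIDDEN_LAYERS)
    neg = sum(int((model.W_hh[l] < 0).sum()) for l in HIDDEN_LAYERS)
    ratio = pos / neg if neg else math.inf
    return pos, neg, ratio


def perturb_weights(model: RNNModel, spec: PerturbationSpec) -> RNNModel:
    """Return a perturbed copy of ``model``; the original is untouched.

    Only the four hidden layers' recurrent matrices are altered; feedforward
    weights, biases, the output unit's self-recurrence and the readout stay
    bit-identical.
    """
    out = model.copy()
    lam = spec.level
    hidden = [out.W_hh[l] for l in HIDDEN_LAYERS]
    if spec.experiment == "negative":
        for w in hidden:
            w[w < 0] *= 1.0 - lam
    elif spec.experiment == "positive":
        for w in hidden:
            w[w > 0] *= 1.0 + lam
    else:  # random subset of both signs
        sizes = [w.size for w in hidden]
        total = sum(sizes)
        n_pick = int(spec.random_fraction * total)
        rng = np.random.default_rng(spec.seed)
        picked = rng.choice(total, size=n_pick, replace=False)
        mask_flat = np.zeros(total, dtype=bool)
        mask_flat[picked] = True
        offset = 0
        for w in hidden:
            mask = mask_flat[offset : offset + w.size].reshape(w.shape)
            w[mask & (w > 0)] *= 1.0 + lam
            w[mask & (w < 0)] *= 1.0 - lam
            offset += w.size
    return out


def _as_waveform(pred: np.ndarray) -> EvokedWaveform:
    return EvokedWaveform(np.asarray(pred), t0_ms=0.0, sampling_rate_hz=250.0)


def _peak(pred: np.ndarray) -> tuple[float, float]:
    """(latency_ms, signed amplitude) of the absolute peak on the 4 ms grid.

    Uses the evoked-analysis default search window (100-300 ms
    post-trigger), the same convention applied to the sensor-space AEFs.
    """
    res = detect_peak(_as_waveform(pred))
    return res.latency_ms, res.amplitude


def prediction_metrics(
    pred_s: np.ndarray,
    pred_d: np.ndarray,
    baseline_s: np.ndarray,
    baseline_d: np.ndarray,
) -> dict[str, float]:
    """Peak, mismatch and relative-increase metrics of a prediction pair.

    Peaks follow the evoked-analysis conventions (max |value| within the
    default 100-300 ms search window, earliest-time tie-break); the
    mismatch score is the mean |D - S| over the full prediction; relative
    increases compare peak amplitudes to the pre-perturbation baseline
    predictions.
    """
    lat_s, amp_s = _peak(pred_s)
    lat_d, amp_d = _peak(pred_d)
    _, base_amp_s = _peak(baseline_s)
    _, base_amp_d = _peak(baseline_d)
    return {
        "peak_amplitude_s": amp_s,
        "peak_latency_s_ms": lat_s,
        "peak_amplitude_d": amp_d,
        "peak_latency_d_ms": lat_d,
        "mmn": float(np.abs(np.asarray(pred_d) - np.asarray(pred_s)).mean()),
        "relative_increase_s": (abs(amp_s) - abs(base_amp_s)) / abs(base_amp_s),
        "relative_increase_d": (abs(amp_d) - abs(base_amp_d)) / abs(base_amp_d),
    }


def extract_latents(model: RNNModel, spec: Spectrogram | np.ndarray) -> np.ndarray:
    """Fourth hidden layer's activation sequence (64 units x 138 frames)."""
    trace = forward(model, spec, training_mode=False)
    return trace.layer_states[HIDDEN_LAYERS[-1]]


def pca_project(latents: np.ndarray, n_components: int = 2) -> LatentTrajectory:
    """Project a units x frames activation matrix onto its top components.

    Timepoints are the observations and units the variables, so the
    trajectory lives in unit-space; scores are (n_components, 138).
    """
    latents = np.asarray(latents, dtype=float)
    if latents.ndim != 2:
        raise ValueError("latents must be a 2-D units x frames matrix")
    obs = latents.T  # frames x units
    if np.allclose(obs.var(axis=0), 0.0):
        raise ValueError("degenerate input: zero variance across timepoints")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(obs)  # (frames, n_components)
    return LatentTrajectory(
        scores=scores.T, explained_variance_ratio=pca.explained_variance_ratio_
    )


def stability_metrics(traj: LatentTrajectory) -> tuple[float, float]:
    """Start-to-end distance and convex-hull area of a 2-D latent trajectory.

    A trajectory that returns near its starting point (small distance)
    reflects transient, stable dynamics; the hull area scales with the
    overall excursion of the latent activity.
    """
    pts = np.asarray(traj.scores).T  # (frames, 2)
    if pts.shape[0] < 3:
        raise ValueError("trajectory needs at least 3 timepoints")
    dist = float(np.linalg.norm(pts[-1] - pts[0]))
    try:
        area = float(ConvexHull(pts).volume)  # 2-D hull "volume" is its area
    except QhullError:  # degenerate (collinear / constant) trajectories
        area = 0.0
    return dist, area


def _mean_latents(model: RNNModel, dataset: Dataset, split: str = "all") -> np.ndarray:
    """Layer-4 activations averaged over distinct stimulus types."""
    if split == "all":
        idx = np.arange(len(dataset.bank))
    else:
        idx = np.unique(dataset.splits[split]["idx"])
    mats = [extract_latents(model, dataset.bank[j].T) for j in idx]
    return np.mean(mats, axis=0)


def run_experiment(
    model: RNNModel,
    experiment: str,
    dataset: Dataset,
    levels=DEFAULT_LEVELS,
    random_fraction: float = 0.5,
    seed: int = 0,
    baseline: dict[str, np.ndarray] | None = None,
) -> list[PerturbationResult]:
    """Run one perturbation experiment over a ladder of levels.

    Every level perturbs the pristine trained model (levels are never
    cumulative) and is evaluated on the dataset's test split.  ``baseline``
    may supply precomputed pre-perturbation mean predictions keyed 'S'/'D'.
    """
    levels = tuple(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if baseline is None:
        baseline = mean_condition_predictions(model, dataset)
    x_test, y_test, _ = dataset.block("test")

    results = []
    for lam in levels:
        spec = PerturbationSpec(experiment, lam, random_fraction, seed)
        perturbed = model if lam == 0.0 else perturb_weights(model, spec)
        mse = evaluate(perturbed, x_test, y_test)
        preds = mean_condition_predictions(perturbed, dataset)
        metrics = prediction_metrics(
            preds["S"], preds["D"], baseline["S"], baseline["D"]
        )
        traj = pca_project(_mean_latents(perturbed, dataset))
        dist, area = stability_metrics(traj)
        results.append(
            PerturbationResult(
                experiment=experiment,
                level=lam,
                test_mse=mse,
                latent_start_end_distance=dist,
                latent_area=area,
                **metrics,
            )
        )
    return results


def results_table(results: list[PerturbationResult]) -> pd.DataFrame:
    """Flatten a result list into a levels x metrics table."""
    return pd.DataFrame([r.__dict__ for r in results])
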