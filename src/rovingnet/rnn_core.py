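"""Hierarchical recurrent network of auditory-evoked field generation.

The model maps a time-frequency encoding of a three-tone stimulus (63
spectral bins x 138 frames) through four hidden layers of 64 rectified
recurrent units to a scalar recurrent output unit, predicting the
group-level evoked response frame by frame:

    h_t = ReLU(W_hh h_{t-1} + W_xh x_t + b_h)        (per hidden layer)
    y_t = W_hy h_t + b_y                              (readout)

Targets are robust-scaled, sign-flipped group AEF templates plus Gaussian
label noise; training minimises the mean squared error over the 138 frames
with Adam.  Forward pass, backpropagation through time and the optimiser
are implemented directly in numpy, keeping every weight matrix explicit so
the perturbation stage (:mod:`rovingnet.perturb_lab`) can address the
hidden layers' recurrent weights individually.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import windows

from .meg_synth import EvokedWaveform
from .stimgen import AUDIO_RATE_HZ, StimulusTriad, synthesize_triad_waveform

try:  # optional JIT acceleration of the time-step scans
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@_njit(cache=True)
def _scan_relu_tm(pre, w_h_t):
    """h_t = relu(pre_t + h_{t-1} W_hh^T), time-major (T, B, n), h_0 = 0."""
    n_t, batch, size = pre.shape
    h = np.empty_like(pre)
    h_t = np.zeros((batch, size), dtype=np.float32)
    zero = np.float32(0.0)
    for t in range(n_t):
        h_t = np.maximum(pre[t] + h_t @ w_h_t, zero)
        h[t] = h_t
    return h


@_njit(cache=True)
def _scan_relu_grad_tm(g_h_out, relu_open, w_h):
    """Reverse-time pre-activation gradients, time-major (T, B, n)."""
    n_t, batch, size = g_h_out.shape
    g_a = np.empty_like(g_h_out)
    carry = np.zeros((batch, size), dtype=np.float32)
    for t in range(n_t - 1, -1, -1):
        g_t = (g_h_out[t] + carry) * relu_open[t]
        g_a[t] = g_t
        carry = g_t @ w_h
    return g_a


def _scan_relu(pre, w_h):
    """Batch-major wrapper around the time-major compiled scan."""
    pre_tm = np.ascontiguousarray(pre.transpose(1, 0, 2))
    h = _scan_relu_tm(pre_tm, np.ascontiguousarray(w_h.T))
    return h.transpose(1, 0, 2)


def _scan_relu_grad(g_h_out, relu_open, w_h):
    g_tm = np.ascontiguousarray(g_h_out.transpose(1, 0, 2))
    r_tm = np.ascontiguousarray(relu_open.transpose(1, 0, 2))
    g_a = _scan_relu_grad_tm(g_tm, r_tm, np.ascontiguousarray(w_h))
    return g_a.transpose(1, 0, 2)

__all__ = [
    "N_INPUT",
    "N_HIDDEN",
    "N_LAYERS",
    "N_FRAMES",
    "FRAME_STEP_MS",
    "STFT_WINDOW",
    "STFT_HOP",
    "STFT_MAG_SCALE",
    "STFT_PAD_SAMPLES",
    "TRAIN_COMBOS",
    "TEST_COMBOS",
    "Spectrogram",
    "RNNModel",
    "StateTrace",
    "LabelSet",
    "TrainConfig",
    "Dataset",
    "stft_encode",
    "spectrogram_bank",
    "make_labels",
    "init_model",
    "forward",
    "predict",
    "make_dataset",
    "train",
    "evaluate",
    "mean_condition_predictions",
    "save_model",
    "load_model",
]

N_INPUT = 63  # one-sided spectral bins of a 125-point transform
N_HIDDEN = 64
#: unit count per layer below the output unit: a 63-unit input layer and
#: four 64-unit recurrent hidden layers.  The input layer relays the
#: spectrogram through a learned linear map with rectification; it carries
#: no self-recurrence (the hidden and output layers are the recurrent
#: ones), so all perturbable temporal structure lives in the hidden stack.
LAYER_SIZES = (N_INPUT, N_HIDDEN, N_HIDDEN, N_HIDDEN, N_HIDDEN)
N_LAYERS = len(LAYER_SIZES)
#: indices of the four hidden layers (perturbation and E:I accounting
#: address these only)
HIDDEN_LAYERS = (1, 2, 3, 4)
N_FRAMES = 138
FRAME_STEP_MS = 4.0  # aligns one-to-one with the 250 Hz label grid

STFT_WINDOW = 125  # Hann window length (samples at 5000 Hz)
STFT_HOP = 20  # 125 - 105 overlap
#: magnitudes are divided by sum(hann)/2 so a unit-amplitude sinusoid at a
#: bin centre has magnitude ~1; keeps network inputs on an O(1) scale
STFT_MAG_SCALE = float(windows.hann(STFT_WINDOW, sym=False).sum() / 2.0)
#: tail zero-padding so (pad - window) / hop + 1 == 138 frames
STFT_PAD_SAMPLES = STFT_WINDOW + (N_FRAMES - 1) * STFT_HOP  # 2865

#: stimulus combinations assigned to training (standards of 250 and 500 Hz
#: plus three upward deviants) ...
TRAIN_COMBOS: tuple[tuple[float, float, float], ...] = (
    (250.0, 250.0, 250.0),
    (500.0, 500.0, 500.0),
    (250.0, 250.0, 500.0),
    (250.0, 250.0, 1000.0),
    (500.0, 500.0, 1000.0),
)
#: ... and to testing (the held-out 1000 Hz standard and downward deviants),
#: so the test probes generalisation to unseen tone combinations
TEST_COMBOS: tuple[tuple[float, float, float], ...] = (
    (1000.0, 1000.0, 1000.0),
    (500.0, 500.0, 250.0),
    (1000.0, 1000.0, 250.0),
    (1000.0, 1000.0, 500.0),
)


@dataclass(frozen=True)
class Spectrogram:
    """Non-negative time-frequency magnitudes, bins x frames."""

    magnitudes: np.ndarray  # (63, 138)
    bin_spacing_hz: float
    frame_step_ms: float
    condition: str | None = None

    def __post_init__(self):
        if self.magnitudes.shape != (N_INPUT, N_FRAMES):
            raise ValueError(
                f"expected ({N_INPUT}, {N_FRAMES}) magnitudes, "
                f"got {self.magnitudes.shape}"
            )


def stft_encode(triad: StimulusTriad) -> Spectrogram:
    """Short-time Fourier magnitude encoding of a triad waveform.

    Hann-windowed 125-sample segments with hop 20 (105-sample overlap); the
    waveform is zero-padded at the tail to 2865 samples so that exactly 138
    frames result, one per 4 ms, aligned with the 250 Hz label grid.
    """
    if triad.sampling_rate_hz != AUDIO_RATE_HZ:
        raise ValueError(
            f"triad must be sampled at {AUDIO_RATE_HZ:g} Hz, "
            f"got {triad.sampling_rate_hz:g}"
        )
    wave = np.asarray(triad.waveform, dtype=float)
    if len(wave) > STFT_PAD_SAMPLES:
        raise ValueError("waveform longer than the padded frame span")
    padded = np.zeros(STFT_PAD_SAMPLES)
    padded[: len(wave)] = wave
    win = windows.hann(STFT_WINDOW, sym=False)
    starts = np.arange(N_FRAMES) * STFT_HOP
    frames = padded[starts[:, None] + np.arange(STFT_WINDOW)] * win
    mags = np.abs(np.fft.rfft(frames, axis=1)).T / STFT_MAG_SCALE  # (63, 138)
    return Spectrogram(
        magnitudes=mags,
        bin_spacing_hz=AUDIO_RATE_HZ / STFT_WINDOW,
        frame_step_ms=FRAME_STEP_MS,
        condition=triad.condition,
    )


def spectrogram_bank(combos) -> tuple[np.ndarray, list[str]]:
    """Encode a list of frequency triples; returns (K, 138, 63) inputs."""
    mats, conds = [], []
    for combo in combos:
        spec = stft_encode(synthesize_triad_waveform(combo))
        mats.append(spec.magnitudes.T)  # frames x bins
        conds.append(spec.condition)
    return np.stack(mats), conds


@dataclass
class LabelSet:
    """Robust-scaled, flipped target waveforms and their noisy replicates."""

    clean_s: np.ndarray  # (138,)
    clean_d: np.ndarray
    labels_s: np.ndarray  # (n_per_condition, 138)
    labels_d: np.ndarray
    center: float  # median of the pooled raw templates
    scale: float  # interquartile range of the pooled raw templates
    flip: float  # +-1 applied after scaling
    noise_sd: float


def make_labels(
    aef_s: EvokedWaveform,
    aef_d: EvokedWaveform,
    n_per_condition: int = 1200,
    noise_sd: float = 0.6,
    seed: int = 0,
) -> LabelSet:
    """Build training targets from a pair of group AEF templates.

    Robust scaling (median 0, IQR 1) is fitted on the pooled S+D samples and
    applied to both; the result is sign-flipped so the dominant deflection is
    positive; each condition then receives ``n_per_condition`` replicates
    with i.i.d. Gaussian noise of standard deviation ``noise_sd``.
    """
    s = np.asarray(aef_s.samples, dtype=float)
    d = np.asarray(aef_d.samples, dtype=float)
    if s.shape != (N_FRAMES,) or d.shape != (N_FRAMES,):
        raise ValueError(f"templates must have {N_FRAMES} samples on the label grid")
    pooled = np.concatenate([s, d])
    center = float(np.median(pooled))
    q1, q3 = np.percentile(pooled, [25, 75])
    scale = float(q3 - q1)
    if scale == 0:
        raise ValueError("degenerate scale: pooled template IQR is zero")
    clean_s = (s - center) / scale
    clean_d = (d - center) / scale
    # flip so the dominant deflection points upward
    peak = clean_s[np.argmax(np.abs(clean_s))]
    flip = -1.0 if peak < 0 else 1.0
    clean_s = flip * clean_s
    clean_d = flip * clean_d

    rng = np.random.default_rng(seed)
    labels_s = clean_s[None, :] + rng.normal(0.0, noise_sd, (n_per_condition, N_FRAMES))
    labels_d = clean_d[None, :] + rng.normal(0.0, noise_sd, (n_per_condition, N_FRAMES))
    return LabelSet(clean_s, clean_d, labels_s, labels_d, center, scale, flip, noise_sd)


@dataclass
class RNNModel:
    """All weight matrices and biases of the hierarchical network.

    ``W_xh[l]``/``W_hh[l]``/``b_h[l]`` are layer ``l``'s feedforward weights,
    recurrent weights and bias; layer 0 is the 63-unit recurrent input
    layer, layers 1-4 the 64-unit hidden layers (``HIDDEN_LAYERS``).  The
    output layer is a single recurrent unit
    with identity activation whose state is the prediction:
    ``y_t = W_hy h4_t + w_oo y_{t-1} + b_y``, where ``W_hy`` are the weights
    between the last hidden layer and the output unit and ``w_oo`` its
    self-recurrence (a 1x1 orthogonal matrix, i.e. unity, at
    initialisation).  With ``output_mode="readout"`` the self-recurrence is
    held at zero, giving a pure per-frame affine readout.
    """

    W_xh: list  # [ (63,63), (64,63), (64,64) x3 ]
    W_hh: list  # [ (63,63), (64,64) x4 ]
    b_h: list  # [ (63,), (64,) x4 ]
    W_hy: np.ndarray  # (64,)
    w_oo: np.ndarray  # scalar array
    b_y: np.ndarray  # scalar array
    dropout_rate: float = 0.15
    output_mode: str = "recurrent"

    def copy(self) -> "RNNModel":
        return _copy.deepcopy(self)

    def parameters(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every trainable parameter."""
        params = {}
        for l in range(N_LAYERS):
            params[f"W_xh{l}"] = self.W_xh[l]
            params[f"W_hh{l}"] = self.W_hh[l]
            params[f"b_h{l}"] = self.b_h[l]
        params.update(W_hy=self.W_hy, w_oo=self.w_oo, b_y=self.b_y)
        return params


@dataclass
class StateTrace:
    """Per-layer hidden-state sequences and the frame-wise prediction."""

    layer_states: list  # [ (64, 138) x4 ]
    output_state: np.ndarray  # (138,)
    prediction: np.ndarray  # (138,)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def init_model(
    seed: int = 0, dropout_rate: float = 0.15, output_mode: str = "recurrent"
) -> RNNModel:
    """Initialise weights: Glorot-uniform feedforward, orthogonal recurrent
    (from a QR factorisation of a normal matrix), zero biases."""
    if output_mode not in ("recurrent", "readout"):
        raise ValueError(f"unknown output_mode {output_mode!r}")
    rng = np.random.default_rng(seed)
    W_xh, W_hh, b_h = [], [], []
    fan_in = N_INPUT
    for l, size in enumerate(LAYER_SIZES):
        W_xh.append(_glorot(rng, fan_in, size, (size, fan_in)))
        # the input layer (l = 0) is not recurrent; its W_hh stays zero
        W_hh.append(_orthogonal(rng, size) if l in HIDDEN_LAYERS else np.zeros((size, size)))
        b_h.append(np.zeros(size))
        fan_in = size
    W_hy = _glorot(rng, N_HIDDEN, 1, (N_HIDDEN,))
    # the output unit's 1x1 orthogonal recurrent init is taken as +1
    w_oo = np.array(1.0) if output_mode == "recurrent" else np.array(0.0)
    return RNNModel(
        W_xh=W_xh, W_hh=W_hh, b_h=b_h,
        W_hy=W_hy, w_oo=w_oo, b_y=np.array(0.0),
        dropout_rate=dropout_rate, output_mode=output_mode,
    )


def _forward_batch(model: RNNModel, x: np.ndarray, dropout_rng=None):
    """Run the network on a (batch, frames, bins) input block.

    Returns (prediction, output_state, last-layer dropped output, caches);
    each cache holds (layer input, hidden states, dropout mask).
    """
    batch, n_t, _ = x.shape
    rate = model.dropout_rate
    use_dropout = dropout_rng is not None and rate > 0
    keep = np.float32(1.0 - rate)

    # compute in float32 against float64 master weights
    d = np.asarray(x, dtype=np.float32)
    caches = []
    for l in range(N_LAYERS):
        w_x = model.W_xh[l].astype(np.float32)
        w_h = model.W_hh[l].astype(np.float32)
        b = model.b_h[l].astype(np.float32)
        if use_dropout and l in HIDDEN_LAYERS:
            # dropout in the hidden layers: units of the layer's input are
            # dropped from its feedforward transformation, one mask per
            # sequence (held fixed across timesteps)
            mask = (
                dropout_rng.random((batch, 1, d.shape[-1]), dtype=np.float32)
                >= rate
            )
            d_used = d * mask / keep
        else:
            mask = None
            d_used = d
        pre = d_used @ w_x.T + b  # feedforward drive for all frames at once
        h = _scan_relu(pre, w_h)  # h_0 = 0
        caches.append((d_used, h, mask))
        d = h

    pre_o = d @ model.W_hy.astype(np.float32) + np.float32(model.b_y)  # (batch, n_t)
    f = np.empty((batch, n_t), dtype=np.float32)
    s_t = np.zeros(batch, dtype=np.float32)
    w_oo = np.float32(model.w_oo)
    for t in range(n_t):
        s_t = pre_o[:, t] + w_oo * s_t
        f[:, t] = s_t
    return f, f, d, caches


def forward(
    model: RNNModel,
    spec: Spectrogram | np.ndarray,
    training_mode: bool = False,
    seed: int = 0,
) -> StateTrace:
    """Single-input forward pass returning the full state trace.

    Hidden states start at zero; dropout is applied to hidden-layer output
    sequences only when ``training_mode`` is on.
    """
    mags = spec.magnitudes if isinstance(spec, Spectrogram) else np.asarray(spec)
    if mags.shape != (N_INPUT, N_FRAMES):
        raise ValueError(f"expected ({N_INPUT}, {N_FRAMES}) input, got {mags.shape}")
    rng = np.random.default_rng(seed) if training_mode else None
    f, s, _, caches = _forward_batch(model, mags.T[None], dropout_rng=rng)
    return StateTrace(
        layer_states=[c[1][0].T for c in caches],
        output_state=s[0],
        prediction=f[0],
    )


def predict(model: RNNModel, x: np.ndarray) -> np.ndarray:
    """Deterministic predictions for a (batch, frames, bins) block."""
    f, _, _, _ = _forward_batch(model, x)
    return f.astype(np.float64)


def _backward_batch(model: RNNModel, x, y, f, s, d4, caches):
    """Backpropagation through time for one batch; returns name -> grad."""
    batch, n_t = f.shape
    grads: dict[str, np.ndarray] = {}
    g_f = 2.0 * (f - np.asarray(y, dtype=np.float32)) / np.float32(n_t * batch)

    # scalar recurrent output unit (identity activation); its state is the
    # prediction, so gradients flow back through the self-recurrence
    w_oo = np.float32(model.w_oo)
    g_s = np.empty_like(s)
    acc = np.zeros(batch, dtype=np.float32)
    for t in range(n_t - 1, -1, -1):
        acc = g_f[:, t] + w_oo * acc
        g_s[:, t] = acc
    s_prev = np.concatenate(
        [np.zeros((batch, 1), dtype=s.dtype), s[:, :-1]], axis=1
    )
    grads["w_oo"] = np.array((g_s * s_prev).sum())
    grads["b_y"] = np.array(g_s.sum())
    grads["W_hy"] = np.einsum("bt,btu->u", g_s, d4)
    if model.output_mode == "readout":
        grads["w_oo"] = np.array(0.0)
    g_d = g_s[:, :, None] * model.W_hy.astype(np.float32)[None, None, :]

    keep = np.float32(1.0 - model.dropout_rate)
    for l in range(N_LAYERS - 1, -1, -1):
        d_used, h, mask = caches[l]
        w_h = model.W_hh[l]
        size = w_h.shape[0]
        g_a = _scan_relu_grad(
            np.ascontiguousarray(g_d),
            (h > 0).astype(np.float32),
            w_h.astype(np.float32),
        )
        h_prev = np.concatenate(
            [np.zeros((batch, 1, size), dtype=h.dtype), h[:, :-1]], axis=1
        )
        g_flat = g_a.reshape(batch * n_t, size)
        grads[f"W_xh{l}"] = g_flat.T @ d_used.reshape(batch * n_t, -1)
        if l in HIDDEN_LAYERS:
            grads[f"W_hh{l}"] = g_flat.T @ h_prev.reshape(batch * n_t, size)
        else:  # the input layer carries no recurrence
            grads[f"W_hh{l}"] = np.zeros_like(model.W_hh[l])
        grads[f"b_h{l}"] = g_a.sum(axis=(0, 1))
        if l > 0:
            g_d = g_a @ model.W_xh[l].astype(np.float32)
            if mask is not None:  # back through the input dropout
                g_d = g_d * mask / keep
    return grads


class _Adam:
    """Adaptive moment estimation on a flat parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = np.asarray(grads[k], dtype=np.float64)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    epochs: int = 10
    dropout: float = 0.15
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.split) <= 0:
            raise ValueError("every split partition must be non-empty")


@dataclass
class Dataset:
    """Instances = (input combination index, noisy target waveform).

    Inputs live in a small bank of distinct spectrograms; train/validation
    instances draw combinations from the training pool, test instances from
    the held-out pool.
    """

    bank: np.ndarray  # (n_combos, 138, 63)
    bank_conditions: list  # 'S'/'D' per combo
    bank_combos: list  # frequency triples per combo
    splits: dict  # name -> dict(idx, labels, conditions)

    def block(self, split: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(inputs, targets, conditions) arrays for one split."""
        part = self.splits[split]
        return self.bank[part["idx"]], part["labels"], part["conditions"]


def make_dataset(
    labels: LabelSet,
    seed: int = 0,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> Dataset:
    """Pair every label replicate with a stimulus of its condition.

    The label replicates of each condition are split 70:15:15; train and
    validation instances are paired with uniformly drawn training-pool
    combinations, test instances with held-out-pool combinations.
    """
    combos = list(TRAIN_COMBOS) + list(TEST_COMBOS)
    bank, conds = spectrogram_bank(combos)
    train_pool = {
        c: [i for i, combo in enumerate(TRAIN_COMBOS) if conds[i] == c]
        for c in ("S", "D")
    }
    test_pool = {
        c: [
            len(TRAIN_COMBOS) + j
            for j in range(len(TEST_COMBOS))
            if conds[len(TRAIN_COMBOS) + j] == c
        ]
        for c in ("S", "D")
    }

    rng = np.random.default_rng(seed)
    parts: dict[str, dict] = {
        k: {"idx": [], "labels": [], "conditions": []}
        for k in ("train", "val", "test")
    }
    for cond, reps in (("S", labels.labels_s), ("D", labels.labels_d)):
        n = reps.shape[0]
        order = rng.permutation(n)
        n_test = int(round(split[2] * n))
        n_val = int(round(split[1] * n))
        sections = {
            "test": order[:n_test],
            "val": order[n_test : n_test + n_val],
            "train": order[n_test + n_val :],
        }
        for name, rows in sections.items():
            pool = test_pool[cond] if name == "test" else train_pool[cond]
            drawn = rng.choice(pool, size=len(rows))
            parts[name]["idx"].append(drawn)
            parts[name]["labels"].append(reps[rows])
            parts[name]["conditions"].append(np.full(len(rows), cond))

    splits = {}
    for name, p in parts.items():
        if not p["idx"] or sum(len(a) for a in p["idx"]) == 0:
            raise ValueError(f"split partition {name!r} is empty")
        splits[name] = {
            "idx": np.concatenate(p["idx"]),
            "labels": np.concatenate(p["labels"]),
            "conditions": np.concatenate(p["conditions"]),
        }
    return Dataset(bank=bank, bank_conditions=conds, bank_combos=combos, splits=splits)


def train(
    model: RNNModel, dataset: Dataset, config: TrainConfig = TrainConfig()
) -> tuple[RNNModel, pd.DataFrame]:
    """Train a copy of ``model`` on the dataset's training split.

    Records per-epoch training MSE (dropout active, averaged over batches)
    and validation MSE (dropout off).  Returns the trained copy and the loss
    history as a table with columns epoch/train_mse/val_mse.
    """
    model = model.copy()
    model.dropout_rate = config.dropout
    params = model.parameters()
    opt = _Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    x_val, y_val, _ = dataset.block("val")
    idx_train = dataset.splits["train"]["idx"]
    y_train = dataset.splits["train"]["labels"]
    n_train = len(idx_train)

    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        batch_losses = []
        for start in range(0, n_train, config.batch_size):
            rows = order[start : start + config.batch_size]
            x = dataset.bank[idx_train[rows]]
            y = y_train[rows]
            f, s, d4, caches = _forward_batch(model, x, dropout_rng=rng)
            batch_losses.append(float(np.mean((f - y) ** 2)))
            grads = _backward_batch(model, x, y, f, s, d4, caches)
            if config.learning_rate > 0:
                opt.step(params, grads)
        val_mse = evaluate(model, x_val, y_val)
        history.append(
            {
                "epoch": epoch + 1,
                "train_mse": float(np.mean(batch_losses)),
                "val_mse": val_mse,
            }
        )
    return model, pd.DataFrame(history)


def evaluate(model: RNNModel, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
    """Mean squared error over a (batch, frames, bins) block, dropout off."""
    total, count = 0.0, 0
    for start in range(0, len(x), batch_size):
        f = predict(model, x[start : start + batch_size])
        yb = y[start : start + batch_size]
        total += float(((f - yb) ** 2).sum())
        count += yb.size
    return total / count


def mean_condition_predictions(
    model: RNNModel, dataset: Dataset, split: str = "all"
) -> dict[str, np.ndarray]:
    """Mean prediction per condition, each stimulus type weighted equally.

    With ``split="all"`` (default) the average runs over every distinct
    stimulus type, training and held-out pools alike; naming a split
    restricts it to that split's types.
    """
    if split == "all":
        idx = np.arange(len(dataset.bank))
    else:
        idx = np.unique(dataset.splits[split]["idx"])
    preds = predict(model, dataset.bank[idx])
    out = {}
    for cond in ("S", "D"):
        rows = [i for i, j in enumerate(idx) if dataset.bank_conditions[j] == cond]
        out[cond] = preds[rows].mean(axis=0)
    return out


def save_model(model: RNNModel, path) -> None:
    """Serialise model parameters to a named-array .npz container."""
    arrays = {k: np.asarray(v) for k, v in model.parameters().items()}
    arrays["dropout_rate"] = np.array(model.dropout_rate)
    arrays["output_mode"] = np.array(model.output_mode)
    arrays["format_version"] = np.array(1)
    np.savez(path, **arrays)


def load_model(path) -> RNNModel:
    with np.load(path, allow_pickle=False) as f:
        return RNNModel(
            W_xh=[f[f"W_xh{l}"] for l in range(N_LAYERS)],
            W_hh=[f[f"W_hh{l}"] for l in range(N_LAYERS)],
            b_h=[f[f"b_h{l}"] for l in range(N_LAYERS)],
            W_hy=f["W_hy"],
            w_oo=f["w_oo"],
            b_y=f["b_y"],
            dropout_rate=float(f["dropout_rate"]),
            output_mode=str(f["output_mode"]),
        )
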