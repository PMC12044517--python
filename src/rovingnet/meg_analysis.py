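"""Sensor-space analysis: preprocessing, evoked averaging, peak metrics,
spatio-temporal cluster-based permutation testing and mismatch scoring.

The cluster test controls the family-wise error rate over channels x time
by thresholding per-point Welch t statistics, summing them within
spatio-temporally connected clusters, and comparing observed cluster masses
against a permutation null of per-permutation maxima (condition labels
permuted across trials).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, sparse
from scipy.sparse import csgraph

from .meg_synth import EpochsSet, EvokedWaveform

__all__ = [
    "PreprocessConfig",
    "EvokedArray",
    "ClusterResult",
    "PeakResult",
    "EmptyResultError",
    "preprocess_epochs",
    "compute_aef",
    "detect_peak",
    "welch_t",
    "find_clusters",
    "cluster_permutation_test",
    "compute_mmn",
    "cluster_table",
]


class EmptyResultError(RuntimeError):
    """No trials survived a selection or rejection step."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    Pipeline order: zero-phase low-pass filter -> downsample to
    ``target_rate_hz`` -> baseline-correct -> peak-to-peak trial rejection.
    """

    lowpass_hz: float = 30.0
    filter_order: int = 4
    target_rate_hz: float = 250.0
    baseline_window_ms: tuple[float, float] = (-400.0, 0.0)
    reject_max_ptp_ft: float = 4000.0
    reject_min_ptp_ft: float = 1.0

    def __post_init__(self):
        if self.lowpass_hz >= self.target_rate_hz / 2.0:
            raise ValueError("low-pass cutoff must be below target Nyquist")


@dataclass
class EvokedArray:
    """Per-channel evoked responses: (n_channels, n_times) on one grid."""

    data: np.ndarray
    t0_ms: float
    sampling_rate_hz: float

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[1]
        return self.t0_ms + np.arange(n) * 1000.0 / self.sampling_rate_hz

    def channel(self, index: int) -> EvokedWaveform:
        return EvokedWaveform(
            self.data[index], t0_ms=self.t0_ms, sampling_rate_hz=self.sampling_rate_hz
        )


@dataclass(frozen=True)
class ClusterResult:
    """One spatio-temporal cluster of suprathreshold S-vs-D differences."""

    channel_set: tuple[int, ...]
    time_window_ms: tuple[float, float]
    cluster_statistic: float
    p_value: float
    sign: int
    significant: bool


@dataclass(frozen=True)
class PeakResult:
    latency_ms: float
    amplitude: float
    channel: int | None = None


def preprocess_epochs(epochs: EpochsSet, config: PreprocessConfig | None = None) -> EpochsSet:
    """Filter, downsample, baseline-correct and reject trials.

    Raises :class:`EmptyResultError` if every trial is rejected.
    """
    if config is None:
        config = PreprocessConfig()
    rate = epochs.sampling_rate_hz
    if rate < 2.0 * config.lowpass_hz:
        raise ValueError("epoch rate below twice the low-pass cutoff")

    sos = signal.butter(
        config.filter_order, config.lowpass_hz, btype="low", fs=rate, output="sos"
    )
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)

    decim = rate / config.target_rate_hz
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError("target rate must evenly divide the raw rate")
    decim = int(round(decim))
    data = data[..., ::decim]
    times = epochs.t0_ms + np.arange(data.shape[-1]) * 1000.0 / config.target_rate_hz

    lo, hi = config.baseline_window_ms
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError("baseline window outside the epoch span")
    base = (times >= lo) & (times <= hi)
    data = data - data[..., base].mean(axis=-1, keepdims=True)

    ptp = data.max(axis=-1) - data.min(axis=-1)  # (n_trials, n_channels)
    too_big = (ptp > config.reject_max_ptp_ft).any(axis=1)
    too_flat = (ptp < config.reject_min_ptp_ft).all(axis=1)
    keep = ~(too_big | too_flat)
    if not keep.any():
        raise EmptyResultError(
            f"all {len(keep)} trials rejected "
            f"({int(too_big.sum())} over {config.reject_max_ptp_ft} fT, "
            f"{int(too_flat.sum())} flat)"
        )
    return replace(
        epochs,
        data=np.ascontiguousarray(data[keep]),
        conditions=epochs.conditions[keep],
        sampling_rate_hz=config.target_rate_hz,
        n_rejected=int((~keep).sum()),
    )


def compute_aef(epochs: EpochsSet, condition: str = "all") -> EvokedArray:
    """Per-channel trial average (the auditory-evoked field)."""
    if condition == "all":
        data = epochs.data
    elif condition in ("S", "D"):
        data = epochs.data[epochs.conditions == condition]
    else:
        raise ValueError(f"condition must be 'S', 'D' or 'all', got {condition!r}")
    if data.shape[0] == 0:
        raise EmptyResultError(f"no trials of condition {condition!r}")
    return EvokedArray(
        data.mean(axis=0), t0_ms=epochs.t0_ms, sampling_rate_hz=epochs.sampling_rate_hz
    )


def detect_peak(
    evoked: EvokedWaveform | EvokedArray,
    search_window_ms: tuple[float, float] = (100.0, 300.0),
) -> PeakResult:
    """Latency and signed value of the maximum-|value| sample in a window.

    Ties break toward the earliest time.  For multichannel input the
    channel with the globally largest |value| inside the window is selected
    first.
    """
    times = evoked.times_ms
    lo, hi = search_window_ms
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError("search window outside the waveform span")
    win = (times >= lo) & (times <= hi)

    if isinstance(evoked, EvokedArray):
        seg = evoked.data[:, win]
        chan = int(np.argmax(np.abs(seg).max(axis=1)))
        idx = int(np.argmax(np.abs(seg[chan])))
        return PeakResult(
            latency_ms=float(times[win][idx]),
            amplitude=float(seg[chan, idx]),
            channel=chan,
        )
    seg = np.asarray(evoked.samples)[win]
    idx = int(np.argmax(np.abs(seg)))  # argmax returns the first maximum
    return PeakResult(latency_ms=float(times[win][idx]), amplitude=float(seg[idx]))


def welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sample unequal-variance t statistic along axis 0."""
    nx, ny = x.shape[0], y.shape[0]
    vx = x.var(axis=0, ddof=1) / nx
    vy = y.var(axis=0, ddof=1) / ny
    denom = np.sqrt(vx + vy)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(axis=0) - y.mean(axis=0)) / denom
    return np.where(denom == 0, 0.0, t)


def _adjacency_pairs(adjacency: sparse.spmatrix, n_channels: int) -> np.ndarray:
    adj = sparse.coo_matrix(adjacency)
    if adj.shape != (n_channels, n_channels):
        raise ValueError("adjacency must be n_channels x n_channels")
    mask = adj.row < adj.col
    return np.column_stack([adj.row[mask], adj.col[mask]])


def find_clusters(
    stat_map: np.ndarray,
    threshold: float,
    adjacency: sparse.spmatrix,
) -> list[tuple[np.ndarray, np.ndarray, float, int]]:
    """Group suprathreshold (channel, time) points into connected clusters.

    Positive (stat > threshold) and negative (stat < -threshold) exceedances
    form separate clusters.  Points are connected through channel adjacency
    at the same timepoint or consecutive timepoints at the same channel.
    Returns (channels, time_indices, mass, sign) per cluster.
    """
    if threshold <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    n_ch, n_t = stat_map.shape
    pairs = _adjacency_pairs(adjacency, n_ch)
    out = []
    for sign in (1, -1):
        mask = stat_map > threshold if sign == 1 else stat_map < -threshold
        if not mask.any():
            continue
        node_id = -np.ones((n_ch, n_t), dtype=np.int64)
        ch_idx, t_idx = np.nonzero(mask)
        node_id[ch_idx, t_idx] = np.arange(ch_idx.size)

        rows, cols = [], []
        # temporal edges: same channel, consecutive samples
        both = mask[:, :-1] & mask[:, 1:]
        r, c = np.nonzero(both)
        rows.append(node_id[r, c])
        cols.append(node_id[r, c + 1])
        # spatial edges: adjacent channels, same sample
        if pairs.size:
            both = mask[pairs[:, 0]] & mask[pairs[:, 1]]
            p, t = np.nonzero(both)
            rows.append(node_id[pairs[p, 0], t])
            cols.append(node_id[pairs[p, 1], t])
        n_nodes = ch_idx.size
        graph = sparse.coo_matrix(
            (
                np.ones(sum(len(r) for r in rows)),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(n_nodes, n_nodes),
        )
        n_comp, comp = csgraph.connected_components(graph, directed=False)
        for k in range(n_comp):
            member = comp == k
            chs = ch_idx[member]
            ts = t_idx[member]
            mass = float(stat_map[chs, ts].sum())
            out.append((chs, ts, mass, sign))
    return out


def cluster_permutation_test(
    epochs_s: EpochsSet,
    epochs_d: EpochsSet,
    adjacency: sparse.spmatrix,
    cluster_threshold: float = 3.3,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[ClusterResult]:
    """Spatio-temporal cluster-based permutation test between conditions.

    The null distribution records, per permutation of trial condition
    labels, the maximum |cluster mass|; p-values use the
    ``(1 + exceedances) / (1 + n_permutations)`` estimator.
    """
    if epochs_s.n_trials == 0 or epochs_d.n_trials == 0:
        raise EmptyResultError("both conditions need at least one trial")
    if n_permutations < 100:
        import warnings

        warnings.warn(
            f"n_permutations={n_permutations} is low; p-value resolution is coarse",
            stacklevel=2,
        )
    n_s = epochs_s.n_trials
    x = np.concatenate([epochs_s.data, epochs_d.data], axis=0)
    n_total, n_ch, n_t = x.shape
    times = epochs_s.times_ms

    t_obs = welch_t(x[:n_s], x[n_s:])
    clusters = find_clusters(t_obs, cluster_threshold, adjacency)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(n_total)
        t_perm = welch_t(x[perm[:n_s]], x[perm[n_s:]])
        perm_clusters = find_clusters(t_perm, cluster_threshold, adjacency)
        if perm_clusters:
            null_max[i] = max(abs(m) for _, _, m, _ in perm_clusters)

    results = []
    for chs, ts, mass, sign in clusters:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_permutations)
        results.append(
            ClusterResult(
                channel_set=tuple(sorted(set(int(c) for c in chs))),
                time_window_ms=(float(times[ts.min()]), float(times[ts.max()])),
                cluster_statistic=mass,
                p_value=float(p),
                sign=sign,
                significant=bool(p <= alpha),
            )
        )
    results.sort(key=lambda r: abs(r.cluster_statistic), reverse=True)
    return results


def compute_mmn(
    aef_s: EvokedArray,
    aef_d: EvokedArray,
    channel_set,
    time_window_ms: tuple[float, float],
) -> tuple[EvokedWaveform, float]:
    """Mismatch response: channel-averaged D-S difference and its MAE score.

    The score is the mean of |D - S| over ``channel_set`` x
    ``time_window_ms``; the returned waveform is the channel-averaged
    difference over the full epoch.
    """
    channel_set = np.asarray(list(channel_set), dtype=int)
    if channel_set.size == 0:
        raise ValueError("channel_set must be non-empty")
    diff = aef_d.data[channel_set] - aef_s.data[channel_set]
    waveform = EvokedWaveform(
        diff.mean(axis=0), t0_ms=aef_s.t0_ms, sampling_rate_hz=aef_s.sampling_rate_hz
    )
    times = aef_s.times_ms
    lo, hi = time_window_ms
    win = (times >= lo) & (times <= hi)
    if not win.any():
        raise ValueError("time window contains no samples")
    score = float(np.abs(diff[:, win]).mean())
    return waveform, score


def cluster_table(results: list[ClusterResult]):
    """Cluster list as a delimited-text-ready table."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sign": [r.sign for r in results],
            "n_channels": [len(r.channel_set) for r in results],
            "t_start_ms": [r.time_window_ms[0] for r in results],
            "t_end_ms": [r.time_window_ms[1] for r in results],
            "stat": [r.cluster_statistic for r in results],
            "p": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
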