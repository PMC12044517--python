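"""Preprocessing, evoked averaging, peak detection, cluster permutation
testing and mismatch scoring."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import sparse, stats

from rovingnet import meg_analysis, meg_synth
from rovingnet.meg_analysis import (
    EmptyResultError,
    EvokedArray,
    PreprocessConfig,
    cluster_permutation_test,
    compute_aef,
    compute_mmn,
    detect_peak,
    find_clusters,
    preprocess_epochs,
    welch_t,
)
from rovingnet.meg_synth import CONTROL_PARAMS, EvokedWaveform


def _noisy_epochs(n_per_cond=20, n_channels=16, noise=50.0, seed=0, **kwargs):
    return meg_synth.generate_synthetic_epochs(
        CONTROL_PARAMS,
        n_trials_per_condition=n_per_cond,
        n_channels=n_channels,
        noise_sd=noise,
        seed=seed,
        **kwargs,
    )


class TestPreprocess:
    def test_downsampled_span(self):
        out = preprocess_epochs(_noisy_epochs())
        assert out.data.shape[-1] == 238  # -400..548 ms at 250 Hz
        assert out.sampling_rate_hz == 250.0
        assert out.times_ms[0] == -400.0

    def test_baseline_mean_is_zero(self):
        out = preprocess_epochs(_noisy_epochs(seed=2))
        base = (out.times_ms >= -400.0) & (out.times_ms <= 0.0)
        means = out.data[..., base].mean(axis=-1)
        assert np.abs(means).max() < 1e-9 * np.abs(out.data).max()

    def test_low_frequency_amplitude_preserved(self):
        # a 5 Hz sinusoid passes the 30 Hz low-pass with < 1% amplitude change
        epochs = _noisy_epochs(n_per_cond=1, noise=0.0)
        t = epochs.times_ms / 1000.0
        epochs.data[...] = 100.0 * np.sin(2 * np.pi * 5.0 * t)[None, None, :]
        out = preprocess_epochs(epochs)
        mid = out.data[0, 0][(out.times_ms > -300) & (out.times_ms < 450)]
        assert np.abs(mid).max() == pytest.approx(100.0, rel=0.01)

    def test_large_amplitude_trial_rejected(self):
        epochs = _noisy_epochs(n_per_cond=5, seed=3)
        epochs.data[2, 4, 500:520] += 5000.0  # square pulse on one channel
        out = preprocess_epochs(epochs)
        assert out.n_trials == 9
        assert out.n_rejected == 1

    def test_flat_trial_rejected(self):
        epochs = _noisy_epochs(n_per_cond=5, seed=4)
        epochs.data[3] = 0.0  # flat at every channel
        out = preprocess_epochs(epochs)
        assert out.n_rejected == 1

    def test_all_trials_rejected_raises_with_counts(self):
        epochs = _noisy_epochs(n_per_cond=2, noise=0.0)
        epochs.data[...] = 0.0
        with pytest.raises(EmptyResultError, match="4 trials"):
            preprocess_epochs(epochs)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            PreprocessConfig(lowpass_hz=130.0)
        epochs = _noisy_epochs(n_per_cond=2)
        with pytest.raises(ValueError, match="baseline"):
            preprocess_epochs(epochs, PreprocessConfig(baseline_window_ms=(-900, 0)))


class TestComputeAEF:
    def test_mean_equals_direct_summation_oracle(self, rng):
        epochs = _noisy_epochs(n_per_cond=7, seed=5)
        aef = compute_aef(epochs, "all")
        # brute-force per-sample average
        expected = np.zeros(epochs.data.shape[1:])
        for trial in epochs.data:
            expected += trial
        expected /= epochs.n_trials
        assert np.allclose(aef.data, expected)

    def test_noise_free_average_is_gain_times_template(self, noiseless_epochs):
        aef = compute_aef(noiseless_epochs, "S")
        template = meg_synth.generate_group_aef(
            CONTROL_PARAMS, "S", times_ms=noiseless_epochs.times_ms
        ).samples
        expected = noiseless_epochs.channel_gains[:, None] * template[None, :]
        assert np.allclose(aef.data, expected)

    def test_grand_average_is_count_weighted_mean(self):
        epochs = _noisy_epochs(n_per_cond=4, seed=6)
        epochs = replace(
            epochs,
            data=epochs.data[1:],
            conditions=epochs.conditions[1:],
        )  # 3 S, 4 D: unbalanced
        aef_all = compute_aef(epochs, "all")
        aef_s = compute_aef(epochs, "S")
        aef_d = compute_aef(epochs, "D")
        weighted = (3 * aef_s.data + 4 * aef_d.data) / 7
        assert np.allclose(aef_all.data, weighted)

    def test_no_trials_raises(self, noiseless_epochs):
        empty = replace(
            noiseless_epochs,
            data=noiseless_epochs.data[:0],
            conditions=noiseless_epochs.conditions[:0],
        )
        with pytest.raises(EmptyResultError):
            compute_aef(empty, "all")


class TestDetectPeak:
    def test_injected_bump_found_at_its_centre(self):
        times = np.arange(0, 548, 4.0)
        bump = 7.0 * np.exp(-0.5 * ((times - 160.0) / 20.0) ** 2)
        res = detect_peak(EvokedWaveform(bump), (100, 300))
        assert res.latency_ms == 160.0
        assert res.amplitude == pytest.approx(7.0)

    def test_tie_breaks_to_earliest_time(self):
        times = np.arange(0, 548, 4.0)
        samples = np.zeros_like(times)
        samples[times == 140.0] = -5.0
        samples[times == 160.0] = 5.0
        res = detect_peak(EvokedWaveform(samples), (100, 300))
        assert res.latency_ms == 140.0
        assert res.amplitude == -5.0

    def test_multichannel_selects_globally_largest_channel(self):
        data = np.zeros((3, 138))
        data[1, 40] = -9.0  # 160 ms, largest magnitude
        data[2, 30] = 5.0
        res = detect_peak(EvokedArray(data, 0.0, 250.0), (100, 300))
        assert res.channel == 1
        assert res.latency_ms == 160.0

    def test_control_synthetic_grand_average_peak(self):
        epochs = preprocess_epochs(_noisy_epochs(n_per_cond=50, seed=8))
        res = detect_peak(compute_aef(epochs, "S"))
        assert res.latency_ms == pytest.approx(144.0, abs=4.0)
        assert abs(res.amplitude) == pytest.approx(181.0, rel=0.1)

    def test_window_outside_span_raises(self):
        with pytest.raises(ValueError):
            detect_peak(EvokedWaveform(np.zeros(138)), (500, 600))


class TestWelchT:
    def test_matches_scipy_oracle(self, rng):
        x = rng.standard_normal((12, 4, 9))
        y = 0.3 + 1.7 * rng.standard_normal((17, 4, 9))
        ours = welch_t(x, y)
        ref = stats.ttest_ind(x, y, axis=0, equal_var=False).statistic
        assert np.allclose(ours, ref)


def _bfs_clusters(mask, adj):
    """Exhaustive connected-components oracle over a boolean mask."""
    n_ch, n_t = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    clusters = []
    for c0 in range(n_ch):
        for t0 in range(n_t):
            if mask[c0, t0] and not seen[c0, t0]:
                comp, queue = [], [(c0, t0)]
                seen[c0, t0] = True
                while queue:
                    c, t = queue.pop()
                    comp.append((c, t))
                    neighbours = [(c, t - 1), (c, t + 1)] + [
                        (c2, t) for c2 in range(n_ch) if adj[c, c2]
                    ]
                    for c2, t2 in neighbours:
                        if (
                            0 <= c2 < n_ch
                            and 0 <= t2 < n_t
                            and mask[c2, t2]
                            and not seen[c2, t2]
                        ):
                            seen[c2, t2] = True
                            queue.append((c2, t2))
                clusters.append(frozenset(comp))
    return set(clusters)


class TestFindClusters:
    def test_matches_bfs_oracle_on_random_instances(self, rng):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)  # chain
        adjacency = sparse.csr_matrix(adj)
        for _ in range(100):
            stat = rng.standard_normal((3, 10)) * 3.0
            found = find_clusters(stat, 2.0, adjacency)
            for sign in (1, -1):
                mask = stat > 2.0 if sign == 1 else stat < -2.0
                expected = _bfs_clusters(mask, adj)
                ours = {
                    frozenset(zip(chs.tolist(), ts.tolist()))
                    for chs, ts, _, s in found
                    if s == sign
                }
                assert ours == expected
                # cluster mass equals the sum of member statistics
                for chs, ts, mass, s in found:
                    if s == sign:
                        assert mass == pytest.approx(stat[chs, ts].sum())

    def test_threshold_must_be_positive(self):
        adjacency = sparse.csr_matrix(np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            find_clusters(np.zeros((2, 5)), 0.0, adjacency)


class TestClusterPermutationTest:
    def test_planted_effect_recovered(self):
        epochs = preprocess_epochs(_noisy_epochs(n_per_cond=150, seed=9))
        gains = meg_synth.dipolar_gains(epochs.channel_positions)
        planted = meg_synth.default_cluster_channels(epochs.channel_positions, gains)
        adjacency = meg_synth.grid_adjacency(epochs.channel_positions)
        results = cluster_permutation_test(
            epochs.select("S"),
            epochs.select("D"),
            adjacency,
            n_permutations=200,
            seed=1,
        )
        significant = [r for r in results if r.significant]
        assert significant
        top = significant[0]
        assert set(top.channel_set) & set(planted.tolist())
        lo, hi = CONTROL_PARAMS.deviant_window_ms
        assert top.time_window_ms[0] <= hi and top.time_window_ms[1] >= lo

    def test_huge_threshold_gives_empty_result(self):
        epochs = preprocess_epochs(_noisy_epochs(n_per_cond=10, seed=10))
        adjacency = meg_synth.grid_adjacency(epochs.channel_positions)
        results = cluster_permutation_test(
            epochs.select("S"),
            epochs.select("D"),
            adjacency,
            cluster_threshold=1e6,
            n_permutations=100,
            seed=0,
        )
        assert results == []

    def test_low_permutation_count_warns(self):
        epochs = preprocess_epochs(_noisy_epochs(n_per_cond=5, seed=11))
        adjacency = meg_synth.grid_adjacency(epochs.channel_positions)
        with pytest.warns(UserWarning, match="n_permutations"):
            cluster_permutation_test(
                epochs.select("S"),
                epochs.select("D"),
                adjacency,
                n_permutations=50,
                seed=0,
            )

    def test_matches_mne_observed_cluster_masses(self):
        # independent cross-check of the cluster machinery: identical
        # threshold and statistic, compared on observed cluster masses
        mne_stats = pytest.importorskip("mne.stats")
        epochs = preprocess_epochs(_noisy_epochs(n_per_cond=40, n_channels=16, seed=12))
        adjacency = meg_synth.grid_adjacency(epochs.channel_positions)
        xs = epochs.select("S").data
        xd = epochs.select("D").data
        ours = cluster_permutation_test(
            epochs.select("S"), epochs.select("D"), adjacency,
            cluster_threshold=3.3, n_permutations=100, seed=0,
        )

        _, clusters, _, _ = mne_stats.spatio_temporal_cluster_test(
            [xs.transpose(0, 2, 1), xd.transpose(0, 2, 1)],
            threshold=3.3,
            n_permutations=2,
            adjacency=adjacency,
            stat_fun=welch_t,  # pointwise statistic, chunk-shape agnostic
            tail=0,
            out_type="mask",
            seed=0,
            verbose="error",
        )
        t_obs = welch_t(xs, xd)
        mne_masses = sorted(
            float(t_obs[m.T].sum()) for m in clusters
        )
        our_masses = sorted(r.cluster_statistic for r in ours)
        assert np.allclose(our_masses, mne_masses, atol=1e-8)


class TestComputeMMN:
    def _pair(self, rng):
        s = EvokedArray(rng.standard_normal((6, 138)), 0.0, 250.0)
        d = EvokedArray(rng.standard_normal((6, 138)), 0.0, 250.0)
        return s, d

    def test_identical_inputs_score_zero(self, rng):
        s, _ = self._pair(rng)
        wave, score = compute_mmn(s, s, [0, 1, 2], (100, 300))
        assert score == 0.0
        assert not wave.samples.any()

    def test_constant_offset_scores_its_magnitude(self, rng):
        s, _ = self._pair(rng)
        d = EvokedArray(s.data - 2.5, 0.0, 250.0)
        _, score = compute_mmn(s, d, [0, 3], (0, 548))
        assert score == pytest.approx(2.5)

    def test_matches_double_loop_oracle(self, rng):
        s, d = self._pair(rng)
        channels = [1, 2, 5]
        window = (120.0, 260.0)
        _, score = compute_mmn(s, d, channels, window)
        times = s.times_ms
        total, count = 0.0, 0
        for c in channels:
            for i, t in enumerate(times):
                if window[0] <= t <= window[1]:
                    total += abs(d.data[c, i] - s.data[c, i])
                    count += 1
        assert score == pytest.approx(total / count)

    def test_score_nonnegative_and_zero_only_on_agreement(self, rng):
        s, d = self._pair(rng)
        _, score = compute_mmn(s, d, [0], (0, 548))
        assert score > 0.0

    def test_empty_channel_set_rejected(self, rng):
        s, d = self._pair(rng)
        with pytest.raises(ValueError):
            compute_mmn(s, d, [], (100, 200))
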