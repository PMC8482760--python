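import math

import numpy as np
import pytest

from nanopulse.physics import NoisePSDParams, blockade_amplitude, noise_rms, open_pore_current
from nanopulse.simulate import (
    DriftConfig,
    Event,
    EventTable,
    JumpConfig,
    SimCondition,
    SimSettings,
    condition_grid,
    default_grid,
    generate_dataset,
    generate_trace,
    sample_events,
    spike_waveform,
    synth_baseline,
    synth_colored_noise,
)


class TestSampleEvents:
    def test_zero_concentration_empty(self, settings, rng):
        cond = SimCondition(0.0, 10.0, 1.0, 4.0, trace_length_s=5.0)
        assert len(sample_events(cond, rng, settings)) == 0

    def test_binomial_mean(self, settings):
        # oracle: Binomial mean k_cap * C * T = 20 * 1 * 100 = 2000
        cond = SimCondition(1.0, 10.0, 1.0, 4.0, trace_length_s=100.0)
        counts = [len(sample_events(cond, np.random.default_rng(s), settings))
                  for s in range(200)]
        n_steps = cond.n_samples
        p = 20.0 * 1.0 / cond.fs_Hz
        mean, sd = n_steps * p, math.sqrt(n_steps * p * (1 - p))
        se = sd / math.sqrt(len(counts))
        assert abs(np.mean(counts) - mean) < 3 * se + 2  # +2 for end-of-trace drops

    def test_sorted_and_in_range(self, settings, rng):
        cond = SimCondition(0.8, 10.0, 1.0, 4.0, trace_length_s=10.0)
        table = sample_events(cond, rng, settings)
        starts = [e.t_start_s for e in table]
        assert starts == sorted(starts)
        assert all(0 <= e.t_start_s and e.t_end_s <= 10.0 for e in table)

    def test_excessive_rate_rejected(self, rng):
        cond = SimCondition(1.0, 10.0, 1.0, 4.0, trace_length_s=1.0, fs_Hz=10.0)
        with pytest.raises(ValueError):
            sample_events(cond, rng, SimSettings(k_cap_per_s_nM=100.0))

    def test_variance_to_mean_ratio(self, settings):
        # counts ~ Binomial(n, p): var/mean = 1 - p (close to 1 here)
        cond = SimCondition(1.0, 10.0, 0.5, 4.0, trace_length_s=20.0)
        counts = np.array([
            len(sample_events(cond, np.random.default_rng(1000 + s), settings))
            for s in range(300)
        ])
        ratio = counts.var() / counts.mean()
        assert 0.8 < ratio < 1.2


class TestSpikeWaveform:
    def test_apex_equals_amplitude(self):
        ev = Event(0.0, 2.0, 0.45, 0.3)
        w = spike_waveform(ev, 10_000.0)
        assert w.max() == pytest.approx(0.45, rel=1e-12)
        assert w.size == 20

    def test_symmetric_for_central_apex(self):
        ev = Event(0.0, 2.1, 1.0, 0.5)  # 21 samples, odd
        w = spike_waveform(ev, 10_000.0)
        assert np.allclose(w, w[::-1])

    def test_area_matches_triangle(self):
        ev = Event(0.0, 5.0, 0.8, 0.4)
        fs = 10_000.0
        w = spike_waveform(ev, fs)
        area = w.sum() / fs
        expected = 0.5 * 0.8 * 5.0e-3
        assert area == pytest.approx(expected, rel=0.05)

    def test_degenerate_duration_rejected(self):
        with pytest.raises(ValueError):
            spike_waveform(Event(0.0, 0.1, 1.0, 0.5), 10_000.0)


class TestColoredNoise:
    def test_zero_psd_gives_zeros(self, rng):
        p = NoisePSDParams(a_flicker=0, a_electrode=0, a_white=0, a_dielectric=0)
        y = synth_colored_noise(p, 4096, 10_000.0, rng)
        assert np.allclose(y, 0.0)

    def test_rms_matches_quadrature(self, rng):
        p = NoisePSDParams()
        y = synth_colored_noise(p, 2**20, 10_000.0, rng)
        assert y.std() == pytest.approx(noise_rms(p), rel=0.03)

    def test_zero_mean_gaussian(self, rng):
        p = NoisePSDParams()
        y = synth_colored_noise(p, 2**18, 10_000.0, rng)
        assert abs(y.mean()) < 0.05 * y.std()
        # fourth-moment check against Gaussian kurtosis
        k = np.mean(((y - y.mean()) / y.std()) ** 4)
        assert 2.7 < k < 3.3

    def test_periodogram_matches_target_per_decade(self):
        from scipy.signal import welch

        p = NoisePSDParams()
        fs, n = 10_000.0, 2**16
        acc = None
        for s in range(50):
            y = synth_colored_noise(p, n, fs, np.random.default_rng(s))
            f, pxx = welch(y, fs=fs, nperseg=4096)
            acc = pxx if acc is None else acc + pxx
        acc /= 50
        for lo, hi in ((10, 100), (100, 1000), (1000, 4000)):
            band = (f >= lo) & (f < hi)
            target = np.array([
                p.a_flicker / ff + p.a_electrode / ff**0.5 + p.a_white
                + p.a_dielectric * ff for ff in f[band]])
            assert np.mean(acc[band]) == pytest.approx(np.mean(target), rel=0.10)


class TestBaseline:
    def test_constant_when_disabled(self, rng):
        base = synth_baseline(10_000, 10_000.0, 4.2,
                              JumpConfig(rate_per_s=0.0, amp_frac=0.0),
                              DriftConfig(amp_frac_max=0.0), rng)
        assert np.allclose(base, 4.2)

    def test_drift_time_mean_near_zero(self):
        # long trace vs slowest drift period -> sinusoid means vanish
        means, scales = [], []
        for s in range(10):
            base = synth_baseline(400 * 100, 100.0, 4.2,
                                  JumpConfig(0.0, 0.0),
                                  DriftConfig(f_lo_Hz=0.05, f_hi_Hz=2.0),
                                  np.random.default_rng(s))
            drift = base - 4.2
            means.append(abs(drift.mean()))
            scales.append(np.abs(drift).max())
        assert np.mean(means) < 0.05 * np.mean(scales)

    def test_jump_count_binomial_mean(self):
        n, fs, rate = 200_000, 10_000.0, 5.0
        counts = []
        for s in range(40):
            base = synth_baseline(n, fs, 1.0, JumpConfig(rate_per_s=rate),
                                  DriftConfig(amp_frac_max=0.0),
                                  np.random.default_rng(s))
            counts.append(np.count_nonzero(np.diff(base)))
        expected = n * rate / fs
        se = math.sqrt(expected) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se


class TestGenerateTrace:
    def test_zero_events_clean_equals_baseline(self, settings):
        cond = SimCondition(0.0, 10.0, 1.0, 4.0, trace_length_s=2.0)
        tr = generate_trace(cond, 5, settings)
        assert len(tr.events) == 0
        i0 = open_pore_current(settings.pore, settings.electrolyte, cond.bias_V)
        baseline = synth_baseline(cond.n_samples, cond.fs_Hz, i0,
                                  settings.jumps, settings.drift,
                                  np.random.default_rng(5))
        np.testing.assert_array_equal(tr.clean, baseline)

    def test_blockade_depth_at_apex(self, settings, quiet_trace):
        tr = quiet_trace
        cond = tr.condition
        i0 = open_pore_current(settings.pore, settings.electrolyte, cond.bias_V)
        rng = np.random.default_rng(tr.seed)
        sample_events(cond, rng, settings)  # replay rng consumption
        baseline = synth_baseline(cond.n_samples, cond.fs_Hz, i0,
                                  settings.jumps, settings.drift, rng)
        depth = baseline - tr.clean
        n_overlap = 0
        for ev in tr.events:
            n = int(round(ev.duration_ms * 1e-3 * cond.fs_Hz))
            start = int(round(ev.t_start_s * cond.fs_Hz))
            apex = start + int(round(ev.rise_fraction * (n - 1)))
            if depth[apex] > ev.amplitude_nA * 1.5:
                n_overlap += 1  # overlapping events superpose
                continue
            assert depth[apex] == pytest.approx(ev.amplitude_nA, rel=1e-9)
        assert n_overlap <= len(tr.events) // 2

    def test_same_seed_bit_identical(self, settings):
        cond = SimCondition(0.4, 8.0, 1.5, 2.0, trace_length_s=3.0)
        t1 = generate_trace(cond, 99, settings)
        t2 = generate_trace(cond, 99, settings)
        np.testing.assert_array_equal(t1.noisy, t2.noisy)
        np.testing.assert_array_equal(t1.clean, t2.clean)
        assert t1.events == t2.events

    def test_noise_mean_and_rms(self, settings, snr4_trace):
        # noisy - clean is the calibrated noise: mean ~ 0, RMS within 3%
        tr = snr4_trace
        noise = tr.noisy - tr.clean
        assert abs(noise.mean()) < 0.05 * noise.std()
        i0 = open_pore_current(settings.pore, settings.electrolyte,
                               tr.condition.bias_V)
        amp = blockade_amplitude(settings.pore, tr.condition.d_np_nm, i0)
        target_rms = amp / (6.0 * tr.condition.snr)
        assert noise.std() == pytest.approx(target_rms, rel=0.03)

    def test_realized_snr_within_5pct(self, settings):
        for seed, (c, d, w, snr) in enumerate(
                [(0.1, 5.0, 1.0, 4.0), (0.5, 12.0, 3.0, 1.0),
                 (1.0, 17.0, 0.5, 0.25)]):
            cond = SimCondition(c, d, w, snr, trace_length_s=5.0)
            tr = generate_trace(cond, 300 + seed, settings)
            i0 = open_pore_current(settings.pore, settings.electrolyte, 0.3)
            amp = blockade_amplitude(settings.pore, d, i0)
            realized = amp / (6.0 * (tr.noisy - tr.clean).std())
            assert realized == pytest.approx(snr, rel=0.05)


class TestLabelsIndependentRecount:
    def test_labels_match_clean_trace_scan(self, settings, quiet_trace):
        """Recover events from the clean trace by an independent residual scan
        and compare with the recorded table."""
        tr = quiet_trace
        cond = tr.condition
        i0 = open_pore_current(settings.pore, settings.electrolyte, cond.bias_V)
        rng = np.random.default_rng(tr.seed)
        sample_events(cond, rng, settings)
        baseline = synth_baseline(cond.n_samples, cond.fs_Hz, i0,
                                  settings.jumps, settings.drift, rng)
        residual = baseline - tr.clean
        active = residual > 1e-12
        # contiguous active runs = events (quiet fixture has no overlaps
        # touching each other if gaps exist; count only well-separated runs)
        edges = np.flatnonzero(np.diff(active.astype(int)))
        runs = []
        start = None
        for i in np.flatnonzero(active):
            if start is None:
                start = i
                prev = i
            elif i == prev + 1:
                prev = i
            else:
                runs.append((start, prev))
                start, prev = i, i
        if start is not None:
            runs.append((start, prev))
        overlapping = len(tr.events) - len(runs)
        if overlapping == 0:
            assert len(runs) == len(tr.events)
            for (a, b), ev in zip(runs, tr.events):
                assert residual[a:b + 1].max() == pytest.approx(
                    ev.amplitude_nA, rel=1e-9)
                dur_ms = (b - a + 1) / cond.fs_Hz * 1e3
                assert dur_ms == pytest.approx(ev.duration_ms, abs=0.2)
        else:
            assert overlapping > 0  # overlapped events merged into runs


class TestDataset:
    def test_default_grid_size(self):
        assert len(default_grid(4.0)) == 20 * 15 * 5

    def test_scaled_grid_window_counts(self, settings):
        conds = condition_grid([0.2, 1.0], [8.0, 14.0], [1.0, 3.0], 4.0)
        splits = {"train": 30, "val": 11, "test": 7}
        traces, manifest = generate_dataset(conds, splits, 3, settings)
        for split, want in splits.items():
            got = sum(int(round(t.condition.trace_length_s / 0.5))
                      for t in traces[split])
            assert got == want
        assert {m["split"] for m in manifest} == set(splits)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset([], {"train": 10}, 0)
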