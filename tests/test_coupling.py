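"""Spike-triggered averaging, STA latency, spike-field coherence."""

import numpy as np
import pytest
from scipy.special import iv

from optothal import (
    EphysParams,
    LFPEpochs,
    STAResult,
    gen_coupled_lfp,
    gen_entrained_spikes,
    shoulder_comparison,
    spike_field_coherence,
    spike_triggered_average,
    sta_latency,
)

from conftest import make_train


def kernel_lfp(spike_rel_s, kernel, n_trials=10, fs=1000.0, t0_ms=-500.0,
               n_samples=1300):
    """LFP that is exactly the kernel dropped at each within-trial spike."""
    data = np.zeros((n_trials, n_samples))
    spikes = []
    for i in range(n_trials):
        for s in spike_rel_s:
            j = int(round((s - t0_ms / 1000.0) * fs))
            j1 = min(j + kernel.size, n_samples)
            data[i, j:j1] += kernel[: j1 - j]
            spikes.append(i * 1.5 + 0.5 + s)
    ep = LFPEpochs(data=data, fs_hz=fs, t0_ms=t0_ms)
    return make_train(sorted(spikes), n_trials=n_trials), ep


def gauss_kernel(tau_ms=3.8, amp=40.0, sigma_ms=1.5, fs=1000.0):
    t = np.arange(0.0, 30.0, 1000.0 / fs)
    return -amp * np.exp(-0.5 * ((t - tau_ms) / sigma_ms) ** 2)


class TestSTA:
    def test_recovers_kernel_exactly(self):
        """With well-separated spikes and no noise the STA equals the
        coupling kernel (linearity of averaging)."""
        k = gauss_kernel()
        train, ep = kernel_lfp([0.1, 0.3], k)
        sta = spike_triggered_average(train, ep)
        assert sta.n_spikes == 20
        center = np.argmin(np.abs(sta.lags_ms))
        np.testing.assert_allclose(sta.sta_uv[center: center + k.size], k,
                                   atol=1e-9)
        np.testing.assert_allclose(sta.sta_uv[:center], 0.0, atol=1e-9)

    def test_noise_sta_shrinks_with_spike_count(self):
        """For LFP independent of spikes, max|STA| scales ~ 1/sqrt(n)."""
        def max_sta(n_spikes, seed):
            r = np.random.default_rng(seed)
            n_tr = max(1, n_spikes // 100)
            data = r.normal(0, 10.0, (n_tr, 3000))
            ep = LFPEpochs(data=data, fs_hz=1000.0, t0_ms=-500.0)
            per = n_spikes // n_tr
            spikes = np.concatenate([
                i * 3.0 + 0.5 + np.sort(r.uniform(0.0, 2.0, per))
                for i in range(n_tr)
            ])
            train = make_train(np.sort(spikes), n_trials=n_tr, trial_len_s=3.0,
                               stim_s=2.0)
            return np.abs(spike_triggered_average(train, ep).sta_uv).max()

        small = max_sta(100, 1)
        big = max_sta(10000, 2)
        ratio = big / small
        assert 0.1 / 3 < ratio < 0.1 * 3

    def test_edge_spikes_dropped_and_counted(self):
        k = gauss_kernel()
        train, ep = kernel_lfp([0.05, 0.3], k, n_trials=3)
        # trim the LFP so the first spike sits 90 ms from the matrix edge:
        # its +/-100 ms epoch no longer fits and it must be dropped
        ep2 = LFPEpochs(data=ep.data[:, 460:], fs_hz=1000.0, t0_ms=-40.0)
        sta = spike_triggered_average(train, ep2)
        assert sta.n_spikes == 3      # only the 0.3 s spike per trial
        assert sta.n_dropped == 3

    def test_linearity(self, rng):
        k = gauss_kernel()
        train, ep1 = kernel_lfp([0.2], k)
        ep2 = LFPEpochs(data=rng.normal(size=ep1.data.shape), fs_hz=1000.0,
                        t0_ms=-500.0)
        a, b = 2.5, -1.25
        mix = LFPEpochs(data=a * ep1.data + b * ep2.data, fs_hz=1000.0,
                        t0_ms=-500.0)
        s_mix = spike_triggered_average(train, mix).sta_uv
        s1 = spike_triggered_average(train, ep1).sta_uv
        s2 = spike_triggered_average(train, ep2).sta_uv
        np.testing.assert_allclose(s_mix, a * s1 + b * s2, atol=1e-10)


class TestLatency:
    def test_negative_peak_recovered_at_nearest_sample(self):
        train, ep = kernel_lfp([0.1, 0.3], gauss_kernel(tau_ms=3.8))
        assert spike_triggered_average(train, ep).latency_ms == 4.0

    def test_flat_sta_absent(self):
        sta = STAResult(lags_ms=np.arange(-100.0, 101.0),
                        sta_uv=np.zeros(201), n_spikes=10, n_dropped=0,
                        fs_hz=1000.0)
        assert sta_latency(sta) is None

    def test_first_peak_not_deepest(self):
        lags = np.arange(-100.0, 101.0)
        v = np.zeros(201)
        rng = np.random.default_rng(3)
        v[lags < 0] = rng.normal(0, 0.5, (lags < 0).sum())
        v[np.where(lags == 3.0)[0][0]] = -10.0   # first negative peak
        v[np.where(lags == 20.0)[0][0]] = -30.0  # deeper but later
        sta = STAResult(lags_ms=lags, sta_uv=v, n_spikes=50, n_dropped=0,
                        fs_hz=1000.0)
        assert sta_latency(sta) == 3.0


class TestSFC:
    def test_identical_epochs_unity(self):
        row = np.sin(2 * np.pi * 40 * np.arange(1300) / 1000.0) * 20
        ep = LFPEpochs(data=np.tile(row, (8, 1)), fs_hz=1000.0, t0_ms=-500.0)
        spikes = [i * 1.5 + 0.75 for i in range(8)]  # same position each trial
        sfc = spike_field_coherence(make_train(spikes, n_trials=8), ep)
        valid = ~np.isnan(sfc.sfc)
        np.testing.assert_allclose(sfc.sfc[valid], 1.0, atol=1e-9)

    def test_bounded_on_random_inputs(self, rng):
        for _ in range(25):
            n_tr = int(rng.integers(2, 6))
            data = rng.normal(size=(n_tr, 1300)) * rng.uniform(0.1, 50)
            ep = LFPEpochs(data=data, fs_hz=1000.0, t0_ms=-500.0)
            spikes = np.sort(np.concatenate([
                i * 1.5 + 0.5 + rng.uniform(0.0, 0.5, 5) for i in range(n_tr)
            ]))
            sfc = spike_field_coherence(make_train(spikes, n_trials=n_tr), ep)
            valid = sfc.sfc[~np.isnan(sfc.sfc)]
            assert np.all(valid >= 0.0) and np.all(valid <= 1.0 + 1e-9)

    def test_incoherent_spikes_scale_inverse_n(self):
        """Spikes at random phases of a sinusoidal field: SFC at the field
        frequency approaches 1/N."""
        vals = []
        n_spk = 100
        for seed in range(100):
            r = np.random.default_rng(seed)
            row = 30 * np.sin(2 * np.pi * 40 * np.arange(3500) / 1000.0)
            ep = LFPEpochs(data=row[None, :], fs_hz=1000.0, t0_ms=-500.0)
            spikes = np.sort(0.5 + r.uniform(0.0, 2.4, n_spk))
            train = make_train(spikes, n_trials=1, trial_len_s=3.5, stim_s=2.4)
            sfc = spike_field_coherence(train, ep)
            j = np.argmin(np.abs(sfc.frequencies_hz - 40.0))
            vals.append(sfc.sfc[j])
        mean = np.mean(vals)
        assert 0.5 / n_spk < mean < 1.5 / n_spk

    def test_von_mises_jitter_matches_characteristic_function(self):
        """Spikes locked to a 40 Hz field with von Mises phase jitter
        (kappa=4): SFC at 40 Hz approaches the squared phasor mean
        rho^2 = (I1(k)/I0(k))^2 of the jitter distribution."""
        rho = iv(1, 4.0) / iv(0, 4.0)
        n_spk = 500
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            row = 30 * np.sin(2 * np.pi * 40 * np.arange(6000) / 1000.0)
            ep = LFPEpochs(data=row[None, :], fs_hz=1000.0, t0_ms=-500.0)
            cycle = 1.0 / 40.0
            base = 0.5 + r.integers(0, int(4.8 / cycle), n_spk) * cycle
            jitter = r.vonmises(0.0, 4.0, n_spk) / (2 * np.pi) * cycle
            spikes = np.sort(np.unique(base + jitter))
            train = make_train(spikes, n_trials=1, trial_len_s=6.0, stim_s=4.9)
            sfc = spike_field_coherence(train, ep)
            j = np.argmin(np.abs(sfc.frequencies_hz - 40.0))
            vals.append(sfc.sfc[j])
        expected = rho**2 + (1 - rho**2) / n_spk
        sd = np.std(vals)
        assert np.mean(vals) == pytest.approx(expected, abs=2 * sd + 0.02)


class TestShoulderComparison:
    def test_strong_locking_significant(self):
        p = EphysParams(mod_depth=0.8, stim_gain=2.0, seed=7, n_trials=20)
        spikes = gen_entrained_spikes(p)
        lfp = gen_coupled_lfp(spikes, p)
        sh = shoulder_comparison(spikes, lfp, 40.0, seed=1, n_boot=300)
        assert sh.significant and sh.sfc_stim > sh.sfc_shoulder

    def test_unlocked_spikes_rarely_significant(self):
        n_sig = 0
        for seed in range(50):
            p = EphysParams(mod_depth=0.0, osc_amp_uv=0.0,
                            kernel=(3.8, 0.0, 3.0), seed=seed, n_trials=10)
            spikes = gen_entrained_spikes(p)
            lfp = gen_coupled_lfp(spikes, p)
            sh = shoulder_comparison(spikes, lfp, 40.0, seed=seed, n_boot=150)
            n_sig += sh.significant
        assert n_sig <= 5  # >= 90% non-significant

    def test_identical_epochs_null_result(self):
        row = np.sin(2 * np.pi * 40 * np.arange(1300) / 1000.0) * 20
        ep = LFPEpochs(data=np.tile(row, (60, 1)), fs_hz=1000.0, t0_ms=-500.0)
        spikes = [i * 1.5 + 0.75 for i in range(60)]
        sh = shoulder_comparison(make_train(spikes, n_trials=60), ep, 40.0,
                                 seed=0, n_boot=120)
        assert sh.p_value == 1.0 and not sh.significant

    def test_too_few_spikes_rejected(self):
        row = np.zeros(1300)
        ep = LFPEpochs(data=np.tile(row, (3, 1)), fs_hz=1000.0, t0_ms=-500.0)
        with pytest.raises(ValueError):
            shoulder_comparison(make_train([0.75], n_trials=3), ep, 40.0,
                                seed=0)

    def test_small_bootstrap_warns(self):
        p = EphysParams(seed=3, n_trials=10)
        spikes = gen_entrained_spikes(p)
        lfp = gen_coupled_lfp(spikes, p)
        with pytest.warns(UserWarning):
            shoulder_comparison(spikes, lfp, 40.0, seed=0, n_boot=50)
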