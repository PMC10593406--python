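import numpy as np
import pytest

from optothal import (
    BehavioralSession,
    EpochSpec,
    LFPEpochs,
    SpikeTrain,
    StimulusCondition,
    TrialRecord,
)


def make_session(trials, modality="visual", frequency_hz=40.0):
    """Build a validated session from (index, onset_ms, response_ms) tuples."""
    recs = tuple(TrialRecord(i, o, r) for i, o, r in trials)
    cond = StimulusCondition(modality=modality, frequency_hz=frequency_hz,
                             amplitude_mw=10.0)
    return BehavioralSession(animal_id="t", session_id="s", trials=recs,
                             condition=cond)


def make_train(spike_times_s, n_trials=1, trial_len_s=1.5, baseline_s=0.5,
               stim_s=0.5, frequency_hz=40.0, unit_id="u"):
    """Spike train on a regular trial grid (baseline then stimulation)."""
    epochs = tuple(
        EpochSpec(
            trial_start_s=i * trial_len_s,
            stim_onset_s=i * trial_len_s + baseline_s,
            stim_offset_s=i * trial_len_s + baseline_s + stim_s,
            frequency_hz=frequency_hz,
        )
        for i in range(n_trials)
    )
    return SpikeTrain(unit_id=unit_id, spike_times_s=np.asarray(spike_times_s,
                                                                dtype=float),
                      trials=epochs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def sine_epochs():
    """20 trials of a noiseless 40 Hz, 50 uV sinusoid confined to the
    stimulation window [0, 500) ms; fs = 1000 Hz, epoch spans [-500, 800) ms."""
    fs = 1000.0
    t = -0.5 + np.arange(1300) / fs
    stim = (t >= 0) & (t < 0.5)
    row = np.where(stim, 50.0 * np.cos(2 * np.pi * 40.0 * t), 0.0)
    data = np.tile(row, (20, 1))
    return LFPEpochs(data=data, fs_hz=fs, t0_ms=-500.0, site_id="sine")
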