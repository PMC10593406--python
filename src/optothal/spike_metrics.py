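"""Spike-train analyses: PSTH, spectrum, bursts, phase locking, ON/OFF motifs.

These quantify how thalamic (LGN) units respond to periodic optogenetic
drive: the peri-stimulus time histogram and the Fourier spectrum of the
trial-summed train show entrainment at the stimulation frequency and its
harmonics; burst detection counts the classic thalamic burst motif (two or
more spikes with inter-spike intervals under 4 ms preceded by at least
50 ms of silence); vector strength measures phase locking to the
stimulation cycle; and the ON/OFF motif classifier separates units driven
during stimulation from those responding at its offset.

Cycle phases are anchored at stimulation onset (the light-ON edge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import EpochSpec, SpikeTrain, ValidationError
from .stats_core import paired_t_test, rayleigh_test

__all__ = [
    "PSTH",
    "BurstSummary",
    "PhaseLocking",
    "ResponseMotif",
    "compute_psth",
    "spike_train_spectrum",
    "detect_bursts",
    "vector_strength",
    "classify_response_motif",
]


@dataclass(frozen=True)
class PSTH:
    bin_edges_ms: np.ndarray  # len = n_bins + 1, relative to stim onset
    rate_hz: np.ndarray       # trial-averaged firing rate per bin
    n_trials: int


@dataclass(frozen=True)
class BurstSummary:
    bursts: tuple[tuple[float, int], ...]  # (start_s, n_spikes) per burst
    burst_spike_fraction: float
    n_spikes_total: int


@dataclass(frozen=True)
class PhaseLocking:
    frequency_hz: float
    R: float        # vector strength |mean unit phasor|, 0..1
    N: int          # spikes entering the estimate
    p_rayleigh: float


@dataclass(frozen=True)
class ResponseMotif:
    unit_id: str
    on_p: float
    off_p: float
    motif: str                    # ON | OFF | BOTH | NONE
    on_rate_stim: float           # Hz during stimulation
    rate_baseline: float          # Hz pre-stimulus
    off_rate_post: float          # Hz after offset
    off_latency_ms: float | None  # PSTH peak after offset, when OFF


def _per_trial_spikes(train: SpikeTrain, epoch: EpochSpec,
                      t0_s: float, t1_s: float) -> np.ndarray:
    """Spike times in seconds relative to stim onset, within [t0, t1)."""
    rel = train.spike_times_s - epoch.stim_onset_s
    return rel[(rel >= t0_s) & (rel < t1_s)]


def compute_psth(
    train: SpikeTrain,
    window_ms: tuple[float, float] = (-500.0, 1000.0),
    bin_ms: float = 5.0,
) -> PSTH:
    """Peri-stimulus time histogram aligned to stimulation onset.

    rate[b] = (spike count in bin b, summed over trials) / (n_trials * bin width).
    The window end is trimmed to a whole number of bins.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    if not train.trials:
        raise ValueError("PSTH requires at least one trial epoch")
    pre, post = window_ms
    n_bins = int(np.floor((post - pre) / bin_ms))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    edges = pre + bin_ms * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for epoch in train.trials:
        rel_ms = 1000.0 * _per_trial_spikes(train, epoch, pre / 1000.0,
                                            edges[-1] / 1000.0)
        counts += np.histogram(rel_ms, bins=edges)[0]
    n_trials = len(train.trials)
    rate = counts / (n_trials * bin_ms / 1000.0)
    return PSTH(bin_edges_ms=edges, rate_hz=rate, n_trials=n_trials)


def spike_train_spectrum(
    train: SpikeTrain, bin_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Amplitude spectrum of the trial-summed binned spike train.

    The train is binned at ``bin_ms`` over the stimulation window, summed
    across trials, mean-subtracted and Fourier transformed. Returns
    ``(frequencies_hz, amplitude, peak_hz)``; ``peak_hz`` is None for an
    empty train. Entrained trains show a peak at the stimulation frequency
    with harmonics. The window must cover at least two stimulation cycles.
    """
    if not train.trials:
        raise ValueError("spectrum requires trial epochs")
    ep0 = train.trials[0]
    win_s = ep0.stim_offset_s - ep0.stim_onset_s
    if win_s < 2.0 / ep0.frequency_hz:
        raise ValueError("stimulation window shorter than 2 cycles")
    n_bins = int(round(1000.0 * win_s / bin_ms))
    edges_s = np.arange(n_bins + 1) * (bin_ms / 1000.0)
    summed = np.zeros(n_bins)
    for epoch in train.trials:
        rel = _per_trial_spikes(train, epoch, 0.0, win_s)
        summed += np.histogram(rel, bins=edges_s)[0]
    freqs = np.fft.rfftfreq(n_bins, d=bin_ms / 1000.0)
    if summed.sum() == 0:
        return freqs, np.zeros(freqs.size), None
    amp = np.abs(np.fft.rfft(summed - summed.mean()))
    peak_hz = float(freqs[1:][np.argmax(amp[1:])])  # skip DC
    return freqs, amp, peak_hz


def detect_bursts(
    spike_times_s,
    isi_max_ms: float = 4.0,
    silence_min_ms: float = 50.0,
) -> BurstSummary:
    """Detect thalamic bursts by the ISI rule.

    A burst starts at spike i if the preceding gap is >= ``silence_min_ms``
    (the first spike of the record qualifies) and the following inter-spike
    interval is strictly < ``isi_max_ms``; it extends while successive ISIs
    stay < ``isi_max_ms``. The burst-spike fraction is the share of all
    spikes that fall inside bursts.
    """
    t = np.asarray(spike_times_s, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValidationError("spike times must be strictly sorted")
    isi_max_s = isi_max_ms / 1000.0
    silence_s = silence_min_ms / 1000.0
    bursts: list[tuple[float, int]] = []
    n_burst_spikes = 0
    i = 0
    n = t.size
    while i < n - 1:
        preceded_by_silence = i == 0 or (t[i] - t[i - 1]) >= silence_s
        if preceded_by_silence and (t[i + 1] - t[i]) < isi_max_s:
            j = i + 1
            while j < n - 1 and (t[j + 1] - t[j]) < isi_max_s:
                j += 1
            size = j - i + 1
            bursts.append((float(t[i]), size))
            n_burst_spikes += size
            i = j + 1
        else:
            i += 1
    frac = n_burst_spikes / n if n else 0.0
    return BurstSummary(
        bursts=tuple(bursts), burst_spike_fraction=frac, n_spikes_total=int(n)
    )


def vector_strength(
    train: SpikeTrain, frequency_hz: float | None = None
) -> PhaseLocking | None:
    """Phase locking of stimulation-window spikes to the stimulation cycle.

    Each spike at time t (relative to its trial's stimulation onset) gets
    phase theta = 2*pi*frac(t * f); R = |(1/N) sum_j exp(i*theta_j)|.
    Significance via the Rayleigh test. Returns None when no spike falls
    inside any stimulation window.
    """
    if not train.trials:
        raise ValueError("vector strength requires trial epochs")
    f = frequency_hz if frequency_hz is not None else train.trials[0].frequency_hz
    phases: list[np.ndarray] = []
    for epoch in train.trials:
        rel = _per_trial_spikes(train, epoch, 0.0,
                                epoch.stim_offset_s - epoch.stim_onset_s)
        phases.append(2.0 * np.pi * np.mod(rel * f, 1.0))
    theta = np.concatenate(phases) if phases else np.empty(0)
    n = theta.size
    if n == 0:
        return None
    R = float(np.abs(np.mean(np.exp(1j * theta))))
    R = min(R, 1.0)
    p = rayleigh_test(R, n).p_value
    return PhaseLocking(frequency_hz=f, R=R, N=int(n), p_rayleigh=p)


def _trial_rates(train: SpikeTrain, t0_s: float, t1_s: float) -> np.ndarray:
    dur = t1_s - t0_s
    return np.array([
        _per_trial_spikes(train, ep, t0_s, t1_s).size / dur
        for ep in train.trials
    ])


def classify_response_motif(
    train: SpikeTrain,
    alpha: float = 0.05,
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0),
    stim_window_ms: tuple[float, float] | None = None,
    post_window_ms: tuple[float, float] | None = None,
    psth_bin_ms: float = 5.0,
) -> ResponseMotif:
    """Classify a unit as ON, OFF, BOTH, or NONE.

    ON: the per-trial firing rate during stimulation exceeds the pre-
    stimulus baseline rate (paired t-test, p < alpha, stim > baseline).
    OFF: the rate in the post-offset window exceeds baseline likewise.
    The OFF latency is the time of the peak of the post-offset PSTH.
    Defaults: stim window = the full stimulation period, post window =
    150 ms after offset (bracketing the ~50 ms offset-response latencies
    typical of thalamocortical circuits).
    """
    if len(train.trials) < 5:
        raise ValueError("motif classification requires at least 5 trials")
    ep0 = train.trials[0]
    stim_dur_ms = 1000.0 * (ep0.stim_offset_s - ep0.stim_onset_s)
    if stim_window_ms is None:
        stim_window_ms = (0.0, stim_dur_ms)
    if post_window_ms is None:
        post_window_ms = (stim_dur_ms, stim_dur_ms + 150.0)

    base = _trial_rates(train, baseline_window_ms[0] / 1e3, baseline_window_ms[1] / 1e3)
    stim = _trial_rates(train, stim_window_ms[0] / 1e3, stim_window_ms[1] / 1e3)
    post = _trial_rates(train, post_window_ms[0] / 1e3, post_window_ms[1] / 1e3)

    t_on = paired_t_test(stim, base)
    t_off = paired_t_test(post, base)
    is_on = t_on.p_value < alpha and stim.mean() > base.mean()
    is_off = t_off.p_value < alpha and post.mean() > base.mean()
    motif = {(True, True): "BOTH", (True, False): "ON",
             (False, True): "OFF", (False, False): "NONE"}[(is_on, is_off)]

    off_latency = None
    if is_off:
        psth = compute_psth(train, window_ms=post_window_ms, bin_ms=psth_bin_ms)
        centers = 0.5 * (psth.bin_edges_ms[:-1] + psth.bin_edges_ms[1:])
        off_latency = float(centers[np.argmax(psth.rate_hz)] - stim_window_ms[1])

    return ResponseMotif(
        unit_id=train.unit_id,
        on_p=t_on.p_value,
        off_p=t_off.p_value,
        motif=motif,
        on_rate_stim=float(stim.mean()),
        rate_baseline=float(base.mean()),
        off_rate_post=float(post.mean()),
        off_latency_ms=off_latency,
    )
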