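"""Thalamocortical coupling: spike-triggered average, latency, coherence.

The spike-triggered average (STA) is the mean of +/-100 ms cortical-LFP
epochs centered on thalamic spikes; with monosynaptic thalamocortical
drive it shows a sharp depth-negative deflection a few milliseconds after
the spike, and the time of its first negative peak is taken as the
response latency.

Spike-field coherence (SFC) normalizes the STA's power spectrum by the
mean power spectrum of the individual spike-centered epochs::

    SFC(f) = P_STA(f) / Pbar(f)

which is bounded in [0, 1]: it equals 1 when every epoch is identical
(perfect spike-field locking) and decays as 1/N for N spikes at random
phases of the field. Coherence at the stimulation frequency is compared
against a shoulder frequency (f_stim - 3 Hz by default) with a
spike-resampling bootstrap.

Spikes are snapped to the nearest LFP sample; epochs extending past the
trial boundaries are dropped and counted, never zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import LFPEpochs, SpikeTrain

__all__ = [
    "STAResult",
    "SFCResult",
    "ShoulderComparison",
    "spike_triggered_average",
    "sta_latency",
    "spike_field_coherence",
    "shoulder_comparison",
]


@dataclass(frozen=True)
class STAResult:
    lags_ms: np.ndarray
    sta_uv: np.ndarray
    n_spikes: int          # spikes averaged
    n_dropped: int         # spikes too close to a trial edge
    fs_hz: float
    latency_ms: float | None = None


@dataclass(frozen=True)
class SFCResult:
    frequencies_hz: np.ndarray
    sfc: np.ndarray
    n_spikes: int


@dataclass(frozen=True)
class ShoulderComparison:
    f_stim_hz: float
    sfc_stim: float
    f_shoulder_hz: float
    sfc_shoulder: float
    p_value: float
    significant: bool
    n_boot: int


def _collect_epochs(
    spikes: SpikeTrain, lfp: LFPEpochs, half_window_ms: float,
    stim_only: bool = True,
) -> tuple[np.ndarray, int]:
    """Stack the LFP epochs centered on each valid spike.

    Trial i of the LFP matrix is paired with epoch i of the spike train;
    spike times are mapped to samples through the trial's stimulation
    onset and the LFP's t0. By default only spikes inside the stimulation
    window trigger epochs (the coupling analysis targets the driven
    period); ``stim_only=False`` admits every spike covered by the LFP.
    Returns (epochs matrix, n_dropped).
    """
    if len(spikes.trials) != lfp.n_trials:
        raise ValueError(
            f"spike train has {len(spikes.trials)} trial epochs but the LFP "
            f"matrix has {lfp.n_trials} trials"
        )
    half = int(round(half_window_ms * lfp.fs_hz / 1000.0))
    rows: list[np.ndarray] = []
    dropped = 0
    for i, epoch in enumerate(spikes.trials):
        if stim_only:
            t_lo, t_hi = epoch.stim_onset_s, epoch.stim_offset_s
        else:
            # absolute time span covered by this trial's LFP row
            t_lo = epoch.stim_onset_s + lfp.t0_ms / 1000.0
            t_hi = t_lo + lfp.n_samples / lfp.fs_hz
        in_trial = spikes.spike_times_s[
            (spikes.spike_times_s >= t_lo) & (spikes.spike_times_s < t_hi)
        ]
        for t in in_trial:
            rel_s = t - epoch.stim_onset_s
            center = int(round((rel_s - lfp.t0_ms / 1000.0) * lfp.fs_hz))
            if center - half < 0 or center + half >= lfp.n_samples:
                dropped += 1
                continue
            rows.append(lfp.data[i, center - half: center + half + 1])
    if not rows:
        return np.empty((0, 2 * half + 1)), dropped
    return np.stack(rows), dropped


def spike_triggered_average(
    spikes: SpikeTrain, lfp: LFPEpochs, half_window_ms: float = 100.0,
    stim_only: bool = True,
) -> STAResult | None:
    """Mean of the +/- ``half_window_ms`` LFP epochs around each spike.

    Spikes whose full epoch does not fit inside their trial's LFP are
    dropped and counted in ``n_dropped``. Returns None when no spike has
    a valid epoch.
    """
    epochs, dropped = _collect_epochs(spikes, lfp, half_window_ms, stim_only)
    if epochs.shape[0] == 0:
        return None
    half = (epochs.shape[1] - 1) // 2
    lags = 1000.0 * (np.arange(-half, half + 1)) / lfp.fs_hz
    sta = epochs.mean(axis=0)
    res = STAResult(
        lags_ms=lags, sta_uv=sta, n_spikes=epochs.shape[0],
        n_dropped=dropped, fs_hz=lfp.fs_hz,
    )
    return STAResult(**{**res.__dict__, "latency_ms": sta_latency(res)})


def sta_latency(sta: STAResult, threshold_sd: float = 3.0) -> float | None:
    """Latency = first negative peak of the STA at positive lag.

    A candidate is a local minimum at lag > 0 whose value is below
    -``threshold_sd`` robust standard deviations of the pre-spike
    (negative-lag) STA; the robust SD is 1.4826 * MAD. Returns the
    earliest such lag in ms, or None when no peak qualifies.
    """
    v = sta.sta_uv
    lags = sta.lags_ms
    pre = v[lags < 0]
    if pre.size < 3:
        return None
    mad = np.median(np.abs(pre - np.median(pre)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        robust_sd = float(np.std(pre)) or np.finfo(float).tiny
    thresh = -threshold_sd * robust_sd
    for i in range(1, v.size - 1):
        if lags[i] <= 0:
            continue
        if v[i] < v[i - 1] and v[i] <= v[i + 1] and v[i] < thresh:
            return float(lags[i])
    return None


def spike_field_coherence(
    spikes: SpikeTrain, lfp: LFPEpochs, half_window_ms: float = 100.0,
    stim_only: bool = True,
) -> SFCResult | None:
    """SFC(f) = power spectrum of the STA / mean epoch power spectrum.

    Epoch validity rules are the same as for the STA. Frequencies where
    the mean epoch power is zero are reported as NaN. Returns None when
    no valid spike epochs exist.
    """
    epochs, _ = _collect_epochs(spikes, lfp, half_window_ms, stim_only)
    return _sfc_from_epochs(epochs, lfp.fs_hz)


def _sfc_from_epochs(epochs: np.ndarray, fs_hz: float) -> SFCResult | None:
    n_spk = epochs.shape[0]
    if n_spk == 0:
        return None
    n = epochs.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    p_sta = np.abs(np.fft.rfft(epochs.mean(axis=0))) ** 2
    p_bar = np.mean(np.abs(np.fft.rfft(epochs, axis=1)) ** 2, axis=0)
    # bins with (numerically) zero mean power carry no phase information
    nonzero = p_bar > p_bar.max() * 1e-15 if p_bar.max() > 0 else p_bar > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sfc = np.where(nonzero, p_sta / p_bar, np.nan)
    return SFCResult(frequencies_hz=freqs, sfc=sfc, n_spikes=n_spk)


def _sfc_at(result: SFCResult, f: float) -> float:
    j = int(np.argmin(np.abs(result.frequencies_hz - f)))
    return float(result.sfc[j])


def shoulder_comparison(
    spikes: SpikeTrain,
    lfp: LFPEpochs,
    f_stim: float,
    offset_hz: float = 3.0,
    n_boot: int = 1000,
    seed: int | None = None,
    half_window_ms: float = 100.0,
    stim_only: bool = True,
    min_spikes: int = 50,
) -> ShoulderComparison:
    """Bootstrap test of SFC(f_stim) > SFC(f_stim - offset).

    Spike epochs are resampled with replacement ``n_boot`` times and the
    SFC difference recomputed; p is the fraction of bootstrap differences
    <= 0, significant at alpha = 0.05. With identical epochs the observed
    difference is 0 and p is reported as 1.
    """
    import warnings

    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unreliable bootstrap p-value")
    epochs, _ = _collect_epochs(spikes, lfp, half_window_ms, stim_only)
    if epochs.shape[0] < min_spikes:
        raise ValueError(
            f"shoulder comparison requires >= {min_spikes} valid spikes, "
            f"got {epochs.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    base = _sfc_from_epochs(epochs, lfp.fs_hz)
    f_sh = f_stim - offset_hz
    obs_stim = _sfc_at(base, f_stim)
    obs_sh = _sfc_at(base, f_sh)
    n = epochs.shape[0]
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        res = _sfc_from_epochs(epochs[idx], lfp.fs_hz)
        diffs[b] = _sfc_at(res, f_stim) - _sfc_at(res, f_sh)
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        p = float(np.mean(diffs <= 0.0))
    return ShoulderComparison(
        f_stim_hz=f_stim,
        sfc_stim=obs_stim,
        f_shoulder_hz=f_sh,
        sfc_shoulder=obs_sh,
        p_value=p,
        significant=p < 0.05,
        n_boot=n_boot,
    )
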