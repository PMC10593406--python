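"""LFP spectral entrainment and single-trial spectral decoding.

Entrainment: per trial, the Fourier spectral amplitude (SA) of the field
potential at the stimulation frequency is compared between a pre-stimulus
baseline window and the stimulation window with a paired t-test; a site is
entrained when the stimulation SA is significantly larger.

Single-trial decoding treats each site as a detector of its own
stimulation: on each trial, a *hit* is scored when the stimulation-window
SA at f_stim exceeds the SA at the control frequency f_stim - 3 Hz, and a
*false alarm* when the baseline SA at f_stim exceeds the stimulation SA at
f_stim. The resulting hit/false-alarm fractions are converted to a neural
d' with the same corrected z-difference machinery as the behavioral
analysis, so behavioral and neural sensitivities are directly comparable.

Spectral estimator: rectangular window (no taper), mean subtraction only,
amplitude normalization 2/n so a pure sinusoid of amplitude A yields
SA = A at its frequency. Windows are zero-padded to a 1 Hz frequency grid
by default so that the f_stim - 3 Hz control lands on a grid point; with
padding disabled the requested frequency maps to the nearest grid bin,
ties rounding down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior_sdt import compute_dprime_bias
from .io_formats import LFPEpochs, ValidationError
from .stats_core import paired_t_test

__all__ = [
    "SpectralAmplitudes",
    "EntrainmentResult",
    "NeuralDetection",
    "spectral_amplitude",
    "entrainment_test",
    "evoked_average",
    "single_trial_detection",
    "frequency_sweep",
]

LOWPASS_BOUND_HZ = 300.0


@dataclass(frozen=True)
class SpectralAmplitudes:
    frequencies_hz: np.ndarray   # requested frequencies
    grid_hz: np.ndarray          # grid bins actually used, same length
    sa: np.ndarray               # n_trials x n_freqs, per-trial amplitudes
    window: str                  # "baseline" or "stim"


@dataclass(frozen=True)
class EntrainmentResult:
    site_id: str
    f_stim_hz: float
    mean_sa_baseline: float
    mean_sa_stim: float
    p_value: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class NeuralDetection:
    f_stim_hz: float
    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    n_trials: int


def _nearest_bin(f: float, grid_spacing: float) -> int:
    """Nearest grid bin index; exact half-way ties round DOWN in frequency."""
    q = f / grid_spacing
    lo = int(np.floor(q))
    return lo + 1 if (q - lo) > 0.5 + 1e-12 else lo


def spectral_amplitude(
    epochs: LFPEpochs,
    window_ms: tuple[float, float],
    freqs,
    label: str = "stim",
    pad_to_hz: float | None = 1.0,
) -> SpectralAmplitudes:
    """Per-trial Fourier spectral amplitudes at the requested frequencies.

    Each trial's segment in ``window_ms`` (relative to stimulation onset)
    is mean-subtracted and transformed; amplitudes are normalized by
    2/n_samples of the *unpadded* segment so a pure sinusoid of amplitude
    A gives SA = A. ``pad_to_hz`` zero-pads the segment to that frequency
    resolution (None disables padding, leaving the natural 1/T grid).
    Requested frequencies above the 300 Hz low-pass bound are rejected.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs > LOWPASS_BOUND_HZ):
        raise ValueError(
            f"requested frequency above the {LOWPASS_BOUND_HZ:.0f} Hz low-pass bound"
        )
    if np.any(freqs < 0):
        raise ValueError("frequencies must be non-negative")
    t = epochs.times_ms
    t0, t1 = window_ms
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1000.0 / epochs.fs_hz + 1e-9:
        raise ValueError(f"window {window_ms} not fully inside the epoch")
    mask = (t >= t0 - 1e-9) & (t < t1 - 1e-9)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("window contains fewer than 2 samples")
    win_s = n / epochs.fs_hz
    fmin = freqs[freqs > 0].min() if np.any(freqs > 0) else None
    if fmin is not None and win_s < 2.0 / fmin:
        raise ValueError("window shorter than 2 cycles of the lowest frequency")

    seg = epochs.data[:, mask]
    seg = seg - seg.mean(axis=1, keepdims=True)
    if pad_to_hz is not None:
        n_fft = max(n, int(round(epochs.fs_hz / pad_to_hz)))
    else:
        n_fft = n
    spec = np.abs(np.fft.rfft(seg, n=n_fft, axis=1)) * (2.0 / n)
    grid_spacing = epochs.fs_hz / n_fft
    idx = np.array([_nearest_bin(f, grid_spacing) for f in freqs])
    idx = np.clip(idx, 0, spec.shape[1] - 1)
    return SpectralAmplitudes(
        frequencies_hz=freqs,
        grid_hz=idx * grid_spacing,
        sa=spec[:, idx],
        window=label,
    )


def entrainment_test(
    baseline: SpectralAmplitudes,
    stim: SpectralAmplitudes,
    f_stim: float,
    alpha: float = 0.01,
    site_id: str = "",
) -> EntrainmentResult:
    """Paired t-test of per-trial SA(f_stim), stimulation vs baseline.

    A site is *entrained* when p < alpha AND the mean stimulation SA
    exceeds the baseline SA.
    """
    if baseline.sa.shape[0] != stim.sa.shape[0]:
        raise ValidationError("baseline and stimulation trial counts differ")

    def _col(sa: SpectralAmplitudes) -> np.ndarray:
        j = int(np.argmin(np.abs(sa.frequencies_hz - f_stim)))
        return sa.sa[:, j]

    b, s = _col(baseline), _col(stim)
    res = paired_t_test(s, b)
    sig = (res.p_value < alpha) and (s.mean() > b.mean())
    return EntrainmentResult(
        site_id=site_id,
        f_stim_hz=f_stim,
        mean_sa_baseline=float(b.mean()),
        mean_sa_stim=float(s.mean()),
        p_value=res.p_value,
        significant=bool(sig),
        degenerate=res.degenerate,
    )


def evoked_average(epochs: LFPEpochs) -> tuple[np.ndarray, np.ndarray | None]:
    """Pointwise trial mean and SEM of the epoch matrix.

    SEM is None for a single trial.
    """
    mean = epochs.data.mean(axis=0)
    if epochs.n_trials < 2:
        return mean, None
    sem = epochs.data.std(axis=0, ddof=1) / np.sqrt(epochs.n_trials)
    return mean, sem


def single_trial_detection(
    stim_sa: SpectralAmplitudes,
    base_sa: SpectralAmplitudes,
    f_stim: float,
    control_offset_hz: float = 3.0,
) -> NeuralDetection:
    """Score the site as a single-trial detector of its own stimulation.

    hit      <=>  SA_stim(f_stim)  >  SA_stim(f_stim - offset)
    false alarm <=> SA_base(f_stim) > SA_stim(f_stim)

    Exact ties count against detection (strict inequality). Rates are
    trial fractions; d' is the corrected z-difference.
    """
    if f_stim - control_offset_hz <= 0:
        raise ValueError("control frequency must be positive")
    if stim_sa.sa.shape[0] != base_sa.sa.shape[0]:
        raise ValidationError("stim and baseline trial counts differ")

    def _col(sa: SpectralAmplitudes, f: float) -> np.ndarray:
        j = int(np.argmin(np.abs(sa.frequencies_hz - f)))
        if abs(sa.frequencies_hz[j] - f) > 1e-6:
            raise ValueError(
                f"frequency {f} Hz not among the computed amplitudes"
            )
        return sa.sa[:, j]

    s_f = _col(stim_sa, f_stim)
    s_c = _col(stim_sa, f_stim - control_offset_hz)
    b_f = _col(base_sa, f_stim)
    n = s_f.size
    hr = float(np.mean(s_f > s_c))
    far = float(np.mean(b_f > s_f))
    m = compute_dprime_bias(hr, far, n_signal=n, n_noise=n)
    return NeuralDetection(
        f_stim_hz=f_stim,
        hit_rate=hr,
        false_alarm_rate=far,
        d_prime=m.d_prime,
        n_trials=n,
    )


def frequency_sweep(
    epoch_sets: dict[float, LFPEpochs],
    stim_window_ms: tuple[float, float] = (0.0, 500.0),
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0),
    control_offset_hz: float = 3.0,
    pad_to_hz: float | None = 1.0,
) -> list[NeuralDetection]:
    """Single-trial detection at each stimulation frequency.

    ``epoch_sets`` maps f_stim -> LFPEpochs recorded at that stimulation
    frequency. Requires at least two frequencies; rows come back sorted by
    frequency, deterministically.
    """
    if len(epoch_sets) < 2:
        raise ValueError("frequency sweep requires at least 2 frequencies")
    out = []
    for f in sorted(epoch_sets):
        ep = epoch_sets[f]
        freqs = [f - control_offset_hz, f]
        stim = spectral_amplitude(ep, stim_window_ms, freqs, "stim", pad_to_hz)
        base = spectral_amplitude(ep, baseline_window_ms, freqs, "baseline", pad_to_hz)
        out.append(single_trial_detection(stim, base, f, control_offset_hz))
    return out
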