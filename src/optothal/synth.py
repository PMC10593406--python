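"""Synthetic behavioral sessions and paired spike/LFP datasets.

Every analysis stage in this package has a recovery-based test surface:
the generator produces data with known ground-truth parameters, and the
analyses must recover them. The emulated experiment is periodic (30-80 Hz,
50% duty cycle) optogenetic stimulation of visual thalamus:

* **Behavior** — a nose-poke detection task. Stimulus onsets are uniform
  on 250-1750 ms after poke entry. The observer detects the stimulus with
  probability ``p_detect`` and then withdraws after a shifted-lognormal
  latency; independently, a memoryless early-withdrawal process with
  constant hazard produces premature responses. The earliest event wins.
  Closed-form expected hit and false-alarm rates under the analysis
  partition are provided (:func:`expected_rates`) so estimator recovery
  can be checked analytically.

* **Spikes** — an inhomogeneous Poisson train, rate
  r(t) = r0 * (1 + m*cos(2*pi*f*t - phi)) during stimulation and r0 at
  baseline, generated by thinning (exact, no time-binning). Sinusoidal
  modulation is the default because it gives the analytic vector strength
  R = m/2; an optional exponential adaptation envelope and burst
  insertion add realism and are excluded from analytic checks. A square
  (duty-cycle) drive option exists for realism.

* **LFP** — the sum of a causal biphasic spike-coupling kernel whose
  negative peak sits at a controllable lag (default 3.8 ms), a
  stimulation-frequency oscillation of controllable amplitude confined to
  the stimulation window, and 1/f-shaped noise band-limited to 300 Hz.

Same seed, same outputs, byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as spsig
from scipy.stats import norm

from .io_formats import (
    BehavioralSession,
    EpochSpec,
    LFPEpochs,
    SpikeTrain,
    StimulusCondition,
    TrialRecord,
)

__all__ = [
    "ObserverParams",
    "EphysParams",
    "Experiment",
    "gen_behavior_session",
    "expected_rates",
    "gen_entrained_spikes",
    "gen_coupled_lfp",
    "gen_experiment",
    "SCENARIOS",
]

ONSET_LO_MS = 250.0
ONSET_HI_MS = 1750.0
RESPONSE_WINDOW_MS = 500.0


@dataclass(frozen=True)
class ObserverParams:
    """Generative model of the behaving animal.

    ``p_detect``: probability of responding to the stimulus within the
    response window. ``latency_shift_ms, latency_mu, latency_sigma``:
    shifted-lognormal response latency (ms),
    latency = shift + LogNormal(mu, sigma). ``early_hazard_per_s``:
    constant hazard of spontaneous premature withdrawal, per second.
    """

    p_detect: float = 0.8
    latency_shift_ms: float = 150.0
    latency_mu: float = math.log(120.0)
    latency_sigma: float = 0.4
    early_hazard_per_s: float = 0.2
    n_trials: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_detect <= 1.0):
            raise ValueError("p_detect must be in [0, 1]")
        if self.early_hazard_per_s < 0:
            raise ValueError("hazard must be >= 0")


def gen_behavior_session(
    params: ObserverParams, animal_id: str = "sim", session_id: str = "s0"
) -> BehavioralSession:
    """Simulate one session of the nose-poke task.

    Per trial: onset ~ U(250, 1750) ms; premature withdrawal time
    W ~ Exp(hazard) from poke entry; with probability ``p_detect`` a
    detection response at onset + latency draw. The earliest event is the
    recorded response; events after trial timeout (onset + 1000 ms) leave
    the response absent.
    """
    rng = np.random.default_rng(params.seed)
    lam_ms = params.early_hazard_per_s / 1000.0
    trials = []
    for i in range(params.n_trials):
        onset = float(rng.uniform(ONSET_LO_MS, ONSET_HI_MS))
        w = float(rng.exponential(1.0 / lam_ms)) if lam_ms > 0 else math.inf
        if rng.random() < params.p_detect:
            lat = params.latency_shift_ms + float(
                rng.lognormal(params.latency_mu, params.latency_sigma)
            )
            r = onset + lat
        else:
            r = math.inf
        resp = min(w, r)
        timeout = onset + 1000.0
        response_ms = resp if resp <= timeout else None
        trials.append(TrialRecord(trial_index=i, onset_ms=onset,
                                  response_ms=response_ms))
    condition = StimulusCondition(modality="optogenetic", frequency_hz=40.0,
                                  amplitude_mw=10.0)
    return BehavioralSession(animal_id=animal_id, session_id=session_id,
                             trials=tuple(trials), condition=condition)


def expected_rates(
    params: ObserverParams,
    window_ms: float = RESPONSE_WINDOW_MS,
) -> tuple[float, float]:
    """Closed-form expected (Hr, FAr) of the generative observer under the
    onset-time partition analysis.

    For an early trial with onset o the response is min(W, o + L) where
    W ~ Exp(lambda) and L is the detection latency (present with
    probability p_d), so

        P(hit | o) = e^(-lambda*o) - e^(-lambda*(o+w)) * (1 - p_d*q),
        q = P(L <= w),

    and a false alarm on a late trial is W landing in the virtual window
    [o-750, o-750+w]. Averaging over the uniform onset halves gives the
    expected rates (Hr over [250, 1000), FAr over [1000, 1750]). Validated
    against brute-force Monte Carlo in the test suite.
    """
    lam = params.early_hazard_per_s / 1000.0  # per ms
    half = (ONSET_HI_MS - ONSET_LO_MS) / 2.0  # 750 ms
    w = window_ms
    if w > params.latency_shift_ms:
        q = float(norm.cdf(
            (math.log(w - params.latency_shift_ms) - params.latency_mu)
            / params.latency_sigma
        ))
    else:
        q = 0.0
    a, b = ONSET_LO_MS, ONSET_LO_MS + half       # early half [250, 1000)
    c, d = ONSET_LO_MS + half, ONSET_HI_MS       # late half [1000, 1750]
    if lam == 0:
        hr = params.p_detect * q
        return hr, 0.0
    integral = (math.exp(-lam * a) - math.exp(-lam * b)) / lam
    hr = (1.0 - math.exp(-lam * w) * (1.0 - params.p_detect * q)) * integral / half
    # FA window for onset o is [o - 750, o - 750 + w]
    int_late = (math.exp(-lam * c) - math.exp(-lam * d)) / lam
    far = (math.exp(lam * half) - math.exp(lam * (half - w))) * int_late / half
    return hr, far


# ---------------------------------------------------------------- ephys


@dataclass(frozen=True)
class EphysParams:
    """Ground truth for one paired spike/LFP dataset.

    Rates in Hz, times in ms, amplitudes in microvolts. ``stim_gain``
    multiplies the mean rate during stimulation (driven units fire above
    baseline); ``mod_depth`` is the sinusoidal rate-modulation depth m
    (analytic vector strength m/2, independent of the gain);
    ``kernel`` = (negative-peak latency ms, peak depth uV, width
    ms) of the causal spike->field coupling kernel; ``osc_amp_uv`` the
    stimulation-frequency field oscillation; ``noise`` = (1/f exponent,
    SD uV) of the band-limited background.
    """

    f_stim_hz: float = 40.0
    duty_cycle: float = 0.5
    stim_ms: float = 500.0
    baseline_ms: float = 500.0
    post_ms: float = 300.0
    r0_hz: float = 20.0
    stim_gain: float = 1.0
    mod_depth: float = 0.6
    phase_deg: float = 0.0
    adaptation_tau_ms: float | None = None
    burst_prob: float = 0.0
    drive: str = "sinusoidal"  # or "square" (duty-cycle pulse train)
    kernel: tuple[float, float, float] = (3.8, 40.0, 3.0)
    osc_amp_uv: float = 30.0
    noise: tuple[float, float] = (1.0, 15.0)
    lowpass_hz: float | None = 300.0
    fs_hz: float = 1000.0
    n_trials: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mod_depth <= 1.0):
            raise ValueError("mod_depth must be in [0, 1]")
        if self.fs_hz < 600:
            raise ValueError("fs_hz must be >= 600")
        if self.drive not in ("sinusoidal", "square"):
            raise ValueError(f"unknown drive {self.drive!r}")

    @property
    def trial_len_s(self) -> float:
        return (self.baseline_ms + self.stim_ms + self.post_ms) / 1000.0


def _rate_fn(p: EphysParams):
    """Trial-relative rate function r(t_s) and its upper bound, t=0 at
    trial start."""
    b_s = p.baseline_ms / 1000.0
    stim_s = p.stim_ms / 1000.0
    phi = math.radians(p.phase_deg)

    def rate(t: np.ndarray) -> np.ndarray:
        rel = t - b_s
        in_stim = (rel >= 0) & (rel < stim_s)
        if p.drive == "sinusoidal":
            mod = 1.0 + p.mod_depth * np.cos(
                2 * np.pi * p.f_stim_hz * rel - phi)
        else:
            frac = np.mod(rel * p.f_stim_hz, 1.0)
            mod = 1.0 + p.mod_depth * (2.0 * (frac < p.duty_cycle) - 1.0)
        r = np.where(in_stim, p.r0_hz * p.stim_gain * mod, p.r0_hz)
        if p.adaptation_tau_ms is not None:
            env = np.exp(-np.maximum(rel, 0.0) / (p.adaptation_tau_ms / 1000.0))
            r = np.where(in_stim, r * env, r)
        return r

    return rate, p.r0_hz * max(p.stim_gain, 1.0) * (1.0 + p.mod_depth)


def gen_entrained_spikes(params: EphysParams, unit_id: str = "sim-unit") -> SpikeTrain:
    """Inhomogeneous Poisson spike train by thinning, on the trial grid.

    Trial i occupies [i*T, (i+1)*T) with T = baseline + stim + post;
    stimulation onset at i*T + baseline. Optional burst insertion replaces
    a fraction ``burst_prob`` of spikes by 2-3 spikes with <4 ms ISIs.
    """
    rng = np.random.default_rng(params.seed)
    rate, r_max = _rate_fn(params)
    T = params.trial_len_s
    all_spikes: list[np.ndarray] = []
    epochs: list[EpochSpec] = []
    for i in range(params.n_trials):
        start = i * T
        n_cand = rng.poisson(r_max * T)
        cand = np.sort(rng.uniform(0.0, T, size=n_cand))
        keep = rng.random(n_cand) < rate(cand) / r_max
        spikes = cand[keep]
        if params.burst_prob > 0 and spikes.size:
            extra = []
            sel = rng.random(spikes.size) < params.burst_prob
            for t in spikes[sel]:
                n_extra = int(rng.integers(1, 3))  # burst of 2 or 3 total
                isis = rng.uniform(0.0015, 0.0035, size=n_extra)
                extra.extend(t + np.cumsum(isis))
            spikes = np.sort(np.concatenate([spikes, np.array(extra)]))
        all_spikes.append(start + spikes)
        epochs.append(EpochSpec(
            trial_start_s=start,
            stim_onset_s=start + params.baseline_ms / 1000.0,
            stim_offset_s=start + (params.baseline_ms + params.stim_ms) / 1000.0,
            frequency_hz=params.f_stim_hz,
        ))
    times = np.concatenate(all_spikes) if all_spikes else np.empty(0)
    times = np.unique(times)  # guard strict sortedness against collisions
    return SpikeTrain(unit_id=unit_id, spike_times_s=times, trials=tuple(epochs))


def _coupling_kernel(params: EphysParams) -> np.ndarray:
    """Causal biphasic kernel: depth-negative peak at the given latency
    followed by a smaller positive rebound."""
    tau_ms, amp_uv, width_ms = params.kernel
    sigma_ms = width_ms / 2.0
    dur_ms = tau_ms + 8.0 * sigma_ms
    t = np.arange(0.0, dur_ms, 1000.0 / params.fs_hz)
    k = -amp_uv * np.exp(-0.5 * ((t - tau_ms) / sigma_ms) ** 2)
    k += 0.25 * amp_uv * np.exp(-0.5 * ((t - tau_ms - 3 * sigma_ms) / sigma_ms) ** 2)
    return k


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, sd: float, fmax: float = 300.0) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise, band-limited to <= fmax."""
    if sd == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = (freqs > 0) & (freqs <= fmax)
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    # complex Gaussian spectrum with the target amplitude profile
    re = rng.standard_normal(freqs.size)
    im = rng.standard_normal(freqs.size)
    x = np.fft.irfft(shape * (re + 1j * im), n=n)
    x *= sd / x.std()
    return x


def gen_coupled_lfp(spikes: SpikeTrain, params: EphysParams,
                    site_id: str = "sim-site") -> LFPEpochs:
    """Cortical LFP coupled to the given spike train, on the same trials.

    Per trial: sum of the coupling kernel at each spike time, plus an
    ``osc_amp_uv`` cosine at the stimulation frequency during the
    stimulation window, plus band-limited 1/f noise; the sum is then
    zero-phase low-passed at ``lowpass_hz``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0x1F9)))
    fs = params.fs_hz
    n_samples = int(round(params.trial_len_s * fs))
    t0_ms = -params.baseline_ms
    kernel = _coupling_kernel(params)
    exp_n, sd = params.noise
    data = np.zeros((params.n_trials, n_samples))
    t_rel_s = (t0_ms / 1000.0) + np.arange(n_samples) / fs  # rel to stim onset
    stim_mask = (t_rel_s >= 0) & (t_rel_s < params.stim_ms / 1000.0)
    for i, epoch in enumerate(spikes.trials):
        row = np.zeros(n_samples)
        t_lo = epoch.stim_onset_s + t0_ms / 1000.0
        in_trial = spikes.spike_times_s[
            (spikes.spike_times_s >= t_lo)
            & (spikes.spike_times_s < t_lo + n_samples / fs)
        ]
        for t_spk in in_trial:
            j0 = int(round((t_spk - t_lo) * fs))
            j1 = min(j0 + kernel.size, n_samples)
            if j0 < n_samples:
                row[j0:j1] += kernel[: j1 - j0]
        if params.osc_amp_uv:
            row[stim_mask] += params.osc_amp_uv * np.cos(
                2 * np.pi * params.f_stim_hz * t_rel_s[stim_mask])
        row += _pink_noise(rng, n_samples, fs, exp_n, sd)
        data[i] = row
    if params.lowpass_hz is not None and params.lowpass_hz < fs / 2:
        sos = spsig.butter(4, params.lowpass_hz, btype="low", fs=fs, output="sos")
        data = spsig.sosfiltfilt(sos, data, axis=1)
    return LFPEpochs(data=data, fs_hz=fs, t0_ms=t0_ms, site_id=site_id)


# ----------------------------------------------------------- experiments


@dataclass(frozen=True)
class Experiment:
    """One synthetic dataset bundle with its machine-readable ground truth.

    ``spikes`` and ``lfp`` are keyed by stimulation frequency (a single
    40 Hz entry except for the frequency sweep).
    """

    session: BehavioralSession
    spikes: dict[float, SpikeTrain]
    lfp: dict[float, LFPEpochs]
    ground_truth: dict


SCENARIOS = ("null", "weak", "strong", "frequency_sweep")

_SWEEP_FREQS = (30.0, 40.0, 60.0, 80.0)


def _scenario_params(scenario: str, seed: int):
    if scenario == "null":
        obs = ObserverParams(p_detect=0.0, early_hazard_per_s=0.3, seed=seed)
        eph = dict(mod_depth=0.0, osc_amp_uv=0.0, kernel=(3.8, 0.0, 3.0))
    elif scenario == "weak":
        obs = ObserverParams(p_detect=0.4, early_hazard_per_s=0.25, seed=seed)
        eph = dict(mod_depth=0.3, stim_gain=1.3, osc_amp_uv=7.5,
                   kernel=(3.8, 15.0, 3.0))
    elif scenario in ("strong", "frequency_sweep"):
        obs = ObserverParams(p_detect=0.8, early_hazard_per_s=0.2, seed=seed)
        eph = dict(mod_depth=0.8, stim_gain=2.0, osc_amp_uv=30.0,
                   kernel=(3.8, 40.0, 3.0), burst_prob=0.005)
    else:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    return obs, eph


def gen_experiment(scenario: str, seed: int = 0, n_trials_ephys: int = 20) -> Experiment:
    """Generate a named preset: behavior session + paired spikes/LFP.

    Presets: ``null`` (no detection, no entrainment, no coupling),
    ``weak``, ``strong``, and ``frequency_sweep`` (the strong protocol at
    30/40/60/80 Hz). The ground-truth record lists every generator
    parameter and the analytic expectations derivable from them.
    """
    obs, eph_over = _scenario_params(scenario, seed)
    freqs = _SWEEP_FREQS if scenario == "frequency_sweep" else (40.0,)
    session = gen_behavior_session(obs, session_id=f"{scenario}-behavior")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(freqs))]
    spikes: dict[float, SpikeTrain] = {}
    lfp: dict[float, LFPEpochs] = {}
    eparams: dict[float, EphysParams] = {}
    for f, s in zip(freqs, child_seeds):
        p = EphysParams(f_stim_hz=f, n_trials=n_trials_ephys, seed=s, **eph_over)
        eparams[f] = p
        spikes[f] = gen_entrained_spikes(p, unit_id=f"{scenario}-{f:g}Hz")
        lfp[f] = gen_coupled_lfp(spikes[f], p, site_id=f"{scenario}-{f:g}Hz")
    hr, far = expected_rates(obs)
    gt = {
        "scenario": scenario,
        "seed": seed,
        "observer": asdict(obs),
        "expected_hit_rate": hr,
        "expected_false_alarm_rate": far,
        "ephys": {f"{f:g}": asdict(p) for f, p in eparams.items()},
        "analytic_vector_strength": eparams[freqs[0]].mod_depth / 2.0,
        "kernel_latency_ms": eparams[freqs[0]].kernel[0],
    }
    return Experiment(session=session, spikes=spikes, lfp=lfp, ground_truth=gt)
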