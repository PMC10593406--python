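# Methods

This note documents the models behind each analysis stage, the synthetic
generator that stands in for animal recordings, the numerical choices that
were genuinely open, and what the recovery tests do and do not establish.

## Reaction-time signal detection without catch trials

The task presents a stimulus on *every* trial, with onset uniform on
250–1750 ms after nose-poke entry, and rewards withdrawal within a 500 ms
response window. Classical SDT needs signal-absent trials; the analysis
manufactures them by partitioning trials at the onset midpoint (1000 ms,
assigned to the late half). Early-onset trials provide hits, misses, and
early aborts against the true window; late-onset trials provide false
alarms, correct rejections, and late aborts against a *virtual* window.

Open choices fixed here:

* **Virtual-window placement.** The virtual window is the hit window
  shifted earlier by the 750 ms partition half-width. Under the uniform
  onset design this deterministic shift preserves the marginal
  distribution of window start times, so hit and virtual windows are
  statistically indistinguishable in clock time — the property the
  construction needs. A randomized placement (virtual onset drawn
  uniformly from the early half) is available via
  `classify_trials(..., virtual_window="random")`.
* **Responses after the virtual window but before the late onset** count
  as correct rejections (the rejection criterion is "no response during
  the false-alarm window").
* **Window inclusion** is closed on both ends; boundary responses are
  hits/false alarms.
* **Extreme rates.** Rates of exactly 0 or 1 have no z-score; they are
  pulled to `1/(2N)` and `1 − 1/(2N)` of the relevant trial denominator
  before the quantile transform, and `correction_applied` records it.

Sign convention: bias `b = −(z(Hr)+z(FAr))/2` is negative for a liberal
observer (false alarms dominate) and positive for a conservative one
(misses dominate).

## Spike metrics

* **PSTH**: 5 ms bins by default, rate = trial-summed count /
  (n_trials × bin width); the integral times n_trials × bin equals the
  in-window spike count exactly.
* **Spike-train spectrum**: the stimulation-window train is binned at
  1 ms, summed over trials, mean-subtracted, and Fourier transformed; an
  entrained unit shows a peak at the stimulation frequency plus harmonics.
  The window must span ≥ 2 stimulation cycles.
* **Bursts**: a burst starts at a spike preceded by ≥ 50 ms of silence
  (the first spike of a record qualifies) whose next inter-spike interval
  is strictly < 4 ms, and extends while ISIs stay < 4 ms. Both boundary
  conventions (strict 4 ms, inclusive 50 ms) are exercised against an
  independent O(n²) scanner in the tests.
* **Vector strength**: spike phases are measured within the stimulation
  cycle, cycles anchored at stimulation onset (the light-ON edge — the
  phase reference is a convention; R is invariant to any common phase
  offset). Only stimulation-window spikes enter. Significance uses the
  Rayleigh statistic `Z = N R²` with the first-order corrected p-value
  `exp(−Z)[1 + (2Z − Z²)/(4N)]`, accurate for N ≈ 10–10⁴.
* **ON/OFF motifs**: per-trial firing rates in a 500 ms pre-stimulus
  baseline, the stimulation window, and a 150 ms post-offset window are
  compared by paired t-tests at α = 0.05. The post window length brackets
  the ~50 ms offset-response latencies of thalamocortical circuits; the
  OFF latency is read from the peak of the post-offset PSTH.

## LFP spectral analysis and decoding

Per trial, the windowed signal is mean-subtracted (no taper) and Fourier
transformed with amplitude normalization 2/n, so a pure sinusoid of
amplitude A gives SA = A at its frequency. The stimulation window is the
full 500 ms stimulation period; the baseline is the 500 ms immediately
before onset, so both windows share one spectral grid.

A 500 ms window has a natural 2 Hz grid on which the f_stim − 3 Hz control
frequency cannot fall. Windows are therefore zero-padded to a 1 Hz grid by
default (`pad_to_hz=1`); with padding disabled, requested frequencies map
to the nearest bin with half-way ties rounding down (37 → 36 Hz), and the
bins actually used are reported in `grid_hz`. Exact SA ties count against
detection — the conservative direction.

The single-trial decoder scores hit/false-alarm fractions per site and
converts them to d' through the same corrected z-difference as the
behavioral analysis, making neural and behavioral sensitivity directly
comparable.

## Thalamocortical coupling

STA epochs are ±100 ms of cortical LFP around each thalamic spike, spikes
snapped to the nearest LFP sample; epochs that would cross the trial's
recorded span are dropped and counted. By default only stimulation-window
spikes trigger epochs: the coupling analysis targets the driven period,
and baseline spikes — whose epochs contain no stimulus-locked field —
only dilute the estimate (`stim_only=False` restores the full-trial
behaviour).

**SFC** uses the *power* spectrum of the STA over the mean epoch power,
`SFC(f) = P_STA(f)/P̄(f)`. By Jensen's inequality this ratio is bounded by
1, reached when every epoch is identical, and decays as 1/N for spikes at
independent random field phases — both limits are tested. Bins whose mean
power is numerically zero (below 1e−15 of the spectral maximum) carry no
phase information and are reported as NaN.

**Latency** is the first local minimum of the STA at positive lag that
falls below 3 robust standard deviations (1.4826 × MAD) of the pre-spike
STA. The threshold rejects noise minima; under very strong entrainment the
pre-spike STA itself oscillates coherently, which inflates this reference
— a known limitation discussed below.

**Shoulder comparison**: coherence at f_stim vs f_stim − 3 Hz, tested by
resampling spike epochs with replacement (default 1000 draws); p is the
fraction of bootstrap differences ≤ 0.

## Synthetic generator

The generator emulates the study conditions: onsets uniform on
250–1750 ms, a 500 ms stimulation period at 50% duty cycle, stimulation
frequencies 30–80 Hz, LFP sampled at 1 kHz and low-passed at 300 Hz.

* **Observer**: detection with probability `p_detect`, shifted-lognormal
  response latency (defaults 150 ms shift, median 120 ms, σ = 0.4 — a
  ~270 ms median reaction time), and a memoryless premature-withdrawal
  hazard (0.2 s⁻¹). Closed-form expected Hr/FAr under the partition
  analysis are derived by integrating the exponential-race model over the
  uniform onset halves; the tests validate the closed form against an
  independent vectorized Monte Carlo before using it as the recovery
  target. With these defaults the observer sits at d' ≈ 2.0 — the upper
  range of trained performance on such tasks.
* **Spikes**: inhomogeneous Poisson by thinning (exact; no time binning),
  rate `r0·g·(1 + m·cos(2πft − φ))` during stimulation and `r0 = 20 Hz`
  at baseline. Sinusoidal modulation is the default because it gives the
  analytic vector strength `R = m/2`; a square (duty-cycle) drive exists
  for realism and is excluded from analytic checks. Optional exponential
  adaptation emulates the rapid response decay seen at high stimulation
  frequencies; optional burst insertion converts a fraction of spikes
  into < 4 ms ISI doublets/triplets.
* **LFP**: sum of a causal biphasic kernel per spike (negative peak at
  3.8 ms, 40 µV deep, 3 ms wide — the depth-negative deflection evoked by
  a thalamic volley), a stimulation-frequency cosine confined to the
  stimulation window, and 1/f-shaped noise (exponent 1, SD 15 µV)
  band-limited to 300 Hz, then zero-phase low-passed at 300 Hz.
* **Presets**: `null` (no detection, no modulation, no coupling), `weak`,
  `strong`, `frequency_sweep` (the strong protocol at 30/40/60/80 Hz).
  The strong preset uses modulation depth 0.8 with a ×2 stimulation rate
  gain: strong enough that every coupling phenomenon (entrainment,
  shoulder-frequency coherence excess, STA latency) is robustly
  detectable, while avoiding the extreme rate clustering of m = 1, where
  the oscillatory STA background can defeat the latency threshold.
  Seeding is hierarchical (`SeedSequence` spawn keys), so identical seeds
  give byte-identical outputs.

## What the tests show — and don't

The recovery suite establishes that each estimator returns the generating
parameter under the generator's assumptions: Poisson spiking, stationary
sinusoidal modulation, linear spike→field coupling, Gaussian 1/f noise,
an exponential withdrawal hazard. Real recordings violate all of these to
some degree (refractoriness, non-stationary adaptation, shared noise
across trials, non-Poisson bursting), so passing tests demonstrate
correctness of the analysis chain, not validity of those assumptions in
any particular dataset. Problem sizes were chosen to keep the full suite
under a minute of compute: 2000-trial behavioral sessions, 15–400 trial
ephys runs, 100-seed null ensembles.

Known limitations:

* The latency threshold (3 robust SDs of the pre-spike STA) becomes
  conservative under very strong entrainment, since the reference window
  then contains coherent oscillation rather than noise.
* The SFC of multi-unit-like data contains a broadband self-spike
  (kernel) component at all frequencies; the shoulder comparison is the
  appropriate control for stimulation-specific coherence.
* The closed-form observer expectations assume the deterministic −750 ms
  virtual-window placement; the randomized placement option changes
  per-trial labels but not the marginal rates.
* Chance-level decoding (|d'| < 0.2) is a property of seed ensembles, not
  of every individual seed: at 200 trials a single null d' has a standard
  error near 0.13.
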