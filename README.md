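# optothal

Analysis pipeline for experiments in which periodic optogenetic stimulation
of the visual thalamus (LGN) must be detected — by a behaving animal in a
reaction-time task, and by the cortical circuit it projects to. The package
implements the full analysis chain for such experiments:

* **Behavior** — signal-detection analysis of a nose-poke detection task
  *without catch trials*. Stimulus onsets are uniform on 250–1750 ms after
  poke entry; trials are partitioned into two 750 ms halves by onset time.
  Early trials yield hits (withdrawal within the 500 ms response window),
  misses, and early aborts; on late trials a *virtual* response window,
  placed 750 ms before the true onset, defines false alarms and correct
  rejections. Rates and metrics follow standard SDT:

  `Hr = H/(H+M+Abort_early)`, `FAr = FA/(FA+CR+Abort_late)`,
  `d' = z(Hr) − z(FAr)`, `b = −(z(Hr)+z(FAr))/2`.

* **Spikes** — PSTH, spike-train amplitude spectrum, thalamic burst
  detection (≥2 spikes with inter-spike intervals < 4 ms, preceded by
  ≥ 50 ms of silence), phase locking via vector strength
  `R = |N⁻¹ Σⱼ e^{iθⱼ}|` with Rayleigh-test significance (`Z = N R²`),
  and ON/OFF response-motif classification by paired t-tests of per-trial
  rates against baseline.

* **LFP** — per-trial Fourier spectral amplitude (SA) at the stimulation
  frequency; entrainment as a paired t-test of SA(f_stim) during
  stimulation vs baseline; and single-trial spectral decoding: a *hit* when
  SA_stim(f_stim) > SA_stim(f_stim−3 Hz), a *false alarm* when
  SA_baseline(f_stim) > SA_stim(f_stim), converted to a neural d' with the
  same corrected z-difference as the behavioral analysis.

* **Thalamocortical coupling** — spike-triggered average (STA) of the
  cortical LFP on thalamic spikes (±100 ms), response latency as the time
  of the first negative STA peak, and spike-field coherence
  `SFC(f) = P_STA(f)/P̄(f)` (STA power over mean epoch power, bounded in
  [0, 1]), with a spike-resampling bootstrap comparing coherence at the
  stimulation frequency against a shoulder frequency 3 Hz below.

* **Synthetic data** — generators for all three data products with known
  ground truth: a behavioral observer with closed-form expected hit and
  false-alarm rates, inhomogeneous-Poisson spike trains with analytic
  vector strength `R = m/2`, and an LFP built from a spike-coupling kernel,
  a stimulation-frequency oscillation, and 1/f noise band-limited to
  300 Hz. Every analysis stage is tested by recovering these parameters.

## Worked example

```python
import optothal as ot

exp = ot.gen_experiment("strong", seed=7)          # behavior + spikes + LFP
m = ot.session_metrics(exp.session)
print(f"Hr={m.hit_rate:.3f} FAr={m.false_alarm_rate:.3f} "
      f"d'={m.d_prime:.2f} bias={m.bias:.2f}")

spikes, lfp = exp.spikes[40.0], exp.lfp[40.0]
pl = ot.vector_strength(spikes)
sta = ot.spike_triggered_average(spikes, lfp)
print(f"R={pl.R:.3f} (N={pl.N}, Rayleigh p={pl.p_rayleigh:.2g}); "
      f"STA latency={sta.latency_ms} ms")
```

prints

```
Hr=0.749 FAr=0.093 d'=1.99 bias=0.32
R=0.397 (N=426, Rayleigh p=0); STA latency=4.0 ms
```

The observer detects ~75% of early-onset stimuli while withdrawing
prematurely in ~9% of virtual windows, a sensitivity of d' ≈ 2. The
thalamic unit is strongly phase-locked to the 40 Hz light cycle
(ground-truth modulation 0.8, so R ≈ 0.4), and each thalamic spike is
followed ~4 ms later by a depth-negative cortical LFP deflection — the
generator's kernel latency of 3.8 ms at the 1 kHz sample grid.

A command-line interface wraps the same stages:

```sh
optothal run --scenario strong --seed 7 --out results/
optothal simulate --scenario null --seed 1 --out data/
optothal behavior --log data/behavior.csv --out behavior.csv
```

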