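"""Reaction-time signal-detection analysis of the nose-poke detection task.

The task has no catch trials: every trial carries a stimulus whose onset is
drawn uniformly on 250-1750 ms after nose-poke entry. Signal detection
theory is applied by partitioning trials into two 750 ms halves by onset
time. Early trials (onset in [250, 1000)) yield hits (withdrawal within the
500 ms response window after onset), misses (later or no withdrawal), or
early aborts (withdrawal before onset). For late trials (onset in
[1000, 1750]) a *virtual* response window — the hit window shifted earlier
by the 750 ms partition half-width — defines false alarms; withdrawal
before it is a late abort and anything else a correct rejection. Because
the virtual window precedes the true onset, its timing is indistinguishable
to the animal from a hit window, but no stimulus has yet occurred in it.

Rates and signal-detection metrics::

    Hr  = H / (H + M + Abort_early)
    FAr = FA / (FA + CR + Abort_late)
    d'  = z(Hr) - z(FAr)
    b   = -(z(Hr) + z(FAr)) / 2

where z is the inverse standard normal CDF. Negative bias marks a liberal
observer (more false alarms), positive a conservative one (more misses).
Extreme rates (0 or 1) are replaced by 1/(2N) and 1 - 1/(2N) of the
relevant denominator before taking z.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .io_formats import BehavioralSession, ValidationError
from .stats_core import TestResult, normal_quantile, one_sample_t_test

__all__ = [
    "Outcome",
    "TrialOutcome",
    "OutcomeCounts",
    "DetectionMetrics",
    "classify_trials",
    "compute_rates",
    "compute_dprime_bias",
    "session_metrics",
    "learning_curve",
]

RESPONSE_WINDOW_MS = 500.0
PARTITION_MS = (250.0, 1000.0, 1750.0)


class Outcome(enum.Enum):
    HIT = "HIT"
    MISS = "MISS"
    FALSE_ALARM = "FALSE_ALARM"
    CORRECT_REJECTION = "CORRECT_REJECTION"
    ABORT_EARLY = "ABORT_EARLY"
    ABORT_LATE = "ABORT_LATE"


@dataclass(frozen=True)
class TrialOutcome:
    trial_index: int
    label: Outcome
    window_start_ms: float
    window_end_ms: float


@dataclass(frozen=True)
class OutcomeCounts:
    H: int
    M: int
    FA: int
    CR: int
    abort_early: int
    abort_late: int

    def __post_init__(self) -> None:
        if min(self.H, self.M, self.FA, self.CR,
               self.abort_early, self.abort_late) < 0:
            raise ValueError("outcome counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.H + self.M + self.FA + self.CR + self.abort_early + self.abort_late


@dataclass(frozen=True)
class DetectionMetrics:
    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    bias: float
    correction_applied: bool
    counts: OutcomeCounts | None = None
    median_hit_rt_ms: float | None = None


def classify_trials(
    session: BehavioralSession,
    response_window_ms: float = RESPONSE_WINDOW_MS,
    partition_ms: tuple[float, float, float] = PARTITION_MS,
    virtual_window: str = "shift",
    rng: np.random.Generator | None = None,
) -> tuple[list[TrialOutcome], OutcomeCounts]:
    """Assign each trial one of the six outcomes and tally the counts.

    ``virtual_window`` places the late-trial false-alarm window: "shift"
    (default) puts it at ``onset - half_width`` deterministically, which
    preserves the marginal window-time distribution under the uniform
    onset design; "random" draws a virtual onset uniformly from the early
    partition (requires ``rng``).

    Window inclusion is closed on both ends; onset exactly at the
    partition midpoint belongs to the late half.
    """
    lo, mid, hi = partition_ms
    half_width = mid - lo
    if virtual_window not in ("shift", "random"):
        raise ValueError(f"unknown virtual_window policy {virtual_window!r}")
    if virtual_window == "random" and rng is None:
        raise ValueError("virtual_window='random' requires an rng")

    outcomes: list[TrialOutcome] = []
    tally = {k: 0 for k in Outcome}
    for t in session.trials:
        onset, resp = t.onset_ms, t.response_ms
        if not (lo <= onset <= hi):
            raise ValidationError(
                f"trial {t.trial_index}: onset {onset} outside partition [{lo}, {hi}]"
            )
        if onset < mid:  # early half: the true response window
            w0, w1 = onset, onset + response_window_ms
            if resp is None or resp > w1:
                label = Outcome.MISS
            elif resp < w0:
                label = Outcome.ABORT_EARLY
            else:
                label = Outcome.HIT
        else:  # late half: virtual window before the true onset
            if virtual_window == "shift":
                w0 = onset - half_width
            else:
                w0 = float(rng.uniform(lo, mid))
            w1 = w0 + response_window_ms
            if resp is not None and w0 <= resp <= w1:
                label = Outcome.FALSE_ALARM
            elif resp is not None and resp < w0:
                label = Outcome.ABORT_LATE
            else:
                label = Outcome.CORRECT_REJECTION
        tally[label] += 1
        outcomes.append(TrialOutcome(t.trial_index, label, w0, w1))

    counts = OutcomeCounts(
        H=tally[Outcome.HIT],
        M=tally[Outcome.MISS],
        FA=tally[Outcome.FALSE_ALARM],
        CR=tally[Outcome.CORRECT_REJECTION],
        abort_early=tally[Outcome.ABORT_EARLY],
        abort_late=tally[Outcome.ABORT_LATE],
    )
    assert counts.n_trials == session.n_trials
    return outcomes, counts


def compute_rates(counts: OutcomeCounts) -> tuple[float, float]:
    """Hr = H/(H+M+Abort_early), FAr = FA/(FA+CR+Abort_late)."""
    denom_h = counts.H + counts.M + counts.abort_early
    denom_f = counts.FA + counts.CR + counts.abort_late
    if denom_h == 0 or denom_f == 0:
        raise ValueError("empty trial partition: cannot form rates")
    return counts.H / denom_h, counts.FA / denom_f


def _correct_rate(rate: float, n: int) -> tuple[float, bool]:
    if rate <= 0.0:
        return 1.0 / (2 * n), True
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n), True
    return rate, False


def compute_dprime_bias(
    hit_rate: float,
    false_alarm_rate: float,
    n_signal: int = 1,
    n_noise: int = 1,
    correction: str = "loglinear",
) -> DetectionMetrics:
    """d' = z(Hr) - z(FAr); bias b = -(z(Hr) + z(FAr))/2.

    Rates of exactly 0 or 1 are first pulled to the open interval using
    1/(2N) of the relevant denominator (``n_signal`` for Hr, ``n_noise``
    for FAr); ``correction_applied`` records whether this happened.
    """
    if correction not in ("loglinear", "none"):
        raise ValueError(f"unknown correction policy {correction!r}")
    hr, far = hit_rate, false_alarm_rate
    applied = False
    if correction == "loglinear":
        hr, a1 = _correct_rate(hr, n_signal)
        far, a2 = _correct_rate(far, n_noise)
        applied = a1 or a2
    z_h = normal_quantile(hr)
    z_f = normal_quantile(far)
    return DetectionMetrics(
        hit_rate=hr,
        false_alarm_rate=far,
        d_prime=z_h - z_f,
        bias=-(z_h + z_f) / 2.0,
        correction_applied=applied,
    )


def session_metrics(
    session: BehavioralSession,
    response_window_ms: float = RESPONSE_WINDOW_MS,
    partition_ms: tuple[float, float, float] = PARTITION_MS,
) -> DetectionMetrics:
    """Classify, form rates, and compute d'/bias for one session.

    Also reports the median hit reaction time (response minus onset, ms).
    """
    outcomes, counts = classify_trials(session, response_window_ms, partition_ms)
    hr, far = compute_rates(counts)
    m = compute_dprime_bias(
        hr, far,
        n_signal=counts.H + counts.M + counts.abort_early,
        n_noise=counts.FA + counts.CR + counts.abort_late,
    )
    hit_idx = {o.trial_index for o in outcomes if o.label is Outcome.HIT}
    rts = [t.response_ms - t.onset_ms for t in session.trials
           if t.trial_index in hit_idx]
    median_rt = float(np.median(rts)) if rts else None
    return DetectionMetrics(
        hit_rate=m.hit_rate,
        false_alarm_rate=m.false_alarm_rate,
        d_prime=m.d_prime,
        bias=m.bias,
        correction_applied=m.correction_applied,
        counts=counts,
        median_hit_rt_ms=median_rt,
    )


def learning_curve(
    sessions: list[BehavioralSession], final_k: int = 4
) -> tuple[list[DetectionMetrics], TestResult]:
    """Per-session metrics in order, plus a one-sample t-test of d' against
    zero over the final ``final_k`` sessions (the acquisition criterion).
    """
    if not sessions:
        raise ValueError("learning_curve requires at least one session")
    if final_k > len(sessions):
        raise ValueError(
            f"final_k={final_k} exceeds the {len(sessions)} sessions provided"
        )
    metrics = [session_metrics(s) for s in sessions]
    dprimes = np.array([m.d_prime for m in metrics[-final_k:]])
    if dprimes.size == 1:
        raise ValueError("need at least 2 final sessions for the t-test")
    return metrics, one_sample_t_test(dprimes, 0.0)
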