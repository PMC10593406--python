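"""Shared statistical primitives.

Four small tests used throughout the pipeline: the inverse standard normal
CDF (the z(.) of the d'/bias formulas), a paired t-test with explicit
degenerate-variance handling, a 2x2 Pearson chi-square, and the Rayleigh
test of circular uniformity used for spike phase locking.

All tests are two-sided unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "normal_quantile",
    "paired_t_test",
    "one_sample_t_test",
    "chi_square_2x2",
    "rayleigh_test",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Parameters
    ----------
    statistic : float
        The test statistic (t, chi-square, or Rayleigh Z).
    df : float or None
        Degrees of freedom, where the test has them.
    p_value : float
        Two-sided p-value in [0, 1].
    degenerate : bool
        True when the sampling distribution collapsed (e.g. zero variance
        of paired differences) and the p-value is a limit, not an estimate.
    """

    statistic: float
    df: float | None
    p_value: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def normal_quantile(p: float) -> float:
    """Inverse standard normal CDF, z = Phi^-1(p).

    Raises ValueError unless 0 < p < 1.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"normal_quantile requires 0 < p < 1, got {p}")
    return float(sps.norm.ppf(p))


def _t_from_diffs(d: np.ndarray) -> TestResult:
    n = d.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if np.ptp(d) == 0.0:
        # Degenerate: all differences identical.
        if mean == 0.0:
            return TestResult(statistic=0.0, df=df, p_value=1.0, degenerate=True)
        t = math.inf if mean > 0 else -math.inf
        return TestResult(statistic=t, df=df, p_value=0.0, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=df, p_value=min(p, 1.0))


def paired_t_test(x, y) -> TestResult:
    """Two-sided paired t-test of ``x`` against ``y``.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and df = n - 1. Zero
    variance of the differences is reported with ``degenerate=True``:
    p = 1 when every difference is exactly zero, p = 0 (with infinite t)
    when the common difference is nonzero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired t-test requires equal-length 1-D samples")
    return _t_from_diffs(x - y)


def one_sample_t_test(x, popmean: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test of ``x`` against ``popmean``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("one-sample t-test requires a 1-D sample")
    return _t_from_diffs(x - popmean)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1.

    No continuity correction. Requires non-negative counts and strictly
    positive row and column margins.
    """
    counts = (a, b, c, d)
    if any(v < 0 for v in counts):
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("chi-square 2x2 requires positive margins")
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=float(stat), df=1, p_value=p)


def rayleigh_test(R: float, N: int) -> TestResult:
    """Rayleigh test of circular uniformity from vector strength.

    Z = N * R**2; the p-value uses the first-order corrected approximation
    p = exp(-Z) * [1 + (2Z - Z^2) / (4N)], clipped to [0, 1], which is
    accurate for the spike counts (roughly 10 to 10^4) typical of
    stimulation-epoch recordings.
    """
    if not (0.0 <= R <= 1.0):
        raise ValueError(f"vector strength R must lie in [0, 1], got {R}")
    if N < 1:
        raise ValueError("N must be >= 1")
    Z = N * R * R
    # exp(-Z) underflows gracefully to 0 for large Z
    with np.errstate(over="ignore"):
        p = math.exp(-Z) * (1.0 + (2.0 * Z - Z * Z) / (4.0 * N))
    p = min(max(p, 0.0), 1.0)
    return TestResult(statistic=Z, df=None, p_value=p)
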