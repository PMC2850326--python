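"""Optimiser benchmarking statistics.

Given run logs (best objective value at fixed intervals), this module
computes mean descent curves with standard errors and 95% ranges,
time-to-target statistics with success rates (exact Clopper-Pearson
binomial intervals), relative and absolute speed-up ratios, and Fieller
confidence intervals for ratios of Gaussian means.

Definitions: *relative* speed-up compares the serial algorithm with K
islands against the parallel algorithm on K nodes (a pure
communication-overhead measure; K would be ideal); *absolute* speed-up
compares the best serial configuration (K* islands — one, for the gap-gene
benchmark) against the parallel algorithm, the practically relevant gain.
All metrics are pure functions of the logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .islands import RunLog

__all__ = [
    "DescentCurve",
    "TargetStats",
    "descent_curve",
    "time_to_target",
    "binomial_ci",
    "fieller_ci",
    "speedup",
    "parse_duration",
    "format_duration",
]


@dataclass(frozen=True)
class DescentCurve:
    """Per-interval summary of best-so-far objective values over runs."""

    table: pd.DataFrame  # columns: interval, mean, se, lo95, hi95

    def __post_init__(self):
        t = self.table
        if not ((t["lo95"] <= t["mean"] + 1e-12)
                & (t["mean"] <= t["hi95"] + 1e-12)).all():
            raise ValueError("envelope must contain the mean")


@dataclass(frozen=True)
class TargetStats:
    """Time-to-target summary for one target objective value.

    ``mean_time``/``se_time`` summarise first-crossing times over the runs
    that reached the target (the standard error uses the number of attempts
    as the denominator, matching the benchmark's convention); the success
    rate carries an exact binomial 95% interval.
    """

    target: float
    n_attempts: int
    n_reached: int
    mean_time: float | None
    se_time: float | None
    ci_time: tuple[float, float] | None
    success_rate: float
    ci_success: tuple[float, float]

    def __post_init__(self):
        if self.n_reached > self.n_attempts:
            raise ValueError("n_reached cannot exceed n_attempts")


def descent_curve(logs: list[RunLog], use_time: bool = False) -> DescentCurve:
    """Mean, standard error and empirical 95% range per log interval.

    Logs must share a common generation grid; ``use_time`` averages elapsed
    seconds per interval as the x-axis instead of generations.
    """
    if len(logs) < 2:
        raise ValueError("need at least two logs")
    grids = [tuple(log.generations) for log in logs]
    if len(set(grids)) != 1:
        raise ValueError("logs have mismatched interval grids")
    values = np.vstack([log.best_so_far() for log in logs])
    x = (np.vstack([log.elapsed for log in logs]).mean(axis=0)
         if use_time else np.asarray(grids[0], dtype=float))
    n = values.shape[0]
    mean = values.mean(axis=0)
    se = values.std(axis=0, ddof=1) / np.sqrt(n)
    lo, hi = np.percentile(values, [2.5, 97.5], axis=0)
    return DescentCurve(table=pd.DataFrame(
        {"interval": x, "mean": mean, "se": se, "lo95": lo, "hi95": hi}))


def _first_crossing(log: RunLog, target: float, use_time: bool) -> float | None:
    best = log.best_so_far()
    hit = np.nonzero(best <= target)[0]
    if hit.size == 0:
        return None
    i = int(hit[0])
    return float(log.elapsed[i] if use_time else log.generations[i])


def binomial_ci(successes: int, n: int, confidence: float = 0.95
                ) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    alpha = 1.0 - confidence
    lo = sps.beta.ppf(alpha / 2, successes, n - successes + 1) if successes else 0.0
    hi = (sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
          if successes < n else 1.0)
    return float(lo), float(hi)


def time_to_target(logs: list[RunLog], target: float, use_time: bool = False,
                   confidence: float = 0.95) -> TargetStats:
    """First-crossing statistics for one target objective value.

    The mean time is over runs that actually reached the target; the
    success rate is the proportion of runs that did, with an exact binomial
    confidence interval.
    """
    times = [_first_crossing(log, target, use_time) for log in logs]
    reached = [t for t in times if t is not None]
    n_attempts, n_reached = len(times), len(reached)
    if n_reached:
        mean = float(np.mean(reached))
        sd = float(np.std(reached, ddof=1)) if n_reached > 1 else 0.0
        se = sd / np.sqrt(n_attempts)
        z = sps.norm.ppf(0.5 + confidence / 2)
        ci = (mean - z * se, mean + z * se)
    else:
        mean = se = ci = None
    rate = n_reached / n_attempts if n_attempts else 0.0
    return TargetStats(target=target, n_attempts=n_attempts,
                       n_reached=n_reached, mean_time=mean, se_time=se,
                       ci_time=ci, success_rate=rate,
                       ci_success=binomial_ci(n_reached, n_attempts,
                                              confidence))


def fieller_ci(num_mean: float, num_se: float, den_mean: float, den_se: float,
               confidence: float = 0.95
               ) -> tuple[float | None, float | None, bool]:
    """Fieller interval for the ratio of two independent Gaussian means.

    Returns (low, high, bounded).  When the denominator is not
    significantly nonzero at the requested confidence the interval is
    unbounded (``bounded=False`` with None endpoints where infinite).
    """
    if num_se < 0 or den_se < 0:
        raise ValueError("standard errors must be non-negative")
    z = float(sps.norm.ppf(0.5 + confidence / 2))
    a, b = num_mean, den_mean
    disc = (a * b) ** 2 - (b ** 2 - z ** 2 * den_se ** 2) \
        * (a ** 2 - z ** 2 * num_se ** 2)
    denom = b ** 2 - z ** 2 * den_se ** 2
    if denom <= 0:
        return None, None, False
    if disc < 0:
        disc = 0.0
    lo = (a * b - np.sqrt(disc)) / denom
    hi = (a * b + np.sqrt(disc)) / denom
    return float(lo), float(hi), True


def speedup(serial: TargetStats, parallel: TargetStats,
            confidence: float = 0.95) -> tuple[float, tuple[float | None, float | None]]:
    """Speed-up ratio (serial time / parallel time) with a Fieller interval.

    Pass the serial stats for K islands against parallel stats for K nodes
    to obtain the *relative* speed-up, or the stats of the optimal serial
    configuration (K* islands) to obtain the *absolute* speed-up.  Both
    target values must agree.
    """
    if serial.target != parallel.target:
        raise ValueError("serial and parallel stats must share a target")
    if serial.mean_time is None or parallel.mean_time is None:
        raise ValueError("both sides must have reached the target")
    if parallel.mean_time == 0:
        raise ValueError("parallel mean time is zero")
    ratio = serial.mean_time / parallel.mean_time
    lo, hi, _ = fieller_ci(serial.mean_time, serial.se_time or 0.0,
                           parallel.mean_time, parallel.se_time or 0.0,
                           confidence)
    return float(ratio), (lo, hi)


def parse_duration(text: str) -> float:
    """Parse an ``H:MM`` (or ``H:MM:SS``) duration into minutes."""
    parts = text.strip().split(":")
    if len(parts) == 2:
        h, m = parts
        return int(h) * 60 + float(m)
    if len(parts) == 3:
        h, m, s = parts
        return int(h) * 60 + float(m) + float(s) / 60
    raise ValueError(f"cannot parse duration {text!r}")


def format_duration(minutes: float) -> str:
    h, m = divmod(round(minutes), 60)
    return f"{int(h)}:{int(m):02d}"
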