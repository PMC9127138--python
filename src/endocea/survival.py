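"""Published survival summaries -> monthly transition probabilities.

Under an exponential time-to-event assumption a median time-to-event m
(months) maps to a monthly event probability

    P(1 month) = 1 - 0.5 ** (1 / m),

the probability form of the constant hazard R = ln 2 / m through
P = 1 - exp(-R).  This module implements that closed form, the generic
rate <-> probability conversions, an exponential least-squares fit to
Kaplan-Meier (KM) survival points standing in for digitized curves, a
builder that assembles a three-state transition matrix from published
medians (calibrating the post-progression death probability when no
post-progression summary is published), and a validator that checks a
transition matrix against the closed form.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .markov import DEATH, PD, PFS, TransitionMatrix, run_cohort


@dataclass(frozen=True)
class SurvivalSummary:
    """Published median PFS / OS (months) for one arm and population."""

    median_pfs: float
    median_os: float
    arm: str = ""
    population: str = "overall"

    def __post_init__(self) -> None:
        if self.median_pfs <= 0 or self.median_os <= 0:
            raise ValueError("survival medians must be positive")
        if self.median_os < self.median_pfs:
            raise ValueError(
                f"median OS ({self.median_os}) below median PFS ({self.median_pfs})"
            )


@dataclass(frozen=True)
class KMPoints:
    """Ordered Kaplan-Meier survival points (time in months, S(t))."""

    times: tuple[float, ...]
    survival: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.survival):
            raise ValueError("times and survival must have equal length")
        if len(self.times) == 0:
            raise ValueError("at least one point required")
        if self.times[0] < 0:
            raise ValueError("times must be non-negative")
        if any(t2 < t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be non-decreasing")
        if any(not 0.0 <= s <= 1.0 for s in self.survival):
            raise ValueError("survival values must lie in [0, 1]")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(self.survival, self.survival[1:])):
            raise ValueError("survival must be non-increasing")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "KMPoints":
        ts, ss = zip(*pairs)
        return cls(tuple(float(t) for t in ts), tuple(float(s) for s in ss))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time_months", "survival"])
            writer.writerows(zip(self.times, self.survival))

    @classmethod
    def from_csv(cls, path: str | Path) -> "KMPoints":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            pairs = [(float(row["time_months"]), float(row["survival"])) for row in reader]
        return cls.from_pairs(pairs)


def median_to_monthly_prob(median: float, cycle: float = 1.0) -> float:
    """Per-cycle event probability implied by an exponential median."""
    if median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    if cycle <= 0:
        raise ValueError(f"cycle length must be positive, got {cycle}")
    return 1.0 - 0.5 ** (cycle / median)


def rate_to_prob(rate: float, cycle: float = 1.0) -> float:
    """P = 1 - exp(-R * cycle) for a constant monthly hazard R."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return 1.0 - math.exp(-rate * cycle)


def prob_to_rate(prob: float, cycle: float = 1.0) -> float:
    """R = -ln(1 - P) / cycle; the inverse of :func:`rate_to_prob`."""
    if not 0.0 <= prob < 1.0:
        raise ValueError(f"probability must lie in [0, 1), got {prob}")
    return -math.log1p(-prob) / cycle


def fit_exponential(points: KMPoints) -> float:
    """Least-squares exponential rate from KM survival points.

    Fits -ln S(t) = R * t through the origin by ordinary least squares,
    i.e. R = sum(t * y) / sum(t^2) with y = -ln S(t).  Points at S = 1
    carry no information beyond the origin and points at S = 0 have an
    infinite transform; both are dropped.
    """
    ts, ys = [], []
    for t, s in zip(points.times, points.survival):
        if 0.0 < s < 1.0 and t > 0:
            ts.append(t)
            ys.append(-math.log(s))
    if not ts:
        raise ValueError("no informative points: all survival values are 0 or 1")
    t = np.asarray(ts)
    y = np.asarray(ys)
    return float(np.dot(t, y) / np.dot(t, t))


def _simulated_median_os(matrix: TransitionMatrix, horizon: int) -> float:
    """Cycle at which cohort survival (1 - Death occupancy) crosses 0.5.

    Linear interpolation between the bracketing cycles; inf when survival
    never crosses within the horizon.
    """
    trace = run_cohort(matrix, horizon)
    surv = 1.0 - trace.occupancy[:, DEATH]
    below = np.nonzero(surv <= 0.5)[0]
    if below.size == 0:
        return math.inf
    i = int(below[0])
    if i == 0:
        return 0.0
    s_prev, s_cur = surv[i - 1], surv[i]
    return (i - 1) + (s_prev - 0.5) / (s_prev - s_cur)


def derive_transitions(
    summary: SurvivalSummary,
    pd_death_prob: float | str = "calibrate",
    cycle: float = 1.0,
    horizon: int = 600,
    tol: float = 1e-6,
) -> TransitionMatrix:
    """Build a three-state matrix from published medians.

    The monthly PFS-exit probability comes from the PFS median and the
    PFS->Death probability from the OS median (deaths before progression
    assumed to track the marginal OS hazard); PFS->PD is the difference,
    floored at zero.  PD->Death is either supplied or calibrated by
    bisection so the cohort's simulated median OS (interpolated survival
    crossing of 0.5) matches the published OS median.
    """
    import warnings

    p_exit = median_to_monthly_prob(summary.median_pfs, cycle)
    p_fd = median_to_monthly_prob(summary.median_os, cycle)
    if p_fd > p_exit:
        warnings.warn(
            "PFS->Death probability exceeds total PFS-exit probability; "
            "flooring PFS->PD at 0",
            stacklevel=2,
        )
    p_fp = max(p_exit - p_fd, 0.0)

    def build(q: float) -> TransitionMatrix:
        return TransitionMatrix.from_probs(
            pfs_pd=p_fp, pfs_death=p_fd, pd_death=q
        )

    if pd_death_prob != "calibrate":
        return build(float(pd_death_prob))

    lo, hi = 1e-9, 1.0 - 1e-9
    f = lambda q: _simulated_median_os(build(q), horizon) - summary.median_os
    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo >= 0 >= f_hi):
        raise ValueError(
            "cannot bracket PD->Death calibration: simulated median OS at the "
            f"bracket ends is {f_lo + summary.median_os:.3g} / "
            f"{f_hi + summary.median_os:.3g} vs target {summary.median_os}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return build(0.5 * (lo + hi))


def validate_transitions(
    matrix: TransitionMatrix,
    summary: SurvivalSummary,
    tol_exit: float = 0.02,
    tol_death: float = 0.001,
) -> dict:
    """Check a matrix against the closed-form median conversion.

    Compares the matrix's total PFS-exit probability with the value the
    PFS median implies, and PFS->Death with the value the OS median
    implies; returns a JSON-serializable report with both discrepancies
    and pass flags at the given tolerances.
    """
    p = matrix.probs
    exit_model = float(p[PFS, PD] + p[PFS, DEATH])
    death_model = float(p[PFS, DEATH])
    exit_formula = median_to_monthly_prob(summary.median_pfs)
    death_formula = median_to_monthly_prob(summary.median_os)
    exit_delta = abs(exit_model - exit_formula)
    death_delta = abs(death_model - death_formula)
    return {
        "arm": summary.arm,
        "population": summary.population,
        "median_pfs": summary.median_pfs,
        "median_os": summary.median_os,
        "pfs_exit_model": exit_model,
        "pfs_exit_formula": exit_formula,
        "pfs_exit_discrepancy": exit_delta,
        "pfs_exit_pass": bool(exit_delta < tol_exit),
        "pfs_death_model": death_model,
        "pfs_death_formula": death_formula,
        "pfs_death_discrepancy": death_delta,
        "pfs_death_pass": bool(death_delta < tol_death),
        "tol_exit": tol_exit,
        "tol_death": tol_death,
        "pass": bool(exit_delta < tol_exit and death_delta < tol_death),
    }
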