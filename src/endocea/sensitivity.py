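"""One-way (tornado) and probabilistic sensitivity analysis.

The one-way analysis re-runs the deterministic model at each parameter's
low and high value (published range, else base +/- 25%) holding all else
at base, and sorts parameters by the resulting ICER swing.

The probabilistic sensitivity analysis (PSA) is second-order: each of n
draws samples every uncertain parameter from a mean-preserving
distribution fitted to its (base, low, high) description — Gamma for
costs, Beta for utilities, both by the method of moments with the range
read as a 95% interval (SD = (high - low) / (2 x 1.96)) — re-prices both
arms through the cohort model, and records paired (cost, QALY) outcomes.
Transition probabilities are fixed and so the cohort traces are shared
across draws; re-pricing a fixed trace is algebraically identical to
re-running the cohort.  Cost-effectiveness acceptability curves (CEAC)
report, per willingness-to-pay value, the fraction of draws with positive
incremental net monetary benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import accumulate, run_cohort
from .scenario import (
    UTILITY_PD,
    UTILITY_PFS,
    ParamSpec,
    ScenarioConfig,
    run_scenario,
)

logger = logging.getLogger(__name__)

_Z95 = 1.96  # two-sided 95% normal quantile (conventional rounding)


@dataclass(frozen=True)
class ParameterDistribution:
    """A sampling distribution fitted to (base, low, high)."""

    name: str
    base: float
    low: float | None
    high: float | None
    family: str
    shape: float = 0.0  # Gamma shape / Beta alpha
    scale: float = 0.0  # Gamma scale / Beta beta

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "Gamma":
            return rng.gamma(self.shape, self.scale, size=size)
        if self.family == "Beta":
            return rng.beta(self.shape, self.scale, size=size)
        return np.full(size, self.base)

    def mean(self) -> float:
        if self.family == "Gamma":
            return self.shape * self.scale
        if self.family == "Beta":
            return self.shape / (self.shape + self.scale)
        return self.base


def fit_distribution(
    base: float,
    low: float | None,
    high: float | None,
    family: str,
    name: str = "",
    range_z: float = _Z95,
) -> ParameterDistribution:
    """Method-of-moments fit with mean = base and the range as a 95% CI.

    Gamma: shape = mean^2 / var, scale = var / mean.  Beta: the standard
    two-moment inversion, with the variance clipped just inside the
    feasible bound mean x (1 - mean) when the stated range is too wide
    for the [0, 1] support.  A degenerate range (or the Fixed family)
    yields a point mass at base.

    ``range_z`` sets how many standard deviations the half-range spans
    (1.96 reads (low, high) as a 95% interval; 1.0 reads it as
    mean +/- SD).
    """
    if family not in ("Gamma", "Beta", "Fixed"):
        raise ValueError(f"unknown distribution family {family!r}")
    if family == "Fixed" or low is None or high is None or high <= low:
        return ParameterDistribution(name, base, low, high, "Fixed")
    sd = (high - low) / (2.0 * range_z)
    var = sd * sd
    if family == "Gamma":
        if base <= 0:
            raise ValueError(f"parameter {name!r}: Gamma requires a positive base")
        return ParameterDistribution(
            name, base, low, high, "Gamma", shape=base * base / var, scale=var / base
        )
    if not 0.0 < base < 1.0:
        raise ValueError(f"parameter {name!r}: Beta requires base in (0, 1)")
    bound = base * (1.0 - base)
    var = min(var, 0.999 * bound)
    kappa = bound / var - 1.0
    return ParameterDistribution(
        name, base, low, high, "Beta", shape=base * kappa, scale=(1.0 - base) * kappa
    )


def distributions_for(
    config: ScenarioConfig, range_z: float = _Z95
) -> tuple[ParameterDistribution, ...]:
    """Fit a distribution to every ranged parameter of a scenario."""
    return tuple(
        fit_distribution(
            p.base, p.low, p.high, p.family if p.has_range else "Fixed", p.name, range_z
        )
        for p in config.parameters()
    )


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado: ICER at the parameter's low and high value."""

    name: str
    base: float
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_high - self.icer_low)


def one_way_tornado(
    config: ScenarioConfig,
    parameters: tuple[ParamSpec, ...] | None = None,
    span: float = 0.25,
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """Deterministic one-way sensitivity analysis, sorted by ICER swing."""
    if parameters is None:
        parameters = config.tornado_parameters(span)
    known = {p.name for p in config.parameters()} | {
        arm.acquisition_total_key for arm in config.arms
    }
    entries = []
    for p in parameters:
        if p.name not in known:
            raise KeyError(f"tornado parameter {p.name!r} not found in the scenario")
        low = p.low if p.low is not None else p.base * (1.0 - span)
        high = p.high if p.high is not None else p.base * (1.0 + span)
        icers = []
        for value in (low, high):
            result = run_scenario(config.build({p.name: value}), wtp)
            icers.append(result.incremental.icer)
        entries.append(
            TornadoEntry(p.name, p.base, low, high, icer_low=icers[0], icer_high=icers[1])
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.name for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    )


@dataclass(frozen=True)
class PSASampleSet:
    """Paired per-draw outcomes for both arms under sampled parameters."""

    seed: int
    n: int
    arm_names: tuple[str, str]  # (intervention, comparator)
    cost: np.ndarray  # (n, 2) discounted totals, columns follow arm_names
    qaly: np.ndarray  # (n, 2)
    draws: pd.DataFrame  # sampled parameter values, one column per parameter
    n_clipped: int = 0

    def incremental_cost(self) -> np.ndarray:
        return self.cost[:, 0] - self.cost[:, 1]

    def incremental_qaly(self) -> np.ndarray:
        return self.qaly[:, 0] - self.qaly[:, 1]

    def summary(self) -> pd.DataFrame:
        """Mean and SD of cost and QALYs per arm across the draws."""
        return pd.DataFrame(
            {
                "mean_cost": self.cost.mean(axis=0),
                "sd_cost": self.cost.std(axis=0, ddof=1),
                "mean_qaly": self.qaly.mean(axis=0),
                "sd_qaly": self.qaly.std(axis=0, ddof=1),
            },
            index=list(self.arm_names),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Per-draw outcomes joined with the sampled parameter values."""
        inter, comp = self.arm_names
        out = pd.DataFrame(
            {
                f"cost_{inter}": self.cost[:, 0],
                f"cost_{comp}": self.cost[:, 1],
                f"qaly_{inter}": self.qaly[:, 0],
                f"qaly_{comp}": self.qaly[:, 1],
            }
        )
        return pd.concat([out, self.draws], axis=1)


DEFAULT_PSA_SEED = 20220510


def run_psa(
    config: ScenarioConfig,
    distributions: tuple[ParameterDistribution, ...] | None = None,
    n: int = 10_000,
    seed: int = DEFAULT_PSA_SEED,
) -> PSASampleSet:
    """Second-order Monte-Carlo PSA with ``n`` parameter-set draws.

    Transition probabilities are fixed inputs, so each arm's cohort trace
    is computed once and re-priced per draw; utilities sampled outside
    [0, 1] are clipped with a logged count.
    """
    if distributions is None:
        distributions = distributions_for(config)
    rng = np.random.default_rng(seed)
    sampled: dict[str, np.ndarray] = {}
    n_clipped = 0
    for dist in distributions:
        values = dist.sample(rng, n)
        if dist.name in (UTILITY_PFS, UTILITY_PD):
            clipped = np.clip(values, 0.0, 1.0)
            n_clipped += int((clipped != values).sum())
            values = clipped
        sampled[dist.name] = values
    if n_clipped:
        logger.info("clipped %d sampled utility values into [0, 1]", n_clipped)

    base_spec = config.build()
    inter, comp = base_spec.intervention.name, base_spec.comparator.name
    traces = {
        arm.name: run_cohort(arm.matrix, base_spec.horizon_cycles)
        for arm in base_spec.arms
    }
    varying = [d.name for d in distributions if d.family != "Fixed"]
    cost = np.empty((n, 2))
    qaly = np.empty((n, 2))
    for i in range(n):
        overrides = {name: float(sampled[name][i]) for name in varying}
        spec_i = config.build(overrides)
        for j, arm_name in enumerate((inter, comp)):
            outcome = accumulate(
                traces[arm_name],
                spec_i.arm(arm_name).valuation,
                spec_i.discount,
                spec_i.half_cycle_correction,
            )
            cost[i, j] = outcome.cost_total
            qaly[i, j] = outcome.qaly_total
    return PSASampleSet(
        seed=seed,
        n=n,
        arm_names=(inter, comp),
        cost=cost,
        qaly=qaly,
        draws=pd.DataFrame(sampled),
        n_clipped=n_clipped,
    )


@dataclass(frozen=True)
class CEACPoint:
    """Probability the intervention is cost-effective at one WTP value."""

    wtp: float
    probability: float


def ceac(samples: PSASampleSet, wtp_grid: list[float] | np.ndarray) -> list[CEACPoint]:
    """Acceptability curve: P(incremental NMB > 0) per WTP value."""
    if samples.n == 0:
        raise ValueError("empty PSA sample set")
    d_cost = samples.incremental_cost()
    d_qaly = samples.incremental_qaly()
    points = []
    for wtp in wtp_grid:
        nmb = wtp * d_qaly - d_cost
        points.append(CEACPoint(float(wtp), float(np.mean(nmb > 0))))
    return points


def ceac_table(points: list[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"wtp": [p.wtp for p in points], "probability": [p.probability for p in points]}
    )
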