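"""Synthetic inputs: pseudo individual-patient data and random scenarios.

No patient-level data from the source trial are available, so the
survival-input pathway is exercised on simulated cohorts: exponential
progression times at the published PFS median, an exponential
post-progression survival time whose rate is solved numerically so the
marginal overall-survival median matches the published OS median, and
optional independent exponential censoring.  Kaplan-Meier curves
estimated from these cohorts (via lifelines) stand in for digitized
trial curves.  Randomized full scenario configurations support
property-based testing of the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.optimize import brentq

from .scenario import (
    AdverseEventConfig,
    ArmConfig,
    ParamSpec,
    ScenarioConfig,
)
from .survival import KMPoints


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one simulated survival cohort."""

    n: int
    median_pfs: float
    median_os: float
    censoring_rate: float = 0.0  # exponential censoring hazard per month
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if self.median_pfs <= 0 or self.median_os <= 0:
            raise ValueError("medians must be positive")
        if self.median_os < self.median_pfs:
            raise ValueError(
                f"median OS ({self.median_os}) below median PFS ({self.median_pfs})"
            )
        if self.censoring_rate < 0:
            raise ValueError("censoring rate must be non-negative")


def _sum_exp_survival(t: float, a: float, b: float) -> float:
    """S(t) of the sum of independent Exp(a) and Exp(b) variables."""
    if abs(a - b) < 1e-12:
        return float((1.0 + a * t) * math.exp(-a * t))
    return float((b * math.exp(-a * t) - a * math.exp(-b * t)) / (b - a))


def post_progression_rate(median_pfs: float, median_os: float) -> float:
    """Exponential post-progression hazard matching the marginal OS median.

    OS = PFS + post-progression time; solves S_OS(median_os) = 0.5 for
    the post-progression rate.  Infinite (no post-progression survival)
    when the medians coincide.
    """
    a = math.log(2.0) / median_pfs
    if median_os <= median_pfs * (1.0 + 1e-9):
        return math.inf
    return float(
        brentq(lambda b: _sum_exp_survival(median_os, a, b) - 0.5, 1e-8, 1e4)
    )


def simulate_ipd(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Simulate per-patient PFS / OS times with optional censoring.

    Returns a frame with columns patient_id, pfs_months, pfs_event,
    os_months, os_event; times are censored observations and the event
    flags mark uncensored ones.
    """
    rng = np.random.default_rng(spec.seed)
    a = math.log(2.0) / spec.median_pfs
    pfs = rng.exponential(1.0 / a, size=spec.n)
    b = post_progression_rate(spec.median_pfs, spec.median_os)
    post = np.zeros(spec.n) if math.isinf(b) else rng.exponential(1.0 / b, size=spec.n)
    os_time = pfs + post
    if spec.censoring_rate > 0:
        censor = rng.exponential(1.0 / spec.censoring_rate, size=spec.n)
    else:
        censor = np.full(spec.n, np.inf)
    return pd.DataFrame(
        {
            "patient_id": np.arange(spec.n),
            "pfs_months": np.minimum(pfs, censor),
            "pfs_event": pfs <= censor,
            "os_months": np.minimum(os_time, censor),
            "os_event": os_time <= censor,
        }
    )


def km_from_ipd(ipd: pd.DataFrame, endpoint: str = "pfs") -> KMPoints:
    """Kaplan-Meier product-limit survival points from simulated IPD.

    ``endpoint`` selects the pfs or os columns; points are emitted at the
    observed event times (censoring only re-weights the risk set), in the
    two-column form the survival-input fitters consume.
    """
    if endpoint not in ("pfs", "os"):
        raise ValueError("endpoint must be 'pfs' or 'os'")
    times = ipd[f"{endpoint}_months"].to_numpy()
    events = ipd[f"{endpoint}_event"].to_numpy()
    if not events.any():
        raise ValueError("no events: Kaplan-Meier curve is uninformative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events])
    survival = kmf.survival_function_at_times(event_times).to_numpy()
    return KMPoints(tuple(float(t) for t in event_times), tuple(float(s) for s in survival))


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    ipd.to_csv(path, index=False)


def _random_param(rng: np.random.Generator, name: str, base: float, family: str) -> ParamSpec:
    return ParamSpec(name, base, 0.75 * base, 1.25 * base, family)


def _random_arm(rng: np.random.Generator, name: str, role: str) -> ArmConfig:
    pfs_exit = float(rng.uniform(0.05, 0.5))
    death_share = float(rng.uniform(0.1, 0.9))
    pfs_death = pfs_exit * death_share
    pd_death = float(rng.uniform(0.02, 0.3))
    n_drugs = int(rng.integers(1, 3))
    drugs = tuple(
        _random_param(rng, f"{name} drug {i}", float(rng.uniform(100, 20_000)), "Gamma")
        for i in range(n_drugs)
    )
    total = sum(d.base for d in drugs) + float(rng.uniform(0, 500))
    aes = tuple(
        AdverseEventConfig(
            f"{name} AE {i}",
            float(rng.uniform(0, 0.5)),
            _random_param(rng, f"{name} AE {i}", float(rng.uniform(500, 15_000)), "Gamma"),
        )
        for i in range(int(rng.integers(0, 4)))
    )
    return ArmConfig(
        name=name,
        role=role,
        transitions={
            "pfs_pfs": 1.0 - pfs_exit,
            "pfs_pd": pfs_exit - pfs_death,
            "pfs_death": pfs_death,
            "pd_pd": 1.0 - pd_death,
            "pd_death": pd_death,
        },
        drug_acquisition_monthly_total=total,
        drugs=drugs,
        administration_minutes_monthly=float(rng.uniform(0, 120)),
        adverse_events=aes,
        subsequent_therapy_acceptance_rate=float(rng.uniform(0, 1)),
    )


def random_scenario(seed: int) -> ScenarioConfig:
    """A fully valid random two-arm scenario for property-based testing.

    Matrices are row-stochastic with absorbing Death and strictly
    positive death probabilities from both live states; costs are
    non-negative; utilities lie in [0, 1] with PD no better than PFS.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    u_pfs = float(rng.uniform(0.3, 0.99))
    u_pd = float(rng.uniform(0.05, u_pfs))
    median_pfs = float(rng.uniform(2, 12))
    return ScenarioConfig(
        label=f"random scenario {seed}",
        population="synthetic",
        arms=(
            _random_arm(rng, "A", "intervention"),
            _random_arm(rng, "B", "comparator"),
        ),
        utility_pfs=ParamSpec("Utility of PFS state", u_pfs, 0.75 * u_pfs, min(1.0, 1.25 * u_pfs), "Beta"),
        utility_pd=ParamSpec("Utility of PD state", u_pd, 0.75 * u_pd, min(1.0, 1.25 * u_pd), "Beta"),
        disease_management=_random_param(
            rng, "Costs of disease management", float(rng.uniform(50, 1000)), "Gamma"
        ),
        testing=_random_param(
            rng, "Testing for dMMR/MSI-H status-one set", float(rng.uniform(0.01, 2000)), "Gamma"
        ),
        palliative_care=_random_param(
            rng, "Costs of palliative care-one set", float(rng.uniform(0.01, 20_000)), "Gamma"
        ),
        administration_cost_per_10min=_random_param(
            rng, "Costs of administration per 10 mins", float(rng.uniform(10, 100)), "Gamma"
        ),
        horizon_cycles=600,
        discount_annual_rate=float(rng.uniform(0.0, 0.05)),
        wtp_per_qaly=100_000.0,
        survival={
            "A": (median_pfs, median_pfs + float(rng.uniform(0.5, 12))),
        },
    )
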