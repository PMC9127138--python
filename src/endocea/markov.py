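"""Three-state Markov cohort engine.

States are ordered (PFS, PD, Death): progression-free, progressed
disease, and death.  A cohort starts in PFS, moves under a monthly
row-stochastic transition matrix with Death absorbing and no recovery
from PD, and accumulates per-state costs and quality-adjusted life-years
(QALYs) with annual discounting and an optional half-cycle correction.

Accumulation conventions
------------------------
* Cycle-start occupancy counting over a horizon of T cycles; the
  half-cycle correction is the trapezoidal variant (half weight on
  cycle 0, full weight on cycles 1..T-1, half weight on cycle T).
* Discount factor at cycle t is (1 + annual_rate) ** (-t * cycle / 12).
* One-time entry costs are charged at cycle 0 undiscounted; transition
  costs (palliative care) are charged to the Death inflow of each cycle
  at the arriving cycle's discount factor, attributed to the cost bucket
  of the state the patient died from.  Neither is half-cycle corrected.
* QALYs are occupancy x utility x (cycle length / 12) years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

STATES: tuple[str, str, str] = ("PFS", "PD", "Death")
PFS, PD, DEATH = 0, 1, 2

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 3x3 monthly transition matrix over (PFS, PD, Death)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix, got shape {p.shape}")
        if (p < -1e-15).any() or (p > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = p.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_ROW_TOL, rtol=0):
            raise ValueError(f"rows must sum to 1, got {rows}")
        if not np.allclose(p[DEATH], [0.0, 0.0, 1.0], atol=1e-15):
            raise ValueError("Death must be absorbing: last row must be (0, 0, 1)")
        if p[PD, PFS] != 0.0:
            raise ValueError("recovery PD->PFS is not modelled; entry must be 0")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_probs(
        cls, pfs_pd: float, pfs_death: float, pd_death: float
    ) -> "TransitionMatrix":
        """Build from the three free probabilities; stay-probabilities fill rows."""
        return cls(
            np.array(
                [
                    [1.0 - pfs_pd - pfs_death, pfs_pd, pfs_death],
                    [0.0, 1.0 - pd_death, pd_death],
                    [0.0, 0.0, 1.0],
                ]
            )
        )


@dataclass(frozen=True)
class StateValuation:
    """Monthly costs, utilities and event costs attached to the states."""

    monthly_cost: tuple[float, float, float]
    utility: tuple[float, float, float]
    death_transition_cost: float = 0.0
    entry_cost: float = 0.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.monthly_cost):
            raise ValueError("monthly costs must be non-negative")
        if any(not 0.0 <= u <= 1.0 for u in self.utility):
            raise ValueError("utilities must lie in [0, 1]")
        if self.utility[DEATH] != 0.0:
            raise ValueError("Death utility must be 0")
        if self.death_transition_cost < 0 or self.entry_cost < 0:
            raise ValueError("event costs must be non-negative")


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate applied with monthly compounding."""

    annual_rate: float = 0.03
    cycle_length_months: float = 1.0

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.cycle_length_months <= 0:
            raise ValueError("cycle length must be positive")

    def factors(self, n_cycles: int) -> np.ndarray:
        t = np.arange(n_cycles + 1)
        return (1.0 + self.annual_rate) ** (-t * self.cycle_length_months / 12.0)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle plus the inter-cycle transition flows."""

    occupancy: np.ndarray  # (n_cycles + 1, 3)
    flows: np.ndarray  # (n_cycles, 3, 3); flows[t, i, j] moves during cycle t

    @property
    def n_cycles(self) -> int:
        return self.flows.shape[0]


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted and undiscounted totals with per-state decompositions."""

    cost_total: float
    qaly_total: float
    cost_by_state: dict[str, float]
    qaly_by_state: dict[str, float]
    undiscounted_cost_total: float
    undiscounted_qaly_total: float
    undiscounted_cost_by_state: dict[str, float] = field(default_factory=dict)
    undiscounted_qaly_by_state: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise comparison of two arm outcomes at a willingness-to-pay."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    nmb: float
    wtp: float
    dominance: str | None  # "intervention", "comparator", or None


def run_cohort(
    matrix: TransitionMatrix,
    n_cycles: int,
    initial: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> CohortTrace:
    """Propagate a cohort for ``n_cycles`` monthly cycles.

    Occupancy at cycle t is the initial distribution left-multiplied by
    the matrix t times; flows[t] records the mass moving i -> j between
    cycles t and t + 1 (needed for one-time transition costs).
    """
    init = np.asarray(initial, dtype=float)
    if init.shape != (3,) or (init < 0).any() or abs(init.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancy must be a length-3 distribution")
    p = matrix.probs
    occ = np.empty((n_cycles + 1, 3))
    flows = np.empty((n_cycles, 3, 3))
    occ[0] = init
    for t in range(n_cycles):
        flows[t] = occ[t][:, None] * p
        occ[t + 1] = flows[t].sum(axis=0)
    return CohortTrace(occupancy=occ, flows=flows)


def accumulate(
    trace: CohortTrace,
    valuation: StateValuation,
    discount: DiscountSpec = DiscountSpec(),
    half_cycle: bool = True,
) -> ArmOutcome:
    """Accumulate discounted costs and QALYs over a cohort trace."""
    n = trace.n_cycles
    occ = trace.occupancy
    live = occ[n, :DEATH].sum()
    if live > 1e-4:
        warnings.warn(
            f"horizon too short for convergence: live occupancy {live:.2e} "
            "remains at the final cycle",
            stacklevel=2,
        )

    weights = np.ones(n + 1)
    if half_cycle:
        weights[0] = 0.5
        weights[n] = 0.5
    else:
        weights[n] = 0.0

    disc = discount.factors(n)
    years_per_cycle = discount.cycle_length_months / 12.0
    cost = np.asarray(valuation.monthly_cost)
    util = np.asarray(valuation.utility)

    def totals(factors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        person_cycles = (weights * factors) @ occ  # per-state weighted sums
        cost_by_state = person_cycles * cost
        qaly_by_state = person_cycles * util * years_per_cycle
        # palliative-care transition cost on the Death inflow, discounted at
        # the arriving cycle, attributed to the source state's bucket
        death_inflow = trace.flows[:, :DEATH, DEATH]  # (n, 2) from PFS / PD
        cost_by_state[:DEATH] += (
            factors[1:] @ death_inflow
        ) * valuation.death_transition_cost
        # entry costs at cycle 0, undiscounted, split by initial occupancy
        cost_by_state += occ[0] * valuation.entry_cost
        return cost_by_state, qaly_by_state

    cost_disc, qaly_disc = totals(disc)
    cost_undisc, qaly_undisc = totals(np.ones(n + 1))
    return ArmOutcome(
        cost_total=float(cost_disc.sum()),
        qaly_total=float(qaly_disc.sum()),
        cost_by_state=dict(zip(STATES, cost_disc.tolist())),
        qaly_by_state=dict(zip(STATES, qaly_disc.tolist())),
        undiscounted_cost_total=float(cost_undisc.sum()),
        undiscounted_qaly_total=float(qaly_undisc.sum()),
        undiscounted_cost_by_state=dict(zip(STATES, cost_undisc.tolist())),
        undiscounted_qaly_by_state=dict(zip(STATES, qaly_undisc.tolist())),
    )


def compare(a: ArmOutcome, b: ArmOutcome, wtp: float = 100_000.0) -> IncrementalResult:
    """Incremental result of arm ``a`` versus comparator ``b``.

    The incremental cost-effectiveness ratio (ICER) is delta-cost over
    delta-QALY; when one arm simply dominates (cheaper and more
    effective) the ratio is meaningless and the dominance flag is set
    instead.  Net monetary benefit is wtp x dQALY - dCost.
    """
    d_cost = a.cost_total - b.cost_total
    d_qaly = a.qaly_total - b.qaly_total
    dominance = None
    if d_cost < 0 and d_qaly > 0:
        dominance = "intervention"
    elif d_cost > 0 and d_qaly < 0:
        dominance = "comparator"
    icer = None
    if dominance is None and d_qaly != 0.0:
        icer = d_cost / d_qaly
    return IncrementalResult(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        icer=icer,
        nmb=wtp * d_qaly - d_cost,
        wtp=wtp,
        dominance=dominance,
    )
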