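"""Per-state monthly cost arithmetic.

The model prices each health state per monthly cycle from its components:
drug acquisition, incidence-weighted grade 3-4 adverse-event (AE)
management, routine disease management, and — in the progressed-disease
state — crossover subsequent therapy priced off the *other* arm's
progression-free monthly total.  One-time costs (biomarker testing at
model entry) and transition costs (palliative care on entering Death) are
kept apart from the monthly totals; the cohort engine applies them to
flows, not occupancy.

All arithmetic is carried out in full floating-point precision; currency
is rounded (2 decimal places, half-up) only at presentation via
:func:`round_currency`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal


def round_currency(amount: float) -> Decimal:
    """Round a dollar amount to cents, half-up, for presentation."""
    return Decimal(repr(float(amount))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class AdverseEventItem:
    """A grade 3-4 adverse event attributed to one arm.

    ``grade34_rate`` is the trial incidence (proportion of patients),
    ``management_cost`` the one-off management cost per event in USD.
    """

    name: str
    grade34_rate: float
    management_cost: float
    attributed_arm: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.grade34_rate <= 1.0:
            raise ValueError(
                f"adverse event {self.name!r}: rate {self.grade34_rate} outside [0, 1]"
            )
        if self.management_cost < 0:
            raise ValueError(
                f"adverse event {self.name!r}: negative management cost {self.management_cost}"
            )


@dataclass(frozen=True)
class DrugCostSpec:
    """Monthly drug acquisition, given directly or from unit components.

    Either ``monthly_acquisition_cost`` is set, or the unit component
    fields (``unit_price`` per mg or per administration, ``dose``,
    ``administrations_per_month``) are.  ``body_surface_area`` scales a
    per-m2 dose; an administration-time component may be bundled via
    ``admin_minutes_per_administration`` and ``admin_cost_per_10min``.
    """

    name: str
    monthly_acquisition_cost: float | None = None
    unit_price: float | None = None
    dose: float | None = None
    administrations_per_month: float | None = None
    body_surface_area: float | None = None
    admin_minutes_per_administration: float = 0.0
    admin_cost_per_10min: float = 0.0

    def __post_init__(self) -> None:
        for label, value in (
            ("monthly_acquisition_cost", self.monthly_acquisition_cost),
            ("unit_price", self.unit_price),
            ("dose", self.dose),
            ("administrations_per_month", self.administrations_per_month),
            ("admin_minutes_per_administration", self.admin_minutes_per_administration),
            ("admin_cost_per_10min", self.admin_cost_per_10min),
        ):
            if value is not None and value < 0:
                raise ValueError(f"drug {self.name!r}: negative {label} ({value})")


@dataclass(frozen=True)
class StateCostSpec:
    """Monthly and event-driven costs of one health state in one arm."""

    drug_acquisition: float = 0.0
    ae_management: float = 0.0
    disease_management: float = 0.0
    subsequent_therapy: float = 0.0
    one_time_entry_costs: tuple[tuple[str, float], ...] = field(default_factory=tuple)
    transition_costs: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for label, value in (
            ("drug_acquisition", self.drug_acquisition),
            ("ae_management", self.ae_management),
            ("disease_management", self.disease_management),
            ("subsequent_therapy", self.subsequent_therapy),
        ):
            if value < 0:
                raise ValueError(f"negative {label} component ({value})")
        for label, value in (*self.one_time_entry_costs, *self.transition_costs):
            if value < 0:
                raise ValueError(f"negative event cost {label!r} ({value})")


def ae_management_cost(items: list[AdverseEventItem] | tuple[AdverseEventItem, ...]) -> float:
    """Incidence-weighted monthly AE management cost: sum of rate x cost."""
    return float(sum(item.grade34_rate * item.management_cost for item in items))


def subsequent_therapy_cost(
    other_arm_pfs_monthly_total: float,
    disease_management: float,
    acceptance_rate: float,
) -> float:
    """Monthly crossover subsequent-therapy cost in the progressed state.

    Patients failing one arm are assumed to cross over to the other arm's
    regimen with probability ``acceptance_rate``; the cost transferred is
    the other arm's progression-free monthly total net of the disease
    management that the progressed state already pays.
    """
    if not 0.0 <= acceptance_rate <= 1.0:
        raise ValueError(f"acceptance rate {acceptance_rate} outside [0, 1]")
    if other_arm_pfs_monthly_total < disease_management:
        raise ValueError(
            "other arm's monthly total "
            f"({other_arm_pfs_monthly_total}) below disease management ({disease_management})"
        )
    return acceptance_rate * (other_arm_pfs_monthly_total - disease_management)


def drug_acquisition_monthly(spec: DrugCostSpec) -> float:
    """Monthly acquisition cost of one drug.

    A directly stated monthly cost wins; otherwise the cost is assembled
    from unit price x dose x administrations per month, with optional
    body-surface-area scaling of the dose and a bundled administration-time
    charge (minutes / 10 x cost per 10 minutes, per administration).
    """
    if spec.monthly_acquisition_cost is not None:
        return float(spec.monthly_acquisition_cost)
    if spec.unit_price is None or spec.dose is None or spec.administrations_per_month is None:
        raise ValueError(
            f"drug {spec.name!r}: give either monthly_acquisition_cost or all of "
            "unit_price, dose and administrations_per_month"
        )
    dose = spec.dose * (spec.body_surface_area if spec.body_surface_area is not None else 1.0)
    monthly = spec.unit_price * dose * spec.administrations_per_month
    monthly += (
        spec.admin_minutes_per_administration / 10.0
        * spec.admin_cost_per_10min
        * spec.administrations_per_month
    )
    return float(monthly)


def state_monthly_total(spec: StateCostSpec) -> float:
    """Sum of the recurring monthly components of a state cost spec.

    One-time entry costs and transition costs are event-driven and
    deliberately excluded.
    """
    return float(
        spec.drug_acquisition
        + spec.ae_management
        + spec.disease_management
        + spec.subsequent_therapy
    )
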