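"""Scenario configuration: YAML schema, validation, and model assembly.

A :class:`ScenarioConfig` mirrors the published input table of the
comparison: per-arm transition probabilities, drug acquisition costs with
their component decomposition, adverse-event (AE) incidences and unit
management costs, shared disease-management / testing / palliative-care
costs, utilities, discounting, horizon and the willingness-to-pay (WTP)
threshold.  ``build()`` resolves it — optionally under a parameter
override mapping, which is how the sensitivity analyses re-price the
model — into an immutable :class:`ScenarioSpec` of transition matrices
and state valuations ready for the cohort engine.

Resolution rules
----------------
* An arm's monthly drug-acquisition cost is the published arm total plus
  the deviation of each sampled component (drug or administration time)
  from its base value, so the published total is reproduced exactly at
  base while component-level uncertainty still propagates.
* The progressed-disease (PD) state pays disease management plus
  crossover subsequent therapy: acceptance rate x (the other arm's
  progression-free monthly total net of disease management).
* Biomarker testing is a one-time entry cost in both arms; palliative
  care is a transition cost on entering Death.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .costs import StateCostSpec, ae_management_cost, state_monthly_total
from .markov import (
    DiscountSpec,
    StateValuation,
    TransitionMatrix,
    accumulate,
    compare,
    run_cohort,
)

_FAMILIES = ("Gamma", "Beta", "Fixed")

# canonical override / parameter names shared by the sensitivity analyses
ADMIN_COST = "Costs of administration per 10 mins"
DISEASE_MANAGEMENT = "Costs of disease management"
TESTING = "Testing for dMMR/MSI-H status-one set"
PALLIATIVE = "Costs of palliative care-one set"
UTILITY_PFS = "Utility of PFS state"
UTILITY_PD = "Utility of PD state"


class ConfigError(ValueError):
    """A scenario configuration violated the schema or an invariant."""


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain scalar input: base value, range, distribution family."""

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    family: str = "Fixed"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(
                f"parameter {self.name!r}: unknown distribution {self.family!r} "
                f"(expected one of {_FAMILIES})"
            )
        if self.low is not None and self.high is not None:
            if not self.low <= self.base <= self.high:
                raise ConfigError(
                    f"parameter {self.name!r}: base {self.base} outside "
                    f"range [{self.low}, {self.high}]"
                )

    @property
    def has_range(self) -> bool:
        return self.low is not None and self.high is not None


@dataclass(frozen=True)
class AdverseEventConfig:
    name: str
    grade34_rate: float
    cost: ParamSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.grade34_rate <= 1.0:
            raise ConfigError(
                f"adverse event {self.name!r}: grade 3-4 rate "
                f"{self.grade34_rate} outside [0, 1]"
            )


@dataclass(frozen=True)
class ArmConfig:
    name: str
    role: str  # "intervention" or "comparator"
    transitions: Mapping[str, float]
    drug_acquisition_monthly_total: float
    drugs: tuple[ParamSpec, ...] = ()
    administration_minutes_monthly: float = 0.0
    adverse_events: tuple[AdverseEventConfig, ...] = ()
    subsequent_therapy_acceptance_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("intervention", "comparator"):
            raise ConfigError(f"arm {self.name!r}: role must be intervention/comparator")
        if not 0.0 <= self.subsequent_therapy_acceptance_rate <= 1.0:
            raise ConfigError(
                f"arm {self.name!r}: subsequent-therapy acceptance rate outside [0, 1]"
            )
        if self.drug_acquisition_monthly_total < 0:
            raise ConfigError(f"arm {self.name!r}: negative drug acquisition total")
        t = self.transitions
        pfs_row = t["pfs_pfs"] + t["pfs_pd"] + t["pfs_death"]
        pd_row = t["pd_pd"] + t["pd_death"]
        if abs(pfs_row - 1.0) > 1e-9 or abs(pd_row - 1.0) > 1e-9:
            raise ConfigError(
                f"arm {self.name!r}: transition rows must sum to 1 "
                f"(PFS row {pfs_row}, PD row {pd_row})"
            )

    def matrix(self) -> TransitionMatrix:
        t = self.transitions
        return TransitionMatrix.from_probs(
            pfs_pd=t["pfs_pd"], pfs_death=t["pfs_death"], pd_death=t["pd_death"]
        )

    @property
    def acquisition_total_key(self) -> str:
        return f"Costs of drug acquisition ({self.name})"


@dataclass(frozen=True)
class ArmSpec:
    """A fully resolved arm: transition matrix, valuation, cost decomposition."""

    name: str
    role: str
    matrix: TransitionMatrix
    valuation: StateValuation
    state_costs: dict[str, StateCostSpec]


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete resolved parameterization of one two-arm comparison."""

    label: str
    population: str
    arms: tuple[ArmSpec, ArmSpec]
    discount: DiscountSpec
    horizon_cycles: int
    wtp_per_qaly: float
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        roles = sorted(a.role for a in self.arms)
        if roles != ["comparator", "intervention"]:
            raise ConfigError("a scenario needs one intervention and one comparator arm")
        if self.horizon_cycles < 1:
            raise ConfigError("horizon must be at least one cycle")

    @property
    def intervention(self) -> ArmSpec:
        return next(a for a in self.arms if a.role == "intervention")

    @property
    def comparator(self) -> ArmSpec:
        return next(a for a in self.arms if a.role == "comparator")

    def arm(self, name: str) -> ArmSpec:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass(frozen=True)
class ScenarioResult:
    """Base-case outcomes of one scenario run."""

    spec: ScenarioSpec
    outcomes: dict[str, Any]  # arm name -> ArmOutcome
    incremental: Any  # IncrementalResult, intervention vs comparator


@dataclass(frozen=True)
class ScenarioConfig:
    label: str
    population: str
    arms: tuple[ArmConfig, ArmConfig]
    utility_pfs: ParamSpec
    utility_pd: ParamSpec
    disease_management: ParamSpec
    testing: ParamSpec
    palliative_care: ParamSpec
    administration_cost_per_10min: ParamSpec
    horizon_cycles: int = 600
    cycle_length_months: float = 1.0
    discount_annual_rate: float = 0.03
    wtp_per_qaly: float = 100_000.0
    half_cycle_correction: bool = True
    utility_death: ParamSpec = ParamSpec("Utility of Death", 0.0)
    survival: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u in (self.utility_pfs, self.utility_pd, self.utility_death):
            if not 0.0 <= u.base <= 1.0:
                raise ConfigError(
                    f"{u.name!r}: utility {u.base} outside [0, 1]"
                )
        if self.utility_death.base != 0.0:
            raise ConfigError("Death utility must be 0")

    # -- parameter registry -------------------------------------------------

    def parameters(self) -> tuple[ParamSpec, ...]:
        """Every scalar input with its uncertainty description.

        Component-level: individual drugs, administration time cost, AE
        unit costs, disease management, testing, palliative care, and the
        two live-state utilities.  This is the default sampling set of
        the probabilistic sensitivity analysis (those with a Fixed family
        or no range are never varied).
        """
        params: list[ParamSpec] = []
        for arm in self.arms:
            params.extend(arm.drugs)
        params.append(self.administration_cost_per_10min)
        for arm in self.arms:
            params.extend(ae.cost for ae in arm.adverse_events)
        params.extend(
            [
                self.disease_management,
                self.testing,
                self.palliative_care,
                self.utility_pfs,
                self.utility_pd,
            ]
        )
        return tuple(params)

    def tornado_parameters(self, span: float = 0.25) -> tuple[ParamSpec, ...]:
        """Default one-way sensitivity set.

        Per-arm drug acquisition is varied as a single combined total
        (the published tornado groups an arm's regimen cost into one
        bar); every other ranged input is varied individually.  Inputs
        without a published range get base x (1 -/+ span), with utilities
        capped at 1.
        """
        params: list[ParamSpec] = []
        for arm in self.arms:
            total = arm.drug_acquisition_monthly_total
            params.append(
                ParamSpec(
                    arm.acquisition_total_key,
                    total,
                    total * (1.0 - span),
                    total * (1.0 + span),
                    "Gamma",
                )
            )
        for p in self.parameters():
            if any(p.name == d.name for arm in self.arms for d in arm.drugs):
                continue  # folded into the per-arm acquisition totals
            if not p.has_range:
                low = p.base * (1.0 - span)
                high = p.base * (1.0 + span)
                if p.name in (UTILITY_PFS, UTILITY_PD):
                    high = min(high, 1.0)
                p = replace(p, low=low, high=high)
            params.append(p)
        return tuple(params)

    # -- resolution ---------------------------------------------------------

    def build(self, overrides: Mapping[str, float] | None = None) -> ScenarioSpec:
        """Resolve to a runnable :class:`ScenarioSpec`.

        ``overrides`` maps canonical parameter names (see
        :meth:`parameters`, plus the per-arm combined
        ``"Costs of drug acquisition (<arm>)"`` keys) to replacement
        values; anything not overridden stays at base.
        """
        ov = dict(overrides or {})
        used: set[str] = set()

        def value(p: ParamSpec) -> float:
            if p.name in ov:
                used.add(p.name)
                return float(ov[p.name])
            return p.base

        adm_delta = value(self.administration_cost_per_10min) - (
            self.administration_cost_per_10min.base
        )
        dm = value(self.disease_management)
        entry = value(self.testing)
        palliative = value(self.palliative_care)
        u_pfs = value(self.utility_pfs)
        u_pd = value(self.utility_pd)

        pfs_specs: dict[str, StateCostSpec] = {}
        for arm in self.arms:
            total = arm.drug_acquisition_monthly_total
            if arm.acquisition_total_key in ov:
                used.add(arm.acquisition_total_key)
                total = float(ov[arm.acquisition_total_key])
            acquisition = (
                total
                + sum(value(d) - d.base for d in arm.drugs)
                + arm.administration_minutes_monthly / 10.0 * adm_delta
            )
            ae_monthly = sum(
                ae.grade34_rate * value(ae.cost) for ae in arm.adverse_events
            )
            pfs_specs[arm.name] = StateCostSpec(
                drug_acquisition=acquisition,
                ae_management=ae_monthly,
                disease_management=dm,
                one_time_entry_costs=((TESTING, entry),),
            )

        unknown = set(ov) - used
        if unknown:
            raise ConfigError(f"unknown override parameter(s): {sorted(unknown)}")

        arm_specs = []
        for arm in self.arms:
            other = next(a for a in self.arms if a.name != arm.name)
            other_total = state_monthly_total(pfs_specs[other.name])
            subsequent = arm.subsequent_therapy_acceptance_rate * max(
                other_total - dm, 0.0
            )
            pd_spec = StateCostSpec(
                disease_management=dm,
                subsequent_therapy=subsequent,
                transition_costs=((PALLIATIVE, palliative),),
            )
            valuation = StateValuation(
                monthly_cost=(
                    state_monthly_total(pfs_specs[arm.name]),
                    state_monthly_total(pd_spec),
                    0.0,
                ),
                utility=(u_pfs, u_pd, 0.0),
                death_transition_cost=palliative,
                entry_cost=entry,
            )
            arm_specs.append(
                ArmSpec(
                    name=arm.name,
                    role=arm.role,
                    matrix=arm.matrix(),
                    valuation=valuation,
                    state_costs={
                        "PFS": pfs_specs[arm.name],
                        "PD": pd_spec,
                        "Death": StateCostSpec(),
                    },
                )
            )
        return ScenarioSpec(
            label=self.label,
            population=self.population,
            arms=tuple(arm_specs),
            discount=DiscountSpec(self.discount_annual_rate, self.cycle_length_months),
            horizon_cycles=self.horizon_cycles,
            wtp_per_qaly=self.wtp_per_qaly,
            half_cycle_correction=self.half_cycle_correction,
        )


def run_scenario(spec: ScenarioSpec, wtp: float | None = None) -> ScenarioResult:
    """Run both arms of a resolved scenario and compare them."""
    outcomes = {}
    for arm in spec.arms:
        trace = run_cohort(arm.matrix, spec.horizon_cycles)
        outcomes[arm.name] = accumulate(
            trace, arm.valuation, spec.discount, spec.half_cycle_correction
        )
    incremental = compare(
        outcomes[spec.intervention.name],
        outcomes[spec.comparator.name],
        wtp if wtp is not None else spec.wtp_per_qaly,
    )
    return ScenarioResult(spec=spec, outcomes=outcomes, incremental=incremental)


# -- YAML (de)serialization ---------------------------------------------------


def _take(mapping: dict, key: str, context: str, default: Any = ...) -> Any:
    if key in mapping:
        return mapping.pop(key)
    if default is ...:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return default


def _check_empty(mapping: dict, context: str) -> None:
    if mapping:
        raise ConfigError(f"{context}: unknown key(s) {sorted(mapping)}")


def _param_from(node: Any, name: str, context: str, value_key: str = "base") -> ParamSpec:
    if isinstance(node, (int, float)):
        return ParamSpec(name, float(node))
    if not isinstance(node, dict):
        raise ConfigError(f"{context}: expected a number or mapping")
    node = dict(node)
    base = float(_take(node, value_key, context))
    low = _take(node, "low", context, None)
    high = _take(node, "high", context, None)
    family = _take(node, "distribution", context, "Fixed")
    _check_empty(node, context)
    return ParamSpec(
        name,
        base,
        None if low is None else float(low),
        None if high is None else float(high),
        str(family),
    )


def _param_to(p: ParamSpec, value_key: str = "base") -> Any:
    if p.low is None and p.high is None and p.family == "Fixed":
        return p.base
    out: dict[str, Any] = {value_key: p.base}
    if p.low is not None:
        out["low"] = p.low
    if p.high is not None:
        out["high"] = p.high
    out["distribution"] = p.family
    return out


_TRANSITION_KEYS = ("pfs_pfs", "pfs_pd", "pfs_death", "pd_pd", "pd_death")


def _arm_from(node: dict, context: str) -> ArmConfig:
    node = dict(node)
    name = str(_take(node, "name", context))
    context = f"{context} ({name})"
    role = str(_take(node, "role", context))
    transitions = dict(_take(node, "transitions", context))
    for key in _TRANSITION_KEYS:
        if key not in transitions:
            raise ConfigError(f"{context}: transitions missing {key!r}")
    extra = set(transitions) - set(_TRANSITION_KEYS)
    if extra:
        raise ConfigError(f"{context}: unknown transition key(s) {sorted(extra)}")
    drugs = tuple(
        _param_from(
            {k: v for k, v in dict(d).items() if k != "name"},
            str(dict(d)["name"]),
            f"{context} drug",
            value_key="monthly_cost",
        )
        for d in _take(node, "drugs", context, [])
    )
    aes = []
    for raw in _take(node, "adverse_events", context, []):
        raw = dict(raw)
        ae_name = str(_take(raw, "name", f"{context} adverse event"))
        rate = float(_take(raw, "grade34_rate", f"{context} {ae_name}"))
        cost = _param_from(raw, ae_name, f"{context} {ae_name}", value_key="management_cost")
        aes.append(AdverseEventConfig(ae_name, rate, cost))
    arm = ArmConfig(
        name=name,
        role=role,
        transitions={k: float(transitions[k]) for k in _TRANSITION_KEYS},
        drug_acquisition_monthly_total=float(
            _take(node, "drug_acquisition_monthly_total", context)
        ),
        drugs=drugs,
        administration_minutes_monthly=float(
            _take(node, "administration_minutes_monthly", context, 0.0)
        ),
        adverse_events=tuple(aes),
        subsequent_therapy_acceptance_rate=float(
            _take(node, "subsequent_therapy_acceptance_rate", context, 0.0)
        ),
    )
    _check_empty(node, context)
    return arm


def _arm_to(arm: ArmConfig) -> dict:
    out: dict[str, Any] = {
        "name": arm.name,
        "role": arm.role,
        "transitions": dict(arm.transitions),
        "drug_acquisition_monthly_total": arm.drug_acquisition_monthly_total,
    }
    if arm.drugs:
        out["drugs"] = [
            {"name": d.name, **_as_dict(_param_to(d, "monthly_cost"), "monthly_cost", d)}
            for d in arm.drugs
        ]
    if arm.administration_minutes_monthly:
        out["administration_minutes_monthly"] = arm.administration_minutes_monthly
    if arm.adverse_events:
        out["adverse_events"] = [
            {
                "name": ae.name,
                "grade34_rate": ae.grade34_rate,
                **_as_dict(_param_to(ae.cost, "management_cost"), "management_cost", ae.cost),
            }
            for ae in arm.adverse_events
        ]
    if arm.subsequent_therapy_acceptance_rate:
        out["subsequent_therapy_acceptance_rate"] = arm.subsequent_therapy_acceptance_rate
    return out


def _as_dict(rendered: Any, value_key: str, p: ParamSpec) -> dict:
    if isinstance(rendered, dict):
        return rendered
    return {value_key: p.base}


def scenario_from_dict(raw: dict) -> ScenarioConfig:
    raw = dict(raw)
    context = "scenario"
    label = str(_take(raw, "label", context))
    population = str(_take(raw, "population", context))
    arms = tuple(_arm_from(a, "arm") for a in _take(raw, "arms", context))
    if len(arms) != 2:
        raise ConfigError("scenario: exactly two arms required")
    utilities = dict(_take(raw, "utilities", context))
    u_pfs = _param_from(_take(utilities, "pfs", "utilities"), UTILITY_PFS, "utilities.pfs")
    u_pd = _param_from(_take(utilities, "pd", "utilities"), UTILITY_PD, "utilities.pd")
    u_death = _param_from(
        _take(utilities, "death", "utilities", 0.0), "Utility of Death", "utilities.death"
    )
    _check_empty(utilities, "utilities")
    shared = dict(_take(raw, "shared_costs", context))
    dm = _param_from(
        _take(shared, "disease_management_monthly", "shared_costs"),
        DISEASE_MANAGEMENT,
        "shared_costs.disease_management_monthly",
    )
    testing = _param_from(
        _take(shared, "dmmr_msih_testing_entry", "shared_costs"),
        TESTING,
        "shared_costs.dmmr_msih_testing_entry",
    )
    palliative = _param_from(
        _take(shared, "palliative_care_on_death", "shared_costs"),
        PALLIATIVE,
        "shared_costs.palliative_care_on_death",
    )
    _check_empty(shared, "shared_costs")
    admin = _param_from(
        _take(raw, "administration_cost_per_10min", context, 0.0),
        ADMIN_COST,
        "administration_cost_per_10min",
    )
    survival = {}
    for arm_name, node in dict(_take(raw, "survival", context, {})).items():
        node = dict(node)
        survival[str(arm_name)] = (
            float(_take(node, "median_pfs_months", f"survival.{arm_name}")),
            float(_take(node, "median_os_months", f"survival.{arm_name}")),
        )
        _check_empty(node, f"survival.{arm_name}")
    config = ScenarioConfig(
        label=label,
        population=population,
        arms=arms,
        utility_pfs=u_pfs,
        utility_pd=u_pd,
        utility_death=u_death,
        disease_management=dm,
        testing=testing,
        palliative_care=palliative,
        administration_cost_per_10min=admin,
        horizon_cycles=int(_take(raw, "horizon_cycles", context, 600)),
        cycle_length_months=float(_take(raw, "cycle_length_months", context, 1.0)),
        discount_annual_rate=float(_take(raw, "discount_annual_rate", context, 0.03)),
        wtp_per_qaly=float(_take(raw, "wtp_per_qaly", context, 100_000.0)),
        half_cycle_correction=bool(_take(raw, "half_cycle_correction", context, True)),
        survival=survival,
    )
    _check_empty(raw, context)
    config.build()  # run every nested invariant check at load time
    return config


def scenario_to_dict(config: ScenarioConfig) -> dict:
    out: dict[str, Any] = {
        "label": config.label,
        "population": config.population,
        "horizon_cycles": config.horizon_cycles,
        "cycle_length_months": config.cycle_length_months,
        "discount_annual_rate": config.discount_annual_rate,
        "wtp_per_qaly": config.wtp_per_qaly,
        "half_cycle_correction": config.half_cycle_correction,
        "administration_cost_per_10min": _param_to(config.administration_cost_per_10min),
        "utilities": {
            "pfs": _param_to(config.utility_pfs),
            "pd": _param_to(config.utility_pd),
            "death": _param_to(config.utility_death),
        },
        "shared_costs": {
            "disease_management_monthly": _param_to(config.disease_management),
            "dmmr_msih_testing_entry": _param_to(config.testing),
            "palliative_care_on_death": _param_to(config.palliative_care),
        },
        "arms": [_arm_to(a) for a in config.arms],
    }
    if config.survival:
        out["survival"] = {
            arm: {"median_pfs_months": pfs, "median_os_months": os_}
            for arm, (pfs, os_) in config.survival.items()
        }
    return out


def load_scenario(source: str | Path) -> ScenarioConfig:
    """Load a scenario from a YAML file path or YAML text."""
    text: str
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = source
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("scenario config must be a YAML mapping")
    return scenario_from_dict(raw)


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(config), sort_keys=False))


def builtin_scenario(name: str) -> ScenarioConfig:
    """Load a packaged scenario fixture by stem (e.g. ``keynote775_base``)."""
    resource = importlib.resources.files("endocea.data").joinpath(f"{name}.yaml")
    return load_scenario(resource.read_text())
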