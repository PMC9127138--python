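"""Cost arithmetic: published component sums must reproduce to the cent."""

from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endocea.costs import (
    AdverseEventItem,
    DrugCostSpec,
    StateCostSpec,
    ae_management_cost,
    drug_acquisition_monthly,
    round_currency,
    state_monthly_total,
    subsequent_therapy_cost,
)

LP_AES = [
    AdverseEventItem("Hypertension", 0.379, 7965.60),
    AdverseEventItem("Diarrhea", 0.076, 7795.80),
]
CHEMO_AES = [
    AdverseEventItem("Anemia", 0.147, 14314.20),
    AdverseEventItem("Neutropenia", 0.258, 14429.73),
    AdverseEventItem("Neutrophil count decreased", 0.212, 14429.73),
    AdverseEventItem("WBC decreased", 0.103, 7071.65),
]


@pytest.mark.parametrize(
    "items, expected",
    [
        (LP_AES, "3611.44"),
        (CHEMO_AES, "9614.54"),
        ([], "0.00"),
    ],
    ids=["combination-arm", "chemotherapy-arm", "empty"],
)
def test_ae_management_cost_reproduces_published_totals(items, expected):
    assert round_currency(ae_management_cost(items)) == Decimal(expected)


def test_adverse_event_validation_names_offending_item():
    with pytest.raises(ValueError, match="Hypertension"):
        AdverseEventItem("Hypertension", -0.1, 100.0)
    with pytest.raises(ValueError, match="Anemia"):
        AdverseEventItem("Anemia", 0.1, -5.0)


@given(
    rates=st.lists(st.floats(0, 0.5), min_size=1, max_size=6),
    scale=st.floats(1.01, 2.0),
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_ae_cost_is_linear_in_rates(rates, scale):
    items = [AdverseEventItem(f"ae{i}", r, 1000.0 * (i + 1)) for i, r in enumerate(rates)]
    scaled = [
        AdverseEventItem(f"ae{i}", min(r * scale, 1.0), 1000.0 * (i + 1))
        for i, r in enumerate(rates)
    ]
    if all(r * scale <= 1.0 for r in rates):
        assert ae_management_cost(scaled) == pytest.approx(
            scale * ae_management_cost(items), rel=1e-12
        )


@pytest.mark.parametrize(
    "other_total, dm, rate, expected",
    [
        (10740.27, 360.42, 0.280, "2906.36"),
        (36792.62, 360.42, 0.481, "17523.89"),
        (12345.67, 360.42, 0.0, "0.00"),
    ],
    ids=["lp-crossover", "chemo-crossover", "zero-acceptance"],
)
def test_subsequent_therapy_published_values(other_total, dm, rate, expected):
    assert round_currency(subsequent_therapy_cost(other_total, dm, rate)) == Decimal(expected)


def test_subsequent_therapy_validation():
    with pytest.raises(ValueError, match="acceptance rate"):
        subsequent_therapy_cost(1000.0, 100.0, 1.5)
    with pytest.raises(ValueError, match="disease management"):
        subsequent_therapy_cost(50.0, 100.0, 0.5)


@given(
    rate=st.floats(0.0, 1.0),
    rate2=st.floats(0.0, 1.0),
    total=st.floats(500.0, 50_000.0),
    total2=st.floats(500.0, 50_000.0),
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_subsequent_therapy_monotone(rate, rate2, total, total2):
    dm = 360.42
    lo_r, hi_r = sorted((rate, rate2))
    lo_t, hi_t = sorted((total, total2))
    assert subsequent_therapy_cost(lo_t, dm, hi_r) >= subsequent_therapy_cost(lo_t, dm, lo_r)
    assert subsequent_therapy_cost(hi_t, dm, hi_r) >= subsequent_therapy_cost(lo_t, dm, hi_r)


class TestDrugAcquisition:
    def test_stated_monthly_cost_passes_through(self):
        spec = DrugCostSpec("Lenvatinib", monthly_acquisition_cost=16166.98)
        assert drug_acquisition_monthly(spec) == 16166.98

    def test_component_formula(self):
        # unit price x daily dose x dosing days per month
        spec = DrugCostSpec(
            "generic", unit_price=2.00, dose=13.8, administrations_per_month=30.44
        )
        assert round_currency(drug_acquisition_monthly(spec)) == Decimal("840.14")

    def test_zero_unit_price(self):
        spec = DrugCostSpec("free", unit_price=0.0, dose=13.8, administrations_per_month=30.44)
        assert drug_acquisition_monthly(spec) == 0.0

    def test_bsa_and_administration_bundling(self):
        # 60 mg/m2 x 1.71 m2, one administration, 30 min at $55.98/10 min
        spec = DrugCostSpec(
            "Doxorubicin",
            unit_price=1.0,
            dose=60.0,
            body_surface_area=1.71,
            administrations_per_month=1.0,
            admin_minutes_per_administration=30.0,
            admin_cost_per_10min=55.98,
        )
        assert drug_acquisition_monthly(spec) == pytest.approx(60 * 1.71 + 3 * 55.98)

    def test_incomplete_spec_rejected(self):
        with pytest.raises(ValueError, match="monthly_acquisition_cost"):
            drug_acquisition_monthly(DrugCostSpec("broken", unit_price=2.0))

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError, match="unit_price"):
            DrugCostSpec("bad", unit_price=-1.0, dose=1.0, administrations_per_month=1.0)


@pytest.mark.parametrize(
    "spec, expected",
    [
        (
            StateCostSpec(drug_acquisition=32820.76, ae_management=3611.44, disease_management=360.42),
            "36792.62",
        ),
        (StateCostSpec(disease_management=360.42, subsequent_therapy=2906.36), "3266.78"),
        (StateCostSpec(), "0.00"),
    ],
    ids=["lp-pfs", "lp-pd", "all-zero"],
)
def test_state_monthly_total(spec, expected):
    assert round_currency(state_monthly_total(spec)) == Decimal(expected)


def test_state_total_equals_sum_of_single_component_decompositions():
    spec = StateCostSpec(
        drug_acquisition=100.0, ae_management=25.5, disease_management=3.25,
        subsequent_therapy=17.0,
    )
    parts = [
        StateCostSpec(drug_acquisition=100.0),
        StateCostSpec(ae_management=25.5),
        StateCostSpec(disease_management=3.25),
        StateCostSpec(subsequent_therapy=17.0),
    ]
    assert state_monthly_total(spec) == pytest.approx(
        sum(state_monthly_total(p) for p in parts), rel=1e-12
    )


def test_event_costs_excluded_from_monthly_total():
    spec = StateCostSpec(
        disease_management=360.42,
        one_time_entry_costs=(("testing", 666.40),),
        transition_costs=(("palliative", 11266.07),),
    )
    assert state_monthly_total(spec) == pytest.approx(360.42)


def test_round_currency_is_half_up():
    assert round_currency(2.675) == Decimal("2.68")
    assert round_currency(2906.358) == Decimal("2906.36")
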