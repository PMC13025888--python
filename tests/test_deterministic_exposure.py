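import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tindiet.deterministic_exposure import (
    category_contributions,
    compute_edi,
    hazard_grid,
    organotin_scenario_assessment,
    scenario_exposure_table,
    sum_edi,
    total_hazard,
)
from tindiet.errors import DataValidationError, DomainError
from tindiet.study_data import SCENARIO_MAP, consumption_lookup

AGE_ORDER = ("le6", "7_12", "13_17", "18_59", "ge60")


@pytest.mark.parametrize(
    "conc,intake,bw,expected",
    [
        (80.73, 40.0, 62.1, 52.00),  # canned fruits, adults, high-high scenario
        (0.50, 100.0, 19.9, 2.51),  # fish, children <=6, high-high scenario
        (5.0, 0.0, 60.0, 0.00),
    ],
)
def test_edi_anchor_values(conc, intake, bw, expected):
    assert round(compute_edi(conc, intake, bw), 2) == expected


def test_edi_rejects_zero_body_weight_and_negative_inputs():
    with pytest.raises(DomainError):
        compute_edi(1.0, 1.0, 0.0)
    with pytest.raises(DomainError):
        compute_edi(-1.0, 1.0, 60.0)


@settings(max_examples=100, derandomize=True)
@given(
    conc=st.floats(0.001, 100), intake=st.floats(0.001, 500),
    bw=st.floats(5, 120), k=st.floats(0.1, 10),
)
def test_edi_is_linear_in_each_factor(conc, intake, bw, k):
    base = compute_edi(conc, intake, bw)
    assert compute_edi(k * conc, intake, bw) == pytest.approx(k * base, rel=1e-9)
    assert compute_edi(conc, k * intake, bw) == pytest.approx(k * base, rel=1e-9)
    assert compute_edi(conc, intake, 2 * bw) == pytest.approx(base / 2, rel=1e-9)


def test_scenario_grid_shape_and_monotonicity(summaries, consumption):
    cells = scenario_exposure_table(summaries, consumption)
    assert len(cells) == 25 * 5 * 4
    grid = {(c.item.type_name, c.age.label, c.scenario.label): c.edi for c in cells}
    lookup = consumption_lookup(consumption)
    for s in summaries:
        for age in AGE_ORDER:
            cq = lookup[(s.item.type_name, age)]
            if cq.p50 > cq.p95:  # printed inverted cells break cons-monotonicity
                continue
            a, b, c, d = (grid[(s.item.type_name, age, x)] for x in "ABCD")
            assert a <= b + 1e-12 and a <= c + 1e-12
            assert b <= d + 1e-12 and c <= d + 1e-12


def test_missing_consumption_pairing_is_reported(summaries, consumption):
    partial = [q for q in consumption if q.item.type_name != "Fish"]
    with pytest.raises(DataValidationError, match="Fish"):
        scenario_exposure_table(summaries, partial)


def test_aquatic_scenario_c_row_reproduces_published_sums(summaries, consumption):
    aquatic = [s for s in summaries if s.item.category == "fresh_aquatic"]
    cells = scenario_exposure_table(aquatic, consumption)
    totals = sum_edi(cells)
    observed = [round(totals[(age, "C")], 2) for age in AGE_ORDER]
    assert observed == [1.60, 0.94, 0.83, 0.78, 0.70]
    c_le6 = [c for c in cells if c.age.label == "le6" and c.scenario.label == "C"]
    assert round(total_hazard(c_le6, reference=0.1).thq) == 16


def test_total_hazard_sums_per_item_quotients(summaries, consumption):
    cells = [
        c for c in scenario_exposure_table(summaries, consumption)
        if c.age.label == "18_59" and c.scenario.label == "D"
    ]
    h = total_hazard(cells, reference=300.0)
    assert h.thq == pytest.approx(sum(h.per_item_hq.values()), rel=1e-9)
    assert h.sum_edi == pytest.approx(h.thq * 300.0, rel=1e-12)
    assert not h.exceeds


def test_thq_is_additive_over_disjoint_item_sets(summaries, consumption):
    cells = [
        c for c in scenario_exposure_table(summaries, consumption)
        if c.age.label == "le6" and c.scenario.label == "C"
    ]
    left = [c for c in cells if c.item.category == "canned"]
    right = [c for c in cells if c.item.category != "canned"]
    whole = total_hazard(cells, 300.0).thq
    assert whole == pytest.approx(
        total_hazard(left, 300.0).thq + total_hazard(right, 300.0).thq, rel=1e-12
    )


def test_total_hazard_of_empty_cells_is_zero():
    h = total_hazard([], reference=300.0)
    assert h.sum_edi == 0.0 and h.thq == 0.0


def test_total_hazard_rejects_mixed_groups_and_bad_reference(summaries, consumption):
    cells = scenario_exposure_table(summaries, consumption)
    with pytest.raises(DataValidationError):
        total_hazard(cells, 300.0)
    with pytest.raises(DomainError):
        total_hazard(cells[:1], 0.0)


def test_category_contributions_normalise(summaries, consumption):
    cells = [
        c for c in scenario_exposure_table(summaries, consumption)
        if c.age.label == "18_59" and c.scenario.label == "D"
    ]
    shares = category_contributions(cells)
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
    # canned fruits alone contribute 52.00 of the 65.29 total
    assert shares["canned"] > 0.8
    only_canned = [c for c in cells if c.item.category == "canned"]
    assert category_contributions(only_canned) == {"canned": pytest.approx(1.0)}


def test_category_contributions_undefined_for_zero_total(summaries, consumption):
    zero_cells = [
        c for c in scenario_exposure_table(summaries, consumption)
        if c.age.label == "le6" and c.scenario.label == "A"
        and c.item.type_name == "Green Tea"
    ]
    shares = category_contributions(zero_cells)
    assert all(np.isnan(v) for v in shares.values())


def test_organotin_screen_scales_linearly_with_fraction(summaries, consumption):
    full = organotin_scenario_assessment(summaries, consumption, reproduce_table4=True)
    scaled = organotin_scenario_assessment(summaries, consumption, fraction=0.0583)
    fmap = {(h.age.label, h.scenario.label): h for h in full}
    for h in scaled:
        ref = fmap[(h.age.label, h.scenario.label)]
        assert h.sum_edi == pytest.approx(0.0583 * ref.sum_edi, rel=1e-12)
        assert h.thq == pytest.approx(0.0583 * ref.thq, rel=1e-12)


def test_organotin_screen_uses_aquatic_items_only(summaries, consumption):
    hazards = organotin_scenario_assessment(summaries, consumption, reproduce_table4=True)
    assert len(hazards) == 20
    names = {name for h in hazards for name in h.per_item_hq}
    assert names == {"Fish", "Crustaceans", "Mollusks"}


def test_scenario_grid_hazards_never_exceed_one_at_the_reference_dose(
    summaries, consumption
):
    _, hazards = hazard_grid(summaries, consumption, reference=300.0)
    assert len(hazards) == 20
    assert all(h.thq < 1 for h in hazards)


def test_scenarios_are_the_four_documented_pairings():
    assert {(s.cons_q, s.conc_q) for s in SCENARIO_MAP.values()} == {
        (0.50, 0.50), (0.95, 0.50), (0.50, 0.95), (0.95, 0.95)
    }
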