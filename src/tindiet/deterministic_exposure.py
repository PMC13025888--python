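"""Deterministic scenario-grid exposure and hazard quotients.

The estimated daily intake for one food item is

    EDI = C x CR / BW        [ug/kg bw/day]

with C the tin concentration (mg/kg, i.e. ug/g), CR the daily consumption
(g/day) and BW the body weight (kg); since mg/kg and ug/g coincide no
explicit unit factor appears. Four screening scenarios cross median/high
consumption with median/high contamination (A: P50xP50, B: P95xP50,
C: P50xP95, D: P95xP95). Hazard quotients divide each EDI by a
toxicological reference dose; the total hazard quotient (THQ) sums them
over food items, with values above 1 flagged for concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isclose

import pandas as pd

from .errors import DataValidationError, DomainError
from .study_data import (
    SCENARIOS,
    AgeGroup,
    ConcentrationSummary,
    ConsumptionQuantiles,
    FoodItem,
    Scenario,
    ToxConstants,
    age_groups,
    consumption_lookup,
)

AQUATIC_CATEGORY = "fresh_aquatic"


@dataclass(frozen=True)
class ExposureCell:
    """EDI for one item x age group x scenario (ug/kg bw/day)."""

    item: FoodItem
    age: AgeGroup
    scenario: Scenario
    edi: float

    def __post_init__(self) -> None:
        if self.edi < 0:
            raise DataValidationError("edi must be >= 0")


@dataclass(frozen=True)
class HazardSummary:
    """Summed exposure and hazard for one age group x scenario."""

    age: AgeGroup
    scenario: Scenario
    sum_edi: float
    thq: float
    per_item_hq: dict[str, float] = field(default_factory=dict)
    reference: float = float("nan")

    @property
    def exceeds(self) -> bool:
        return self.thq > 1.0


def compute_edi(conc: float, intake: float, bw: float) -> float:
    """Daily intake of tin per kg body weight (ug/kg bw/day)."""
    if conc < 0 or intake < 0:
        raise DomainError("concentration and intake must be >= 0")
    if not bw > 0:
        raise DomainError("body weight must be > 0")
    return conc * intake / bw


def _conc_at(summary: ConcentrationSummary, q: float) -> float:
    if isclose(q, 0.50):
        return summary.p50
    if isclose(q, 0.95):
        return summary.p95
    raise DomainError(f"summary tables only carry P50/P95 concentrations (q={q})")


def _cons_at(cq: ConsumptionQuantiles, q: float) -> float:
    if isclose(q, 0.50):
        return cq.p50
    if isclose(q, 0.95):
        return cq.p95
    raise DomainError(f"consumption tables only carry P50/P95 intakes (q={q})")


def scenario_exposure_table(
    summaries: list[ConcentrationSummary],
    consumption: list[ConsumptionQuantiles],
    ages: list[AgeGroup] | None = None,
    scenarios: tuple[Scenario, ...] = SCENARIOS,
) -> list[ExposureCell]:
    """One EDI cell per item x age x scenario from summary-table quantiles."""
    ages = ages if ages is not None else age_groups()
    lookup = consumption_lookup(consumption)
    missing = [
        (s.item.type_name, a.label)
        for s in summaries
        for a in ages
        if (s.item.type_name, a.label) not in lookup
    ]
    if missing:
        raise DataValidationError(f"consumption cells missing for: {missing}")
    cells = []
    for summary in summaries:
        for age in ages:
            cq = lookup[(summary.item.type_name, age.label)]
            for scen in scenarios:
                cells.append(
                    ExposureCell(
                        item=summary.item,
                        age=age,
                        scenario=scen,
                        edi=compute_edi(
                            _conc_at(summary, scen.conc_q),
                            _cons_at(cq, scen.cons_q),
                            age.body_weight,
                        ),
                    )
                )
    return cells


def sum_edi(cells: list[ExposureCell]) -> dict[tuple[str, str], float]:
    """Summed EDI keyed by (age label, scenario label)."""
    totals: dict[tuple[str, str], float] = {}
    for c in cells:
        key = (c.age.label, c.scenario.label)
        totals[key] = totals.get(key, 0.0) + c.edi
    return totals


def total_hazard(cells: list[ExposureCell], reference: float) -> HazardSummary:
    """THQ of one age group x scenario against a reference dose."""
    if not reference > 0:
        raise DomainError("reference dose must be > 0")
    keys = {(c.age.label, c.scenario.label) for c in cells}
    if len(keys) > 1:
        raise DataValidationError(f"cells span several age x scenario groups: {sorted(keys)}")
    per_item_hq = {}
    for c in cells:
        per_item_hq[c.item.type_name] = per_item_hq.get(c.item.type_name, 0.0) + c.edi / reference
    total = sum(c.edi for c in cells)
    if cells:
        age, scen = cells[0].age, cells[0].scenario
    else:
        age, scen = AgeGroup("total", 57.0), SCENARIOS[0]
    return HazardSummary(
        age=age,
        scenario=scen,
        sum_edi=total,
        thq=total / reference,
        per_item_hq=per_item_hq,
        reference=reference,
    )


def category_contributions(cells: list[ExposureCell]) -> dict[str, float]:
    """Share of the summed EDI per food category (one age x scenario).

    When the summed EDI is zero the shares are undefined and reported as
    NaN rather than raising a division error.
    """
    if not cells:
        raise DomainError("category_contributions: no cells")
    keys = {(c.age.label, c.scenario.label) for c in cells}
    if len(keys) > 1:
        raise DataValidationError(f"cells span several age x scenario groups: {sorted(keys)}")
    per_cat: dict[str, float] = {}
    for c in cells:
        per_cat[c.item.category] = per_cat.get(c.item.category, 0.0) + c.edi
    total = sum(per_cat.values())
    if total == 0.0:
        return {cat: float("nan") for cat in per_cat}
    return {cat: v / total for cat, v in per_cat.items()}


def organotin_scenario_assessment(
    summaries: list[ConcentrationSummary],
    consumption: list[ConsumptionQuantiles],
    ages: list[AgeGroup] | None = None,
    constants: ToxConstants | None = None,
    fraction: float | None = None,
    categories: tuple[str, ...] = (AQUATIC_CATEGORY,),
    reproduce_table4: bool = False,
) -> list[HazardSummary]:
    """Scenario-grid organotin screening for selected categories.

    Organotin EDI is the total-tin EDI scaled by the conservative
    organotin fraction, compared against the tin-basis organotin TDI. The
    published scenario table is only recovered with ``reproduce_table4``,
    which compares *unscaled* total-tin EDIs against the organotin TDI
    (equivalently fraction = 1); the formula-as-stated default applies the
    literature fraction 0.0583.
    """
    constants = constants or ToxConstants()
    if fraction is None:
        fraction = 1.0 if reproduce_table4 else constants.organotin_fraction
    if not 0.0 < fraction <= 1.0:
        raise DomainError("organotin fraction must be in (0, 1]")
    tdi = constants.tdi_organotin_as_sn
    subset = [s for s in summaries if s.item.category in categories]
    cells = scenario_exposure_table(subset, consumption, ages)
    out = []
    by_group: dict[tuple[str, str], list[ExposureCell]] = {}
    for c in cells:
        by_group.setdefault((c.age.label, c.scenario.label), []).append(c)
    for group in by_group.values():
        base = total_hazard(group, reference=tdi)
        out.append(
            HazardSummary(
                age=base.age,
                scenario=base.scenario,
                sum_edi=base.sum_edi * fraction,
                thq=base.thq * fraction,
                per_item_hq={k: v * fraction for k, v in base.per_item_hq.items()},
                reference=tdi,
            )
        )
    return out


def hazard_grid(
    summaries: list[ConcentrationSummary],
    consumption: list[ConsumptionQuantiles],
    reference: float,
    ages: list[AgeGroup] | None = None,
) -> tuple[list[ExposureCell], list[HazardSummary]]:
    """Full cells plus one HazardSummary per age x scenario."""
    cells = scenario_exposure_table(summaries, consumption, ages)
    by_group: dict[tuple[str, str], list[ExposureCell]] = {}
    for c in cells:
        by_group.setdefault((c.age.label, c.scenario.label), []).append(c)
    hazards = [total_hazard(group, reference) for group in by_group.values()]
    return cells, hazards


def contribution_grid(cells: list[ExposureCell]) -> pd.DataFrame:
    """Category contribution shares for every age x scenario (long format)."""
    by_group: dict[tuple[str, str], list[ExposureCell]] = {}
    for c in cells:
        by_group.setdefault((c.age.label, c.scenario.label), []).append(c)
    rows = []
    for (age, scen), group in sorted(by_group.items()):
        for cat, share in category_contributions(group).items():
            rows.append(
                {"age_group": age, "scenario": scen, "category": cat, "share": share}
            )
    return pd.DataFrame(rows, columns=["age_group", "scenario", "category", "share"])
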