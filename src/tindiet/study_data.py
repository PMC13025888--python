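"""Domain types, packaged survey/laboratory fixtures, and CSV I/O.

The package ships two transcribed summary tables from a provincial food
surveillance programme: per-food-type total-tin concentration summaries
(25 food types in five categories, 2014 samples, mg/kg dry weight) and
per-age-group consumption quantiles with body weights (g/day, kg). All
downstream stages consume the types defined here.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import DataValidationError, DomainError, SchemaError

CATEGORIES = ("fresh_vegetables", "tea", "fresh_aquatic", "fresh_fruits", "canned")

#: Method detection limits, mg/kg dry weight. Tea is dehydrated before
#: analysis and carries a slightly higher limit.
LOD_DEFAULT = 0.004
LOD_TEA = 0.008

AGE_LABELS = ("le6", "7_12", "13_17", "18_59", "ge60")
TOTAL_LABEL = "total"

#: Mean body weight per age group (kg); ``total`` is the whole-population
#: average used by the probabilistic assessment.
BODY_WEIGHTS = {
    "le6": 19.9,
    "7_12": 33.7,
    "13_17": 52.3,
    "18_59": 62.1,
    "ge60": 60.4,
    "total": 57.0,
}


def lod_for_category(category: str) -> float:
    return LOD_TEA if category == "tea" else LOD_DEFAULT


@dataclass(frozen=True)
class FoodItem:
    """One of the 25 surveyed food types."""

    category: str
    type_name: str
    lod: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DataValidationError(
                f"unknown category {self.category!r} for {self.type_name!r}"
            )
        if not self.lod > 0:
            raise DataValidationError(f"{self.type_name}: lod must be > 0")


@dataclass(frozen=True)
class AgeGroup:
    """A consumption-survey age stratum with its mean body weight (kg)."""

    label: str
    body_weight: float

    def __post_init__(self) -> None:
        if self.label not in AGE_LABELS and self.label != TOTAL_LABEL:
            raise DataValidationError(f"unknown age-group label {self.label!r}")
        if not self.body_weight > 0:
            raise DataValidationError(f"{self.label}: body weight must be > 0")


AGE_GROUPS: dict[str, AgeGroup] = {
    label: AgeGroup(label, kg) for label, kg in BODY_WEIGHTS.items()
}


def age_groups(include_total: bool = False) -> list[AgeGroup]:
    """The five study age groups, optionally with the total population."""
    labels = AGE_LABELS + ((TOTAL_LABEL,) if include_total else ())
    return [AGE_GROUPS[lab] for lab in labels]


@dataclass
class ConcentrationSample:
    """A single laboratory tin measurement with censoring status.

    ``value`` is mg/kg dry weight. Non-detects are left-censored at the
    item's LOD; once ``substituted`` is set the value is exactly lod/2.
    """

    item: FoodItem
    value: float
    detected: bool
    substituted: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DataValidationError(f"{self.item.type_name}: value must be >= 0")
        if not self.detected and self.substituted:
            if not math.isclose(self.value, self.item.lod / 2.0, rel_tol=1e-9):
                raise DataValidationError(
                    f"{self.item.type_name}: substituted non-detect must equal lod/2"
                )


@dataclass(frozen=True)
class ConcentrationSummary:
    """Descriptive record for one food type (study-table layout)."""

    item: FoodItem
    n: int
    n_detect: int
    mean: float
    p50: float
    p95: float
    iqr: float
    min: float
    max: float

    def __post_init__(self) -> None:
        name = self.item.type_name
        if not 0 <= self.n_detect <= self.n:
            raise DataValidationError(f"{name}: need 0 <= n_detect <= n")
        if not self.min <= self.p50 <= self.p95 <= self.max:
            raise DataValidationError(
                f"{name}: quantile ordering min <= p50 <= p95 <= max violated"
            )
        if self.iqr < 0:
            raise DataValidationError(f"{name}: iqr must be >= 0")
        if not self.min <= self.mean <= self.max:
            raise DataValidationError(f"{name}: mean must lie within [min, max]")

    @property
    def detect_rate(self) -> float:
        return self.n_detect / self.n if self.n else float("nan")


@dataclass(frozen=True)
class ConsumptionQuantiles:
    """Printed P50/P95 daily intake (g/day) for one item x age group."""

    item: FoodItem
    age: AgeGroup
    p50: float
    p95: float

    def __post_init__(self) -> None:
        if self.p50 < 0 or self.p95 < 0:
            raise DataValidationError(
                f"{self.item.type_name}/{self.age.label}: negative intake quantile"
            )


@dataclass
class ConsumptionRecord:
    """An individual daily-intake draw used by the Monte Carlo stage."""

    respondent_id: str
    age: AgeGroup
    item: FoodItem
    intake: float
    body_weight: float

    def __post_init__(self) -> None:
        if self.intake < 0:
            raise DataValidationError(f"{self.respondent_id}: intake must be >= 0")
        if not self.body_weight > 0:
            raise DataValidationError(f"{self.respondent_id}: body weight must be > 0")


@dataclass(frozen=True)
class ToxConstants:
    """Toxicological benchmarks and regulatory limits.

    Units: reference doses and TDIs in ug/kg bw/day; limits in mg/kg.
    ``organotin_fraction`` is the conservative literature organotin share of
    total tin used for screening; ``tdi_organotin_as_sn`` expresses the
    organotin TDI on a tin-mass basis.
    """

    rfd_total_sn: float = 300.0
    tdi_organotin_compound: float = 0.25
    tdi_organotin_as_sn: float = 0.10
    organotin_fraction: float = 0.0583
    limit_canned: float = 200.0
    limit_canned_beverage: float = 100.0
    limit_other: float = 200.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if not getattr(self, f.name) > 0:
                raise DataValidationError(f"constant {f.name} must be positive")
        if not 0 < self.organotin_fraction <= 1:
            raise DataValidationError("organotin_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ToxConstants":
        """Load overrides from a flat key/value YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown constant keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class Scenario:
    """A deterministic consumption-quantile x concentration-quantile pairing."""

    label: str
    cons_q: float
    conc_q: float


#: The four screening scenarios: median/high consumption crossed with
#: median/high contamination.
SCENARIOS: tuple[Scenario, ...] = (
    Scenario("A", 0.50, 0.50),
    Scenario("B", 0.95, 0.50),
    Scenario("C", 0.50, 0.95),
    Scenario("D", 0.95, 0.95),
)
SCENARIO_MAP = {s.label: s for s in SCENARIOS}


@dataclass(frozen=True)
class StudyDesignParams:
    """Inputs of the survey sample-size formula n = z^2 p (1-p) / d^2."""

    z: float = 1.96
    p: float = 0.5
    d: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise DomainError("anticipated proportion p must be in [0, 1]")
        if not self.d > 0:
            raise DomainError("allowable error d must be > 0")


def required_sample_size(params: StudyDesignParams) -> float:
    """Theoretical minimum survey size, unrounded.

    With the conventional z = 1.96, p = 0.5, d = 0.10 this evaluates to
    96.04 samples.
    """
    return params.z**2 * params.p * (1.0 - params.p) / params.d**2


# ---------------------------------------------------------------------------
# fixtures and CSV I/O

_CONC_COLUMNS = [
    "category", "type_name", "n", "n_detect",
    "mean", "p50", "p95", "iqr", "min", "max", "lod",
]
_CONS_COLUMNS = ["type_name", "age_group", "p50_g_day", "p95_g_day"]
_BW_COLUMNS = ["age_group", "kg"]


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture CSV (concentrations/consumption/body_weights)."""
    return Path(str(resources.files("tindiet.data").joinpath(f"{name}.csv")))


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def load_concentration_summaries(path: str | Path | None = None) -> list[ConcentrationSummary]:
    """Read per-food-type concentration summaries (packaged table by default)."""
    df = _read_csv(path or fixture_path("concentrations"), _CONC_COLUMNS)
    out = []
    for i, row in df.iterrows():
        try:
            item = FoodItem(str(row["category"]), str(row["type_name"]), float(row["lod"]))
            out.append(
                ConcentrationSummary(
                    item=item,
                    n=int(row["n"]),
                    n_detect=int(row["n_detect"]),
                    mean=float(row["mean"]),
                    p50=float(row["p50"]),
                    p95=float(row["p95"]),
                    iqr=float(row["iqr"]),
                    min=float(row["min"]),
                    max=float(row["max"]),
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"concentrations row {i}: {exc}") from exc
    return out


def load_body_weights(path: str | Path | None = None) -> dict[str, float]:
    df = _read_csv(path or fixture_path("body_weights"), _BW_COLUMNS)
    weights = {}
    for i, row in df.iterrows():
        label, kg = str(row["age_group"]), float(row["kg"])
        if kg <= 0:
            raise DataValidationError(f"body_weights row {i} ({label}): kg must be > 0")
        weights[label] = kg
    return weights


def load_consumption_quantiles(
    path: str | Path | None = None,
    body_weights_path: str | Path | None = None,
    items: list[FoodItem] | None = None,
    strict: bool | None = None,
) -> list[ConsumptionQuantiles]:
    """Read per item x age intake quantiles, with body weights attached.

    ``strict`` controls handling of cells with p50 > p95: user-supplied
    files raise (default), while the packaged table is loaded permissively
    because the source prints two inverted Dark Tea cells that its own
    downstream tables confirm were used as-is; these are surfaced as a
    warning rather than silently accepted.
    """
    if strict is None:
        strict = path is not None
    df = _read_csv(path or fixture_path("consumption"), _CONS_COLUMNS)
    weights = load_body_weights(body_weights_path)
    item_map = {it.type_name: it for it in (items or default_food_items())}
    out = []
    for i, row in df.iterrows():
        name = str(row["type_name"])
        if name not in item_map:
            raise DataValidationError(f"consumption row {i}: unknown food type {name!r}")
        label = str(row["age_group"])
        if label not in weights:
            raise DataValidationError(f"consumption row {i}: unknown age group {label!r}")
        p50, p95 = float(row["p50_g_day"]), float(row["p95_g_day"])
        if p50 > p95:
            msg = f"consumption row {i} ({name}/{label}): p50_g_day > p95_g_day"
            if strict:
                raise DataValidationError(msg)
            warnings.warn(msg + " (kept as printed)", stacklevel=2)
        out.append(
            ConsumptionQuantiles(
                item=item_map[name], age=AgeGroup(label, weights[label]), p50=p50, p95=p95
            )
        )
    return out


def default_food_items() -> list[FoodItem]:
    """The 25 surveyed food types, in study-table order."""
    return [s.item for s in load_concentration_summaries()]


def consumption_lookup(
    quantiles: list[ConsumptionQuantiles],
) -> dict[tuple[str, str], ConsumptionQuantiles]:
    """Index a consumption table by (type_name, age label)."""
    return {(q.item.type_name, q.age.label): q for q in quantiles}


def write_concentration_summaries(
    summaries: list[ConcentrationSummary], path: str | Path
) -> None:
    rows = [
        {
            "category": s.item.category,
            "type_name": s.item.type_name,
            "n": s.n,
            "n_detect": s.n_detect,
            "mean": s.mean,
            "p50": s.p50,
            "p95": s.p95,
            "iqr": s.iqr,
            "min": s.min,
            "max": s.max,
            "lod": s.item.lod,
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=_CONC_COLUMNS).to_csv(path, index=False)


def write_consumption_quantiles(
    quantiles: list[ConsumptionQuantiles], path: str | Path
) -> None:
    rows = [
        {
            "type_name": q.item.type_name,
            "age_group": q.age.label,
            "p50_g_day": q.p50,
            "p95_g_day": q.p95,
        }
        for q in quantiles
    ]
    pd.DataFrame(rows, columns=_CONS_COLUMNS).to_csv(path, index=False)


# sample/record level I/O (synthetic or user-supplied laboratory layouts)

_SAMPLE_COLUMNS = ["category", "type_name", "lod", "value", "detected", "substituted"]
_RECORD_COLUMNS = ["respondent_id", "age_group", "type_name", "intake_g_day", "body_weight_kg"]


def write_concentration_samples(samples: list[ConcentrationSample], path: str | Path) -> None:
    rows = [
        {
            "category": s.item.category,
            "type_name": s.item.type_name,
            "lod": s.item.lod,
            "value": repr(s.value),
            "detected": s.detected,
            "substituted": s.substituted,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=_SAMPLE_COLUMNS).to_csv(path, index=False)


def load_concentration_samples(path: str | Path) -> list[ConcentrationSample]:
    df = _read_csv(path, _SAMPLE_COLUMNS)
    return [
        ConcentrationSample(
            item=FoodItem(str(r["category"]), str(r["type_name"]), float(r["lod"])),
            value=float(r["value"]),
            detected=bool(r["detected"]),
            substituted=bool(r["substituted"]),
        )
        for _, r in df.iterrows()
    ]


def write_consumption_records(records: list[ConsumptionRecord], path: str | Path) -> None:
    rows = [
        {
            "respondent_id": r.respondent_id,
            "age_group": r.age.label,
            "type_name": r.item.type_name,
            "intake_g_day": repr(r.intake),
            "body_weight_kg": r.body_weight,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)


def load_consumption_records(
    path: str | Path, items: list[FoodItem] | None = None
) -> list[ConsumptionRecord]:
    df = _read_csv(path, _RECORD_COLUMNS)
    item_map = {it.type_name: it for it in (items or default_food_items())}
    out = []
    for i, r in df.iterrows():
        name = str(r["type_name"])
        if name not in item_map:
            raise DataValidationError(f"records row {i}: unknown food type {name!r}")
        label = str(r["age_group"])
        out.append(
            ConsumptionRecord(
                respondent_id=str(r["respondent_id"]),
                age=AgeGroup(label, float(r["body_weight_kg"])),
                item=item_map[name],
                intake=float(r["intake_g_day"]),
                body_weight=float(r["body_weight_kg"]),
            )
        )
    return out
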