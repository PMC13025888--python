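"""Pipeline orchestration and table renderers mirroring the study layouts.

Outputs are plain CSV data products (the two figures are emitted as tidy
tables, not images). Every file written by :func:`run_pipeline` is a pure
function of the manifest contents — no timestamps or environment state —
so a run is regenerable bit-exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .concentration_stats import compliance_screen, substitute_nondetects, summarize_concentrations
from .deterministic_exposure import (
    AQUATIC_CATEGORY,
    ExposureCell,
    HazardSummary,
    contribution_grid,
    hazard_grid,
    organotin_scenario_assessment,
)
from .errors import DataValidationError, TindietError
from .probabilistic_organotin import (
    MCConfig,
    PercentileAtTDI,
    ReverseResult,
    percentile_at_tdi_with_ci,
    reverse_assessment,
)
from .study_data import (
    AGE_GROUPS,
    AGE_LABELS,
    ConcentrationSample,
    ConcentrationSummary,
    ConsumptionRecord,
    ToxConstants,
    age_groups,
    load_concentration_summaries,
    load_consumption_quantiles,
    write_concentration_samples,
    write_consumption_records,
)
from .synthetic_data import (
    calibrate_concentration_spec,
    calibrate_consumption_spec,
    generate_concentration_samples,
    generate_consumption_records,
    mixture_quantile,
)

log = logging.getLogger("tindiet")

SCENARIO_ORDER = ("A", "B", "C", "D")


def _fmt(x: float, nd: int) -> str:
    return f"{x:.{nd}f}"


def render_table(results, layout: str) -> pd.DataFrame:
    """Render stage results in one of the study's table layouts.

    ``layout`` is one of table1, table3, table4, table5, fig1, fig2.
    Rounding follows the printed conventions (concentrations and EDIs to
    2 decimals; scenario-grid THQ to 4; organotin THQ to 1).
    """
    if layout == "table1":
        rows = [
            {
                "category": s.item.category,
                "type_name": s.item.type_name,
                "n": s.n,
                "n_detect": s.n_detect,
                "detect_pct": _fmt(100.0 * s.detect_rate, 0),
                "mean": _fmt(s.mean, 2),
                "p50": _fmt(s.p50, 2),
                "p95": _fmt(s.p95, 2),
                "iqr": _fmt(s.iqr, 2),
                "min": _fmt(s.min, 2),
                "max": _fmt(s.max, 2),
            }
            for s in results
        ]
        cols = ["category", "type_name", "n", "n_detect", "detect_pct",
                "mean", "p50", "p95", "iqr", "min", "max"]
        return pd.DataFrame(rows, columns=cols)

    if layout == "table3":
        cells: list[ExposureCell] = results["cells"]
        hazards: list[HazardSummary] = results["hazards"]
        if not cells:
            return pd.DataFrame(columns=["type_name"])
        item_order = list(dict.fromkeys(c.item.type_name for c in cells))
        col_keys = [(s, a) for s in SCENARIO_ORDER for a in AGE_LABELS]
        grid = {(c.item.type_name, (c.scenario.label, c.age.label)): c.edi for c in cells}
        hmap = {(h.scenario.label, h.age.label): h for h in hazards}
        data = []
        for name in item_order:
            row = {"type_name": name}
            row.update({f"{s}_{a}": _fmt(grid[(name, (s, a))], 2) for s, a in col_keys})
            data.append(row)
        data.append({"type_name": "sum_edi",
                     **{f"{s}_{a}": _fmt(hmap[(s, a)].sum_edi, 2) for s, a in col_keys}})
        data.append({"type_name": "thq",
                     **{f"{s}_{a}": _fmt(hmap[(s, a)].thq, 4) for s, a in col_keys}})
        return pd.DataFrame(data, columns=["type_name"] + [f"{s}_{a}" for s, a in col_keys])

    if layout == "table4":
        hazards = list(results)
        cols = ["scenario", "quantity"] + list(AGE_LABELS)
        if not hazards:
            return pd.DataFrame(columns=cols)
        hmap = {(h.scenario.label, h.age.label): h for h in hazards}
        rows = []
        for s in SCENARIO_ORDER:
            if not any(k[0] == s for k in hmap):
                continue
            rows.append({"scenario": s, "quantity": "sum_edi",
                         **{a: _fmt(hmap[(s, a)].sum_edi, 2) for a in AGE_LABELS}})
            rows.append({"scenario": s, "quantity": "thq",
                         **{a: _fmt(hmap[(s, a)].thq, 1) for a in AGE_LABELS}})
        return pd.DataFrame(rows, columns=cols)

    if layout == "table5":
        rows = [
            {
                "age_group": r.age.label,
                "fraction_applied": res_fraction,
                "percentile_at_tdi_pct": _fmt(r.percentile, 1),
                "edi_at_percentile": _fmt(r.edi_at_percentile, 1),
                "ci_low_pct": _fmt(r.ci_low, 1),
                "ci_high_pct": _fmt(r.ci_high, 1),
            }
            for res_fraction, group in results
            for r in group
        ]
        cols = ["age_group", "fraction_applied", "percentile_at_tdi_pct",
                "edi_at_percentile", "ci_low_pct", "ci_high_pct"]
        return pd.DataFrame(rows, columns=cols)

    if layout == "fig1":
        df = results.copy()
        if not df.empty:
            df["share"] = df["share"].map(lambda v: _fmt(v, 4))
        return df

    if layout == "fig2":
        rows = [
            {
                "category": r.category,
                "q": r.q,
                "p_min_pct": _fmt(r.p_min, 2),
                "ci_low_pct": _fmt(r.ci_low, 2),
                "ci_high_pct": _fmt(r.ci_high, 2),
            }
            for r in results
        ]
        return pd.DataFrame(rows, columns=["category", "q", "p_min_pct",
                                           "ci_low_pct", "ci_high_pct"])

    raise DataValidationError(f"unknown table layout {layout!r}")


@dataclass
class PipelineConfig:
    """End-to-end run configuration; everything an output depends on."""

    concentrations_path: str | None = None
    consumption_path: str | None = None
    body_weights_path: str | None = None
    constants: ToxConstants = field(default_factory=ToxConstants)
    out_dir: str = "tindiet_out"
    seed: int = 0
    iterations: int = 10_000
    replicates: int = 200
    n_per_age: int = 1_000
    zero_prob_default: float = 0.6
    reproduce_table4: bool = True
    simulate: bool = True

    def mc(self) -> MCConfig:
        return MCConfig(iterations=self.iterations, replicates=self.replicates,
                        seed=self.seed)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except TindietError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrapped
    return deco


@_stage("simulate-data")
def simulate_study_data(
    summaries: list[ConcentrationSummary],
    consumption,
    n_per_age: int,
    seed: int,
    zero_prob_default: float = 0.6,
) -> tuple[list[ConcentrationSample], list[ConsumptionRecord], pd.DataFrame]:
    """Generate sample- and respondent-level data plus a calibration report."""
    samples: list[ConcentrationSample] = []
    report_rows = []
    for i, s in enumerate(summaries):
        spec = calibrate_concentration_spec(s)
        samples.extend(generate_concentration_samples(spec, s.n, seed + i))
        report_rows.append(
            {
                "type_name": s.item.type_name,
                "detect_prob": spec.detect_prob,
                "log_mu": spec.log_mu,
                "log_sigma": spec.log_sigma,
                "matched_p50": spec.matched_p50,
                "matched_p95": spec.matched_p95,
                "model_p50": float(mixture_quantile(spec, 0.50)[0]),
                "model_p95": float(mixture_quantile(spec, 0.95)[0]),
                "target_p50": s.p50,
                "target_p95": s.p95,
            }
        )
    specs = [calibrate_consumption_spec(q, zero_prob_default) for q in consumption]
    records = generate_consumption_records(specs, n_per_age, seed + len(summaries))
    return samples, records, pd.DataFrame(report_rows)


@_stage("summarize")
def summarize_stage(samples, constants):
    subbed = substitute_nondetects(samples)
    by_item: dict[str, list[ConcentrationSample]] = {}
    for s in subbed:
        by_item.setdefault(s.item.type_name, []).append(s)
    summaries = [summarize_concentrations(group) for group in by_item.values()]
    return summaries, compliance_screen(subbed, constants)


def _group_by_category(samples, records):
    s_by, r_by = {}, {}
    for s in samples:
        s_by.setdefault(s.item.category, []).append(s)
    for r in records:
        r_by.setdefault(r.item.category, []).append(r)
    return s_by, r_by


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the CSV bundle plus a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    summaries = load_concentration_summaries(config.concentrations_path)
    consumption = load_consumption_quantiles(
        config.consumption_path, config.body_weights_path
    )
    constants = config.constants

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    # deterministic stages run from the summary tables
    cells, hazards = hazard_grid(summaries, consumption, constants.rfd_total_sn)
    emit("table3", render_table({"cells": cells, "hazards": hazards}, "table3"))
    emit("fig1", render_table(contribution_grid(cells), "fig1"))
    emit(
        "table4",
        render_table(
            organotin_scenario_assessment(
                summaries, consumption, constants=constants,
                reproduce_table4=config.reproduce_table4,
            ),
            "table4",
        ),
    )

    if config.simulate:
        samples, records, calib = simulate_study_data(
            summaries, consumption, config.n_per_age, config.seed,
            config.zero_prob_default,
        )
        write_concentration_samples(samples, out / "samples.csv")
        written["samples"] = out / "samples.csv"
        write_consumption_records(records, out / "records.csv")
        written["records"] = out / "records.csv"
        emit("calibration_report", calib)

        resum, compliance = summarize_stage(samples, constants)
        emit("table1", render_table(resum, "table1"))
        emit("compliance", compliance)

        mc = config.mc()
        s_by, r_by = _group_by_category(samples, records)
        emit("fig2", render_table(
            reverse_assessment(s_by, r_by, mc, constants), "fig2"))

        aq_samples = s_by.get(AQUATIC_CATEGORY, [])
        table5_results = []
        for fraction in (1.0, constants.organotin_fraction):
            group = []
            for age in age_groups():
                recs = [r for r in r_by.get(AQUATIC_CATEGORY, [])
                        if r.age.label == age.label]
                group.append(percentile_at_tdi_with_ci(
                    aq_samples, recs, age, mc, constants, fraction))
            group.append(percentile_at_tdi_with_ci(
                aq_samples, r_by.get(AQUATIC_CATEGORY, []),
                AGE_GROUPS["total"], mc, constants, fraction))
            table5_results.append((fraction, group))
        emit("table5", render_table(table5_results, "table5"))

    manifest = {
        "package": "tindiet",
        "version": __version__,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "outputs": sorted(written),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = out / "manifest.json"
    return written
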