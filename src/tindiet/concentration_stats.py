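"""Non-detect substitution, descriptive summaries and compliance screening.

Left-censored measurements (below the method LOD) are replaced by one half
of the LOD before any statistic is computed — the standard screening-level
treatment for trace contaminants. Summaries reproduce the study-table
layout (n, detects, mean, P50, P95, IQR, min, max) and samples are screened
against the applicable regulatory maximum levels.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, DomainError
from .study_data import ConcentrationSample, ConcentrationSummary, ToxConstants

#: Quantile conventions: ``linear`` interpolates between order statistics at
#: position (n-1)q; ``nearest_rank`` is the inverted-CDF convention kept for
#: sensitivity checks.
QUANTILE_METHODS = {"linear": "linear", "nearest_rank": "inverted_cdf"}


def substitute_nondetects(
    samples: Sequence[ConcentrationSample],
) -> list[ConcentrationSample]:
    """Replace every non-detect value by lod/2 (idempotent).

    Detected samples pass through unchanged. A non-detect whose recorded
    value exceeds its LOD is contradictory input and raises.
    """
    out = []
    for i, s in enumerate(samples):
        if s.detected:
            out.append(dataclasses.replace(s))
            continue
        if not s.substituted and s.value > s.item.lod:
            raise DataValidationError(
                f"sample {i} ({s.item.type_name}): non-detect value {s.value} "
                f"exceeds LOD {s.item.lod}"
            )
        out.append(dataclasses.replace(s, value=s.item.lod / 2.0, substituted=True))
    return out


def empirical_quantile(
    values: Sequence[float] | np.ndarray, q: float, method: str = "linear"
) -> float:
    """Empirical quantile of ``values`` at probability ``q``."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("empirical_quantile: empty input")
    if not 0.0 <= q <= 1.0:
        raise DomainError(f"empirical_quantile: q={q} outside [0, 1]")
    if method not in QUANTILE_METHODS:
        raise DomainError(f"unknown quantile method {method!r}")
    return float(np.quantile(arr, q, method=QUANTILE_METHODS[method]))


def summarize_concentrations(
    samples: Sequence[ConcentrationSample], method: str = "linear"
) -> ConcentrationSummary:
    """Descriptive summary of substituted samples for a single food type."""
    if not samples:
        raise DomainError("summarize_concentrations: no samples")
    items = {s.item for s in samples}
    if len(items) != 1:
        names = sorted(it.type_name for it in items)
        raise DataValidationError(f"mixed food types in one summary: {names}")
    vals = np.array([s.value for s in samples], dtype=float)
    q = lambda p: empirical_quantile(vals, p, method=method)  # noqa: E731
    return ConcentrationSummary(
        item=samples[0].item,
        n=len(samples),
        n_detect=sum(1 for s in samples if s.detected),
        mean=float(vals.mean()),
        p50=q(0.50),
        p95=q(0.95),
        iqr=q(0.75) - q(0.25),
        min=float(vals.min()),
        max=float(vals.max()),
    )


def compliance_screen(
    samples: Sequence[ConcentrationSample],
    constants: ToxConstants | None = None,
) -> pd.DataFrame:
    """Count samples above the applicable maximum allowable level.

    Returns one row per food type and limit. Non-canned categories are
    screened against ``limit_other``; canned foods are screened against
    both the solid-food limit and the stricter beverage-level variant,
    because the applicable canned threshold is product-dependent. Zero
    counts are reported explicitly.
    """
    constants = constants or ToxConstants()
    groups: dict[tuple[str, str], list[float]] = {}
    for s in samples:
        groups.setdefault((s.item.category, s.item.type_name), []).append(s.value)
    rows = []
    for (category, name), vals in groups.items():
        arr = np.asarray(vals)
        limits = (
            [constants.limit_canned, constants.limit_canned_beverage]
            if category == "canned"
            else [constants.limit_other]
        )
        for limit in limits:
            rows.append(
                {
                    "category": category,
                    "type_name": name,
                    "n": arr.size,
                    "limit_mg_kg": limit,
                    "n_exceed": int((arr > limit).sum()),
                }
            )
    return pd.DataFrame(
        rows, columns=["category", "type_name", "n", "limit_mg_kg", "n_exceed"]
    )
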