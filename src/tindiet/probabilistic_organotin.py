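"""Monte Carlo exposure simulation, percentile-at-TDI, and the reverse
minimum organotin-conversion statistic.

Each Monte Carlo iteration resamples one concentration (uniformly, with
replacement, from the substituted sample values — an empirical bootstrap)
and one consumption record, and forms

    exposure = concentration x intake x fraction / body_weight

in ug/kg bw/day. Two summary statistics are reported with replicate-based
95% confidence intervals:

* the *percentile at the TDI*: the inclusive empirical CDF of the
  simulated exposure distribution evaluated at the tolerable daily
  intake, in percent — the share of iterations at or below the TDI;
* the *minimum conversion proportion* p_min = 100 x TDI / Q(q): the
  smallest share of total tin that would need to occur as organotin for
  exposure at the distribution's conservative quantile Q(q) to reach the
  organotin TDI. Q is taken in the upper tail (default q = 0.995, the
  top half-percentile) so that p_min is a worst-case screening value;
  p_min is capped at 100%.

Point estimates of replicate-based statistics are replicate medians with
2.5th/97.5th percentile intervals, so the interval always contains the
point estimate.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .concentration_stats import empirical_quantile
from .errors import DomainError
from .study_data import (
    AGE_GROUPS,
    AgeGroup,
    ConcentrationSample,
    ConsumptionRecord,
    ToxConstants,
)

#: Conservative exposure quantile for the reverse assessment (upper 0.5%).
REVERSE_Q = 0.995


@dataclass(frozen=True)
class MCConfig:
    iterations: int = 10_000
    replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise DomainError("iterations must be >= 1")
        if self.replicates < 2:
            raise DomainError("replicates must be >= 2")


@dataclass
class ExposureDraws:
    """Simulated exposure distribution for one age group."""

    age: AgeGroup
    fraction_applied: float
    draws: np.ndarray

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if (self.draws < 0).any():
            raise DomainError("exposure draws must be >= 0")


@dataclass(frozen=True)
class PercentileAtTDI:
    age: AgeGroup
    percentile: float
    ci_low: float
    ci_high: float
    edi_at_percentile: float = float("nan")

    def __post_init__(self) -> None:
        if not self.ci_low <= self.percentile <= self.ci_high:
            raise DomainError("CI must bracket the point estimate")


@dataclass(frozen=True)
class ReverseResult:
    category: str
    q: float
    p_min: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.p_min <= self.ci_high:
            raise DomainError("CI must bracket the point estimate")
        if self.p_min > 100.0 + 1e-9:
            raise DomainError("p_min is a capped percentage")


def _values(samples: Sequence[ConcentrationSample]) -> np.ndarray:
    return np.array([s.value for s in samples], dtype=float)


def _intakes(records: Sequence[ConsumptionRecord]) -> np.ndarray:
    return np.array([r.intake for r in records], dtype=float)


def simulate_exposure_draws(
    samples: Sequence[ConcentrationSample],
    records: Sequence[ConsumptionRecord],
    age: AgeGroup,
    fraction: float,
    config: MCConfig,
    rng: np.random.Generator | None = None,
) -> ExposureDraws:
    """Bootstrap-resample concentration x intake exposures for one age group."""
    if len(samples) == 0 or len(records) == 0:
        raise DomainError("simulate_exposure_draws: empty samples or records")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    conc = _values(samples)
    intake = _intakes(records)
    ci = rng.integers(conc.size, size=config.iterations)
    ri = rng.integers(intake.size, size=config.iterations)
    draws = conc[ci] * intake[ri] * fraction / age.body_weight
    return ExposureDraws(age=age, fraction_applied=fraction, draws=draws)


def percentile_at_tdi(draws: ExposureDraws | np.ndarray, tdi: float) -> float:
    """Inclusive empirical CDF (in percent) of the draws at the TDI."""
    arr = draws.draws if isinstance(draws, ExposureDraws) else np.asarray(draws, float)
    if arr.size == 0:
        raise DomainError("percentile_at_tdi: empty draws")
    if not tdi > 0:
        raise DomainError("percentile_at_tdi: tdi must be > 0")
    return 100.0 * float((arr <= tdi).sum()) / arr.size


def min_conversion_proportion(
    draws: ExposureDraws | np.ndarray, tdi_sn: float, q: float = REVERSE_Q
) -> float:
    """Minimum organotin share (percent) for Q(q) exposure to reach the TDI."""
    arr = draws.draws if isinstance(draws, ExposureDraws) else np.asarray(draws, float)
    if not 0.0 < q < 1.0:
        raise DomainError("min_conversion_proportion: q must be in (0, 1)")
    if not tdi_sn > 0:
        raise DomainError("min_conversion_proportion: tdi must be > 0")
    quant = empirical_quantile(arr, q)
    if quant <= 0.0:
        warnings.warn(
            "exposure quantile is zero; minimum conversion proportion capped at 100%",
            stacklevel=2,
        )
        return 100.0
    return min(100.0, 100.0 * tdi_sn / quant)


def replicate_seeds(config: MCConfig) -> np.ndarray:
    """Deterministic child seeds for the replicate simulations."""
    return np.random.default_rng(config.seed).integers(2**31 - 1, size=config.replicates)


def replicate_confidence_interval(
    statistic: Callable[[int], float], config: MCConfig
) -> tuple[float, float]:
    """2.5th/97.5th percentile interval of a seeded statistic over replicates."""
    vals = np.array([statistic(int(s)) for s in replicate_seeds(config)], dtype=float)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def _replicate_summary(vals: np.ndarray) -> tuple[float, float, float]:
    lo, mid, hi = np.percentile(np.asarray(vals, float), [2.5, 50.0, 97.5])
    return float(lo), float(mid), float(hi)


def percentile_at_tdi_with_ci(
    samples: Sequence[ConcentrationSample],
    records: Sequence[ConsumptionRecord],
    age: AgeGroup,
    config: MCConfig,
    constants: ToxConstants | None = None,
    fraction: float = 1.0,
) -> PercentileAtTDI:
    """Percentile-at-TDI with a replicate-percentile confidence interval."""
    constants = constants or ToxConstants()
    tdi = constants.tdi_organotin_as_sn

    def stat(seed: int) -> float:
        d = simulate_exposure_draws(samples, records, age, fraction, config,
                                    rng=np.random.default_rng(seed))
        return percentile_at_tdi(d, tdi)

    vals = np.array([stat(int(s)) for s in replicate_seeds(config)])
    lo, mid, hi = _replicate_summary(vals)
    return PercentileAtTDI(
        age=age, percentile=mid, ci_low=lo, ci_high=hi, edi_at_percentile=tdi
    )


TOTAL_DIET = "total_diet"


def reverse_assessment(
    samples_by_category: dict[str, Sequence[ConcentrationSample]],
    records_by_category: dict[str, Sequence[ConsumptionRecord]],
    config: MCConfig,
    constants: ToxConstants | None = None,
    q: float = REVERSE_Q,
    age: AgeGroup | None = None,
) -> list[ReverseResult]:
    """Minimum conversion proportion per food category and for the total diet.

    Within one iteration, every category contributes one exposure draw and
    the total diet is their sum, so the total-diet exposure dominates each
    category pointwise and its p_min is a lower bound on every category's.
    The whole-population body weight (57 kg) applies unless another age
    group is requested; the exposure is computed on total tin
    (fraction = 1), which the conversion statistic then rescales.
    """
    constants = constants or ToxConstants()
    age = age or AGE_GROUPS["total"]
    if set(samples_by_category) != set(records_by_category) or not samples_by_category:
        raise DomainError("reverse_assessment: categories must be non-empty and aligned")
    categories = sorted(samples_by_category)
    conc = {c: _values(samples_by_category[c]) for c in categories}
    intake = {c: _intakes(records_by_category[c]) for c in categories}
    for c in categories:
        if conc[c].size == 0 or intake[c].size == 0:
            raise DomainError(f"reverse_assessment: empty data for category {c!r}")
    tdi = constants.tdi_organotin_as_sn

    def one_run(seed: int) -> dict[str, float]:
        rng = np.random.default_rng(seed)
        total = np.zeros(config.iterations)
        pmin = {}
        for c in categories:
            ci = rng.integers(conc[c].size, size=config.iterations)
            ri = rng.integers(intake[c].size, size=config.iterations)
            d = conc[c][ci] * intake[c][ri] / age.body_weight
            total += d
            pmin[c] = min_conversion_proportion(d, tdi, q)
        pmin[TOTAL_DIET] = min_conversion_proportion(total, tdi, q)
        return pmin

    runs = [one_run(int(s)) for s in replicate_seeds(config)]
    results = []
    for c in categories + [TOTAL_DIET]:
        lo, mid, hi = _replicate_summary(np.array([r[c] for r in runs]))
        results.append(ReverseResult(category=c, q=q, p_min=mid, ci_low=lo, ci_high=hi))
    return results
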