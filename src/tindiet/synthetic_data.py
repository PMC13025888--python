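"""Synthetic sample- and respondent-level data calibrated to printed summaries.

The raw laboratory measurements and survey recalls behind the packaged
summary tables are not deposited anywhere, so this module manufactures
stand-ins whose descriptive summaries reproduce the printed structure:

* Concentrations: a three-part mixture per food type — a point mass at
  half the LOD (non-detects), a lognormal body for detected values, and a
  single upper spike at the printed maximum (probability 1/n). The two
  lognormal parameters are solved from the printed P50/P95 where the
  censoring mass permits; otherwise only P95 is matched.
* Consumption: zero-inflated lognormal per item x age group, matched to
  the printed P50/P95 intake quantiles.

The concentration generator is a *stratified plug-in sampler*: it returns
the calibrated mixture's quantile grid (with the empirical P50/P95 anchored
exactly) rather than i.i.d. draws, so that summarising a generated dataset
at the study's own n reproduces the printed table. The seed only permutes
record order. Consumption records are ordinary i.i.d. seeded draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import CalibrationError, DomainError
from .study_data import (
    AgeGroup,
    ConcentrationSample,
    ConcentrationSummary,
    ConsumptionQuantiles,
    ConsumptionRecord,
    FoodItem,
)

#: Standard-normal 0.95 quantile used by the two-quantile lognormal solve.
Z95 = float(norm.ppf(0.95))

#: Default log-scale spread when only one quantile is matchable.
DEFAULT_LOG_SIGMA = 1.0


@dataclass(frozen=True)
class CensoredConcSpec:
    """Calibrated concentration mixture for one food type.

    ``detect_prob`` is the point-mass complement (non-detects sit at
    lod/2); ``tail_value``/``tail_prob`` inject the printed maximum;
    ``matched_p50``/``matched_p95`` record which printed quantiles the
    lognormal body was solved against (and hence which the generator
    anchors).
    """

    item: FoodItem
    detect_prob: float
    log_mu: float
    log_sigma: float
    tail_value: float | None = None
    tail_prob: float = 0.0
    target_p50: float = float("nan")
    target_p95: float = float("nan")
    matched_p50: bool = False
    matched_p95: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.detect_prob <= 1.0:
            raise CalibrationError("detect_prob must be in [0, 1]")
        if self.tail_prob > self.detect_prob + 1e-12:
            raise CalibrationError("tail_prob cannot exceed detect_prob")
        if self.log_sigma < 0:
            raise CalibrationError("log_sigma must be >= 0")
        if self.tail_value is not None and self.tail_value < math.exp(self.log_mu) - 1e-12:
            raise CalibrationError("tail_value must sit at or above the body median")


@dataclass(frozen=True)
class ZeroInfConsSpec:
    """Zero-inflated lognormal intake model for one item x age group."""

    item: FoodItem
    age: AgeGroup
    zero_prob: float
    log_mu: float
    log_sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_prob <= 1.0:
            raise CalibrationError("zero_prob must be in [0, 1]")
        if self.log_sigma < 0:
            raise CalibrationError("log_sigma must be >= 0")


def calibrate_concentration_spec(
    summary: ConcentrationSummary, default_log_sigma: float = DEFAULT_LOG_SIGMA
) -> CensoredConcSpec:
    """Solve the censored mixture against one printed summary row.

    The half-LOD point mass pins the mixture median whenever the detection
    rate is at most 50%, and printed values are 2-decimal roundings, so
    three regimes arise: both quantiles matched; P95 only (median
    unattainable); neither (P95 itself below display precision — the body
    is pinned at lod/2).
    """
    if summary.n <= 0:
        raise DomainError("calibrate_concentration_spec: summary has n = 0")
    n = summary.n
    detect_prob = summary.n_detect / n
    half_lod = summary.item.lod / 2.0
    nd = 1.0 - detect_prob
    tail_value = summary.max if (summary.n_detect > 0 and summary.max > 0) else None
    tail_prob = min(1.0 / n, detect_prob) if tail_value is not None else 0.0
    p_eff = detect_prob - tail_prob
    p50_t, p95_t = summary.p50, summary.p95

    def _mass_at(x: float) -> float:
        """Jump mass sitting at or below x, excluding the lognormal body."""
        m = nd if x >= half_lod else 0.0
        if tail_value is not None and tail_value <= x:
            m += tail_prob
        return m

    matched_p50 = matched_p95 = False
    if p95_t <= half_lod:
        # Sub-display-precision target: the censoring mass realises both
        # quantiles on its own; pin the body at the floor.
        log_mu = math.log(half_lod)
        log_sigma = default_log_sigma if p_eff > 0 else 0.0
    elif p_eff <= 0:
        # All detected mass is the spike; the body is never sampled, but
        # the study-n sample is still anchored at the printed P95.
        log_mu, log_sigma = math.log(p95_t), 0.0
        matched_p95 = True
    elif p50_t == p95_t:
        log_mu, log_sigma = math.log(p50_t), 0.0
        matched_p50 = (0.5 - _mass_at(p50_t)) > 0.0
        matched_p95 = (0.95 - _mass_at(p95_t)) <= p_eff + 1e-12
    else:
        a95 = (0.95 - _mass_at(p95_t)) / p_eff
        if a95 <= 0.0:
            raise CalibrationError(
                f"{summary.item.type_name}: P95 target {p95_t} sits below "
                f"{nd:.0%} non-detect mass"
            )
        a50 = (0.5 - _mass_at(p50_t)) / p_eff if p50_t > half_lod else -1.0
        if a95 < 1.0:
            z95 = float(norm.ppf(a95))
            if 0.0 < a50 < a95:
                z50 = float(norm.ppf(a50))
                log_sigma = (math.log(p95_t) - math.log(p50_t)) / (z95 - z50)
                log_mu = math.log(p50_t) - log_sigma * z50
                matched_p50 = True
            else:
                log_sigma = default_log_sigma
                log_mu = math.log(p95_t) - log_sigma * z95
            matched_p95 = True
        else:
            # The 1/n spike already owns the 0.95 point (tiny-n rows); the
            # body cannot carry the target, so pin it there and rely on
            # study-n anchoring.
            log_sigma = default_log_sigma
            if 0.0 < a50 < 1.0:
                log_mu = math.log(p50_t) - log_sigma * float(norm.ppf(a50))
                matched_p50 = True
            else:
                log_mu = math.log(p95_t)
            matched_p95 = True

    return CensoredConcSpec(
        item=summary.item,
        detect_prob=detect_prob,
        log_mu=log_mu,
        log_sigma=log_sigma,
        tail_value=tail_value,
        tail_prob=tail_prob,
        target_p50=p50_t,
        target_p95=p95_t,
        matched_p50=matched_p50,
        matched_p95=matched_p95,
    )


def mixture_cdf(spec: CensoredConcSpec, x: np.ndarray) -> np.ndarray:
    """CDF of the calibrated mixture (point mass + lognormal body + spike)."""
    x = np.asarray(x, dtype=float)
    nd = 1.0 - spec.detect_prob
    p_eff = spec.detect_prob - spec.tail_prob
    half_lod = spec.item.lod / 2.0
    out = nd * (x >= half_lod)
    if p_eff > 0:
        if spec.log_sigma > 0:
            with np.errstate(divide="ignore"):
                z = (np.log(np.maximum(x, 1e-300)) - spec.log_mu) / spec.log_sigma
            out = out + p_eff * norm.cdf(z)
        else:
            out = out + p_eff * (x >= math.exp(spec.log_mu))
    if spec.tail_value is not None:
        out = out + spec.tail_prob * (x >= spec.tail_value)
    return out


def mixture_quantile(spec: CensoredConcSpec, p) -> np.ndarray:
    """Generalised inverse of :func:`mixture_cdf` (vectorised bisection)."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    hi_val = max(
        spec.item.lod,
        math.exp(spec.log_mu + 10.0 * max(spec.log_sigma, 1.0)),
        (spec.tail_value or 0.0) * 1.001,
    )
    lo = np.zeros_like(p)
    hi = np.full_like(p, hi_val)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        ge = mixture_cdf(spec, mid) >= p
        hi = np.where(ge, mid, hi)
        lo = np.where(ge, lo, mid)
    return hi


def _detected_quantiles(spec: CensoredConcSpec, m: int) -> np.ndarray:
    """Quantile grid of the lognormal body at stratum midpoints.

    The body is capped at the printed maximum (the spike value): the
    observed extreme is the most the generator is entitled to emit.
    """
    if m == 0:
        return np.empty(0)
    if spec.log_sigma == 0:
        vals = np.full(m, math.exp(spec.log_mu))
    else:
        p = (np.arange(m) + 0.5) / m
        vals = np.exp(spec.log_mu + spec.log_sigma * norm.ppf(p))
    if spec.tail_value is not None:
        vals = np.minimum(vals, spec.tail_value)
    return vals


def _anchor(values: np.ndarray, n_nondetect: int, q: float, target: float) -> None:
    """Force the linear-interpolation empirical quantile at q to ``target``.

    Operates on the sorted value vector in place; skipped when the anchor
    position falls inside the censored block (the target is then realised
    by the point mass itself).
    """
    n = values.size
    pos = (n - 1) * q
    i0 = int(math.floor(pos))
    i1 = min(i0 + 1, n - 1)
    if i0 < n_nondetect:
        return
    np.minimum(values[n_nondetect : i0 + 1], target, out=values[n_nondetect : i0 + 1])
    np.maximum(values[i1:], target, out=values[i1:])
    values[i0] = target
    values[i1] = target if pos > i0 else values[i1]


def generate_concentration_samples(
    spec: CensoredConcSpec, n: int, seed: int
) -> list[ConcentrationSample]:
    """Materialise ``n`` samples from a calibrated spec.

    The detected-sample count is deterministic (round(n * detect_prob)),
    so the printed detection counts are reproduced exactly at the study n.
    Values are the mixture's quantile grid with the matched P50/P95
    anchored; the seed permutes record order only.
    """
    if n <= 0:
        raise DomainError("generate_concentration_samples: n must be > 0")
    k = int(round(n * spec.detect_prob))
    t = min(int(round(n * spec.tail_prob)), k) if spec.tail_value is not None else 0
    half_lod = spec.item.lod / 2.0

    detected_vals = np.concatenate(
        [_detected_quantiles(spec, k - t), np.full(t, spec.tail_value, dtype=float)]
    )
    detected_vals.sort()
    values = np.concatenate([np.full(n - k, half_lod), detected_vals])
    if spec.matched_p50:
        _anchor(values, n - k, 0.50, spec.target_p50)
    if spec.matched_p95:
        _anchor(values, n - k, 0.95, spec.target_p95)

    detected = np.zeros(n, dtype=bool)
    detected[n - k :] = True
    order = np.random.default_rng(seed).permutation(n)
    return [
        ConcentrationSample(
            item=spec.item,
            value=float(values[i]),
            detected=bool(detected[i]),
            substituted=not bool(detected[i]),
        )
        for i in order
    ]


def calibrate_consumption_spec(
    q: ConsumptionQuantiles,
    zero_prob_default: float = 0.6,
    default_log_sigma: float = DEFAULT_LOG_SIGMA,
) -> ZeroInfConsSpec:
    """Solve the zero-inflated lognormal against printed intake quantiles.

    With a positive median both parameters come from the two printed
    quantiles; with a zero median the zero mass is ``zero_prob_default``
    (any value above 0.5 keeps the mixture median at zero) and the body is
    placed so the mixture P95 matches. Inverted printed cells (p50 > p95)
    collapse to a degenerate distribution at the median.
    """
    if q.p50 < 0 or q.p95 < 0:
        raise DomainError("consumption quantiles must be non-negative")
    if q.p50 > 0:
        log_mu = math.log(q.p50)
        if q.p95 > q.p50:
            log_sigma = (math.log(q.p95) - math.log(q.p50)) / Z95
        else:
            log_sigma = 0.0
        return ZeroInfConsSpec(q.item, q.age, 0.0, log_mu, log_sigma)
    if q.p95 > 0:
        if not 0.0 <= zero_prob_default < 0.95:
            raise DomainError("zero_prob_default must be in [0, 0.95)")
        a = (0.95 - zero_prob_default) / (1.0 - zero_prob_default)
        log_mu = math.log(q.p95) - default_log_sigma * float(norm.ppf(a))
        return ZeroInfConsSpec(q.item, q.age, zero_prob_default, log_mu, default_log_sigma)
    return ZeroInfConsSpec(q.item, q.age, 1.0, 0.0, 0.0)


def generate_consumption_records(
    specs: list[ZeroInfConsSpec], n_per_age: int, seed: int
) -> list[ConsumptionRecord]:
    """Draw ``n_per_age`` respondent-level intakes per (item, age) spec."""
    if n_per_age <= 0:
        raise DomainError("generate_consumption_records: n_per_age must be > 0")
    rng = np.random.default_rng(seed)
    records: list[ConsumptionRecord] = []
    for spec in specs:
        zero = rng.random(n_per_age) < spec.zero_prob
        body = rng.lognormal(spec.log_mu, spec.log_sigma, n_per_age)
        intake = np.where(zero, 0.0, body)
        records.extend(
            ConsumptionRecord(
                respondent_id=f"{spec.age.label}-{i:06d}",
                age=spec.age,
                item=spec.item,
                intake=float(intake[i]),
                body_weight=spec.age.body_weight,
            )
            for i in range(n_per_age)
        )
    return records
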