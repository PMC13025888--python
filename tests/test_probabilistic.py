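import dataclasses

import numpy as np
import pytest
from scipy.stats import lognorm, norm

from tindiet.errors import DomainError
from tindiet.probabilistic_organotin import (
    TOTAL_DIET,
    ExposureDraws,
    MCConfig,
    min_conversion_proportion,
    percentile_at_tdi,
    percentile_at_tdi_with_ci,
    replicate_confidence_interval,
    reverse_assessment,
    simulate_exposure_draws,
)
from tindiet.study_data import AGE_GROUPS, ConcentrationSample, ConsumptionRecord, FoodItem

FISH = FoodItem("fresh_aquatic", "Fish", 0.004)
TOTAL = AGE_GROUPS["total"]


def _samples(values):
    return [ConcentrationSample(FISH, float(v), detected=True) for v in values]


def _records(intakes, age=TOTAL):
    return [
        ConsumptionRecord(f"r{i}", age, FISH, float(v), age.body_weight)
        for i, v in enumerate(intakes)
    ]


def test_degenerate_inputs_give_closed_form_exposure():
    cfg = MCConfig(iterations=500, seed=1)
    d = simulate_exposure_draws(_samples([0.2] * 10), _records([100.0] * 10), TOTAL, 1.0, cfg)
    assert np.allclose(d.draws, 0.2 * 100 / 57)
    assert round(d.draws[0], 4) == 0.3509


def test_draws_are_bit_identical_under_one_seed():
    cfg = MCConfig(iterations=2000, seed=42)
    s, r = _samples(np.linspace(0.01, 2, 50)), _records(np.linspace(5, 300, 80))
    a = simulate_exposure_draws(s, r, TOTAL, 1.0, cfg)
    b = simulate_exposure_draws(s, r, TOTAL, 1.0, cfg)
    assert np.array_equal(a.draws, b.draws)


def test_fraction_rescales_draws_exactly():
    cfg = MCConfig(iterations=2000, seed=42)
    s, r = _samples(np.linspace(0.01, 2, 50)), _records(np.linspace(5, 300, 80))
    full = simulate_exposure_draws(s, r, TOTAL, 1.0, cfg)
    part = simulate_exposure_draws(s, r, TOTAL, 0.0583, cfg)
    assert np.allclose(part.draws / full.draws, 0.0583, rtol=1e-12)


def test_simulate_rejects_empty_inputs():
    cfg = MCConfig(iterations=10, seed=0)
    with pytest.raises(DomainError):
        simulate_exposure_draws([], _records([1.0]), TOTAL, 1.0, cfg)
    with pytest.raises(DomainError):
        simulate_exposure_draws(_samples([1.0]), [], TOTAL, 1.0, cfg)


def test_percentile_at_tdi_counts_inclusively():
    draws = np.arange(1, 101) / 100.0  # 0.01 .. 1.00
    assert percentile_at_tdi(draws, 0.1) == 10.0
    assert percentile_at_tdi(np.full(50, 0.1), 0.1) == 100.0
    shuffled = np.random.default_rng(0).permutation(draws)
    assert percentile_at_tdi(shuffled, 0.1) == 10.0  # permutation-invariant


def test_percentile_at_tdi_monotone_in_tdi():
    draws = np.random.default_rng(5).lognormal(-2, 1, 5000)
    tdis = [0.01, 0.05, 0.1, 0.5]
    vals = [percentile_at_tdi(draws, t) for t in tdis]
    assert vals == sorted(vals)


def _product_lognormal_mc(mu_c, s_c, mu_i, s_i, iterations, seed, n_source=40_000):
    rng = np.random.default_rng(seed)
    conc = rng.lognormal(mu_c, s_c, n_source)
    intake = rng.lognormal(mu_i, s_i, n_source)
    cfg = MCConfig(iterations=iterations, seed=seed + 1)
    d = simulate_exposure_draws(_samples(conc), _records(intake), TOTAL, 1.0, cfg)
    return d, n_source


def test_percentile_at_tdi_recovers_product_lognormal_cdf():
    mu_c, s_c, mu_i, s_i = -2.0, 0.8, 4.0, 0.5
    d, n_src = _product_lognormal_mc(mu_c, s_c, mu_i, s_i, 10_000, seed=7)
    mu = mu_c + mu_i - np.log(57.0)
    sigma = np.hypot(s_c, s_i)
    tdi = 0.1
    expected = 100.0 * norm.cdf((np.log(tdi) - mu) / sigma)
    p = expected / 100.0
    se = 100.0 * np.sqrt(p * (1 - p)) * (1 / np.sqrt(10_000) + 2 / np.sqrt(n_src))
    assert percentile_at_tdi(d, tdi) == pytest.approx(expected, abs=3 * se)


def test_min_conversion_proportion_examples_and_cap():
    assert min_conversion_proportion(np.full(100, 10.0), 0.1, q=0.995) == 1.0
    assert min_conversion_proportion(np.full(100, 0.05), 0.1, q=0.995) == 100.0
    with pytest.warns(UserWarning, match="capped"):
        assert min_conversion_proportion(np.zeros(100), 0.1, q=0.995) == 100.0


def test_min_conversion_proportion_recovers_analytic_quantile():
    mu_c, s_c, mu_i, s_i = -2.0, 0.8, 4.0, 0.5
    d, n_src = _product_lognormal_mc(mu_c, s_c, mu_i, s_i, 10_000, seed=13)
    mu = mu_c + mu_i - np.log(57.0)
    sigma = np.hypot(s_c, s_i)
    q = 0.995
    quant = lognorm.ppf(q, s=sigma, scale=np.exp(mu))
    expected = 100.0 * 0.1 / quant
    dens = lognorm.pdf(quant, s=sigma, scale=np.exp(mu))
    se_quant = np.sqrt(q * (1 - q)) * (1 / np.sqrt(10_000) + 2 / np.sqrt(n_src)) / dens
    tol = expected * (se_quant / quant)
    assert min_conversion_proportion(d, 0.1, q=q) == pytest.approx(expected, abs=3 * tol)


def test_min_conversion_is_antitone_in_exposure_scale():
    draws = np.random.default_rng(3).lognormal(0, 1, 20_000)
    base = min_conversion_proportion(draws, 0.1)
    assert min_conversion_proportion(draws * 4.0, 0.1) == pytest.approx(base / 4, rel=1e-9)


def test_replicate_interval_of_constant_statistic_is_degenerate():
    cfg = MCConfig(iterations=10, replicates=40, seed=2)
    lo, hi = replicate_confidence_interval(lambda seed: 3.25, cfg)
    assert lo == hi == 3.25


def test_replicate_interval_brackets_the_replicate_median():
    cfg = MCConfig(iterations=10, replicates=60, seed=2)

    def stat(seed):
        return float(np.random.default_rng(seed).normal(10, 2, 50).mean())

    lo, hi = replicate_confidence_interval(stat, cfg)
    from tindiet.probabilistic_organotin import replicate_seeds

    med = float(np.median([stat(int(s)) for s in replicate_seeds(cfg)]))
    assert lo <= med <= hi


def test_replicate_interval_width_follows_clt_rate():
    cfg = MCConfig(iterations=10, replicates=150, seed=8)

    def make_stat(m):
        return lambda seed: float(np.random.default_rng(seed).normal(0, 1, m).mean())

    lo1, hi1 = replicate_confidence_interval(make_stat(200), cfg)
    lo2, hi2 = replicate_confidence_interval(make_stat(800), cfg)
    ratio = (hi2 - lo2) / (hi1 - lo1)
    assert ratio == pytest.approx(0.5, rel=0.30)


def test_percentile_at_tdi_ci_brackets_point_estimate():
    s = _samples(np.random.default_rng(1).lognormal(-2, 1, 500))
    r = _records(np.random.default_rng(2).lognormal(4, 0.5, 500))
    res = percentile_at_tdi_with_ci(
        s, r, TOTAL, MCConfig(iterations=2000, replicates=30, seed=9)
    )
    assert res.ci_low <= res.percentile <= res.ci_high
    assert 0 <= res.percentile <= 100


def test_reverse_single_category_total_equals_category():
    s = {"canned": _samples(np.random.default_rng(1).lognormal(0, 1, 300))}
    r = {"canned": _records(np.random.default_rng(2).lognormal(3, 0.5, 300))}
    res = reverse_assessment(s, r, MCConfig(iterations=2000, replicates=10, seed=4))
    by = {x.category: x for x in res}
    assert by[TOTAL_DIET].p_min == by["canned"].p_min
    assert by[TOTAL_DIET].ci_low == by["canned"].ci_low


def test_reverse_total_diet_dominates_every_category(by_category):
    s_by, r_by = by_category
    res = reverse_assessment(
        s_by, r_by, MCConfig(iterations=4000, replicates=10, seed=6)
    )
    by = {x.category: x for x in res}
    for cat, x in by.items():
        if cat != TOTAL_DIET:
            assert by[TOTAL_DIET].p_min <= x.p_min + 1e-12


def test_reverse_orders_stochastically_dominated_categories():
    rng = np.random.default_rng(10)
    records = _records(rng.lognormal(3, 0.5, 400))
    s = {
        "hot": _samples(rng.lognormal(1.0, 0.5, 400)),
        "cold": _samples(rng.lognormal(-1.0, 0.5, 400)),
    }
    r = {"hot": records, "cold": records}
    res = {x.category: x for x in reverse_assessment(
        s, r, MCConfig(iterations=4000, replicates=10, seed=11))}
    assert res["hot"].p_min < res["cold"].p_min


def test_exposure_draws_reject_negative_values():
    with pytest.raises(DomainError):
        ExposureDraws(TOTAL, 1.0, np.array([-0.1, 0.2]))
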