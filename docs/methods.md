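# Methods

`tindiet` implements a screening-level dietary risk assessment for total
tin (Sn) and organotin compounds, built around two summary tables from a
provincial food-surveillance programme: per-food-type Sn concentration
summaries (25 food types, five categories, 2014 laboratory samples, mg/kg
dry weight) and per-age-group consumption quantiles with mean body weights
(five age strata; whole-population body weight 57 kg). This note records
the models, the parameter choices, and the places where the design was
genuinely open.

## Exposure model

The estimated daily intake for a food item is

    EDI = C × CR / BW        [µg/kg bw/day]

with C the Sn concentration (mg/kg ≡ µg/g), CR the daily consumption
(g/day) and BW the body weight (kg). Concentrations are carried on a
single consistent basis throughout (the source tables are dry-weight; no
wet-weight conversion factor is available, so the identity conversion is
applied and results are interpreted on that basis).

Hazard quotients divide an EDI by a toxicological reference:

* total Sn — oral minimal risk level 300 µg/kg bw/day (chronic, inorganic
  tin; conservatively applied to total Sn);
* organotin compounds — group TDI 0.25 µg/kg bw/day, ≈ 0.10 µg-Sn/kg
  bw/day on a tin-mass basis, which is the reference used everywhere the
  exposure is expressed as tin.

THQ is the sum of per-item quotients; THQ > 1 flags potential concern.

## Deterministic scenario grid

Four scenarios cross median/high consumption with median/high
contamination: A = P50×P50, B = P95×P50, C = P50×P95, D = P95×P95. The
grid is evaluated for every item × age group; P50/P95 are taken directly
from the summary tables (or from sample-level data through the same
quantile code path when such data are supplied). Items with a printed P50
consumption of 0 g/day contribute exactly 0 in P50-consumption scenarios —
no imputation.

Organotin screening multiplies the total-Sn EDI of fresh aquatic products
by a conservative literature fraction of organotin in total tin (5.83%,
the lowest documented mollusk ratio) and compares it with the organotin
TDI. The published scenario table is only recovered when the fraction is
left at 1 (total-Sn EDIs compared directly against the organotin TDI);
both modes are provided (`reproduce_table4` / `--reproduce-table4`), the
formula-as-written fraction being the default, and the discrepancy is
surfaced rather than silently resolved.

Display rounding follows the source layouts (EDI to 2 decimals, grid THQ
to 4, organotin THQ to 1); all computation is unrounded.

Known limitation: the printed summary tables are 2-decimal roundings. The
scenario grid recomputed from them reproduces the published high-scenario
anchor cells exactly after rounding, but cells driven by sub-precision
medians (printed 0.00/0.01 mg/kg) or coarse P95s can deviate by more than
the rounding budget — the original analysis used unrounded percentiles
that are not recoverable from print. The consumption table also prints two
inverted Dark Tea cells (P50 > P95); they are kept as printed because the
published grid demonstrably used them as-is, and the loader warns.

## Left-censoring

Measurements below the method LOD (0.004 mg/kg; 0.008 mg/kg for tea) are
replaced by LOD/2 before any statistic is computed. Substitution is
idempotent and recorded per sample. A sensitivity comparison with
zero-substitution is available by configuring the constants. Quantiles use
linear interpolation between order statistics at position (n−1)q, with a
nearest-rank option for sensitivity checks; IQR = Q0.75 − Q0.25 under the
same convention.

## Synthetic data generator

The raw laboratory and survey records are unavailable by design, so the
generator manufactures stand-ins calibrated to the printed summaries.

**Concentrations.** A three-part mixture per food type: a point mass at
LOD/2 with probability 1 − detection rate; a lognormal body for detected
values; and a single spike at the printed maximum with probability 1/n,
emulating the heavy upper tails (e.g. canned fungi: mean 1.61 vs P95 0.48
mg/kg). The lognormal parameters are solved in closed form from the
printed P50/P95 via the mixture CDF. Three regimes arise:

* both quantiles matched — possible only when the detection rate exceeds
  50% (otherwise the half-LOD point mass pins the median);
* P95 only — the body σ defaults to 1.0 on the log scale and µ is placed
  from the P95 equation;
* neither — printed P95 at or below LOD/2 (sub-display-precision rows),
  where the censoring mass realises the quantiles on its own.

For a handful of very small rows (n ≤ 19) the 1/n spike already owns the
upper 5% of mass and the body cannot carry the P95; the body is then
pinned at the target. The body is capped at the printed maximum: the
generator never emits values beyond the observed extreme, which also
keeps synthetic datasets compliant with the 200 mg/kg regulatory limits,
as the study reports for the real data.

The generator is a *stratified plug-in sampler*, not an i.i.d. sampler:
it emits the calibrated mixture's quantile grid with the matched P50/P95
anchored exactly at the empirical-quantile positions, the detected-sample
count fixed at round(n × detection rate), and a seeded permutation for
record order. This is a deliberate design choice: the generator's contract
is to reproduce the printed summary statistics *at the study's own sample
sizes* (down to n = 8), where i.i.d. sampling noise would exceed any
useful reproduction tolerance. The cost is that a single generated dataset
understates sampling variability; anything that needs resampling noise
gets it from the bootstrap step of the Monte Carlo stage, not from the
generator.

**Consumption.** Zero-inflated lognormal per item × age group. With a
positive printed median, both parameters come from the two printed
quantiles (σ = ln(P95/P50)/1.6449, the denominator being the
standard-normal 0.95 quantile). With a zero median, the zero mass defaults
to 0.6 — any value above 0.5 keeps the mixture median at zero; 0.6 is the
minimal-assumption choice and is configurable — and the body is placed so
the mixture P95 matches. Records are ordinary seeded i.i.d. draws; their
calibration is verified at n ≥ 10,000.

What passing tests on these data do and do not show: they validate the
pipeline's arithmetic, its censoring handling, and the qualitative
category ordering of the probabilistic statistics; they cannot validate
population-level magnitudes, which depend on the unpublished respondent-
and sample-level data. Real survey data would add intra-respondent
correlation across items, seasonal and regional structure, and non-
lognormal consumption shapes that the generator does not emulate.

## Monte Carlo stage

Each iteration resamples one concentration (uniform with replacement over
the substituted sample values — an empirical bootstrap) and one
consumption record, forming exposure = C × CR × fraction / BW with the
age group's body weight (57 kg for the whole population). Defaults:
10,000 iterations; 200 replicate simulations for confidence intervals.

* **Percentile at TDI** — the inclusive empirical CDF at the TDI, in
  percent: the share of iterations at or below the organotin TDI. Higher
  values mean fewer individuals exceed it.
* **Minimum conversion proportion** — p_min = 100 × TDI / Q(q), capped at
  100%, where Q(q) is a conservative quantile of the *total-Sn* exposure
  distribution (fraction = 1 by definition of the statistic). The default
  q = 0.995 takes the top half-percentile of the simulated distribution:
  back-calculating the published category values shows they correspond to
  upper-tail exposures (e.g. canned foods ≈ 62 µg/kg bw/day ≈ the P95
  canned-fruit concentration × a high intake / 57 kg), and a lower-tail
  read would cap every category at 100% under any zero-inflated
  consumption model. q is a parameter for probing other conservatism
  levels.

For the reverse assessment, categories are simulated jointly: within one
iteration each category contributes one draw and the total diet is their
sum, so the total-diet exposure dominates every category pointwise and
its p_min is a structural lower bound on each category's.

Confidence intervals are percentile intervals (2.5th/97.5th) over
independent seeded replicate simulations; the reported point estimate is
the replicate median, so the interval always brackets it. The replicate
count controls the smoothness of the interval estimate, not its width —
the width reflects the statistic's own sampling spread at the configured
iteration count.

Determinism: every stochastic stage derives its streams from a single
seed (`numpy.random.default_rng`); identical configuration reproduces
every output byte-for-byte, and the run manifest echoes the full
configuration.

## Problem sizes used in the shipped checks

The test suite and pipeline defaults run the synthetic stage at the study
sample sizes (2014 concentration samples) with 400–1,000 consumption
records per item × age group, Monte Carlo at 10,000 iterations, and 10–20
replicates for interval checks in tests (200 in the pipeline default).
These sizes were chosen so the distributional checks resolve the
tolerances they assert while remaining quick to run.

## Compliance screening

Samples are screened against the national maximum allowable levels:
200 mg/kg for non-canned categories, and for canned foods both the
200 mg/kg solid-food limit and the 100 mg/kg beverage-level variant. Both
canned thresholds are reported because the applicable one is
product-dependent and the source material is internally inconsistent
about which bound the canned data satisfy (a printed canned-fruit maximum
of 134 mg/kg alongside a sub-100 narrative); the package reports against
both rather than resolving the contradiction. Zero exceedance counts are
reported explicitly.
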