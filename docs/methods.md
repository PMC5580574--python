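# Methods

## Model

The package assesses a multi-year, multi-site monitoring record of eight
water-quality indicators against the five-class surface-water standards
(GB3838-2002) and a weighted composite pollution index (PI).

**Aggregation.** Input records are long-format `(site, year, indicator,
value)` rows. Values are aggregated to one annual mean per indicator by
an arithmetic mean over sites and samples. Missing indicator-years are an
error rather than being skipped: a weighted sum over a varying indicator
set is not comparable across years. All measured quantities must be
strictly positive (concentrations, depths, pH readings).

**Single-factor evaluation.** Each value is assigned the best class whose
limit it satisfies, with the boundary belonging to the better class (≤ the
limit for pollutant-direction indicators, ≥ for benefit-direction). A
value failing even the class-V limit falls in the conventional sixth
category "worse than V". pH is class I inside its 6–9 interval and worse
than V outside, since the standard uses one interval for all classes.
Transparency and chlorophyll-a have no class table in the standard; for
them only first-class compliance is evaluated, against targets of 5 m and
0.002 mg/L respectively, which are carried as ordinary first-class
constants. The per-year overall verdict, where wanted, is the worst
indicator class (`AssessmentResults.worst_class`).

The bundled limit tables use the lake/reservoir columns for TN and TP,
appropriate for a lagoon-type wetland and consistent with the first-class
targets of 0.2 and 0.01 mg/L (the river columns do not reach these
values). The river TP column ships as an alternative
(`StandardsSet.using_alt_limits("TP", "river")`) because the appropriate
column can be debatable for wetlands fed by river systems; with lake
limits a TP of 0.268 mg/L is worse than class V, with river limits it is
class IV.

**Standardization and PI.** Sub-indices put every indicator on a common
pollution scale where 1 = exactly at the first-class target:

| direction | sub-index | indicators |
|---|---|---|
| pollutant | Ci / Coi | COD, TN, TP, petroleum, chlorophyll-a |
| benefit | Coi / Ci | DO, transparency |
| range | \|Ci − mid\| / half-width | pH (6–9 → \|Ci − 7.5\| / 1.5) |

The composite index is the weighted average PI = Σ Wi·si with weights
summing to one. A plain Ci/Coi for the benefit indicators would reward
*low* oxygen and clarity; the inverse ratio is the direction-correct
choice and, on the bundled dataset, reproduces the published index series
to within 0.05. A residual gap of up to ~0.04 against the published
values remains; the original computation's handling of pH/DO was not
published, and we document the convention rather than tuning per-year.

**Weights.** Weights can be supplied directly (the bundled expert scheme:
pollution and biological indicators 0.157–0.178, general indicators
0.036–0.107, sum exactly 1) or derived from a pairwise judgment matrix by
the principal-eigenvector method (power iteration, relative tolerance
1e-10, cap 10,000 iterations). Consistency is measured by
CR = [(λmax − n)/(n − 1)] / RI(n) with Saaty's random-index constants and
the conventional CR < 0.1 acceptance rule; 2×2 reciprocal matrices are
always consistent (CR defined as 0). A row-geometric-mean solver is
provided as a cross-check; the two agree to 1e-6 on consistent matrices.
A matrix can also be built from per-indicator verbal importance scores
1..5, mapping a score difference d to the ratio d+1. Note this additive
mapping is only exactly transitive when at most two distinct scores
appear; with more levels the matrix has a small positive CR (still well
below 0.1), which the weight derivation handles as usual.

**Pollution levels.** The PI series' population standard deviation
(divisor n, not n−1 — the published per-indicator SD column and PI spread
are reproducible only with divisor n) defines three SD-wide levels
anchored at the series minimum: slight [PImin, PImin+SD), moderate
[PImin+SD, PImin+2·SD), severe [PImin+2·SD, PImin+3·SD]. Intervals are
lower-inclusive; bounds are kept at full precision internally and rounded
(default one decimal) only in printed reports. A PI outside
[PImin, PImin+3·SD] — possible when classifying new data against a
historical scheme — is clamped to the nearest level and flagged
`out_of_calibration`, since the scheme defines no open-ended levels. A
constant PI series (SD = 0) has no meaningful scheme and is an error.

**Trend typing.** Each indicator's pollution-scale sub-index series is
labelled with one of four types by a deterministic rule with configurable
thresholds (`TrendThresholds`):

1. *stable* — coefficient of variation (population SD / mean) of the
   measured series below 0.05 **and** standard-compliant in every year.
   The CV uses the measured scale because the midpoint-deviation
   sub-index of a range indicator (pH) exaggerates relative variation.
2. *improving* — net relative change first→last ≤ −30% and near-monotonic
   decline: at most one counter-trend step, no larger than 5% of the
   series range. (*deteriorative* is the mirror image for increases.)
3. *floating* — everything else.

The dip tolerance is what distinguishes a genuine recovery with one small
rebound (DO: 1.32 → 0.80 → 0.79 → 0.82) from an oscillating series whose
net change happens to be large (COD: −33% net but with a mid-series surge
of 80% of the range). The defaults reproduce the published four-type
grouping of the bundled dataset; they are configuration, not constants,
and at least three time points are required.

**Percent changes.** Reported as signed 100·(later − earlier)/earlier on
the measured scale. Three percent-change sentences in the source
narrative (TP "13.02%", DO "70%", chlorophyll-a "61.6%/41.1%") are not
arithmetically consistent with the published annual means under any
baseline pairing we could construct; they are excluded from the
reproduction tests, which cover the five figures that are consistent.

A related caveat: the source text states TN was "below class V"
throughout, but the 2010 mean (1.69 mg/L) sits within the lake class-V
limit of 2.0 and so classes as V; only 2011–2013 exceed it. The package
reports what the arithmetic gives.

## Synthetic data

The generator (`ScenarioSpec` → `generate`) emulates the statistical
shape of lake/wetland monitoring series so every stage is testable
without external data. Per indicator it draws positive values from a
lognormal whose parameters are set so the **mean** of the pollution-scale
sub-index equals a configurable *exceedance ratio* (1 = at target; 20 =
the TP-like regime), with relative scatter σ (the `noise` knob) and a
year-trend shape: `flat`, `linear_up`/`linear_down` (ramp by
`trend_factor` across the span) or `spike` (one year multiplied by
`trend_factor`). Benefit indicators are mirrored (higher exceedance →
lower concentration); pH is drawn uniformly inside its interval with a
configurable compliance probability, else just above it. Identical spec
and seed give byte-identical tables.

Defaults (3 sites, noise 0, flat) mirror the bundled study's shape: a
handful of stations reported as annual means. What the generator does
*not* emulate: seasonal cycles, spatial correlation between sites,
detection-limit censoring, and cross-indicator correlation (e.g. TN–TP
co-variation from shared runoff sources). Tests passing on synthetic data
therefore demonstrate the pipeline's arithmetic and contracts, not
robustness to those real-data features.

The bundled fixture (`qilihai_fixture`) is the published 2010–2013
eight-indicator annual-mean dataset as a single pseudo-site (only annual
means were published, so site aggregation is a pass-through), with the
matching standards and expert weights.

## Numerical choices and problem sizes

- Weight-sum and PI-decomposition invariants are enforced at 1e-9;
  power-iteration convergence at 1e-10 relative.
- Reciprocity of judgment matrices is checked at 1e-9 relative.
- Randomized property tests use 100–1000 draws and 200 synthetic sites,
  which keeps the full suite under a few seconds while leaving Monte
  Carlo margins (3 standard errors) comfortably resolvable.
- Tie-breaks: class boundaries belong to the better class; level
  boundaries are lower-inclusive; the level scheme anchors at the exact
  (unrounded) series minimum.

## Limitations

- No unit harmonization: inputs must be mg/L (transparency in m).
- Single-level AHP only; no group aggregation or fuzzy variants.
- The trend rule is qualitative typing, not a statistical trend test
  (no Mann–Kendall significance or Sen slope).
- The SD-level scheme is relative to the observed series: it describes
  variation within the assessed period and is not transferable across
  water bodies.
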