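# Methods

## Scoring model

Both Nutri-Score algorithm versions are realised as pure band-table
lookups plus one aggregation rule; nothing is fitted. A band table is
an ordered threshold sequence with one point level per band
(`len(points) == len(thresholds) + 1`), which accommodates both the
uniformly graded components (0..max) and the non-uniform
fruits/vegetables/legumes (FVL) component (foods `{0,1,2,5}`,
new-beverages `{0,2,4,6}` at thresholds 40/60/80%).

**Boundary convention.** The published grids summarise each component
as "≤min → 0 points, ≥max → max points". We take both anchors as
inclusive and make interior bands left-open/right-closed: a value
equal to an interior threshold falls in the band *below* it. The
single point where this deviates from some official texts is the top
anchor itself (e.g. exactly 3350 kJ scores 10 here, 9 in a strictly
">" reading); the convention is centralised in `BandTable.score` so a
different reading is a one-line change. No rounding is applied to
nutrient inputs before lookup — declared label values are scored
as-is.

**Interior thresholds.** The published summaries print only the
anchors and point ranges; the shipped YAML carries the full official
Santé publique France threshold grids for all four (version, class)
pairs. A fallback generator (`uniform_band_table`) spaces thresholds
evenly between the anchors with step `(max − min)/(max_points − 1)`;
it reproduces the official 2017 grids exactly for energy, saturated
fat, salt and protein, but not for sugar, whose official old grid
rounds two interior thresholds (31 and 40 instead of 31.5 and 40.5) —
the fallback is therefore a convenience for anchor-only
specifications, never the source of truth.

**Aggregation.** Negative points N sum energy, sugar, SFA and salt
points (plus a flat 4-point penalty for non-nutritive sweeteners in
new-algorithm beverages). Protein counting is conditional: old
general foods count protein iff `N < 11` or FVL is at its maximum
point level; new general foods iff `N < 11`; beverages always. The
rule is configurable per call (`protein_rule=` override) and the
breakdown records whether protein was counted, so alternative readings
of the conditional remain testable. Totals are integers by
construction.

**Routing.** All six categories are scored as general foods except
milk alternatives: general foods under the old algorithm, beverages
under the new one. A reserved `water` category exists solely to
exercise the waters-only label-A rule of the beverage scales; the
old-beverages spec is present and validated but never routed to by the
six study categories. Its FVL grading follows the published 0–5
summary rather than older official texts that grade beverages' fruit
and vegetable content to 10 points — the discrepancy is documented
here, not resolved, since the class is unused.

**Labels.** Cut-off scales are validated on load to partition the
integers with no gaps or overlaps; on beverage scales A is assigned
iff the product is a water, regardless of score.

## Guideline compliance

Dutch Wheel-of-Five criteria for replacement products: meat
alternatives — protein ≥ 20 E%, SFA ≤ 2.5 g, salt ≤ 1.125 g, iron
≥ 0.8 mg, vitamin B12 ≥ 0.24 µg per 100 g; milk alternatives —
protein ≥ 20 E%, total sugar ≤ 6 g, SFA ≤ 1.1 g, salt ≤ 0.15 g,
calcium ≥ 80 mg, B12 ≥ 0.24 µg per 100 mL. All comparisons are
inclusive at the threshold. The sugar criterion uses total sugar (the
collected field); declared fortificant content is evaluated with no
intrinsic/added distinction. Protein E% is `protein_g × 4 kcal /
energy_kcal × 100`; it is an error to request it for a 0-kcal product
in isolation, but for compliance and descriptive summaries such a
product's protein energy share is taken as 0%. Per-label percentages
are `100 × passing / group size`; empty label groups are absent from
the report rather than reported as 0%.

## Statistics

Scores and compositions in this product segment are strongly
non-normal (a Shapiro–Wilk screen is provided and documents this), so
all summaries are medians with 25th/75th percentiles (linear
interpolation between order statistics, numpy's default) and all tests
are nonparametric and two-sided at α = 0.05 with no multiple-testing
correction:

* **Within category, between versions** (paired by product): Wilcoxon
  signed-rank on new − old score differences. Zero differences are
  discarded (Wilcoxon's original convention). The exact null
  distribution is used for n ≤ 25 when the nonzero magnitudes are
  untied; otherwise the tie-corrected normal approximation. The
  policy is configurable (`StatOptions`) and the method used is
  recorded in the output.
* **Within label group, between versions** (independent groups, since
  group membership differs by version): Mann–Whitney U per nutrient.
  A label held by no product under one version (label A for new-
  algorithm milk alternatives, structurally) yields rows marked
  not-computable instead of a test.

Degenerate inputs are flagged, never silently tested: fewer than 2
pairs, all-zero differences, constant samples, n < 3 for the
normality screen.

## Synthetic generator

The generator emulates the statistical structure of a supermarket
inventory of plant-based alternatives, not any real product list.
Strictly positive nutrients are log-normal, pinned by the two
quantiles such inventories report: `σ = ln(q75/median)/z₀.₇₅`,
`μ = ln(median)`. Nutrients with a genuine point mass at zero
(sugar in unsweetened drinks) get a configurable zero-inflation
probability. FVL is truncated-normal on [0, 100]. Fortification is
all-or-nothing per product — one Bernoulli draw switches the whole
fortificant block (iron 2.1 mg, calcium 120 mg, vitamin B12 0.38 µg
per 100 g/mL) on or off, because fortification is a brand-level
decision; the fortificant marginal is exactly two-point. Declared
energy is floored at the macro-implied minimum
(4·protein + 4·sugar + 9·SFA + 2·fiber kcal) so no synthetic label is
internally impossible, and values are rounded to label-like precision
(0.1 kcal, 0.01 g, 0.1% FVL).

Category defaults (per 100 g; milk per 100 mL; median and q75):
meat 175/205 kcal, protein 14/17 g, salt 1.1/1.35 g; milk 40/52 kcal,
protein 1.5/3.2 g, sugar 2.5/5.5 g with 25% unsweetened, salt
0.10/0.12 g, 10% sweetener incidence; fish, cold cuts, dessert and
cheese alternatives use typical Dutch supermarket compositions
(`simulate.default_config`). Fortification incidence 10–38% by
category. Nutrients are drawn independently apart from the energy
floor — real inventories correlate protein with energy and brand
families share recipes, neither of which is emulated. Passing tests
therefore demonstrate the engine's and pipeline's correctness and the
*structural* consequences of the algorithm change (no beverage A
labels, healthy-share decline, sugar-selected B group), not the
study's empirical percentages, which depend on the real product mix.

Default problem sizes — 200 products per category for pipeline runs,
5,000 for quantile-recovery checks — keep every analysis comfortably
in the seconds range while leaving sampling error well below the
effects being demonstrated.

## Known limitations

* The new algorithm's special scales (red meat; fats, oils, nuts and
  seeds; cheese) are out of scope: every product routes to general
  foods or beverages, which is how this product segment is scored.
* Sodium→salt conversion, ingredient-list parsing and density
  (g↔mL) conversion are not attempted; inputs are the declared per-100
  values.
* The FVL ingredient-class map is a starter vocabulary; real data
  will need extension (unlisted ingredients conservatively do not
  qualify).
* Exact Wilcoxon p-values with tied magnitudes fall back to the
  corrected normal approximation rather than a tie-aware exact
  enumeration.
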