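# nutriscore

Dual-version Nutri-Score / FSAm-NPS scoring and old-versus-new
comparison for plant-based meat, fish, and dairy alternatives.

## The problem

Nutri-Score is the five-letter (A–E, dark green to red) front-of-pack
label adopted by seven European countries. Its underlying FSAm-NPS
score (modified UK FSA nutrient-profiling system) was revised in 2022
(general foods) and 2023 (beverages) after concerns that the original
2017 algorithm disagreed with national dietary guidelines — notably for
plant-based meat and dairy alternatives, a fast-growing supermarket
segment with known nutritional weak spots (salt, protein, iron,
calcium, vitamin B12). This package implements **both** algorithm
versions as a tested scoring engine and reproduces the analysis that
quantifies what the revision changes for these products: score and
label distributions per category, compliance with the Dutch
dietary-guideline (Wheel of Five) criteria, and nutrient comparisons
within the groups of products holding a "healthy" label A or B under
each version.

## The score

For a product with composition per 100 g (foods) or 100 mL
(beverages), each component is mapped to points through a band table
(an ordered threshold sequence):

```
N = pts(energy kJ) + pts(sugar g) + pts(SFA g) + pts(salt g)  [+ 4 if NNS, beverages-new]
P = pts(protein g) + pts(fiber g) + pts(FVL %)
FSAm-NPS = N − P'        P' = P minus protein points when the counting rule excludes them
```

Protein counting: old general foods count protein only if `N < 11` or
the FVL component is at its maximum; new general foods only if
`N < 11`; beverages always. The total maps to a letter through the
version- and class-specific cut-off scale; on beverage scales label A
is reserved for waters. Routing is the revision's key structural
change: milk alternatives are general foods under the old algorithm
but beverages under the new one. Band thresholds, label scales,
guideline criteria, and the FVL ingredient-class map ship as editable
YAML under `src/nutriscore/data/`.

Because the original product database is not public, the package
includes a seedable synthetic generator (`nutriscore.simulate`)
emulating the six categories with log-normal nutrients pinned by
median/75th-percentile pairs and all-or-nothing fortification.

## Worked example

```python
import nutriscore as ns

products = ns.generate_products(ns.default_config(200), seed=1)
milk = [p for p in products if p.category == ns.Category.milk_alt]
old, _ = ns.score_table(milk, "old")
new, _ = ns.score_table(milk, "new")
for v, b in (("old", old), ("new", new)):
    print(v, {l: sum(x.label == l for x in b) for l in "ABCDE"})
```

prints

```
old {'A': 94, 'B': 98, 'C': 6, 'D': 2, 'E': 0}
new {'A': 0, 'B': 75, 'C': 83, 'D': 20, 'E': 22}
```

Under the old algorithm 96% of the synthetic milk alternatives hold a
healthy label A or B; under the new algorithm the share drops to 37.5%
and **no** milk alternative holds label A — structurally impossible,
since only waters receive A on the beverage scale. The full bundle
(per-product scores, per-category medians with Wilcoxon signed-rank
tests, label-shift table, Mann–Whitney A/B-subset comparisons,
compliance reports, run manifest) comes from
`ns.run_full_analysis(ns.RunConfig(seed=1, output_dir="out"))` or the
CLI:

```bash
nutriscore simulate --seed 1 --n-per-category 200 --out products.csv
nutriscore score   --input products.csv --version new --out scores.csv
nutriscore comply  --input products.csv --version new --out compliance.csv
nutriscore report  --seed 1 --out-dir out        # everything at once
```

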