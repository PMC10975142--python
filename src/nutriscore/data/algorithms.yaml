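# Band tables and label scales for the FSAm-NPS / Nutri-Score algorithms.
#
# Two versions are bundled: the original 2017 algorithm ("old") and the
# 2022 (general foods) / 2023 (beverages) revision ("new").  Each band
# table lists its interior thresholds in increasing order and one point
# level per band (len(points) == len(thresholds) + 1).  Lookup semantics
# live in nutriscore.bands.BandTable: values at or below the first
# threshold score 0, values at or above the last threshold score the
# component maximum, interior bands are left-open / right-closed.
#
# Sources: the official Santé publique France scoring grids.  Salt
# thresholds are the official sodium steps (90 mg old, 80 mg new)
# expressed as salt (sodium x 2.5).  The old beverage FVL component is
# graded 0/1/2/5 here (max 5); official old-beverage texts grade
# fruits/vegetables up to 10 points, but that class is never routed to
# by this package and the 0-5 grading is retained for consistency with
# the general-foods scale.

old:
  general_foods:
    negative:
      energy_kj:
        thresholds: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      sugar_g:
        thresholds: [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      sfa_g:
        thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      salt_g:
        thresholds: [0.225, 0.45, 0.675, 0.9, 1.125, 1.35, 1.575, 1.8, 2.025, 2.25]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    positive:
      protein_g:
        thresholds: [1.6, 3.2, 4.8, 6.4, 8.0]
        points: [0, 1, 2, 3, 4, 5]
      fiber_g:
        thresholds: [0.9, 1.9, 2.8, 3.7, 4.7]
        points: [0, 1, 2, 3, 4, 5]
      fvl_percent:
        thresholds: [40, 60, 80]
        points: [0, 1, 2, 5]
    protein_rule: n_lt_11_or_max_fvl
    label_scale:
      water_only_a: false
      cutoffs:          # letter: [min, max]; null = unbounded
        A: [null, -1]
        B: [0, 2]
        C: [3, 10]
        D: [11, 18]
        E: [19, null]

  beverages:
    negative:
      energy_kj:
        thresholds: [0, 30, 60, 90, 120, 150, 180, 210, 240, 270]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      sugar_g:
        thresholds: [0, 1.5, 3, 4.5, 6, 7.5, 9, 10.5, 12, 13.5]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      sfa_g:
        thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      salt_g:
        thresholds: [0.225, 0.45, 0.675, 0.9, 1.125, 1.35, 1.575, 1.8, 2.025, 2.25]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    positive:
      protein_g:
        thresholds: [1.6, 3.2, 4.8, 6.4, 8.0]
        points: [0, 1, 2, 3, 4, 5]
      fiber_g:
        thresholds: [0.9, 1.9, 2.8, 3.7, 4.7]
        points: [0, 1, 2, 3, 4, 5]
      fvl_percent:
        thresholds: [40, 60, 80]
        points: [0, 1, 2, 5]
    protein_rule: always
    label_scale:
      water_only_a: true
      cutoffs:
        B: [null, 1]
        C: [2, 5]
        D: [6, 9]
        E: [10, null]

new:
  general_foods:
    negative:
      energy_kj:
        thresholds: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      sugar_g:
        thresholds: [3.4, 6.8, 10, 14, 17, 20, 24, 27, 31, 34, 37, 41, 44, 48, 51]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
      sfa_g:
        thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      salt_g:
        thresholds: [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0,
                     2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
                 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
    positive:
      protein_g:
        thresholds: [2.4, 4.8, 7.2, 9.6, 12, 14, 17]
        points: [0, 1, 2, 3, 4, 5, 6, 7]
      fiber_g:
        thresholds: [3.0, 4.1, 5.2, 6.3, 7.4]
        points: [0, 1, 2, 3, 4, 5]
      fvl_percent:
        thresholds: [40, 60, 80]
        points: [0, 1, 2, 5]
    protein_rule: n_lt_11
    label_scale:
      water_only_a: false
      cutoffs:
        A: [null, 0]
        B: [1, 2]
        C: [3, 10]
        D: [11, 18]
        E: [19, null]

  beverages:
    negative:
      energy_kj:
        thresholds: [30, 90, 150, 210, 240, 270, 300, 330, 360, 390]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      sugar_g:
        thresholds: [0.5, 2, 3.5, 5, 6, 7, 8, 9, 10, 11]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      sfa_g:
        thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      salt_g:
        thresholds: [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0,
                     2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
        points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
                 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
    nns_points: 4
    positive:
      protein_g:
        thresholds: [1.2, 1.5, 1.8, 2.1, 2.4, 2.7, 3.0]
        points: [0, 1, 2, 3, 4, 5, 6, 7]
      fiber_g:
        thresholds: [3.0, 4.1, 5.2, 6.3, 7.4]
        points: [0, 1, 2, 3, 4, 5]
      fvl_percent:
        thresholds: [40, 60, 80]
        points: [0, 2, 4, 6]
    protein_rule: always
    label_scale:
      water_only_a: true
      cutoffs:
        B: [null, 2]
        C: [3, 6]
        D: [7, 9]
        E: [10, null]
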