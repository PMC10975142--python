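# Component anchor summary for both algorithm versions: the value at or
# below which a component scores 0 points (min), the value at or above
# which it scores its maximum (max), and that maximum.  This is the
# coarse published summary of the scoring grids (the full interior
# thresholds live in algorithms.yaml); it drives the uniform fallback
# band generator and the anchor-fidelity tests.

old:
  general_foods:
    energy_kj:   {min: 335,   max: 3350, max_points: 10, direction: negative}
    sugar_g:     {min: 4.5,   max: 45,   max_points: 10, direction: negative}
    sfa_g:       {min: 1,     max: 10,   max_points: 10, direction: negative}
    salt_g:      {min: 0.225, max: 2.25, max_points: 10, direction: negative}
    protein_g:   {min: 1.6,   max: 8.0,  max_points: 5,  direction: positive}
    fiber_g:     {min: 0.9,   max: 4.7,  max_points: 5,  direction: positive}
    fvl_percent: {min: 40,    max: 80,   max_points: 5,  direction: positive}
  beverages:
    energy_kj:   {min: 0,     max: 270,  max_points: 10, direction: negative}
    sugar_g:     {min: 0,     max: 13.5, max_points: 10, direction: negative}
    sfa_g:       {min: 1,     max: 10,   max_points: 10, direction: negative}
    salt_g:      {min: 0.225, max: 2.25, max_points: 10, direction: negative}
    protein_g:   {min: 1.6,   max: 8.0,  max_points: 5,  direction: positive}
    fiber_g:     {min: 0.9,   max: 4.7,  max_points: 5,  direction: positive}
    fvl_percent: {min: 40,    max: 80,   max_points: 5,  direction: positive}
new:
  general_foods:
    energy_kj:   {min: 335,   max: 3350, max_points: 10, direction: negative}
    sugar_g:     {min: 3.4,   max: 51,   max_points: 15, direction: negative}
    sfa_g:       {min: 1,     max: 10,   max_points: 10, direction: negative}
    salt_g:      {min: 0.2,   max: 4,    max_points: 20, direction: negative}
    protein_g:   {min: 2.4,   max: 17,   max_points: 7,  direction: positive}
    fiber_g:     {min: 3.0,   max: 7.4,  max_points: 5,  direction: positive}
    fvl_percent: {min: 40,    max: 80,   max_points: 5,  direction: positive}
  beverages:
    energy_kj:   {min: 30,    max: 390,  max_points: 10, direction: negative}
    sugar_g:     {min: 0.5,   max: 11,   max_points: 10, direction: negative}
    sfa_g:       {min: 1,     max: 10,   max_points: 10, direction: negative}
    salt_g:      {min: 0.2,   max: 4,    max_points: 20, direction: negative}
    protein_g:   {min: 1.2,   max: 3,    max_points: 7,  direction: positive}
    fiber_g:     {min: 3.0,   max: 7.4,  max_points: 5,  direction: positive}
    fvl_percent: {min: 40,    max: 80,   max_points: 6,  direction: positive}
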