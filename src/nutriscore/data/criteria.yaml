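# Dutch dietary-guideline (Wheel of Five) criteria for plant-based
# replacement products.  Metrics resolve against an imputed
# NutrientProfile; protein_epct is the derived protein energy share.
# Comparisons are inclusive at the threshold.

meat_alt:
  - {metric: protein_epct, op: ge, threshold: 20}    # E%
  - {metric: sfa_g,        op: le, threshold: 2.5}   # g / 100 g
  - {metric: salt_g,       op: le, threshold: 1.125} # g / 100 g
  - {metric: iron_mg,      op: ge, threshold: 0.8}   # mg / 100 g
  - {metric: vitb12_ug,    op: ge, threshold: 0.24}  # ug / 100 g

milk_alt:
  - {metric: protein_epct, op: ge, threshold: 20}    # E%
  - {metric: sugar_g,      op: le, threshold: 6}     # g / 100 mL (total sugar)
  - {metric: sfa_g,        op: le, threshold: 1.1}   # g / 100 mL
  - {metric: salt_g,       op: le, threshold: 0.15}  # g / 100 mL
  - {metric: calcium_mg,   op: ge, threshold: 80}    # mg / 100 mL
  - {metric: vitb12_ug,    op: ge, threshold: 0.24}  # ug / 100 mL
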