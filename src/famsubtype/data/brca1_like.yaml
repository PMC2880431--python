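# Illustrative (synthetic) single-gene specification: a rare dominant
# allele with high, ER-negative-shifted penetrance, in the published order
# of magnitude for a BRCA1-like gene. Demonstration values only -- not a
# reproduction of any published penetrance analysis.
allele_frequency: 0.0006
age_range: [20, 85]
hazards:
  noncarrier:
    # hazard bands [age_lo, age_hi, yearly hazard); uncovered years are 0
    ER-negative:
      - [20, 40, 0.00005]
      - [40, 50, 0.00020]
      - [50, 65, 0.00045]
      - [65, 86, 0.00050]
    ER-positive:
      - [20, 40, 0.00020]
      - [40, 50, 0.00080]
      - [50, 65, 0.00180]
      - [65, 86, 0.00200]
  carrier:
    ER-negative:
      - [20, 40, 0.00263]
      - [40, 50, 0.01050]
      - [50, 65, 0.00945]
      - [65, 86, 0.01050]
    ER-positive:
      - [20, 40, 0.00113]
      - [40, 50, 0.00450]
      - [50, 65, 0.00405]
      - [65, 86, 0.00450]
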