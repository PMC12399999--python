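# Measles configuration.
#
# First-dose measles-containing vaccine only; the vaccine targets all
# measles so the attributable fraction is 1.  Relative-risk magnitudes are
# ILLUSTRATIVE placeholders; supply your own for real analyses.
disease: measles

case_factors:
  - name: stunting
    levels: [none, moderate, severe]
    rr: [1.0, 1.30, 1.70]
  - name: underweight
    levels: [none, moderate, severe]
    rr: [1.0, 1.25, 1.60]
  - name: vitamin_a_deficiency
    levels: [no, yes]
    rr: [1.0, 1.50]
  - name: wasting
    levels: [none, moderate, severe]
    rr: [1.0, 1.40, 1.90]

death_factors:
  - name: stunting
    levels: [none, moderate, severe]
    rr: [1.0, 1.40, 1.90]
  - name: underweight
    levels: [none, moderate, severe]
    rr: [1.0, 1.35, 1.80]
  - name: vitamin_a_deficiency
    levels: [no, yes]
    rr: [1.0, 1.60]
  - name: wasting
    levels: [none, moderate, severe]
    rr: [1.0, 1.50, 2.10]

vaccines:
  - name: mcv
    efficacy: 0.85
    ui: [0.83, 0.87]
    attributable_fraction: 1.0

treatment:
  efficacy: 0.62
  ui: [0.52, 0.82]
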