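# Pneumonia configuration.
#
# Vaccine efficacies are scaled downstream by the attributable fractions:
# pneumococcus causes 33.0% of pneumonia cases and Haemophilus influenzae
# type b 21.6%.  Relative-risk magnitudes are ILLUSTRATIVE placeholders;
# supply your own for real analyses.
disease: pneumonia

case_factors:
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
  - name: pcv
    efficacy: 0.58
    ui: [0.29, 0.75]
    attributable_fraction: 0.330
  - name: penta3
    efficacy: 0.93
    ui: [0.83, 0.97]
    attributable_fraction: 0.216

treatment:
  efficacy: 0.70
  ui: [0.52, 0.82]
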