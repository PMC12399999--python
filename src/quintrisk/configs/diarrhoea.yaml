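# Diarrhoea configuration.
#
# Vaccine and treatment efficacies are published point estimates with 95%
# uncertainty intervals.  The relative-risk magnitudes below are
# ILLUSTRATIVE placeholders with plausible moderate values: the source
# studies behind each factor are not distributed with this package, and any
# real analysis must replace them with the user's own inputs.
disease: diarrhoea

case_factors:
  - name: stunting
    levels: [none, moderate, severe]
    rr: [1.0, 1.30, 1.70]
  - name: underweight
    levels: [none, moderate, severe]
    rr: [1.0, 1.25, 1.60]
  - name: unsafe_sanitation
    levels: [improved, unimproved]
    rr: [1.0, 1.40]
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
  - name: wasting
    levels: [none, moderate, severe]
    rr: [1.0, 1.50, 2.10]

vaccines:
  - name: rotavirus
    efficacy: 0.50
    ui: [0.11, 0.72]
    # fraction of diarrhoea cases attributable to rotavirus; illustrative
    attributable_fraction: 0.28

treatment:
  efficacy: 0.93
  ui: [0.83, 0.98]
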