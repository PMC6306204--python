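# Seed perturbation classes at the OrganismPhenotype stage.
stage: OrganismPhenotype
classes:
  - label: disease risk
    source: LOCAL
    definition: altered probability of developing the disease
  - label: disease activity
    source: LOCAL
    definition: altered severity or activity of established disease
  - label: disease process
    source: LOCAL
    definition: altered organism-level pathological process
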