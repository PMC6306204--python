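# Seed perturbation classes at the MacromolecularComplex stage.
stage: MacromolecularComplex
classes:
  - label: complex abundance
    source: LOCAL
    definition: altered concentration of an assembled complex
  - label: complex composition
    source: LOCAL
    definition: altered subunit membership of a complex
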