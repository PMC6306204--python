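# Seed perturbation classes at the Protein stage (open, extensible set).
stage: Protein
classes:
  - label: missense substitution
    source: LOCAL
    definition: amino acid substitution in a protein sequence
  - label: protein abundance
    source: LOCAL
    definition: altered amount of a protein (e.g. in serum or in a cell)
  - label: protein stability
    source: LOCAL
    definition: altered folding stability or half-life
  - label: protein degradation
    source: LOCAL
    definition: altered degradation properties (e.g. ubiquitination rate)
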