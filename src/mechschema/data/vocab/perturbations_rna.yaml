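# Seed perturbation classes at the RNA stage (open, extensible set).
stage: RNA
classes:
  - label: RNA abundance
    source: LOCAL
    definition: altered amount of a transcript
  - label: RNA stability
    source: LOCAL
    definition: altered transcript half-life
  - label: RNA splicing pattern
    source: LOCAL
    definition: altered exon usage or splice-site choice
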