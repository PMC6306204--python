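# Seed perturbation classes at the Tissue stage (open, extensible set).
stage: Tissue
classes:
  - label: tissue integrity
    source: LOCAL
    definition: altered structural integrity of a tissue layer
  - label: inflammatory response
    source: LOCAL
    definition: altered inflammatory state of a tissue
  - label: immune response
    source: LOCAL
    definition: altered tissue-level immune response
  - label: tissue response
    source: LOCAL
    definition: altered tissue-level response to a stimulus
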