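# Seed perturbation classes at the Cell stage (open, extensible set).
stage: Cell
classes:
  - label: cell signaling
    source: LOCAL
    definition: altered intracellular or cell-cell signaling state
  - label: cell activation
    source: LOCAL
    definition: altered activation state of a cell population
  - label: cell process
    source: LOCAL
    definition: altered execution of a cellular process (e.g. autophagy)
  - label: cell response
    source: LOCAL
    definition: altered cellular response to a stimulus
  - label: cell stress response
    source: LOCAL
    definition: altered stress-response program (e.g. unfolded protein response)
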