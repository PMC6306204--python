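# Built-in perturbation classes at the DNA stage.
# The DNA stage has a closed set of four classes.
stage: DNA
classes:
  - label: SNV
    curie: SO:0001483
    source: SO
    definition: single nucleotide variant
  - label: IN/DEL
    curie: SO:1000032
    source: SO
    definition: insertion or deletion of one or more bases
  - label: CNV
    curie: SO:0001019
    source: SO
    definition: copy number variation
  - label: chromosomal rearrangement
    curie: SO:1000183
    source: SO
    definition: large-scale chromosome structure variation
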