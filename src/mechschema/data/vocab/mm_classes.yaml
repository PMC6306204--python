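# Built-in mechanism-module (MM) classes, keyed by ordered stage pair.
# to_stage: null means the class applies from from_stage to any later stage
# (used for the closed RNA-origin set). All other entries are seed LOCAL
# terms; the set is open and extensible through the registry.
groups:
  - from_stage: RNA
    to_stage: null
    classes:
      - label: altered intra-RNA interactions
        source: LOCAL
      - label: altered RNA/RNA interactions
        source: LOCAL
      - label: altered RNA/protein interactions
        source: LOCAL
      - label: altered RNA/splicing factor interactions
        source: LOCAL
      - label: altered RNA editing
        source: LOCAL
  - from_stage: DNA
    to_stage: Protein
    classes:
      - label: altered protein synthesis
        source: LOCAL
        definition: variant changes the product of transcription and translation
  - from_stage: Protein
    to_stage: MacromolecularComplex
    classes:
      - label: weaker protein-protein interaction
        source: LOCAL
        definition: reduced binding affinity between two proteins
      - label: decreased ligand availability
        source: LOCAL
        definition: less ligand present to drive complex formation
  - from_stage: MacromolecularComplex
    to_stage: Cell
    classes:
      - label: decreased receptor signal transduction
        source: LOCAL
  - from_stage: Cell
    to_stage: Cell
    classes:
      - label: altered macrophage activation
        source: LOCAL
      - label: altered epithelial wound healing
        source: LOCAL
  - from_stage: Cell
    to_stage: Tissue
    classes:
      - label: decreased barrier maintenance
        source: LOCAL
  - from_stage: Tissue
    to_stage: Tissue
    classes:
      - label: altered innate immune regulation
        source: LOCAL
  - from_stage: Tissue
    to_stage: OrganismPhenotype
    classes:
      - label: increased disease susceptibility
        source: LOCAL
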