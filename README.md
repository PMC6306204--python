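# mechschema

Tools for representing human disease mechanisms as formal, validated,
serializable graphs, and for reasoning over collections of them.

Most of what is known about how a genetic variant, a drug, or an
environmental exposure produces a disease phenotype is scattered across
papers as prose. `mechschema` encodes that knowledge as a **mechanism
schema**: a directed graph alternating between

- **substate perturbations (SSPs)** — altered entity states, each placed at
  one of nine stages of biological organization (DNA, RNA, Protein,
  MacromolecularComplex, Organelle, Cell, Tissue, Organ,
  OrganismPhenotype), and
- **mechanism modules (MMs)** — the activities that convert input SSPs into
  output SSPs,

so each step is an SSP → MM → SSP triplet, rooted at a trigger (a risk
variant, a drug intervention, or an environmental change) and terminating
at an organism-phenotype SSP. What is *not* known is represented
explicitly: black MMs for unknown mechanisms (with a "?" when even the
existence of the causal link is uncertain), AND / OR / AND-OR branches for
ambiguity, and a 1–5 confidence value with evidence entries on every
element (rendered green / orange / red).

The package is aimed at curators and computational biologists who want
machine-readable mechanism knowledge: it ships the graph model, a
controlled-vocabulary layer (DNA-stage perturbation classes and RNA-origin
MM classes are closed sets; everything else is an extensible registry with
GO / SO / VariO / NCIT / MeSH CURIEs), a structural validator with stable
error codes, a canonical JSON document format with DOT/GraphML export, and
analyses over schema collections:

- **disease graphs** — schemas for one disease merged, with SSPs identified
  across loci by a (stage, entity, class, modifier) key;
- **patient subgraphs** — the part of the disease graph whose risk triggers
  a patient actually carries;
- **drug overlap** — shared SSPs between a patient graph and a drug schema,
  for prioritizing drug choice;
- **epistasis candidates** — locus pairs whose mechanisms converge on a
  shared intermediate SSP, as testable interaction hypotheses;
- **classification queries** — "which mechanisms involve decreased protein
  abundance?".

## Worked example

The bundled MSP-locus schema describes a moderately well understood Crohn
disease locus: the GWAS marker SNP rs3197999 perturbs
macrophage-stimulating protein (MSP), lowering MSP-RON complex
concentration and downstream signaling, with branches for the two
published causal accounts and for the innate-immunity vs. wound-healing
ambiguity.

```python
from mechschema import msp_schema, schema_stats, validate_schema

schema = msp_schema()
print(validate_schema(schema).valid)
stats = schema_stats(schema)
print(stats.n_ssp, stats.n_mm, stats.n_unknown_mm, stats.n_branch_sections)
```

prints

```
True
11 12 2 2
```

— the schema is structurally valid and contains 11 SSPs and 12 MMs, of
which 2 are black (the mechanism lowering serum MSP, and the link from
macrophage activation to inflammation), and 2 branch ambiguities.

The same is available from the shell, composably:

```sh
$ mechschema fixture msp | mechschema stats -
{
  "schema_id": "crohn-msp",
  "n_ssp": 11,
  "n_mm": 12,
  "n_unknown_mm": 2,
  ...
}
$ mechschema fixture crohn-mini > crohn.json
$ mechschema epistasis crohn.json        # 8 convergent locus pairs
$ mechschema export --format dot crohn.json | dot -Tpng > graph.png
```

Other subcommands: `validate [--strict]`, `merge [--aliases F]`,
`subgraph --genotype F`, `overlap --drug F`,
`query --stage S --class C [--modifier M]`, `generate --steps N --seed N`.
`-` reads a document from standard input; exit status is 0 on success, 1
when validation finds errors, 2 on usage errors.

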