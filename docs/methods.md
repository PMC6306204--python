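# Methods

## The model

A mechanism schema is a directed graph over three node kinds. *Substate
perturbations* (SSPs) are altered entity states — "decreased serum MSP
abundance" — each placed at one of nine totally ordered stages of
biological organization (DNA < RNA < Protein < MacromolecularComplex <
Organelle < Cell < Tissue < Organ < OrganismPhenotype). *Mechanism
modules* (MMs) are the activities, or groups of entities and activities,
that convert input SSPs into output SSPs. *Triggers* are the roots: a
genetic variant (rsID), a drug intervention, or an environmental change.
Edges alternate — Trigger→SSP or Trigger→MM, SSP→MM, MM→SSP — so every
mechanism step is an SSP-MM-SSP triplet and the graph is bipartite over
SSPs and MMs. An MM may take several input SSPs and produce several
output SSPs (a hyperstep); stages may be skipped along a path (an RNA
perturbation can act directly on a cell state); consecutive steps may sit
within one stage.

Ignorance and uncertainty are modelled, not elided:

- an MM with `known=False` is a **black MM**: the causal link is asserted
  but its mechanism is unknown. With `uncertain_existence=True` the link
  itself is conjectural (drawn with a "?"). Black MMs are exempt from
  class and evidence checks — they declare ignorance rather than omit
  data.
- fan-out and fan-in greater than one must carry **branch logic** (AND,
  OR, AND_OR). These are annotations of ambiguity or multiplicity, not
  boolean gates; no logical evaluation is performed on them.
- every SSP and known MM carries a **confidence** value 1–5 (or unknown)
  plus evidence entries (source id, comment, kind). Display banding maps
  {1,2}→red, {3}→orange, {4,5}→green; the formalism fixes three colors
  and a five-point scale but not the assignment, so the symmetric banding
  is a package choice and is configurable per call.

Schemas are acyclic by default. A schema-level `allow_feedback` flag
admits cycles, needed for feedback mechanisms such as the TGFβ1→SMAD7
induction loop in the bundled drug schema. Intervention sites (octagons)
and environmental marks attach to nodes by reference rather than by
edges, so they never disturb the bipartite alternation.

## Vocabularies

Perturbation classes are keyed by stage, MM classes by ordered stage pair
(within-stage MMs use an equal pair; the closed RNA-origin set applies
from RNA to any stage). The DNA-stage perturbation set (SNV, IN/DEL, CNV,
chromosomal rearrangement) and the five RNA-origin MM classes are closed;
all other stage vocabularies ship as seed LOCAL terms and are extensible
through a registry that appends in registration order and never shadows a
built-in label. Term references use CURIEs whose prefix must match their
source ontology (GO, SO, VariO, NCIT, MeSH); resolution is prefix
validation only — no ontology release is downloaded and term existence is
not checked, which keeps the package self-contained; full term lookup is
a pluggable extension point. An SSP carries at most one modifier (from
the closed set increased, decreased, no, altered, sooner, later), or
none; the formalism does not define modifier combination, so it is
disallowed.

## Validation

`validate_schema` re-checks every rule (construction-time mutators also
enforce them, but documents read from disk may violate any of them) and
reports issues with stable codes; the report is valid iff no
error-severity issue exists. Two rules are warnings by design: a missing
organism-phenotype sink (schemas for poorly studied loci legitimately end
early) and backward stage transitions (a step whose output sits at a
lower stage than its input — legal, but usually either a feedback link or
a curation slip). LOCAL class terms warn in default mode and fail under
`strict`, since the non-closed vocabularies are intentionally open.
Degree and cycle checks run over alternation-legal edges only, so a
single bad edge yields a single issue rather than a cascade. Issues are
sorted by locus then code, making reports deterministic and diffable.

## Serialization

One schema per JSON document, written canonically: nodes and edges
sorted, keys ordered, unknown confidence serialized as the string
`"unknown"`. Two writes of one schema are byte-identical, so documents
diff cleanly under curator review. A disease graph is a directory of
documents plus a JSON manifest (`disease`, `schemas` paths, `aliases`).
Telescoped sub-schemas serialize by reference (the `telescoped_ref`
field), never inline; expansion is the explicit `expand_telescoped`
operation. DOT and GraphML exports carry the notation's visual attributes
(shape, fill color, "?" labels); DOT is emitted directly as text and
GraphML through networkx. BEL encoding is a stub raising
`NotImplementedError`.

## Identity and merging

Two SSPs in different schemas denote the same perturbation iff their
four-field key matches: stage, canonicalized entity label (case-folded,
trimmed, internal whitespace collapsed), class label (case-folded), and
modifier. A curator alias table (canonical-label mapping applied to
entities before key construction) widens identity where labels diverge.
MM nodes never merge, even with identical class labels: an MM is a
locus-specific activity, and cross-locus sharing is expressed through
SSPs only. Merging is order-insensitive and flat, so the merged graph's
serialized form is independent of input order; provenance records every
contributing schema per node.

`patient_subgraph` keeps exactly the member schemas whose trigger label
appears in the genotype (a two-column TSV of trigger label and 0/1
presence) and re-merges them; it is monotone in the genotype by
construction. The model is presence/absence of the risk trigger only —
protective alleles are not distinguished.

## Epistasis candidates

Each locus contributes the set of SSP keys reachable from its trigger in
the merged graph (reachability runs over merged nodes, so convergent
paths through another locus's continuation count). Candidate pairs are
those with a non-empty intersection. Because every complete schema
reaches the disease-phenotype sink, organism-phenotype SSPs are
stop-listed by default — convergence must occur at an intermediate stage
to be informative; the stop-list is a configurable stage set and can be
disabled. Output is sorted by locus pair and reports the shared keys and
the earliest shared stage.

## Telescope expansion

`expand_telescoped` replaces a telescoped MM by its referenced
sub-schema's steps. The sub-schema's boundary SSPs (entry SSPs with no
incoming step edge, exit SSPs with no outgoing one) merge onto the MM's
former input/output SSPs — matched by identity key first, positionally
otherwise — and internal nodes are spliced in under namespaced ids, so
the node count increases by (internal sub-schema nodes − 1) and
alternation is preserved. Sub-schema triggers are dropped; a boundary
that is an MM rather than an SSP is a splice error.

## The random-schema generator

Property tests and the round-trip suite run on generated schemas, built
from a seeded `random.Random` so identical parameters and seed give a
byte-identical document. The backbone is a trigger plus `n_steps`
SSP-MM-SSP steps whose stage ranks are a sorted draw from DNA (rank 0) to
OrganismPhenotype (rank 8), so stages never decrease along a path. At
each intermediate SSP an OR split opens with probability `p_branch`
(an alternative MM rejoining at the next SSP, with join logic set); each
MM is black with probability `p_unknown`, and black MMs are
question-marked with probability `p_uncertain`. Confidence is sampled
from a distribution over {1..5, unknown} defaulting to
(0.05, 0.15, 0.30, 0.30, 0.15; 0.05) — mid-heavy, matching curated
content where most steps have moderate support. Generated schemas always
validate with zero errors.

What the generator emulates is the *structural* variety of curated
schemas — branching, ignorance, confidence spread, stage skipping. It
does not emulate biological content: entity labels are synthetic, SSP
sharing between generated schemas arises from label coincidence rather
than biology, and branch logic is always OR. Passing property tests
therefore demonstrates structural correctness (round-trip fidelity,
validator completeness, oracle agreement), not biological plausibility of
any schema.

## Curated fixtures

Three curated examples anchor the tests: the MSP-locus Crohn disease
schema (trigger rs3197999; two black MMs; an OR ambiguity between
weaker MSP-RON binding and lowered serum MSP; an AND-OR ambiguity
between innate-immunity and wound-healing paths), the Mongersen drug
schema (SMAD7 antisense knockdown relieving suppression of TGFβ1
signaling, with the induction feedback loop and an existing intervention
site), and a mini disease graph of eight Crohn loci converging in three
groups (mucosal-layer integrity: MUC1, MUC2; unfolded protein response:
XBP1, ORMDL3; autophagy: NOD2, ATG16L1, LRRK2, IRGM) before a shared
bacterial-penetration SSP and the risk sink. The published description of
the MSP figure names its elements but does not tabulate the full node
inventory, so the fixture encodes every named element and treats the
documented counts (2 black MMs, 2 branch sections) as the normative
anchors. Fixture confidences follow a documented convention:
experimentally supported steps 4, contested or single-study steps 3,
steps adjacent to black MMs 2. The Mongersen schema carries both the
disease substate it relieves ("decreased anti-inflammatory response to
TGFβ1", the SSP through which it overlaps disease-locus schemas) and the
restored state downstream of the drug effect, since identity keys include
the modifier. The shared bacterial-penetration SSP of the mini graph is
placed at the organism-phenotype stage: it is a disease-proximal,
organism-level process, and this placement keeps the default epistasis
stop-list focused on within-group convergence. Each fixture ships both as
a constructor and as a canonical JSON document; tests assert byte
equality between the two.

## Numerical and degenerate-input choices

- Confidence values are range-checked at mutation time but representable
  out of range, so the validator can report them in foreign documents.
- An empty schema is reportable (missing trigger error, missing sink
  warning), not an exception.
- Duplicate edges are rejected at construction; documents with duplicate
  ids fail parsing.
- Label comparisons throughout (classes, queries, identity keys) are
  case-insensitive exact matches after whitespace normalization; no fuzzy
  matching.
- Problem sizes in the test suite — 1,000 schemas for round-trip, 100
  instances per brute-force oracle, ~10,000 MMs for the black-MM fraction
  check (three-standard-error band) — were chosen to exercise the
  properties at desk scale; the whole suite runs in a few seconds.

## Known limitations

- No execution semantics: branch logic and confidence are annotations;
  the package does not simulate or propagate anything.
- Ontology terms are validated by prefix only; a CURIE can reference a
  nonexistent term.
- SSP identity is label-based; synonymous entity labels split nodes
  unless aliased by a curator.
- Zygosity and dose are free-text trigger detail, not structured fields.
- Drug and environment schemas reuse the genetic-variant machinery;
  pharmacological detail (dose-response, kinetics) is out of scope.
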