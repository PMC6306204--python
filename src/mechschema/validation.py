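"""Structural validation of mechanism schemas.

Every rule of the formalism is checked and reported with a stable code;
problems are collected, never thrown, so a report always covers the whole
schema. Codes (bit-exact):

========================  ========  =============================================
code                      severity  rule
========================  ========  =============================================
ALTERNATION               error     edges must be Trigger→SSP/MM, SSP→MM or MM→SSP
NO_TRIGGER                error     schema must begin with at least one trigger
NO_PHENOTYPE_SINK         warning   no organism-phenotype SSP terminates the schema
CLASS_STAGE_MISMATCH      error     built-in class used at the wrong stage
CONFIDENCE_RANGE          error     confidence outside the 1-5 scale
MISSING_BRANCH_LOGIC      error     fan-out/fan-in > 1 without AND/OR/AND-OR logic
BLACK_MM_INCONSISTENT     error     black-MM flag combination violates invariants
DANGLING_REF              error     edge/attachment/logic references a missing id
CYCLE_WITHOUT_FLAG        error     cycle present but feedback flag not set
BACKWARD_STAGE            warning   step output at a lower stage than its input
LOCAL_TERM                warning   class label not in any built-in vocabulary
                                    (error under strict mode)
========================  ========  =============================================

A missing organism-phenotype sink is only a warning: schemas for poorly
studied loci legitimately end at a black box. Black MMs represent declared
ignorance and are exempt from class and evidence checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import networkx as nx

from .model import BranchDirection, MechanismSchema, MMNode, SSPNode, UNKNOWN
from .vocab import Stage, Vocabulary, default_vocabulary

__all__ = [
    "ERROR_CODES",
    "ValidationIssue",
    "ValidationOptions",
    "ValidationReport",
    "validate_schema",
    "is_valid",
]

ERROR_CODES = (
    "ALTERNATION",
    "NO_TRIGGER",
    "NO_PHENOTYPE_SINK",
    "CLASS_STAGE_MISMATCH",
    "CONFIDENCE_RANGE",
    "MISSING_BRANCH_LOGIC",
    "BLACK_MM_INCONSISTENT",
    "DANGLING_REF",
    "CYCLE_WITHOUT_FLAG",
    "BACKWARD_STAGE",
    "LOCAL_TERM",
)


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    severity: str  # "error" | "warning"
    node_or_edge: str
    message: str

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity,
            "node_or_edge": self.node_or_edge,
            "message": self.message,
        }


@dataclass(frozen=True)
class ValidationOptions:
    """Strictness flags. ``strict`` turns LOCAL-term warnings into errors."""

    strict: bool = False


@dataclass
class ValidationReport:
    schema_id: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def codes(self) -> set[str]:
        return {i.code for i in self.issues}

    def to_dict(self) -> dict:
        return {
            "schema_id": self.schema_id,
            "valid": self.valid,
            "issues": [i.to_dict() for i in self.issues],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, ensure_ascii=False)


def validate_schema(
    schema: MechanismSchema,
    options: Optional[ValidationOptions] = None,
    vocabulary: Optional[Vocabulary] = None,
) -> ValidationReport:
    """Check *schema* against every rule of the formalism.

    Issue order is deterministic: sorted by locus (node id or edge string)
    then code, so identical inputs yield identical reports.
    """
    opts = options or ValidationOptions()
    vocab = vocabulary or default_vocabulary()
    issues: list[ValidationIssue] = []

    def add(code: str, severity: str, locus: str, message: str) -> None:
        issues.append(ValidationIssue(code, severity, locus, message))

    nodes = schema.nodes

    # Dangling references (edges, branch logic, intervention attachments).
    resolved_edges: list[tuple[str, str]] = []
    for a, b in schema.edges:
        missing = [x for x in (a, b) if x not in nodes]
        if missing:
            add(
                "DANGLING_REF",
                "error",
                f"{a}->{b}",
                f"edge references missing node id(s) {missing}",
            )
        else:
            resolved_edges.append((a, b))
    for (node_id, direction), bl in schema.branch_logic.items():
        if node_id not in nodes:
            add(
                "DANGLING_REF",
                "error",
                node_id,
                f"branch logic on missing node {node_id!r}",
            )
    for site in schema.interventions.values():
        if site.attached_to not in nodes:
            add(
                "DANGLING_REF",
                "error",
                site.id,
                f"intervention site attached to missing node {site.attached_to!r}",
            )

    # Alternation over resolvable edges. Later structural checks (degree,
    # cycles) only consider legal edges so one bad edge yields one issue.
    legal_edges: list[tuple[str, str]] = []
    for a, b in resolved_edges:
        pair = (nodes[a].kind, nodes[b].kind)
        if pair not in MechanismSchema._ALLOWED_EDGES:
            add(
                "ALTERNATION",
                "error",
                f"{a}->{b}",
                f"illegal {pair[0]}→{pair[1]} edge; steps alternate SSP and MM",
            )
        else:
            legal_edges.append((a, b))

    # Trigger presence.
    if not schema.triggers:
        add(
            "NO_TRIGGER",
            "error",
            schema.id,
            "schema must begin with a genetic variant, drug intervention, "
            "or environmental change",
        )

    # Organism-phenotype terminal.
    if not any(s.stage is Stage.ORGANISM_PHENOTYPE for s in schema.ssps):
        add(
            "NO_PHENOTYPE_SINK",
            "warning",
            schema.id,
            "no organism-phenotype SSP; the downstream mechanism is unrecorded",
        )

    # Per-SSP checks: class-stage consistency, LOCAL terms, confidence.
    local_severity = "error" if opts.strict else "warning"
    for ssp in schema.ssps:
        builtin_stages = vocab.find_builtin_perturbation_stages(ssp.perturbation_class)
        if builtin_stages and ssp.stage not in builtin_stages:
            add(
                "CLASS_STAGE_MISMATCH",
                "error",
                ssp.id,
                f"class {ssp.perturbation_class!r} is built-in at "
                f"{sorted(s.value for s in builtin_stages)}, "
                f"but node is at stage {ssp.stage}",
            )
        elif not builtin_stages and (
            ssp.perturbation_class.casefold()
            not in vocab.perturbation_labels(ssp.stage)
        ):
            add(
                "LOCAL_TERM",
                local_severity,
                ssp.id,
                f"perturbation class {ssp.perturbation_class!r} is not a "
                f"registered term at stage {ssp.stage}",
            )
        if not ssp.confidence.in_range:
            add(
                "CONFIDENCE_RANGE",
                "error",
                ssp.id,
                f"confidence {ssp.confidence.value!r} outside 1-5",
            )

    # Per-MM checks: flag consistency, LOCAL class, confidence.
    known_mm_labels = {
        c.label.casefold()
        for c in vocab._builtin_mms  # read-only use of the built-in table
    }
    for exts in vocab._ext_mms.values():
        known_mm_labels.update(c.label.casefold() for c in exts)
    for mm in schema.mms:
        flags_bad = (
            (mm.known and mm.mm_class is UNKNOWN)
            or (not mm.known and mm.mm_class is not UNKNOWN)
            or (mm.uncertain_existence and mm.known)
            or (mm.telescoped_ref is not None and not mm.known)
        )
        if flags_bad:
            add(
                "BLACK_MM_INCONSISTENT",
                "error",
                mm.id,
                "black-MM flags inconsistent (known/uncertain_existence/"
                "class/telescoped_ref)",
            )
        if not mm.confidence.in_range:
            add(
                "CONFIDENCE_RANGE",
                "error",
                mm.id,
                f"confidence {mm.confidence.value!r} outside 1-5",
            )
        # Black MMs declare ignorance: no class or evidence checks.
        if mm.known and isinstance(mm.mm_class, str):
            if mm.mm_class.casefold() not in known_mm_labels:
                add(
                    "LOCAL_TERM",
                    local_severity,
                    mm.id,
                    f"MM class {mm.mm_class!r} is not a registered term",
                )

    # Branch logic wherever fan-out/fan-in exceeds 1.
    out_deg: dict[str, int] = {}
    in_deg: dict[str, int] = {}
    for a, b in legal_edges:
        out_deg[a] = out_deg.get(a, 0) + 1
        in_deg[b] = in_deg.get(b, 0) + 1
    for node_id, deg in out_deg.items():
        if deg > 1 and (node_id, BranchDirection.SPLIT) not in schema.branch_logic:
            add(
                "MISSING_BRANCH_LOGIC",
                "error",
                node_id,
                f"fan-out {deg} without split AND/OR/AND-OR logic",
            )
    for node_id, deg in in_deg.items():
        if deg > 1 and (node_id, BranchDirection.JOIN) not in schema.branch_logic:
            add(
                "MISSING_BRANCH_LOGIC",
                "error",
                node_id,
                f"fan-in {deg} without join AND/OR/AND-OR logic",
            )

    # Acyclicity unless the feedback flag is set.
    g = nx.DiGraph(legal_edges)
    if not schema.allow_feedback and not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        add(
            "CYCLE_WITHOUT_FLAG",
            "error",
            "->".join(a for a, _ in cycle),
            "cycle present but the schema feedback flag is not set",
        )

    # Backward stage transitions (warning): step output below its input.
    for mm in schema.mms:
        if mm.id not in nodes:
            continue
        ins = [
            nodes[a]
            for a in schema.predecessors(mm.id)
            if a in nodes and nodes[a].kind == "ssp"
        ]
        outs = [
            nodes[b]
            for b in schema.successors(mm.id)
            if b in nodes and nodes[b].kind == "ssp"
        ]
        for i in ins:
            for o in outs:
                if o.stage.rank < i.stage.rank:
                    add(
                        "BACKWARD_STAGE",
                        "warning",
                        mm.id,
                        f"step goes backward from {i.stage} ({i.id}) "
                        f"to {o.stage} ({o.id})",
                    )

    issues.sort(key=lambda i: (i.node_or_edge, i.code))
    return ValidationReport(schema_id=schema.id, issues=issues)


def is_valid(schema: MechanismSchema) -> bool:
    """True iff ``validate_schema`` with default options finds no errors."""
    return validate_schema(schema).valid
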