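"""Analyses over schemas and schema collections.

The central object is the disease-mechanism graph: the union of the
per-locus schemas for one disease, in which SSP nodes that describe the
same perturbation are identified across schemas. Identity is a four-field
key — stage, canonicalized entity label, perturbation class, modifier —
optionally widened by a curator alias table mapping entity labels onto a
canonical label. MM nodes never merge: an MM is a locus-specific activity,
and sharing between loci is expressed through SSPs only.

On top of the merged graph sit the hypothesis-generation analyses:
patient subgraphs (only the schemas whose risk trigger the patient
carries), drug-schema overlap (shared SSP keys prioritize drug choice),
epistasis candidates (locus pairs whose mechanisms converge on a shared
intermediate SSP), and mechanism-based classification queries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import networkx as nx

from .errors import DanglingReferenceError, MergeError, SpliceError
from .model import (
    BranchDirection,
    BranchLogic,
    MechanismSchema,
    SSPNode,
)
from .vocab import Modifier, Stage

__all__ = [
    "SSPIdentityKey",
    "SchemaStats",
    "DiseaseGraph",
    "OverlapReport",
    "EpistasisCandidate",
    "schema_stats",
    "merge_schemas",
    "patient_subgraph",
    "read_genotype",
    "drug_overlap",
    "epistasis_candidates",
    "classify_query",
    "expand_telescoped",
]

_WS = re.compile(r"\s+")


def canonical_entity(label: str, aliases: Optional[dict[str, str]] = None) -> str:
    """Case-fold, trim and collapse whitespace; then apply the alias table."""
    canon = _WS.sub(" ", label.strip()).casefold()
    if aliases:
        # alias table keys are canonicalized the same way
        canon = aliases.get(canon, canon)
    return canon


@dataclass(frozen=True, order=True)
class SSPIdentityKey:
    """The identity of an SSP across schemas.

    Two SSP nodes denote the same perturbation iff their keys are equal
    (after entity-label canonicalization and aliasing).
    """

    stage: str
    entity: str
    perturbation_class: str
    modifier: str  # "" when absent

    @classmethod
    def of(
        cls, ssp: SSPNode, aliases: Optional[dict[str, str]] = None
    ) -> "SSPIdentityKey":
        return cls(
            stage=ssp.stage.value,
            entity=canonical_entity(ssp.entity, aliases),
            perturbation_class=ssp.perturbation_class.casefold(),
            modifier="" if ssp.modifier is None else ssp.modifier.value,
        )

    def to_tuple(self) -> tuple[str, str, str, str]:
        return (self.stage, self.entity, self.perturbation_class, self.modifier)

    def __str__(self) -> str:
        mod = self.modifier or "-"
        return f"{self.stage}|{self.entity}|{self.perturbation_class}|{mod}"


# -- statistics ----------------------------------------------------------


@dataclass
class SchemaStats:
    """Gap-and-uncertainty statistics for one schema."""

    schema_id: str
    n_ssp: int
    n_mm: int
    n_unknown_mm: int
    n_uncertain_mm: int
    n_branch_sections: int
    confidence_histogram: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "schema_id": self.schema_id,
            "n_ssp": self.n_ssp,
            "n_mm": self.n_mm,
            "n_unknown_mm": self.n_unknown_mm,
            "n_uncertain_mm": self.n_uncertain_mm,
            "n_branch_sections": self.n_branch_sections,
            "confidence_histogram": dict(self.confidence_histogram),
        }


def schema_stats(schema: MechanismSchema) -> SchemaStats:
    """Count SSPs, MMs, black/question-marked MMs, branch sections, and
    the confidence histogram over all SSP and MM nodes."""
    hist = {str(v): 0 for v in range(1, 6)}
    hist["unknown"] = 0
    for node in list(schema.ssps) + list(schema.mms):
        key = "unknown" if node.confidence.is_unknown else str(node.confidence.value)
        hist[key] = hist.get(key, 0) + 1
    unknown_mms = [m for m in schema.mms if m.is_black]
    return SchemaStats(
        schema_id=schema.id,
        n_ssp=len(schema.ssps),
        n_mm=len(schema.mms),
        n_unknown_mm=len(unknown_mms),
        n_uncertain_mm=sum(1 for m in unknown_mms if m.uncertain_existence),
        n_branch_sections=sum(
            1
            for (_, direction) in schema.branch_logic
            if direction is BranchDirection.SPLIT
        ),
        confidence_histogram=hist,
    )


# -- disease graphs ------------------------------------------------------


def _ssp_merged_id(key: SSPIdentityKey) -> str:
    return f"ssp::{key}"


@dataclass
class DiseaseGraph:
    """Union of the schemas for one disease, with key-identified SSPs.

    ``graph`` is a networkx DiGraph whose nodes carry ``kind`` ("ssp",
    "mm", "trigger") and, for SSPs, the identity ``key``. ``provenance``
    maps every merged node id to the ids of the contributing schemas.
    """

    disease: str
    schemas: list[MechanismSchema]
    graph: nx.DiGraph
    provenance: dict[str, set[str]]
    aliases: dict[str, str] = field(default_factory=dict)

    @property
    def member_schemas(self) -> list[str]:
        return [s.id for s in self.schemas]

    def ssp_keys(self) -> set[SSPIdentityKey]:
        return {
            data["key"]
            for _, data in self.graph.nodes(data=True)
            if data.get("kind") == "ssp"
        }

    def key_provenance(self, key: SSPIdentityKey) -> set[str]:
        return set(self.provenance.get(_ssp_merged_id(key), set()))

    def to_dict(self) -> dict:
        nodes = []
        for node_id, data in sorted(self.graph.nodes(data=True)):
            rec = {
                "id": node_id,
                "kind": data.get("kind"),
                "label": data.get("label", ""),
                "schemas": sorted(self.provenance.get(node_id, set())),
            }
            if data.get("kind") == "ssp":
                rec["key"] = data["key"].to_tuple()
            nodes.append(rec)
        return {
            "disease": self.disease,
            "member_schemas": sorted(self.member_schemas),
            "nodes": nodes,
            "edges": sorted([a, b] for a, b in self.graph.edges()),
        }


def schema_ssp_keys(
    schema: MechanismSchema, aliases: Optional[dict[str, str]] = None
) -> set[SSPIdentityKey]:
    """The identity-key set of one schema's SSP nodes."""
    return {SSPIdentityKey.of(s, aliases) for s in schema.ssps}


def _normalize_aliases(aliases: Optional[dict[str, str]]) -> dict[str, str]:
    if not aliases:
        return {}
    return {
        canonical_entity(k): canonical_entity(v) for k, v in aliases.items()
    }


def merge_schemas(
    schemas: Sequence[MechanismSchema],
    aliases: Optional[dict[str, str]] = None,
    disease: Optional[str] = None,
) -> DiseaseGraph:
    """Merge schemas for one disease into a disease-mechanism graph.

    SSP nodes with equal identity keys (or aliased entity labels) collapse
    into a single node with merged provenance; MM and trigger nodes are
    kept per-schema (namespaced ``schema_id::node_id``), so all edges are
    retained and alternation is preserved.

    Raises :class:`MergeError` if the schemas carry conflicting non-empty
    disease labels.
    """
    aliases = _normalize_aliases(aliases)
    labels = {s.disease for s in schemas if s.disease}
    if disease is None:
        if len(labels) > 1:
            raise MergeError(f"disease label mismatch across schemas: {sorted(labels)}")
        disease = next(iter(labels), "")
    elif labels and labels != {disease}:
        raise MergeError(
            f"disease label mismatch: expected {disease!r}, found {sorted(labels)}"
        )

    g = nx.DiGraph()
    provenance: dict[str, set[str]] = {}

    def merged_id(schema: MechanismSchema, node_id: str) -> str:
        node = schema.nodes[node_id]
        if node.kind == "ssp":
            return _ssp_merged_id(SSPIdentityKey.of(node, aliases))
        return f"{schema.id}::{node_id}"

    for schema in schemas:
        for node in schema.nodes.values():
            mid = merged_id(schema, node.id)
            if node.kind == "ssp":
                key = SSPIdentityKey.of(node, aliases)
                if mid not in g:
                    g.add_node(
                        mid,
                        kind="ssp",
                        key=key,
                        stage=node.stage,
                        label=node.entity,
                    )
            elif node.kind == "mm":
                g.add_node(mid, kind="mm", label=str(node.mm_class), black=node.is_black)
            else:
                g.add_node(
                    mid,
                    kind="trigger",
                    label=node.label,
                    trigger_kind=node.trigger_kind,
                )
            provenance.setdefault(mid, set()).add(schema.id)
        for a, b in schema.edges:
            if a in schema.nodes and b in schema.nodes:
                g.add_edge(merged_id(schema, a), merged_id(schema, b))

    return DiseaseGraph(
        disease=disease,
        schemas=list(schemas),
        graph=g,
        provenance=provenance,
        aliases=aliases,
    )


# -- patient subgraphs ---------------------------------------------------


def read_genotype(source) -> set[str]:
    """Parse a two-column genotype file: trigger label TAB present {0,1}.

    Returns the set of trigger labels marked present. Blank lines and
    ``#`` comments are ignored.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    present = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ValueError(
                f"genotype line {lineno}: expected 'label<TAB>0|1', got {line!r}"
            )
        if parts[1] == "1":
            present.add(parts[0])
    return present


def patient_subgraph(
    graph: DiseaseGraph,
    genotype: Iterable[str],
    strict: bool = False,
) -> DiseaseGraph:
    """The part of the disease graph relevant to one patient.

    A member schema is retained iff at least one of its trigger labels is
    in *genotype*; retained schemas are re-merged with the same alias
    table. Genotype labels matching no schema trigger are ignored by
    default and raise ``KeyError`` under ``strict``.
    """
    genotype = set(genotype)
    all_triggers = {t.label for s in graph.schemas for t in s.triggers}
    unknown = genotype - all_triggers
    if unknown and strict:
        raise KeyError(f"genotype labels match no schema trigger: {sorted(unknown)}")
    selected = [
        s
        for s in graph.schemas
        if any(t.label in genotype for t in s.triggers)
    ]
    return merge_schemas(selected, aliases=graph.aliases, disease=graph.disease)


# -- drug overlap --------------------------------------------------------


@dataclass
class OverlapReport:
    """Shared SSP identity keys between a patient graph and a drug schema."""

    drug_schema_id: str
    patient_graph_id: str
    shared_keys: list[SSPIdentityKey]
    provenance: dict[str, list[str]]  # str(key) -> contributing patient schemas

    @property
    def overlap_count(self) -> int:
        return len(self.shared_keys)

    def to_dict(self) -> dict:
        return {
            "drug_schema_id": self.drug_schema_id,
            "patient_graph_id": self.patient_graph_id,
            "overlap_count": self.overlap_count,
            "shared_keys": [k.to_tuple() for k in self.shared_keys],
            "provenance": {str(k): self.provenance[str(k)] for k in self.shared_keys},
        }


def drug_overlap(patient: DiseaseGraph, drug_schema: MechanismSchema) -> OverlapReport:
    """Intersect the patient graph's SSP keys with a drug schema's.

    The size and stage placement of the overlap is the basis for
    prioritizing drug choice for that patient.
    """
    drug_keys = schema_ssp_keys(drug_schema, patient.aliases)
    shared = sorted(patient.ssp_keys() & drug_keys)
    return OverlapReport(
        drug_schema_id=drug_schema.id,
        patient_graph_id=patient.disease or ",".join(patient.member_schemas),
        shared_keys=shared,
        provenance={str(k): sorted(patient.key_provenance(k)) for k in shared},
    )


# -- epistasis candidates ------------------------------------------------


@dataclass(frozen=True)
class EpistasisCandidate:
    """An unordered locus pair whose mechanisms converge on shared SSPs."""

    locus_a: str
    locus_b: str
    shared_keys: tuple[SSPIdentityKey, ...]
    earliest_shared_stage: Stage

    def to_dict(self) -> dict:
        return {
            "locus_a": self.locus_a,
            "locus_b": self.locus_b,
            "shared_keys": [k.to_tuple() for k in self.shared_keys],
            "earliest_shared_stage": self.earliest_shared_stage.value,
        }


DEFAULT_STOP_STAGES = frozenset({Stage.ORGANISM_PHENOTYPE})


def reachable_ssp_keys(
    graph: DiseaseGraph,
    schema: MechanismSchema,
    stop_stages: frozenset[Stage] = DEFAULT_STOP_STAGES,
) -> set[SSPIdentityKey]:
    """SSP keys reachable from *schema*'s triggers in the merged graph,
    excluding stop-listed stages."""
    keys: set[SSPIdentityKey] = set()
    for trigger in schema.triggers:
        start = f"{schema.id}::{trigger.id}"
        if start not in graph.graph:
            continue
        reach = nx.descendants(graph.graph, start) | {start}
        for node_id in reach:
            data = graph.graph.nodes[node_id]
            if data.get("kind") == "ssp" and data["stage"] not in stop_stages:
                keys.add(data["key"])
    return keys


def epistasis_candidates(
    graph: DiseaseGraph,
    stop_stages: Optional[frozenset[Stage]] = DEFAULT_STOP_STAGES,
) -> list[EpistasisCandidate]:
    """All unordered locus pairs whose trigger-reachable SSP key sets
    intersect.

    Every schema reaches the disease-phenotype sink, so phenotype-stage
    SSPs are stop-listed by default; convergence must occur at an
    intermediate stage to be a candidate. Pass ``stop_stages=None`` (or an
    empty set) to disable the stop-list. Output is sorted by locus pair.
    """
    if stop_stages is None:
        stop_stages = frozenset()
    per_locus: dict[str, set[SSPIdentityKey]] = {}
    for schema in graph.schemas:
        locus = schema.locus or schema.id
        per_locus.setdefault(locus, set()).update(
            reachable_ssp_keys(graph, schema, stop_stages)
        )
    loci = sorted(per_locus)
    out = []
    for i, a in enumerate(loci):
        for b in loci[i + 1 :]:
            shared = sorted(per_locus[a] & per_locus[b])
            if shared:
                earliest = min(
                    (Stage.from_name(k.stage) for k in shared), key=lambda s: s.rank
                )
                out.append(
                    EpistasisCandidate(
                        locus_a=a,
                        locus_b=b,
                        shared_keys=tuple(shared),
                        earliest_shared_stage=earliest,
                    )
                )
    return out


# -- classification queries ----------------------------------------------


def classify_query(
    schemas: Sequence[MechanismSchema],
    stage: Stage | str,
    class_label: str,
    modifier: Optional[Modifier | str] = None,
) -> list[tuple[str, list[str]]]:
    """Which schemas involve a given perturbation (or MM) class at a stage?

    Matches SSP nodes by (stage, class, optional modifier); MM nodes match
    when their class label equals *class_label* and any of their input
    SSPs sits at *stage*. Label matching is case-insensitive exact.
    Returns ``[(schema_id, [node_ids]), ...]`` for schemas with matches.
    """
    stage = Stage.from_name(stage) if isinstance(stage, str) else stage
    if isinstance(modifier, str):
        modifier = Modifier.from_label(modifier)
    needle = class_label.casefold()
    results = []
    for schema in schemas:
        hits = []
        for ssp in schema.ssps:
            if (
                ssp.stage is stage
                and ssp.perturbation_class.casefold() == needle
                and (modifier is None or ssp.modifier is modifier)
            ):
                hits.append(ssp.id)
        for mm in schema.mms:
            if not mm.known or not isinstance(mm.mm_class, str):
                continue
            if mm.mm_class.casefold() != needle:
                continue
            input_stages = {
                schema.nodes[a].stage
                for a in schema.predecessors(mm.id)
                if a in schema.nodes and schema.nodes[a].kind == "ssp"
            }
            if stage in input_stages:
                hits.append(mm.id)
        if hits:
            results.append((schema.id, sorted(hits)))
    return sorted(results)


# -- telescope expansion -------------------------------------------------


def expand_telescoped(
    schema: MechanismSchema,
    mm_id: str,
    resolver: Optional[Callable[[str], MechanismSchema]] = None,
) -> MechanismSchema:
    """Replace a telescoped MM by the steps of its referenced sub-schema.

    The sub-schema's boundary SSPs (its entry and exit SSP nodes) are
    merged onto the MM's former input and output SSPs — matched by
    identity key when possible, otherwise positionally — and its internal
    nodes are spliced in with namespaced ids. The result still alternates
    SSP/MM. Returns a new schema; the input is untouched.
    """
    from .serialization import read_schema  # local import to avoid a cycle

    mm = schema.node(mm_id)
    if mm.kind != "mm" or mm.telescoped_ref is None:
        raise DanglingReferenceError(f"node {mm_id!r} is not a telescoped MM")
    if resolver is None:
        def resolver(ref: str) -> MechanismSchema:
            with open(ref, encoding="utf-8") as fh:
                return read_schema(fh)
    try:
        sub = resolver(mm.telescoped_ref)
    except (OSError, KeyError) as exc:
        raise DanglingReferenceError(
            f"telescoped reference {mm.telescoped_ref!r} cannot be resolved: {exc}"
        ) from exc

    # Boundary of the sub-schema, ignoring its trigger(s).
    sub_step_ids = [n.id for n in sub.nodes.values() if n.kind in ("ssp", "mm")]
    step_edges = [
        (a, b)
        for a, b in sub.edges
        if a in sub.nodes
        and b in sub.nodes
        and sub.nodes[a].kind != "trigger"
        and sub.nodes[b].kind != "trigger"
    ]
    has_in = {b for _, b in step_edges}
    has_out = {a for a, _ in step_edges}
    entries = sorted(
        n for n in sub_step_ids if sub.nodes[n].kind == "ssp" and n not in has_in
    )
    exits = sorted(
        n for n in sub_step_ids if sub.nodes[n].kind == "ssp" and n not in has_out
    )
    if not entries or not exits:
        raise SpliceError(
            f"sub-schema {sub.id!r} has no SSP entry/exit boundary to splice"
        )
    bad_boundary = [
        n
        for n in sub_step_ids
        if sub.nodes[n].kind == "mm" and (n not in has_in or n not in has_out)
    ]
    if bad_boundary:
        raise SpliceError(
            f"sub-schema boundary nodes {bad_boundary} are MMs, not SSPs"
        )

    preds = [p for p in schema.predecessors(mm_id) if schema.nodes[p].kind == "ssp"]
    succs = [s for s in schema.successors(mm_id) if schema.nodes[s].kind == "ssp"]

    def match_boundary(boundary: list[str], hosts: list[str]) -> dict[str, str]:
        """Map sub boundary SSP ids onto host SSP ids (key match, then
        positional)."""
        host_by_key = {
            SSPIdentityKey.of(schema.nodes[h]): h for h in sorted(hosts)
        }
        mapping = {}
        unmatched_b, unmatched_h = [], sorted(hosts)
        for b in boundary:
            key = SSPIdentityKey.of(sub.nodes[b])
            if key in host_by_key and host_by_key[key] in unmatched_h:
                mapping[b] = host_by_key[key]
                unmatched_h.remove(host_by_key[key])
            else:
                unmatched_b.append(b)
        if len(unmatched_b) != len(unmatched_h) and unmatched_b:
            raise SpliceError(
                f"cannot match sub-schema boundary {unmatched_b} onto host "
                f"SSPs {unmatched_h}"
            )
        mapping.update(zip(unmatched_b, unmatched_h))
        return mapping

    boundary_map = match_boundary(entries, preds)
    boundary_map.update(match_boundary(exits, succs))

    import copy

    out = copy.deepcopy(schema)
    del out.nodes[mm_id]
    out.edges = [(a, b) for a, b in out.edges if mm_id not in (a, b)]
    out.branch_logic = {
        k: v for k, v in out.branch_logic.items() if k[0] != mm_id
    }

    def new_id(sub_node_id: str) -> str:
        if sub_node_id in boundary_map:
            return boundary_map[sub_node_id]
        return f"{mm_id}.{sub_node_id}"

    for n in sub_step_ids:
        if n in boundary_map:
            continue
        clone = copy.deepcopy(sub.nodes[n])
        clone.id = new_id(n)
        out.nodes[clone.id] = clone
    for a, b in step_edges:
        edge = (new_id(a), new_id(b))
        if edge not in out.edges:
            out.edges.append(edge)
    for (node_id, direction), bl in sub.branch_logic.items():
        if node_id in sub.nodes and sub.nodes[node_id].kind != "trigger":
            mapped = new_id(node_id)
            key = (mapped, direction)
            if key not in out.branch_logic:
                out.branch_logic[key] = BranchLogic(mapped, direction, bl.logic)
    return out
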