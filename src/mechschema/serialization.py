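"""On-disk schema documents and graph-format exports.

A schema document is a single canonical JSON file: nodes and edges sorted,
keys in fixed order, so two writes of the same schema are byte-identical
and documents diff cleanly under curator review. Reading is lenient about
rule violations (the validator reports those) but strict about structure:
missing keys and unresolvable edge endpoints raise parse errors carrying a
JSON path.

Exports render the notation's visual conventions: ovals for SSPs and MMs,
black fill for unknown (black) MMs with "?" appended when their existence
is uncertain, octagons for intervention sites, a cloud-tagged note shape
for environmental triggers, and confidence colors (green/orange/red) on
known elements.
"""

from __future__ import annotations

import json
from typing import Optional, TextIO, Union

import networkx as nx

from .errors import (
    DocumentParseError,
    ExportFormatError,
    FormatVersionError,
    SerializationError,
)
from .model import (
    BranchDirection,
    BranchLogic,
    BranchLogicKind,
    Confidence,
    EvidenceEntry,
    EvidenceKind,
    InterventionSite,
    MechanismSchema,
    MMNode,
    SSPNode,
    TriggerNode,
    UNKNOWN,
    confidence_color,
)
from .vocab import Modifier, Stage, TermRef, TriggerKind

__all__ = [
    "FORMAT_VERSION",
    "write_schema",
    "read_schema",
    "export_graph",
    "export_bel",
]

FORMAT_VERSION = "1.0"


# -- writing -------------------------------------------------------------


def _confidence_to_json(c: Confidence) -> Union[int, str]:
    return "unknown" if c.is_unknown else c.value


def _evidence_to_json(entries: list[EvidenceEntry]) -> list[dict]:
    return [
        {
            "source_id": e.source_id,
            "comment": e.comment,
            "evidence_kind": e.evidence_kind.value,
        }
        for e in entries
    ]


def _termref_to_json(t: Optional[TermRef]) -> Optional[dict]:
    if t is None:
        return None
    out = {"label": t.label, "source": t.source}
    if t.curie is not None:
        out["curie"] = t.curie
    if t.definition is not None:
        out["definition"] = t.definition
    return out


def schema_to_dict(schema: MechanismSchema) -> dict:
    """The document body for *schema* (plain JSON-compatible dict)."""
    ssps = []
    for n in sorted(schema.ssps, key=lambda n: n.id):
        ssps.append(
            {
                "id": n.id,
                "stage": n.stage.value,
                "entity": n.entity,
                "entity_ref": _termref_to_json(n.entity_ref),
                "perturbation_class": n.perturbation_class,
                "modifier": None if n.modifier is None else n.modifier.value,
                "description": n.description,
                "confidence": _confidence_to_json(n.confidence),
                "evidence": _evidence_to_json(n.evidence),
            }
        )
    mms = []
    for n in sorted(schema.mms, key=lambda n: n.id):
        mms.append(
            {
                "id": n.id,
                "mm_class": "unknown" if n.mm_class is UNKNOWN else n.mm_class,
                "known": n.known,
                "uncertain_existence": n.uncertain_existence,
                "activity_description": n.activity_description,
                "participating_entities": list(n.participating_entities),
                "telescoped_ref": n.telescoped_ref,
                "confidence": _confidence_to_json(n.confidence),
                "evidence": _evidence_to_json(n.evidence),
            }
        )
    triggers = [
        {
            "id": n.id,
            "kind": n.trigger_kind.value,
            "label": n.label,
            "detail": n.detail,
        }
        for n in sorted(schema.triggers, key=lambda n: n.id)
    ]
    interventions = [
        {
            "id": s.id,
            "attached_to": s.attached_to,
            "status": s.status,
            "label": s.label,
        }
        for s in sorted(schema.interventions.values(), key=lambda s: s.id)
    ]
    branch_logic = [
        {
            "node_id": bl.node_id,
            "direction": bl.direction.value,
            "logic": bl.logic.value,
        }
        for bl in sorted(
            schema.branch_logic.values(),
            key=lambda bl: (bl.node_id, bl.direction.value),
        )
    ]
    return {
        "id": schema.id,
        "disease": schema.disease,
        "locus": schema.locus,
        "allow_feedback": schema.allow_feedback,
        "metadata": dict(schema.metadata),
        "triggers": triggers,
        "ssps": ssps,
        "mms": mms,
        "interventions": interventions,
        "edges": sorted([list(e) for e in schema.edges]),
        "branch_logic": branch_logic,
    }


def write_schema(
    schema: MechanismSchema, target: Optional[Union[str, TextIO]] = None
) -> str:
    """Serialize *schema* to canonical JSON text.

    If *target* is a path or text handle the document is also written
    there. Two writes of the same schema are byte-identical.
    """
    doc = {"format_version": FORMAT_VERSION, "schema": schema_to_dict(schema)}
    try:
        text = json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    except (TypeError, ValueError) as exc:
        raise SerializationError(f"schema not serializable: {exc}") from exc
    if target is not None:
        if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
            with open(target, "w", encoding="utf-8") as fh:
                fh.write(text)
        else:
            target.write(text)
    return text


# -- reading -------------------------------------------------------------


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise DocumentParseError(f"missing required key {key!r}", f"{path}.{key}")
    return mapping[key]


def _confidence_from_json(value, path: str) -> Confidence:
    if value == "unknown" or value is None:
        return Confidence.unknown()
    if isinstance(value, bool) or not isinstance(value, int):
        raise DocumentParseError(
            f"confidence must be an integer or 'unknown', got {value!r}", path
        )
    return Confidence(value)


def _evidence_from_json(entries, path: str) -> list[EvidenceEntry]:
    out = []
    for i, rec in enumerate(entries):
        try:
            kind = EvidenceKind(rec.get("evidence_kind", "experimental"))
        except ValueError:
            raise DocumentParseError(
                f"unknown evidence_kind {rec.get('evidence_kind')!r}",
                f"{path}[{i}].evidence_kind",
            ) from None
        out.append(
            EvidenceEntry(
                source_id=rec.get("source_id", ""),
                comment=rec.get("comment", ""),
                evidence_kind=kind,
            )
        )
    return out


def _termref_from_json(rec, path: str) -> Optional[TermRef]:
    if rec is None:
        return None
    return TermRef(
        label=_require(rec, "label", path),
        source=rec.get("source", "LOCAL"),
        curie=rec.get("curie"),
        definition=rec.get("definition"),
    )


def read_schema(document: Union[str, dict, TextIO]) -> MechanismSchema:
    """Reconstruct a schema from a JSON document (text, dict, or handle).

    Structural problems raise :class:`DocumentParseError` with the JSON
    path; rule violations (bad alternation, out-of-range confidence, ...)
    are preserved for the validator to report.
    """
    if hasattr(document, "read"):
        document = document.read()
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise DocumentParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(document, dict):
        raise DocumentParseError("document must be a JSON object")

    version = _require(document, "format_version", "$")
    if version != FORMAT_VERSION:
        raise FormatVersionError(
            f"unsupported format_version {version!r}; this reader supports "
            f"{FORMAT_VERSION!r}",
            "$.format_version",
        )
    body = _require(document, "schema", "$")
    schema = MechanismSchema(
        id=_require(body, "id", "$.schema"),
        disease=body.get("disease", ""),
        locus=body.get("locus", ""),
        allow_feedback=bool(body.get("allow_feedback", False)),
        metadata=body.get("metadata", {}),
    )

    for i, rec in enumerate(body.get("triggers", [])):
        path = f"$.schema.triggers[{i}]"
        try:
            kind = TriggerKind(_require(rec, "kind", path))
        except ValueError:
            raise DocumentParseError(
                f"unknown trigger kind {rec.get('kind')!r}", f"{path}.kind"
            ) from None
        node = TriggerNode(
            id=_require(rec, "id", path),
            trigger_kind=kind,
            label=rec.get("label", ""),
            detail=rec.get("detail", ""),
        )
        schema.nodes[node.id] = node

    for i, rec in enumerate(body.get("ssps", [])):
        path = f"$.schema.ssps[{i}]"
        modifier = rec.get("modifier")
        node = SSPNode(
            id=_require(rec, "id", path),
            stage=Stage.from_name(_require(rec, "stage", path)),
            entity=_require(rec, "entity", path),
            perturbation_class=_require(rec, "perturbation_class", path),
            entity_ref=_termref_from_json(rec.get("entity_ref"), f"{path}.entity_ref"),
            modifier=None if modifier is None else Modifier.from_label(modifier),
            description=rec.get("description", ""),
            confidence=_confidence_from_json(
                rec.get("confidence", "unknown"), f"{path}.confidence"
            ),
            evidence=_evidence_from_json(rec.get("evidence", []), f"{path}.evidence"),
        )
        schema.nodes[node.id] = node

    for i, rec in enumerate(body.get("mms", [])):
        path = f"$.schema.mms[{i}]"
        raw_class = _require(rec, "mm_class", path)
        node = MMNode(
            id=_require(rec, "id", path),
            mm_class=UNKNOWN if raw_class == "unknown" else raw_class,
            known=bool(rec.get("known", True)),
            uncertain_existence=bool(rec.get("uncertain_existence", False)),
            activity_description=rec.get("activity_description", ""),
            participating_entities=list(rec.get("participating_entities", [])),
            telescoped_ref=rec.get("telescoped_ref"),
            confidence=_confidence_from_json(
                rec.get("confidence", "unknown"), f"{path}.confidence"
            ),
            evidence=_evidence_from_json(rec.get("evidence", []), f"{path}.evidence"),
        )
        schema.nodes[node.id] = node

    for i, rec in enumerate(body.get("interventions", [])):
        path = f"$.schema.interventions[{i}]"
        site = InterventionSite(
            id=_require(rec, "id", path),
            attached_to=_require(rec, "attached_to", path),
            status=rec.get("status", "possible"),
            label=rec.get("label", ""),
        )
        schema.interventions[site.id] = site

    for i, pair in enumerate(body.get("edges", [])):
        path = f"$.schema.edges[{i}]"
        if not isinstance(pair, (list, tuple)) or len(pair) != 2:
            raise DocumentParseError("edge must be a [from, to] pair", path)
        a, b = pair
        for endpoint in (a, b):
            if endpoint not in schema.nodes:
                raise DocumentParseError(
                    f"edge references nonexistent node id {endpoint!r}", path
                )
        schema.edges.append((a, b))

    for i, rec in enumerate(body.get("branch_logic", [])):
        path = f"$.schema.branch_logic[{i}]"
        try:
            direction = BranchDirection(_require(rec, "direction", path))
            logic = BranchLogicKind(_require(rec, "logic", path))
        except ValueError as exc:
            raise DocumentParseError(str(exc), path) from None
        node_id = _require(rec, "node_id", path)
        schema.branch_logic[(node_id, direction)] = BranchLogic(
            node_id, direction, logic
        )

    return schema


# -- exports -------------------------------------------------------------


def _node_visuals(schema: MechanismSchema, node) -> dict:
    """Shape/fill/label attributes implementing the notation conventions."""
    if node.kind == "ssp":
        label = node.entity
        if node.modifier is not None:
            label = f"{node.modifier.value} {label}"
        color = confidence_color(node.confidence)
        return {
            "shape": "oval",
            "fillcolor": color or "lightgray",
            "label": label,
            "category": "ssp",
        }
    if node.kind == "mm":
        if node.is_black:
            label = "?" if node.uncertain_existence else ""
            return {
                "shape": "oval",
                "fillcolor": "black",
                "fontcolor": "white",
                "label": label,
                "category": "mm",
            }
        color = confidence_color(node.confidence)
        return {
            "shape": "oval",
            "fillcolor": color or "lightgray",
            "label": str(node.mm_class),
            "category": "mm",
        }
    # trigger
    if node.trigger_kind is TriggerKind.ENVIRONMENTAL_CHANGE:
        # Rendered as a cloud; DOT has no cloud shape, tag a note instead.
        return {
            "shape": "note",
            "fillcolor": "white",
            "label": f"cloud: {node.label}",
            "category": "trigger",
        }
    return {
        "shape": "box",
        "fillcolor": "white",
        "label": node.label,
        "category": "trigger",
    }


def _build_export_graph(schema: MechanismSchema) -> nx.DiGraph:
    g = nx.DiGraph(name=schema.id)
    for node in schema.nodes.values():
        g.add_node(node.id, **_node_visuals(schema, node))
    for site in schema.interventions.values():
        g.add_node(
            site.id,
            shape="octagon",
            fillcolor="lightblue",
            label=site.label or site.id,
            category="intervention",
        )
        if site.attached_to in schema.nodes:
            g.add_edge(site.id, site.attached_to, style="dashed")
    for a, b in schema.edges:
        for endpoint in (a, b):
            if endpoint not in g:
                g.add_node(endpoint, label=endpoint)
        g.add_edge(a, b, style="solid")
    return g


def _to_dot(g: nx.DiGraph) -> str:
    def esc(s: str) -> str:
        return str(s).replace("\\", "\\\\").replace('"', '\\"')

    lines = [f'digraph "{esc(g.name or "schema")}" {{', "  rankdir=LR;"]
    for node_id, attrs in sorted(g.nodes(data=True)):
        parts = [f'label="{esc(attrs.get("label", node_id))}"', 'style="filled"']
        for key in ("shape", "fillcolor", "fontcolor"):
            if key in attrs:
                parts.append(f'{key}="{esc(attrs[key])}"')
        lines.append(f'  "{esc(node_id)}" [{", ".join(parts)}];')
    for a, b, attrs in sorted(g.edges(data=True)):
        style = attrs.get("style", "solid")
        lines.append(f'  "{esc(a)}" -> "{esc(b)}" [style="{style}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graph(schema: MechanismSchema, format: str = "dot") -> str:
    """Render *schema* as DOT or GraphML text with notation attributes."""
    if format not in ("dot", "graphml"):
        raise ExportFormatError(
            f"unsupported export format {format!r}; use 'dot' or 'graphml'"
        )
    g = _build_export_graph(schema)
    if format == "dot":
        return _to_dot(g)
    return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"


def export_bel(schema: MechanismSchema) -> str:
    """Biological Expression Language encoding (not implemented).

    Schemas are planned to be expressible in BEL (https://biological-
    expression-language.github.io/); this release only defines the JSON
    document dialect and DOT/GraphML exports.
    """
    raise NotImplementedError(
        "BEL export is not implemented; use write_schema (JSON) or "
        "export_graph ('dot'/'graphml')"
    )
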