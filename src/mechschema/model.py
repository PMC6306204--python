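"""The mechanism-schema graph model.

A mechanism schema describes how a trigger — a genetic variant, a drug
intervention, or an environmental change — produces a disease phenotype
through a chain of steps. Each step is a triplet: an input substate
perturbation (SSP), a mechanism module (MM), and an output SSP. SSPs are
altered entity states placed at one of nine stages of biological
organization; MMs are the activities that convert input SSPs into output
SSPs. The graph is therefore bipartite and directed, with edges
alternating SSP→MM and MM→SSP (triggers may feed either node kind).

Ignorance and uncertainty are first-class: an MM whose internal mechanism
is unknown is "black" (``known=False``); if even the existence of the
causal link is uncertain the black MM additionally carries a question mark
(``uncertain_existence=True``). Ambiguity between alternative or
concurrent paths is annotated with AND / OR / AND-OR branch logic, and
every node carries a 1–5 confidence with literature evidence entries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .errors import (
    AlternationError,
    BranchLogicError,
    DanglingReferenceError,
    InconsistentFlagsError,
    SchemaConstructionError,
    StageClassMismatchError,
)
from .vocab import (
    Modifier,
    Stage,
    TermRef,
    TriggerKind,
    Vocabulary,
    default_vocabulary,
)

__all__ = [
    "EvidenceEntry",
    "Confidence",
    "UNKNOWN",
    "SSPNode",
    "MMNode",
    "TriggerNode",
    "InterventionSite",
    "BranchDirection",
    "BranchLogicKind",
    "BranchLogic",
    "MechanismSchema",
    "confidence_color",
    "DEFAULT_CONFIDENCE_BANDS",
]


class EvidenceKind(enum.Enum):
    EXPERIMENTAL = "experimental"
    COMPUTATIONAL = "computational"
    CLINICAL = "clinical"
    ASSERTED = "asserted"


@dataclass(frozen=True)
class EvidenceEntry:
    """A literature or data source supporting a schema element."""

    source_id: str
    comment: str = ""
    evidence_kind: EvidenceKind = EvidenceKind.EXPERIMENTAL

    def __post_init__(self):
        if self.evidence_kind is not EvidenceKind.ASSERTED and not self.source_id:
            raise SchemaConstructionError(
                "evidence entries need a source_id unless kind is 'asserted'"
            )


class _Unknown:
    """Sentinel for an unknown confidence or MM class."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNKNOWN"


UNKNOWN = _Unknown()


@dataclass(frozen=True)
class Confidence:
    """Curator confidence, an integer 1–5, or unknown (value None).

    Construction does not range-check so that the validator can report
    out-of-range values found in documents; schema mutators do check.
    """

    value: Optional[int] = None

    @classmethod
    def unknown(cls) -> "Confidence":
        return cls(None)

    @property
    def is_unknown(self) -> bool:
        return self.value is None

    @property
    def in_range(self) -> bool:
        return self.value is None or (
            isinstance(self.value, int) and 1 <= self.value <= 5
        )


# Banding of the 1-5 scale onto the three display colors. Symmetric split:
# low {1,2}, medium {3}, high {4,5}. Configurable via the `bands` argument.
DEFAULT_CONFIDENCE_BANDS = {1: "red", 2: "red", 3: "orange", 4: "green", 5: "green"}


def confidence_color(
    confidence: Confidence, bands: Optional[dict[int, str]] = None
) -> Optional[str]:
    """Map a confidence to its display color.

    Returns "red", "orange" or "green"; None for unknown confidence
    (renderers draw gray).
    """
    if confidence.is_unknown:
        return None
    table = DEFAULT_CONFIDENCE_BANDS if bands is None else bands
    try:
        return table[confidence.value]
    except KeyError:
        raise SchemaConstructionError(
            f"confidence {confidence.value!r} outside the 1-5 scale"
        ) from None


@dataclass
class SSPNode:
    """A substate perturbation: a perturbed entity state at one stage."""

    id: str
    stage: Stage
    entity: str
    perturbation_class: str
    entity_ref: Optional[TermRef] = None
    modifier: Optional[Modifier] = None
    description: str = ""
    confidence: Confidence = field(default_factory=Confidence.unknown)
    evidence: list[EvidenceEntry] = field(default_factory=list)

    kind = "ssp"


@dataclass
class MMNode:
    """A mechanism module; black (unknown) when ``known`` is False."""

    id: str
    mm_class: Union[str, _Unknown]
    known: bool = True
    uncertain_existence: bool = False
    activity_description: str = ""
    participating_entities: list[str] = field(default_factory=list)
    telescoped_ref: Optional[str] = None
    confidence: Confidence = field(default_factory=Confidence.unknown)
    evidence: list[EvidenceEntry] = field(default_factory=list)

    kind = "mm"

    @property
    def is_black(self) -> bool:
        return not self.known


@dataclass
class TriggerNode:
    """The root perturbation a schema begins with."""

    id: str
    trigger_kind: TriggerKind
    label: str
    detail: str = ""

    kind = "trigger"


@dataclass
class InterventionSite:
    """A possible or existing drug-intervention site (or environment mark).

    Attaches to an SSP or MM by reference, not by a graph edge, so it
    never participates in the bipartite alternation.
    """

    id: str
    attached_to: str
    status: str = "possible"  # possible | existing
    label: str = ""

    kind = "intervention"


class BranchDirection(enum.Enum):
    SPLIT = "split"
    JOIN = "join"


class BranchLogicKind(enum.Enum):
    AND = "AND"
    OR = "OR"
    AND_OR = "AND_OR"


@dataclass(frozen=True)
class BranchLogic:
    """AND/OR/AND-OR annotation at a fan-out (split) or fan-in (join)."""

    node_id: str
    direction: BranchDirection
    logic: BranchLogicKind


_NODE_ID_PREFIXES = {"ssp": "ssp", "mm": "mm", "trigger": "trg", "intervention": "ivn"}


class MechanismSchema:
    """A directed bipartite graph of SSP and MM nodes rooted at triggers.

    Mutation goes through ``add_trigger`` / ``add_ssp`` / ``add_mm`` /
    ``link`` / ``set_branch_logic``, which enforce construction-time
    invariants (alternation, flag consistency, confidence range). The
    structural validator re-checks everything, so documents read from disk
    can carry violations and still be reported on.
    """

    def __init__(
        self,
        id: str,
        disease: str = "",
        locus: str = "",
        allow_feedback: bool = False,
        metadata: Optional[dict] = None,
        vocabulary: Optional[Vocabulary] = None,
    ):
        self.id = id
        self.disease = disease
        self.locus = locus
        self.allow_feedback = allow_feedback
        self.metadata: dict = dict(metadata or {})
        self.nodes: dict[str, Union[SSPNode, MMNode, TriggerNode]] = {}
        self.interventions: dict[str, InterventionSite] = {}
        self.edges: list[tuple[str, str]] = []
        self.branch_logic: dict[tuple[str, BranchDirection], BranchLogic] = {}
        self._vocabulary = vocabulary or default_vocabulary()
        self._id_counters: dict[str, int] = {}

    # -- node accessors --------------------------------------------------

    @property
    def ssps(self) -> list[SSPNode]:
        return [n for n in self.nodes.values() if n.kind == "ssp"]

    @property
    def mms(self) -> list[MMNode]:
        return [n for n in self.nodes.values() if n.kind == "mm"]

    @property
    def triggers(self) -> list[TriggerNode]:
        return [n for n in self.nodes.values() if n.kind == "trigger"]

    def node(self, node_id: str) -> Union[SSPNode, MMNode, TriggerNode]:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise DanglingReferenceError(
                f"no node {node_id!r} in schema {self.id!r}"
            ) from None

    def _fresh_id(self, kind: str, explicit: Optional[str]) -> str:
        if explicit is not None:
            if explicit in self.nodes or explicit in self.interventions:
                raise SchemaConstructionError(f"duplicate node id {explicit!r}")
            return explicit
        prefix = _NODE_ID_PREFIXES[kind]
        n = self._id_counters.get(kind, 0) + 1
        while f"{prefix}{n}" in self.nodes or f"{prefix}{n}" in self.interventions:
            n += 1
        self._id_counters[kind] = n
        return f"{prefix}{n}"

    # -- mutation --------------------------------------------------------

    def add_trigger(
        self,
        trigger_kind: TriggerKind | str,
        label: str,
        detail: str = "",
        id: Optional[str] = None,
    ) -> str:
        if isinstance(trigger_kind, str):
            trigger_kind = TriggerKind(trigger_kind)
        node_id = self._fresh_id("trigger", id)
        self.nodes[node_id] = TriggerNode(node_id, trigger_kind, label, detail)
        return node_id

    def add_ssp(
        self,
        stage: Stage | str,
        entity: str,
        perturbation_class: str,
        modifier: Optional[Modifier | str] = None,
        description: str = "",
        confidence: Confidence | int | None = None,
        evidence: Optional[Iterable[EvidenceEntry]] = None,
        entity_ref: Optional[TermRef] = None,
        id: Optional[str] = None,
    ) -> str:
        """Add an SSP node; returns the fresh node id.

        A class label that is built-in at some other stage but not at this
        one is rejected (stage-class mismatch); labels unknown to any
        built-in vocabulary are accepted as LOCAL terms.
        """
        stage = Stage.from_name(stage) if isinstance(stage, str) else stage
        if isinstance(modifier, str):
            modifier = Modifier.from_label(modifier)
        conf = _coerce_confidence(confidence)
        if not conf.in_range:
            raise SchemaConstructionError(
                f"confidence {conf.value!r} outside the 1-5 scale"
            )
        builtin_stages = self._vocabulary.find_builtin_perturbation_stages(
            perturbation_class
        )
        if builtin_stages and stage not in builtin_stages:
            raise StageClassMismatchError(
                f"class {perturbation_class!r} is built-in at "
                f"{sorted(s.value for s in builtin_stages)}, not at {stage}"
            )
        node_id = self._fresh_id("ssp", id)
        self.nodes[node_id] = SSPNode(
            id=node_id,
            stage=stage,
            entity=entity,
            perturbation_class=perturbation_class,
            entity_ref=entity_ref,
            modifier=modifier,
            description=description,
            confidence=conf,
            evidence=list(evidence or []),
        )
        return node_id

    def add_mm(
        self,
        mm_class: Union[str, _Unknown] = UNKNOWN,
        known: bool = True,
        uncertain_existence: bool = False,
        activity_description: str = "",
        participating_entities: Optional[Iterable[str]] = None,
        telescoped_ref: Optional[str] = None,
        confidence: Confidence | int | None = None,
        evidence: Optional[Iterable[EvidenceEntry]] = None,
        id: Optional[str] = None,
    ) -> str:
        """Add an MM node; black MMs are ``known=False`` with class UNKNOWN."""
        if known and mm_class is UNKNOWN:
            raise InconsistentFlagsError("a known MM needs a class; got UNKNOWN")
        if not known and mm_class is not UNKNOWN:
            raise InconsistentFlagsError(
                "a black (unknown) MM cannot carry a class"
            )
        if uncertain_existence and known:
            raise InconsistentFlagsError(
                "uncertain_existence marks a black MM; known must be False"
            )
        if telescoped_ref is not None and not known:
            raise InconsistentFlagsError("a black MM cannot be telescoped")
        conf = _coerce_confidence(confidence)
        if not conf.in_range:
            raise SchemaConstructionError(
                f"confidence {conf.value!r} outside the 1-5 scale"
            )
        node_id = self._fresh_id("mm", id)
        self.nodes[node_id] = MMNode(
            id=node_id,
            mm_class=mm_class,
            known=known,
            uncertain_existence=uncertain_existence,
            activity_description=activity_description,
            participating_entities=list(participating_entities or []),
            telescoped_ref=telescoped_ref,
            confidence=conf,
            evidence=list(evidence or []),
        )
        return node_id

    def add_intervention(
        self,
        attached_to: str,
        status: str = "possible",
        label: str = "",
        id: Optional[str] = None,
    ) -> str:
        if attached_to not in self.nodes:
            raise DanglingReferenceError(
                f"intervention site attaches to unknown node {attached_to!r}"
            )
        if status not in ("possible", "existing"):
            raise SchemaConstructionError(
                f"intervention status must be 'possible' or 'existing', got {status!r}"
            )
        site_id = self._fresh_id("intervention", id)
        self.interventions[site_id] = InterventionSite(site_id, attached_to, status, label)
        return site_id

    # Legal (source kind, target kind) pairs for edges.
    _ALLOWED_EDGES = {
        ("trigger", "ssp"),
        ("trigger", "mm"),
        ("ssp", "mm"),
        ("mm", "ssp"),
    }

    def link(self, from_id: str, to_id: str) -> tuple[str, str]:
        """Add a directed edge, enforcing SSP/MM alternation."""
        src = self.node(from_id)
        dst = self.node(to_id)
        if (src.kind, dst.kind) not in self._ALLOWED_EDGES:
            raise AlternationError(
                f"illegal edge {src.kind}→{dst.kind} ({from_id!r}→{to_id!r}); "
                "edges must alternate SSP→MM / MM→SSP (triggers feed either)"
            )
        edge = (from_id, to_id)
        if edge in self.edges:
            raise SchemaConstructionError(f"duplicate edge {edge!r}")
        self.edges.append(edge)
        return edge

    def set_branch_logic(
        self,
        node_id: str,
        direction: BranchDirection | str,
        logic: BranchLogicKind | str,
    ) -> BranchLogic:
        self.node(node_id)
        if isinstance(direction, str):
            try:
                direction = BranchDirection(direction)
            except ValueError:
                raise BranchLogicError(f"unknown branch direction {direction!r}") from None
        if isinstance(logic, str):
            try:
                logic = BranchLogicKind(logic)
            except ValueError:
                raise BranchLogicError(f"unknown branch logic {logic!r}") from None
        bl = BranchLogic(node_id, direction, logic)
        self.branch_logic[(node_id, direction)] = bl
        return bl

    # -- degree helpers (over schema edges only) -------------------------

    def out_degree(self, node_id: str) -> int:
        return sum(1 for a, _ in self.edges if a == node_id)

    def in_degree(self, node_id: str) -> int:
        return sum(1 for _, b in self.edges if b == node_id)

    def successors(self, node_id: str) -> list[str]:
        return [b for a, b in self.edges if a == node_id]

    def predecessors(self, node_id: str) -> list[str]:
        return [a for a, b in self.edges if b == node_id]


def _coerce_confidence(value: Confidence | int | None) -> Confidence:
    if isinstance(value, Confidence):
        return value
    if value is None or value is UNKNOWN:
        return Confidence.unknown()
    return Confidence(value)
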