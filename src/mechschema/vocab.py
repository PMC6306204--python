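"""Controlled vocabularies for mechanism schemas.

Perturbations and mechanism modules (MMs) are typed against small
per-stage vocabularies. Nine stages of biological organization are fixed
and totally ordered, from DNA up to the organism phenotype. The DNA-stage
perturbation classes and the RNA-origin MM classes are closed sets; every
other vocabulary is an open seed set that users extend through a registry.
Class names reference external ontologies (GO, SO, VariO, NCIT, MeSH) by
CURIE where a suitable term exists, and are otherwise LOCAL.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .errors import TermError, TermParseError, VocabularyError

__all__ = [
    "Stage",
    "TriggerKind",
    "Modifier",
    "TermRef",
    "PerturbationClass",
    "MMClass",
    "Vocabulary",
    "default_vocabulary",
    "perturbation_classes",
    "mm_classes",
    "modifiers",
    "register_perturbation_class",
    "register_mm_class",
    "resolve_prefix",
]


class Stage(enum.Enum):
    """The nine ordered stages of biological organization."""

    DNA = "DNA"
    RNA = "RNA"
    PROTEIN = "Protein"
    MACROMOLECULAR_COMPLEX = "MacromolecularComplex"
    ORGANELLE = "Organelle"
    CELL = "Cell"
    TISSUE = "Tissue"
    ORGAN = "Organ"
    ORGANISM_PHENOTYPE = "OrganismPhenotype"

    @property
    def rank(self) -> int:
        return _STAGE_RANKS[self]

    @classmethod
    def from_name(cls, name: str) -> "Stage":
        try:
            return cls(name)
        except ValueError:
            raise VocabularyError(
                f"unknown stage {name!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None

    def __lt__(self, other: "Stage") -> bool:
        return self.rank < other.rank

    def __str__(self) -> str:
        return self.value


_STAGE_RANKS = {s: i for i, s in enumerate(Stage)}


class TriggerKind(enum.Enum):
    """Root perturbation kinds a schema may begin with."""

    GENETIC_VARIANT = "genetic_variant"
    DRUG_INTERVENTION = "drug_intervention"
    ENVIRONMENTAL_CHANGE = "environmental_change"


class Modifier(enum.Enum):
    """Closed modifier vocabulary; an SSP carries at most one (or none)."""

    INCREASED = "increased"
    DECREASED = "decreased"
    NO = "no"
    ALTERED = "altered"
    SOONER = "sooner"
    LATER = "later"

    @classmethod
    def from_label(cls, label: str) -> "Modifier":
        try:
            return cls(label)
        except ValueError:
            raise VocabularyError(f"unknown modifier {label!r}") from None


# Ontology prefixes accepted in CURIEs, mapped to their source label.
_PREFIX_SOURCES = {
    "GO": "GO",
    "SO": "SO",
    "VariO": "VariO",
    "NCIT": "NCIT",
    "MESH": "MESH",
    "MeSH": "MESH",
}

VALID_SOURCES = frozenset({"GO", "SO", "VariO", "NCIT", "MESH", "LOCAL"})


def resolve_prefix(curie: str) -> str:
    """Map a CURIE to its ontology source label.

    >>> resolve_prefix("GO:0006914")
    'GO'
    """
    if not isinstance(curie, str) or ":" not in curie:
        raise TermParseError(f"malformed CURIE {curie!r}; expected prefix:localid")
    prefix, _, local = curie.partition(":")
    if not prefix or not local:
        raise TermParseError(f"malformed CURIE {curie!r}; expected prefix:localid")
    try:
        return _PREFIX_SOURCES[prefix]
    except KeyError:
        raise TermError(f"unknown ontology prefix {prefix!r} in {curie!r}") from None


@dataclass(frozen=True)
class TermRef:
    """Reference to an ontology term, or a LOCAL label without one."""

    label: str
    source: str = "LOCAL"
    curie: Optional[str] = None
    definition: Optional[str] = None

    def __post_init__(self):
        if self.source not in VALID_SOURCES:
            raise TermError(f"unknown term source {self.source!r}")
        if self.source == "LOCAL":
            if self.curie is not None:
                raise TermError("LOCAL terms carry no CURIE")
        else:
            if self.curie is None:
                raise TermError(f"{self.source} term {self.label!r} requires a CURIE")
            if resolve_prefix(self.curie) != self.source:
                raise TermError(
                    f"CURIE {self.curie!r} prefix does not match source {self.source!r}"
                )


@dataclass(frozen=True)
class PerturbationClass:
    """A perturbation class attached to one stage."""

    stage: Stage
    term: TermRef

    @property
    def label(self) -> str:
        return self.term.label


@dataclass(frozen=True)
class MMClass:
    """An MM class for an ordered stage pair.

    ``to_stage`` of None means the class applies from ``from_stage`` to any
    stage (used for the closed RNA-origin set, which the formalism defines
    by origin stage alone).
    """

    from_stage: Stage
    to_stage: Optional[Stage]
    term: TermRef

    @property
    def label(self) -> str:
        return self.term.label


def _load_yaml(name: str) -> dict:
    path = resources.files("mechschema").joinpath("data").joinpath("vocab").joinpath(name)
    return yaml.safe_load(path.read_text(encoding="utf-8"))


def _term_from_record(rec: dict) -> TermRef:
    return TermRef(
        label=rec["label"],
        source=rec.get("source", "LOCAL"),
        curie=rec.get("curie"),
        definition=rec.get("definition"),
    )


_PERTURBATION_FILES = {
    Stage.DNA: "perturbations_dna.yaml",
    Stage.RNA: "perturbations_rna.yaml",
    Stage.PROTEIN: "perturbations_protein.yaml",
    Stage.MACROMOLECULAR_COMPLEX: "perturbations_macromolecular_complex.yaml",
    Stage.ORGANELLE: "perturbations_organelle.yaml",
    Stage.CELL: "perturbations_cell.yaml",
    Stage.TISSUE: "perturbations_tissue.yaml",
    Stage.ORGAN: "perturbations_organ.yaml",
    Stage.ORGANISM_PHENOTYPE: "perturbations_organism_phenotype.yaml",
}

_MODIFIER_ORDER = tuple(Modifier)


class Vocabulary:
    """Built-in vocabularies plus a user extension registry.

    Built-ins are loaded once from the packaged data files and are
    immutable; extensions are appended in registration order and may never
    shadow a built-in label (case-insensitive) for the same stage or pair.
    """

    def __init__(self):
        self._builtin_perturbations: dict[Stage, tuple[PerturbationClass, ...]] = {}
        for stage, fname in _PERTURBATION_FILES.items():
            data = _load_yaml(fname)
            assert Stage.from_name(data["stage"]) is stage
            self._builtin_perturbations[stage] = tuple(
                PerturbationClass(stage=stage, term=_term_from_record(r))
                for r in data["classes"]
            )
        self._builtin_mms: list[MMClass] = []
        for group in _load_yaml("mm_classes.yaml")["groups"]:
            from_stage = Stage.from_name(group["from_stage"])
            to_stage = (
                None
                if group["to_stage"] is None
                else Stage.from_name(group["to_stage"])
            )
            for rec in group["classes"]:
                self._builtin_mms.append(
                    MMClass(from_stage, to_stage, _term_from_record(rec))
                )
        self._ext_perturbations: dict[Stage, list[PerturbationClass]] = {
            s: [] for s in Stage
        }
        self._ext_mms: dict[tuple[Stage, Stage], list[MMClass]] = {}

    # -- lookups ---------------------------------------------------------

    def perturbation_classes(self, stage: Stage | str) -> list[PerturbationClass]:
        """Built-in plus registered classes for *stage*, in stable order."""
        stage = self._coerce_stage(stage)
        return list(self._builtin_perturbations[stage]) + list(
            self._ext_perturbations[stage]
        )

    def mm_classes(
        self, from_stage: Stage | str, to_stage: Stage | str
    ) -> list[MMClass]:
        """Built-in plus registered MM classes for the ordered stage pair."""
        from_stage = self._coerce_stage(from_stage)
        to_stage = self._coerce_stage(to_stage)
        out = [
            c
            for c in self._builtin_mms
            if c.from_stage is from_stage
            and (c.to_stage is None or c.to_stage is to_stage)
        ]
        out.extend(self._ext_mms.get((from_stage, to_stage), []))
        return out

    def modifiers(self) -> list[Modifier]:
        """The six modifiers in their documented fixed order."""
        return list(_MODIFIER_ORDER)

    def perturbation_labels(self, stage: Stage) -> set[str]:
        return {c.label.casefold() for c in self.perturbation_classes(stage)}

    def find_builtin_perturbation_stages(self, label: str) -> set[Stage]:
        """Stages at which *label* is a built-in perturbation class."""
        needle = label.casefold()
        return {
            stage
            for stage, classes in self._builtin_perturbations.items()
            if any(c.label.casefold() == needle for c in classes)
        }

    # -- registration ----------------------------------------------------

    def register_perturbation_class(
        self, stage: Stage | str, term: TermRef
    ) -> PerturbationClass:
        stage = self._coerce_stage(stage)
        needle = term.label.casefold()
        if any(
            c.label.casefold() == needle for c in self._builtin_perturbations[stage]
        ):
            raise VocabularyError(
                f"cannot shadow built-in perturbation class {term.label!r} at {stage}"
            )
        cls = PerturbationClass(stage=stage, term=term)
        self._ext_perturbations[stage].append(cls)
        return cls

    def register_mm_class(
        self, from_stage: Stage | str, to_stage: Stage | str, term: TermRef
    ) -> MMClass:
        from_stage = self._coerce_stage(from_stage)
        to_stage = self._coerce_stage(to_stage)
        needle = term.label.casefold()
        if any(c.label.casefold() == needle for c in self.mm_classes(from_stage, to_stage)):
            raise VocabularyError(
                f"cannot shadow MM class {term.label!r} for "
                f"({from_stage}, {to_stage})"
            )
        cls = MMClass(from_stage, to_stage, term)
        self._ext_mms.setdefault((from_stage, to_stage), []).append(cls)
        return cls

    @staticmethod
    def _coerce_stage(stage: Stage | str) -> Stage:
        if isinstance(stage, Stage):
            return stage
        return Stage.from_name(stage)


_default_vocabulary: Optional[Vocabulary] = None


def default_vocabulary() -> Vocabulary:
    """The process-wide vocabulary instance (lazy singleton)."""
    global _default_vocabulary
    if _default_vocabulary is None:
        _default_vocabulary = Vocabulary()
    return _default_vocabulary


def perturbation_classes(stage: Stage | str) -> list[PerturbationClass]:
    return default_vocabulary().perturbation_classes(stage)


def mm_classes(from_stage: Stage | str, to_stage: Stage | str) -> list[MMClass]:
    return default_vocabulary().mm_classes(from_stage, to_stage)


def modifiers() -> list[Modifier]:
    return default_vocabulary().modifiers()


def register_perturbation_class(stage: Stage | str, term: TermRef) -> PerturbationClass:
    return default_vocabulary().register_perturbation_class(stage, term)


def register_mm_class(
    from_stage: Stage | str, to_stage: Stage | str, term: TermRef
) -> MMClass:
    return default_vocabulary().register_mm_class(from_stage, to_stage, term)
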