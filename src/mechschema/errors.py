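"""Exception hierarchy for the mechanism-schema toolkit."""


class MechSchemaError(Exception):
    """Base class for all package errors."""


class VocabularyError(MechSchemaError):
    """Unknown stage or illegal vocabulary registration."""


class TermError(MechSchemaError):
    """Unknown ontology prefix or unresolvable term."""


class TermParseError(TermError):
    """CURIE does not have the prefix:localid shape."""


class SchemaConstructionError(MechSchemaError):
    """Illegal node or edge addition to a schema."""


class StageClassMismatchError(SchemaConstructionError):
    """A built-in perturbation class used at the wrong stage."""


class AlternationError(SchemaConstructionError):
    """Edge violates the SSP/MM alternation rule."""


class DanglingReferenceError(SchemaConstructionError):
    """Edge or attachment refers to a node id that does not exist."""


class InconsistentFlagsError(SchemaConstructionError):
    """Black-MM flag combination violates the MM invariants."""


class BranchLogicError(SchemaConstructionError):
    """Unknown branch direction or logic label."""


class SerializationError(MechSchemaError):
    """Schema cannot be serialized."""


class DocumentParseError(MechSchemaError):
    """Schema document is structurally invalid; carries a JSON path."""

    def __init__(self, message: str, path: str = "$"):
        super().__init__(f"{message} (at {path})")
        self.path = path


class FormatVersionError(DocumentParseError):
    """Document format_version is unsupported."""


class ExportFormatError(MechSchemaError):
    """Unsupported graph export format label."""


class MergeError(MechSchemaError):
    """Schemas cannot be merged (e.g. disease label mismatch)."""


class SpliceError(MechSchemaError):
    """Telescoped sub-schema cannot be spliced into its host."""


class GeneratorParameterError(MechSchemaError):
    """Invalid random-schema generator parameters."""
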