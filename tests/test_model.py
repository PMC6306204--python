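"""Schema construction: node addition, alternation, branch logic, colors."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechschema import (
    Confidence,
    MechanismSchema,
    Stage,
    TriggerKind,
    UNKNOWN,
    confidence_color,
)
from mechschema.errors import (
    AlternationError,
    BranchLogicError,
    InconsistentFlagsError,
    SchemaConstructionError,
    StageClassMismatchError,
)
from tests.conftest import make_random_schema


@pytest.fixture
def schema():
    return MechanismSchema(id="s", disease="d")


class TestAddSSP:
    def test_dna_ssp_at_rank_zero(self, schema):
        node_id = schema.add_ssp(Stage.DNA, "MSP gene region", "SNV")
        assert schema.nodes[node_id].stage.rank == 0
        assert len(schema.nodes) == 1

    def test_confidence_out_of_range_rejected(self, schema):
        with pytest.raises(SchemaConstructionError):
            schema.add_ssp(Stage.DNA, "x", "SNV", confidence=7)

    def test_builtin_class_at_wrong_stage_rejected(self, schema):
        with pytest.raises(StageClassMismatchError):
            schema.add_ssp(Stage.PROTEIN, "MSP", "SNV")

    def test_ids_unique_and_stable(self, schema):
        a = schema.add_ssp(Stage.DNA, "a", "SNV")
        b = schema.add_ssp(Stage.DNA, "b", "CNV")
        assert a != b
        schema.add_mm("altered protein synthesis")
        assert schema.nodes[a].entity == "a" and schema.nodes[b].entity == "b"

    def test_explicit_duplicate_id_rejected(self, schema):
        schema.add_ssp(Stage.DNA, "a", "SNV", id="n1")
        with pytest.raises(SchemaConstructionError):
            schema.add_ssp(Stage.DNA, "b", "CNV", id="n1")


class TestAddMM:
    def test_black_mm(self, schema):
        mm = schema.add_mm(UNKNOWN, known=False)
        assert schema.nodes[mm].is_black
        assert schema.nodes[mm].mm_class is UNKNOWN

    def test_known_without_class_inconsistent(self, schema):
        with pytest.raises(InconsistentFlagsError):
            schema.add_mm(UNKNOWN, known=True)

    def test_uncertain_known_inconsistent(self, schema):
        with pytest.raises(InconsistentFlagsError):
            schema.add_mm("x", known=True, uncertain_existence=True)

    def test_black_with_class_inconsistent(self, schema):
        with pytest.raises(InconsistentFlagsError):
            schema.add_mm("some activity", known=False)

    def test_black_telescoped_inconsistent(self, schema):
        with pytest.raises(InconsistentFlagsError):
            schema.add_mm(UNKNOWN, known=False, telescoped_ref="sub.json")

    def test_ordinary_mm_with_class(self, schema):
        mm = schema.add_mm("weaker protein-protein interaction")
        assert not schema.nodes[mm].is_black


class TestLink:
    def test_canonical_triplet(self, schema):
        s1 = schema.add_ssp(Stage.DNA, "a", "SNV")
        mm = schema.add_mm("altered protein synthesis")
        s2 = schema.add_ssp(Stage.PROTEIN, "b", "protein abundance")
        schema.link(s1, mm)
        schema.link(mm, s2)
        assert schema.edges == [(s1, mm), (mm, s2)]

    def test_ssp_to_ssp_rejected(self, schema):
        s1 = schema.add_ssp(Stage.DNA, "a", "SNV")
        s2 = schema.add_ssp(Stage.DNA, "b", "CNV")
        with pytest.raises(AlternationError):
            schema.link(s1, s2)

    def test_mm_to_mm_rejected(self, schema):
        m1 = schema.add_mm("altered protein synthesis")
        m2 = schema.add_mm("decreased ligand availability")
        with pytest.raises(AlternationError):
            schema.link(m1, m2)

    def test_trigger_feeds_either_kind(self, schema):
        t = schema.add_trigger(TriggerKind.GENETIC_VARIANT, "rs1")
        s = schema.add_ssp(Stage.DNA, "a", "SNV")
        m = schema.add_mm("altered protein synthesis")
        schema.link(t, s)
        schema.link(t, m)

    def test_duplicate_edge_rejected(self, schema):
        s1 = schema.add_ssp(Stage.DNA, "a", "SNV")
        mm = schema.add_mm("altered protein synthesis")
        schema.link(s1, mm)
        with pytest.raises(SchemaConstructionError):
            schema.link(s1, mm)


class TestBranchLogic:
    def test_or_and_andor_recorded(self, schema):
        s = schema.add_ssp(Stage.PROTEIN, "MSP", "protein abundance")
        schema.set_branch_logic(s, "split", "OR")
        schema.set_branch_logic(s, "join", "AND_OR")
        assert len(schema.branch_logic) == 2

    def test_unknown_logic_rejected(self, schema):
        s = schema.add_ssp(Stage.PROTEIN, "MSP", "protein abundance")
        with pytest.raises(BranchLogicError):
            schema.set_branch_logic(s, "split", "XOR")


class TestConfidenceColor:
    @pytest.mark.parametrize(
        "value,color",
        [(1, "red"), (2, "red"), (3, "orange"), (4, "green"), (5, "green")],
    )
    def test_banding(self, value, color):
        assert confidence_color(Confidence(value)) == color

    def test_unknown_gives_no_color(self):
        assert confidence_color(Confidence.unknown()) is None

    def test_monotone_and_surjective(self):
        order = {"red": 0, "orange": 1, "green": 2}
        colors = [confidence_color(Confidence(v)) for v in range(1, 6)]
        assert sorted(set(colors)) == ["green", "orange", "red"]
        assert all(order[a] <= order[b] for a, b in zip(colors, colors[1:]))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10**6))
def test_alternation_holds_on_randomly_built_schemas(seed):
    """Every edge produced by add/link respects the alternation rule."""
    s = make_random_schema(seed)
    for a, b in s.edges:
        pair = (s.nodes[a].kind, s.nodes[b].kind)
        assert pair in {("trigger", "ssp"), ("trigger", "mm"), ("ssp", "mm"), ("mm", "ssp")}
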