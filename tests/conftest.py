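"""Shared fixtures: curated schemas and seeded-defect injectors."""

from __future__ import annotations

import random

import pytest

from mechschema import (
    Confidence,
    GeneratorParams,
    MechanismSchema,
    crohn_mini_graph,
    mongersen_schema,
    msp_schema,
    random_schema,
)
from mechschema.model import BranchDirection


@pytest.fixture
def msp() -> MechanismSchema:
    return msp_schema()


@pytest.fixture
def mongersen() -> MechanismSchema:
    return mongersen_schema()


@pytest.fixture
def crohn() -> list[MechanismSchema]:
    return crohn_mini_graph()


def make_random_schema(seed: int, max_steps: int = 8) -> MechanismSchema:
    """A generated schema with seed-derived parameters (deterministic)."""
    r = random.Random(seed)
    params = GeneratorParams(
        n_steps=r.randint(1, max_steps),
        p_branch=r.random(),
        p_unknown=r.random(),
        p_uncertain=r.random(),
        seed=seed,
    )
    return random_schema(params)


# ---------------------------------------------------------------------------
# Seeded defects: each function takes a freshly built, fully valid schema and
# injects exactly one violation of its rule family, returning the schema.
# Warning-level families (NO_PHENOTYPE_SINK, BACKWARD_STAGE, LOCAL_TERM) leave
# the schema error-free but must surface their code.


def _inject_alternation(s):
    s.edges.append(("ssp_dna", "ssp_prot"))
    return s


def _inject_no_trigger(s):
    del s.nodes["trg1"]
    s.edges = [(a, b) for a, b in s.edges if "trg1" not in (a, b)]
    return s


def _inject_no_phenotype_sink(s):
    del s.nodes["ssp_risk"]
    s.edges = [(a, b) for a, b in s.edges if "ssp_risk" not in (a, b)]
    s.branch_logic = {k: v for k, v in s.branch_logic.items() if k[0] != "ssp_risk"}
    return s


def _inject_class_stage_mismatch(s):
    s.nodes["ssp_prot"].perturbation_class = "SNV"  # DNA-only built-in
    return s


def _inject_confidence_range(s):
    s.nodes["ssp_dna"].confidence = Confidence(0)
    return s


def _inject_missing_branch_logic(s):
    del s.branch_logic[("ssp_prot", BranchDirection.SPLIT)]
    return s


def _inject_black_mm_inconsistent(s):
    s.nodes["mm_black1"].known = True
    return s


def _inject_dangling_ref(s):
    s.edges.append(("ssp_risk", "ghost-node"))
    return s


def _inject_cycle_without_flag(s):
    # A legal alternating cycle; branch logic at the re-entry point keeps
    # the cycle itself the only defect.
    mm = s.add_mm("altered macrophage activation", id="mm_cycle")
    s.edges.append(("ssp_risk", mm))
    s.edges.append((mm, "ssp_dna"))
    s.set_branch_logic("ssp_dna", "join", "AND")
    return s


def _inject_backward_stage(s):
    # Tissue-stage SSP feeding a step whose output is back at the Cell
    # stage, on the other branch so no cycle is formed.
    mm = s.add_mm("altered macrophage activation", id="mm_back")
    s.edges.append(("ssp_barrier", mm))
    s.edges.append((mm, "ssp_mac"))
    s.set_branch_logic("ssp_barrier", "split", "AND")
    s.set_branch_logic("ssp_mac", "join", "AND")
    return s


def _inject_local_term(s):
    s.nodes["ssp_dna"].perturbation_class = "entirely novel perturbation"
    return s


DEFECT_INJECTORS = {
    "ALTERNATION": _inject_alternation,
    "NO_TRIGGER": _inject_no_trigger,
    "NO_PHENOTYPE_SINK": _inject_no_phenotype_sink,
    "CLASS_STAGE_MISMATCH": _inject_class_stage_mismatch,
    "CONFIDENCE_RANGE": _inject_confidence_range,
    "MISSING_BRANCH_LOGIC": _inject_missing_branch_logic,
    "BLACK_MM_INCONSISTENT": _inject_black_mm_inconsistent,
    "DANGLING_REF": _inject_dangling_ref,
    "CYCLE_WITHOUT_FLAG": _inject_cycle_without_flag,
    "BACKWARD_STAGE": _inject_backward_stage,
    "LOCAL_TERM": _inject_local_term,
}
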