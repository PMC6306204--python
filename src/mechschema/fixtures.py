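"""Curated example schemas and a seeded random-schema generator.

Three curated examples cover the formalism end to end:

* ``msp_schema`` — a moderately well understood Crohn disease locus: the
  GWAS marker SNP rs3197999 perturbs macrophage-stimulating protein
  (MSP), lowering MSP-RON complex concentration and downstream signaling,
  with two black (unknown) MMs and two branch ambiguities (an OR between
  two causal accounts of the complex loss, and an AND-OR between an
  innate-immunity path and a wound-healing path).
* ``mongersen_schema`` — a drug-trigger schema: an antisense inhibitor of
  SMAD7 expression relieves SMAD7's suppression of TGFβ1 signaling,
  restoring the anti-inflammatory response; the TGFβ1→SMAD7 induction
  feedback loop requires the schema feedback flag.
* ``crohn_mini_graph`` — eight minimal single-path schemas for loci that
  converge on shared intermediate SSPs (mucosal-layer integrity for
  MUC1/MUC2, the unfolded protein response for XBP1/ORMDL3, autophagy for
  NOD2/ATG16L1/LRRK2/IRGM) and then on a common bacterial-penetration SSP
  and the disease-risk sink.

``random_schema`` generates arbitrarily large schemas that always pass
validation with zero errors, for property-based testing.

Fixture confidence convention: experimentally supported steps carry 4,
contested or single-study steps 3, steps adjacent to unknown MMs 2;
black MMs have unknown confidence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Union

from .errors import GeneratorParameterError
from .model import EvidenceEntry, EvidenceKind, MechanismSchema, UNKNOWN
from .vocab import Modifier, Stage, TriggerKind, default_vocabulary

__all__ = [
    "msp_schema",
    "mongersen_schema",
    "crohn_mini_graph",
    "GeneratorParams",
    "random_schema",
    "packaged_fixture_text",
]


def _asserted(comment: str) -> list[EvidenceEntry]:
    return [EvidenceEntry(source_id="", comment=comment, evidence_kind=EvidenceKind.ASSERTED)]


def msp_schema() -> MechanismSchema:
    """The MSP-locus Crohn disease schema (rs3197999)."""
    s = MechanismSchema(
        id="crohn-msp",
        disease="Crohn disease",
        locus="MSP",
        metadata={"curator": "mechschema fixtures", "version": "1"},
    )
    trg = s.add_trigger(
        TriggerKind.GENETIC_VARIANT,
        "rs3197999",
        detail="HET or HOM; GWAS marker SNP associated with increased Crohn disease risk",
        id="trg1",
    )
    dna = s.add_ssp(
        Stage.DNA,
        "MSP gene region",
        "SNV",
        description="missense SNP present in the MSP coding region",
        confidence=4,
        evidence=_asserted("GWAS association of rs3197999 with Crohn disease"),
        id="ssp_dna",
    )
    mm_syn = s.add_mm(
        "altered protein synthesis",
        activity_description="the variant codon is translated into the protein product",
        confidence=4,
        id="mm_syn",
    )
    prot = s.add_ssp(
        Stage.PROTEIN,
        "MSP",
        "missense substitution",
        modifier="altered",
        description="missense substitution in MSP",
        confidence=4,
        id="ssp_prot",
    )
    # First ambiguity (OR): weaker MSP-RON binding vs lower serum MSP,
    # both accounts converging on less MSP-RON complex.
    mm_ron = s.add_mm(
        "weaker protein-protein interaction",
        participating_entities=["MSP", "RON"],
        activity_description="reduced binding affinity between MSP and the RON receptor",
        confidence=3,
        evidence=_asserted("one study reports weaker MSP-RON binding"),
        id="mm_ron",
    )
    mm_black1 = s.add_mm(
        UNKNOWN,
        known=False,
        activity_description=(
            "mechanism lowering serum MSP is unknown (decreased expression, "
            "lower protein stability, or altered degradation?)"
        ),
        id="mm_black1",
    )
    serum = s.add_ssp(
        Stage.PROTEIN,
        "serum MSP",
        "protein abundance",
        modifier="decreased",
        description="lower serum abundance of MSP in carriers of the risk allele",
        confidence=3,
        evidence=_asserted("a second study reports lower serum MSP but unchanged binding"),
        id="ssp_serum",
    )
    mm_avail = s.add_mm(
        "decreased ligand availability",
        activity_description="less circulating MSP available to engage RON",
        confidence=3,
        id="mm_avail",
    )
    cplx = s.add_ssp(
        Stage.MACROMOLECULAR_COMPLEX,
        "MSP-RON complex",
        "complex abundance",
        modifier="decreased",
        description="lower concentration of the MSP-RON protein complex",
        confidence=4,
        id="ssp_cplx",
    )
    mm_sig = s.add_mm(
        "decreased receptor signal transduction",
        confidence=4,
        id="mm_sig",
    )
    sig = s.add_ssp(
        Stage.CELL,
        "RON intracellular signaling",
        "cell signaling",
        modifier="decreased",
        confidence=4,
        id="ssp_sig",
    )
    # Second ambiguity (AND/OR): innate immunity and/or wound healing.
    mm_mac = s.add_mm("altered macrophage activation", confidence=2, id="mm_mac")
    mac = s.add_ssp(
        Stage.CELL,
        "macrophage activation",
        "cell activation",
        modifier="altered",
        confidence=2,
        id="ssp_mac",
    )
    mm_black2 = s.add_mm(
        UNKNOWN,
        known=False,
        activity_description=(
            "altered macrophage activation raises the inflammatory response "
            "by an unclear mechanism"
        ),
        id="mm_black2",
    )
    infl = s.add_ssp(
        Stage.TISSUE,
        "inflammatory response",
        "inflammatory response",
        modifier="increased",
        confidence=2,
        id="ssp_infl",
    )
    mm_imm = s.add_mm("altered innate immune regulation", confidence=3, id="mm_imm")
    imm = s.add_ssp(
        Stage.TISSUE,
        "innate immune response",
        "immune response",
        modifier="decreased",
        confidence=3,
        id="ssp_imm",
    )
    mm_wound = s.add_mm("altered epithelial wound healing", confidence=2, id="mm_wound")
    wound = s.add_ssp(
        Stage.CELL,
        "epithelial wound healing",
        "cell process",
        modifier="altered",
        confidence=2,
        id="ssp_wound",
    )
    mm_barrier = s.add_mm("decreased barrier maintenance", confidence=3, id="mm_barrier")
    barrier = s.add_ssp(
        Stage.TISSUE,
        "gut barrier integrity",
        "tissue integrity",
        modifier="decreased",
        confidence=3,
        id="ssp_barrier",
    )
    mm_risk1 = s.add_mm("increased disease susceptibility", confidence=3, id="mm_risk1")
    mm_risk2 = s.add_mm("increased disease susceptibility", confidence=3, id="mm_risk2")
    risk = s.add_ssp(
        Stage.ORGANISM_PHENOTYPE,
        "Crohn disease risk",
        "disease risk",
        modifier="increased",
        confidence=4,
        id="ssp_risk",
    )

    s.link(trg, dna)
    s.link(dna, mm_syn)
    s.link(mm_syn, prot)
    s.link(prot, mm_ron)
    s.link(prot, mm_black1)
    s.link(mm_black1, serum)
    s.link(serum, mm_avail)
    s.link(mm_ron, cplx)
    s.link(mm_avail, cplx)
    s.link(cplx, mm_sig)
    s.link(mm_sig, sig)
    s.link(sig, mm_mac)
    s.link(sig, mm_wound)
    s.link(mm_mac, mac)
    s.link(mac, mm_black2)
    s.link(mm_black2, infl)
    s.link(infl, mm_imm)
    s.link(mm_imm, imm)
    s.link(imm, mm_risk1)
    s.link(mm_risk1, risk)
    s.link(mm_wound, wound)
    s.link(wound, mm_barrier)
    s.link(mm_barrier, barrier)
    s.link(barrier, mm_risk2)
    s.link(mm_risk2, risk)

    s.set_branch_logic(prot, "split", "OR")
    s.set_branch_logic(cplx, "join", "OR")
    s.set_branch_logic(sig, "split", "AND_OR")
    s.set_branch_logic(risk, "join", "AND_OR")

    s.add_intervention(
        cplx,
        status="possible",
        label="compound bridging the MSP-RON structural interface",
        id="ivn1",
    )
    return s


def mongersen_schema() -> MechanismSchema:
    """Drug-trigger schema for the SMAD7 antisense inhibitor Mongersen."""
    s = MechanismSchema(
        id="drug-mongersen",
        disease="Crohn disease",
        locus="SMAD7",
        allow_feedback=True,
        metadata={"curator": "mechschema fixtures", "version": "1"},
    )
    trg = s.add_trigger(
        TriggerKind.DRUG_INTERVENTION,
        "Mongersen",
        detail="antisense oligonucleotide inhibitor of SMAD7 expression",
        id="trg1",
    )
    smad7 = s.add_ssp(
        Stage.PROTEIN,
        "SMAD7",
        "protein abundance",
        modifier="decreased",
        description="antisense knockdown lowers SMAD7 protein",
        confidence=4,
        id="ssp_smad7",
    )
    # Disease substate the drug relieves: in the untreated state SMAD7
    # suppresses TGFβ1 signaling, blunting its anti-inflammatory effect.
    anti_dec = s.add_ssp(
        Stage.CELL,
        "anti-inflammatory response to TGFβ1",
        "cell response",
        modifier="decreased",
        description=(
            "pre-existing disease perturbation: SMAD7 reduces the "
            "anti-inflammatory response to TGFβ1"
        ),
        confidence=4,
        id="ssp_anti_dec",
    )
    mm_relief = s.add_mm(
        "decreased suppression of TGFβ1 signaling",
        activity_description=(
            "with less SMAD7, TGFβ1 receptor signaling is no longer blocked"
        ),
        confidence=4,
        id="mm_relief",
    )
    anti_inc = s.add_ssp(
        Stage.TISSUE,
        "anti-inflammatory response",
        "tissue response",
        modifier="increased",
        confidence=3,
        id="ssp_anti_inc",
    )
    mm_calm = s.add_mm(
        "suppression of mucosal inflammation",
        confidence=3,
        id="mm_calm",
    )
    activity = s.add_ssp(
        Stage.ORGANISM_PHENOTYPE,
        "Crohn disease activity",
        "disease activity",
        modifier="decreased",
        confidence=4,
        id="ssp_activity",
    )
    # Negative feedback: TGFβ1 signaling induces SMAD7 expression.
    mm_fb = s.add_mm(
        "TGFβ1 induction of SMAD7 expression",
        activity_description="negative feedback loop closing on SMAD7",
        confidence=3,
        id="mm_fb",
    )

    s.link(trg, smad7)
    s.link(smad7, mm_relief)
    s.link(anti_dec, mm_relief)
    s.link(mm_relief, anti_inc)
    s.link(anti_inc, mm_calm)
    s.link(mm_calm, activity)
    s.link(anti_inc, mm_fb)
    s.link(mm_fb, smad7)

    s.set_branch_logic(mm_relief, "join", "AND")
    s.set_branch_logic(anti_inc, "split", "AND")
    s.set_branch_logic(smad7, "join", "AND")

    s.add_intervention(
        smad7,
        status="existing",
        label="Mongersen antisense oligonucleotide",
        id="ivn1",
    )
    return s


_CROHN_GROUPS = [
    # (group SSP stage, entity, class, modifier, loci)
    (
        Stage.TISSUE,
        "mucosal layer integrity",
        "tissue integrity",
        "decreased",
        ["MUC1", "MUC2"],
    ),
    (
        Stage.CELL,
        "unfolded protein response",
        "cell stress response",
        "altered",
        ["XBP1", "ORMDL3"],
    ),
    (
        Stage.CELL,
        "autophagy",
        "cell process",
        "decreased",
        ["NOD2", "ATG16L1", "LRRK2", "IRGM"],
    ),
]


def crohn_mini_graph() -> list[MechanismSchema]:
    """Eight minimal Crohn-locus schemas converging on shared SSPs."""
    schemas = []
    for stage, entity, pclass, modifier, loci in _CROHN_GROUPS:
        for locus in loci:
            s = MechanismSchema(
                id=f"crohn-{locus.lower()}",
                disease="Crohn disease",
                locus=locus,
                metadata={"curator": "mechschema fixtures", "version": "1"},
            )
            trg = s.add_trigger(
                TriggerKind.GENETIC_VARIANT,
                f"{locus} risk variant",
                id="trg1",
            )
            dna = s.add_ssp(
                Stage.DNA,
                f"{locus} locus",
                "SNV",
                confidence=4,
                id="ssp_dna",
            )
            mm1 = s.add_mm(
                f"altered {locus} gene product function",
                confidence=3,
                id="mm_func",
            )
            group = s.add_ssp(
                stage,
                entity,
                pclass,
                modifier=modifier,
                confidence=3,
                id="ssp_group",
            )
            mm2 = s.add_mm(
                "weakened defense against bacterial entry",
                confidence=3,
                id="mm_defense",
            )
            pen = s.add_ssp(
                Stage.ORGANISM_PHENOTYPE,
                "bacterial penetration of the mucosal layer",
                "disease process",
                modifier="increased",
                confidence=3,
                id="ssp_pen",
            )
            mm3 = s.add_mm(
                "increased disease susceptibility",
                confidence=3,
                id="mm_risk",
            )
            risk = s.add_ssp(
                Stage.ORGANISM_PHENOTYPE,
                "Crohn disease risk",
                "disease risk",
                modifier="increased",
                confidence=4,
                id="ssp_risk",
            )
            s.link(trg, dna)
            s.link(dna, mm1)
            s.link(mm1, group)
            s.link(group, mm2)
            s.link(mm2, pen)
            s.link(pen, mm3)
            s.link(mm3, risk)
            schemas.append(s)
    return schemas


# -- random generator ----------------------------------------------------

_DEFAULT_CONFIDENCE_WEIGHTS = {
    1: 0.05,
    2: 0.15,
    3: 0.30,
    4: 0.30,
    5: 0.15,
    "unknown": 0.05,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the random-schema generator.

    n_steps
        number of backbone SSP-MM-SSP steps (≥ 1).
    p_branch
        probability of opening an OR split at each intermediate SSP
        (an alternative MM path rejoining at the next SSP).
    p_unknown
        probability that any MM is black (unknown mechanism).
    p_uncertain
        probability that a black MM is additionally question-marked.
    confidence_weights
        sampling distribution over {1..5, "unknown"} for node confidence.
    seed
        RNG seed; identical parameters and seed give a byte-identical
        serialized schema.
    """

    n_steps: int
    p_branch: float = 0.0
    p_unknown: float = 0.0
    p_uncertain: float = 0.0
    confidence_weights: dict = field(
        default_factory=lambda: dict(_DEFAULT_CONFIDENCE_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.n_steps, int) or self.n_steps < 1:
            raise GeneratorParameterError(f"n_steps must be an integer ≥ 1, got {self.n_steps!r}")
        for name in ("p_branch", "p_unknown", "p_uncertain"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise GeneratorParameterError(f"{name} must be in [0, 1], got {p!r}")
        expected = {1, 2, 3, 4, 5, "unknown"}
        if set(self.confidence_weights) != expected:
            raise GeneratorParameterError(
                f"confidence_weights keys must be {expected}"
            )
        weights = list(self.confidence_weights.values())
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise GeneratorParameterError("confidence_weights must be ≥ 0 and sum to 1")


_CONFIDENCE_KEYS = (1, 2, 3, 4, 5, "unknown")


def random_schema(params: GeneratorParams) -> MechanismSchema:
    """Generate a schema that passes validation with zero errors.

    The backbone is a trigger followed by ``n_steps`` SSP-MM-SSP steps
    whose stages climb monotonically from DNA to the organism phenotype.
    Intermediate SSPs may open OR splits (alternative black-or-known MM
    paths rejoining at the next SSP). Deterministic for a fixed seed.
    """
    rng = random.Random(params.seed)
    vocab = default_vocabulary()
    n = params.n_steps

    # Non-decreasing stage ranks from DNA (0) to OrganismPhenotype (8).
    stages_list = list(Stage)
    if n == 1:
        ranks = [0, 8]
    else:
        mids = sorted(rng.randint(0, 8) for _ in range(n - 1))
        ranks = [0] + mids + [8]

    s = MechanismSchema(
        id=f"random-{params.seed}",
        disease="synthetic disease",
        locus=f"LOC{params.seed}",
        metadata={"generator": "random_schema"},
    )

    def sample_confidence() -> Union[int, None]:
        weights = [params.confidence_weights[k] for k in _CONFIDENCE_KEYS]
        key = rng.choices(_CONFIDENCE_KEYS, weights=weights, k=1)[0]
        return None if key == "unknown" else key

    def sample_modifier() -> Union[str, None]:
        if rng.random() < 0.3:
            return None
        return rng.choice([m.value for m in Modifier])

    def make_ssp(i: int, rank: int) -> str:
        stage = stages_list[rank]
        builtins = vocab.perturbation_classes(stage)
        if builtins:
            pclass = rng.choice([c.label for c in builtins])
        else:
            pclass = f"synthetic {stage.value.lower()} substate"
        return s.add_ssp(
            stage,
            f"entity-{i}",
            pclass,
            modifier=sample_modifier(),
            confidence=sample_confidence(),
            id=f"ssp{i}",
        )

    def make_mm(tag: str, from_rank: int, to_rank: int) -> str:
        if rng.random() < params.p_unknown:
            uncertain = rng.random() < params.p_uncertain
            return s.add_mm(
                UNKNOWN, known=False, uncertain_existence=uncertain, id=f"mm{tag}"
            )
        candidates = vocab.mm_classes(stages_list[from_rank], stages_list[to_rank])
        if candidates:
            label = rng.choice([c.label for c in candidates])
        else:
            label = f"synthetic activity {tag}"
        return s.add_mm(label, confidence=sample_confidence(), id=f"mm{tag}")

    trg = s.add_trigger(
        TriggerKind.GENETIC_VARIANT, f"rs{rng.randrange(10**6, 10**7)}", id="trg1"
    )
    ssp_ids = [make_ssp(0, ranks[0])]
    s.link(trg, ssp_ids[0])
    for i in range(1, n + 1):
        mm = make_mm(str(i), ranks[i - 1], ranks[i])
        ssp = make_ssp(i, ranks[i])
        s.link(ssp_ids[-1], mm)
        s.link(mm, ssp)
        ssp_ids.append(ssp)

    # OR splits at intermediate SSPs: alternative path to the next SSP.
    for i in range(1, n):
        if rng.random() < params.p_branch:
            alt = make_mm(f"alt{i}", ranks[i], ranks[i + 1])
            s.link(ssp_ids[i], alt)
            s.link(alt, ssp_ids[i + 1])
            s.set_branch_logic(ssp_ids[i], "split", "OR")
            s.set_branch_logic(ssp_ids[i + 1], "join", "OR")
    return s


def packaged_fixture_text(name: str) -> str:
    """The canonical JSON document text shipped for a curated fixture.

    *name* is one of "msp", "mongersen", "crohn_mini".
    """
    path = (
        resources.files("mechschema")
        .joinpath("data")
        .joinpath("fixtures")
        .joinpath(f"{name}.json")
    )
    return path.read_text(encoding="utf-8")
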