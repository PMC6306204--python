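"""Disease-graph analyses, each checked against a brute-force oracle."""

import re
from collections import deque

import pytest

from mechschema import (
    MechanismSchema,
    Stage,
    TriggerKind,
    classify_query,
    crohn_mini_graph,
    drug_overlap,
    epistasis_candidates,
    expand_telescoped,
    is_valid,
    merge_schemas,
    mongersen_schema,
    msp_schema,
    patient_subgraph,
    schema_stats,
    validate_schema,
)
from mechschema.errors import DanglingReferenceError, MergeError, SpliceError
from mechschema.graph_ops import read_genotype
from tests.conftest import make_random_schema


# -- independent oracle helpers (deliberately re-implemented) -------------


def oracle_key(ssp):
    entity = re.sub(r"\s+", " ", ssp.entity.strip()).casefold()
    modifier = "" if ssp.modifier is None else ssp.modifier.value
    return (ssp.stage.value, entity, ssp.perturbation_class.casefold(), modifier)


def oracle_key_set(schema):
    return {oracle_key(s) for s in schema.ssps}


def oracle_reachable_keys(schemas, exclude_phenotype=True):
    """Per-locus reachable SSP keys via explicit BFS on the merged graph."""
    node_map = {}  # (schema_id, node_id) -> merged id
    adjacency = {}
    for s in schemas:
        for n in s.nodes.values():
            mid = ("ssp", oracle_key(n)) if n.kind == "ssp" else (s.id, n.id)
            node_map[(s.id, n.id)] = mid
            adjacency.setdefault(mid, set())
        for a, b in s.edges:
            adjacency[node_map[(s.id, a)]].add(node_map[(s.id, b)])
    per_locus = {}
    key_stage = {}
    for s in schemas:
        for n in s.ssps:
            key_stage[oracle_key(n)] = n.stage
    for s in schemas:
        seen = set()
        queue = deque(node_map[(s.id, t.id)] for t in s.triggers)
        while queue:
            cur = queue.popleft()
            if cur in seen:
                continue
            seen.add(cur)
            queue.extend(adjacency.get(cur, ()))
        keys = {mid[1] for mid in seen if mid[0] == "ssp"}
        if exclude_phenotype:
            keys = {k for k in keys if key_stage[k] is not Stage.ORGANISM_PHENOTYPE}
        per_locus.setdefault(s.locus or s.id, set()).update(keys)
    return per_locus


def _linear_schema(schema_id, locus, entities, disease="d"):
    """Chain of DNA-stage SSPs (distinct entities) ending at a phenotype."""
    s = MechanismSchema(id=schema_id, disease=disease, locus=locus)
    t = s.add_trigger(TriggerKind.GENETIC_VARIANT, f"{locus} variant")
    prev = s.add_ssp(Stage.DNA, entities[0], "SNV")
    s.link(t, prev)
    for entity in entities[1:]:
        mm = s.add_mm("altered protein synthesis")
        nxt = s.add_ssp(Stage.PROTEIN, entity, "protein abundance")
        s.link(prev, mm)
        s.link(mm, nxt)
        prev = nxt
    return s


# -- schema statistics ----------------------------------------------------


class TestSchemaStats:
    def test_msp_gap_counts(self, msp):
        st = schema_stats(msp)
        assert st.n_unknown_mm == 2
        assert st.n_branch_sections == 2
        assert st.n_uncertain_mm == 0
        assert st.n_uncertain_mm <= st.n_unknown_mm <= st.n_mm

    def test_single_triplet_counts(self):
        s = _linear_schema("s1", "L", ["a", "b"])
        st = schema_stats(s)
        assert st.n_mm == 1 and st.n_unknown_mm == 0 and st.n_ssp == 2

    def test_confidence_histogram_totals(self, msp):
        st = schema_stats(msp)
        assert sum(st.confidence_histogram.values()) == st.n_ssp + st.n_mm
        assert st.confidence_histogram["unknown"] == 2  # the two black MMs


# -- merging --------------------------------------------------------------


class TestMerge:
    def test_disjoint_union_counts(self):
        a = _linear_schema("a", "A", ["a0", "a1", "a2", "a3", "a4"])
        b = _linear_schema("b", "B", ["b0", "b1", "b2", "b3"])
        merged = merge_schemas([a, b])
        n_ssp = sum(
            1 for _, d in merged.graph.nodes(data=True) if d.get("kind") == "ssp"
        )
        assert n_ssp == 9

    def test_shared_innate_immune_ssp_has_both_provenances(self, msp):
        nod2 = MechanismSchema(id="crohn-nod2", disease="Crohn disease", locus="NOD2")
        t = nod2.add_trigger(TriggerKind.GENETIC_VARIANT, "NOD2 risk variant")
        dna = nod2.add_ssp(Stage.DNA, "NOD2 locus", "SNV")
        mm = nod2.add_mm("altered innate immune regulation")
        imm = nod2.add_ssp(
            Stage.TISSUE, "innate immune response", "immune response",
            modifier="decreased",
        )
        nod2.link(t, dna)
        nod2.link(dna, mm)
        nod2.link(mm, imm)

        merged = merge_schemas([msp, nod2])
        key = next(k for k in merged.ssp_keys() if k.entity == "innate immune response")
        assert merged.key_provenance(key) == {"crohn-msp", "crohn-nod2"}

    def test_disease_label_mismatch_rejected(self, msp, mongersen):
        mongersen.disease = "ulcerative colitis"
        with pytest.raises(MergeError):
            merge_schemas([msp, mongersen])

    def test_alias_table_identifies_entities(self):
        a = _linear_schema("a", "A", ["ssp x"])
        b = _linear_schema("b", "B", ["SSP  Y"])
        merged = merge_schemas([a, b], aliases={"ssp y": "ssp x"})
        n_ssp = sum(
            1 for _, d in merged.graph.nodes(data=True) if d.get("kind") == "ssp"
        )
        assert n_ssp == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_merged_ssp_count_matches_key_union_oracle(self, seed):
        a, b = make_random_schema(2 * seed), make_random_schema(2 * seed + 1)
        b.disease = a.disease
        merged = merge_schemas([a, b])
        n_ssp = sum(
            1 for _, d in merged.graph.nodes(data=True) if d.get("kind") == "ssp"
        )
        assert n_ssp == len(oracle_key_set(a) | oracle_key_set(b))

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_is_order_insensitive(self, seed):
        trio = [make_random_schema(3 * seed + i) for i in range(3)]
        for s in trio:
            s.disease = "synthetic disease"
        forward = merge_schemas(trio).to_dict()
        reverse = merge_schemas(trio[::-1]).to_dict()
        rotated = merge_schemas(trio[1:] + trio[:1]).to_dict()
        assert forward == reverse == rotated

    def test_mm_nodes_never_merge(self):
        a = _linear_schema("a", "A", ["x", "y"])
        b = _linear_schema("b", "B", ["p", "q"])
        merged = merge_schemas([a, b])
        mms = [n for n, d in merged.graph.nodes(data=True) if d.get("kind") == "mm"]
        assert len(mms) == 2  # identical class labels, still one per schema


# -- patient subgraphs ----------------------------------------------------


class TestPatientSubgraph:
    def test_all_triggers_reproduces_full_graph(self, crohn):
        graph = merge_schemas(crohn)
        everything = {t.label for s in crohn for t in s.triggers}
        sub = patient_subgraph(graph, everything)
        assert sub.to_dict() == graph.to_dict()

    def test_empty_genotype_gives_empty_subgraph(self, crohn):
        sub = patient_subgraph(merge_schemas(crohn), set())
        assert sub.graph.number_of_nodes() == 0

    def test_single_trigger_selects_that_schema(self, crohn):
        graph = merge_schemas(crohn[:3])
        sub = patient_subgraph(graph, {"MUC1 risk variant"})
        assert sub.member_schemas == ["crohn-muc1"]
        assert sub.graph.number_of_nodes() == len(crohn[0].nodes)

    def test_monotone_under_trigger_addition(self, crohn):
        graph = merge_schemas(crohn)
        labels = sorted({t.label for s in crohn for t in s.triggers})
        prev_nodes: set = set()
        for k in range(len(labels) + 1):
            sub = patient_subgraph(graph, set(labels[:k]))
            nodes = set(sub.graph.nodes())
            assert prev_nodes <= nodes
            prev_nodes = nodes

    def test_unknown_label_ignored_unless_strict(self, crohn):
        graph = merge_schemas(crohn)
        sub = patient_subgraph(graph, {"no-such-variant"})
        assert sub.graph.number_of_nodes() == 0
        with pytest.raises(KeyError):
            patient_subgraph(graph, {"no-such-variant"}, strict=True)

    def test_genotype_file_parsing(self, tmp_path):
        p = tmp_path / "genotype.tsv"
        p.write_text(
            "# patient 1\nMUC1 risk variant\t1\nNOD2 risk variant\t0\n",
            encoding="utf-8",
        )
        assert read_genotype(p) == {"MUC1 risk variant"}
        bad = tmp_path / "bad.tsv"
        bad.write_text("MUC1 risk variant\tyes\n", encoding="utf-8")
        with pytest.raises(ValueError):
            read_genotype(bad)


# -- drug overlap ---------------------------------------------------------


def _smad7_locus_schema():
    s = MechanismSchema(id="crohn-smad7", disease="Crohn disease", locus="SMAD7")
    t = s.add_trigger(TriggerKind.GENETIC_VARIANT, "SMAD7 risk variant")
    dna = s.add_ssp(Stage.DNA, "SMAD7 locus", "SNV")
    mm1 = s.add_mm("altered protein synthesis")
    smad7 = s.add_ssp(Stage.PROTEIN, "SMAD7", "protein abundance", modifier="increased")
    mm2 = s.add_mm("increased suppression of TGFβ1 signaling")
    anti = s.add_ssp(
        Stage.CELL,
        "anti-inflammatory response to TGFβ1",
        "cell response",
        modifier="decreased",
    )
    mm3 = s.add_mm("increased disease susceptibility")
    risk = s.add_ssp(
        Stage.ORGANISM_PHENOTYPE, "Crohn disease risk", "disease risk",
        modifier="increased",
    )
    for a, b in [(t, dna), (dna, mm1), (mm1, smad7), (smad7, mm2), (mm2, anti),
                 (anti, mm3), (mm3, risk)]:
        s.link(a, b)
    return s


class TestDrugOverlap:
    def test_disjoint_schemas_overlap_zero(self, crohn):
        patient = merge_schemas(crohn[:1])
        report = drug_overlap(patient, _linear_schema("drug", "D", ["z1", "z2"], disease="Crohn disease"))
        assert report.overlap_count == 0 and report.shared_keys == []

    def test_mongersen_shares_tgfb1_response_ssp(self, mongersen):
        patient = merge_schemas([_smad7_locus_schema()])
        report = drug_overlap(patient, mongersen)
        shared_entities = {k.entity for k in report.shared_keys}
        assert "anti-inflammatory response to tgfβ1" in shared_entities
        key = next(
            k for k in report.shared_keys
            if k.entity == "anti-inflammatory response to tgfβ1"
        )
        assert key.modifier == "decreased"
        assert report.provenance[str(key)] == ["crohn-smad7"]

    @pytest.mark.parametrize("seed", range(100))
    def test_overlap_matches_set_intersection_oracle(self, seed):
        patient_schema = make_random_schema(2 * seed)
        drug = make_random_schema(2 * seed + 1)
        drug.disease = patient_schema.disease
        patient = merge_schemas([patient_schema])
        report = drug_overlap(patient, drug)
        expected = oracle_key_set(patient_schema) & oracle_key_set(drug)
        assert {k.to_tuple() for k in report.shared_keys} == expected
        assert report.overlap_count == len(expected)
        assert report.overlap_count <= min(
            len(oracle_key_set(patient_schema)), len(oracle_key_set(drug))
        )


# -- epistasis candidates -------------------------------------------------


class TestEpistasisCandidates:
    def test_autophagy_loci_form_all_six_pairs(self, crohn):
        graph = merge_schemas(crohn)
        pairs = {(c.locus_a, c.locus_b) for c in epistasis_candidates(graph)}
        autophagy = ["ATG16L1", "IRGM", "LRRK2", "NOD2"]
        within = {
            (a, b) for i, a in enumerate(autophagy) for b in autophagy[i + 1:]
        }
        assert within <= pairs
        assert len(within) == 6
        assert ("MUC1", "MUC2") in pairs

    def test_stoplist_disabled_yields_all_28_pairs(self, crohn):
        graph = merge_schemas(crohn)
        assert len(epistasis_candidates(graph, stop_stages=None)) == 28
        assert len(epistasis_candidates(graph)) == 8

    def test_disjoint_schemas_yield_no_candidates(self):
        a = _linear_schema("a", "A", ["x1", "x2"])
        b = _linear_schema("b", "B", ["y1", "y2"])
        assert epistasis_candidates(merge_schemas([a, b])) == []

    def test_pairs_sorted_and_unordered(self, crohn):
        cands = epistasis_candidates(merge_schemas(crohn))
        for c in cands:
            assert c.locus_a < c.locus_b
        keys = [(c.locus_a, c.locus_b) for c in cands]
        assert keys == sorted(keys)

    def test_earliest_shared_stage_reported(self, crohn):
        graph = merge_schemas(crohn)
        by_pair = {
            (c.locus_a, c.locus_b): c.earliest_shared_stage
            for c in epistasis_candidates(graph)
        }
        assert by_pair[("MUC1", "MUC2")] is Stage.TISSUE
        assert by_pair[("ATG16L1", "NOD2")] is Stage.CELL

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_pairwise_intersection_oracle(self, seed):
        schemas = [make_random_schema(3 * seed + i) for i in range(3)]
        for s in schemas:
            s.disease = "synthetic disease"
        graph = merge_schemas(schemas)
        per_locus = oracle_reachable_keys(schemas)
        loci = sorted(per_locus)
        expected = []
        for i, a in enumerate(loci):
            for b in loci[i + 1:]:
                shared = per_locus[a] & per_locus[b]
                if shared:
                    expected.append((a, b, shared))
        got = [
            (c.locus_a, c.locus_b, {k.to_tuple() for k in c.shared_keys})
            for c in epistasis_candidates(graph)
        ]
        assert got == expected


# -- classification queries -----------------------------------------------


class TestClassifyQuery:
    def test_decreased_protein_abundance_matches_msp(self, msp):
        hits = classify_query([msp], Stage.PROTEIN, "protein abundance", "decreased")
        assert hits == [("crohn-msp", ["ssp_serum"])]

    def test_unused_label_yields_empty(self, msp):
        assert classify_query([msp], Stage.PROTEIN, "no such class") == []

    def test_mm_class_query_matches_on_input_stage(self, msp):
        hits = classify_query([msp], Stage.PROTEIN, "weaker protein-protein interaction")
        assert hits == [("crohn-msp", ["mm_ron"])]

    @pytest.mark.parametrize("seed", range(100))
    def test_ssp_query_agrees_with_linear_scan(self, seed):
        schema = make_random_schema(seed)
        # probe with a class actually present, if any
        if not schema.ssps:
            return
        probe = schema.ssps[0]
        hits = classify_query(
            [schema], probe.stage, probe.perturbation_class, probe.modifier
        )
        expected_nodes = sorted(
            n.id
            for n in schema.ssps
            if n.stage is probe.stage
            and n.perturbation_class.casefold() == probe.perturbation_class.casefold()
            and (probe.modifier is None or n.modifier is probe.modifier)
        )
        assert hits == [(schema.id, expected_nodes)]


# -- telescope expansion --------------------------------------------------


def _host_and_sub():
    host = MechanismSchema(id="host", disease="d", locus="L")
    t = host.add_trigger(TriggerKind.GENETIC_VARIANT, "rs1")
    s1 = host.add_ssp(Stage.DNA, "gene G", "SNV", id="s1")
    mm = host.add_mm(
        "altered protein synthesis", telescoped_ref="sub1", id="mm_tel"
    )
    s2 = host.add_ssp(
        Stage.PROTEIN, "protein G", "protein abundance", id="s2",
        modifier="decreased",
    )
    phen_mm = host.add_mm("increased disease susceptibility")
    phen = host.add_ssp(Stage.ORGANISM_PHENOTYPE, "risk", "disease risk")
    host.link(t, s1)
    host.link(s1, mm)
    host.link(mm, s2)
    host.link(s2, phen_mm)
    host.link(phen_mm, phen)

    sub = MechanismSchema(id="sub1", disease="d", locus="L")
    e1 = sub.add_ssp(Stage.DNA, "gene G", "SNV", id="e1")
    m1 = sub.add_mm("altered protein synthesis", id="m1")
    mid = sub.add_ssp(Stage.RNA, "G transcript", "RNA abundance", id="mid",
                      modifier="decreased")
    m2 = sub.add_mm("altered RNA/protein interactions", id="m2")
    x1 = sub.add_ssp(Stage.PROTEIN, "protein G", "protein abundance", id="x1",
                     modifier="decreased")
    sub.link(e1, m1)
    sub.link(m1, mid)
    sub.link(mid, m2)
    sub.link(m2, x1)
    return host, sub


class TestExpandTelescoped:
    def test_two_step_sub_schema_splice_arithmetic(self):
        host, sub = _host_and_sub()
        expanded = expand_telescoped(host, "mm_tel", resolver={"sub1": sub}.__getitem__)
        internal = 3  # m1, mid, m2; boundary SSPs merge with host neighbors
        assert len(expanded.nodes) == len(host.nodes) - 1 + internal
        assert len(expanded.nodes) - len(host.nodes) == internal - 1

    def test_expanded_schema_passes_validation(self):
        host, sub = _host_and_sub()
        assert is_valid(host)
        expanded = expand_telescoped(host, "mm_tel", resolver={"sub1": sub}.__getitem__)
        report = validate_schema(expanded)
        assert "ALTERNATION" not in report.codes()
        assert report.valid

    def test_dangling_reference_rejected(self):
        host, _ = _host_and_sub()
        with pytest.raises(DanglingReferenceError):
            expand_telescoped(host, "mm_tel", resolver={}.__getitem__)

    def test_non_ssp_boundary_rejected(self):
        host, _ = _host_and_sub()
        bad = MechanismSchema(id="sub1", disease="d")
        m = bad.add_mm("altered protein synthesis", id="m_entry")
        x = bad.add_ssp(Stage.PROTEIN, "protein G", "protein abundance", id="x")
        bad.link(m, x)
        with pytest.raises(SpliceError):
            expand_telescoped(host, "mm_tel", resolver={"sub1": bad}.__getitem__)

    def test_default_resolver_reads_documents(self, tmp_path):
        from mechschema import write_schema

        host, sub = _host_and_sub()
        path = tmp_path / "sub1.json"
        path.write_text(write_schema(sub), encoding="utf-8")
        host.nodes["mm_tel"].telescoped_ref = str(path)
        expanded = expand_telescoped(host, "mm_tel")
        assert is_valid(expanded)
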