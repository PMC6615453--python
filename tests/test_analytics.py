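"""Cohort roll-up, counts, stratified fractions, breakdowns."""

import random

import pytest
from rdflib import Literal
from rdflib.namespace import RDF

import xenograph as xg
from xenograph.vocab import FEATURE_AMPLIFICATION, SEQUENCE_ALTERATION


def build_cohort(vocab, cases):
    """Hand-built cohort: cases = list of dicts with keys
    depth_chain (#bioentities under the tissue), variants (list of
    (gene_sym, type, instance_name, node_index)), response ((delta, node_index) or None)."""
    g = xg.TripleStore()
    treatment = g.local("treatment/cetuximab")
    g.add((treatment, RDF.type, vocab.Treatment))
    genes = {}
    for sym in ("BRAF", "EGFR", "ERBB2", "KRAS"):
        genes[sym] = g.local(f"gene/{sym}")
        g.add((genes[sym], RDF.type, vocab.Gene))
        g.add((genes[sym], vocab.symbol, Literal(sym)))
    for i, spec in enumerate(cases):
        case = g.local(f"case/{i}")
        g.add((case, RDF.type, vocab.Case))
        tissue = g.local(f"case/{i}/t0")
        g.add((tissue, RDF.type, vocab.Tissue))
        g.add((case, vocab.generates, tissue))
        nodes = [case, tissue]
        parent = tissue
        for d in range(spec.get("depth_chain", 2)):
            b = g.local(f"case/{i}/b{d}")
            g.add((b, RDF.type, vocab.Bioentity))
            g.add((parent, vocab.generates, b))
            nodes.append(b)
            parent = b
        for sym, atype, iname, at in spec.get("variants", []):
            inst = g.local(f"alt/{iname}")
            cls = (vocab.Sequence_Alteration if atype == SEQUENCE_ALTERATION
                   else vocab.Feature_amplification)
            pred = (vocab.has_sequence_alteration
                    if atype == SEQUENCE_ALTERATION
                    else vocab.has_feature_amplification)
            g.add((inst, RDF.type, cls))
            g.add((genes[sym], pred, inst))
            xg.annotate(g, nodes[at], inst, {"session": f"c{i}{iname}{at}"})
        for resp in spec.get("responses", []):
            delta, at = resp
            xg.annotate_response(
                g, xg.ResponseObservation(nodes[at], treatment, delta),
                {"session": f"c{i}r{at}{delta}"})
    state = xg.materialize(g)
    return g, state, genes, treatment


THREE_CASES = [
    # annotations at depth 3 (leaf bioentity)
    {"depth_chain": 2, "variants": [("KRAS", SEQUENCE_ALTERATION, "KRAS_G12D", 3)],
     "responses": [(60.0, 3)]},
    {"depth_chain": 2, "variants": [("EGFR", FEATURE_AMPLIFICATION, "EGFR_amp", 2),
                                    ("KRAS", SEQUENCE_ALTERATION, "KRAS_G12V", 3)],
     "responses": [(-70.0, 2)]},
    {"depth_chain": 2, "variants": [], "responses": [(10.0, 1)]},
]


class TestRollUp:
    def test_hand_enumeration_of_three_trees(self, vocab):
        g, state, genes, treatment = build_cohort(vocab, THREE_CASES)
        table = xg.roll_up(state, genes.values())
        assert len(table) == 3
        r0 = table.rows[g.local("case/0")]
        assert r0.altered_genes_by_type == {genes["KRAS"]: {SEQUENCE_ALTERATION}}
        assert r0.responses[treatment].label == "negative"
        assert r0.responses[treatment].n_observations == 1
        r1 = table.rows[g.local("case/1")]
        assert r1.altered_genes_by_type == {
            genes["EGFR"]: {FEATURE_AMPLIFICATION},
            genes["KRAS"]: {SEQUENCE_ALTERATION}}
        assert r1.responses[treatment].label == "positive"
        r2 = table.rows[g.local("case/2")]
        assert not r2.has_variant
        assert r2.responses[treatment].label == "neutral"

    def test_leaf_annotation_attributed_to_root_case(self, vocab):
        cases = [{"depth_chain": 4,
                  "variants": [("BRAF", SEQUENCE_ALTERATION, "BRAF_V600E", 5)]}]
        g, state, genes, _ = build_cohort(vocab, cases)
        table = xg.roll_up(state, genes.values())
        assert table.rows[g.local("case/0")].altered_genes_by_type == {
            genes["BRAF"]: {SEQUENCE_ALTERATION}}

    def test_empty_graph_gives_empty_table(self):
        state = xg.materialize(xg.TripleStore())
        assert len(xg.roll_up(state, [])) == 0

    def test_replicate_observations_averaged_then_classified(self, vocab):
        cases = [{"depth_chain": 2, "responses": [(100.0, 2), (-80.0, 3)]}]
        g, state, genes, treatment = build_cohort(vocab, cases)
        table = xg.roll_up(state, genes.values())
        resp = table.rows[g.local("case/0")].responses[treatment]
        assert resp.mean_variation == pytest.approx(10.0)
        assert resp.label == "neutral"
        assert resp.n_observations == 2
        worst = xg.roll_up(state, genes.values(), aggregate="worst")
        assert worst.rows[g.local("case/0")].responses[treatment].label == \
            "negative"

    def test_flattening_annotation_depth_invariance(self, vocab):
        """Moving an annotation to any depth leaves the table unchanged."""
        rng = random.Random(9)
        tables = []
        for depth in (1, 2, 3, 5):
            cases = [{"depth_chain": 5,
                      "variants": [("KRAS", SEQUENCE_ALTERATION, "KRAS_G12D",
                                    depth)],
                      "responses": [(50.0, rng.randint(0, 6))]}]
            g, state, genes, treatment = build_cohort(vocab, cases)
            table = xg.roll_up(state, genes.values())
            row = table.rows[g.local("case/0")]
            tables.append((
                {str(k): v for k, v in row.altered_genes_by_type.items()},
                row.responses[treatment].label))
        assert all(t == tables[0] for t in tables)

    def test_rollup_matches_no_reasoner_traversal(self, vocab):
        """Equivalence with a plain graph-walk oracle that never touches
        inferred triples."""
        g, state, genes, treatment = build_cohort(vocab, THREE_CASES)
        table = xg.roll_up(state, genes.values())

        # oracle: DFS over asserted generates edges, manual predicate lifting
        def oracle_row(case):
            nodes = [case]
            stack = [case]
            while stack:
                x = stack.pop()
                for _, _, child in g.match((x, vocab.generates, None)):
                    if (x, vocab.generates, child) in g.asserted:
                        nodes.append(child)
                        stack.append(child)
            altered = {}
            for node in nodes:
                for _, _, ann in g.match((node, vocab.has_annotation, None)):
                    if (node, vocab.has_annotation, ann) not in g.asserted:
                        continue
                    ref = g.match((ann, vocab.has_reference, None))[0][2]
                    for pred in (vocab.has_sequence_alteration,
                                 vocab.has_feature_amplification):
                        for gene, _, _ in g.match((None, pred, ref)):
                            atype = (SEQUENCE_ALTERATION
                                     if pred == vocab.has_sequence_alteration
                                     else FEATURE_AMPLIFICATION)
                            altered.setdefault(gene, set()).add(atype)
            return altered

        for case, row in table.rows.items():
            assert row.altered_genes_by_type == oracle_row(case)


class TestCounts:
    def test_counts_match_generator_ground_truth(self):
        cfg = xg.CohortConfig(n_cases=150, seed=3,
                              response=xg.ResponseModel(p_observed=0.8),
                              p_variant_observed=0.9)
        g, truth = xg.generate_cohort(cfg)
        state = xg.materialize(g)
        genes = xg.genes_by_symbol(g, cfg.panel)
        table = xg.roll_up(state, genes.values())
        counts = xg.count_cohort(table)
        assert counts == {
            "n_variant_annotated": truth.n_variant_annotated,
            "n_response_annotated": truth.n_response_annotated,
            "n_both": truth.n_both,
        }
        assert counts["n_both"] <= min(counts["n_variant_annotated"],
                                       counts["n_response_annotated"])

    def test_empty_table_counts_zero(self):
        counts = xg.count_cohort(xg.CaseFeatureTable())
        assert counts == {"n_variant_annotated": 0, "n_response_annotated": 0,
                          "n_both": 0}


class TestSubsetsAndFractions:
    @pytest.fixture()
    def cohort(self, vocab):
        return build_cohort(vocab, THREE_CASES)

    def test_mutations_only_and_amplifications_only_disjoint(self, cohort):
        g, state, genes, treatment = cohort
        table = xg.roll_up(state, genes.values())
        panel = frozenset(genes.values())
        muts = {c for c, r in table.rows.items()
                if xg.SubsetSpec("mutations_only", panel).contains(r)}
        amps = {c for c, r in table.rows.items()
                if xg.SubsetSpec("amplifications_only", panel).contains(r)}
        assert not muts & amps

    def test_subsets_partition_cohort(self, cohort):
        g, state, genes, treatment = cohort
        table = xg.roll_up(state, genes.values())
        panel = frozenset(genes.values())
        both = {c for c, r in table.rows.items()
                if r.altered_genes([SEQUENCE_ALTERATION]) & panel
                and r.altered_genes([FEATURE_AMPLIFICATION]) & panel}
        muts = {c for c, r in table.rows.items()
                if xg.SubsetSpec("mutations_only", panel).contains(r)}
        amps = {c for c, r in table.rows.items()
                if xg.SubsetSpec("amplifications_only", panel).contains(r)}
        none = {c for c, r in table.rows.items()
                if xg.SubsetSpec("no_variant", panel).contains(r)}
        assert muts | amps | both | none == set(table.rows)

    def test_panel_required_for_restricted_modes(self):
        with pytest.raises(ValueError):
            xg.SubsetSpec("mutations_only", frozenset())

    def test_fractions_sum_to_one_and_exact_sets_used(self, cohort):
        g, state, genes, treatment = cohort
        table = xg.roll_up(state, genes.values())
        panel = frozenset(genes.values())
        matrix = xg.stratified_response_fractions(
            table, xg.SubsetSpec("any_variant", panel), treatment)
        for stratum, n in matrix.counts.items():
            if n:
                assert sum(matrix.fractions[stratum].values()) == \
                    pytest.approx(1.0, abs=1e-9)
        # case/1 has {EGFR, KRAS}: counted in the pair stratum only
        pair = frozenset({genes["EGFR"], genes["KRAS"]})
        assert matrix.counts[pair] == 1
        assert matrix.counts[frozenset({genes["EGFR"]})] == 0
        assert matrix.counts[frozenset({genes["KRAS"]})] == 1

    def test_all_negative_stratum_fractions(self, vocab):
        cases = [{"variants": [("KRAS", SEQUENCE_ALTERATION, "KRAS_G12D", 2)],
                  "responses": [(80.0, 2)]}] * 3
        g, state, genes, treatment = build_cohort(vocab, cases)
        table = xg.roll_up(state, genes.values())
        matrix = xg.stratified_response_fractions(
            table, xg.SubsetSpec("any_variant", frozenset(genes.values())),
            treatment)
        stratum = frozenset({genes["KRAS"]})
        assert matrix.fractions[stratum] == {"positive": 0.0, "neutral": 0.0,
                                             "negative": 1.0}

    def test_planted_negative_fraction_recovered(self):
        """Generator plants P(negative | >=1 variant) = 0.7; the stratified
        fractions recover it within the binomial band at n=400."""
        cfg = xg.CohortConfig(n_cases=400, seed=7)
        g, truth = xg.generate_cohort(cfg)
        state = xg.materialize(g)
        genes = xg.genes_by_symbol(g, cfg.panel)
        table = xg.roll_up(state, genes.values())
        treatment = g.local("treatment/cetuximab")
        matrix = xg.stratified_response_fractions(
            table, xg.SubsetSpec("any_variant", frozenset(genes.values())),
            treatment)
        assert matrix.overall()["negative"] == pytest.approx(0.70, abs=0.05)


class TestDistributionsAndBreakdown:
    def test_variant_distribution_recovers_ground_truth(self):
        cfg = xg.CohortConfig(n_cases=120, seed=11)
        g, truth = xg.generate_cohort(cfg)
        state = xg.materialize(g)
        genes = xg.genes_by_symbol(g, cfg.panel)
        table = xg.roll_up(state, genes.values())
        dist = xg.variant_distribution(
            table, xg.SubsetSpec("all", frozenset(genes.values())))
        expected = {}
        for case in truth.cases.values():
            for gene, atype in case.altered:
                expected[(gene, atype)] = expected.get((gene, atype), 0) + 1
        got = {(r.gene, r.alteration_type): r.n_cases
               for r in dist.itertuples()}
        assert got == expected

    def test_empty_subset_distribution_is_empty(self, vocab):
        g, state, genes, _ = build_cohort(vocab, [
            {"variants": [("KRAS", SEQUENCE_ALTERATION, "KRAS_G12D", 2)]}])
        table = xg.roll_up(state, genes.values())
        dist = xg.variant_distribution(
            table, xg.SubsetSpec("amplifications_only",
                                 frozenset(genes.values())))
        assert dist.empty

    def test_breakdown_restricted_to_nonresponders(self, vocab):
        cases = [
            {"variants": [("KRAS", SEQUENCE_ALTERATION, "KRAS_G12D", 2)],
             "responses": [(80.0, 2)]},
            {"variants": [("KRAS", SEQUENCE_ALTERATION, "KRAS_G12V", 2)],
             "responses": [(90.0, 2)]},
            {"variants": [("EGFR", FEATURE_AMPLIFICATION, "EGFR_amp", 2)],
             "responses": [(-80.0, 2)]},  # responder, excluded
        ]
        g, state, genes, treatment = build_cohort(vocab, cases)
        table = xg.roll_up(state, genes.values())
        bd = xg.nonresponder_breakdown(table, treatment)
        assert set(bd["gene"]) == {"KRAS"}
        assert set(bd["instance"]) == {"KRAS_G12D", "KRAS_G12V"}

    def test_amplification_instances_collapse_to_type_level(self, vocab):
        cases = [{"variants": [("ERBB2", FEATURE_AMPLIFICATION, "ERBB2_amp", 2)],
                  "responses": [(50.0, 2)]}]
        g, state, genes, treatment = build_cohort(vocab, cases)
        table = xg.roll_up(state, genes.values())
        bd = xg.nonresponder_breakdown(table, treatment)
        assert len(bd) == 1
        assert bd.iloc[0]["alteration_type"] == FEATURE_AMPLIFICATION
        assert bd.iloc[0]["instance"] is None

    def test_no_negative_cases_gives_empty_breakdown(self, vocab):
        g, state, genes, treatment = build_cohort(vocab, [
            {"variants": [("KRAS", SEQUENCE_ALTERATION, "KRAS_G12D", 2)],
             "responses": [(-90.0, 2)]}])
        table = xg.roll_up(state, genes.values())
        assert xg.nonresponder_breakdown(table, treatment).empty

    def test_breakdown_leaf_counts_partition_occurrences(self, vocab):
        cases = [
            {"variants": [("KRAS", SEQUENCE_ALTERATION, "KRAS_G12D", 2),
                          ("EGFR", FEATURE_AMPLIFICATION, "EGFR_amp", 2)],
             "responses": [(70.0, 2)]},
            {"variants": [("KRAS", SEQUENCE_ALTERATION, "KRAS_G12D", 2)],
             "responses": [(40.0, 2)]},
        ]
        g, state, genes, treatment = build_cohort(vocab, cases)
        table = xg.roll_up(state, genes.values())
        bd = xg.nonresponder_breakdown(table, treatment)
        total_occurrences = sum(len(r.variants) for r in table.rows.values()
                                if r.responses[treatment].label == "negative")
        assert bd["n_cases"].sum() == total_occurrences
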