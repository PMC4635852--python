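import itertools

import numpy as np
import pytest

from oracles import brute_hypergeom_tail, brute_module_edges, brute_pathway_edges
from txsubtypes import (
    GeneSet,
    GeneSetCollection,
    Interaction,
    InteractionTable,
    SyntheticConfig,
    generate,
    generate_genesets,
    generate_interactions,
    hypergeom_pvalue,
    induce_module,
    overrepresentation,
    pathway_overlap_network,
    partition_genes,
    run_three_way,
)


class TestHypergeom:
    def test_exact_enumeration_example(self):
        # draw 2 of 4, set of 2: both in the set in 1 of C(4,2)=6 draws
        assert hypergeom_pvalue(4, 2, 2, 2) == pytest.approx(1 / 6)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_pvalue(100, 10, 5, 0) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 4, 3, 4)
        with pytest.raises(ValueError):
            hypergeom_pvalue(5, 6, 2, 1)

    def test_matches_enumeration_for_all_small_tuples(self):
        for M in range(1, 13):
            for n_set in range(M + 1):
                for n_input in range(M + 1):
                    for k in range(min(n_set, n_input) + 1):
                        assert hypergeom_pvalue(M, n_set, n_input, k) == \
                            pytest.approx(
                                brute_hypergeom_tail(M, n_set, n_input, k),
                                abs=1e-12), (M, n_set, n_input, k)


def _collection(*member_lists):
    return GeneSetCollection([
        GeneSet(f"S{i}", f"set {i}", frozenset(members))
        for i, members in enumerate(member_lists)])


class TestOverrepresentation:
    def test_perfect_input_is_overwhelming_hit(self):
        universe = [f"g{i}" for i in range(1000)]
        target = universe[:10]
        coll = _collection(target, universe[500:530])
        result = overrepresentation(target, coll, universe)
        assert result.hit_ids == ["S0"]
        assert result.table.loc["S0", "p"] < 1e-15

    def test_disjoint_input_yields_no_hits(self):
        universe = [f"g{i}" for i in range(100)]
        coll = _collection(universe[:10])
        result = overrepresentation(universe[50:60], coll, universe)
        assert result.hit_ids == []
        assert result.table.loc["S0", "p"] == 1.0

    def test_min_overlap_gate(self):
        universe = [f"g{i}" for i in range(40)]
        coll = _collection(universe[:1])
        result = overrepresentation(universe[:2], coll, universe)
        # p = 2/40 = 0.05 > 0.01 and overlap 1 < 2: excluded on both gates
        assert result.table.loc["S0", "n_overlap"] == 1
        assert result.hit_ids == []

    def test_members_outside_universe_ignored(self):
        universe = [f"g{i}" for i in range(50)]
        inside = universe[:8]
        with_stray = list(inside) + ["alien1", "alien2"]
        res_a = overrepresentation(inside, _collection(inside), universe)
        res_b = overrepresentation(inside, _collection(with_stray), universe)
        assert res_a.table.loc["S0", "p"] == res_b.table.loc["S0", "p"]
        assert res_b.table.loc["S0", "n_set"] == 8

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(60)]
        coll = _collection(universe[:15], universe[10:30])
        inp = universe[5:20]
        p1 = overrepresentation(inp, coll, universe).table["p"]
        shuffled_inp = list(inp)
        rng.shuffle(shuffled_inp)
        shuffled_universe = list(universe)
        rng.shuffle(shuffled_universe)
        p2 = overrepresentation(shuffled_inp, coll, shuffled_universe).table["p"]
        assert dict(p1) == dict(p2)

    def test_empty_inputs_rejected(self):
        coll = _collection(["a"])
        with pytest.raises(ValueError, match="universe"):
            overrepresentation(["a"], coll, [])
        with pytest.raises(ValueError, match="input"):
            overrepresentation([], coll, ["a"])

    def test_q_values_computed_over_all_tested_sets(self):
        universe = [f"g{i}" for i in range(200)]
        coll = _collection(universe[:10], universe[100:110], universe[150:160])
        result = overrepresentation(universe[:10], coll, universe)
        from txsubtypes import bh_fdr

        np.testing.assert_allclose(
            np.sort(result.table["q"]),
            np.sort(bh_fdr(result.table["p"].to_numpy())))


class TestPathwayNetwork:
    def _result(self, input_members):
        """Build an EnrichmentResult-like object via a real ORA call whose
        hits have the requested per-set input members."""
        all_members = sorted(set(itertools.chain.from_iterable(
            input_members.values())))
        universe = [f"u{i}" for i in range(400)] + all_members
        coll = GeneSetCollection([
            GeneSet(name, "", frozenset(members))
            for name, members in input_members.items()])
        return overrepresentation(all_members, coll, universe), coll

    def test_two_thirds_overlap_makes_edge(self):
        result, coll = self._result({"P1": {"a", "b", "c"}, "P2": {"a", "b", "d"}})
        graph = pathway_overlap_network(result, coll)
        assert graph.has_edge("P1", "P2")
        assert graph.edges["P1", "P2"]["overlap_fraction"] == pytest.approx(2 / 3)

    def test_identical_and_disjoint_sets(self):
        result, coll = self._result({
            "P1": {"a", "b", "c"}, "P2": {"a", "b", "c"}, "P3": {"x", "y", "z"}})
        graph = pathway_overlap_network(result, coll)
        assert graph.edges["P1", "P2"]["overlap_fraction"] == 1.0
        assert not graph.has_edge("P1", "P3") and not graph.has_edge("P2", "P3")

    def test_edge_set_matches_brute_force_scan(self):
        rng = np.random.default_rng(31)
        universe = [f"g{i}" for i in range(300)]
        sets = {f"P{i}": set(rng.choice(universe[:60], size=rng.integers(3, 12),
                                        replace=False))
                for i in range(8)}
        result, coll = self._result(sets)
        graph = pathway_overlap_network(result, coll, edge_min=0.3)
        hits = result.hits
        genes_of = {sid: set(hits.loc[sid, "overlap_genes"])
                    for sid in hits.index}
        expected = brute_pathway_edges(genes_of, 0.3)
        got = {frozenset(e) for e in graph.edges}
        assert got == expected
        # symmetry comes with an undirected graph; degree bookkeeping sane
        assert all(graph.has_edge(b, a) for a, b in graph.edges)


PPI = InteractionTable([
    Interaction("g1", "g2", "ppi", confidence=0.95),
    Interaction("g2", "g9", "ppi", confidence=0.99),
    Interaction("g1", "g3", "ppi", confidence=0.5),
])


class TestInducedModules:
    def test_ppi_needs_both_endpoints(self):
        module = induce_module({"g1", "g2"}, PPI, "ppi")
        assert set(module.edges) == {("g1", "g2")}
        assert module.nodes["g1"]["in_input"]

    def test_low_confidence_dropped(self):
        module = induce_module({"g1", "g2", "g3"}, PPI, "ppi")
        assert not module.has_edge("g1", "g3")
        relaxed = induce_module({"g1", "g2", "g3"}, PPI, "ppi",
                                confidence_min=0.4)
        assert relaxed.has_edge("g1", "g3")

    def test_drug_attached_as_satellite(self):
        table = InteractionTable([
            Interaction("D1", "g1", "drug_target", confidence=0.95),
            Interaction("D2", "g7", "drug_target", confidence=0.95),
        ])
        module = induce_module({"g1"}, table, "drug_target")
        assert module.nodes["D1"]["type"] == "drug"
        assert not module.nodes["D1"]["in_input"]
        assert "D2" not in module
        # every attached node touches an input gene
        for node, data in module.nodes(data=True):
            if not data["in_input"]:
                assert any(module.nodes[t]["in_input"]
                           for t in module.successors(node))

    def test_unknown_kind_rejected(self):
        with pytest.raises(Exception, match="kind"):
            induce_module({"g1"}, PPI, "metabolic")

    def test_matches_brute_force_and_monotone_in_confidence(self):
        rng = np.random.default_rng(44)
        genes = [f"g{i}" for i in range(30)]
        edges = []
        for _ in range(120):
            a, b = rng.choice(genes, size=2, replace=False)
            kind = ["ppi", "regulatory", "drug_target"][rng.integers(3)]
            edges.append(Interaction(
                f"R_{a}" if kind != "ppi" else a, b, kind,
                confidence=float(rng.uniform(0.3, 1.0))))
        table = InteractionTable(edges)
        inp = set(rng.choice(genes, size=12, replace=False))
        previous_edges = None
        for cmin in (0.3, 0.6, 0.9, 0.95):
            for kind in ("ppi", "regulatory", "drug_target"):
                module = induce_module(inp, table, kind, confidence_min=cmin)
                expected = brute_module_edges(inp, edges, kind, cmin)
                # the graph collapses duplicate (source, target) draws
                assert set(module.edges) == set(expected)
            module = induce_module(inp, table, "ppi", confidence_min=cmin)
            current = set(module.edges)
            if previous_edges is not None:
                assert current <= previous_edges  # tightening never adds
            previous_edges = current


class TestThreeWay:
    def test_empty_list_warns_instead_of_failing(self):
        universe = [f"g{i}" for i in range(50)]
        coll = _collection(universe[:5])
        part = partition_genes({"g0", "g1", "g2"}, {"g0", "g1", "g2"})
        results = run_three_way(part, coll, {}, universe)
        assert results["unique_a"].warning == "empty gene list"
        assert results["unique_a"].enrichment is None
        assert results["core"].enrichment is not None

    def test_planted_sets_enrich_only_their_own_list(self):
        matrix, truth = generate(SyntheticConfig(seed=2))
        sets = generate_genesets(truth, seed=2)
        interactions = generate_interactions(truth, seed=2)
        part = partition_genes(
            set(truth.core_genes) | set(truth.unique_a_genes),
            set(truth.core_genes) | set(truth.unique_b_genes))
        tables = {k: InteractionTable(interactions.of_kind(k))
                  for k in ("ppi", "regulatory", "drug_target")}
        results = run_three_way(part, sets, tables, list(truth.gene_class))
        matching = {"core": "SET_CORE", "unique_a": "SET_UNIQUE_A",
                    "unique_b": "SET_UNIQUE_B"}
        for name, result in results.items():
            hits = set(result.enrichment.hit_ids)
            assert matching[name] in hits
            assert not (set(matching.values()) - {matching[name]}) & hits

    def test_modules_recover_class_regulator_and_drug(self):
        matrix, truth = generate(SyntheticConfig(seed=4))
        interactions = generate_interactions(truth, seed=4)
        module = induce_module(truth.unique_a_genes,
                               InteractionTable(interactions.of_kind("regulatory")),
                               "regulatory")
        assert "TF_A" in module and module.nodes["TF_A"]["type"] == "tf"
        drugs = induce_module(truth.unique_a_genes,
                              InteractionTable(interactions.of_kind("drug_target")),
                              "drug_target")
        assert "DRUG_A" in drugs
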