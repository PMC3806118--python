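import numpy as np
import pytest

from lactmir.io_tables import AnnotationSet, FormatError
from lactmir.ontology import (
    enrich_clusters,
    enrichment_score,
    fisher_enrichment,
    level_slice,
    parse_obo,
    propagate,
    write_obo,
)
from lactmir.clustering import ClusterAssignment
from lactmir.consensus import consensus
from lactmir.io_tables import PredictionTable
from lactmir.simulate import simulate_ontology

from conftest import build_ontology, random_dag
from oracles import (
    enrichment_score_by_walk,
    fisher_two_sided_exact,
    propagated_by_walk,
)


def annotations(mapping):
    return AnnotationSet(direct={g: set(ts) for g, ts in mapping.items()})


OBO_DIAMOND = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: a
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: b
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: x
namespace: biological_process
is_a: GO:0000002 ! a

[Term]
id: GO:0000005
name: c
namespace: biological_process
is_a: GO:0000002 ! a
is_a: GO:0000003 ! b
is_a: GO:0000004 ! x

[Term]
id: GO:0000099
name: gone
namespace: biological_process
is_obsolete: true
"""


class TestParseObo:
    def test_levels_use_shortest_path(self, tmp_path):
        path = tmp_path / "dag.obo"
        path.write_text(OBO_DIAMOND)
        graph = parse_obo(path)
        assert graph.levels["GO:0000001"] == 1
        assert graph.levels["GO:0000002"] == 2
        # c reaches the root through a 2-edge and a 3-edge path: level 3
        assert graph.levels["GO:0000005"] == 3
        assert "GO:0000099" not in graph.graph  # obsolete skipped
        assert graph.roots == {"biological_process": "GO:0000001"}

    def test_cycle_rejected(self, tmp_path):
        path = tmp_path / "cyclic.obo"
        path.write_text(
            "[Term]\nid: A\nnamespace: bp\nis_a: B\n\n[Term]\nid: B\nnamespace: bp\nis_a: A\n"
            "\n[Term]\nid: R\nnamespace: bp\n"
        )
        with pytest.raises(FormatError, match="cyclic"):
            parse_obo(path)

    def test_round_trip(self, tmp_path):
        sim = simulate_ontology(n_terms=30, seed=9, out_dir=tmp_path)
        back = parse_obo(sim.obo_path)
        assert set(back.graph.edges) == set(sim.graph.graph.edges)
        assert back.levels == sim.graph.levels


class TestPropagate:
    def test_leaf_annotation_reaches_all_ancestors(self, tmp_path):
        path = tmp_path / "dag.obo"
        path.write_text(OBO_DIAMOND)
        graph = parse_obo(path)
        prop = propagate(graph, annotations({"G1": {"GO:0000005"}}))
        for term in ("GO:0000005", "GO:0000004", "GO:0000003", "GO:0000002", "GO:0000001"):
            assert prop.propagated[term] == frozenset({"G1"})
        # diamond: counted once at the top despite multiple paths
        assert len(prop.propagated["GO:0000001"]) == 1

    def test_unknown_term_listed(self, tmp_path):
        path = tmp_path / "dag.obo"
        path.write_text(OBO_DIAMOND)
        graph = parse_obo(path)
        with pytest.raises(Exception, match="GO:9999999"):
            propagate(graph, annotations({"G1": {"GO:9999999"}}))

    def test_matches_descendant_walk_on_random_dags(self, rng):
        for _ in range(20):
            graph = random_dag(rng, n_terms=int(rng.integers(5, 51)))
            terms = list(graph.graph.nodes)
            direct = {}
            for g in range(15):
                gene = f"G{g}"
                for t in rng.choice(terms, size=2, replace=False):
                    direct.setdefault(gene, set()).add(t)
            prop = propagate(graph, annotations(direct))
            per_term = {}
            for gene, ts in direct.items():
                for t in ts:
                    per_term.setdefault(t, set()).add(gene)
            assert prop.propagated == propagated_by_walk(graph, per_term)
            # superset invariant on every is_a edge
            for child, parent in graph.graph.edges:
                assert prop.propagated[parent] >= prop.propagated[child]


class TestEnrichmentScore:
    def test_direct_only_term_scores_its_gene_count(self):
        graph = build_ontology([("t1", "root")])
        direct = annotations({f"G{i}": {"t1"} for i in range(7)})
        for alpha in (0.2, 0.6, 1.0):
            assert enrichment_score(graph, direct, "t1", alpha=alpha).score == 7.0

    def test_child_contribution_discounted(self):
        graph = build_ontology([("child", "parent"), ("parent", "root")])
        direct = annotations({f"G{i}": {"child"} for i in range(4)})
        result = enrichment_score(graph, direct, "parent", alpha=0.6)
        assert result.score == pytest.approx(2.4)
        assert result.contributions == [("child", 4, 1)]

    def test_monotone_in_alpha(self, rng):
        graph = random_dag(rng, n_terms=25)
        terms = list(graph.graph.nodes)
        direct = annotations(
            {f"G{i}": {terms[int(rng.integers(len(terms)))]} for i in range(20)}
        )
        root = graph.roots["biological_process"]
        scores = [enrichment_score(graph, direct, root, a).score for a in (0.2, 0.5, 0.9, 1.0)]
        assert scores == sorted(scores)

    def test_tree_root_with_alpha_one_counts_every_annotation(self, rng):
        graph = random_dag(rng, n_terms=30, p_extra=0.0)  # tree: unique paths
        terms = list(graph.graph.nodes)
        direct = {}
        for i in range(25):
            direct[f"G{i}"] = {terms[int(rng.integers(len(terms)))]}
        total = sum(len(ts) for ts in direct.values())
        root = graph.roots["biological_process"]
        assert enrichment_score(graph, annotations(direct), root, alpha=1.0).score == total

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(15):
            graph = random_dag(rng, n_terms=int(rng.integers(5, 41)))
            terms = list(graph.graph.nodes)
            direct = {f"G{i}": {terms[int(rng.integers(len(terms)))]} for i in range(12)}
            per_term = {}
            for gene, ts in direct.items():
                for t in ts:
                    per_term.setdefault(t, set()).add(gene)
            term = terms[int(rng.integers(len(terms)))]
            ours = enrichment_score(graph, annotations(direct), term, alpha=0.6).score
            assert ours == pytest.approx(
                enrichment_score_by_walk(graph, per_term, term, 0.6), abs=1e-12
            )


class TestLevelSlice:
    def test_root_level_and_beyond_depth(self):
        graph = build_ontology([("a", "root"), ("b", "root"), ("c", "a")])
        prop = propagate(graph, annotations({"G1": {"c"}, "G2": {"b"}}))
        level1 = level_slice(graph, prop, 1)
        assert level1.to_dict("records") == [
            {"term": "root", "name": "root", "namespace": "biological_process", "gene_count": 2}
        ]
        level2 = level_slice(graph, prop, 2)
        assert dict(zip(level2["term"], level2["gene_count"])) == {"a": 1, "b": 1}
        assert level_slice(graph, prop, 9).empty


class TestFisher:
    def test_equal_fractions_give_p_one(self):
        graph = build_ontology([("t", "root")])
        prop = propagate(graph, annotations({"A1": {"t"}, "A2": {"t"}, "B1": {"t"}, "B2": {"t"}}))
        out = fisher_enrichment({"A1", "A2", "A3", "A4"}, {"B1", "B2", "B3", "B4"}, prop)
        term = [o for o in out if o.term == "t"][0]
        assert term.p_value == pytest.approx(1.0)
        assert not term.significant

    @pytest.mark.parametrize(
        "table,expected",
        [((3, 0, 0, 3), 2 / 20), ((10, 0, 0, 10), 2 / 184756)],
    )
    def test_known_two_tailed_values(self, table, expected):
        a, b, c, d = table
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert p == pytest.approx(expected, rel=1e-9)
        assert float(fisher_two_sided_exact(a, b, c, d)) == pytest.approx(expected, rel=1e-12)

    def test_overlapping_sets_rejected(self):
        graph = build_ontology([("t", "root")])
        prop = propagate(graph, annotations({"A": {"t"}}))
        with pytest.raises(ValueError, match="overlap"):
            fisher_enrichment({"A", "B"}, {"B", "C"}, prop)

    def test_direction_flags(self):
        graph = build_ontology([("t", "root")])
        prop = propagate(graph, annotations({f"A{i}": {"t"} for i in range(5)}))
        out = fisher_enrichment(
            {f"A{i}" for i in range(5)}, {f"B{i}" for i in range(5)}, prop
        )
        term = [o for o in out if o.term == "t"][0]
        assert term.direction == "over"
        assert (term.test_annotated, term.ref_annotated) == (5, 0)


class TestEnrichClusters:
    def _bundle(self, multiplier, seed=13):
        genes = {
            "A": [f"A{i:02d}" for i in range(30)],
            "B": [f"B{i:02d}" for i in range(30)],
        }
        sim = simulate_ontology(
            n_terms=40,
            genes=genes,
            enriched_spec=[("A", None, multiplier)],
            seed=seed,
            background_rate=0.05,
        )
        tables = [
            PredictionTable(
                program=f"p{k}", targets={"mA": set(genes["A"]), "mB": set(genes["B"])}
            )
            for k in range(3)
        ]
        voted = consensus(tables, ["mA", "mB"], min_support=3)
        assignment = ClusterAssignment(labels={"mA": "A", "mB": "B"})
        return sim, voted, assignment

    def test_planted_term_flagged_only_in_its_cluster(self):
        sim, voted, assignment = self._bundle(multiplier=12)
        results = enrich_clusters(assignment, voted, sim.graph, sim.annotations)
        planted = sim.truth.enriched_terms["A"][0]
        flagged_a = {o.term for o in results["A"] if o.significant and o.direction == "over"}
        flagged_b = {o.term for o in results["B"] if o.significant and o.direction == "over"}
        assert planted in flagged_a
        assert planted not in flagged_b

    def test_single_cluster_rejected(self):
        sim, voted, _ = self._bundle(multiplier=1)
        only_a = ClusterAssignment(labels={"mA": "A", "mB": "A"})
        with pytest.raises(ValueError, match="two clusters"):
            enrich_clusters(only_a, voted, sim.graph, sim.annotations)

    def test_zero_significance_level_flags_nothing(self):
        sim, voted, assignment = self._bundle(multiplier=12)
        results = enrich_clusters(assignment, voted, sim.graph, sim.annotations, alpha_sig=0.0)
        assert all(not o.significant for outs in results.values() for o in outs)

    def test_bh_correction_is_more_conservative(self):
        sim, voted, assignment = self._bundle(multiplier=12)
        raw = enrich_clusters(assignment, voted, sim.graph, sim.annotations)
        adj = enrich_clusters(assignment, voted, sim.graph, sim.annotations, fdr=True)
        for lab in raw:
            raw_sig = {o.term for o in raw[lab] if o.significant}
            adj_sig = {o.term for o in adj[lab] if o.significant}
            assert adj_sig <= raw_sig
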