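"""GO-slim mapping and hypergeometric enrichment."""

from itertools import combinations
from math import comb

import pytest

from tagdge.enrichment import (
    OntologyGraph,
    hypergeom_enrich,
    map_to_slim,
    nearest_slim_ancestors,
    read_gene2go,
    read_slim_terms,
)


def _graph(edges, terms=None):
    """edges: child -> parents mapping."""
    ids = set(edges)
    for ps in edges.values():
        ids |= set(ps)
    if terms:
        ids |= set(terms)
    return OntologyGraph(
        {t: {"name": t, "namespace": "biological_process"} for t in ids},
        {c: frozenset(p) for c, p in edges.items()},
    )


class TestNearestSlim:
    def test_slim_term_maps_to_itself(self):
        g = _graph({"a": ["b"]})
        assert nearest_slim_ancestors("a", g, frozenset(["a", "b"])) == {"a"}

    def test_chain_nearer_slim_shields_farther(self):
        g = _graph({"a": ["b"], "b": ["c"]})
        assert nearest_slim_ancestors("a", g, frozenset(["b", "c"])) == {"b"}

    def test_diamond_keeps_both_paths(self):
        g = _graph({"a": ["b", "c"], "b": ["d"], "c": ["d"]})
        assert nearest_slim_ancestors("a", g, frozenset(["b", "c"])) == {"b", "c"}

    def test_no_slim_ancestor_maps_to_nothing(self):
        g = _graph({"a": ["b"]})
        assert nearest_slim_ancestors("a", g, frozenset(["z"])) == frozenset()
        # (z exists in graph when declared; here mapping is simply empty)


class TestMapToSlim:
    def test_gene_union_over_annotations(self):
        g = _graph({"a": ["b"], "b": ["c"], "x": ["c"]})
        gene2go = {"g1": {"a", "x"}, "g2": {"b"}}
        mapped = map_to_slim(gene2go, g, ["b", "c"])
        assert mapped == {"g1": {"b", "c"}, "g2": {"b"}}

    def test_unknown_annotated_term_skipped(self, caplog):
        g = _graph({"a": ["b"]})
        mapped = map_to_slim({"g1": {"a", "nope"}}, g, ["b"])
        assert mapped == {"g1": {"b"}}

    def test_unknown_slim_term_rejected(self):
        g = _graph({"a": ["b"]})
        with pytest.raises(ValueError, match="slim"):
            map_to_slim({"g1": {"a"}}, g, ["missing"])

    def test_every_slim_assignment_is_an_ancestor_or_self(self):
        g = _graph(
            {
                "a": ["b", "c"],
                "b": ["d"],
                "c": ["e"],
                "d": ["root"],
                "e": ["root"],
                "f": ["d"],
            }
        )
        gene2go = {"g1": {"a"}, "g2": {"f"}, "g3": {"d"}}
        mapped = map_to_slim(gene2go, g, ["b", "d", "e"])
        for gene, slims in mapped.items():
            for s in slims:
                reachable = any(
                    s == t or s in g.ancestors(t) for t in gene2go[gene]
                )
                assert reachable


class TestOntologyGraph:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            _graph({"a": ["b"], "b": ["a"]})

    def test_obo_roundtrip(self, tmp_path):
        obo = "\n".join(
            [
                "format-version: 1.2",
                "ontology: test",
                "",
                "[Term]",
                "id: GO:0000001",
                "name: root",
                "namespace: biological_process",
                "",
                "[Term]",
                "id: GO:0000002",
                "name: child",
                "namespace: biological_process",
                "is_a: GO:0000001 ! root",
                "",
            ]
        )
        path = tmp_path / "mini.obo"
        path.write_text(obo)
        g = OntologyGraph.from_obo(str(path))
        assert g.parents_of("GO:0000002") == {"GO:0000001"}
        assert g.name("GO:0000002") == "child"
        assert g.namespace("GO:0000001") == "biological_process"

    def test_slim_and_gene2go_readers(self, tmp_path):
        slim = tmp_path / "slim.txt"
        slim.write_text("# comment\nGO:0000001\nGO:0000002 extra\n\n")
        assert read_slim_terms(slim) == ["GO:0000001", "GO:0000002"]
        g2g = tmp_path / "gene2go.tsv"
        g2g.write_text("g1\tGO:0000001\ng1\tGO:0000002\ng2\tGO:0000001\n")
        assert read_gene2go(g2g) == {
            "g1": {"GO:0000001", "GO:0000002"},
            "g2": {"GO:0000001"},
        }


class TestHypergeomEnrich:
    def test_closed_form_example(self):
        # M=10, K=5, n=4, k=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210
        gene2slim = {f"g{i}": frozenset(["t"]) for i in range(5)}
        population = [f"g{i}" for i in range(10)]
        study = ["g0", "g1", "g2", "g3"]
        res = hypergeom_enrich(study, population, gene2slim)
        assert res.loc[0, "p_value"] == pytest.approx(5 / 210, rel=1e-12)
        assert res.loc[0, "percentage"] == pytest.approx(100.0)

    def test_zero_hits_gives_p_one(self):
        gene2slim = {"g0": frozenset(["t"])}
        res = hypergeom_enrich(["g1"], ["g0", "g1"], gene2slim)
        assert res.loc[0, "p_value"] == 1.0

    def test_study_equals_population_gives_p_one(self):
        gene2slim = {f"g{i}": frozenset(["t"]) for i in range(4)}
        pop = [f"g{i}" for i in range(6)]
        res = hypergeom_enrich(pop, pop, gene2slim)
        assert res.loc[0, "study_hits"] == res.loc[0, "population_hits"]
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_study_outside_population_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["x"], ["a"], {})

    @pytest.mark.parametrize("m_total,big_k,n_study", [(8, 3, 4), (12, 5, 6), (10, 7, 3)])
    def test_matches_exhaustive_enumeration(self, m_total, big_k, n_study):
        population = [f"g{i}" for i in range(m_total)]
        gene2slim = {g: frozenset(["t"]) for g in population[:big_k]}
        # enumerate every possible study draw and compare the upper tail
        for study in combinations(population, n_study):
            k = sum(1 for g in study if g in gene2slim)
            exhaustive = sum(
                comb(big_k, j) * comb(m_total - big_k, n_study - j)
                for j in range(k, min(big_k, n_study) + 1)
            ) / comb(m_total, n_study)
            res = hypergeom_enrich(list(study), population, gene2slim)
            assert res.loc[0, "p_value"] == pytest.approx(exhaustive, rel=1e-12)

    def test_k_bounded_by_study_size(self):
        gene2slim = {f"g{i}": frozenset(["a", "b"]) for i in range(6)}
        res = hypergeom_enrich([f"g{i}" for i in range(3)], [f"g{i}" for i in range(6)], gene2slim)
        assert (res["study_hits"] <= res["study_size"]).all()
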