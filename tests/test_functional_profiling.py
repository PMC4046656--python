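import numpy as np
import pytest

from deno_profiler.functional_profiling import (
    ec_pathway_profile,
    load_default_ec_pathway_map,
    rollup_to_slim,
    term_frequencies,
)
from deno_profiler.io_formats import OntologyBundle, ProteinCatalogRecord


def random_dag(rng, n_terms, slim_size):
    """A random child->parent DAG over one namespace plus a slim sample."""
    terms = [f"T{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        for parent in rng.choice(i, size=min(int(rng.integers(1, 3)), i), replace=False):
            rel = "is_a" if rng.random() < 0.8 else "part_of"
            edges.append((terms[i], terms[int(parent)], rel))
    slim = {terms[int(i)] for i in rng.choice(n_terms, size=slim_size, replace=False)}
    bundle = OntologyBundle({t: "biological_process" for t in terms},
                            {t: t for t in terms}, edges, frozenset(slim))
    bundle.validate()
    return bundle


def brute_force_ancestors(bundle, term):
    parents = {}
    for child, parent, rel in bundle.edges:
        if rel in ("is_a", "part_of"):
            parents.setdefault(child, set()).add(parent)
    seen, stack = {term}, [term]
    while stack:
        for p in parents.get(stack.pop(), ()):
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return seen


class TestRollupToSlim:
    def test_slim_term_maps_to_itself(self, chain_ontology):
        assert rollup_to_slim("b", chain_ontology) == {"b"}

    def test_chain_reaches_slim_ancestor(self, chain_ontology):
        assert rollup_to_slim("t", chain_ontology) == {"b"}

    def test_disconnected_term_rolls_to_nothing(self):
        bundle = OntologyBundle(
            {"x": "biological_process", "b": "biological_process"},
            {"x": "x", "b": "b"}, [], frozenset({"b"}),
        )
        assert rollup_to_slim("x", bundle) == set()

    def test_unknown_term_is_fatal(self, chain_ontology):
        with pytest.raises(KeyError):
            rollup_to_slim("nope", chain_ontology)

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(10):
            bundle = random_dag(rng, 60, 8)
            for term in bundle.terms:
                expected = brute_force_ancestors(bundle, term) & bundle.slim_set
                assert rollup_to_slim(term, bundle) == expected

    def test_enlarging_slim_never_shrinks_rollup(self, rng):
        bundle = random_dag(rng, 60, 5)
        bigger = OntologyBundle(bundle.namespace_of, bundle.name_of, bundle.edges,
                                frozenset(set(bundle.slim_set) | {"T000", "T030"}))
        for term in bundle.terms:
            assert rollup_to_slim(term, bundle) <= rollup_to_slim(term, bigger)

    def test_nearest_only_keeps_minimum_distance_slims(self):
        # diamond: t -> a -> b(root); slim {a, b}: nearest keeps a only
        bundle = OntologyBundle(
            {t: "biological_process" for t in ("t", "a", "b")},
            {t: t for t in ("t", "a", "b")},
            [("t", "a", "is_a"), ("a", "b", "is_a")],
            frozenset({"a", "b"}),
        )
        assert rollup_to_slim("t", bundle) == {"a", "b"}
        assert rollup_to_slim("t", bundle, nearest_only=True) == {"a"}


class TestTermFrequencies:
    def test_gene_contributes_once_per_term(self, chain_ontology):
        # both specific terms roll up to the same slim term
        annotations = {"g1": {"t", "a"}}
        table = term_frequencies({"set1": {"g1"}}, annotations, chain_ontology, use_slim=True)
        assert table.loc[table.term == "b", "set1"].tolist() == [1]

    def test_empty_gene_set(self, chain_ontology):
        table = term_frequencies({"set1": set()}, {}, chain_ontology)
        assert table.empty

    def test_matches_bruteforce_tally(self, rng):
        bundle = random_dag(rng, 40, 6)
        terms = sorted(bundle.terms)
        genes = [f"g{i}" for i in range(30)]
        annotations = {
            g: {terms[int(i)] for i in rng.choice(len(terms), size=rng.integers(1, 5), replace=False)}
            for g in genes
        }
        set_a, set_b = set(genes[:15]), set(genes[15:])
        table = term_frequencies({"A": set_a, "B": set_b}, annotations, bundle)
        for _, row in table.iterrows():
            assert row["A"] == sum(1 for g in set_a if row["term"] in annotations[g])
            assert row["B"] == sum(1 for g in set_b if row["term"] in annotations[g])

    def test_adding_annotation_never_decreases_counts(self, rng):
        bundle = random_dag(rng, 30, 4)
        terms = sorted(bundle.terms)
        annotations = {"g1": {terms[0]}, "g2": {terms[1]}}
        before = term_frequencies({"A": {"g1", "g2"}}, annotations, bundle, use_slim=True)
        annotations["g1"] = annotations["g1"] | {terms[2]}
        after = term_frequencies({"A": {"g1", "g2"}}, annotations, bundle, use_slim=True)
        before_counts = dict(zip(before.term, before.A))
        after_counts = dict(zip(after.term, after.A))
        for term, count in before_counts.items():
            assert after_counts.get(term, 0) >= count


class TestEcPathwayProfile:
    def test_worked_starch_sucrose_example(self):
        catalog = {
            "U1": ProteinCatalogRecord("U1", 100, "Beta-fructofuranosidase",
                                       ec_codes=frozenset({"3.2.1.26"})),
            "U2": ProteinCatalogRecord("U2", 100, "Sucrose synthase",
                                       ec_codes=frozenset({"2.4.1.13"})),
        }
        profile = ec_pathway_profile({"U1", "U2"}, catalog, load_default_ec_pathway_map())
        assert profile.enzyme_counts["Starch and sucrose metabolism"] == 2

    def test_no_degs_gives_empty_profile(self):
        assert ec_pathway_profile(set(), {}, load_default_ec_pathway_map()).ec_sets == {}

    def test_malformed_ec_in_map_is_fatal(self):
        with pytest.raises(ValueError, match="EC"):
            ec_pathway_profile(set(), {}, [("not-an-ec", "Pathway")])

    def test_matches_bruteforce_join_and_count(self, rng):
        ecs = [f"{a}.{b}.{c}.{d}" for a in (1, 2) for b in (1, 2) for c in (1, 2) for d in (1, 2)]
        pathways = [f"pw{i}" for i in range(5)]
        mapping = [(ec, pathways[int(rng.integers(5))]) for ec in ecs for _ in range(rng.integers(1, 3))]
        catalog = {
            f"U{i}": ProteinCatalogRecord(
                f"U{i}", 100, "enzyme",
                ec_codes=frozenset(ecs[int(j)] for j in rng.choice(len(ecs), size=rng.integers(0, 4), replace=False)),
            )
            for i in range(20)
        }
        degs = {f"U{i}" for i in range(10)}
        profile = ec_pathway_profile(degs, catalog, mapping)
        deg_ecs = set().union(*(catalog[u].ec_codes for u in degs))
        expected = {}
        for ec, pw in mapping:
            if ec in deg_ecs:
                expected.setdefault(pw, set()).add(ec)
        assert {p: set(s) for p, s in profile.ec_sets.items()} == expected

    def test_frame_sorted_by_enzyme_count(self):
        catalog = {"U1": ProteinCatalogRecord("U1", 100, "x",
                                              ec_codes=frozenset({"1.1.1.1", "2.2.2.2"}))}
        mapping = [("1.1.1.1", "pwA"), ("2.2.2.2", "pwA"), ("1.1.1.1", "pwB")]
        frame = ec_pathway_profile({"U1"}, catalog, mapping).to_frame()
        assert frame.pathway.tolist() == ["pwA", "pwB"]
        assert frame.enzyme_count.tolist() == [2, 1]
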