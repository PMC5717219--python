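"""Clone merging, ancestry constraints and phylogeny enumeration."""

import itertools

import numpy as np
import pytest

from themis.phylogeny import (
    ROOT,
    CloneProfile,
    PhylogenyTree,
    clone_similarity,
    containment_constraints,
    detect_intermediates,
    enumerate_phylogenies,
    infer_ancestry_constraints,
)


def profile(cid, units=None, snvs=(), prev=None, eprev=None):
    return CloneProfile(
        clone_id=cid,
        cna_units=dict(units or {}),
        snv_sites=frozenset(snvs),
        prevalence_by_biopsy=dict(prev or {}),
        event_prevalence_by_biopsy=dict(eprev or prev or {}),
    )


# ---------------------------------------------------------------------------
# Brute-force tree enumeration oracle (independent of the implementation)

def oracle_enumerate(ids, constraints):
    """All rooted trees by checking every parent map with direct ancestor walks."""
    trees = []
    for combo in itertools.product(*[[ROOT] + [o for o in ids if o != c]
                                     for c in ids]):
        parent = dict(zip(ids, combo))

        def ancestors(n):
            seen = []
            while parent.get(n, ROOT) != ROOT:
                n = parent[n]
                if n in seen:
                    return None  # cycle
                seen.append(n)
            return seen

        anc = {n: ancestors(n) for n in ids}
        if any(v is None for v in anc.values()):
            continue
        if all(a in anc[b] for a, b in constraints):
            trees.append(frozenset(parent.items()))
    return set(trees)


class TestSimilarity:
    def test_identical_profiles(self):
        a = profile("a", {("c1", 10): (3, 1)}, [("c1", 99)])
        b = profile("b", {("c1", 10): (3, 1)}, [("c1", 99)])
        assert clone_similarity(a, b) == 1.0

    def test_disjoint_profiles(self):
        a = profile("a", {("c1", 10): (3, 1)})
        b = profile("b", {("c2", 10): (1, 0)})
        assert clone_similarity(a, b) == 0.0

    def test_partial_overlap_set_arithmetic(self):
        a = profile("a", {("c1", 1): (3, 1), ("c1", 2): (1, 0)})
        b = profile("b", {("c1", 1): (3, 1), ("c1", 3): (1, 0)})
        assert clone_similarity(a, b) == pytest.approx(1 / 3)

    def test_same_unit_different_genotype_not_shared(self):
        a = profile("a", {("c1", 1): (3, 1)})
        b = profile("b", {("c1", 1): (1, 0)})
        assert clone_similarity(a, b) == 0.0


class TestAncestryConstraints:
    def test_rule_instantiated(self):
        a = profile("a", prev={0: 0.7})
        b = profile("b", prev={0: 0.5})
        assert infer_ancestry_constraints([a, b]) == {("a", "b")}

    def test_no_constraint_when_sum_below_one(self):
        a = profile("a", prev={0: 0.5})
        b = profile("b", prev={0: 0.4})
        assert infer_ancestry_constraints([a, b]) == set()

    def test_strict_inequality_boundary(self):
        a = profile("a", prev={0: 0.6})
        b = profile("b", prev={0: 0.6})
        assert infer_ancestry_constraints([a, b]) == set()

    def test_dominance_must_hold_everywhere(self):
        a = profile("a", prev={0: 0.7, 1: 0.3})
        b = profile("b", prev={0: 0.5, 1: 0.4})
        assert infer_ancestry_constraints([a, b]) == set()

    def test_containment_is_separate_and_directional(self):
        small = profile("s", {("c1", i): (1, 0) for i in range(5)})
        big = profile("b", {("c1", i): (1, 0) for i in range(12)})
        assert containment_constraints([small, big]) == {("s", "b")}


class TestIntermediates:
    def test_shared_split_creates_intermediate(self):
        shared = {("c1", i): (1, 0) for i in range(8)}
        a = profile("a", {**shared, **{("c2", i): (3, 1) for i in range(8)}})
        b = profile("b", {**shared, **{("c3", i): (1, 1) for i in range(8)}})
        nodes, cons = detect_intermediates([a, b])
        assert len(nodes) == 1
        inter = nodes[0]
        assert set(inter.cna_units) == set(shared)
        assert (inter.clone_id, "a") in cons and (inter.clone_id, "b") in cons

    def test_no_intermediate_for_containment(self):
        small = profile("a", {("c1", i): (1, 0) for i in range(8)})
        big = profile("b", {("c1", i): (1, 0) for i in range(16)})
        nodes, cons = detect_intermediates([small, big])
        assert nodes == []


class TestEnumeration:
    def test_two_clones_no_constraints_gives_three_trees(self):
        clones = [profile("A"), profile("B")]
        trees = enumerate_phylogenies(clones, set())
        assert len(trees) == 3
        parents = {frozenset(t.parent.items()) for t in trees}
        assert parents == {
            frozenset({("A", ROOT), ("B", ROOT)}),
            frozenset({("A", ROOT), ("B", "A")}),
            frozenset({("B", ROOT), ("A", "B")}),
        }

    def test_single_constraint_forces_chain(self):
        clones = [profile("A"), profile("B")]
        trees = enumerate_phylogenies(clones, {("A", "B")})
        assert len(trees) == 1
        assert trees[0].parent == {"A": ROOT, "B": "A"}

    def test_chain_constraints_force_single_tree(self):
        clones = [profile(c) for c in "ABC"]
        trees = enumerate_phylogenies(clones, {("A", "B"), ("B", "C")})
        assert len(trees) == 1
        assert trees[0].parent == {"A": ROOT, "B": "A", "C": "B"}

    @pytest.mark.parametrize("n_clones", [2, 3])
    def test_matches_brute_force_for_random_constraints(self, rng, n_clones):
        ids = [chr(65 + i) for i in range(n_clones)]
        for _ in range(20):
            cons = set()
            for a, b in itertools.permutations(ids, 2):
                if rng.random() < 0.3 and (b, a) not in cons:
                    cons.add((a, b))
            import networkx as nx

            if not nx.is_directed_acyclic_graph(nx.DiGraph(cons)):
                continue
            got = {frozenset(t.parent.items())
                   for t in enumerate_phylogenies([profile(i) for i in ids], cons)}
            assert got == oracle_enumerate(ids, cons)

    def test_every_emitted_tree_satisfies_every_constraint(self, rng):
        ids = list("ABCD")
        cons = {("A", "C"), ("B", "D")}
        trees = enumerate_phylogenies([profile(i) for i in ids], cons)
        assert trees
        for t in trees:
            for a, b in cons:
                assert t.is_ancestor(a, b)

    def test_cyclic_constraints_rejected(self):
        with pytest.raises(ValueError):
            enumerate_phylogenies([profile("A"), profile("B")],
                                  {("A", "B"), ("B", "A")})


class TestTreeStructure:
    def make_tree(self):
        # the branching clone history: A -> B -> CD -> {C, D}
        t = PhylogenyTree(parent={"A": ROOT, "B": "A", "CD": "B",
                                  "C": "CD", "D": "CD"})
        t.prevalences = {
            "A": {0: 0.40}, "B": {0: 0.35}, "CD": {}, "C": {}, "D": {},
        }
        return t

    def test_effective_prevalence_is_subtree_sum(self):
        t = self.make_tree()
        # events on the root-adjacent edge are carried by the whole tumor:
        # 0.40 + 0.35 = 0.75 in this biopsy
        assert t.effective_prevalence("A", 0) == pytest.approx(0.75)
        assert t.effective_prevalence("B", 0) == pytest.approx(0.35)
        assert t.effective_prevalence("C", 0) == 0.0

    def test_newick_round_trips_through_independent_parser(self, tmp_path):
        import dendropy

        t = self.make_tree()
        nwk = t.to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        labels = {l.taxon.label if l.taxon else l.label
                  for l in tree.leaf_node_iter()}
        assert {"C", "D"} <= {str(x).split("[")[0] for x in labels}
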