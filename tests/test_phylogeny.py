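import itertools

import numpy as np
import pytest

from clonevo.phylogeny import (
    SubcloneTree,
    all_rooted_trees,
    classify_topology,
    enumerate_trees,
    precedence_matrix,
    precedence_test,
    to_dot,
    to_newick,
    tree_cost,
)

TIGHT = [0.01, 0.01, 0.01]


class TestPrecedenceTest:
    def test_strict_dominance(self):
        i, j = [1, 1, 1], [0.4, 0.3, 0.2]
        assert precedence_test(i, TIGHT, j, TIGHT)
        assert not precedence_test(j, TIGHT, i, TIGHT)

    def test_crossing_prevalences_forces_branching(self):
        i, j = [0.5, 0.1, 0.3], [0.1, 0.5, 0.3]
        assert not precedence_test(i, TIGHT, j, TIGHT)
        assert not precedence_test(j, TIGHT, i, TIGHT)

    def test_identical_means_indistinguishable(self):
        m = [0.4, 0.4, 0.4]
        assert precedence_test(m, TIGHT, m, TIGHT)
        assert precedence_test(m, TIGHT, m, TIGHT)


def brute_force_trees(ids, prevalence, may_parent, sum_tol=0.10):
    """Independent enumeration: all parent functions, cycle-checked, rescored."""
    root, rest = ids[0], ids[1:]
    results = []
    for parents in itertools.product(ids, repeat=len(rest)):
        pmap = dict(zip(rest, parents))
        pmap[root] = None
        # acyclicity: walk up from every node
        ok = True
        for node in rest:
            seen, cur = set(), node
            while cur is not None:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = pmap[cur]
            if not ok:
                break
        if not ok:
            continue
        tree = SubcloneTree(parents=pmap, prevalence=prevalence, cost=0, root=root)
        tree.cost = tree_cost(tree, may_parent, sum_tol)
        results.append(tree)
    return results


class TestEnumerateTrees:
    def test_tree_count_matches_cayley(self):
        for n in range(2, 7):
            assert len(all_rooted_trees(n)) == n ** (n - 2)

    def test_nested_clusters_minimal_set_matches_brute_force(self):
        """Nested prevalences: exhaustive search agrees with an independent
        parent-function enumeration, and the chain is among the minima."""
        means = {"A": [1, 1, 1], "B": [0.6, 0.5, 0.7], "C": [0.2, 0.1, 0.3]}
        sds = {k: TIGHT for k in means}
        trees = enumerate_trees(means, sds)
        assert trees[0].cost == 0
        prevalence = {k: np.array(v, float) for k, v in means.items()}
        prevalence["root"] = np.ones(3)
        may = precedence_matrix(
            {**{k: np.array(v) for k, v in means.items()}, "root": np.ones(3)},
            {**{k: np.array(TIGHT) for k in means}, "root": np.zeros(3)},
        )
        brute = brute_force_trees(["root", "A", "B", "C"], prevalence, may)
        best = min(t.cost for t in brute)
        brute_minimal = {tuple(sorted((k, str(v)) for k, v in t.parents.items()))
                         for t in brute if t.cost == best}
        got = {tuple(sorted((k, str(v)) for k, v in t.parents.items())) for t in trees}
        assert got == brute_minimal
        chain = {"root": None, "A": "root", "B": "A", "C": "B"}
        assert any(t.parents == chain for t in trees)

    def test_sum_rule_violation_counted(self):
        """Siblings summing to 1.15 under a parent at 1.0 violate one region."""
        means = {"A": [0.65, 0.1, 0.1], "B": [0.5, 0.1, 0.1]}
        tree = SubcloneTree(
            parents={"root": None, "A": "root", "B": "root"},
            prevalence={"root": np.ones(3), "A": np.array(means["A"]),
                        "B": np.array(means["B"])},
            cost=0,
        )
        may = precedence_matrix(
            {"root": np.ones(3), **{k: np.array(v) for k, v in means.items()}},
            {"root": np.zeros(3), **{k: np.array(TIGHT) for k in means}},
        )
        assert tree_cost(tree, may, sum_tol=0.10) == 1  # only region 0: 1.15 > 1.10
        assert tree_cost(tree, may, sum_tol=0.20) == 0

    def test_single_cluster(self):
        trees = enumerate_trees({"A": [0.5, 0.5]}, {"A": [0.02, 0.02]})
        assert len(trees) == 1
        assert trees[0].parents == {"root": None, "A": "root"}
        assert trees[0].cost == 0

    def test_relabeling_invariance(self):
        means = {"X": [0.8, 0.7, 0.9], "Y": [0.4, 0.3, 0.5], "Z": [0.1, 0.05, 0.2]}
        sds = {k: TIGHT for k in means}
        trees_a = enumerate_trees(means, sds)
        mapping = {"X": "P", "Y": "Q", "Z": "R"}
        trees_b = enumerate_trees(
            {mapping[k]: v for k, v in means.items()},
            {mapping[k]: v for k, v in sds.items()},
        )
        relabel = {**mapping, "root": "root"}
        set_a = {
            frozenset((relabel[c], relabel[p] if p else None) for c, p in t.parents.items())
            for t in trees_a
        }
        set_b = {
            frozenset((c, p) for c, p in t.parents.items()) for t in trees_b
        }
        assert set_a == set_b

    def test_cost_recount_matches_on_every_returned_tree(self, rng):
        for trial in range(10):
            k = int(rng.integers(2, 6))
            means = {f"C{i}": rng.uniform(0, 1, 3) for i in range(k)}
            sds = {f"C{i}": rng.uniform(0.01, 0.1, 3) for i in range(k)}
            trees = enumerate_trees(means, sds)
            may = precedence_matrix(
                {**means, "root": np.ones(3)},
                {**sds, "root": np.zeros(3)},
            )
            for t in trees[:50]:
                assert tree_cost(t, may) == t.cost

    def test_too_many_clusters_rejected(self):
        means = {f"C{i}": [0.5] for i in range(9)}
        sds = {f"C{i}": [0.02] for i in range(9)}
        with pytest.raises(ValueError, match="reduce"):
            enumerate_trees(means, sds)

    def test_strictly_nested_zero_noise_chain_is_minimal(self, rng):
        """Noise-free nested prevalences always admit the chain at cost 0."""
        for _ in range(5):
            k = int(rng.integers(2, 6))
            vals = np.sort(rng.uniform(0.05, 0.95, size=(k, 3)), axis=0)[::-1]
            means = {f"C{i}": vals[i] for i in range(k)}
            sds = {f"C{i}": np.zeros(3) for i in range(k)}
            trees = enumerate_trees(means, sds)
            assert trees[0].cost == 0
            chain = {"root": None, "C0": "root"}
            chain.update({f"C{i}": f"C{i-1}" for i in range(1, k)})
            assert any(t.parents == chain for t in trees)


class TestClassifyTopology:
    def test_chain_is_linear(self):
        tree = SubcloneTree(
            parents={"root": None, "A": "root", "B": "A"},
            prevalence={"root": np.ones(3), "A": np.full(3, 0.8), "B": np.full(3, 0.3)},
            cost=0,
        )
        assert classify_topology(tree) == ("linear", False)

    def test_two_children_is_branched(self):
        tree = SubcloneTree(
            parents={"root": None, "A": "root", "B": "root"},
            prevalence={"root": np.ones(3), "A": np.full(3, 0.6), "B": np.full(3, 0.3)},
            cost=0,
        )
        topo, sync = classify_topology(tree)
        assert topo == "branched"
        assert not sync  # cluster A is high everywhere -> one primary

    def test_disjoint_lineages_flag_synchronous_primaries(self):
        tree = SubcloneTree(
            parents={"root": None, "A": "root", "B": "root"},
            prevalence={
                "root": np.ones(3),
                "A": np.array([0.8, 0.2, 0.0]),
                "B": np.array([0.0, 0.3, 0.9]),
            },
            cost=0,
        )
        assert classify_topology(tree) == ("branched", True)


def test_newick_and_dot_render():
    tree = SubcloneTree(
        parents={"root": None, "A": "root", "B": "A"},
        prevalence={"root": np.ones(2), "A": np.full(2, 0.7), "B": np.full(2, 0.2)},
        cost=0,
    )
    nwk = to_newick(tree)
    assert nwk == "((B)A)root;[cost=0]"
    dot = to_dot(tree)
    assert '"A" -> "B"' in dot and dot.startswith("digraph")
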