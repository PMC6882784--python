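"""Subclone hierarchy reconstruction from cluster prevalences.

Under the infinite sites assumption, a mutation cluster's ancestors carry
at least its cancer cell prevalence in every tumor region.  Each ordered
pair of clusters is tested for compatible temporal ordering (a one-sided
z criterion per region: ancestry is rejected when the candidate child's
mean prevalence exceeds the candidate parent's by more than
``z(alpha) * pooled sd`` in any region).  Every rooted labeled tree over
the clusters — the root is the knock-in transgene cluster, added when
absent, with prevalence fixed at 1 — is then scored by the number of
parent-child precedence violations plus the number of region-wise sum-rule
violations (children prevalences summing above the parent's), and all
minimal-cost trees are returned.  Exhaustive enumeration (n^(n-2) rooted
labeled trees via Prüfer sequences) is exact at this scale of 2-7 mutation
clusters per tumor.

Topology is linear when every node has at most one child, branched
otherwise; two synchronous primary tumors are flagged when the root has
two or more children and no cluster is at high prevalence in all analyzed
regions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

__all__ = [
    "SubcloneTree",
    "precedence_test",
    "precedence_matrix",
    "enumerate_trees",
    "classify_topology",
    "tree_cost",
    "to_newick",
    "to_dot",
]

ROOT = "root"
SD_FLOOR = 0.02
MAX_CLUSTERS = 8

_TREE_CACHE: dict[int, np.ndarray] = {}


# ---------------------------------------------------------------------------
# precedence testing


def precedence_test(mean_i, sd_i, mean_j, sd_j, alpha: float = 0.05) -> bool:
    """May cluster i be an ancestor of cluster j?

    Returns False when, in any region, j's mean prevalence exceeds i's by
    more than ``z(1-alpha)`` pooled standard deviations (one-sided
    violation).  Standard deviations are floored at 0.02 so that clusters
    with few members are not spuriously ordered.
    """
    mi, mj = np.asarray(mean_i, float), np.asarray(mean_j, float)
    si = np.maximum(np.asarray(sd_i, float), SD_FLOOR)
    sj = np.maximum(np.asarray(sd_j, float), SD_FLOOR)
    z = stats.norm.ppf(1 - alpha)
    pooled = np.sqrt(si**2 + sj**2)
    ok = ~np.any(mj - mi > z * pooled)
    return bool(ok)


def precedence_matrix(means: dict, sds: dict, alpha: float = 0.05) -> dict:
    """Pairwise ``may_parent[i][j]`` over all ordered cluster pairs."""
    ids = list(means)
    return {
        i: {j: (i == j) or precedence_test(means[i], sds[i], means[j], sds[j], alpha) for j in ids}
        for i in ids
    }


# ---------------------------------------------------------------------------
# exhaustive enumeration of rooted labeled trees


def _decode_pruefer(seq: tuple, n: int) -> list[tuple[int, int]]:
    """Prüfer sequence -> edge list on nodes 0..n-1 (standard decoding)."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for v in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u = heapq.heappop(leaves)
    w = heapq.heappop(leaves)
    edges.append((u, w))
    return edges


def _orient(edges, n) -> list[int]:
    """Orient an undirected tree away from node 0 -> parent vector."""
    adj = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    parent = [-1] * n
    stack = [0]
    seen = [False] * n
    seen[0] = True
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                stack.append(v)
    return parent


def all_rooted_trees(n: int) -> np.ndarray:
    """All parent vectors of rooted labeled trees on n nodes with root 0.

    Shape (n^(n-2), n); entry [t, v] is the parent of node v in tree t
    (-1 for the root).  Cached per n.
    """
    if n in _TREE_CACHE:
        return _TREE_CACHE[n]
    if n == 1:
        out = np.full((1, 1), -1, dtype=np.int8)
    elif n == 2:
        out = np.array([[-1, 0]], dtype=np.int8)
    else:
        vecs = [
            _orient(_decode_pruefer(seq, n), n)
            for seq in product(range(n), repeat=n - 2)
        ]
        out = np.array(vecs, dtype=np.int8)
    _TREE_CACHE[n] = out
    return out


def _score_trees(parents: np.ndarray, prev: np.ndarray, viol: np.ndarray, sum_tol: float):
    """Vectorized cost of every tree: precedence + sum-rule violations."""
    n_trees, n = parents.shape
    cost = np.zeros(n_trees, dtype=np.int32)
    for c in range(1, n):
        cost += viol[parents[:, c], c]
    n_regions = prev.shape[1]
    tree_idx = np.arange(n_trees)[:, None]
    for r in range(n_regions):
        child_prev = prev[1:, r]
        S = np.zeros((n_trees, n), dtype=np.float64)
        np.add.at(S, (tree_idx, parents[:, 1:]), child_prev[None, :])
        cost += (S > prev[:, r][None, :] + sum_tol).sum(axis=1).astype(np.int32)
    return cost


@dataclass
class SubcloneTree:
    """A rooted subclone hierarchy with its violation cost."""

    parents: dict  # node id -> parent id (None for root)
    prevalence: dict  # node id -> per-region prevalence array
    cost: int
    topology: str | None = None
    synchronous_primary: bool = False
    root: str | int = ROOT

    def children(self, node):
        return sorted(
            (c for c, p in self.parents.items() if p == node), key=str
        )


def tree_cost(tree: SubcloneTree, may_parent: dict, sum_tol: float = 0.10) -> int:
    """Independent recount of a tree's precedence + sum-rule violations."""
    cost = 0
    for child, parent in tree.parents.items():
        if parent is None:
            continue
        if not may_parent[parent][child]:
            cost += 1
    n_regions = len(next(iter(tree.prevalence.values())))
    for node in tree.parents:
        kids = tree.children(node)
        if not kids:
            continue
        for r in range(n_regions):
            if sum(tree.prevalence[k][r] for k in kids) > tree.prevalence[node][r] + sum_tol:
                cost += 1
    return cost


def enumerate_trees(
    means: dict,
    sds: dict,
    alpha: float = 0.05,
    sum_tol: float = 0.10,
    root_id=ROOT,
) -> list[SubcloneTree]:
    """Score every rooted tree over the clusters; return the minimal-cost set.

    ``means``/``sds`` map cluster id to per-region arrays.  A root cluster
    with prevalence 1.0 everywhere is added when ``root_id`` is absent
    (the knock-in transgene cluster common to all cancer cells).  Output
    order is deterministic (lexicographic in the parent vector).
    """
    means = dict(means)
    sds = dict(sds)
    n_regions = len(np.atleast_1d(next(iter(means.values()))))
    if root_id not in means:
        means[root_id] = np.ones(n_regions)
        sds[root_id] = np.zeros(n_regions)
    cluster_ids = [root_id] + sorted((i for i in means if i != root_id), key=str)
    n = len(cluster_ids)
    if n - 1 > MAX_CLUSTERS:
        raise ValueError(
            f"{n - 1} clusters exceeds the exhaustive-search limit of "
            f"{MAX_CLUSTERS}; reduce the number of clusters"
        )
    may = precedence_matrix(means, sds, alpha)
    prev = np.array([np.atleast_1d(np.asarray(means[i], float)) for i in cluster_ids])
    viol = np.array(
        [[0 if may[pi][ci] else 1 for ci in cluster_ids] for pi in cluster_ids],
        dtype=np.int32,
    )
    parents = all_rooted_trees(n)
    cost = _score_trees(parents, prev, viol, sum_tol)
    best = int(cost.min())
    sel = np.flatnonzero(cost == best)
    order = np.lexsort(parents[sel].T[::-1])
    trees = []
    for t in sel[order]:
        pv = parents[t]
        pmap = {
            cluster_ids[v]: (None if pv[v] < 0 else cluster_ids[pv[v]]) for v in range(n)
        }
        trees.append(
            SubcloneTree(
                parents=pmap,
                prevalence={cluster_ids[v]: prev[v] for v in range(n)},
                cost=best,
                root=root_id,
            )
        )
    return trees


# ---------------------------------------------------------------------------
# topology classification and output formats


def classify_topology(
    tree: SubcloneTree, high_prevalence: float = 0.5
) -> tuple[str, bool]:
    """Classify a minimal-cost tree as linear or branched.

    A tree is linear when every node has at most one child.  The
    synchronous-primary flag is set when the root has two or more children
    and no non-root cluster is at high prevalence (>= ``high_prevalence``)
    in every analyzed region — the signature of two independently
    initiated tumors with no shared clonal expansion.
    """
    linear = all(len(tree.children(node)) <= 1 for node in tree.parents)
    topology = "linear" if linear else "branched"
    no_ubiquitous_clone = not any(
        np.all(np.asarray(tree.prevalence[node]) >= high_prevalence)
        for node in tree.parents
        if node != tree.root
    )
    sync = len(tree.children(tree.root)) >= 2 and no_ubiquitous_clone
    tree.topology = topology
    tree.synchronous_primary = sync
    return topology, sync


def to_newick(tree: SubcloneTree) -> str:
    """Newick string with cluster ids as labels and the cost as a comment."""

    def fmt(node):
        kids = tree.children(node)
        label = str(node)
        if not kids:
            return label
        return "(" + ",".join(fmt(k) for k in kids) + ")" + label

    return f"{fmt(tree.root)};[cost={tree.cost}]"


def to_dot(tree: SubcloneTree) -> str:
    """GraphViz DOT rendering of the hierarchy with prevalence labels."""
    lines = ["digraph subclones {", "  node [shape=box];"]
    for node in sorted(tree.parents, key=str):
        prev = ",".join(f"{v:.2f}" for v in np.atleast_1d(tree.prevalence[node]))
        lines.append(f'  "{node}" [label="{node}\\n[{prev}]"];')
    for child, parent in sorted(tree.parents.items(), key=lambda kv: str(kv[0])):
        if parent is not None:
            lines.append(f'  "{parent}" -> "{child}";')
    lines.append("}")
    return "\n".join(lines)
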