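"""Greedy phylogenetic-diversity (PD) downsampling with per-group caps.

PD of a leaf subset is the total branch length of the minimal connected
subtree spanning it (unrooted convention: the root edge is never
charged; a singleton subset has PD 0). Greedy selection — start from
the most distant leaf pair, then repeatedly add the leaf with the
largest PD increment — attains the optimal PD for every subset size
(greedy optimality of PD on trees), and is how large sequence sets are
reduced to a fixed budget while retaining diversity.

Group-level downsampling mirrors atlas practice: a per-group cap k
(e.g. non-exempt eukaryotes to 1000, each prokaryote family tree to
100) with named groups exempt from reduction.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import dendropy

from .formats_io import ProteinDB

logger = logging.getLogger("tiratlas")


@dataclass
class SelectionResult:
    kept_ids: list[str]
    pd_score: float


def _adjacency(tree: dendropy.Tree):
    """Undirected adjacency over dendropy nodes: id(node) -> list of
    (neighbor_node, edge_length). Root edges of length None count as 0."""
    adj: dict[int, list] = {}
    nodes: dict[int, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        for ch in node.child_nodes():
            ln = ch.edge.length or 0.0
            adj[id(node)].append((ch, ln))
            adj.setdefault(id(ch), []).append((node, ln))
    return adj, nodes


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {lf.taxon.label: lf for lf in tree.leaf_node_iter()}


def _distances_from(adj, start: dendropy.Node):
    """Distances and predecessor pointers from ``start`` over the
    undirected tree (iterative DFS)."""
    dist = {id(start): 0.0}
    parent = {id(start): None}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb, ln in adj[id(node)]:
            if id(nb) not in dist:
                dist[id(nb)] = dist[id(node)] + ln
                parent[id(nb)] = node
                stack.append(nb)
    return dist, parent


def phylogenetic_diversity(tree: dendropy.Tree, leaf_subset) -> float:
    """Sum of branch lengths of the minimal subtree spanning the subset.

    Unrooted convention: an edge counts iff selected leaves occur on
    both of its sides; a singleton subset scores 0.
    """
    subset = set(leaf_subset)
    if not subset:
        raise ValueError("leaf subset must be non-empty")
    leaves = _leaf_map(tree)
    unknown = subset - leaves.keys()
    if unknown:
        raise ValueError(f"unknown leaf ids: {sorted(unknown)}")
    if len(subset) == 1:
        return 0.0
    n_sel = len(subset)
    below: dict[int, int] = {}
    total = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = 1 if node.taxon.label in subset else 0
        else:
            below[id(node)] = sum(below[id(ch)] for ch in node.child_nodes())
        if node.parent_node is not None and 0 < below[id(node)] < n_sel:
            total += node.edge.length or 0.0
    return total


def max_distance_pair(tree: dendropy.Tree) -> tuple[str, str, float]:
    """A leaf pair of maximal path distance (tree diameter), found by the
    double-sweep; ties within each sweep break to the lexicographically
    smaller leaf id."""
    adj, _ = _adjacency(tree)
    leaves = _leaf_map(tree)
    first = leaves[min(leaves)]
    dist, _ = _distances_from(adj, first)
    a = min(leaves, key=lambda name: (-dist[id(leaves[name])], name))
    dist_a, _ = _distances_from(adj, leaves[a])
    b = min(
        (name for name in leaves if name != a),
        key=lambda name: (-dist_a[id(leaves[name])], name),
    )
    x, y = sorted((a, b))
    return x, y, dist_a[id(leaves[b])]


def greedy_max_pd(tree: dendropy.Tree, k: int) -> SelectionResult:
    """Greedy maximum-PD subset of size k.

    Initialized with a leaf pair of maximal path distance; each step
    adds the leaf with the largest PD increment (its distance to the
    current spanning subtree), ties broken by lexicographic leaf id.
    For PD this greedy attains the optimum over all size-k subsets.
    """
    leaves = _leaf_map(tree)
    n = len(leaves)
    if n >= 2 and k < 2:
        raise ValueError("k must be >= 2 when the tree has >= 2 leaves")
    if k >= n:
        ids = sorted(leaves)
        return SelectionResult(ids, phylogenetic_diversity(tree, ids))

    adj, _ = _adjacency(tree)
    a0, b0, diameter = max_distance_pair(tree)
    # orient the walk toward a0: with the traversal rooted at a selected
    # leaf, the spanning subtree always contains the root, so each leaf's
    # path to the subtree climbs only through its predecessors
    _, pred = _distances_from(adj, leaves[a0])
    edge_len = {}
    for nid, nbs in adj.items():
        for nb, ln in nbs:
            edge_len[(nid, id(nb))] = ln

    in_sub: set[int] = set()

    def absorb(leaf_name: str) -> None:
        node = leaves[leaf_name]
        while node is not None and id(node) not in in_sub:
            in_sub.add(id(node))
            node = pred[id(node)]

    def gain(leaf_name: str) -> float:
        g = 0.0
        node = leaves[leaf_name]
        while id(node) not in in_sub:
            up = pred[id(node)]
            g += edge_len[(id(node), id(up))]
            node = up
        return g

    in_sub.add(id(leaves[a0]))
    absorb(b0)
    selected = [a0, b0]
    pd_score = diameter

    heap = [(-gain(name), name) for name in sorted(leaves) if name not in (a0, b0)]
    heapq.heapify(heap)
    while len(selected) < k:
        neg_g, name = heapq.heappop(heap)
        g = gain(name)  # may have shrunk since pushed
        if heap and (-g, name) > heap[0]:
            # no longer the best under the (gain, id) order; requeue
            heapq.heappush(heap, (-g, name))
            continue
        selected.append(name)
        pd_score += g
        absorb(name)
    selected.sort()
    return SelectionResult(selected, pd_score)


def downsample_groups(
    db: ProteinDB,
    per_group_trees: dict[str, dendropy.Tree],
    caps: dict[str, int],
    exempt: set[str] = frozenset(),
) -> ProteinDB:
    """Reduce each capped group to its cap by greedy max-PD on its guide
    tree; exempt groups and groups at/below their cap pass through."""
    by_group: dict[str, list[str]] = {}
    for rec in db:
        by_group.setdefault(rec.group, []).append(rec.id)
    keep: set[str] = set()
    for group, members in by_group.items():
        cap = caps.get(group)
        if group in exempt or cap is None or len(members) <= cap:
            keep.update(members)
            continue
        tree = per_group_trees.get(group)
        if tree is None:
            raise ValueError(
                f"group {group!r} exceeds its cap ({len(members)} > {cap}) "
                "but has no guide tree"
            )
        tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        missing = set(members) - tree_leaves
        if missing:
            raise ValueError(
                f"guide tree for group {group!r} lacks members: "
                f"{sorted(missing)[:5]}..."
            )
        sel = greedy_max_pd(tree, cap)
        chosen = set(sel.kept_ids) & set(members)
        logger.info("group %s: %d -> %d by PD", group, len(members), len(chosen))
        keep.update(chosen)
    return db.subset(keep)
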