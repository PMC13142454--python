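"""Cross-tree consensus clade definition.

Replicate trees over one leaf universe (e.g. four trees from two trim
levels and two bootstrap seeds) vote on which groups of sequences form
robust clades: a clade must be supported (support strictly above
``min_support`` on a 0-100 scale, at least ``min_size`` members) in at
least ``min_trees`` of the trees (best-match Jaccard >= ``j_min``
identifies "the same" clade across trees, the candidate's own tree
counts itself), members lacking co-support in ``min_trees`` trees are
pruned, and only clades retaining strictly more than ``min_retained``
members are reported. Leaves in no reported clade are listed as
unassigned — these are the variably placed branches of an atlas tree.

Atlas-scale defaults: min_support 70, min_size 100, 3 of 4 trees,
min_retained 20; desk-scale tests override the sizes but never the
logical rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

from .formats_io import node_support

logger = logging.getLogger("tiratlas")

DEFAULT_MIN_SUPPORT = 70.0
DEFAULT_MIN_SIZE = 100
DEFAULT_MIN_TREES = 3
DEFAULT_MIN_RETAINED = 20
DEFAULT_J_MIN = 0.5


@dataclass(frozen=True)
class SupportedClade:
    tree_index: int
    leaf_set: frozenset[str]
    support: float


@dataclass
class MatchRecord:
    tree_index: int
    matched: frozenset[str] | None
    jaccard: float
    support: float | None
    reproduced: bool


@dataclass
class ConsensusClade:
    clade_id: str
    candidate: frozenset[str]
    matches: list[MatchRecord]
    retained_members: frozenset[str] = frozenset()
    mean_support: float = 0.0
    nested_in: str | None = None

    @property
    def n_reproduced(self) -> int:
        return sum(m.reproduced for m in self.matches)


def root_on_outgroup(tree: dendropy.Tree, outgroup: set[str]) -> dendropy.Tree:
    """Root (a clone of) the tree on the edge above the outgroup's MRCA."""
    tree = tree.clone(depth=1)
    taxa = [t for t in tree.taxon_namespace if t.label in outgroup]
    if not taxa:
        raise ValueError("no outgroup leaves present in tree")
    if len(taxa) == 1:
        node = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == taxa[0].label
        )
    else:
        node = tree.mrca(taxa=taxa)
        if node is tree.seed_node:
            # outgroup spans the root; root on the first outgroup leaf instead
            node = next(
                lf for lf in tree.leaf_node_iter() if lf.taxon.label == taxa[0].label
            )
    ln = node.edge.length
    tree.reroot_at_edge(node.edge, update_bipartitions=False,
                        length1=(ln or 0.0) / 2, length2=(ln or 0.0) / 2)
    tree.is_rooted = True
    return tree


def supported_clades(
    tree: dendropy.Tree,
    min_support: float = DEFAULT_MIN_SUPPORT,
    min_size: int = DEFAULT_MIN_SIZE,
    tree_index: int = 0,
    outgroup: set[str] | None = None,
) -> list[SupportedClade]:
    """Clades at internal nodes with support strictly > ``min_support``
    and at least ``min_size`` descendant leaves.

    The tree must be rooted, or an outgroup must be given to root it.
    When neither holds, each split's smaller side is treated as the
    clade (logged fallback).
    """
    use_bipartitions = False
    if outgroup:
        tree = root_on_outgroup(tree, outgroup)
    elif not tree.is_rooted:
        logger.info(
            "tree %d unrooted with no outgroup: falling back to bipartition "
            "smaller sides", tree_index,
        )
        use_bipartitions = True
    universe = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    n_total = len(universe)
    out = []
    seen: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is None or sup <= min_support:
            continue
        leaf_set = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if use_bipartitions and len(leaf_set) > n_total - len(leaf_set):
            # the clade is the smaller side of this split
            leaf_set = universe - leaf_set
        if len(leaf_set) < min_size or leaf_set in seen:
            continue
        seen.add(leaf_set)
        out.append(SupportedClade(tree_index, leaf_set, sup))
    return out


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _best_match(
    candidate: frozenset[str], clades: list[SupportedClade]
) -> tuple[SupportedClade | None, float]:
    """Supported clade maximizing Jaccard with the candidate; ties break
    to higher support, then smaller clade, then lexicographic members."""
    best = None
    best_key = None
    for cl in clades:
        j = _jaccard(candidate, cl.leaf_set)
        key = (-j, -cl.support, len(cl.leaf_set), tuple(sorted(cl.leaf_set)))
        if best_key is None or key < best_key:
            best, best_key = cl, key
    if best is None:
        return None, 0.0
    return best, -best_key[0]


def match_across_trees(
    clade_lists: list[list[SupportedClade]],
    j_min: float = DEFAULT_J_MIN,
    min_trees: int = DEFAULT_MIN_TREES,
) -> list[ConsensusClade]:
    """Candidates = union of supported clades over trees; a candidate
    survives iff its best-match Jaccard is >= ``j_min`` in at least
    ``min_trees`` trees (its own tree counts itself, with Jaccard 1)."""
    # distinct candidate sets, deterministic order
    seen: dict[frozenset, SupportedClade] = {}
    for clades in clade_lists:
        for cl in clades:
            if cl.leaf_set not in seen:
                seen[cl.leaf_set] = cl
    survivors: dict[frozenset, ConsensusClade] = {}
    for cand_set, source in sorted(
        seen.items(), key=lambda kv: (-len(kv[0]), tuple(sorted(kv[0])))
    ):
        matches = []
        for t, clades in enumerate(clade_lists):
            if t == source.tree_index:
                matches.append(
                    MatchRecord(t, cand_set, 1.0, source.support, True)
                )
                continue
            best, j = _best_match(cand_set, clades)
            reproduced = best is not None and j >= j_min
            matches.append(
                MatchRecord(
                    t,
                    best.leaf_set if best else None,
                    j,
                    best.support if best else None,
                    reproduced,
                )
            )
        n_rep = sum(m.reproduced for m in matches)
        if n_rep >= min_trees:
            cc = ConsensusClade(
                clade_id="", candidate=cand_set, matches=matches
            )
            if cand_set not in survivors:
                survivors[cand_set] = cc
    out = list(survivors.values())
    for i, cc in enumerate(
        sorted(out, key=lambda c: (-len(c.candidate), tuple(sorted(c.candidate))))
    ):
        cc.clade_id = f"CC{i + 1}"
    return sorted(out, key=lambda c: c.clade_id)


def check_leaf_universes(trees: list[dendropy.Tree]) -> frozenset[str]:
    sets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees]
    for i, s in enumerate(sets[1:], start=1):
        if s != sets[0]:
            diff = sorted(s ^ sets[0])
            raise ValueError(
                f"tree {i} leaf universe differs from tree 0: "
                f"symmetric difference {diff[:10]}"
            )
    return sets[0]


def prune_members(
    candidate: ConsensusClade,
    min_trees: int = DEFAULT_MIN_TREES,
) -> frozenset[str]:
    """Retain a leaf iff it belongs to the candidate's matched supported
    clade in at least ``min_trees`` trees (the candidate's own tree
    counts itself)."""
    retained = []
    for leaf in candidate.candidate:
        n = 0
        for m in candidate.matches:
            if m.matched is not None and m.reproduced and leaf in m.matched:
                n += 1
        if n >= min_trees:
            retained.append(leaf)
    candidate.retained_members = frozenset(retained)
    sups = [m.support for m in candidate.matches if m.reproduced and m.support is not None]
    candidate.mean_support = sum(sups) / len(sups) if sups else 0.0
    return candidate.retained_members


def report_clades(
    candidates: list[ConsensusClade],
    min_retained: int = DEFAULT_MIN_RETAINED,
    universe: frozenset[str] | None = None,
    disjoint: bool = False,
) -> tuple[list[ConsensusClade], list[str]]:
    """Keep candidates with strictly more than ``min_retained`` retained
    members, sorted by retained size descending; record nesting; with
    ``disjoint`` greedily discard clades sharing members with an already
    accepted one. Returns (reported clades, unassigned leaves)."""
    kept = [c for c in candidates if len(c.retained_members) > min_retained]
    kept.sort(
        key=lambda c: (
            -len(c.retained_members),
            -c.mean_support,
            min(c.retained_members) if c.retained_members else "",
        )
    )
    if disjoint:
        accepted: list[ConsensusClade] = []
        used: set[str] = set()
        for c in kept:
            if not (c.retained_members & used):
                accepted.append(c)
                used |= c.retained_members
        kept = accepted
    # nesting relations among reported clades (largest container wins)
    for c in kept:
        for other in kept:
            if other is c:
                continue
            if c.retained_members < other.retained_members:
                if c.nested_in is None:
                    c.nested_in = other.clade_id
    assigned: set[str] = set()
    for c in kept:
        assigned |= c.retained_members
    unassigned = sorted(universe - assigned) if universe is not None else []
    return kept, unassigned


def consensus_clades(
    trees: list[dendropy.Tree],
    min_support: float = DEFAULT_MIN_SUPPORT,
    min_size: int = DEFAULT_MIN_SIZE,
    min_trees: int = DEFAULT_MIN_TREES,
    min_retained: int = DEFAULT_MIN_RETAINED,
    j_min: float = DEFAULT_J_MIN,
    outgroup: set[str] | None = None,
    disjoint: bool = False,
) -> tuple[list[ConsensusClade], list[str]]:
    """End-to-end clade definition over replicate trees."""
    universe = check_leaf_universes(trees)
    clade_lists = [
        supported_clades(t, min_support, min_size, tree_index=i, outgroup=outgroup)
        for i, t in enumerate(trees)
    ]
    candidates = match_across_trees(clade_lists, j_min=j_min, min_trees=min_trees)
    for c in candidates:
        prune_members(c, min_trees=min_trees)
    return report_clades(
        candidates, min_retained=min_retained, universe=universe, disjoint=disjoint
    )
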