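"""Gain/loss reconstruction of gene families on a species tree.

Two modes make a by-inspection gene-family history computable:

* Dollo reconstruction from presence/absence: the family arises exactly
  once (single origin, the natural model for a horizontally transferred
  gene), at the MRCA of the present species; the minimal set of loss
  branches below the origin explains all absences.
* Count parsimony from per-species gene counts: a minimal-cost integer
  labeling of internal nodes (Sankoff dynamic programming, unit cost
  per +-1 copy change along a branch) yields duplication and loss
  counts. Parsimony is a lower bound on the true event count; it equals
  the truth when simulated events are phylogenetically independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("tiratlas")


class NoOriginError(ValueError):
    """All-absent vector: there is no origin to reconstruct."""


@dataclass
class GainLossResult:
    family: str
    origin_leaves: frozenset[str]      # leaf set of the origin node
    loss_branches: list[frozenset[str]]  # leaf set below each loss branch
    n_duplications: int
    n_losses: int
    node_counts: dict[frozenset[str], int] = field(default_factory=dict)


def _leafset(node: dendropy.Node) -> frozenset[str]:
    if node.is_leaf():
        return frozenset([node.taxon.label])
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def dollo_reconstruct(
    species_tree: dendropy.Tree,
    presence: dict[str, int] | dict[str, bool],
    family: str = "fam",
) -> GainLossResult:
    """Single-origin (Dollo) placement with minimal losses.

    Origin = MRCA of present species. A branch below the origin is a
    loss iff its subtree contains no present species while its parent
    is inferred present (i.e. the parent's subtree does). The loss set
    is minimal: merging any two losses or removing one breaks
    consistency with the data.
    """
    leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    unknown = set(presence) - leaves
    if unknown:
        raise ValueError(f"presence vector has unknown species: {sorted(unknown)}")
    present = {sp for sp in leaves if presence.get(sp, 0)}
    if not present:
        raise NoOriginError(f"family {family}: no present species")

    taxa = [t for t in species_tree.taxon_namespace if t.label in present]
    if len(present) == 1:
        origin = next(
            lf for lf in species_tree.leaf_node_iter()
            if lf.taxon.label in present
        )
    else:
        origin = species_tree.mrca(taxa=taxa)

    losses: list[frozenset[str]] = []

    def subtree_has_present(node: dendropy.Node) -> bool:
        return bool(_leafset(node) & present)

    stack = [origin]
    while stack:
        node = stack.pop()
        for ch in node.child_nodes():
            if subtree_has_present(ch):
                stack.append(ch)
            else:
                losses.append(_leafset(ch))
    losses.sort(key=lambda s: (len(s), sorted(s)))
    return GainLossResult(
        family=family,
        origin_leaves=_leafset(origin),
        loss_branches=losses,
        n_duplications=0,
        n_losses=len(losses),
    )


def count_parsimony(
    species_tree: dendropy.Tree,
    counts: dict[str, int],
    max_count: int | None = None,
    family: str = "fam",
) -> GainLossResult:
    """Minimal-cost integer labeling of internal nodes.

    Sankoff DP over copy-number states 0..max_count with cost |Δcount|
    per branch. Duplications are the total positive increment units
    minus the single 0→1 origin unit (counted on a virtual absent stem
    above the root); losses are the total decrement units. Ties resolve
    toward later (leafward) events: downward backtracking prefers the
    child state closest to the parent's, then the smaller state; the
    root prefers the smallest optimal state.
    """
    leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    missing = leaves - set(counts)
    if missing:
        raise ValueError(f"counts missing species: {sorted(missing)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be nonnegative")
    cmax = max(counts.values())
    if max_count is None:
        max_count = max(cmax, 1)
    if cmax > max_count:
        raise ValueError(f"count {cmax} exceeds max_count {max_count}")
    if max_count > 10:
        raise ValueError("count states bounded at 10")
    states = np.arange(max_count + 1)
    delta = np.abs(states[:, None] - states[None, :])  # cost parent->child

    cost: dict[int, np.ndarray] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            c = np.full(max_count + 1, np.inf)
            c[counts[node.taxon.label]] = 0.0
        else:
            c = np.zeros(max_count + 1)
            for ch in node.child_nodes():
                # min over child state of (branch cost + child subtree cost)
                c = c + np.min(delta + cost[id(ch)][None, :], axis=1)
        cost[id(node)] = c

    root = species_tree.seed_node
    root_cost = cost[id(root)]
    best = root_cost.min()
    root_state = int(np.flatnonzero(root_cost == best)[0])  # smallest optimal

    assign: dict[int, int] = {id(root): root_state}
    node_counts: dict[frozenset[str], int] = {_leafset(root): root_state}
    n_pos = root_state  # stem increment units (virtual absent state -> root)
    n_neg = 0
    stack = [root]
    while stack:
        node = stack.pop()
        p = assign[id(node)]
        for ch in node.child_nodes():
            col = delta[p] + cost[id(ch)]
            m = col.min()
            opts = np.flatnonzero(col == m)
            # prefer the state closest to the parent (delay the event),
            # then the smaller state
            s = int(min(opts, key=lambda x: (abs(int(x) - p), int(x))))
            assign[id(ch)] = s
            node_counts[_leafset(ch)] = s
            if s > p:
                n_pos += s - p
            else:
                n_neg += p - s
            stack.append(ch)

    if n_pos == 0 and root_state == 0:
        raise NoOriginError(f"family {family}: reconstructed as never present")
    n_dup = n_pos - 1  # one positive unit is the origin gain
    return GainLossResult(
        family=family,
        origin_leaves=_leafset(root) if root_state > 0 else _first_gain_leafset(
            species_tree, assign
        ),
        loss_branches=[],
        n_duplications=n_dup,
        n_losses=n_neg,
        node_counts=node_counts,
    )


def _first_gain_leafset(
    species_tree: dendropy.Tree, assign: dict[int, int]
) -> frozenset[str]:
    """Leaf set below the shallowest branch where the count first rises
    above zero (the origin under a zero-state root)."""
    for node in species_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if assign[id(node.parent_node)] == 0 and assign[id(node)] > 0:
            return _leafset(node)
    return frozenset()


def recover_simulated_history(
    species_tree: dendropy.Tree,
    matrix: pd.DataFrame,
) -> dict[str, GainLossResult]:
    """Dollo reconstruction of every family column of a presence matrix
    (rows species, columns families). Parsimony loss counts are lower
    bounds on the simulated counts; equality holds when simulated losses
    are phylogenetically independent."""
    out = {}
    for fam in matrix.columns:
        presence = {sp: int(v) for sp, v in matrix[fam].items()}
        out[fam] = dollo_reconstruct(species_tree, presence, family=fam)
    return out


def results_to_frame(results: dict[str, GainLossResult]) -> pd.DataFrame:
    rows = []
    for fam in sorted(results):
        r = results[fam]
        rows.append(
            {
                "family": fam,
                "origin_size": len(r.origin_leaves),
                "origin_leaves": ",".join(sorted(r.origin_leaves)),
                "n_losses": r.n_losses,
                "n_duplications": r.n_duplications,
                "loss_branches": ";".join(
                    ",".join(sorted(s)) for s in r.loss_branches
                ),
            }
        )
    return pd.DataFrame(rows)
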