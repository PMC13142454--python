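"""Alignment trimming, pairwise identity, and a desk-scale tree engine.

The package does not reimplement maximum-likelihood inference or external
multiple aligners; it ingests their outputs. For hermetic end-to-end runs
it provides:

* gap-threshold column trimming (keep a column iff its fraction of
  non-gap residues is at least ``gt``),
* global pairwise identity under a fixed substitution model,
* p-distance matrices with pairwise deletion,
* neighbor-joining trees with deterministic tie-breaks, and
* classical nonparametric bootstrap supports over the NJ engine,
* a template-anchored stacking aligner (each row aligned pairwise to a
  template; residues inserted relative to the template are dropped) as
  the internal multiple-alignment stand-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import (
    GAP,
    MultipleAlignment,
    ProteinRecord,
    aligned_record,
    read_newick,
)

logger = logging.getLogger("tiratlas")

# Fixed global-alignment parameters for pairwise identity; one of several
# defensible conventions, so printed identities from other tools will not
# match digit-for-digit.
IDENTITY_MATRIX = "BLOSUM62"
IDENTITY_GAP_OPEN = -11.0
IDENTITY_GAP_EXTEND = -1.0


class EmptyAlignmentError(ValueError):
    """All columns were removed by trimming."""


@dataclass(frozen=True)
class TrimSpec:
    """Minimum fraction of non-gap residues a column needs to be kept."""

    gt: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.gt <= 1.0:
            raise ValueError(f"gt must be in [0, 1], got {self.gt}")


def trim_columns(
    aln: MultipleAlignment, spec: TrimSpec
) -> tuple[MultipleAlignment, list[int]]:
    """Drop columns whose non-gap fraction falls below ``spec.gt``.

    Returns the trimmed alignment and the kept-column index map
    (0-based original column index per kept column).
    """
    arr = aln.to_array()
    nongap_frac = (arr != GAP).mean(axis=0)
    kept = [c for c in range(aln.n_columns) if nongap_frac[c] >= spec.gt]
    if not kept:
        raise EmptyAlignmentError(
            f"gt={spec.gt} removed all {aln.n_columns} columns"
        )
    sub = arr[:, kept]
    recs = [
        aligned_record(r.id, "".join(row), r.taxon, r.group)
        for r, row in zip(aln.records, sub)
    ]
    return MultipleAlignment(recs), kept


# ---------------------------------------------------------------------------
# Pairwise alignment and identity

def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(IDENTITY_MATRIX)
    aligner.open_gap_score = IDENTITY_GAP_OPEN
    aligner.extend_gap_score = IDENTITY_GAP_EXTEND
    return aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Optimal global alignment of two sequences as two gapped rows."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aln = _global_aligner().align(seq_a, seq_b)[0]
    return _rows_from_coordinates(seq_a, seq_b, aln.coordinates)


def _rows_from_coordinates(
    seq_a: str, seq_b: str, coords: np.ndarray
) -> tuple[str, str]:
    a_parts, b_parts = [], []
    for k in range(coords.shape[1] - 1):
        a0, a1 = coords[0, k], coords[0, k + 1]
        b0, b1 = coords[1, k], coords[1, k + 1]
        if a1 > a0 and b1 > b0:
            a_parts.append(seq_a[a0:a1])
            b_parts.append(seq_b[b0:b1])
        elif a1 > a0:
            a_parts.append(seq_a[a0:a1])
            b_parts.append(GAP * (a1 - a0))
        else:
            a_parts.append(GAP * (b1 - b0))
            b_parts.append(seq_b[b0:b1])
    return "".join(a_parts), "".join(b_parts)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over mutually ungapped columns of the optimal
    global alignment (fixed substitution model and gap costs)."""
    row_a, row_b = align_pair(seq_a, seq_b)
    both = [(x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    same = sum(x == y for x, y in both)
    return 100.0 * same / len(both)


def stack_alignment(
    template: ProteinRecord, records: list[ProteinRecord]
) -> MultipleAlignment:
    """Template-anchored multiple alignment.

    Each record is globally aligned to the template; its residues are
    placed in the template's columns and residues inserted relative to
    the template are dropped. Column count equals the template length.
    Crude next to a real MSA, but deterministic and dependency-free —
    adequate for p-distance trees on domain-length sequences.
    """
    n_cols = len(template.sequence)
    rows = [aligned_record(template.id, template.sequence, template.taxon, template.group)]
    for rec in records:
        if rec.id == template.id:
            continue
        t_row, r_row = align_pair(template.sequence, rec.sequence)
        out = []
        for t_char, r_char in zip(t_row, r_row):
            if t_char != GAP:
                out.append(r_char)
        assert len(out) == n_cols
        rows.append(aligned_record(rec.id, "".join(out), rec.taxon, rec.group))
    return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# Distances

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)


def p_distances(aln: MultipleAlignment) -> DistanceMatrix:
    """Pairwise p-distances (mismatches / compared columns) with pairwise
    deletion of columns where either row is gapped."""
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows")
    arr = aln.to_array()
    codes = np.frombuffer(
        "".join(r.sequence for r in aln.records).encode(), dtype=np.uint8
    ).reshape(aln.n_rows, aln.n_columns)
    gap = codes == ord(GAP)
    n = aln.n_rows
    mat = np.zeros((n, n))
    for i in range(n):
        ok = ~gap[i] & ~gap[i + 1:]
        comp = ok.sum(axis=1)
        if np.any(comp == 0):
            j = i + 1 + int(np.argmax(comp == 0))
            raise ValueError(
                f"rows {aln.records[i].id!r} and {aln.records[j].id!r} share "
                "no comparable columns"
            )
        mism = ((codes[i] != codes[i + 1:]) & ok).sum(axis=1)
        mat[i, i + 1:] = mism / comp
    mat = mat + mat.T
    return DistanceMatrix([r.id for r in aln.records], mat)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted, no supports).

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest (id_i, id_j) pair. Negative branch length
    estimates are clamped to 0 with the deficit moved to the sibling edge.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.matrix.astype(float).copy()
    # each active entry is a (sort key, newick fragment) pair
    labels: list[str] = list(dm.ids)
    frags: list[str] = [_nwk_leaf(t) for t in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = {
            (min(int(a), int(b)), max(int(a), int(b)))
            for a, b in np.argwhere(q == qmin)
        }
        best = min(
            (tuple(sorted((labels[active[a]], labels[active[b]]))), a, b)
            for a, b in ties
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        # distances from the new node u to every other active node
        du = 0.5 * (d[i, active] + d[j, active] - dij)
        u = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k_idx, k in enumerate(active):
            d[u, k] = d[k, u] = du[k_idx]
        d[u, u] = 0.0
        frag = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"
        labels.append(min(labels[i], labels[j]))
        frags.append(frag)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # three-point formulas for the final star join
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    li, lj, lk = max(li, 0.0), max(lj, 0.0), max(lk, 0.0)
    newick = (
        f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g},{frags[k]}:{lk:.10g});"
    )
    return read_newick(newick)


def _nwk_leaf(taxon: str) -> str:
    if any(c in taxon for c in "():;,' \t"):
        return "'" + taxon.replace("'", "''") + "'"
    return taxon


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# Bootstrap

def _bipartitions(tree: dendropy.Tree, universe: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits, each encoded as the side not containing the
    lexicographically smallest taxon (canonical orientation)."""
    anchor = min(universe)
    out = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(universe) - 1:
            continue
        if anchor in side:
            side = universe - side
        out.add(side)
    return out


def bootstrap_support(
    aln: MultipleAlignment, n_reps: int, seed: int
) -> dendropy.Tree:
    """NJ point-estimate tree with classical bootstrap supports (0-100).

    Columns are resampled with replacement ``n_reps`` times; the support
    of each internal branch of the point tree is the percentage of
    replicate trees containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = nj_tree(p_distances(aln))
    universe = frozenset(r.id for r in aln.records)
    point_splits = {}
    anchor = min(universe)
    for node in point.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(universe) - 1:
            continue
        key = universe - side if anchor in side else side
        point_splits[id(node)] = key
    counts = {k: 0 for k in point_splits.values()}

    rng = np.random.default_rng(seed)
    arr = aln.to_array()
    n_cols = aln.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        sub = arr[:, cols]
        recs = [
            aligned_record(r.id, "".join(row), r.taxon, r.group)
            for r, row in zip(aln.records, sub)
        ]
        try:
            rep_tree = nj_tree(p_distances(MultipleAlignment(recs)))
        except ValueError:
            continue  # a replicate can lose all comparable columns for a pair
        rep_splits = _bipartitions(rep_tree, universe)
        for k in counts:
            if k in rep_splits:
                counts[k] += 1

    for node in point.preorder_node_iter():
        key = point_splits.get(id(node))
        if key is not None:
            node.label = f"{100.0 * counts[key] / n_reps:g}"
    return point
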