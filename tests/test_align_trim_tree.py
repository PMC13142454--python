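import dendropy
import numpy as np
import pytest

from tiratlas.align_trim_tree import (
    DistanceMatrix,
    EmptyAlignmentError,
    TrimSpec,
    bootstrap_support,
    nj_tree,
    p_distances,
    pairwise_identity,
    stack_alignment,
    trim_columns,
)
from tiratlas.formats_io import (
    MultipleAlignment,
    ProteinRecord,
    aligned_record,
    node_support,
    tree_to_newick,
)
from .conftest import random_binary_tree


def simple_dp_global(a, b, matrix, gap_open, gap_extend):
    """Independent affine-gap global alignment score (Gotoh three-state
    DP, written from the recurrences, no shared code with the package)."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


class TestTrim:
    def _aln(self, rows):
        return MultipleAlignment(
            [aligned_record(f"r{i}", s) for i, s in enumerate(rows)]
        )

    def test_gt_zero_keeps_everything(self):
        aln = self._aln(["A-C", "-AC", "A--"])
        trimmed, kept = trim_columns(aln, TrimSpec(gt=0.0))
        assert trimmed.n_columns == 3
        assert kept == [0, 1, 2]

    def test_rare_column_removed_at_gt_010(self):
        rows = ["A" + "C" for _ in range(1)]
        # 20 rows; column 0 has 1 non-gap residue (0.05 < 0.1) -> removed
        rows = ["AC"] + ["-C"] * 19
        trimmed, kept = trim_columns(self._aln(rows), TrimSpec(gt=0.1))
        assert kept == [1]

    def test_gt_one_keeps_only_gapless(self):
        aln = self._aln(["AC-G", "ACCG", "AC-G"])
        trimmed, kept = trim_columns(aln, TrimSpec(gt=1.0))
        assert kept == [0, 1, 3]

    def test_all_removed_raises(self):
        aln = self._aln(["--", "--", "A-"])
        with pytest.raises(EmptyAlignmentError):
            trim_columns(aln, TrimSpec(gt=0.9))

    def test_kept_count_matches_direct_recount(self, rng):
        for _ in range(20):
            n_rows = int(rng.integers(2, 12))
            n_cols = int(rng.integers(3, 30))
            arr = rng.choice(list("ACDE-"), size=(n_rows, n_cols))
            aln = self._aln(["".join(r) for r in arr])
            gt = float(rng.uniform(0, 1))
            try:
                trimmed, kept = trim_columns(aln, TrimSpec(gt=gt))
            except EmptyAlignmentError:
                expected = 0
            else:
                expected = len(kept)
            recount = sum(
                1 for c in range(n_cols)
                if (arr[:, c] != "-").sum() / n_rows >= gt
            )
            assert expected == recount


class TestPairwiseIdentity:
    def test_identical_sequences_100(self):
        assert pairwise_identity("ACDEFGHIK", "ACDEFGHIK") == 100.0

    def test_single_mismatch(self):
        assert pairwise_identity("AAAA", "AAAT") == 75.0

    def test_regression_against_independent_dp(self):
        # Score cross-checked against an independent Gotoh DP with the
        # shipped parameters (BLOSUM62, open -11, extend -1); identity
        # value frozen from the resulting optimal alignment.
        from Bio.Align import substitution_matrices

        a, b = "HEAGAWGHEE", "PAWHEAE"
        blosum = substitution_matrices.load("BLOSUM62")
        from tiratlas.align_trim_tree import _global_aligner

        expected_score = simple_dp_global(a, b, blosum, -11.0, -1.0)
        assert _global_aligner().score(a, b) == pytest.approx(expected_score)
        assert pairwise_identity(a, b) == pytest.approx(42.857142857)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")


class TestPDistances:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment(
            [aligned_record("a", "ACDE"), aligned_record("b", "ACDE")]
        )
        assert p_distances(aln).matrix[0, 1] == 0.0

    def test_half_mismatch(self):
        aln = MultipleAlignment(
            [aligned_record("a", "AAAA"), aligned_record("b", "AATT")]
        )
        assert p_distances(aln).matrix[0, 1] == 0.5

    def test_pairwise_deletion(self):
        aln = MultipleAlignment(
            [aligned_record("a", "AC-E"), aligned_record("b", "AT-E")]
        )
        # 3 comparable columns, 1 mismatch
        assert p_distances(aln).matrix[0, 1] == pytest.approx(1 / 3)

    def test_symmetry_random(self, rng):
        rows = [
            aligned_record(f"r{i}", "".join(rng.choice(list("ACDE-"), 30)))
            for i in range(6)
        ]
        m = p_distances(MultipleAlignment(rows)).matrix
        assert np.allclose(m, m.T)


def tree_distance_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    names = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    mat = np.array(
        [
            [
                0.0 if a == b else pdm.patristic_distance(taxa[a], taxa[b])
                for b in names
            ]
            for a in names
        ]
    )
    return DistanceMatrix(names, mat)


def unrooted_rf(t1_newick, t2_newick):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1_newick, schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    b = dendropy.Tree.get(data=t2_newick, schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestNJ:
    def test_four_taxon_additive_recovery_with_lengths(self):
        source = dendropy.Tree.get(
            data="((A:1,B:2):3,(C:4,D:5));", schema="newick"
        )
        dm = tree_distance_matrix(source)
        rec = nj_tree(dm)
        assert unrooted_rf("((A:1,B:2):3,(C:4,D:5));", tree_to_newick(rec)) == 0
        # recovered patristic distances must equal the inputs (additivity)
        rdm = tree_distance_matrix(rec)
        assert np.allclose(rdm.matrix, dm.matrix, atol=1e-9)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]]),
        )
        tree = nj_tree(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        # three-point formulas: a=(dAB+dAC-dBC)/2 etc.
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_taxon_order_invariance(self, rng):
        source = random_binary_tree(rng, 8)
        dm = tree_distance_matrix(source)
        t1 = nj_tree(dm)
        perm = list(rng.permutation(len(dm.ids)))
        dm2 = DistanceMatrix(
            [dm.ids[i] for i in perm], dm.matrix[np.ix_(perm, perm)]
        )
        t2 = nj_tree(dm2)
        assert unrooted_rf(tree_to_newick(t1), tree_to_newick(t2)) == 0

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_matches_skbio_on_random_additive_matrices(self, rng):
        # independent-route cross-check of the whole NJ implementation
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        for _ in range(5):
            source = random_binary_tree(rng, int(rng.integers(5, 10)))
            dm = tree_distance_matrix(source)
            mine = nj_tree(dm)
            theirs = skbio_nj(SkbioDM(dm.matrix, ids=dm.ids))
            assert unrooted_rf(
                tree_to_newick(mine), str(theirs).strip()
            ) == 0


class TestBootstrap:
    def _two_clade_alignment(self, rng, n_per=5, n_cols=60):
        base = "".join(rng.choice(list("ACDEFGHIKL"), n_cols))
        other = "".join(rng.choice(list("MNPQRSTVWY"), n_cols))
        rows = []
        for i in range(n_per):
            rows.append(aligned_record(f"x{i}", base))
            rows.append(aligned_record(f"y{i}", other))
        # add light noise so distances are not degenerate
        noisy = []
        for rec in rows:
            chars = list(rec.sequence)
            for pos in rng.choice(n_cols, 5, replace=False):
                chars[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            noisy.append(aligned_record(rec.id, "".join(chars)))
        return MultipleAlignment(noisy)

    def test_conflict_free_split_gets_high_support(self, rng):
        aln = self._two_clade_alignment(rng)
        tree = bootstrap_support(aln, n_reps=100, seed=3)
        xs = frozenset(f"x{i}" for i in range(5))
        found = []
        universe = frozenset(r.id for r in aln.records)
        for nd in tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if side in (xs, universe - xs):
                found.append(node_support(nd))
        assert found and max(found) >= 95

    def test_fixed_seed_reproducible(self, rng):
        aln = self._two_clade_alignment(rng)
        t1 = bootstrap_support(aln, n_reps=30, seed=7)
        t2 = bootstrap_support(aln, n_reps=30, seed=7)
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_supports_in_range(self, rng):
        aln = self._two_clade_alignment(rng)
        tree = bootstrap_support(aln, n_reps=30, seed=1)
        for nd in tree.internal_nodes():
            s = node_support(nd)
            if s is not None:
                assert 0 <= s <= 100

    def test_zero_reps_rejected(self, rng):
        aln = self._two_clade_alignment(rng)
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_reps=0, seed=1)


class TestStackAlignment:
    def test_template_row_preserved_and_columns_fixed(self):
        template = ProteinRecord("t", "ACDEFGHIKLMNPQRSTVWY")
        others = [
            ProteinRecord("a", "ACDEFGHIKLMNPQRSTVWY"),
            ProteinRecord("b", "ACDEFGHIKLMNPQRSTVW"),
        ]
        msa = stack_alignment(template, [template] + others)
        assert msa.n_columns == 20
        assert msa.records[0].sequence == template.sequence
        assert msa.records[1].sequence == template.sequence
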