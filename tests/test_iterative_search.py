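import itertools
import math

import numpy as np
import pytest

from tiratlas.formats_io import (
    AMINO_ACIDS,
    MultipleAlignment,
    ProteinDB,
    ProteinRecord,
    aligned_record,
    hits_to_frame,
)
from tiratlas.iterative_search import (
    StopConfig,
    build_profile,
    calibrate,
    henikoff_weights,
    iterate_search,
    resolve_overlaps,
    scan_database,
)
from .conftest import mutate_fraction, random_sequence


class TestBuildProfile:
    def test_single_sequence_observed_residue_maximal(self):
        aln = MultipleAlignment([aligned_record("s", "ACD")])
        prof = build_profile(aln)
        for col, aa in enumerate("ACD"):
            assert prof.match_scores[col].argmax() == AMINO_ACIDS.index(aa)

    def test_duplicated_rows_leave_profile_unchanged(self):
        rows = [aligned_record(f"s{i}", seq) for i, seq in
                enumerate(["ACDEF", "ACDEG", "ACEEF"])]
        aln1 = MultipleAlignment(rows)
        dup = [aligned_record(f"d{i}", r.sequence) for i, r in
               enumerate(rows + rows)]
        aln2 = MultipleAlignment(dup)
        p1 = build_profile(aln1)
        p2 = build_profile(aln2)
        assert np.allclose(p1.match_scores, p2.match_scores, atol=1e-12)

    def test_single_column_scores_match_stated_formula(self):
        # one column, 9 A's and 1 C, alpha=1, uniform background p=0.05.
        # Position-based weights: w(A)=1/(2*9) each, w(C)=1/2; total W=1,
        # weighted f(A)=f(C)=0.5. score(a) = log2((W f + alpha p)/((W+alpha) p))
        aln = MultipleAlignment(
            [aligned_record(f"s{i}", "A") for i in range(9)]
            + [aligned_record("s9", "C")]
        )
        uniform = np.full(20, 0.05)
        prof = build_profile(aln, background=uniform)
        expected_a = math.log2((1 * 0.5 + 1 * 0.05) / (2 * 0.05))
        expected_w = math.log2((0 + 0.05) / (2 * 0.05))
        assert prof.match_scores[0][AMINO_ACIDS.index("A")] == pytest.approx(expected_a)
        assert prof.match_scores[0][AMINO_ACIDS.index("C")] == pytest.approx(expected_a)
        assert prof.match_scores[0][AMINO_ACIDS.index("W")] == pytest.approx(expected_w)
        assert prof.match_scores[0][AMINO_ACIDS.index("A")] > 0
        assert prof.match_scores[0][AMINO_ACIDS.index("W")] < 0

    def test_gappy_columns_dropped(self):
        rows = [
            aligned_record("a", "AC-D"),
            aligned_record("b", "AC-D"),
            aligned_record("c", "ACED"),
        ]
        prof = build_profile(MultipleAlignment(rows))
        assert prof.length == 3  # column 3 has 2/3 gaps > 0.5

    def test_weights_sum_preserved_under_duplication(self):
        rows = [aligned_record(f"s{i}", seq) for i, seq in
                enumerate(["ACDEF", "ACDEG", "ACEEF"])]
        w1 = henikoff_weights(MultipleAlignment(rows))
        dup = [aligned_record(f"d{i}", r.sequence)
               for i, r in enumerate(rows + rows)]
        w2 = henikoff_weights(MultipleAlignment(dup))
        assert w1.sum() == pytest.approx(w2.sum())


@pytest.fixture(scope="module")
def toy_profile():
    rng = np.random.default_rng(77)
    anc = random_sequence(rng, 80)
    rows = [aligned_record(f"m{i}", mutate_fraction(rng, anc, 0.1))
            for i in range(5)]
    prof = build_profile(MultipleAlignment(rows), profile_id="toy")
    calibrate(prof, n_decoys=200, decoy_length=300, seed=5)
    return prof, rows


class TestCalibration:
    def test_fixed_seed_reproducible(self, toy_profile):
        prof, _ = toy_profile
        lam1, k1 = prof.lam, prof.k
        lam2, k2 = calibrate(prof, n_decoys=200, decoy_length=300, seed=5)
        assert (lam1, k1) == (lam2, k2)

    def test_evalue_semantics_on_fresh_decoys(self, toy_profile):
        # At threshold E <= 1 on a fresh decoy db, about 1 hit is expected.
        prof, _ = toy_profile
        rng = np.random.default_rng(123)
        db = ProteinDB(
            ProteinRecord(f"d{i}", random_sequence(rng, 300)) for i in range(300)
        )
        n_res = db.total_residues()
        passing = sum(
            1 for rec in db if prof.e_value(prof.score_only(rec.sequence), n_res) <= 1.0
        )
        assert passing <= 4  # expectation 1, generous Monte-Carlo margin

    def test_longer_decoys_score_higher(self, toy_profile):
        prof, _ = toy_profile
        rng = np.random.default_rng(9)
        short = np.mean(
            [prof.score_only(random_sequence(rng, 100)) for _ in range(40)]
        )
        long = np.mean(
            [prof.score_only(random_sequence(rng, 800)) for _ in range(40)]
        )
        assert long > short


class TestScan:
    def test_seed_member_recovered_with_planted_interval(self, toy_profile):
        prof, rows = toy_profile
        rng = np.random.default_rng(4)
        flank_n = random_sequence(rng, 40)
        flank_c = random_sequence(rng, 55)
        inner = rows[0].sequence
        db = ProteinDB([ProteinRecord("t1", flank_n + inner + flank_c)])
        hits = scan_database(prof, db, 1e-3)
        assert len(hits) == 1
        h = hits.iloc[0]
        assert h.e_value <= 1e-3
        assert abs(h.env_start - 41) <= 3
        assert abs(h.env_end - (40 + len(inner))) <= 3

    def test_empty_db_empty_table(self, toy_profile):
        prof, _ = toy_profile
        assert len(scan_database(prof, ProteinDB())) == 0

    def test_pure_decoy_db_nearly_clean(self, toy_profile):
        prof, _ = toy_profile
        rng = np.random.default_rng(55)
        db = ProteinDB(
            ProteinRecord(f"d{i}", random_sequence(rng, 250)) for i in range(1000)
        )
        hits = scan_database(prof, db, 1e-3)
        assert len(hits) <= 1


def brute_force_longest_first(rows):
    """Independent oracle: sort by the documented key, then greedy
    non-overlap selection (re-derived here from first principles)."""
    ordered = sorted(
        rows,
        key=lambda r: (-(r[5] - r[4] + 1), r[3], r[4], str(r[1])),
    )
    taken = []
    for r in ordered:
        if all(r[5] < s or r[4] > e for s, e in taken):
            taken.append((r[4], r[5]))
    return sorted(taken)


class TestResolveOverlaps:
    def _mk(self, envs, target="t1"):
        return hits_to_frame(
            [(target, f"p{i}", 10.0, 1e-5, s, e) for i, (s, e) in enumerate(envs)]
        )

    def test_longest_kept_on_overlap(self):
        out = resolve_overlaps(self._mk([(1, 100), (50, 130)]))
        assert [(r.env_start, r.env_end) for r in out.itertuples()] == [(1, 100)]

    def test_disjoint_both_kept(self):
        out = resolve_overlaps(self._mk([(1, 100), (150, 260)]))
        assert len(out) == 2

    def test_three_way_chain(self):
        out = resolve_overlaps(self._mk([(1, 100), (90, 170), (160, 240)]))
        assert [(r.env_start, r.env_end) for r in out.itertuples()] == [
            (1, 100), (160, 240),
        ]

    def test_matches_bruteforce_on_all_small_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 7))
            envs = []
            for _ in range(n):
                s = int(rng.integers(1, 300))
                e = s + int(rng.integers(0, 120))
                envs.append((s, e))
            rows = [
                ("t", f"p{i}", 5.0, float(rng.uniform(0, 1e-3)), s, e)
                for i, (s, e) in enumerate(envs)
            ]
            out = resolve_overlaps(hits_to_frame(rows))
            got = sorted((r.env_start, r.env_end) for r in out.itertuples())
            assert got == brute_force_longest_first(rows)

    def test_row_order_invariance(self, rng):
        rows = [
            ("t", f"p{i}", 5.0, 1e-4 * (i + 1), 1 + 30 * i, 100 + 30 * i)
            for i in range(5)
        ]
        base = resolve_overlaps(hits_to_frame(rows))
        for perm in itertools.permutations(rows):
            out = resolve_overlaps(hits_to_frame(list(perm)))
            assert out.equals(base)


class TestIteration:
    def _family_db(self, seed=42):
        rng = np.random.default_rng(seed)
        anc = random_sequence(rng, 120)
        members = [mutate_fraction(rng, anc, 0.1) for _ in range(6)]
        db = ProteinDB(
            [ProteinRecord(f"m{i}", s) for i, s in enumerate(members)]
        )
        seed_aln = MultipleAlignment(
            [aligned_record(f"m{i}", s) for i, s in enumerate(members[:4])]
        )
        return db, seed_aln

    def test_seed_only_db_stops_after_two_iterations(self):
        db, seed_aln = self._family_db()
        # db restricted to the seed members themselves
        db = db.subset([f"m{i}" for i in range(4)])
        state, _ = iterate_search(
            seed_aln, db, stop_cfg=StopConfig(seed=1, min_envelope_length=50)
        )
        assert state.n_iterations == 2
        assert state.per_iteration_new == [0, 0]
        assert state.stop_reason == "no-new-hits"

    def test_accumulation_is_monotone_and_terminates(self):
        db, seed_aln = self._family_db()
        state, _ = iterate_search(
            seed_aln, db, stop_cfg=StopConfig(seed=1, min_envelope_length=50)
        )
        assert state.n_iterations >= 2
        assert all(n >= 0 for n in state.per_iteration_new)
        assert {f"m{i}" for i in range(6)} <= state.accepted_ids()

    def test_reject_all_fold_gate_sets_stop_reason(self):
        db, seed_aln = self._family_db()
        state, _ = iterate_search(
            seed_aln, db,
            fold_gate=lambda rec_id: False,
            stop_cfg=StopConfig(seed=1, min_envelope_length=50),
        )
        assert state.stop_reason == "all-new-rejected-by-fold-gate"
        # only the seed members themselves remain accepted
        assert state.accepted_ids() == {f"m{i}" for i in range(4)}

    def test_bridge_subclade_found_only_after_broadening(self):
        # Plant transitivity: subfamily C is detectable from the seed
        # profile, remote subfamily B only once C is folded in.
        rng = np.random.default_rng(42)
        anc = random_sequence(rng, 120)
        a_seqs = [mutate_fraction(rng, anc, 0.10) for _ in range(4)]
        c_anc = mutate_fraction(rng, anc, 0.45)
        c_seqs = [mutate_fraction(rng, c_anc, 0.08) for _ in range(3)]
        b_anc = mutate_fraction(rng, c_anc, 0.45)
        b_seqs = [mutate_fraction(rng, b_anc, 0.08) for _ in range(3)]
        db = ProteinDB()
        for i, s in enumerate(a_seqs):
            db.add(ProteinRecord(f"A{i}", s))
        for i, s in enumerate(c_seqs):
            db.add(ProteinRecord(f"C{i}", s))
        for i, s in enumerate(b_seqs):
            db.add(ProteinRecord(f"B{i}", s))
        for i in range(100):
            db.add(ProteinRecord(f"d{i}", random_sequence(rng, 120)))
        seed_aln = MultipleAlignment(
            [aligned_record(f"A{i}", s) for i, s in enumerate(a_seqs)]
        )
        state, _ = iterate_search(
            seed_aln, db,
            stop_cfg=StopConfig(
                seed=3, e_threshold=1e-12, min_envelope_length=50
            ),
            seed_id="seedA",
        )
        assert state.per_iteration_new[0] == 3        # the bridge subfamily
        assert state.per_iteration_new[1] == 3        # the remote subfamily
        ids = state.accepted_ids()
        assert {"B0", "B1", "B2"} <= ids
        assert not any(i.startswith("d") for i in ids)
        assert state.stop_reason == "no-new-hits"
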