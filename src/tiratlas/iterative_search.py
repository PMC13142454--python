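"""Iterative profile search with saturation stopping and boundary calling.

The discovery engine builds a position-specific scoring model (PSSM)
from a seed alignment, scans a protein database with affine-gap local
alignment, converts scores to E-values through a Gumbel (extreme-value)
calibration against composition-matched shuffled decoys, folds accepted
hits back into the profile, and iterates until saturation. Multiple
seeds are orchestrated in a fixed order; a final boundary pass rescans
all accepted records with all final profiles and resolves overlapping
domain calls by keeping the longest envelope.

The scoring model is a PSSM with affine gap penalties rather than a full
Plan7 profile HMM; an external profile-HMM engine can be substituted by
implementing the ``ProfileEngine`` scan contract. The alignment DP runs
through Biopython's C pairwise aligner with the profile columns encoded
as a custom alphabet, so scores are exactly the PSSM log-odds defined
here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .formats_io import (
    AMINO_ACIDS,
    BACKGROUND_ARRAY,
    GAP,
    MultipleAlignment,
    ProteinDB,
    hits_to_frame,
)

logger = logging.getLogger("tiratlas")

DEFAULT_E_THRESHOLD = 1e-3     # inclusive, mirrors the domE reporting threshold
DEFAULT_GAP_OPEN = 11.0        # bits
DEFAULT_GAP_EXTEND = 1.0       # bits
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_ENVELOPE = 50      # residues
MIN_ITERATIONS = 2
OVERLAP_IDENTITY = 0.5         # reciprocal-overlap fraction for envelope identity

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class DegenerateProfileError(ValueError):
    """Every alignment column was dropped from the match model."""


class CalibrationError(RuntimeError):
    """Decoy score distribution unusable for the Gumbel fit."""


@dataclass
class SearchProfile:
    """PSSM over match columns with affine gap costs and Gumbel calibration."""

    profile_id: str
    match_scores: np.ndarray            # (L, 20) log-odds, bits
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    background: np.ndarray = field(default_factory=lambda: BACKGROUND_ARRAY.copy())
    lam: float | None = None            # Gumbel λ (per bit)
    k: float | None = None              # Karlin-Altschul-style K

    def __post_init__(self):
        if not np.all(np.isfinite(self.match_scores)):
            raise ValueError("profile scores must be finite")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.lam is not None and self.k is not None

    def e_value(self, score: float, db_residues: int) -> float:
        if not self.calibrated:
            raise CalibrationError(f"profile {self.profile_id} not calibrated")
        return float(
            self.k * self.length * db_residues * math.exp(-self.lam * score)
        )

    # -- aligner plumbing ---------------------------------------------------

    def _aligner(self) -> Align.PairwiseAligner:
        cols = tuple(f"#{i}" for i in range(self.length))
        alphabet = cols + tuple(AMINO_ACIDS) + ("X",)
        mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
        arr = np.asarray(mat)
        L = self.length
        arr[:L, L:L + 20] = self.match_scores
        arr[L:L + 20, :L] = self.match_scores.T
        # X scores 0 against every column (unknown residue is neutral-ish
        # but mildly penalized to avoid X-runs aligning)
        arr[:L, L + 20] = -1.0
        arr[L + 20, :L] = -1.0
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = mat
        aligner.open_gap_score = -(self.gap_open)
        aligner.extend_gap_score = -(self.gap_extend)
        self._cols = list(cols)
        return aligner

    def aligner(self) -> Align.PairwiseAligner:
        if not hasattr(self, "_aligner_cache"):
            self._aligner_cache = self._aligner()
        return self._aligner_cache

    def align_local(self, sequence: str):
        """Optimal local alignment of the profile against a sequence.

        Returns (score, env_start, env_end (1-based inclusive),
        profile_cols, target_chars) where the last two are the aligned
        pairs (profile column index or None for target-insertions,
        target position or None for deletions).
        """
        aligner = self.aligner()
        target = list(sequence)
        alns = aligner.align(self._cols, target)
        try:
            aln = alns[0]
        except IndexError:
            return 0.0, None, None, [], []
        coords = aln.coordinates
        t0, t1 = int(coords[1][0]), int(coords[1][-1])
        pairs_p, pairs_t = [], []
        for kk in range(coords.shape[1] - 1):
            p0, p1 = coords[0, kk], coords[0, kk + 1]
            q0, q1 = coords[1, kk], coords[1, kk + 1]
            if p1 > p0 and q1 > q0:
                for off in range(p1 - p0):
                    pairs_p.append(p0 + off)
                    pairs_t.append(q0 + off)
            elif p1 > p0:
                for off in range(p1 - p0):
                    pairs_p.append(p0 + off)
                    pairs_t.append(None)
            else:
                for off in range(q1 - q0):
                    pairs_p.append(None)
                    pairs_t.append(q0 + off)
        return float(aln.score), t0 + 1, t1, pairs_p, pairs_t

    def score_only(self, sequence: str) -> float:
        return float(self.aligner().score(self._cols, list(sequence)))


# ---------------------------------------------------------------------------
# Profile construction

def henikoff_weights(aln: MultipleAlignment) -> np.ndarray:
    """Position-based sequence weights (mean over columns of
    1 / (distinct residues x count of own residue)); gap characters do
    not contribute. Unnormalized, so duplicating every row leaves the
    total weight unchanged."""
    n = aln.n_rows
    weights = np.zeros(n)
    n_used = np.zeros(n)
    for c in range(aln.n_columns):
        col = aln.column(c)
        residues = [ch for ch in col if ch != GAP and ch != "X"]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for ch in residues:
            counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        for i, ch in enumerate(col):
            if ch in counts:
                weights[i] += 1.0 / (r * counts[ch])
                n_used[i] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(n_used > 0, weights / np.maximum(n_used, 1), 0.0)
    if out.sum() == 0:
        out = np.full(n, 1.0 / n)
    return out


def build_profile(
    aln: MultipleAlignment,
    profile_id: str = "profile",
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    max_gap_fraction: float = 0.5,
) -> SearchProfile:
    """PSSM from an alignment.

    Columns with gap fraction > ``max_gap_fraction`` are dropped from
    the match model (logged). The score of residue a at column c is

        log2((W * f_c(a) + α * p(a)) / ((W + α) * p(a)))

    with position-based sequence weights (total weight W), weighted
    observed frequencies f_c, pseudocount weight α and background p.
    """
    if aln.n_rows < 1:
        raise ValueError("alignment must have at least one sequence")
    p = BACKGROUND_ARRAY if background is None else np.asarray(background)
    w = henikoff_weights(aln)
    W = float(w.sum())
    alpha = pseudocount_weight

    kept_cols = []
    for c in range(aln.n_columns):
        col = aln.column(c)
        gap_frac = col.count(GAP) / len(col)
        if gap_frac > max_gap_fraction:
            continue
        kept_cols.append(c)
    if not kept_cols:
        raise DegenerateProfileError(
            "all columns exceeded the gap-fraction limit"
        )
    if len(kept_cols) < aln.n_columns:
        logger.info(
            "profile %s: dropped %d gappy columns of %d",
            profile_id, aln.n_columns - len(kept_cols), aln.n_columns,
        )

    scores = np.zeros((len(kept_cols), 20))
    for out_c, c in enumerate(kept_cols):
        col = aln.column(c)
        f = np.zeros(20)
        wsum = 0.0
        for i, ch in enumerate(col):
            if ch in _AA_INDEX:
                f[_AA_INDEX[ch]] += w[i]
                wsum += w[i]
        if wsum > 0:
            f /= wsum
        scores[out_c] = np.log2((W * f + alpha * p) / ((W + alpha) * p))
    return SearchProfile(
        profile_id, scores, gap_open=gap_open, gap_extend=gap_extend,
        background=p.copy(),
    )


# ---------------------------------------------------------------------------
# Calibration

def calibrate(
    profile: SearchProfile,
    n_decoys: int = 200,
    decoy_length: int = 400,
    seed: int = 0,
) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit of optimal local scores against
    background-composition random decoys.

    Sets and returns (λ, K) of E(S) = K * m * n * exp(-λS), where m is
    the profile length and n the searched residue count.
    """
    if n_decoys < 100:
        raise ValueError("need at least 100 decoys for a stable fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    for i in range(n_decoys):
        idx = rng.choice(20, size=decoy_length, p=profile.background)
        seq = "".join(AMINO_ACIDS[j] for j in idx)
        scores[i] = profile.score_only(seq)
    if np.var(scores) == 0:
        raise CalibrationError("degenerate decoy score distribution")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    # Gumbel location: P(max <= s) = exp(-K m n e^{-λs}) => μ = ln(K m n)/λ
    k = math.exp(lam * loc) / (profile.length * decoy_length)
    profile.lam, profile.k = float(lam), float(k)
    logger.info(
        "calibrated %s: lambda=%.4f K=%.3e (n=%d decoys of %d aa)",
        profile.profile_id, lam, k, n_decoys, decoy_length,
    )
    return profile.lam, profile.k


# ---------------------------------------------------------------------------
# Scanning

def _iter_envelopes(profile: SearchProfile, sequence: str, offset: int,
                    min_score: float, out: list) -> None:
    """Iterated optimal-subalignment extraction: record the optimal local
    hit, then recurse into the flanking segments."""
    if len(sequence) < 10:
        return
    score, s, e, _, _ = profile.align_local(sequence)
    if s is None or score < min_score or e < s:
        return
    out.append((score, offset + s, offset + e))
    _iter_envelopes(profile, sequence[: s - 1], offset, min_score, out)
    _iter_envelopes(profile, sequence[e:], offset + e, min_score, out)


def scan_database(
    profile: SearchProfile,
    db: ProteinDB,
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> pd.DataFrame:
    """Scan every record; report envelopes with E <= threshold.

    E-values use the whole database residue count, so the expected
    number of reported decoy envelopes at threshold E is about E.
    Multiple non-overlapping envelopes per target are found by iterated
    optimal-subalignment extraction.
    """
    if not profile.calibrated:
        raise CalibrationError(
            f"profile {profile.profile_id} must be calibrated before scanning"
        )
    n_res = db.total_residues()
    if n_res == 0:
        return hits_to_frame([])
    # invert the E-value map once: minimal score with E <= threshold
    min_score = math.log(profile.k * profile.length * n_res / e_threshold) / profile.lam
    rows = []
    for rec in db:
        found: list[tuple[float, int, int]] = []
        _iter_envelopes(profile, rec.sequence, 0, min_score, found)
        for score, s, e in found:
            ev = profile.e_value(score, n_res)
            if ev <= e_threshold:
                rows.append((rec.id, profile.profile_id, score, ev, s, e))
    return hits_to_frame(rows)


# ---------------------------------------------------------------------------
# Overlap resolution

def resolve_overlaps(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep, per target, a maximal set of non-overlapping envelopes chosen
    greedily by decreasing length (ties: lower E-value, then lower
    env_start, then profile id). Output order is deterministic and
    independent of input row order."""
    if len(hits) == 0:
        return hits_to_frame([])
    kept_rows = []
    for target, grp in hits.groupby("target_id", sort=True):
        rows = list(grp.itertuples(index=False))
        rows.sort(
            key=lambda r: (
                -(r.env_end - r.env_start + 1),
                r.e_value,
                r.env_start,
                str(r.profile_id),
            )
        )
        taken: list[tuple[int, int]] = []
        for r in rows:
            if all(r.env_end < s or r.env_start > e for s, e in taken):
                taken.append((r.env_start, r.env_end))
                kept_rows.append(tuple(r))
    df = hits_to_frame(kept_rows)
    return df.sort_values(
        ["target_id", "env_start"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Iteration

@dataclass
class IterationState:
    """Bookkeeping of one seed's search-to-saturation run."""

    seed_id: str
    accepted: dict[tuple[str, int, int], float] = field(default_factory=dict)
    per_iteration_new: list[int] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration_new)

    def accepted_ids(self) -> set[str]:
        return {rec_id for rec_id, _, _ in self.accepted}


def _same_envelope(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Envelopes identified up to >= 50% reciprocal overlap."""
    s = max(a[0], b[0])
    e = min(a[1], b[1])
    ov = max(0, e - s + 1)
    la = a[1] - a[0] + 1
    lb = b[1] - b[0] + 1
    return ov >= OVERLAP_IDENTITY * la and ov >= OVERLAP_IDENTITY * lb


def _is_new(state: IterationState, rec_id: str, env: tuple[int, int]) -> bool:
    for (rid, s, e) in state.accepted:
        if rid == rec_id and _same_envelope((s, e), env):
            return False
    return True


def _stack_accepted(
    profile: SearchProfile, db: ProteinDB, state: IterationState
) -> MultipleAlignment:
    """Alignment of accepted envelopes stacked by their profile-aligned
    coordinates (one row per accepted envelope, one column per profile
    match column; target insertions dropped, deletions gapped)."""
    from .formats_io import aligned_record

    rows = []
    L = profile.length
    for (rec_id, s, e) in sorted(state.accepted):
        seq = db[rec_id].sequence[s - 1:e]
        _, _, _, pairs_p, pairs_t = profile.align_local(seq)
        row = [GAP] * L
        for pcol, tpos in zip(pairs_p, pairs_t):
            if pcol is not None and tpos is not None:
                row[pcol] = seq[tpos]
        rows.append(aligned_record(f"{rec_id}/{s}-{e}", "".join(row)))
    return MultipleAlignment(rows)


@dataclass
class StopConfig:
    min_iterations: int = MIN_ITERATIONS
    max_iterations: int = 10
    e_threshold: float = DEFAULT_E_THRESHOLD
    min_envelope_length: int = DEFAULT_MIN_ENVELOPE
    calib_decoys: int = 200
    calib_length: int = 400
    seed: int = 0


def iterate_search(
    seed_alignment: MultipleAlignment,
    db: ProteinDB,
    fold_gate=None,
    stop_cfg: StopConfig | None = None,
    seed_id: str = "seed",
) -> tuple[IterationState, SearchProfile]:
    """Search one seed to saturation.

    Starts from the seed alignment's members (their database records, if
    present, are pre-accepted over their full length). Each iteration
    rebuilds the profile from the stacked accepted envelopes, recalibrates,
    rescans, and accepts new envelopes passing the E threshold, the
    minimum envelope length, and the fold gate. Stops when at least
    ``min_iterations`` scans ran and either no new hits appeared or every
    new hit was rejected by the fold gate.
    """
    cfg = stop_cfg or StopConfig()
    state = IterationState(seed_id=seed_id)
    for rec in seed_alignment.records:
        if rec.id in db:
            state.accepted[(rec.id, 1, len(db[rec.id].sequence))] = math.inf

    profile = build_profile(seed_alignment, profile_id=seed_id)
    calibrate(profile, cfg.calib_decoys, cfg.calib_length, seed=cfg.seed)

    while True:
        hits = scan_database(profile, db, cfg.e_threshold)
        n_new = 0
        n_new_passing = 0
        for row in hits.itertuples(index=False):
            env = (row.env_start, row.env_end)
            if env[1] - env[0] + 1 < cfg.min_envelope_length:
                continue
            if not _is_new(state, row.target_id, env):
                continue
            n_new += 1
            if fold_gate is not None and not fold_gate(row.target_id):
                continue
            n_new_passing += 1
            state.accepted[(row.target_id, env[0], env[1])] = row.e_value
        state.per_iteration_new.append(n_new_passing)
        i = state.n_iterations
        if i >= cfg.min_iterations:
            if n_new == 0:
                state.stop_reason = "no-new-hits"
                break
            if n_new_passing == 0:
                state.stop_reason = "all-new-rejected-by-fold-gate"
                break
        if i >= cfg.max_iterations:
            state.stop_reason = "max-iterations"
            break
        if n_new_passing > 0 or i < cfg.min_iterations:
            if state.accepted:
                stacked = _stack_accepted(profile, db, state)
                profile = build_profile(stacked, profile_id=seed_id)
                calibrate(
                    profile, cfg.calib_decoys, cfg.calib_length,
                    seed=cfg.seed + i,
                )
    return state, profile


def orchestrate_multi_seed(
    seeds: list[tuple[str, MultipleAlignment]],
    db: ProteinDB,
    fold_gate=None,
    stop_cfg: StopConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, IterationState], dict[str, SearchProfile]]:
    """Process seeds in order, each to saturation; then a final boundary
    pass rescans every accepted record with all final profiles, unions
    the hits, and resolves overlaps (longest envelope kept).

    Returns (final DomainHitTable, per-seed IterationState, final profiles).
    """
    if not seeds:
        raise ValueError("need at least one seed")
    cfg = stop_cfg or StopConfig()
    states: dict[str, IterationState] = {}
    profiles: dict[str, SearchProfile] = {}
    for seed_id, aln in seeds:
        state, profile = iterate_search(
            aln, db, fold_gate=fold_gate, stop_cfg=cfg, seed_id=seed_id
        )
        states[seed_id] = state
        profiles[seed_id] = profile
        logger.info(
            "seed %s: %d iterations, %d accepted, stop=%s",
            seed_id, state.n_iterations, len(state.accepted), state.stop_reason,
        )

    accepted_ids = sorted(set().union(*(s.accepted_ids() for s in states.values())))
    accepted_db = db.subset(accepted_ids)
    all_hits = []
    for seed_id, profile in profiles.items():
        all_hits.append(scan_database(profile, accepted_db, cfg.e_threshold))
    combined = pd.concat(all_hits, ignore_index=True) if all_hits else hits_to_frame([])
    combined = combined[
        combined.env_end - combined.env_start + 1 >= cfg.min_envelope_length
    ]
    final = resolve_overlaps(combined)
    return final, states, profiles


def trim_to_envelopes(db: ProteinDB, hits: pd.DataFrame) -> ProteinDB:
    """Trim accepted records to their domain envelope(s); records with
    several envelopes yield one trimmed record per envelope
    (id suffixed /start-end)."""
    out = ProteinDB()
    per_target = hits.groupby("target_id", sort=True)
    multi = {t: len(g) > 1 for t, g in per_target}
    for row in hits.sort_values(["target_id", "env_start"]).itertuples(index=False):
        rec = db[row.target_id]
        dom = rec.sequence[row.env_start - 1:row.env_end]
        rec_id = (
            f"{rec.id}/{row.env_start}-{row.env_end}" if multi[row.target_id] else rec.id
        )
        out.add(type(rec)(rec_id, dom, rec.taxon, rec.group))
    return out


def profile_consensus(profile: SearchProfile) -> str:
    """Highest-scoring residue per match column."""
    return "".join(AMINO_ACIDS[i] for i in profile.match_scores.argmax(axis=1))


def profile_stack_alignment(
    domains: ProteinDB, hits: pd.DataFrame, profiles: dict[str, SearchProfile]
):
    """Profile-anchored multiple alignment of trimmed domain records.

    Each record is stacked on the profile that called its envelope (rows
    over that profile's match columns, target insertions dropped); the
    columns of every profile are then mapped onto the profile with the
    most assigned records through a global alignment of the two profile
    consensus sequences. Within-family alignment quality is that of the
    profile model; between families the mapping is consistent per family.
    """
    from .align_trim_tree import align_pair
    from .formats_io import aligned_record, MultipleAlignment

    assignment: dict[str, str] = {}
    for row in hits.itertuples(index=False):
        rec_id = row.target_id
        key = (
            f"{row.target_id}/{row.env_start}-{row.env_end}"
            if f"{row.target_id}/{row.env_start}-{row.env_end}" in domains
            else row.target_id
        )
        if key in domains and key not in assignment:
            assignment[key] = row.profile_id
    counts: dict[str, int] = {}
    for pid in assignment.values():
        counts[pid] = counts.get(pid, 0) + 1
    ref_id = max(counts, key=lambda p: (counts[p], p))
    ref = profiles[ref_id]
    ref_cons = profile_consensus(ref)

    # column maps: profile column -> reference column (or None)
    col_maps: dict[str, list[int | None]] = {
        ref_id: list(range(ref.length))
    }
    for pid, prof in profiles.items():
        if pid == ref_id or pid not in counts:
            continue
        cons = profile_consensus(prof)
        ref_row, p_row = align_pair(ref_cons, cons)
        cmap: list[int | None] = [None] * prof.length
        ri = pi = 0
        for rc, pc in zip(ref_row, p_row):
            if rc != GAP and pc != GAP:
                cmap[pi] = ri
            if rc != GAP:
                ri += 1
            if pc != GAP:
                pi += 1
        col_maps[pid] = cmap

    rows = []
    for rec in domains:
        pid = assignment.get(rec.id)
        if pid is None:
            continue
        prof = profiles[pid]
        _, _, _, pairs_p, pairs_t = prof.align_local(rec.sequence)
        out = [GAP] * ref.length
        cmap = col_maps[pid]
        for pcol, tpos in zip(pairs_p, pairs_t):
            if pcol is None or tpos is None:
                continue
            ref_col = cmap[pcol]
            if ref_col is not None:
                out[ref_col] = rec.sequence[tpos]
        rows.append(aligned_record(rec.id, "".join(out), rec.taxon, rec.group))
    return MultipleAlignment(rows)
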