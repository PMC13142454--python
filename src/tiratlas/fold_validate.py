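"""Structure-topology validation of candidate domains.

The canonical TIR fold is a flavodoxin-like α/β sandwich: five parallel
β-strands wrapped by five α-helices. Candidate structures (predicted
models, supplied as minimal N/CA/C backbones, or precomputed {H,E,C}
strings) are gated on a count rule: a model passes when it shows at
least ``min_h`` helices and ``min_e`` strands of the expected (5, 5),
with defaults (4, 3). The rule is a lower bound — extra elements never
cause a failure — and no sheet-topology or alternation requirement is
imposed.

Secondary structure is assigned from backbone dihedrals (region-based
classification in the Ramachandran plane), which is dependency-free and
adequate for counting elements on predicted models; externally produced
SS strings (e.g. from a hydrogen-bond assigner) are accepted on the same
footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import BackboneModel

logger = logging.getLogger("tiratlas")

# Ramachandran windows (degrees)
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-170.0, -70.0)
STRAND_PSI_MAIN = (90.0, 180.0)
STRAND_PSI_WRAP = (-180.0, -170.0)

EXPECTED_HELICES = 5
EXPECTED_STRANDS = 5
DEFAULT_MIN_H = 4
DEFAULT_MIN_E = 3


@dataclass(frozen=True)
class SSElement:
    kind: str   # "H" or "E"
    start: int  # 1-based inclusive residue positions in the SS string
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FoldVerdict:
    n_helix_elements: int
    n_strand_elements: int
    passed: bool
    elements: list[SSElement]


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) of p0-p1-p2-p3."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def phi_psi(model: BackboneModel) -> list[tuple[float | None, float | None]]:
    """Per-residue (φ, ψ); None at chain termini and around unassignable
    residues."""
    res = model.residues
    out: list[tuple[float | None, float | None]] = []
    for i, r in enumerate(res):
        phi = psi = None
        if r.assignable:
            if i > 0 and res[i - 1].assignable:
                phi = dihedral(
                    res[i - 1].coords["C"], r.coords["N"],
                    r.coords["CA"], r.coords["C"],
                )
            if i < len(res) - 1 and res[i + 1].assignable:
                psi = dihedral(
                    r.coords["N"], r.coords["CA"],
                    r.coords["C"], res[i + 1].coords["N"],
                )
        out.append((phi, psi))
    return out


def _in(window: tuple[float, float], v: float) -> bool:
    return window[0] <= v <= window[1]


def _classify(phi: float | None, psi: float | None) -> str:
    if phi is None or psi is None:
        return "C"
    if _in(HELIX_PHI, phi) and _in(HELIX_PSI, psi):
        return "H"
    if _in(STRAND_PHI, phi) and (
        _in(STRAND_PSI_MAIN, psi) or _in(STRAND_PSI_WRAP, psi)
    ):
        return "E"
    return "C"


def assign_secondary_structure(model: BackboneModel) -> str:
    """Per-residue {H,E,C} string from backbone dihedrals.

    Single-residue label islands are smoothed to their (agreeing)
    neighbors. Unassignable residues are labeled C with a warning.
    """
    if model.n_assignable() < 5:
        raise ValueError(
            f"too few assignable residues ({model.n_assignable()}); "
            "need >= 5 for dihedrals plus smoothing"
        )
    if model.n_assignable() < len(model):
        logger.warning(
            "%d residues lack backbone atoms; labeled C",
            len(model) - model.n_assignable(),
        )
    labels = [_classify(phi, psi) for phi, psi in phi_psi(model)]
    # smooth single-residue islands flanked by an agreeing pair
    for i in range(1, len(labels) - 1):
        if labels[i - 1] == labels[i + 1] != labels[i]:
            labels[i] = labels[i - 1]
    return "".join(labels)


def segment_elements(
    ss: str, min_helix_len: int = 4, min_strand_len: int = 3
) -> list[SSElement]:
    """Maximal H/E runs meeting the per-type minimum length; shorter runs
    dissolve to coil. Positions are 1-based inclusive."""
    bad = set(ss) - set("HEC")
    if bad:
        raise ValueError(f"invalid SS letters: {sorted(bad)}")
    elements: list[SSElement] = []
    i = 0
    while i < len(ss):
        ch = ss[i]
        j = i
        while j < len(ss) and ss[j] == ch:
            j += 1
        run_len = j - i
        if ch == "H" and run_len >= min_helix_len:
            elements.append(SSElement("H", i + 1, j))
        elif ch == "E" and run_len >= min_strand_len:
            elements.append(SSElement("E", i + 1, j))
        i = j
    return elements


def tir_fold_check(
    elements: list[SSElement],
    min_h: int = DEFAULT_MIN_H,
    min_e: int = DEFAULT_MIN_E,
) -> FoldVerdict:
    """Count helix/strand elements and apply the lower-bound fold rule."""
    n_h = sum(1 for e in elements if e.kind == "H")
    n_e = sum(1 for e in elements if e.kind == "E")
    return FoldVerdict(n_h, n_e, n_h >= min_h and n_e >= min_e, list(elements))


def gate_candidates(
    candidates: dict[str, BackboneModel | str],
    min_h: int = DEFAULT_MIN_H,
    min_e: int = DEFAULT_MIN_E,
    min_helix_len: int = 4,
    min_strand_len: int = 3,
    missing_policy: str = "pass",
):
    """Build the fold-gate predicate for the iterative search.

    ``candidates`` maps record id to a BackboneModel or an {H,E,C}
    string. Returns (predicate: record_id -> bool, verdicts: dict).
    Records without a structure follow ``missing_policy`` ("pass" with a
    warning, or "fail").
    """
    if missing_policy not in ("pass", "fail"):
        raise ValueError("missing_policy must be 'pass' or 'fail'")
    verdicts: dict[str, FoldVerdict] = {}
    for rec_id, obj in candidates.items():
        try:
            ss = obj if isinstance(obj, str) else assign_secondary_structure(obj)
            elements = segment_elements(ss, min_helix_len, min_strand_len)
            verdicts[rec_id] = tir_fold_check(elements, min_h, min_e)
        except (ValueError, KeyError) as exc:
            logger.warning("candidate %s: unusable structure (%s)", rec_id, exc)
            verdicts[rec_id] = FoldVerdict(0, 0, missing_policy == "pass", [])

    def predicate(rec_id: str) -> bool:
        if rec_id in verdicts:
            return verdicts[rec_id].passed
        if missing_policy == "pass":
            logger.warning("candidate %s has no structure; passing through", rec_id)
            return True
        return False

    return predicate, verdicts
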