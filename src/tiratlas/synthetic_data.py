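"""Synthetic inputs with planted ground truth.

Emulates the statistical structure of a cross-kingdom domain search
universe: several deeply diverged domain families, each family a tight
clade of related sequences, every domain embedded inside a longer host
protein between random flanks, plus composition-matched shuffled decoys.
Also generates species trees with planted single-origin gain/loss
histories and idealized protein backbones of prescribed α/β topology.

Nothing downstream reads the truth tables; they exist so tests and the
acceptance experiments can score recall, boundary accuracy, clade
recovery, and event reconstruction against known answers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .formats_io import (
    AMINO_ACIDS,
    BACKGROUND_ARRAY,
    BackboneModel,
    BackboneResidue,
    ProteinDB,
    ProteinRecord,
    read_newick,
)

logger = logging.getLogger("tiratlas")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the planted-truth search universe.

    Defaults define the bundled desk profile: 6 families x 40 members,
    120-residue domains, divergence high enough that inter-family
    identity sits near the twilight zone while intra-family identity
    stays recognizably homologous, and 600 shuffled decoys.
    """

    n_clades: int = 6
    seqs_per_clade: int = 40
    domain_length: int = 120
    subst_rate: float = 0.15       # expected substitutions/site per unit branch
    indel_rate: float = 0.01       # expected indel events/site per unit branch
    flank_length_range: tuple[int, int] = (30, 60)
    n_decoys: int = 600
    seed: int = 0
    # branch-length regime: intra-clade edges ~ U(min,max), inter-clade
    # edges fixed and long (>= 5x the intra mean by construction)
    intra_branch_range: tuple[float, float] = (0.05, 0.25)
    inter_branch_length: float = 5.0

    def __post_init__(self):
        if self.n_clades < 1:
            raise ConfigurationError("n_clades must be >= 1")
        if self.seqs_per_clade < 1:
            raise ConfigurationError("seqs_per_clade must be >= 1")
        if self.domain_length < 20:
            raise ConfigurationError("domain_length must be >= 20")
        if self.subst_rate < 0 or self.indel_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        lo, hi = self.flank_length_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("flank_length_range must be 0 <= min <= max")
        if self.n_decoys < 0:
            raise ConfigurationError("n_decoys must be >= 0")
        intra_mean = sum(self.intra_branch_range) / 2
        if self.inter_branch_length < 5 * intra_mean:
            raise ConfigurationError(
                "inter-clade branches must be >= 5x the intra-clade mean"
            )


@dataclass
class TruthRecord:
    record_id: str
    clade: str              # "clade1".."cladeN" or "decoy"
    dom_start: int | None   # 1-based inclusive, None for decoys
    dom_end: int | None


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)
    ancestors: dict[str, str] = field(default_factory=dict)  # clade -> sequence

    def by_id(self) -> dict[str, TruthRecord]:
        return {t.record_id: t for t in self.records}

    def non_decoys(self) -> list[TruthRecord]:
        return [t for t in self.records if t.clade != "decoy"]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("record_id\tclade\tdom_start\tdom_end\n")
            for t in self.records:
                s = "" if t.dom_start is None else str(t.dom_start)
                e = "" if t.dom_end is None else str(t.dom_end)
                fh.write(f"{t.record_id}\t{t.clade}\t{s}\t{e}\n")


def clade_name(i: int) -> str:
    return f"clade{i}"


def leaf_name(clade_i: int, seq_i: int) -> str:
    return f"c{clade_i}_s{seq_i}"


# ---------------------------------------------------------------------------
# Family tree

def simulate_family_tree(cfg: SimConfig) -> dendropy.Tree:
    """Rooted binary tree with ``n_clades`` monophyletic leaf groups
    separated by long internal branches.

    Each clade subtree is built by random sequential joins with short
    branches; clade roots are then joined by a ladder of long branches.
    """
    rng = np.random.default_rng(_substream(cfg.seed, 1))
    lo, hi = cfg.intra_branch_range

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    clade_frags = []
    for ci in range(1, cfg.n_clades + 1):
        frags = [leaf_name(ci, si) for si in range(1, cfg.seqs_per_clade + 1)]
        while len(frags) > 1:
            i = int(rng.integers(0, len(frags)))
            a = frags.pop(i)
            j = int(rng.integers(0, len(frags)))
            b = frags.pop(j)
            frags.append(f"({a}:{blen():.6g},{b}:{blen():.6g})")
        clade_frags.append(frags[0])

    ib = cfg.inter_branch_length
    tree_str = clade_frags[0]
    if cfg.n_clades == 1:
        if cfg.seqs_per_clade == 1:
            tree_str = f"({tree_str}:{blen():.6g})"
        newick = tree_str + ";"
    else:
        for frag in clade_frags[1:]:
            tree_str = f"({tree_str}:{ib:.6g},{frag}:{ib:.6g})"
        newick = tree_str + ";"
    tree = read_newick(newick)
    tree.is_rooted = True
    return tree


def _substream(seed: int, salt: int) -> int:
    # independent child streams, kept below 2**31
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Sequence evolution

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND_ARRAY)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(seq: str, branch_length: float, cfg: SimConfig,
            rng: np.random.Generator) -> str:
    """Apply Poisson(rate * L * t) substitutions (uniform over the 19
    alternatives) then Poisson indel events with geometric lengths
    (mean 2), scaled by branch length."""
    chars = list(seq)
    L = len(chars)
    n_sub = rng.poisson(cfg.subst_rate * L * branch_length)
    for _ in range(n_sub):
        pos = int(rng.integers(0, len(chars)))
        old = chars[pos]
        alts = AMINO_ACIDS.replace(old, "")
        chars[pos] = alts[int(rng.integers(0, 19))]
    n_indel = rng.poisson(cfg.indel_rate * L * branch_length)
    for _ in range(n_indel):
        ilen = int(rng.geometric(0.5))  # mean 2
        if rng.random() < 0.5 and len(chars) > ilen + 10:
            pos = int(rng.integers(0, len(chars) - ilen))
            del chars[pos:pos + ilen]
        else:
            pos = int(rng.integers(0, len(chars) + 1))
            chars[pos:pos] = list(_random_sequence(rng, ilen))
    return "".join(chars)


def evolve_domain_sequences(
    tree: dendropy.Tree, cfg: SimConfig
) -> tuple[list[ProteinRecord], TruthTable]:
    """One domain-only record per leaf, evolved from per-clade ancestors.

    A single root ancestor is drawn from the background composition and
    evolved down the whole tree, so families share remote homology (as
    domain superfamilies do) while the long inter-clade branches create
    deep divergence between families.
    """
    rng = np.random.default_rng(_substream(cfg.seed, 2))
    root_seq = _random_sequence(rng, cfg.domain_length)
    truth = TruthTable()
    records: list[ProteinRecord] = []

    seqs: dict[int, str] = {}
    root = tree.seed_node
    seqs[id(root)] = root_seq
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_seq = seqs[id(node.parent_node)]
        bl = node.edge.length or 0.0
        seqs[id(node)] = _mutate(parent_seq, bl, cfg, rng)

    # per-clade ancestors = sequence at each clade's MRCA
    leaf_clade = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        ci = int(name.split("_")[0][1:])
        leaf_clade[name] = ci
    taxon_ns = tree.taxon_namespace
    for ci in sorted(set(leaf_clade.values())):
        members = [n for n, c in leaf_clade.items() if c == ci]
        if len(members) == 1:
            node = next(
                lf for lf in tree.leaf_node_iter() if lf.taxon.label == members[0]
            )
        else:
            node = tree.mrca(taxa=[taxon_ns.get_taxon(m) for m in members])
        truth.ancestors[clade_name(ci)] = seqs[id(node)]

    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        ci = leaf_clade[name]
        records.append(
            ProteinRecord(name, seqs[id(leaf)], taxon=name, group=clade_name(ci))
        )
        truth.records.append(
            TruthRecord(name, clade_name(ci), 1, len(seqs[id(leaf)]))
        )
    return records, truth


# ---------------------------------------------------------------------------
# Embedding and decoys

def embed_domains(
    domains: list[ProteinRecord], cfg: SimConfig, truth: TruthTable | None = None
) -> tuple[ProteinDB, TruthTable]:
    """Flank every domain with random sequence and add shuffled decoys.

    Flank lengths are drawn uniformly from ``flank_length_range``
    (inclusive). Decoys are residue-shuffled copies of randomly chosen
    embedded records, so their composition matches the positives.
    Truth coordinates are 1-based inclusive.
    """
    if not domains:
        raise ConfigurationError("no domain records to embed")
    rng = np.random.default_rng(_substream(cfg.seed, 3))
    lo, hi = cfg.flank_length_range
    old_truth = truth.by_id() if truth is not None else {}

    db = ProteinDB()
    new_truth = TruthTable(ancestors=dict(truth.ancestors) if truth else {})
    for rec in domains:
        nlen = int(rng.integers(lo, hi + 1))
        clen = int(rng.integers(lo, hi + 1))
        nflank = _random_sequence(rng, nlen)
        cflank = _random_sequence(rng, clen)
        full = nflank + rec.sequence + cflank
        db.add(ProteinRecord(rec.id, full, rec.taxon, rec.group))
        clade = old_truth[rec.id].clade if rec.id in old_truth else rec.group
        new_truth.records.append(
            TruthRecord(rec.id, clade, nlen + 1, nlen + len(rec.sequence))
        )
    host_seqs = [r.sequence for r in db.records]
    for k in range(1, cfg.n_decoys + 1):
        src = host_seqs[int(rng.integers(0, len(host_seqs)))]
        shuffled = "".join(rng.permutation(list(src)))
        rec_id = f"decoy{k}"
        db.add(ProteinRecord(rec_id, shuffled, taxon=rec_id, group="decoy"))
        new_truth.records.append(TruthRecord(rec_id, "decoy", None, None))
    return db, new_truth


def simulate_database(cfg: SimConfig):
    """Full generator pipeline: tree -> domain sequences -> embedded db.

    Returns (tree, db, truth)."""
    tree = simulate_family_tree(cfg)
    domains, truth = evolve_domain_sequences(tree, cfg)
    db, truth = embed_domains(domains, cfg, truth)
    return tree, db, truth


def seed_alignment_for_clade(
    cfg: SimConfig, truth: TruthTable, db: ProteinDB, clade: str, n_members: int = 8
):
    """Seed alignment from the first ``n_members`` planted domains of a
    family, template-stacked on the first member (generator-side helper
    for building search seeds without external aligners)."""
    from .align_trim_tree import stack_alignment

    members = [t for t in truth.non_decoys() if t.clade == clade][:n_members]
    if not members:
        raise ConfigurationError(f"no members for clade {clade!r}")
    recs = []
    for t in members:
        full = db[t.record_id].sequence
        dom = full[t.dom_start - 1:t.dom_end]
        recs.append(ProteinRecord(t.record_id, dom, group=clade))
    return stack_alignment(recs[0], recs)


# ---------------------------------------------------------------------------
# Presence/absence histories

def simulate_presence_matrix(
    species_tree: dendropy.Tree,
    origin_node: dendropy.Node,
    loss_branches: list[dendropy.Node],
    dup_branches: list[dendropy.Node] | None = None,
    family: str = "fam1",
):
    """Single-origin gain with losses and duplications planted on branches.

    ``loss_branches`` / ``dup_branches`` are nodes whose subtending edge
    carries the event; all must lie strictly inside the origin subtree,
    and loss branches must be disjoint (no loss below another loss).
    Returns (counts: dict species -> int, truth: dict).
    """
    dup_branches = dup_branches or []
    origin_leaves = {lf.taxon.label for lf in _leaves_below(origin_node)}
    for ev in list(loss_branches) + list(dup_branches):
        ev_leaves = {lf.taxon.label for lf in _leaves_below(ev)}
        if not ev_leaves <= origin_leaves or ev is origin_node:
            raise ConfigurationError(
                "event branch outside the origin subtree"
            )
    for i, a in enumerate(loss_branches):
        a_leaves = {lf.taxon.label for lf in _leaves_below(a)}
        for b in loss_branches[i + 1:]:
            b_leaves = {lf.taxon.label for lf in _leaves_below(b)}
            if a_leaves & b_leaves:
                raise ConfigurationError("loss branches must be disjoint")

    counts: dict[str, int] = {}
    lost: set[str] = set()
    for nd in loss_branches:
        lost |= {lf.taxon.label for lf in _leaves_below(nd)}
    for leaf in species_tree.leaf_node_iter():
        name = leaf.taxon.label
        if name not in origin_leaves or name in lost:
            counts[name] = 0
        else:
            counts[name] = 1
    for nd in dup_branches:
        for lf in _leaves_below(nd):
            name = lf.taxon.label
            if counts[name] > 0:
                counts[name] += 1
    truth = {
        "family": family,
        "origin_leaves": frozenset(origin_leaves),
        "n_losses": len(loss_branches),
        "n_duplications": len(dup_branches),
    }
    return counts, truth


def _leaves_below(node: dendropy.Node):
    if node.is_leaf():
        return [node]
    return list(node.leaf_iter())


# ---------------------------------------------------------------------------
# Idealized backbones

# ideal backbone geometry (lengths in Å, angles in degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_ANGLE = {"N-CA-C": 111.0, "CA-C-N": 116.2, "C-N-CA": 121.7}
HELIX_PHI_PSI = (-60.0, -45.0)
STRAND_PHI_PSI = (-120.0, 120.0)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom d given chain a-b-c and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def synthesize_backbone(
    n_helices: int,
    n_strands: int,
    helix_length: int = 10,
    strand_length: int = 6,
    linker_length: int = 4,
    seed: int = 0,
    alternate: bool = True,
) -> tuple[BackboneModel, str]:
    """Backbone (N/CA/C) built from ideal dihedrals, plus its ideal
    secondary-structure truth string.

    Helices use (φ,ψ)=(-60,-45), strands (-120,+120); linkers of at
    least 3 residues get randomized coil dihedrals outside both regions.
    With ``alternate`` the elements interleave β-α-β-α-… as in a
    Rossmann-like α/β topology; otherwise all strands precede helices.
    """
    if n_helices < 0 or n_strands < 0:
        raise ConfigurationError("element counts must be >= 0")
    if linker_length < 3:
        raise ConfigurationError("linkers must be >= 3 residues")
    if helix_length < 4 or strand_length < 3:
        logger.warning(
            "element length below the assigner's minimum: helices < 4 or "
            "strands < 3 residues will dissolve to coil"
        )
    rng = np.random.default_rng(seed)

    elements: list[tuple[str, int]] = []
    if alternate:
        h, e = n_helices, n_strands
        while h or e:
            if e:
                elements.append(("E", strand_length))
                e -= 1
            if h:
                elements.append(("H", helix_length))
                h -= 1
    else:
        elements += [("E", strand_length)] * n_strands
        elements += [("H", helix_length)] * n_helices

    def coil_phi_psi():
        # polyproline-II-like region: outside both assignment windows
        return (float(rng.uniform(-180, -171)), float(rng.uniform(30, 80)))

    phi_psi: list[tuple[float, float]] = []
    ss_chars: list[str] = []
    for _ in range(linker_length):
        phi_psi.append(coil_phi_psi())
        ss_chars.append("C")
    for kind, length in elements:
        target = HELIX_PHI_PSI if kind == "H" else STRAND_PHI_PSI
        for _ in range(length):
            phi_psi.append(target)
            ss_chars.append(kind)
        for _ in range(linker_length):
            phi_psi.append(coil_phi_psi())
            ss_chars.append("C")

    n_res = len(phi_psi)
    residues: list[BackboneResidue] = []
    # seed the first residue explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append(BackboneResidue(1, {"N": n0, "CA": ca0, "C": c0}))
    prev = {"N": n0, "CA": ca0, "C": c0}
    for i in range(1, n_res):
        phi, psi = phi_psi[i]
        _, psi_prev = phi_psi[i - 1]
        # N(i): dihedral psi(i-1) about N(i-1)-CA(i-1)-C(i-1)
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"],
                          _BOND["C-N"], _ANGLE["CA-C-N"], psi_prev)
        # CA(i): omega = 180 about CA(i-1)-C(i-1)-N(i)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i,
                           _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        # C(i): dihedral phi(i) about C(i-1)-N(i)-CA(i)
        c_i = _place_atom(prev["C"], n_i, ca_i,
                          _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        residues.append(BackboneResidue(i + 1, {"N": n_i, "CA": ca_i, "C": c_i}))
        prev = {"N": n_i, "CA": ca_i, "C": c_i}

    return BackboneModel(residues), "".join(ss_chars)
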