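"""Readers, writers and small sequence utilities.

Every interface in the package uses 1-based, inclusive coordinates for
domain envelopes and alignment columns; conversion to 0-based half-open
indexing happens only inside algorithms.

Formats handled: FASTA (plain and aligned), Stockholm (read-only), Newick
trees with internal-node support labels, TSV domain-hit tables, minimal
PDB backbones (ATOM records, N/CA/C only), and FASTA-like secondary-
structure strings over {H, E, C}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("tiratlas")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
GAP = "-"

#: Canonical amino-acid background frequencies (Robinson & Robinson-style
#: composition, renormalized); bundled as a constant so that profile
#: construction and decoy generation need no external data.
BACKGROUND_FREQS = {
    "A": 0.0787, "C": 0.0151, "D": 0.0535, "E": 0.0668, "F": 0.0397,
    "G": 0.0695, "H": 0.0229, "I": 0.0590, "K": 0.0581, "L": 0.0963,
    "M": 0.0238, "N": 0.0406, "P": 0.0484, "Q": 0.0393, "R": 0.0540,
    "S": 0.0683, "T": 0.0541, "V": 0.0673, "W": 0.0114, "Y": 0.0332,
}
_total = sum(BACKGROUND_FREQS.values())
BACKGROUND_FREQS = {a: v / _total for a, v in BACKGROUND_FREQS.items()}
BACKGROUND_ARRAY = np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS])


class DuplicateIdError(ValueError):
    """Two records in one database share an id."""


class UndefinedValueError(ValueError):
    """A quantity is undefined for the given input (e.g. GC of all-N)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with taxon/group annotation.

    ``group`` carries the coarse taxonomic partition used by the
    downsampling stage (e.g. "Metazoa", "Amoebozoa", "Bacteria",
    "Archaea", "other-eukaryote").
    """

    id: str
    sequence: str
    taxon: str = ""
    group: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence length must be >= 1")
        bad = set(self.sequence) - AA_SET - {"X"}
        if bad:
            cleaned = "".join(
                c if c in AA_SET or c == "X" else "X" for c in self.sequence
            )
            logger.warning(
                "record %s: non-canonical letters %s mapped to X",
                self.id, "".join(sorted(bad)),
            )
            object.__setattr__(self, "sequence", cleaned)

    def __len__(self) -> int:
        return len(self.sequence)


class ProteinDB:
    """An ordered collection of ProteinRecords with unique ids."""

    def __init__(self, records: Iterable[ProteinRecord] = ()):
        self.records: list[ProteinRecord] = []
        self._index: dict[str, int] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: ProteinRecord) -> None:
        if rec.id in self._index:
            raise DuplicateIdError(f"duplicate record id: {rec.id!r}")
        self._index[rec.id] = len(self.records)
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def __getitem__(self, rec_id: str) -> ProteinRecord:
        return self.records[self._index[rec_id]]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def total_residues(self) -> int:
        return sum(len(r) for r in self.records)

    def subset(self, ids: Iterable[str]) -> "ProteinDB":
        wanted = set(ids)
        return ProteinDB(r for r in self.records if r.id in wanted)


@dataclass
class MultipleAlignment:
    """Rows of equal length over the amino-acid alphabet plus '-'."""

    records: list[ProteinRecord]

    def __post_init__(self):
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def ungapped(self, i: int) -> str:
        return self.records[i].sequence.replace(GAP, "")

    def column(self, c: int) -> str:
        """Column ``c`` (0-based) as a string of per-row characters."""
        return "".join(r.sequence[c] for r in self.records)

    def to_array(self) -> np.ndarray:
        """(n_rows, n_columns) array of single-character strings."""
        return np.array([list(r.sequence) for r in self.records])


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    rec_id = parts[0].strip().split()[0]
    taxon = parts[1].strip() if len(parts) > 1 else ""
    group = parts[2].strip() if len(parts) > 2 else ""
    return rec_id, taxon, group


def _iter_fasta(path: Path):
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header, chunks = line[1:], []
            elif line.strip():
                chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path) -> ProteinDB:
    """Read a FASTA file into a ProteinDB.

    Headers are parsed as ``id[|taxon[|group]]``; missing fields default
    to "". Duplicate ids raise; an empty file yields an empty db with a
    warning. '.' gap characters are normalized to '-'.
    """
    path = Path(path)
    db = ProteinDB()
    for header, seq in _iter_fasta(path):
        rec_id, taxon, group = _parse_header(header)
        db.add(ProteinRecord(rec_id, seq.upper().replace(".", GAP), taxon, group))
    if len(db) == 0:
        logger.warning("empty FASTA: %s", path)
    return db


def write_fasta(db: Iterable[ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in db:
            header = rec.id
            if rec.taxon or rec.group:
                header += f"|{rec.taxon}"
            if rec.group:
                header += f"|{rec.group}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_alignment(path) -> MultipleAlignment:
    """Read an aligned FASTA file (gap character '-', '.' normalized)."""
    recs = []
    for header, seq in _iter_fasta(Path(path)):
        rec_id, taxon, group = _parse_header(header)
        recs.append(_aligned_record(rec_id, seq, taxon, group))
    return MultipleAlignment(recs)


def _aligned_record(rec_id, seq, taxon="", group="") -> ProteinRecord:
    """Build a record allowed to contain gaps (bypasses alphabet mapping)."""
    seq = seq.upper().replace(".", GAP)
    rec = ProteinRecord.__new__(ProteinRecord)
    object.__setattr__(rec, "id", rec_id)
    object.__setattr__(rec, "sequence", seq)
    object.__setattr__(rec, "taxon", taxon)
    object.__setattr__(rec, "group", group)
    if not rec_id or not seq:
        raise ValueError("aligned record needs id and sequence")
    return rec


def aligned_record(rec_id: str, seq: str, taxon: str = "", group: str = "") -> ProteinRecord:
    """Public constructor for gapped rows."""
    return _aligned_record(rec_id, seq, taxon, group)


def write_alignment(aln: MultipleAlignment, path) -> None:
    write_fasta(aln.records, path)


def read_stockholm(path) -> MultipleAlignment:
    """Read a Stockholm alignment (sequence lines only; markup ignored)."""
    rows: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "//")):
                continue
            name, _, seq = line.partition(" ")
            seq = seq.strip()
            if not seq:
                continue
            if name not in rows:
                rows[name] = []
                order.append(name)
            rows[name].append(seq)
    recs = [_aligned_record(n, "".join(rows[n])) for n in order]
    if not recs:
        raise ValueError(f"no sequence rows in Stockholm file {path}")
    return MultipleAlignment(recs)


# ---------------------------------------------------------------------------
# Newick trees

def read_newick(path_or_string, support_scale: str = "auto") -> dendropy.Tree:
    """Read a Newick tree; internal-node labels are supports on a 0-100 scale.

    support_scale:
      - "auto": if every support is <= 1.0 they are taken as fractions and
        multiplied by 100 (logged); otherwise as percent.
      - "percent": taken as-is.
      - "fraction": multiplied by 100.
    """
    s = str(path_or_string)
    if "(" in s and ";" in s:
        tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=s, schema="newick", preserve_underscores=True)
    supports = []
    for nd in tree.internal_nodes():
        if nd.label is not None and _is_number(nd.label):
            supports.append(float(nd.label))
    if supports:
        if support_scale == "fraction" or (
            support_scale == "auto" and max(supports) <= 1.0
        ):
            if support_scale == "auto":
                logger.info("supports <= 1.0: interpreting as fractions x100")
            for nd in tree.internal_nodes():
                if nd.label is not None and _is_number(nd.label):
                    nd.label = _fmt_support(float(nd.label) * 100.0)
        for nd in tree.internal_nodes():
            if nd.label is not None and _is_number(nd.label):
                v = float(nd.label)
                if not (0.0 <= v <= 100.0):
                    raise ValueError(f"support {v} outside [0, 100]")
    return tree


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def _fmt_support(v: float) -> str:
    return f"{v:g}"


def node_support(node: dendropy.Node) -> float | None:
    """Support of an internal node, or None when absent."""
    if node.label is not None and _is_number(node.label):
        return float(node.label)
    return None


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


# ---------------------------------------------------------------------------
# Domain-hit tables

HIT_COLUMNS = ["target_id", "profile_id", "score", "e_value", "env_start", "env_end"]


def hits_to_frame(rows: Iterable[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=HIT_COLUMNS)
    _validate_hits(df)
    return df


def _validate_hits(df: pd.DataFrame) -> None:
    if len(df) == 0:
        return
    if (df.env_start < 1).any() or (df.env_start > df.env_end).any():
        raise ValueError("envelope coordinates must satisfy 1 <= start <= end")
    if (df.e_value < 0).any():
        raise ValueError("e_value must be >= 0")


def write_hits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=HIT_COLUMNS)


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    _validate_hits(df)
    return df[HIT_COLUMNS]


# ---------------------------------------------------------------------------
# GC content

def compute_gc(seq: str) -> float:
    """GC fraction of a nucleotide sequence; N excluded from both sides."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"not a nucleotide sequence: letters {sorted(bad)}")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise UndefinedValueError("GC undefined: no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / denom


# ---------------------------------------------------------------------------
# Minimal PDB backbones

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class BackboneResidue:
    resnum: int
    coords: dict  # atom name -> np.ndarray(3,)

    @property
    def assignable(self) -> bool:
        return all(a in self.coords for a in BACKBONE_ATOMS)


@dataclass
class BackboneModel:
    """Ordered backbone residues (N/CA/C) of a single chain."""

    residues: list[BackboneResidue]

    def __len__(self) -> int:
        return len(self.residues)

    def n_assignable(self) -> int:
        return sum(r.assignable for r in self.residues)


def read_backbone(path) -> BackboneModel:
    """Parse ATOM records (N, CA, C) of the first chain of a minimal PDB."""
    residues: dict[int, BackboneResidue] = {}
    chain = None
    n_atoms = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            name = line[12:16].strip()
            if name not in BACKBONE_ATOMS:
                continue
            this_chain = line[21]
            if chain is None:
                chain = this_chain
            elif this_chain != chain:
                continue
            resnum = int(line[22:26])
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            residues.setdefault(resnum, BackboneResidue(resnum, {}))
            residues[resnum].coords[name] = xyz
            n_atoms += 1
    if n_atoms == 0:
        raise ValueError(f"no backbone ATOM records in {path}")
    ordered = [residues[k] for k in sorted(residues)]
    n_bad = sum(not r.assignable for r in ordered)
    if n_bad:
        logger.warning("%s: %d residues missing backbone atoms", path, n_bad)
    return BackboneModel(ordered)


def write_backbone(model: BackboneModel, path, chain: str = "A") -> None:
    serial = 1
    with open(path, "w") as fh:
        for res in model.residues:
            for name in BACKBONE_ATOMS:
                if name not in res.coords:
                    continue
                x, y, z = res.coords[name]
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s}GLY {chain}{res.resnum:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                    f"{name[0]}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Secondary-structure strings

SS_ALPHABET = frozenset("HEC")


def read_ss_fasta(path) -> dict[str, str]:
    """FASTA-like file of {H,E,C} strings, keyed by record id."""
    out = {}
    for header, seq in _iter_fasta(Path(path)):
        rec_id, _, _ = _parse_header(header)
        seq = seq.upper()
        bad = set(seq) - SS_ALPHABET
        if bad:
            raise ValueError(f"{rec_id}: invalid SS letters {sorted(bad)}")
        if rec_id in out:
            raise DuplicateIdError(f"duplicate SS record id: {rec_id!r}")
        out[rec_id] = seq
    return out


def write_ss_fasta(ss: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for rec_id, s in ss.items():
            fh.write(f">{rec_id}\n{s}\n")


# ---------------------------------------------------------------------------
# Presence/count matrices (species x family TSV)

def read_presence_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("gene counts must be nonnegative")
    return df.astype(int)


def write_presence_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
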