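"""MSA-guided residue renumbering.

Every chain is mapped onto a class-specific structure-guided MSA: the chain
sequence is matched to its best-identity row, aligned to the ungapped row,
and the composition with the row's gap pattern yields a map from author
residue numbers to 1-based MSA columns ("renumbered positions"). Those
columns serve as a universal residue coordinate across all structures of a
class; the Backbone Brackets live at columns 274/1361 (Class I) and the
Arginine Tweezers at 698/1786 (Class II).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .dataset import global_alignment, global_identity
from .structure import StructureChain, copy_chain

#: below this best-row identity (percent) the mapping is refused
MAPPING_IDENTITY_THRESHOLD = 40.0

#: chains shorter than this are not mapped
MIN_CHAIN_LENGTH = 30


class MappingError(ValueError):
    """Raised when no MSA row matches a chain well enough."""


@dataclass(frozen=True)
class MsaRow:
    row_id: str
    aligned: str

    @property
    def columns(self) -> int:
        return len(self.aligned)

    @property
    def ungapped(self) -> str:
        return self.aligned.replace("-", "").replace(".", "")

    def residue_columns(self) -> list[int]:
        """1-based MSA column of each ungapped residue, in order."""
        return [i + 1 for i, c in enumerate(self.aligned) if c not in "-."]


def read_msa(path: str | Path) -> list[MsaRow]:
    rows = [
        MsaRow(row_id=rec.id, aligned=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not rows:
        raise ValueError(f"no sequences in {path}")
    lengths = {r.columns for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"MSA rows differ in length: {sorted(lengths)}")
    return rows


@dataclass
class RenumberMap:
    """Injective partial map from author numbering to MSA columns."""

    entries: dict[tuple[int, str], int]
    row_id: str = ""
    identity: float = 0.0
    unmapped_author: list[tuple[int, str]] = field(default_factory=list)
    unmapped_columns: list[int] = field(default_factory=list)

    def __post_init__(self):
        cols = list(self.entries.values())
        if len(cols) != len(set(cols)):
            raise ValueError("renumber map is not injective")
        if cols != sorted(cols):
            raise ValueError("MSA columns must increase along the chain")

    def column_of(self, author_number: int, icode: str = "") -> int | None:
        return self.entries.get((author_number, icode))


@dataclass(frozen=True)
class MotifDefinition:
    aars_class: str
    positions: tuple[int, int]
    name: str
    auxiliary: tuple[int, ...] = ()

    def __post_init__(self):
        if self.positions[0] == self.positions[1]:
            raise ValueError("motif positions must be distinct")


BACKBONE_BRACKETS = MotifDefinition("I", (274, 1361), "Backbone Brackets")
ARGININE_TWEEZERS = MotifDefinition("II", (698, 1786), "Arginine Tweezers", (700,))

MOTIF_OF_CLASS = {"I": BACKBONE_BRACKETS, "II": ARGININE_TWEEZERS}

#: named intervals of renumbered positions for the antisense (Rodin-Ohno)
#: region analysis: the Protozyme-bearing "HIGH-Motif 2" region and the
#: Urzyme-extending "KMSKS-Motif 1" region, per class
REGION_CATALOG = {
    ("I", "HIGH-Motif2"): (255, 336),
    ("II", "HIGH-Motif2"): (648, 718),
    ("I", "KMSKS-Motif1"): (1352, 1452),
    ("II", "KMSKS-Motif1"): (347, 371),
}


# ---------------------------------------------------------------------------

def map_chain_to_row(
    chain_seq: str,
    msa: Sequence[MsaRow],
    identity_threshold: float = MAPPING_IDENTITY_THRESHOLD,
):
    """Pick the MSA row with maximal global identity to the chain sequence.

    Returns ``(row, identity, alignment)`` where the alignment is chain
    sequence vs the ungapped row. Raises :class:`MappingError` when the best
    identity falls below the threshold.
    """
    if len(chain_seq) < MIN_CHAIN_LENGTH:
        raise MappingError(
            f"chain sequence too short to map ({len(chain_seq)} residues)"
        )
    best_row, best_ident = None, -1.0
    for row in msa:
        ident = global_identity(chain_seq, row.ungapped)
        if ident > best_ident:
            best_row, best_ident = row, ident
    if best_row is None or best_ident < identity_threshold:
        raise MappingError(
            f"best row identity {best_ident:.1f}% below "
            f"{identity_threshold:.0f}% - mapping refused"
        )
    alignment = global_alignment(chain_seq, best_row.ungapped)
    return best_row, best_ident, alignment


def build_renumber_map(
    chain: StructureChain,
    msa: Sequence[MsaRow],
    chain_seq: str | None = None,
    identity_threshold: float = MAPPING_IDENTITY_THRESHOLD,
) -> RenumberMap:
    """Compose chain->row alignment with the row's gap expansion."""
    from .structure import chain_sequence

    seq = chain_seq if chain_seq is not None else chain_sequence(chain, mode="parent")
    row, ident, alignment = map_chain_to_row(seq, msa, identity_threshold)
    row_cols = row.residue_columns()

    polymer = chain.polymer_residues
    if len(polymer) != len(seq):
        raise ValueError("chain sequence length does not match polymer residues")

    entries: dict[tuple[int, str], int] = {}
    matched_row_idx: set[int] = set()
    blocks_a, blocks_b = alignment.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for off in range(a1 - a0):
            i, j = a0 + off, b0 + off
            res = polymer[i]
            entries[(res.author_number, res.icode)] = row_cols[j]
            matched_row_idx.add(j)

    unmapped_author = [
        (r.author_number, r.icode)
        for r in polymer
        if (r.author_number, r.icode) not in entries
    ]
    unmapped_columns = [
        row_cols[j] for j in range(len(row_cols)) if j not in matched_row_idx
    ]
    return RenumberMap(
        entries=entries,
        row_id=row.row_id,
        identity=ident,
        unmapped_author=unmapped_author,
        unmapped_columns=unmapped_columns,
    )


def renumber_chain(chain: StructureChain, mapping: RenumberMap) -> StructureChain:
    """Return a copy whose polymer residues carry MSA columns as author
    numbers. Ligand records and chain identifiers are left unmodified;
    residues outside the map keep their original numbering."""
    if not mapping.entries:
        raise ValueError("renumber map covers no residues")
    out = copy_chain(chain)
    for res in out.residues:
        if not res.is_polymer:
            continue
        col = mapping.column_of(res.author_number, res.icode)
        if col is not None:
            res.author_number = col
            res.icode = ""
    out.residues.sort(key=lambda r: (not r.is_polymer, r.author_number, r.icode))
    return out


@dataclass
class MotifHit:
    """Motif occurrence in a renumbered chain, or a named absence."""

    motif: MotifDefinition
    residues: tuple | None
    missing: tuple[int, ...] = ()

    @property
    def mapped(self) -> bool:
        return self.residues is not None


def locate_motif(chain: StructureChain, motif: MotifDefinition) -> MotifHit:
    """Find both motif residues (with CA atoms) in a renumbered chain."""
    found = []
    missing = []
    for pos in motif.positions:
        res = chain.residue_at(pos)
        if res is None or res.ca is None or not res.is_polymer:
            missing.append(pos)
        else:
            found.append(res)
    if missing:
        return MotifHit(motif=motif, residues=None, missing=tuple(missing))
    return MotifHit(motif=motif, residues=tuple(found))


# ---------------------------------------------------------------------------
# mapping-table I/O (one row per mapped residue)

def write_mapping_table(
    maps: dict[tuple[str, str], RenumberMap], path: str | Path
) -> None:
    lines = ["pdb_id\tchain\tauthor_number\ticode\tmsa_column"]
    for (pdb_id, chain_id), m in sorted(maps.items()):
        for (num, icode), col in sorted(m.entries.items(), key=lambda kv: kv[1]):
            lines.append(f"{pdb_id}\t{chain_id}\t{num}\t{icode}\t{col}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mapping_table(path: str | Path) -> dict[tuple[str, str], RenumberMap]:
    maps: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("pdb_id")
        for line in fh:
            pdb_id, chain_id, num, icode, col = line.rstrip("\n").split("\t")
            maps.setdefault((pdb_id, chain_id), {})[(int(num), icode)] = int(col)
    return {
        key: RenumberMap(entries=dict(sorted(e.items(), key=lambda kv: kv[1])))
        for key, e in maps.items()
    }
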