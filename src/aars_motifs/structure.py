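"""Structure model: typed chains, residues, atoms and ligands from PDB files.

Parsing is backed by gemmi (PDB fixed-width is the reference dialect; mmCIF
is accepted through the same entry point). Only the first model of
multi-model files is read and, where alternate locations are present, the
highest-occupancy conformer is kept (ties resolved toward altloc 'A').
Waters are excluded. Every other HETATM group is attached to the chain
contributing the most polymer atoms within ``LIGAND_CONTACT_CUTOFF`` of any
of its atoms, or dropped with a log entry if no chain is that close.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: polymer atoms within this distance (A) of a ligand atom count as contacts
#: when attributing a HETATM group to a chain
LIGAND_CONTACT_CUTOFF = 4.0

#: slack added to the sum of covalent radii when inferring bonds in HET
#: groups that carry no connectivity records
BOND_SLACK = 0.4

# single-bond covalent radii (A), Cordero et al. consensus values
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "P": 1.07, "S": 1.05,
    "SE": 1.20, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "NA": 1.66, "MG": 1.41, "K": 2.03, "CA": 1.76, "ZN": 1.22,
    "MN": 1.39, "FE": 1.32, "CO": 1.26, "NI": 1.24, "CU": 1.32,
}

METAL_ELEMENTS = {"NA", "MG", "K", "CA", "ZN", "MN", "FE", "CO", "NI", "CU"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# modified residues mapped to their parent standard residue
PARENT_COMPONENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "CME": "CYS", "MLY": "LYS",
    "KCX": "LYS", "LLP": "LYS", "CSD": "CYS", "OCS": "CYS", "FME": "MET",
}

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom with PDB atom name, element symbol and coordinates (A)."""

    name: str
    element: str
    coords: tuple[float, float, float]

    def __post_init__(self):
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOM_NAMES


@dataclass
class Residue:
    """One residue: author numbering, 3-letter component code, atoms."""

    author_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    is_polymer: bool = True

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in residue {self.name} {self.author_number}"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def label(self) -> str:
        return f"{self.name} {self.author_number}{self.icode}"


@dataclass
class LigandRecord:
    """A heteroatom group with moiety flags driving binding-mode assignment.

    ``has_adenosine_phosphate`` and ``has_amino_acid_part`` are deterministic
    functions of the component code and the inferred atom graph; an
    aminoacyl-adenylate sets both.
    """

    component_code: str
    atoms: list[Atom] = field(default_factory=list)
    author_number: int = 0
    has_adenosine_phosphate: bool = False
    has_amino_acid_part: bool = False

    @property
    def is_metal_ion(self) -> bool:
        return len(self.atoms) == 1 and self.atoms[0].element.upper() in METAL_ELEMENTS


@dataclass
class StructureChain:
    """One polymer chain plus the ligands attributed to it."""

    structure_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[LigandRecord] = field(default_factory=list)

    @property
    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def residue_at(self, author_number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.author_number == author_number and r.icode == icode:
                return r
        return None


# ---------------------------------------------------------------------------
# component dictionary

def _load_component_table() -> dict[str, tuple[bool, bool]]:
    text = resources.files("aars_motifs.data").joinpath("components.json").read_text()
    raw = json.loads(text)
    return {k: (v["adenosine_phosphate"], v["amino_acid_part"]) for k, v in raw.items()}


_COMPONENT_TABLE: dict[str, tuple[bool, bool]] | None = None


def component_table() -> dict[str, tuple[bool, bool]]:
    global _COMPONENT_TABLE
    if _COMPONENT_TABLE is None:
        _COMPONENT_TABLE = _load_component_table()
    return _COMPONENT_TABLE


# ---------------------------------------------------------------------------
# bond graph and moiety detection

def bond_graph(atoms: Sequence[Atom]) -> nx.Graph:
    """Infer covalent bonds: distance < sum of covalent radii + 0.4 A."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    xyz = np.array([a.xyz for a in atoms]) if atoms else np.empty((0, 3))
    for i in range(len(atoms)):
        ri = COVALENT_RADII.get(atoms[i].element.upper(), 0.77)
        d = np.linalg.norm(xyz[i + 1:] - xyz[i], axis=1)
        rj = np.array(
            [COVALENT_RADII.get(a.element.upper(), 0.77) for a in atoms[i + 1:]]
        )
        for off in np.nonzero(d < ri + rj + BOND_SLACK)[0]:
            g.add_edge(i, int(i + 1 + off))
    return g


def _rings(g: nx.Graph) -> list[list[int]]:
    return nx.cycle_basis(g)


def find_nucleotide_moieties(atoms: Sequence[Atom], g: nx.Graph | None = None):
    """Locate adenine-like fused rings, furanose ring and phosphate atoms.

    Returns a dict with index sets ``adenine``, ``ribose``, ``phosphate``
    (possibly empty). The adenine set is the fused 6-5 N-heterocycle with at
    least four nitrogens; the ribose set is a 5-ring with exactly one ring
    oxygen bonded to the heterocycle; phosphate is every P plus its bonded
    oxygens.
    """
    if g is None:
        g = bond_graph(atoms)
    elem = [a.element.upper() for a in atoms]
    rings = _rings(g)
    six = [r for r in rings if len(r) == 6 and all(elem[i] in ("C", "N") for i in r)]
    five_cn = [r for r in rings if len(r) == 5 and all(elem[i] in ("C", "N") for i in r)]
    adenine: set[int] = set()
    for r6 in six:
        for r5 in five_cn:
            shared = set(r6) & set(r5)
            fused = set(r6) | set(r5)
            if len(shared) == 2 and sum(elem[i] == "N" for i in fused) >= 4:
                adenine = fused
                break
        if adenine:
            break

    ribose: set[int] = set()
    for r in rings:
        if len(r) != 5:
            continue
        os = [i for i in r if elem[i] == "O"]
        cs = [i for i in r if elem[i] == "C"]
        if len(os) == 1 and len(cs) == 4:
            ribose = set(r)
            break

    phosphorus = [i for i in range(len(atoms)) if elem[i] == "P"]
    phosphate: set[int] = set(phosphorus)
    for p in phosphorus:
        phosphate |= {n for n in g.neighbors(p) if elem[n] == "O"}

    return {"adenine": adenine, "ribose": ribose, "phosphate": phosphate, "graph": g}


def _has_adenosine_phosphate(atoms: Sequence[Atom], moieties) -> bool:
    adenine, ribose, phosphate = (
        moieties["adenine"], moieties["ribose"], moieties["phosphate"],
    )
    g = moieties["graph"]
    if not adenine or not ribose or not phosphate:
        return False
    # glycosidic bond between heterocycle and furanose
    if not any(g.has_edge(a, r) for a in adenine for r in ribose):
        return False
    # phosphate ester reaches the furanose within two bonds of a P-bound O
    elem = [a.element.upper() for a in atoms]
    for p in (i for i in phosphate if elem[i] == "P"):
        for o in g.neighbors(p):
            if elem[o] != "O":
                continue
            for a in g.neighbors(o):
                if a == p:
                    continue
                if a in ribose or any(n in ribose for n in g.neighbors(a)):
                    return True
    return False


def _has_amino_acid_part(atoms: Sequence[Atom], moieties) -> bool:
    """A free alpha-amino-acid fragment N-CA-C(=O) outside the nucleotide."""
    g = moieties["graph"]
    nucleotide = set().union(
        moieties["adenine"], moieties["ribose"], moieties["phosphate"]
    )
    # also exclude atoms directly bonded to the furanose (C5', O2', O3')
    fringe = {n for i in moieties["ribose"] for n in g.neighbors(i)}
    excluded = nucleotide | fringe
    elem = [a.element.upper() for a in atoms]
    for ca in range(len(atoms)):
        if elem[ca] != "C" or ca in excluded:
            continue
        nbrs = list(g.neighbors(ca))
        has_n = any(elem[n] == "N" and n not in nucleotide for n in nbrs)
        if not has_n:
            continue
        for c in nbrs:
            if elem[c] != "C" or c in nucleotide:
                continue
            n_oxy = sum(1 for x in g.neighbors(c) if elem[x] == "O")
            if n_oxy >= 1:
                return True
    return False


def classify_ligand(
    component_code: str, atoms: Sequence[Atom]
) -> tuple[bool, bool]:
    """Flag a ligand as adenosine-phosphate-containing and/or amino-acid-like.

    The curated component table is consulted first; otherwise the inferred
    atom graph is searched for the nucleotide substructure and for a free
    alpha-amino-acid fragment outside it. Unknown codes with unmatchable
    graphs yield ``(False, False)`` and a log entry.
    """
    table = component_table()
    code = component_code.strip().upper()
    if code in table:
        return table[code]
    if len(atoms) < 3:
        logger.info("ligand %s too small for substructure detection", code)
        return (False, False)
    moieties = find_nucleotide_moieties(atoms)
    has_ap = _has_adenosine_phosphate(atoms, moieties)
    has_aa = _has_amino_acid_part(atoms, moieties)
    if not has_ap and not has_aa:
        logger.info("ligand %s matched no known moiety", code)
    return (has_ap, has_aa)


def assign_ligand_flags(ligand: LigandRecord) -> LigandRecord:
    has_ap, has_aa = classify_ligand(ligand.component_code, ligand.atoms)
    ligand.has_adenosine_phosphate = has_ap
    ligand.has_amino_acid_part = has_aa
    return ligand


# ---------------------------------------------------------------------------
# parsing

def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        key = (atom.occ, -ord(atom.altloc or "A"))
        prev_key = (prev.occ, -ord(prev.altloc or "A"))
        if key > prev_key:
            by_name[atom.name] = atom
    return list(by_name.values())


def _convert_residue(res: gemmi.Residue, is_polymer: bool) -> Residue:
    atoms = [
        Atom(
            name=a.name,
            element=a.element.name.upper() or "X",
            coords=(a.pos.x, a.pos.y, a.pos.z),
        )
        for a in _pick_altloc(res)
    ]
    return Residue(
        author_number=res.seqid.num,
        icode=(res.seqid.icode or "").strip(),
        name=res.name.strip(),
        atoms=atoms,
        is_polymer=is_polymer,
    )


def parse_structure(path: str | Path, model_policy: str = "first") -> list[StructureChain]:
    """Read a PDB (or mmCIF) file into typed chains.

    Returns one :class:`StructureChain` per polymer chain. HETATM groups are
    attached to the nearest chain by the polymer-contact majority rule;
    waters are excluded. Only the first model is read.
    """
    path = Path(path)
    if model_policy != "first":
        raise ValueError("only the first-model policy is supported")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path} contains no models")
    st.setup_entities()
    structure_id = (st.name or path.stem)[:4].lower() or path.stem
    model = st[0]

    chains: list[StructureChain] = []
    het_groups: list[tuple[str, gemmi.Residue]] = []
    for chain in model:
        polymer = chain.get_polymer()
        polymer_names = {(r.seqid.num, r.seqid.icode, r.name) for r in polymer}
        residues = []
        for res in chain:
            if res.is_water():
                continue
            key = (res.seqid.num, res.seqid.icode, res.name)
            if key in polymer_names:
                residues.append(_convert_residue(res, is_polymer=True))
            else:
                het_groups.append((chain.name, res))
        if residues:
            chains.append(
                StructureChain(
                    structure_id=structure_id, chain_id=chain.name, residues=residues
                )
            )
    if not chains:
        logger.warning("%s: no polymer chains found", path)
        return []

    _attach_ligands(chains, het_groups)
    return chains


def _attach_ligands(
    chains: list[StructureChain], het_groups: Iterable[tuple[str, gemmi.Residue]]
) -> None:
    from scipy.spatial import cKDTree

    coords, owner = [], []
    for idx, ch in enumerate(chains):
        for res in ch.polymer_residues:
            for a in res.atoms:
                coords.append(a.xyz)
                owner.append(idx)
    if not coords:
        return
    tree = cKDTree(np.asarray(coords))
    owner_arr = np.asarray(owner)

    for chain_name, res in het_groups:
        lig_res = _convert_residue(res, is_polymer=False)
        counts = np.zeros(len(chains), dtype=int)
        for a in lig_res.atoms:
            for j in tree.query_ball_point(a.xyz, LIGAND_CONTACT_CUTOFF):
                counts[owner_arr[j]] += 1
        if counts.sum() == 0:
            logger.warning(
                "ligand %s %s (chain %s) dropped: no polymer contact within %.1f A",
                lig_res.name, lig_res.author_number, chain_name, LIGAND_CONTACT_CUTOFF,
            )
            continue
        best = counts.max()
        candidates = [i for i, c in enumerate(counts) if c == best]
        target = min(candidates, key=lambda i: chains[i].chain_id)
        record = LigandRecord(
            component_code=lig_res.name,
            atoms=lig_res.atoms,
            author_number=lig_res.author_number,
        )
        assign_ligand_flags(record)
        chains[target].ligands.append(record)


# ---------------------------------------------------------------------------
# writing

def _format_atom_line(
    record: str, serial: int, atom: Atom, res_name: str, chain_id: str,
    res_num: int, icode: str,
) -> str:
    name = atom.name
    if len(name) < 4 and len(atom.element) < 2:
        name = " " + name
    x, y, z = atom.coords
    return (
        f"{record:<6}{serial:>5} {name:<4} {res_name:>3} {chain_id:1}"
        f"{res_num:>4}{icode or ' ':1}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}"
    )


def write_pdb(chains: Sequence[StructureChain], path: str | Path) -> None:
    """Write chains (and their ligands) as fixed-width PDB ATOM/HETATM records."""
    lines: list[str] = []
    serial = 1
    for ch in chains:
        last = None
        for res in ch.residues:
            rec = "ATOM" if res.is_polymer else "HETATM"
            for atom in res.atoms:
                lines.append(
                    _format_atom_line(
                        rec, serial, atom, res.name, ch.chain_id,
                        res.author_number, res.icode,
                    )
                )
                serial += 1
            last = res
        if last is not None:
            lines.append(
                f"TER   {serial:>5}      {last.name:>3} {ch.chain_id:1}"
                f"{last.author_number:>4}{last.icode or ' ':1}"
            )
            serial += 1
        for lig in ch.ligands:
            for atom in lig.atoms:
                lines.append(
                    _format_atom_line(
                        "HETATM", serial, atom, lig.component_code, ch.chain_id,
                        lig.author_number, "",
                    )
                )
                serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sequences

def chain_sequence(chain: StructureChain, mode: str = "strict") -> str:
    """One-letter sequence of the polymer residues.

    ``mode='strict'`` maps any nonstandard residue to 'X'; ``mode='parent'``
    first maps modified residues (e.g. MSE) to their parent component.
    """
    polymer = chain.polymer_residues
    if not polymer:
        raise ValueError(f"chain {chain.chain_id} has no polymer residues")
    out = []
    for res in polymer:
        name = res.name.upper()
        if mode == "parent":
            name = PARENT_COMPONENT.get(name, name)
        out.append(THREE_TO_ONE.get(name, "X"))
    return "".join(out)


def copy_chain(chain: StructureChain) -> StructureChain:
    """Deep-enough copy: residues and ligands are new objects, atoms shared."""
    return StructureChain(
        structure_id=chain.structure_id,
        chain_id=chain.chain_id,
        residues=[replace(r, atoms=list(r.atoms)) for r in chain.residues],
        ligands=[
            LigandRecord(
                component_code=l.component_code,
                atoms=list(l.atoms),
                author_number=l.author_number,
                has_adenosine_phosphate=l.has_adenosine_phosphate,
                has_amino_acid_part=l.has_amino_acid_part,
            )
            for l in chain.ligands
        ],
    )
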