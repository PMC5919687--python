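"""Noncovalent protein-ligand interaction profiling with explicit geometric rules.

Hydrogen positions are not modelled; donor/acceptor capacity is inferred
from heavy-atom chemistry (backbone N donates, backbone O accepts, side
chains per a residue table, ligand N/O act as both). Default cutoffs:

==============  =====================================================
hydrogen bond   donor-acceptor heavy distance <= 4.1 A, donor-angle
                proxy (bonded neighbour - donor - acceptor) >= 100 deg
salt bridge     charged-group centroid distance <= 5.5 A
pi-cation       cation to aromatic-ring centroid <= 6.0 A
pi-stacking     ring-centroid distance <= 5.5 A, planes parallel
                (< 30 deg) or perpendicular (60-90 deg)
hydrophobic     apolar C - apolar C <= 4.0 A (one record per residue
                and fragment, closest pair)
metal complex   metal ion to ligand atom <= 3.0 A
==============  =====================================================

Each ligand atom is attributed to a fragment - phosphate, ribose, adenine
or the aminoacyl part - so that interactions can be grouped by the moiety
they recognise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .structure import (
    Atom,
    LigandRecord,
    Residue,
    StructureChain,
    bond_graph,
    find_nucleotide_moieties,
)

HYDROGEN_BOND = "hydrogen_bond"
SALT_BRIDGE = "salt_bridge"
PI_STACKING = "pi_stacking"
PI_CATION = "pi_cation"
HYDROPHOBIC = "hydrophobic"
METAL_COMPLEX = "metal_complex"

INTERACTION_KINDS = (
    HYDROGEN_BOND, SALT_BRIDGE, PI_STACKING, PI_CATION, HYDROPHOBIC, METAL_COMPLEX,
)

FRAGMENTS = ("phosphate", "ribose", "adenine", "amino_acid_part")


@dataclass(frozen=True)
class InteractionConfig:
    hbond_dist: float = 4.1
    hbond_min_angle: float = 100.0
    saltbridge_dist: float = 5.5
    pication_dist: float = 6.0
    pistack_dist: float = 5.5
    pistack_parallel_max: float = 30.0
    pistack_perp_min: float = 60.0
    pistack_perp_max: float = 90.0
    hydrophobic_dist: float = 4.0
    metal_dist: float = 3.0

    def cutoff(self, kind: str) -> float:
        return {
            HYDROGEN_BOND: self.hbond_dist,
            SALT_BRIDGE: self.saltbridge_dist,
            PI_CATION: self.pication_dist,
            PI_STACKING: self.pistack_dist,
            HYDROPHOBIC: self.hydrophobic_dist,
            METAL_COMPLEX: self.metal_dist,
        }[kind]


@dataclass(frozen=True)
class InteractionRecord:
    kind: str
    residue_position: int
    residue_name: str
    ligand_fragment: str
    distance: float
    backbone_mediated: bool = False
    angle: float | None = None
    protein_atom: str = ""
    ligand_atom: str = ""

    def __post_init__(self):
        if self.backbone_mediated and self.kind != HYDROGEN_BOND:
            raise ValueError("backbone_mediated applies to hydrogen bonds only")


# ---------------------------------------------------------------------------
# protein chemistry tables (heavy-atom donors/acceptors, charges, rings)

SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "ASN": ("ND2",),
    "GLN": ("NE2",), "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"), "TRP": ("NE1",), "CYS": ("SG",),
}

SIDECHAIN_ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",), "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"), "HIS": ("ND1", "NE2"),
}

POSITIVE_GROUPS = {
    "ARG": ("CZ", "NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

NEGATIVE_GROUPS = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
}

AROMATIC_RINGS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}

APOLAR_SIDECHAIN = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "PRO": ("CB", "CG"),
    "TYR": ("CB", "CD1", "CD2", "CE1", "CE2"),
    "THR": ("CG2",),
    "LYS": ("CB", "CG", "CD"),
    "ARG": ("CB", "CG"),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "ASN": ("CB",),
    "ASP": ("CB",),
    "HIS": ("CB",),
    "CYS": ("CB",),
}

_DONOR_NEIGHBOUR = {
    "N": "CA", "OG": "CB", "OG1": "CB", "OH": "CZ", "ND2": "CG", "NE2": "CD",
    "NZ": "CE", "NE": "CD", "NH1": "CZ", "NH2": "CZ", "ND1": "CG",
    "NE1": "CD1", "SG": "CB",
}


# ---------------------------------------------------------------------------
# ligand fragment partition

def ligand_fragment_labels(ligand: LigandRecord) -> list[str]:
    """Fragment label for every ligand atom.

    Phosphate claims P and its bonded oxygens; the adenine-like fused ring
    claims its ring atoms plus exocyclic N/O substituents; the furanose ring
    claims its atoms plus exocyclic oxygens and ring-attached carbons (C5');
    everything left is the aminoacyl part. Non-nucleotide ligands are
    entirely ``amino_acid_part``.
    """
    atoms = ligand.atoms
    moieties = find_nucleotide_moieties(atoms)
    g = moieties["graph"]
    elem = [a.element.upper() for a in atoms]
    labels = ["amino_acid_part"] * len(atoms)

    phosphate = set(moieties["phosphate"])
    adenine_ring = set(moieties["adenine"])
    ribose_ring = set(moieties["ribose"])

    adenine = set(adenine_ring)
    for i in adenine_ring:
        for n in g.neighbors(i):
            if n in phosphate or n in ribose_ring or n in adenine_ring:
                continue
            if elem[n] in ("N", "O"):
                adenine.add(n)

    ribose = set(ribose_ring)
    for i in ribose_ring:
        for n in g.neighbors(i):
            if n in phosphate or n in adenine or n in ribose_ring:
                continue
            if elem[n] == "O":
                ribose.add(n)
            elif elem[n] == "C":
                # exocyclic carbon (C5') unless it starts the aminoacyl arm:
                # keep it with the sugar when it bears no nitrogen
                if not any(elem[m] == "N" for m in g.neighbors(n)):
                    ribose.add(n)

    for i in range(len(atoms)):
        if i in phosphate:
            labels[i] = "phosphate"
        elif i in adenine:
            labels[i] = "adenine"
        elif i in ribose:
            labels[i] = "ribose"
    return labels


def assign_fragment(ligand_atom: Atom, ligand: LigandRecord) -> str:
    labels = ligand_fragment_labels(ligand)
    for i, a in enumerate(ligand.atoms):
        if a is ligand_atom or (a.name == ligand_atom.name and a.coords == ligand_atom.coords):
            return labels[i]
    raise ValueError(f"atom {ligand_atom.name} not part of ligand {ligand.component_code}")


# ---------------------------------------------------------------------------
# geometry helpers

def _centroid(xyz: np.ndarray) -> np.ndarray:
    return xyz.mean(axis=0)


def _plane_normal(xyz: np.ndarray) -> np.ndarray:
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def _angle(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    a = _angle(n1, n2)
    return min(a, 180.0 - a)


# ---------------------------------------------------------------------------
# ligand-side typing

def _ligand_sites(ligand: LigandRecord):
    atoms = ligand.atoms
    g = bond_graph(atoms)
    elem = [a.element.upper() for a in atoms]
    donors_acceptors = [i for i in range(len(atoms)) if elem[i] in ("N", "O")]

    neg_groups = []  # list of (index set, centroid)
    for p in (i for i in range(len(atoms)) if elem[i] == "P"):
        grp = {p} | {n for n in g.neighbors(p) if elem[n] == "O"}
        neg_groups.append(grp)
    for c in (i for i in range(len(atoms)) if elem[i] == "C"):
        term_o = [
            n for n in g.neighbors(c)
            if elem[n] == "O" and g.degree(n) == 1
        ]
        if len(term_o) >= 2:
            neg_groups.append({c, *term_o})

    pos_amines = [
        i for i in range(len(atoms))
        if elem[i] == "N" and g.degree(i) <= 1
    ]

    rings = []
    import networkx as nx

    for ring in nx.cycle_basis(g):
        if len(ring) in (5, 6) and all(elem[i] in ("C", "N") for i in ring):
            xyz = np.array([atoms[i].xyz for i in ring])
            if np.abs((xyz - xyz.mean(0)) @ _plane_normal(xyz)).max() < 0.3:
                rings.append(ring)

    apolar = [
        i for i in range(len(atoms))
        if elem[i] == "C"
        and not any(elem[n] in ("N", "O", "P", "S") for n in g.neighbors(i))
    ]
    return {
        "graph": g, "elements": elem, "donors_acceptors": donors_acceptors,
        "negative_groups": neg_groups, "positive_amines": pos_amines,
        "rings": rings, "apolar": apolar,
    }


def _donor_angle_ok(
    donor_xyz: np.ndarray,
    acceptor_xyz: np.ndarray,
    neighbour_xyz: list[np.ndarray],
    min_angle: float,
) -> bool:
    if not neighbour_xyz:
        return True
    return any(
        _angle(n - donor_xyz, acceptor_xyz - donor_xyz) >= min_angle
        for n in neighbour_xyz
    )


# ---------------------------------------------------------------------------
# main profiler

def annotate_interactions(
    chain: StructureChain,
    ligand: LigandRecord,
    config: InteractionConfig | None = None,
) -> list[InteractionRecord]:
    """Detect noncovalent interactions between a chain and one ligand.

    The chain is expected to be renumbered so that residue author numbers
    are MSA columns; records report those positions. Records are
    deduplicated on (kind, residue, atom pair).
    """
    cfg = config or InteractionConfig()
    records: dict[tuple, InteractionRecord] = {}

    lig_atoms = ligand.atoms
    if not lig_atoms:
        return []
    lig_xyz = np.array([a.xyz for a in lig_atoms])
    if len(lig_atoms) >= 3:
        fragments = ligand_fragment_labels(ligand)
        sites = _ligand_sites(ligand)
    else:
        fragments = ["amino_acid_part"] * len(lig_atoms)
        sites = {
            "graph": bond_graph(lig_atoms),
            "elements": [a.element.upper() for a in lig_atoms],
            "donors_acceptors": [
                i for i, a in enumerate(lig_atoms) if a.element.upper() in ("N", "O")
            ],
            "negative_groups": [], "positive_amines": [], "rings": [], "apolar": [],
        }
    g = sites["graph"]

    def lig_neighbours(i: int) -> list[np.ndarray]:
        return [lig_xyz[n] for n in g.neighbors(i)]

    def add(key, record):
        prev = records.get(key)
        if prev is None or record.distance < prev.distance:
            records[key] = record

    residues = [r for r in chain.polymer_residues if r.atoms]

    # prefilter residues by bounding distance to the ligand
    lig_center = lig_xyz.mean(axis=0)
    lig_radius = float(np.linalg.norm(lig_xyz - lig_center, axis=1).max())
    near = []
    for res in residues:
        xyz = np.array([a.xyz for a in res.atoms])
        if np.linalg.norm(xyz - lig_center, axis=1).min() <= lig_radius + 8.0:
            near.append(res)

    for res in near:
        _hydrogen_bonds(res, lig_atoms, lig_xyz, fragments, sites, cfg, add,
                        lig_neighbours)
        _salt_bridges(res, lig_atoms, lig_xyz, fragments, sites, cfg, add)
        _pi_interactions(res, lig_atoms, lig_xyz, fragments, sites, cfg, add)
        _hydrophobic(res, lig_atoms, lig_xyz, fragments, sites, cfg, add)

    _metal_complexes(chain, ligand, lig_xyz, fragments, cfg, add)
    return sorted(
        records.values(),
        key=lambda r: (r.residue_position, r.kind, r.protein_atom, r.ligand_atom),
    )


def _hydrogen_bonds(res, lig_atoms, lig_xyz, fragments, sites, cfg, add,
                    lig_neighbours):
    name = res.name.upper()
    donors = [a for a in res.atoms if a.name == "N" and name != "PRO"]
    donors += [a for a in res.atoms if a.name in SIDECHAIN_DONORS.get(name, ())]
    acceptors = [a for a in res.atoms if a.name in ("O", "OXT")]
    acceptors += [a for a in res.atoms if a.name in SIDECHAIN_ACCEPTORS.get(name, ())]

    lig_da = sites["donors_acceptors"]

    def neighbour_of(atom: Atom) -> list[np.ndarray]:
        ref = _DONOR_NEIGHBOUR.get(atom.name)
        if ref:
            other = res.atom(ref)
            if other is not None:
                return [other.xyz]
        return []

    for atom in donors:
        for i in lig_da:
            d = float(np.linalg.norm(atom.xyz - lig_xyz[i]))
            if d > cfg.hbond_dist:
                continue
            if not _donor_angle_ok(atom.xyz, lig_xyz[i], neighbour_of(atom),
                                   cfg.hbond_min_angle):
                continue
            add(
                (HYDROGEN_BOND, res.author_number, atom.name, lig_atoms[i].name),
                InteractionRecord(
                    kind=HYDROGEN_BOND,
                    residue_position=res.author_number,
                    residue_name=name,
                    ligand_fragment=fragments[i],
                    distance=round(d, 3),
                    backbone_mediated=atom.is_backbone,
                    protein_atom=atom.name,
                    ligand_atom=lig_atoms[i].name,
                ),
            )
    for atom in acceptors:
        for i in lig_da:
            # ligand side donates: angle proxy at the ligand atom
            d = float(np.linalg.norm(atom.xyz - lig_xyz[i]))
            if d > cfg.hbond_dist:
                continue
            if not _donor_angle_ok(lig_xyz[i], atom.xyz, lig_neighbours(i),
                                   cfg.hbond_min_angle):
                continue
            add(
                (HYDROGEN_BOND, res.author_number, atom.name, lig_atoms[i].name),
                InteractionRecord(
                    kind=HYDROGEN_BOND,
                    residue_position=res.author_number,
                    residue_name=name,
                    ligand_fragment=fragments[i],
                    distance=round(d, 3),
                    backbone_mediated=atom.is_backbone,
                    protein_atom=atom.name,
                    ligand_atom=lig_atoms[i].name,
                ),
            )


def _group_centroid(res, names) -> np.ndarray | None:
    pts = [res.atom(n).xyz for n in names if res.atom(n) is not None]
    if not pts:
        return None
    return np.mean(pts, axis=0)


def _dominant_fragment(group: Iterable[int], fragments) -> str:
    labels = [fragments[i] for i in group]
    return max(set(labels), key=labels.count)


def _salt_bridges(res, lig_atoms, lig_xyz, fragments, sites, cfg, add):
    name = res.name.upper()
    pos_names = POSITIVE_GROUPS.get(name)
    if pos_names:
        centroid = _group_centroid(res, pos_names)
        if centroid is not None:
            for grp in sites["negative_groups"]:
                gc = _centroid(lig_xyz[sorted(grp)])
                d = float(np.linalg.norm(centroid - gc))
                if d <= cfg.saltbridge_dist:
                    add(
                        (SALT_BRIDGE, res.author_number, "+", tuple(sorted(grp))),
                        InteractionRecord(
                            kind=SALT_BRIDGE,
                            residue_position=res.author_number,
                            residue_name=name,
                            ligand_fragment=_dominant_fragment(grp, fragments),
                            distance=round(d, 3),
                            protein_atom=pos_names[0],
                            ligand_atom=lig_atoms[min(grp)].name,
                        ),
                    )
    neg_names = NEGATIVE_GROUPS.get(name)
    if neg_names:
        centroid = _group_centroid(res, neg_names)
        if centroid is not None:
            for i in sites["positive_amines"]:
                d = float(np.linalg.norm(centroid - lig_xyz[i]))
                if d <= cfg.saltbridge_dist:
                    add(
                        (SALT_BRIDGE, res.author_number, "-", (i,)),
                        InteractionRecord(
                            kind=SALT_BRIDGE,
                            residue_position=res.author_number,
                            residue_name=name,
                            ligand_fragment=fragments[i],
                            distance=round(d, 3),
                            protein_atom=neg_names[0],
                            ligand_atom=lig_atoms[i].name,
                        ),
                    )


def _pi_interactions(res, lig_atoms, lig_xyz, fragments, sites, cfg, add):
    name = res.name.upper()
    lig_rings = sites["rings"]

    # protein cation vs ligand ring
    pos_names = POSITIVE_GROUPS.get(name)
    if pos_names and name != "HIS":
        centroid = _group_centroid(res, pos_names)
        if centroid is not None:
            for ring in lig_rings:
                rc = _centroid(lig_xyz[ring])
                d = float(np.linalg.norm(centroid - rc))
                if d <= cfg.pication_dist:
                    add(
                        (PI_CATION, res.author_number, "+", tuple(sorted(ring))),
                        InteractionRecord(
                            kind=PI_CATION,
                            residue_position=res.author_number,
                            residue_name=name,
                            ligand_fragment=_dominant_fragment(ring, fragments),
                            distance=round(d, 3),
                            protein_atom=pos_names[0],
                            ligand_atom=lig_atoms[ring[0]].name,
                        ),
                    )

    # protein aromatic ring vs ligand ring / ligand cation
    for ring_names in AROMATIC_RINGS.get(name, ()):
        pts = [res.atom(n) for n in ring_names]
        if any(p is None for p in pts):
            continue
        xyz = np.array([p.xyz for p in pts])
        centroid, normal = _centroid(xyz), _plane_normal(xyz)
        for ring in lig_rings:
            rxyz = lig_xyz[ring]
            rc, rn = _centroid(rxyz), _plane_normal(rxyz)
            d = float(np.linalg.norm(centroid - rc))
            if d > cfg.pistack_dist:
                continue
            ang = _plane_angle(normal, rn)
            if ang < cfg.pistack_parallel_max or (
                cfg.pistack_perp_min <= ang <= cfg.pistack_perp_max
            ):
                add(
                    (PI_STACKING, res.author_number, ring_names[0],
                     tuple(sorted(ring))),
                    InteractionRecord(
                        kind=PI_STACKING,
                        residue_position=res.author_number,
                        residue_name=name,
                        ligand_fragment=_dominant_fragment(ring, fragments),
                        distance=round(d, 3),
                        angle=round(ang, 2),
                        protein_atom=ring_names[0],
                        ligand_atom=lig_atoms[ring[0]].name,
                    ),
                )
        for i in sites["positive_amines"]:
            d = float(np.linalg.norm(centroid - lig_xyz[i]))
            if d <= cfg.pication_dist:
                add(
                    (PI_CATION, res.author_number, ring_names[0], (i,)),
                    InteractionRecord(
                        kind=PI_CATION,
                        residue_position=res.author_number,
                        residue_name=name,
                        ligand_fragment=fragments[i],
                        distance=round(d, 3),
                        protein_atom=ring_names[0],
                        ligand_atom=lig_atoms[i].name,
                    ),
                )


def _hydrophobic(res, lig_atoms, lig_xyz, fragments, sites, cfg, add):
    name = res.name.upper()
    apolar_names = APOLAR_SIDECHAIN.get(name, ())
    prot = [a for a in res.atoms if a.name in apolar_names]
    if not prot or not sites["apolar"]:
        return
    best: dict[str, tuple[float, Atom, int]] = {}
    for atom in prot:
        for i in sites["apolar"]:
            d = float(np.linalg.norm(atom.xyz - lig_xyz[i]))
            if d > cfg.hydrophobic_dist:
                continue
            frag = fragments[i]
            if frag not in best or d < best[frag][0]:
                best[frag] = (d, atom, i)
    for frag, (d, atom, i) in best.items():
        add(
            (HYDROPHOBIC, res.author_number, frag),
            InteractionRecord(
                kind=HYDROPHOBIC,
                residue_position=res.author_number,
                residue_name=name,
                ligand_fragment=frag,
                distance=round(d, 3),
                protein_atom=atom.name,
                ligand_atom=lig_atoms[i].name,
            ),
        )


def _metal_complexes(chain, ligand, lig_xyz, fragments, cfg, add):
    for ion in chain.ligands:
        if ion is ligand or not ion.is_metal_ion:
            continue
        m = ion.atoms[0]
        dists = np.linalg.norm(lig_xyz - m.xyz, axis=1)
        i = int(dists.argmin())
        if dists[i] <= cfg.metal_dist:
            add(
                (METAL_COMPLEX, ion.author_number, ion.component_code),
                InteractionRecord(
                    kind=METAL_COMPLEX,
                    residue_position=ion.author_number,
                    residue_name=ion.component_code,
                    ligand_fragment=fragments[i],
                    distance=round(float(dists[i]), 3),
                    protein_atom=m.name,
                    ligand_atom=ligand.atoms[i].name,
                ),
            )


# ---------------------------------------------------------------------------
# interaction-preference matrix

@dataclass
class MatrixCell:
    counts: dict[str, int] = field(default_factory=dict)
    no_contact: int = 0

    @property
    def preferred(self) -> tuple[str, ...]:
        if not self.counts:
            return ()
        top = max(self.counts.values())
        winners = sorted(k for k, v in self.counts.items() if v == top)
        return tuple(winners[:2])


@dataclass
class InteractionMatrix:
    """Preferred interaction kinds per (aaRS type, renumbered residue, fragment)."""

    cells: dict[tuple[str, int, str], MatrixCell] = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        out = []
        for (aars_type, position, fragment), cell in sorted(self.cells.items()):
            out.append(
                {
                    "aars_type": aars_type,
                    "position": position,
                    "fragment": fragment,
                    "preferred": "/".join(cell.preferred),
                    "no_contact": cell.no_contact,
                    **{k: cell.counts.get(k, 0) for k in INTERACTION_KINDS},
                }
            )
        return out

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.to_records()).to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1))


def build_interaction_matrix(
    annotated: Sequence[tuple[str, Sequence[InteractionRecord], set[int]]],
    min_types: int = 2,
) -> InteractionMatrix:
    """Aggregate records from M1 representatives into a preference matrix.

    ``annotated``: per chain, its aaRS type, the interaction records against
    the adenosine-phosphate ligand, and the set of renumbered positions
    present in the chain. Residue positions relevant to fewer than
    ``min_types`` aaRS types (counting only non-amino-acid fragments) are
    discarded. Each complex contributes at most one count per interaction
    kind and cell, so multi-atom contacts do not inflate the preference. A
    chain that exposes a position but records no interaction at a
    (position, fragment) cell counts toward that cell's no-contact tally.
    """
    position_types: dict[int, set[str]] = {}
    for aars_type, records, _present in annotated:
        for rec in records:
            if rec.ligand_fragment != "amino_acid_part":
                position_types.setdefault(rec.residue_position, set()).add(aars_type)
    kept = {p for p, types in position_types.items() if len(types) >= min_types}

    observed_fragments: dict[int, set[str]] = {}
    for _aars_type, records, _present in annotated:
        for rec in records:
            if rec.residue_position in kept and rec.ligand_fragment != "amino_acid_part":
                observed_fragments.setdefault(rec.residue_position, set()).add(
                    rec.ligand_fragment
                )

    matrix = InteractionMatrix()
    for aars_type, records, present in annotated:
        by_cell: dict[tuple[int, str], list[InteractionRecord]] = {}
        for rec in records:
            if rec.residue_position in kept and rec.ligand_fragment != "amino_acid_part":
                by_cell.setdefault(
                    (rec.residue_position, rec.ligand_fragment), []
                ).append(rec)
        for pos in kept:
            for frag in observed_fragments.get(pos, ()):  # fragment cells seen anywhere
                key = (aars_type, pos, frag)
                cell = matrix.cells.setdefault(key, MatrixCell())
                recs = by_cell.get((pos, frag), [])
                if recs:
                    for kind in {rec.kind for rec in recs}:
                        cell.counts[kind] = cell.counts.get(kind, 0) + 1
                elif pos in present:
                    cell.no_contact += 1
    return matrix


def write_interaction_records(
    records: Iterable[tuple[str, str, InteractionRecord]], path: str | Path
) -> None:
    """TSV report: one interaction record per row with its chain of origin."""
    lines = [
        "pdb_id\tchain\tkind\tposition\tresidue\tfragment\tdistance\t"
        "angle\tbackbone\tprotein_atom\tligand_atom"
    ]
    for pdb_id, chain_id, r in records:
        lines.append(
            f"{pdb_id}\t{chain_id}\t{r.kind}\t{r.residue_position}\t"
            f"{r.residue_name}\t{r.ligand_fragment}\t{r.distance:.3f}\t"
            f"{'' if r.angle is None else f'{r.angle:.2f}'}\t"
            f"{int(r.backbone_mediated)}\t{r.protein_atom}\t{r.ligand_atom}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
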