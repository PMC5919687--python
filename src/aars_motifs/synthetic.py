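"""Synthetic cohorts with known ground truth for every pipeline stage.

Each toy chain carries the two motif residues of its class (Backbone
Brackets analogues built from leucines, Arginine Tweezers from arginines)
in a canonical frame: the first CA at the origin, the second at the planted
CA-CA distance along x, side chains tilted so the planted angle theta is
exact. Filler residues sit on a distant rail so that the only
protein-ligand contacts are the planted ones. For M1 chains an AMP-like
ligand (idealised adenine + ribose + phosphate built from regular-polygon
geometry) is posed between the motif residues by a small deterministic
search so that exactly the planted interaction inventory fires.

The companion MSA places every chain segment at fixed alignment columns
(motifs at 274/1361 for Class I, 698/1786 for Class II), and the coding
sequences plant conserved codon middle bases at designated column pairs so
that the antisense pairing count is known by construction.

Defaults reproduce the study conditions of the real aaRS dataset: planted
distance/theta distributions use the published per-class, per-mode means
and standard deviations; draws are clipped at three standard deviations so
ligand placement stays feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import BindingMode, ChainAnnotation, write_annotations
from .interactions import (
    HYDROGEN_BOND,
    PI_CATION,
    SALT_BRIDGE,
    annotate_interactions,
)
from .structure import (
    Atom,
    LigandRecord,
    Residue,
    StructureChain,
    assign_ligand_flags,
    write_pdb,
)


class GenerationError(RuntimeError):
    """Raised when no ligand pose satisfies the planted inventory."""


# ---------------------------------------------------------------------------
# study-condition defaults (A / degrees): per class and binding mode

DEFAULT_CA_DISTANCE = {
    "I": {"M1": (17.92, 0.86), "M2": (18.41, 0.82)},
    "II": {"M1": (14.76, 0.66), "M2": (14.93, 0.79)},
}
DEFAULT_THETA = {
    "I": {"M1": (144.90, 20.93), "M2": (141.40, 20.13)},
    "II": {"M1": (91.82, 8.69), "M2": (79.81, 21.67)},
}

#: MSA layout per class: contiguous column segments and motif columns
LAYOUT = {
    "I": {
        "segments": [(266, 291), (1355, 1367)],
        "motifs": (274, 1361),
        "region": (272, 285),
        "msa_length": 1400,
    },
    "II": {
        "segments": [(686, 711), (1780, 1792)],
        "motifs": (698, 1786),
        "region": (688, 701),
        "msa_length": 1800,
    },
}

MOTIF_RESIDUES = {
    "I": {274: ("LEU", "CTG"), 1361: ("LEU", "CTT")},
    "II": {698: ("ARG", "CGT"), 1786: ("ARG", "CGC")},
}

#: planted conserved (residue, codon) per region column; together with the
#: motif arginine these realise the planted complementary middle-base pairs
CONSERVED_CODONS = {
    "I": {275: ("PRO", "CCG"), 281: ("GLN", "CAA"), 284: ("LYS", "AAA")},
    "II": {692: ("LEU", "CTG"), 689: ("MET", "ATG")},
}

#: column pairs (Class I, Class II) with complementary planted middle bases
PLANTED_MIDDLE_PAIRS = ((275, 698), (281, 692), (284, 689))

#: variable-column choices: shared first/last base, four middle bases, so
#: the consensus middle base stays unassigned across a cohort
VARIABLE_CHOICES = (
    ("ALA", "GCA"), ("GLY", "GGA"), ("GLU", "GAA"), ("VAL", "GTA"),
)

FILLER = ("GLY", "GGC")

AARS_TYPES = {"I": ("TrpRS", "TyrRS", "ArgRS"), "II": ("LysRS", "AspRS", "HisRS")}


@dataclass
class SyntheticSpec:
    aars_class: str
    seed: int = 0
    n_chains: int = 100
    m1_fraction: float = 0.5
    motif_present_fraction: float = 1.0
    glycine_fraction: float = 0.0  # Class I only: glycine at the first motif position
    ca_distance: dict | None = None
    theta: dict | None = None
    ligand_code: str = "AMP"
    m2_amino_acid_fraction: float = 0.5
    jitter_sd: float = 0.0

    def __post_init__(self):
        if self.aars_class not in ("I", "II"):
            raise ValueError("aars_class must be 'I' or 'II'")
        if not 0.0 <= self.m1_fraction <= 1.0:
            raise ValueError("m1_fraction must lie in [0, 1]")
        if self.ca_distance is None:
            self.ca_distance = DEFAULT_CA_DISTANCE[self.aars_class]
        if self.theta is None:
            self.theta = DEFAULT_THETA[self.aars_class]


@dataclass
class ChainTruth:
    structure_id: str
    chain_id: str
    aars_class: str
    aars_type: str
    binding_mode: str
    motif_present: bool
    ca_distance: float | None
    theta: float | None
    inventory: frozenset  # of (kind, msa_column, fragment)


@dataclass
class CohortTruth:
    spec: SyntheticSpec
    chains: list[ChainTruth] = field(default_factory=list)

    @property
    def m1_fraction(self) -> float:
        present = [c for c in self.chains if c.motif_present]
        return sum(c.binding_mode == "M1" for c in present) / len(present)

    @property
    def motif_present_fraction(self) -> float:
        return sum(c.motif_present for c in self.chains) / len(self.chains)

    def mean(self, descriptor: str, mode: str) -> float:
        vals = [
            getattr(c, descriptor)
            for c in self.chains
            if c.binding_mode == mode and getattr(c, descriptor) is not None
        ]
        return float(np.mean(vals))


# ---------------------------------------------------------------------------
# idealised AMP template

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def build_amp_template() -> list[Atom]:
    """AMP-like ligand from regular-polygon geometry.

    Adenine: regular hexagon (side 1.39 A) fused to a pentagon sharing the
    C4-C5 edge, with exocyclic N6; ribose: regular pentagon (side 1.43 A)
    with one ring oxygen, exocyclic O2'/O3' and the C5'-O5'-P-O3 phosphate
    arm prolonging the adenine->ribose direction.
    """
    pts: dict[str, np.ndarray] = {}
    hex_names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    for k, nm in enumerate(hex_names):
        ang = np.radians(60.0 * k)
        pts[nm] = 1.39 * np.array([np.cos(ang), np.sin(ang), 0.0])

    a, b = pts["C4"], pts["C5"]
    mid = (a + b) / 2.0
    out_dir = _unit(mid)  # hexagon centred at origin
    s = float(np.linalg.norm(b - a))
    c5 = mid + out_dir * (s / (2.0 * np.tan(np.pi / 5.0)))

    def rotate_about(p, center, angle):
        c, sn = np.cos(angle), np.sin(angle)
        d = p - center
        return center + np.array([c * d[0] - sn * d[1], sn * d[0] + c * d[1], 0.0])

    ang_a = np.arctan2(*(a - c5)[1::-1])
    ang_b = np.arctan2(*(b - c5)[1::-1])
    delta = np.arctan2(np.sin(ang_b - ang_a), np.cos(ang_b - ang_a))
    pts["N7"] = rotate_about(b, c5, delta)
    pts["C8"] = rotate_about(b, c5, 2 * delta)
    pts["N9"] = rotate_about(b, c5, 3 * delta)
    pts["N6"] = pts["C6"] + 1.35 * _unit(pts["C6"])

    # ribose attached at N9, ring in the plane spanned by dir9 and z
    dir9 = _unit(pts["N9"] - c5)
    c1p = pts["N9"] + 1.47 * dir9
    side = 1.43
    r5 = side / (2.0 * np.sin(np.pi / 5.0))
    ring_center = c1p + r5 * dir9
    e1, e2 = dir9, np.array([0.0, 0.0, 1.0])
    ring_names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    for k, nm in enumerate(ring_names):
        ang = np.pi + 2.0 * np.pi * k / 5.0
        pts[nm] = ring_center + r5 * (np.cos(ang) * e1 + np.sin(ang) * e2)

    pts["O2'"] = pts["C2'"] + 1.41 * _unit(pts["C2'"] - ring_center)
    pts["O3'"] = pts["C3'"] + 1.41 * _unit(pts["C3'"] - ring_center)
    pts["C5'"] = pts["C4'"] + 1.52 * dir9
    pts["O5'"] = pts["C5'"] + 1.43 * dir9
    pts["P"] = pts["O5'"] + 1.61 * dir9
    normal = np.cross(e1, e2)
    for k, nm in enumerate(["O1P", "O2P", "O3P"]):
        phi = 2.0 * np.pi * k / 3.0
        direction = _unit(
            np.cos(np.radians(70.0)) * dir9
            + np.sin(np.radians(70.0)) * (np.cos(phi) * e2 + np.sin(phi) * normal)
        )
        pts[nm] = pts["P"] + 1.52 * direction

    elements = {nm: ("N" if nm.startswith("N") else
                     "O" if nm.startswith("O") else
                     "P" if nm == "P" else "C") for nm in pts}
    return [Atom(name=nm, element=elements[nm], coords=tuple(p)) for nm, p in pts.items()]


AMP_TEMPLATE = build_amp_template()


def _template_anchors(atoms: Sequence[Atom]):
    by_name = {a.name: a.xyz for a in atoms}
    phosphate = np.mean(
        [by_name[n] for n in ("P", "O1P", "O2P", "O3P", "O5'")], axis=0
    )
    adenine = np.mean(
        [by_name[n] for n in ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")],
        axis=0,
    )
    return phosphate, adenine


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any perpendicular axis
        axis = _unit(np.cross(u, [1.0, 0.3, 0.2]))
        return _axis_rotation(axis, np.pi)
    axis = _unit(np.cross(u, v))
    return _axis_rotation(axis, float(np.arccos(np.clip(c, -1, 1))))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    t = 1 - c
    return np.array([
        [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
        [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
        [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
    ])


def _place_template(target_p: np.ndarray, direction: np.ndarray, roll: float) -> list[Atom]:
    """Pose the AMP template: phosphate centroid at target_p, the
    phosphate->adenine axis along ``direction``, rolled by ``roll`` rad."""
    pa, ad = _template_anchors(AMP_TEMPLATE)
    axis_t = _unit(ad - pa)
    rot = _rotation_between(axis_t, _unit(direction))
    rot = _axis_rotation(_unit(direction), roll) @ rot
    out = []
    for a in AMP_TEMPLATE:
        p = rot @ (a.xyz - pa) + target_p
        out.append(Atom(name=a.name, element=a.element, coords=tuple(p)))
    return out


# ---------------------------------------------------------------------------
# residue builders

def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(_unit(v), ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def _motif_residue(
    number: int, name: str, ca: np.ndarray, inward: float, side_dir: np.ndarray | None
) -> Residue:
    """Motif residue in the canonical frame; ``inward`` is +1/-1 along x.

    The most distant side-chain carbon lies exactly along ``side_dir`` so
    the planted theta is exact: LEU CD1 at 2.61 A, ARG CZ at 4.20 A.
    """
    atoms = [
        Atom("N", "N", tuple(ca + np.array([1.17 * inward, -0.88, 0.0]))),
        Atom("CA", "C", tuple(ca)),
        Atom("C", "C", tuple(ca + np.array([-0.94 * inward, -1.12, 0.0]))),
        Atom("O", "O", tuple(ca + np.array([-0.94 * inward, -2.35, 0.0]))),
    ]
    if side_dir is not None:
        s = _unit(side_dir)
        lat = _perp(s)
        if name == "LEU":
            atoms += [
                Atom("CB", "C", tuple(ca + 1.45 * s + 0.45 * lat)),
                Atom("CG", "C", tuple(ca + 2.10 * s + 0.55 * lat)),
                Atom("CD1", "C", tuple(ca + 2.61 * s)),
                Atom("CD2", "C", tuple(ca + 2.30 * s + 0.90 * lat)),
            ]
        elif name == "ARG":
            cz = ca + 4.20 * s
            atoms += [
                Atom("CB", "C", tuple(ca + 1.45 * s + 0.50 * lat)),
                Atom("CG", "C", tuple(ca + 2.40 * s + 0.60 * lat)),
                Atom("CD", "C", tuple(ca + 3.30 * s + 0.50 * lat)),
                Atom("NE", "N", tuple(ca + 3.70 * s + 0.30 * lat)),
                Atom("CZ", "C", tuple(cz)),
                Atom("NH1", "N", tuple(cz + 1.24 * lat + 0.30 * s)),
                Atom("NH2", "N", tuple(cz - 1.24 * lat + 0.30 * s)),
            ]
        else:
            raise ValueError(f"unsupported motif residue {name}")
    return Residue(author_number=number, name=name, atoms=atoms)


def _filler_residue(number: int, name: str, index: int) -> Residue:
    ca = np.array([1.9 * index, 14.0, 0.0])
    atoms = [
        Atom("N", "N", tuple(ca + np.array([-0.70, 1.20, 0.0]))),
        Atom("CA", "C", tuple(ca)),
        Atom("C", "C", tuple(ca + np.array([0.80, 1.15, 0.0]))),
        Atom("O", "O", tuple(ca + np.array([0.80, 2.38, 0.0]))),
    ]
    if name != "GLY":
        atoms.append(Atom("CB", "C", tuple(ca + np.array([0.0, -1.30, 0.85]))))
    return Residue(author_number=number, name=name, atoms=atoms)


def _amino_acid_het(anchor: np.ndarray, number: int) -> LigandRecord:
    """A free tryptophan HETATM group near the rail (an M2-style ligand)."""
    base = anchor + np.array([0.0, -2.6, 0.0])
    atoms = [
        Atom("N", "N", tuple(base + np.array([-1.2, 0.0, 0.0]))),
        Atom("CA", "C", tuple(base)),
        Atom("C", "C", tuple(base + np.array([1.3, 0.6, 0.0]))),
        Atom("O", "O", tuple(base + np.array([1.4, 1.82, 0.0]))),
        Atom("CB", "C", tuple(base + np.array([0.0, -1.1, 1.0]))),
    ]
    lig = LigandRecord(component_code="TRP", atoms=atoms, author_number=number)
    return assign_ligand_flags(lig)


# ---------------------------------------------------------------------------
# ligand pose search

def _planted_inventory(aars_class: str, col_a: int, col_b: int) -> frozenset:
    if aars_class == "I":
        return frozenset({
            (HYDROGEN_BOND, col_a, "phosphate"),
            (HYDROGEN_BOND, col_b, "adenine"),
        })
    return frozenset({
        (SALT_BRIDGE, col_a, "phosphate"),
        (PI_CATION, col_b, "adenine"),
        (HYDROGEN_BOND, col_a, "phosphate"),
        (HYDROGEN_BOND, col_b, "adenine"),
    })


def _pose_targets(aars_class: str, res_a: Residue, res_b: Residue):
    """Anchor points between which the ligand axis is stretched."""
    if aars_class == "I":
        p = res_a.atom("N").xyz
        q = res_b.atom("N").xyz
    else:
        def guanidinium(res):
            return np.mean(
                [res.atom(n).xyz for n in ("CZ", "NE", "NH1", "NH2")], axis=0
            )
        p, q = guanidinium(res_a), guanidinium(res_b)
    return p, q


def _find_ligand_pose(
    aars_class: str,
    res_a: Residue,
    res_b: Residue,
    author_to_column: dict[int, int],
    ligand_code: str,
    chain_residues: Sequence[Residue],
) -> LigandRecord:
    """Deterministic grid search over axis offsets and rolls until exactly
    the planted interaction inventory fires."""
    p, q = _pose_targets(aars_class, res_a, res_b)
    axis = _unit(q - p)
    span = float(np.linalg.norm(q - p))
    pa, ad = _template_anchors(AMP_TEMPLATE)
    length = float(np.linalg.norm(ad - pa))
    gap_total = span - length
    target = _planted_inventory(
        aars_class, author_to_column[res_a.author_number],
        author_to_column[res_b.author_number],
    )
    trial_chain = StructureChain(
        structure_id="tmp", chain_id="A", residues=list(chain_residues)
    )
    lift = np.array([0.0, 0.0, 1.0]) if aars_class == "I" else _unit(
        np.cross(axis, [0.0, 1.0, 0.0])
    )
    for frac in (0.5, 0.4, 0.6, 0.3, 0.7, 0.2, 0.8, 0.1, 0.9):
        for h in (0.0, 0.8, 1.6, 2.4, -0.8, 3.2):
            for roll in (0.0, 90.0, 180.0, 270.0, 45.0, 135.0):
                start = p + axis * (gap_total * frac) + h * lift
                atoms = _place_template(start, axis, np.radians(roll))
                lig = LigandRecord(
                    component_code=ligand_code, atoms=atoms, author_number=401
                )
                assign_ligand_flags(lig)
                records = annotate_interactions(trial_chain, lig)
                triples = frozenset(
                    (r.kind, author_to_column.get(r.residue_position, -1),
                     r.ligand_fragment)
                    for r in records
                )
                if triples == target:
                    return lig
    raise GenerationError(
        f"no feasible ligand pose for class {aars_class} "
        f"(span {span:.2f} A, planted inventory {sorted(target)})"
    )


# ---------------------------------------------------------------------------
# chain generation

def _chain_layout(spec: SyntheticSpec):
    lay = LAYOUT[spec.aars_class]
    columns = []
    for lo, hi in lay["segments"]:
        columns.extend(range(lo, hi + 1))
    return lay, columns


def _choose_residues(spec: SyntheticSpec, rng: np.random.Generator, use_glycine: bool):
    """(column -> (residue name, codon)) for one chain."""
    lay, columns = _chain_layout(spec)
    motifs = MOTIF_RESIDUES[spec.aars_class]
    conserved = CONSERVED_CODONS[spec.aars_class]
    lo, hi = lay["region"]
    chosen: dict[int, tuple[str, str]] = {}
    for col in columns:
        if col in motifs:
            chosen[col] = motifs[col]
        elif col in conserved:
            chosen[col] = conserved[col]
        elif lo <= col <= hi:
            chosen[col] = VARIABLE_CHOICES[rng.integers(len(VARIABLE_CHOICES))]
        else:
            chosen[col] = FILLER
    if use_glycine:
        first_motif = lay["motifs"][0]
        chosen[first_motif] = ("GLY", "GGT")
    return lay, columns, chosen


def _truncated_normal(rng, mean, sd, nsigma=3.0, lo=-np.inf, hi=np.inf):
    """Rejection-sampled normal, truncated at +-3 sigma and at [lo, hi].

    Angles are additionally bounded to (0, 180) since theta is a fold-free
    angle; the induced mean shift is part of the generated ground truth
    (recovery is always checked against the realised draws)."""
    if sd == 0:
        return float(min(max(mean, lo), hi))
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= nsigma * sd and lo <= x <= hi:
            return float(x)


def generate_toy_structure(
    spec: SyntheticSpec, index: int
) -> tuple[StructureChain, ChainTruth, dict[int, tuple[str, str]]]:
    """One synthetic chain with its ground truth and column layout.

    Deterministic in (spec.seed, index). Returns the chain (ligands
    attached), the truth record, and the column -> (residue, codon) map.
    """
    rng = np.random.default_rng([spec.seed, index])
    sid = f"s{index:03d}"
    aars_type = AARS_TYPES[spec.aars_class][index % len(AARS_TYPES[spec.aars_class])]

    motif_present = rng.random() < spec.motif_present_fraction
    mode = "M1" if (motif_present and rng.random() < spec.m1_fraction) else "M2"
    use_gly = (
        spec.aars_class == "I"
        and motif_present
        and rng.random() < spec.glycine_fraction
    )

    lay, columns, chosen = _choose_residues(spec, rng, use_gly)
    col_a, col_b = lay["motifs"]
    if not motif_present:
        for col in (col_a, col_b):
            del chosen[col]
        columns = [c for c in columns if c not in (col_a, col_b)]

    d = theta = None
    if motif_present:
        d = _truncated_normal(rng, *spec.ca_distance[mode], lo=5.0)
        theta = _truncated_normal(rng, *spec.theta[mode], lo=1.0, hi=179.0)

    # author numbering: sequential from 5, in column order
    author_of: dict[int, int] = {c: 5 + i for i, c in enumerate(columns)}
    column_of_author = {v: k for k, v in author_of.items()}

    residues: list[Residue] = []
    res_a = res_b = None
    rail_index = 0
    for col in columns:
        name, _codon = chosen[col]
        num = author_of[col]
        if motif_present and col == col_a:
            side = None if name == "GLY" else np.array([0.0, 0.0, 1.0])
            res_a = _motif_residue(num, name, np.array([0.0, 0.0, 0.0]), +1.0, side)
            residues.append(res_a)
        elif motif_present and col == col_b:
            th = np.radians(theta)
            side = np.array([-np.sin(th), 0.0, np.cos(th)])
            res_b = _motif_residue(num, name, np.array([d, 0.0, 0.0]), -1.0, side)
            residues.append(res_b)
        else:
            residues.append(_filler_residue(num, name, rail_index))
            rail_index += 1

    chain = StructureChain(structure_id=sid, chain_id="A", residues=residues)

    inventory: frozenset = frozenset()
    if mode == "M1":
        ligand = _find_ligand_pose(
            spec.aars_class, res_a, res_b, column_of_author,
            spec.ligand_code, residues,
        )
        chain.ligands.append(ligand)
        inventory = _planted_inventory(spec.aars_class, col_a, col_b)
    else:
        if rng.random() < spec.m2_amino_acid_fraction:
            anchor = np.array([1.9 * max(rail_index - 1, 0) / 2.0, 14.0, 0.0])
            chain.ligands.append(_amino_acid_het(anchor, 402))

    if spec.jitter_sd > 0:
        for res in chain.residues:
            res.atoms = [
                Atom(a.name, a.element,
                     tuple(a.xyz + rng.normal(0.0, spec.jitter_sd, 3)))
                for a in res.atoms
            ]

    # theta is undefined when the first motif residue is glycine
    truth_theta = None if use_gly else theta
    truth = ChainTruth(
        structure_id=sid,
        chain_id="A",
        aars_class=spec.aars_class,
        aars_type=aars_type,
        binding_mode=mode,
        motif_present=motif_present,
        ca_distance=d,
        theta=truth_theta,
        inventory=inventory,
    )
    return chain, truth, chosen


# ---------------------------------------------------------------------------
# cohort generation: structures + annotations + MSA + CDS + truth table

def _msa_row(spec: SyntheticSpec, chosen: dict[int, tuple[str, str]]) -> str:
    from .structure import THREE_TO_ONE

    lay = LAYOUT[spec.aars_class]
    row = ["-"] * lay["msa_length"]
    for col, (name, _codon) in chosen.items():
        row[col - 1] = THREE_TO_ONE[name]
    return "".join(row)


def generate_msa_and_cds(
    spec: SyntheticSpec, layouts: dict[str, dict[int, tuple[str, str]]]
):
    """FASTA texts (MSA rows, coding sequences) for a generated cohort."""
    msa_lines, cds_lines = [], []
    for sid, chosen in layouts.items():
        row = _msa_row(spec, chosen)
        msa_lines.append(f">{sid}_A\n{row}")
        codons = [chosen[c][1] for c in sorted(chosen)]
        cds_lines.append(f">{sid}_A\n{''.join(codons)}")
    return "\n".join(msa_lines) + "\n", "\n".join(cds_lines) + "\n"


def generate_cohort(spec: SyntheticSpec, outdir: str | Path) -> CohortTruth:
    """Write a full synthetic cohort: structures/, annotations.tsv,
    msa.fasta, cds.fasta, truth.tsv. Deterministic under spec.seed."""
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    truth = CohortTruth(spec=spec)
    annotations = []
    modes = {}
    layouts: dict[str, dict[int, tuple[str, str]]] = {}
    for index in range(spec.n_chains):
        chain, chain_truth, chosen = generate_toy_structure(spec, index)
        write_pdb([chain], outdir / "structures" / f"{chain.structure_id}.pdb")
        truth.chains.append(chain_truth)
        layouts[chain.structure_id] = chosen
        annotations.append(
            ChainAnnotation(
                structure_id=chain.structure_id,
                chain_id="A",
                aars_class=spec.aars_class,
                aars_type=chain_truth.aars_type,
                superkingdom="bacteria",
                taxonomy_id=511145,
                mutant=False,
                resolution=2.0,
            )
        )
        modes[(chain.structure_id, "A")] = BindingMode(chain_truth.binding_mode)
    write_annotations(annotations, outdir / "annotations.tsv", modes=modes)
    msa_text, cds_text = generate_msa_and_cds(spec, layouts)
    (outdir / "msa.fasta").write_text(msa_text)
    (outdir / "cds.fasta").write_text(cds_text)
    _write_truth(truth, outdir / "truth.tsv")
    return truth


def _write_truth(truth: CohortTruth, path: Path) -> None:
    lines = ["structure_id\tchain\tclass\ttype\tmode\tmotif_present\t"
             "ca_distance\ttheta\tinventory"]
    for c in truth.chains:
        inv = ";".join(
            f"{k}:{col}:{frag}" for k, col, frag in sorted(c.inventory)
        )
        lines.append(
            f"{c.structure_id}\t{c.chain_id}\t{c.aars_class}\t{c.aars_type}\t"
            f"{c.binding_mode}\t{int(c.motif_present)}\t"
            f"{'' if c.ca_distance is None else f'{c.ca_distance:.6f}'}\t"
            f"{'' if c.theta is None else f'{c.theta:.6f}'}\t{inv}"
        )
    path.write_text("\n".join(lines) + "\n")
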