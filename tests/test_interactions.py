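"""Interaction profiler: geometric rules, fragments, preference matrix."""

from __future__ import annotations

import numpy as np
import pytest

from aars_motifs.interactions import (
    HYDROGEN_BOND,
    HYDROPHOBIC,
    METAL_COMPLEX,
    PI_CATION,
    PI_STACKING,
    SALT_BRIDGE,
    InteractionConfig,
    InteractionRecord,
    annotate_interactions,
    assign_fragment,
    build_interaction_matrix,
    ligand_fragment_labels,
)
from aars_motifs.structure import Atom, LigandRecord, Residue, StructureChain
from aars_motifs.synthetic import (
    AMP_TEMPLATE,
    SyntheticSpec,
    _motif_residue,
    generate_toy_structure,
)
from helpers import rigid_transform_chain

CFG = InteractionConfig()


def _chain(*residues, ligands=()):
    return StructureChain("test", "A", residues=list(residues), ligands=list(ligands))


def _gly(number=10, n=(0.0, 0.0, 0.0), ca=(1.4, 0.5, 0.0)):
    return Residue(
        author_number=number, name="GLY",
        atoms=[
            Atom("N", "N", n),
            Atom("CA", "C", ca),
            Atom("C", "C", (2.8, 0.0, 0.0)),
            Atom("O", "O", (3.5, 1.0, 0.0)),
        ],
    )


def _kinds(records):
    return {r.kind for r in records}


class TestHydrogenBond:
    def test_backbone_donor_within_cutoff_and_angle(self):
        lig = LigandRecord("LIG", atoms=[Atom("O1", "O", (-1.0, 0.0, 2.7))])
        records = annotate_interactions(_chain(_gly()), lig)
        assert [r.kind for r in records] == [HYDROGEN_BOND]
        assert records[0].backbone_mediated is True
        assert records[0].distance <= CFG.hbond_dist

    def test_donor_angle_proxy_rejects_backside_approach(self):
        # only N/CA resolved; acceptor at ~60 deg from the N->CA direction
        stub = Residue(
            author_number=10, name="GLY",
            atoms=[Atom("N", "N", (0.0, 0.0, 0.0)), Atom("CA", "C", (1.4, 0.5, 0.0))],
        )
        lig = LigandRecord("LIG", atoms=[Atom("O1", "O", (1.41, 0.5, 2.6))])
        records = annotate_interactions(_chain(stub), lig)
        assert HYDROGEN_BOND not in _kinds(records)

    def test_beyond_distance_cutoff_rejected(self):
        lig = LigandRecord("LIG", atoms=[Atom("O1", "O", (-1.0, 0.0, 5.0))])
        assert annotate_interactions(_chain(_gly()), lig) == []

    def test_sidechain_mediated_bond_not_flagged_backbone(self):
        ser = Residue(
            author_number=11, name="SER",
            atoms=[
                Atom("N", "N", (8.0, 0.0, 0.0)),
                Atom("CA", "C", (9.4, 0.5, 0.0)),
                Atom("CB", "C", (9.4, 0.5, 1.5)),
                Atom("OG", "O", (9.4, 1.6, 2.4)),
            ],
        )
        lig = LigandRecord("LIG", atoms=[Atom("O1", "O", (9.4, 3.0, 4.0))])
        records = annotate_interactions(_chain(ser), lig)
        hb = [r for r in records if r.kind == HYDROGEN_BOND]
        assert hb and all(not r.backbone_mediated for r in hb)


class TestSaltBridgeAndPi:
    def test_arginine_guanidinium_vs_phosphate_group(self):
        arg = _motif_residue(20, "ARG", np.zeros(3), +1.0, np.array([0.0, 0.0, 1.0]))
        phos = [Atom("P", "P", (0.0, 0.0, 9.0))] + [
            Atom(f"O{i}P", "O", tuple(np.array([0.0, 0.0, 9.0]) + 1.5 * d))
            for i, d in enumerate([
                np.array([1.0, 0.0, 0.0]),
                np.array([-0.5, 0.87, 0.0]),
                np.array([-0.5, -0.87, 0.0]),
            ])
        ]
        lig = LigandRecord("LIG", atoms=phos)
        records = annotate_interactions(_chain(arg), lig)
        sb = [r for r in records if r.kind == SALT_BRIDGE]
        assert len(sb) == 1
        assert sb[0].distance <= CFG.saltbridge_dist

    def test_lysine_pi_cation_with_aromatic_ring(self):
        lys = Residue(
            author_number=21, name="LYS",
            atoms=[
                Atom("N", "N", (0.0, -1.4, 0.0)),
                Atom("CA", "C", (0.0, 0.0, 0.0)),
                Atom("NZ", "N", (0.0, 0.0, 3.0)),
            ],
        )
        ring = _benzene(center=(0.0, 0.0, 8.0))
        records = annotate_interactions(_chain(lys), LigandRecord("LIG", atoms=ring))
        pc = [r for r in records if r.kind == PI_CATION]
        assert len(pc) == 1 and pc[0].distance == pytest.approx(5.0, abs=0.01)

    @pytest.mark.parametrize(
        "tilt,expected", [(0.0, True), (80.0, True), (45.0, False)]
    )
    def test_pi_stacking_plane_angle_windows(self, tilt, expected):
        phe = _phe_residue()
        ring = _benzene(center=(0.0, 0.0, 3.5), tilt_deg=tilt)
        records = annotate_interactions(_chain(phe), LigandRecord("LIG", atoms=ring))
        assert (PI_STACKING in _kinds(records)) is expected


def _benzene(center, tilt_deg=0.0):
    atoms = []
    t = np.radians(tilt_deg)
    rot = np.array([
        [1, 0, 0],
        [0, np.cos(t), -np.sin(t)],
        [0, np.sin(t), np.cos(t)],
    ])
    for k in range(6):
        ang = np.radians(60 * k)
        p = rot @ np.array([1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0])
        atoms.append(Atom(f"C{k + 1}", "C", tuple(p + np.asarray(center))))
    return atoms


def _phe_residue():
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = [
        Atom("N", "N", (-3.0, -1.0, 0.0)),
        Atom("CA", "C", (-3.0, 0.0, 0.0)),
        Atom("CB", "C", (-2.0, 0.5, 0.0)),
    ]
    for k, nm in enumerate(names):
        ang = np.radians(60 * k)
        atoms.append(
            Atom(nm, "C", (1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0))
        )
    return Residue(author_number=30, name="PHE", atoms=atoms)


class TestHydrophobicAndMetal:
    def test_apolar_contact_single_record_per_fragment(self):
        leu = _motif_residue(40, "LEU", np.zeros(3), +1.0, np.array([0.0, 0.0, 1.0]))
        lig = LigandRecord(
            "LIG",
            atoms=[
                Atom("C1", "C", (0.0, 0.0, 6.0)),
                Atom("C2", "C", (0.5, 0.0, 6.2)),
                Atom("C3", "C", (9.0, 9.0, 9.0)),
            ],
        )
        records = annotate_interactions(_chain(leu), lig)
        hydro = [r for r in records if r.kind == HYDROPHOBIC]
        assert len(hydro) == 1
        assert hydro[0].distance <= CFG.hydrophobic_dist

    def test_lone_sodium_near_phosphate_oxygen(self):
        amp = LigandRecord("AMP", atoms=list(AMP_TEMPLATE), author_number=401)
        o1p = next(a for a in AMP_TEMPLATE if a.name == "O1P")
        na = LigandRecord(
            "NA",
            atoms=[Atom("NA", "NA", tuple(np.asarray(o1p.coords) + [0.0, 0.0, 2.2]))],
            author_number=402,
        )
        chain = _chain(_gly(number=50), ligands=[amp, na])
        records = annotate_interactions(chain, amp)
        metal = [r for r in records if r.kind == METAL_COMPLEX]
        assert len(metal) == 1
        assert metal[0].distance == pytest.approx(2.2, abs=0.01)
        assert metal[0].ligand_fragment == "phosphate"


class TestFragments:
    def test_partition_of_amp_atoms(self):
        lig = LigandRecord("AMP", atoms=list(AMP_TEMPLATE))
        labels = ligand_fragment_labels(lig)
        assert len(labels) == len(AMP_TEMPLATE)
        by_name = dict(zip([a.name for a in AMP_TEMPLATE], labels))
        assert by_name["P"] == "phosphate"
        assert by_name["O5'"] == "phosphate"
        assert by_name["N6"] == "adenine"
        assert by_name["C8"] == "adenine"
        assert by_name["O2'"] == "ribose"
        assert by_name["C5'"] == "ribose"
        # no AMP atom falls through to the aminoacyl label
        assert "amino_acid_part" not in labels

    def test_aminoacyl_arm_labelled_amino_acid_part(self):
        from test_structure import _trp_adenylate_atoms

        atoms = _trp_adenylate_atoms()
        lig = LigandRecord("XYZ", atoms=atoms)
        labels = dict(zip([a.name for a in atoms], ligand_fragment_labels(lig)))
        assert labels["CA2"] == "amino_acid_part"
        assert labels["N"] == "amino_acid_part"

    def test_non_nucleotide_ligand_all_amino_acid_part(self):
        lig = LigandRecord("LIG", atoms=_benzene((0, 0, 0)))
        assert set(ligand_fragment_labels(lig)) == {"amino_acid_part"}

    def test_assign_fragment_single_atom(self):
        lig = LigandRecord("AMP", atoms=list(AMP_TEMPLATE))
        p = next(a for a in AMP_TEMPLATE if a.name == "P")
        assert assign_fragment(p, lig) == "phosphate"


class TestInvariants:
    def test_records_satisfy_their_own_cutoffs(self):
        spec = SyntheticSpec(aars_class="II", seed=9)
        for idx in range(6):
            chain, truth, _ = generate_toy_structure(spec, idx)
            for lig in chain.ligands:
                if not lig.has_adenosine_phosphate:
                    continue
                for r in annotate_interactions(chain, lig):
                    assert r.distance <= CFG.cutoff(r.kind) + 1e-9

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        for aars_class in ("I", "II"):
            spec = SyntheticSpec(aars_class=aars_class, seed=9, m1_fraction=1.0)
            chain, _, _ = generate_toy_structure(spec, 1)
            lig = next(l for l in chain.ligands if l.has_adenosine_phosphate)
            base = annotate_interactions(chain, lig)
            moved = rigid_transform_chain(chain, rng)
            mlig = next(l for l in moved.ligands if l.has_adenosine_phosphate)
            after = annotate_interactions(moved, mlig)
            key = lambda r: (r.kind, r.residue_position, r.ligand_fragment,
                             r.protein_atom, r.ligand_atom)
            assert sorted(map(key, base)) == sorted(map(key, after))
            for a, b in zip(sorted(base, key=key), sorted(after, key=key)):
                assert a.distance == pytest.approx(b.distance, abs=2e-3)


def _rec(kind, pos, frag):
    return InteractionRecord(
        kind=kind, residue_position=pos, residue_name="ARG",
        ligand_fragment=frag, distance=3.0,
    )


class TestMatrix:
    def test_preferences_ties_and_no_contact(self):
        annotated = [
            ("LysRS", [_rec(SALT_BRIDGE, 698, "phosphate"),
                       _rec(PI_CATION, 1786, "adenine")], {698, 1786}),
            ("AspRS", [_rec(SALT_BRIDGE, 698, "phosphate"),
                       _rec(HYDROGEN_BOND, 698, "phosphate"),
                       _rec(PI_CATION, 1786, "adenine")], {698, 1786}),
            ("HisRS", [], {698, 1786}),
        ]
        matrix = build_interaction_matrix(annotated)
        cell_698 = matrix.cells[("LysRS", 698, "phosphate")]
        assert cell_698.preferred == (SALT_BRIDGE,)
        dual = matrix.cells[("AspRS", 698, "phosphate")]
        assert dual.preferred == tuple(sorted([HYDROGEN_BOND, SALT_BRIDGE]))
        no_contact = matrix.cells[("HisRS", 698, "phosphate")]
        assert no_contact.no_contact == 1 and no_contact.counts == {}

    def test_single_type_positions_discarded(self):
        annotated = [
            ("LysRS", [_rec(SALT_BRIDGE, 698, "phosphate"),
                       _rec(HYDROGEN_BOND, 700, "adenine")], {698, 700}),
            ("AspRS", [_rec(SALT_BRIDGE, 698, "phosphate")], {698, 700}),
        ]
        matrix = build_interaction_matrix(annotated)
        positions = {pos for _, pos, _ in matrix.cells}
        assert positions == {698}

    def test_empty_input_gives_empty_matrix(self):
        assert build_interaction_matrix([]).cells == {}
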