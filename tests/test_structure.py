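"""Structure model: parsing, writing, ligand chemistry."""

from __future__ import annotations

import numpy as np
import pytest

from aars_motifs.structure import (
    Atom,
    LigandRecord,
    Residue,
    StructureChain,
    StructureParseError,
    bond_graph,
    chain_sequence,
    classify_ligand,
    parse_structure,
    write_pdb,
)
from aars_motifs.synthetic import AMP_TEMPLATE, SyntheticSpec, generate_toy_structure


def _toy_chain(index: int = 0, aars_class: str = "I") -> StructureChain:
    chain, _, _ = generate_toy_structure(
        SyntheticSpec(aars_class=aars_class, seed=5), index
    )
    return chain


class TestParseWrite:
    def test_round_trip_preserves_coordinates(self, tmp_path):
        chain = _toy_chain()
        path = tmp_path / "toy.pdb"
        write_pdb([chain], path)
        (parsed,) = parse_structure(path)
        assert [r.name for r in parsed.polymer_residues] == [
            r.name for r in chain.polymer_residues
        ]
        for orig, back in zip(chain.polymer_residues, parsed.polymer_residues):
            assert orig.author_number == back.author_number
            for a, b in zip(orig.atoms, back.atoms):
                assert a.name == b.name and a.element == b.element
                np.testing.assert_allclose(a.xyz, b.xyz, atol=5e-4)

    def test_double_round_trip_is_identity(self, tmp_path):
        chain = _toy_chain(1)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_pdb([chain], p1)
        write_pdb(parse_structure(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_single_residue_no_hetatm(self, tmp_path):
        path = tmp_path / "ala.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   1.400   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       1.400   0.000   0.000  1.00  0.00           C\n"
            "ATOM      4  O   ALA A   1       2.100   1.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        (chain,) = parse_structure(path)
        assert len(chain.polymer_residues) == 1
        assert chain.ligands == []

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   1.400   0.000  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      3  CA BALA A   1       9.000   0.000   0.000  0.70  0.00           C\n"
            "ATOM      4  C   ALA A   1       1.400   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        (chain,) = parse_structure(path)
        ca = chain.polymer_residues[0].ca
        assert ca.coords[0] == pytest.approx(9.0)

    def test_waters_excluded_and_far_ligand_dropped(self, tmp_path):
        chain = _toy_chain()
        path = tmp_path / "wat.pdb"
        write_pdb([chain], path)
        with path.open("a") as fh:
            fh.write(
                "HETATM 900  O   HOH A 501       0.000   0.000   3.000  1.00  0.00           O\n"
                "HETATM 901 NA    NA A 502     500.000 500.000 500.000  1.00  0.00          NA\n"
                "END\n"
            )
        (parsed,) = parse_structure(path)
        codes = [l.component_code for l in parsed.ligands]
        assert "HOH" not in codes and "NA" not in codes

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a coordinate file\n")
        with pytest.raises((StructureParseError, Exception)):
            chains = parse_structure(bad)
            if not chains:
                raise StructureParseError("empty")


class TestLigandAttachment:
    def test_every_het_group_attached_or_dropped(self, tmp_path):
        """Conservation: ligand records in equal HETATM groups kept."""
        for idx in range(4):
            chain = _toy_chain(idx, "II")
            path = tmp_path / f"c{idx}.pdb"
            write_pdb([chain], path)
            (parsed,) = parse_structure(path)
            assert len(parsed.ligands) == len(chain.ligands)

    def test_ligand_assigned_to_majority_contact_chain(self, tmp_path):
        chain = _toy_chain(0, "II")
        far = StructureChain(
            structure_id=chain.structure_id,
            chain_id="B",
            residues=[
                Residue(
                    author_number=1, name="GLY",
                    atoms=[
                        Atom("N", "N", (200.0, 200.0, 201.4)),
                        Atom("CA", "C", (200.0, 200.0, 200.0)),
                        Atom("C", "C", (201.4, 200.0, 200.0)),
                        Atom("O", "O", (202.1, 201.0, 200.0)),
                    ],
                )
            ],
        )
        path = tmp_path / "dimer.pdb"
        lig_count = len(chain.ligands)
        write_pdb([StructureChain(chain.structure_id, "A", chain.residues, chain.ligands), far], path)
        parsed = parse_structure(path)
        by_id = {c.chain_id: c for c in parsed}
        assert len(by_id["A"].ligands) == lig_count
        assert by_id["B"].ligands == []


class TestChainSequence:
    def test_three_to_one(self):
        chain = StructureChain(
            "xxxx", "A",
            residues=[
                Residue(1, "ALA", [Atom("CA", "C", (0, 0, 0))]),
                Residue(2, "GLY", [Atom("CA", "C", (3, 0, 0))]),
                Residue(3, "ARG", [Atom("CA", "C", (6, 0, 0))]),
            ],
        )
        assert chain_sequence(chain) == "AGR"

    def test_modified_residue_modes(self):
        chain = StructureChain(
            "xxxx", "A", residues=[Residue(1, "MSE", [Atom("CA", "C", (0, 0, 0))])]
        )
        assert chain_sequence(chain, mode="strict") == "X"
        assert chain_sequence(chain, mode="parent") == "M"

    def test_empty_polymer_raises(self):
        chain = StructureChain("xxxx", "A", residues=[])
        with pytest.raises(ValueError):
            chain_sequence(chain)


def _trp_adenylate_atoms():
    """AMP template plus an aminoacyl arm esterified to a phosphate oxygen."""
    atoms = list(AMP_TEMPLATE)
    by_name = {a.name: np.asarray(a.coords) for a in atoms}
    o = by_name["O1P"]
    direction = (o - by_name["P"]) / np.linalg.norm(o - by_name["P"])
    cc = o + 1.36 * direction
    ca = cc + np.array([1.1, 1.1, 0.0])
    n = ca + np.array([0.0, 1.47, 0.0])
    ok = cc + np.array([1.1, -0.7, 0.0])
    atoms += [
        Atom("C", "C", tuple(cc)),
        Atom("CA2", "C", tuple(ca)),
        Atom("N", "N", tuple(n)),
        Atom("OXT", "O", tuple(ok)),
    ]
    return atoms


class TestClassifyLigand:
    def test_curated_nucleotide(self):
        assert classify_ligand("ATP", []) == (True, False)

    def test_curated_free_amino_acid(self):
        assert classify_ligand("TRP", []) == (False, True)

    def test_graph_detected_adenosine_phosphate(self):
        assert classify_ligand("XYZ", AMP_TEMPLATE) == (True, False)

    def test_aminoacyl_adenylate_sets_both_flags(self):
        atoms = _trp_adenylate_atoms()
        assert classify_ligand("XYZ", atoms) == (True, True)

    def test_pure_function_repeated_calls_agree(self):
        atoms = _trp_adenylate_atoms()
        first = classify_ligand("XYZ", atoms)
        assert all(classify_ligand("XYZ", atoms) == first for _ in range(3))

    def test_unknown_small_ligand_is_unmatched(self):
        atoms = [Atom("C1", "C", (0, 0, 0)), Atom("O1", "O", (1.3, 0, 0))]
        assert classify_ligand("ZZZ", atoms) == (False, False)

    def test_bond_graph_matches_covalent_distances(self):
        atoms = [
            Atom("C1", "C", (0.0, 0.0, 0.0)),
            Atom("C2", "C", (1.5, 0.0, 0.0)),   # bonded (< 1.92)
            Atom("C3", "C", (3.6, 0.0, 0.0)),   # not bonded to C2 (2.1)
        ]
        g = bond_graph(atoms)
        assert g.has_edge(0, 1) and not g.has_edge(1, 2)
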