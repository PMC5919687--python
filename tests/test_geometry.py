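"""Motif geometry: descriptors, Mann-Whitney, superposition."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aars_motifs.dataset import BindingMode
from aars_motifs.geometry import (
    GeometrySummary,
    MotifObservation,
    ca_distance,
    kabsch_rmsd,
    mann_whitney_u,
    motif_backbone_coords,
    side_chain_angle,
    side_chain_vector,
    summarize_geometry,
    superpose_motifs,
)
from aars_motifs.structure import Atom, Residue
from aars_motifs.synthetic import SyntheticSpec, _motif_residue, generate_toy_structure
from helpers import mwu_exact, quaternion_rmsd, random_rotation


def _res(name, atoms):
    return Residue(author_number=1, name=name, atoms=atoms)


class TestCaDistance:
    def test_three_four_five_triangle(self):
        a = _res("GLY", [Atom("CA", "C", (0.0, 0.0, 0.0))])
        b = _res("GLY", [Atom("CA", "C", (3.0, 4.0, 0.0))])
        assert ca_distance(a, b) == pytest.approx(5.0)

    def test_missing_ca_raises(self):
        a = _res("GLY", [Atom("N", "N", (0.0, 0.0, 0.0))])
        b = _res("GLY", [Atom("CA", "C", (3.0, 4.0, 0.0))])
        with pytest.raises(ValueError):
            ca_distance(a, b)

    def test_planted_distance_recovered_exactly(self):
        spec = SyntheticSpec(
            aars_class="I", seed=3,
            ca_distance={"M1": (14.76, 0.0), "M2": (14.76, 0.0)},
            theta={"M1": (90.0, 0.0), "M2": (90.0, 0.0)},
        )
        chain, truth, chosen = generate_toy_structure(spec, 0)
        author_of = {c: 5 + i for i, c in enumerate(sorted(chosen))}
        ra = chain.residue_at(author_of[274])
        rb = chain.residue_at(author_of[1361])
        assert ca_distance(ra, rb) == pytest.approx(14.76, abs=1e-6)
        assert side_chain_angle(ra, rb) == pytest.approx(90.0, abs=1e-6)


class TestSideChainVector:
    def test_glycine_undefined(self):
        g = _res("GLY", [Atom("CA", "C", (0, 0, 0)), Atom("N", "N", (1, 0, 0))])
        assert side_chain_vector(g) is None

    def test_alanine_uses_cb(self):
        a = _res("ALA", [
            Atom("CA", "C", (0.0, 0.0, 0.0)),
            Atom("CB", "C", (0.0, 0.0, 1.5)),
            Atom("C", "C", (1.4, 0.0, 0.0)),
        ])
        np.testing.assert_allclose(side_chain_vector(a), [0.0, 0.0, 1.5])

    def test_arginine_cz_is_most_distant_by_bruteforce(self):
        arg = _motif_residue(1, "ARG", np.zeros(3), +1.0, np.array([0.0, 0.0, 1.0]))
        vec = side_chain_vector(arg)
        ca = arg.ca.xyz
        carbons = [
            a for a in arg.atoms
            if a.element == "C" and a.name not in ("C", "CA")
        ]
        far = max(carbons, key=lambda a: np.linalg.norm(a.xyz - ca))
        assert far.name == "CZ"
        np.testing.assert_allclose(vec, far.xyz - ca)

    def test_no_sidechain_carbon_undefined(self):
        s = _res("SER", [Atom("CA", "C", (0, 0, 0)), Atom("OG", "O", (0, 0, 1.4))])
        assert side_chain_vector(s) is None


class TestSideChainAngle:
    def _pair(self, v):
        a = _res("ALA", [Atom("CA", "C", (0, 0, 0)), Atom("CB", "C", (0.0, 0.0, 1.5))])
        b = _res("ALA", [Atom("CA", "C", (9, 0, 0)), Atom("CB", "C", tuple(np.array([9, 0, 0]) + v))])
        return a, b

    def test_parallel_zero(self):
        assert side_chain_angle(*self._pair(np.array([0, 0, 1.5]))) == pytest.approx(0.0)

    def test_antiparallel_180(self):
        assert side_chain_angle(*self._pair(np.array([0, 0, -1.5]))) == pytest.approx(180.0)

    def test_orthogonal_90(self):
        assert side_chain_angle(*self._pair(np.array([1.5, 0, 0]))) == pytest.approx(90.0, abs=1e-6)

    def test_symmetry(self):
        a, b = self._pair(np.array([1.0, 0.7, 0.4]))
        assert side_chain_angle(a, b) == pytest.approx(side_chain_angle(b, a))

    def test_glycine_partner_undefined(self):
        a, _ = self._pair(np.array([0, 0, 1.5]))
        g = _res("GLY", [Atom("CA", "C", (9, 0, 0))])
        assert side_chain_angle(a, g) is None


class TestMannWhitney:
    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 1000), min_size=3, max_size=8, unique=True),
        st.lists(st.integers(1001, 2000), min_size=3, max_size=8, unique=True),
    )
    def test_matches_exact_enumeration(self, x, y):
        """Tie-free groups of size <= 8: statistic and two-sided p equal the
        full permutation-enumeration oracle."""
        u, p = mann_whitney_u(x, y)
        u_ref, p_ref = mwu_exact(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_identical_groups_u_half_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p > 0.99

    def test_large_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        y = rng.normal(2, 1, 40)
        _, p = mann_whitney_u(x, y)
        assert p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def _obs(mode, d, theta):
    return MotifObservation(
        structure_id="s", chain_id="A", motif_name="m", positions=(1, 2),
        ca_distance=d, theta=theta, binding_mode=BindingMode(mode),
    )


class TestSummary:
    def test_groups_and_listwise_theta_exclusion(self):
        obs = [
            _obs("M1", 17.0, 140.0),
            _obs("M1", 18.0, None),   # glycine-excluded angle, distance kept
            _obs("M1", 19.0, 150.0),
            _obs("M2", 18.5, 141.0),
            _obs("M2", 18.6, 139.0),
        ]
        s = summarize_geometry(obs)
        assert s.distance["M1"].n == 3
        assert s.theta["M1"].n == 2
        assert s.distance["M1"].mean == pytest.approx(18.0)
        assert s.distance["M2"].sd >= 0

    def test_tests_need_three_per_group(self):
        obs = [_obs("M1", 17.0, None), _obs("M2", 18.0, None)]
        s = summarize_geometry(obs)
        assert s.distance_test is None and s.theta_test is None

    def test_all_undefined_theta_group_absent(self):
        obs = [_obs("M1", 17.0, None), _obs("M1", 18.0, None)]
        s = summarize_geometry(obs)
        assert "M1" not in s.theta


class TestSuperposition:
    def _motif_coords(self, seed=0):
        rng = np.random.default_rng(seed)
        a = _motif_residue(1, "ARG", np.zeros(3), +1.0, np.array([0.0, 0.0, 1.0]))
        b = _motif_residue(2, "ARG", np.array([14.0, 0, 0]), -1.0,
                           np.array([0.0, 0.4, 0.9]))
        return motif_backbone_coords(a, b)

    def test_self_rmsd_zero(self):
        c = self._motif_coords()
        assert kabsch_rmsd(c, c) == pytest.approx(0.0, abs=1e-9)

    def test_rotated_copy_rmsd_zero(self):
        c = self._motif_coords()
        rng = np.random.default_rng(1)
        moved = (random_rotation(rng) @ c.T).T + rng.uniform(-30, 30, 3)
        assert kabsch_rmsd(c, moved) == pytest.approx(0.0, abs=1e-6)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(0, 5, (8, 3))
            b = a + rng.normal(0, 1.0, (8, 3))
            assert kabsch_rmsd(a, b) == pytest.approx(quaternion_rmsd(a, b), abs=1e-9)

    def test_all_vs_all_matrix_and_mean(self):
        rng = np.random.default_rng(3)
        sets = [rng.normal(0, 5, (8, 3)) for _ in range(4)]
        matrix, mean = superpose_motifs(sets)
        assert matrix.shape == (4, 4)
        assert np.allclose(matrix, matrix.T)
        assert np.allclose(np.diag(matrix), 0)
        pairs = matrix[np.triu_indices(4, 1)]
        assert mean == pytest.approx(pairs.mean())

    def test_missing_scoped_atom_gives_none(self):
        a = _res("GLY", [Atom("CA", "C", (0, 0, 0))])
        b = _res("GLY", [Atom("CA", "C", (5, 0, 0))])
        assert motif_backbone_coords(a, b) is None


class TestRigidInvariance:
    def test_descriptors_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        spec = SyntheticSpec(aars_class="II", seed=6, m1_fraction=1.0)
        chain, truth, chosen = generate_toy_structure(spec, 2)
        author_of = {c: 5 + i for i, c in enumerate(sorted(chosen))}
        ra = chain.residue_at(author_of[698])
        rb = chain.residue_at(author_of[1786])
        d0, t0 = ca_distance(ra, rb), side_chain_angle(ra, rb)
        from helpers import rigid_transform_chain

        moved = rigid_transform_chain(chain, rng)
        ma = moved.residue_at(author_of[698])
        mb = moved.residue_at(author_of[1786])
        assert ca_distance(ma, mb) == pytest.approx(d0, abs=1e-9)
        assert side_chain_angle(ma, mb) == pytest.approx(t0, abs=1e-9)
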