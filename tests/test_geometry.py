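"""Geometry descriptors: distances, angles, plane angles, torsions, RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kynox import (AtomRecord, bond_angle, distance, generate_geometry_fixture,
                   geometry_report, kabsch_rmsd, plane_angle, torsion)


def atom(el, x, y, z):
    return AtomRecord(el, float(x), float(y), float(z))


class TestDistance:
    def test_identical_points(self):
        assert distance(atom("O", 0, 0, 0), atom("O", 0, 0, 0)) == 0.0

    def test_pythagorean(self):
        assert distance(atom("O", 0, 0, 0), atom("O", 3, 4, 0)) == 5.0


class TestBondAngle:
    def test_collinear(self):
        a, v, b = atom("O", -1, 0, 0), atom("H", 0, 0, 0), atom("O", 1, 0, 0)
        assert bond_angle(a, v, b) == pytest.approx(180.0)

    def test_right_angle(self):
        a, v, b = atom("O", 1, 0, 0), atom("H", 0, 0, 0), atom("O", 0, 1, 0)
        assert bond_angle(a, v, b) == pytest.approx(90.0)

    def test_zero_arm_raises(self):
        p = atom("O", 0, 0, 0)
        with pytest.raises(ValueError, match="zero-length"):
            bond_angle(p, p, atom("O", 1, 0, 0))


class TestPlaneAngle:
    def test_same_plane(self):
        t = (atom("C", 0, 0, 0), atom("C", 1, 0, 0), atom("C", 0, 1, 0))
        assert plane_angle(t, t) == pytest.approx(0.0)

    def test_perpendicular_planes(self):
        xy = (atom("C", 0, 0, 0), atom("C", 1, 0, 0), atom("C", 0, 1, 0))
        xz = (atom("C", 0, 0, 0), atom("C", 1, 0, 0), atom("C", 0, 0, 1))
        assert plane_angle(xy, xz) == pytest.approx(90.0)

    def test_symmetry(self):
        t1 = (atom("C", 0, 0, 0), atom("C", 1, 0, 0), atom("C", 0, 1, 0.3))
        t2 = (atom("C", 0, 0, 1), atom("C", 1, 0.2, 0), atom("C", 0, 1, 0))
        assert plane_angle(t1, t2) == pytest.approx(plane_angle(t2, t1))

    def test_collinear_raises(self):
        bad = (atom("C", 0, 0, 0), atom("C", 1, 0, 0), atom("C", 2, 0, 0))
        good = (atom("C", 0, 0, 0), atom("C", 1, 0, 0), atom("C", 0, 1, 0))
        with pytest.raises(ValueError, match="collinear"):
            plane_angle(bad, good)


class TestTorsion:
    def test_cis_zero(self):
        assert torsion(atom("C", 1, 1, 0), atom("O", 1, 0, 0),
                       atom("O", 0, 0, 0), atom("C", 0, 1, 0)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_trans_180(self):
        assert torsion(atom("C", 1, 1, 0), atom("O", 1, 0, 0),
                       atom("O", 0, 0, 0), atom("C", 0, -1, 0)) == \
            pytest.approx(180.0)

    def test_reversal_invariance(self):
        # the signed dihedral is invariant under reversing the atom chain
        # (both plane normals negate, so the sign cancels)
        c1, o1 = atom("C", 1, 1, 0.3), atom("O", 1, 0, 0)
        o2, c2 = atom("O", 0, 0, 0), atom("C", 0.2, 1, -0.7)
        assert torsion(c2, o2, o1, c1) == \
            pytest.approx(torsion(c1, o1, o2, c2), abs=1e-9)

    def test_mirror_reflection_negates(self):
        c1, o1 = atom("C", 1, 1, 0.3), atom("O", 1, 0, 0)
        o2, c2 = atom("O", 0, 0, 0), atom("C", 0.2, 1, -0.7)
        mirrored = [atom(a.element, a.x, a.y, -a.z)
                    for a in (c1, o1, o2, c2)]
        t_fwd = torsion(c1, o1, o2, c2)
        t_mir = torsion(*mirrored)
        assert (t_fwd + t_mir) % 360.0 == pytest.approx(0.0, abs=1e-9) or \
            t_fwd + t_mir == pytest.approx(360.0, abs=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="collinear|coincide"):
            torsion(atom("C", 2, 0, 0), atom("O", 1, 0, 0),
                    atom("O", 0, 0, 0), atom("C", 0, 1, 0))


class TestKabschRmsd:
    @staticmethod
    def random_structure(rng, n=25):
        return [AtomRecord("C", *xyz)
                for xyz in rng.uniform(-5, 5, size=(n, 3))]

    @staticmethod
    def rigid_copy(rng, atoms):
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.uniform(-10, 10, size=3)
        coords = np.array([a.position for a in atoms]) @ q.T + t
        return [AtomRecord(a.element, *xyz) for a, xyz in zip(atoms, coords)]

    def test_identical(self):
        rng = np.random.default_rng(0)
        s = self.random_structure(rng)
        assert kabsch_rmsd(s, s) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = self.random_structure(rng)
        assert kabsch_rmsd(s, self.rigid_copy(rng, s)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_bound(self):
        rng = np.random.default_rng(1)
        s = self.random_structure(rng, n=25)
        moved = [AtomRecord(a.element, a.x, a.y, a.z) for a in s]
        moved[0] = AtomRecord(moved[0].element, moved[0].x + 0.1,
                              moved[0].y, moved[0].z)
        r = kabsch_rmsd(s, moved)
        assert 0 < r <= 0.1 / np.sqrt(25) + 1e-12

    def test_symmetry_and_triangle_bound(self):
        rng = np.random.default_rng(2)
        a = self.random_structure(rng, n=12)
        jitter = rng.normal(scale=0.05, size=(12, 3))
        b = [AtomRecord(x.element, *(np.array(x.position) + d))
             for x, d in zip(a, jitter)]
        c = self.rigid_copy(rng, b)
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), rel=1e-9)
        assert kabsch_rmsd(a, c) <= \
            kabsch_rmsd(a, b) + kabsch_rmsd(b, c) + 1e-9

    def test_count_mismatch_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="counts differ"):
            kabsch_rmsd(self.random_structure(rng, 4),
                        self.random_structure(rng, 5))

    def test_element_mismatch_raises(self):
        a = [atom("C", 0, 0, 0), atom("O", 1, 0, 0)]
        b = [atom("C", 0, 0, 0), atom("N", 1, 0, 0)]
        with pytest.raises(ValueError, match="element mismatch"):
            kabsch_rmsd(a, b)

    def test_raw_rmsd_option(self):
        a = [atom("C", 0, 0, 0)]
        b = [atom("C", 1, 0, 0)]
        assert kabsch_rmsd(a, b, superpose=False) == pytest.approx(1.0)


class TestPlantedFixtures:
    # reagent-complex means of hydroxykynurenine pathways
    TARGETS = dict(oho_length=2.75, oho_angle=168.8, plane_angle=67.2,
                   torsion=101.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_all_descriptors_recovered(self, seed):
        atoms, roles, truth = generate_geometry_fixture(seed, self.TARGETS)
        rep = geometry_report(atoms, roles)
        for key, target in self.TARGETS.items():
            assert rep[key] == pytest.approx(target, abs=1e-6), key

    def test_ts_like_torsion_above_180(self):
        targets = dict(self.TARGETS, torsion=350.7)
        atoms, roles, _ = generate_geometry_fixture(0, targets)
        assert geometry_report(atoms, roles)["torsion"] == \
            pytest.approx(350.7, abs=1e-6)

    def test_determinism(self):
        a, _, _ = generate_geometry_fixture(5, self.TARGETS)
        b, _, _ = generate_geometry_fixture(5, self.TARGETS)
        assert a == b

    @given(seed=st.integers(0, 10**6))
    @settings(derandomize=True, max_examples=20)
    def test_rigid_motion_invariance_via_seeds(self, seed):
        # different seeds apply different rigid motions to the same planted
        # construction; every descriptor must be unchanged
        atoms, roles, _ = generate_geometry_fixture(seed, self.TARGETS)
        rep = geometry_report(atoms, roles)
        assert rep["oho_length"] == pytest.approx(2.75, abs=1e-9)
        assert rep["oho_angle"] == pytest.approx(168.8, abs=1e-7)
        assert rep["plane_angle"] == pytest.approx(67.2, abs=1e-7)
        assert rep["torsion"] == pytest.approx(101.0, abs=1e-7)
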