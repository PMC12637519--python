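"""Backbone builder, dihedral measurement, superposition and hinge rotations."""

import numpy as np
import pytest

from conftest import helix_dihedrals, random_dihedrals
from ulktether.geometry import (BOND_C_N, BOND_CA_C, BOND_N_CA, Chain,
                                ChainDiscontinuityError, GeometryError,
                                MembranePlane, SLOT_INDEX, Transform,
                                build_chain, dihedral, height_above_plane,
                                rotation_about_axis, superpose, wrap_angle)


class TestBuildChain:
    def test_virtual_bond_length_trans(self, rng):
        chain = build_chain("AA", random_dihedrals(2, rng))
        ca = chain.coords[:, SLOT_INDEX["CA"]]
        assert np.linalg.norm(ca[1] - ca[0]) == pytest.approx(3.80, abs=0.05)

    def test_bond_lengths_ideal(self, rng):
        chain = build_chain("ADGPK", random_dihedrals(5, rng))
        n = chain.coords[:, SLOT_INDEX["N"]]
        ca = chain.coords[:, SLOT_INDEX["CA"]]
        c = chain.coords[:, SLOT_INDEX["C"]]
        assert np.allclose(np.linalg.norm(ca - n, axis=1), BOND_N_CA, atol=0.02)
        assert np.allclose(np.linalg.norm(c - ca, axis=1), BOND_CA_C, atol=0.02)
        assert np.allclose(np.linalg.norm(n[1:] - c[:-1], axis=1), BOND_C_N, atol=0.02)

    def test_single_residue_has_three_backbone_atoms(self):
        chain = build_chain("A", [(np.nan, 120.0, 180.0)])
        for atom in ("N", "CA", "C"):
            assert np.all(np.isfinite(chain.atom(1, atom)))

    def test_round_trip_dihedrals(self, rng):
        dih = random_dihedrals(30, rng)
        chain = build_chain("A" * 30, dih)
        phi, psi, omega = chain.measure_dihedrals()
        assert np.nanmax(np.abs(wrap_angle(phi[1:] - dih[1:, 0]))) < 1e-6
        assert np.nanmax(np.abs(wrap_angle(psi[:-1] - dih[:-1, 1]))) < 1e-6
        assert np.nanmax(np.abs(np.abs(omega[1:]) - 180.0)) < 1e-6

    def test_rebuild_from_measured_dihedrals_identical(self, rng):
        """Feeding measured dihedrals back reproduces coordinates after superposition."""
        dih = random_dihedrals(20, rng)
        chain = build_chain("A" * 20, dih)
        phi, psi, omega = chain.measure_dihedrals()
        dih2 = np.column_stack([phi, psi, omega])
        dih2[0, 0] = 0.0
        dih2[-1, 1] = dih[-1, 1]          # psi of last residue is unobservable
        rebuilt = build_chain("A" * 20, dih2)
        mask = chain.atom_mask()
        tr, rmsd = superpose(rebuilt.coords[mask], chain.coords[mask])
        assert rmsd < 1e-5

    def test_length_mismatch_raises(self):
        with pytest.raises(GeometryError):
            build_chain("AAA", [(0.0, 0.0, 180.0)] * 2)

    def test_non_finite_angles_raise(self):
        with pytest.raises(GeometryError):
            build_chain("AA", [(0.0, np.nan, 180.0), (0.0, 0.0, 180.0)])

    def test_l_chirality_of_cb(self):
        chain = build_chain("AAA", helix_dihedrals(3))
        i = 1
        d = dihedral(chain.coords[i, SLOT_INDEX["CB"]],
                     chain.coords[i, SLOT_INDEX["CA"]],
                     chain.coords[i, SLOT_INDEX["N"]],
                     chain.coords[i, SLOT_INDEX["C"]])
        assert d == pytest.approx(-122.6, abs=1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_round_trip_property_random_chains(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        dih = random_dihedrals(n, rng)
        chain = build_chain("A" * n, dih)
        phi, psi, _ = chain.measure_dihedrals()
        assert np.nanmax(np.abs(wrap_angle(phi[1:] - dih[1:, 0]))) < 1e-6
        assert np.nanmax(np.abs(wrap_angle(psi[:-1] - dih[:-1, 1]))) < 1e-6


class TestMeasureDihedrals:
    def test_single_residue_all_absent(self):
        chain = build_chain("A", [(np.nan, 100.0, 180.0)])
        phi, psi, omega = chain.measure_dihedrals()
        assert np.all(np.isnan(phi)) and np.all(np.isnan(psi))

    def test_displaced_residue_raises_discontinuity(self, rng):
        chain = build_chain("A" * 6, random_dihedrals(6, rng))
        chain.coords[3] += 10.0
        with pytest.raises(ChainDiscontinuityError):
            chain.measure_dihedrals()


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(6, 3))
        tr, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation(self, rng):
        pts = rng.normal(size=(5, 3))
        tr, rmsd = superpose(pts, pts + np.array([5.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tr.translation, [5.0, 0.0, 0.0], atol=1e-9)

    def test_recovers_constructed_rotation(self, rng):
        pts = rng.normal(size=(8, 3)) * 4
        tr_true = rotation_about_axis(np.zeros(3), rng.normal(size=3), 73.0)
        moved = tr_true.apply(pts)
        tr, rmsd = superpose(pts, moved)
        assert rmsd < 1e-9
        assert np.allclose(tr.rotation, tr_true.rotation, atol=1e-6)

    def test_beats_random_rotations(self, rng):
        """Kabsch RMSD is minimal versus a brute-force random-rotation oracle."""
        from scipy.spatial.transform import Rotation
        mob = rng.normal(size=(7, 3)) * 3
        ref = rng.normal(size=(7, 3)) * 3
        _, rmsd = superpose(mob, ref)
        rand = Rotation.random(10_000, random_state=7).as_matrix()
        mc, rc = mob - mob.mean(0), ref - ref.mean(0)
        rotated = np.einsum("kij,nj->kni", rand, mc)
        rmsds = np.sqrt(np.mean(np.sum((rotated - rc) ** 2, axis=2), axis=1))
        assert rmsd <= rmsds.min() + 1e-12

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_raise(self):
        line = np.outer(np.arange(4, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            superpose(line, line + 1.0)


class TestRotateDihedral:
    def test_zero_delta_identity(self, rng):
        chain = build_chain("A" * 10, random_dihedrals(10, rng))
        ref = chain.coords.copy()
        chain.rotate_dihedral(5, "psi", 0.0)
        assert np.array_equal(chain.coords, ref, equal_nan=True)

    def test_full_turn_identity(self, rng):
        chain = build_chain("A" * 10, random_dihedrals(10, rng))
        ref = chain.coords.copy()
        chain.rotate_dihedral(4, "phi", 360.0)
        assert np.nanmax(np.abs(chain.coords - ref)) < 1e-9

    def test_rotation_inverse(self, rng):
        chain = build_chain("A" * 12, random_dihedrals(12, rng))
        ref = chain.coords.copy()
        chain.rotate_dihedral(6, "psi", 37.5)
        chain.rotate_dihedral(6, "psi", -37.5)
        assert np.nanmax(np.abs(chain.coords - ref)) < 1e-9

    def test_changes_measured_dihedral_by_delta(self, rng):
        chain = build_chain("A" * 8, random_dihedrals(8, rng))
        phi0, _, _ = chain.measure_dihedrals()
        chain.rotate_dihedral(4, "phi", 25.0)
        phi1, _, _ = chain.measure_dihedrals()
        from ulktether.geometry import wrap_angle
        assert wrap_angle(phi1[3] - phi0[3]) == pytest.approx(25.0, abs=1e-9)

    def test_upstream_unmoved_and_rigid_sides(self, rng):
        chain = build_chain("A" * 14, random_dihedrals(14, rng))
        mask = chain.atom_mask()
        before = chain.coords.copy()
        moved_mask = chain.moved_mask(7, "psi")
        chain.rotate_dihedral(7, "psi", 61.0)
        # upstream atoms bit-identical
        up = ~moved_mask & mask
        assert np.array_equal(chain.coords[up], before[up])
        # intra-side pairwise distances preserved on the moved side
        dn = moved_mask & mask
        d0 = np.linalg.norm(before[dn][:, None] - before[dn][None], axis=2)
        d1 = np.linalg.norm(chain.coords[dn][:, None] - chain.coords[dn][None], axis=2)
        assert np.max(np.abs(d1 - d0)) < 1e-9

    def test_bond_geometry_preserved_many_rotations(self, rng):
        """Hinge rotations drift bonds by < 1e-9 A over many random moves."""
        n = 30
        chain = build_chain("A" * n, random_dihedrals(n, rng))
        nn = chain.coords[:, SLOT_INDEX["N"]]
        ca = chain.coords[:, SLOT_INDEX["CA"]]
        d0 = np.linalg.norm(ca - nn, axis=1)
        for _ in range(2000):
            r = int(rng.integers(2, n + 1))
            kind = "phi" if rng.integers(2) == 0 else "psi"
            chain.rotate_dihedral(r, kind, float(rng.normal(0, 5)))
        nn = chain.coords[:, SLOT_INDEX["N"]]
        ca = chain.coords[:, SLOT_INDEX["CA"]]
        assert np.max(np.abs(np.linalg.norm(ca - nn, axis=1) - d0)) < 1e-9

    def test_invalid_hinge(self, rng):
        chain = build_chain("A" * 5, random_dihedrals(5, rng))
        with pytest.raises(GeometryError):
            chain.rotate_dihedral(1, "phi", 5.0)   # first residue has no phi
        with pytest.raises(KeyError):
            chain.rotate_dihedral(99, "psi", 5.0)


class TestTransform:
    def test_invariants_checked(self):
        with pytest.raises(GeometryError):
            Transform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(GeometryError):
            Transform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_inverse(self, rng):
        tr = rotation_about_axis(rng.normal(size=3), rng.normal(size=3), 33.0)
        pts = rng.normal(size=(5, 3))
        assert np.allclose(tr.inverse().apply(tr.apply(pts)), pts, atol=1e-12)


class TestMembranePlane:
    @pytest.mark.parametrize("z,expect", [(0.0, 0.0), (120.0, 120.0), (-3.0, -3.0)])
    def test_height(self, z, expect):
        plane = MembranePlane(z0=0.0)
        assert height_above_plane(np.array([1.0, 2.0, z]), plane) == expect

    def test_half_space(self):
        plane = MembranePlane(z0=5.0)
        assert plane.all_above(np.array([[0.0, 0.0, 5.1]]))
        assert not plane.all_above(np.array([[0.0, 0.0, 5.0]]))
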