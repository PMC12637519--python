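"""Stochastic CCD: move statistics, acceptance rule, convergence, oracles."""

import numpy as np
import pytest

from conftest import random_dihedrals
from ulktether.ccd import (AnchorTask, CCDParams, EffectorAtom, alignment_close,
                           ccd_minimize, ccd_move)
from ulktether.geometry import (Chain, MembranePlane, SLOT_INDEX, build_chain,
                                superpose)
from ulktether.fixtures import make_toy_loop, toy_rotatable


def _free_chain(n, seed=0):
    rng = np.random.default_rng(seed)
    chain = build_chain("A" * n, random_dihedrals(n, rng))
    chain.anchored_end = "N"
    return chain


def _point_task(chain, offset):
    last = int(chain.resids[-1])
    target = chain.atom(last, "C") + np.asarray(offset, dtype=float)
    return AnchorTask("point", (EffectorAtom("chain", last, "C"),), target[None, :])


class TestCcdMove:
    def test_gaussian_move_statistics(self):
        """Sampled rotation angles have mean 0 and unit standard deviation."""
        rng = np.random.default_rng(5)
        deltas = CCDParams().sigma * rng.standard_normal(10_000)
        assert abs(deltas.mean()) < 0.05
        assert deltas.std() == pytest.approx(1.0, rel=0.05)

    def test_zero_objective_rejects_everything(self):
        chain = _free_chain(5)
        last = int(chain.resids[-1])
        task = AnchorTask("point", (EffectorAtom("chain", last, "C"),),
                          chain.atom(last, "C")[None, :].copy())
        ref = chain.coords.copy()
        rng = np.random.default_rng(0)
        for _ in range(50):
            chain2, accepted, _ = ccd_move(chain, task, CCDParams(), rng)
            assert not accepted
            assert np.array_equal(chain2.coords, ref, equal_nan=True)

    def test_acceptance_agrees_with_before_after_oracle(self):
        """Accepted iff the recomputed objective strictly decreases."""
        chain = _free_chain(4, seed=3)
        task = _point_task(chain, [2.0, 1.0, 0.5])
        rng = np.random.default_rng(7)
        last = int(chain.resids[-1])
        for _ in range(300):
            before = np.linalg.norm(chain.atom(last, "C") - task.target[0])
            chain2, accepted, obj = ccd_move(chain, task, CCDParams(), rng)
            after = np.linalg.norm(chain2.atom(last, "C") - task.target[0])
            if accepted:
                assert after < before
            else:
                assert np.array_equal(chain2.coords, chain.coords, equal_nan=True)
            chain = chain2

    def test_rejected_moves_bit_identical(self):
        chain = _free_chain(6, seed=1)
        task = _point_task(chain, [0.0, 0.0, 1.0])
        rng = np.random.default_rng(11)
        rejected = 0
        for _ in range(100):
            chain2, accepted, _ = ccd_move(chain, task, CCDParams(), rng)
            if not accepted:
                rejected += 1
                assert np.array_equal(chain2.coords, chain.coords, equal_nan=True)
            chain = chain2
        assert rejected > 0


class TestCcdMinimize:
    def test_max_moves_zero_is_unconverged_noop(self):
        chain = _free_chain(5)
        task = _point_task(chain, [3.0, 0.0, 0.0])
        res = ccd_minimize(chain, task, CCDParams(max_moves=0),
                           np.random.default_rng(0))
        assert not res.converged
        assert np.array_equal(res.chain.coords, chain.coords, equal_nan=True)

    def test_trace_monotone_nonincreasing(self):
        chain = _free_chain(8, seed=2)
        task = _point_task(chain, [4.0, -2.0, 1.0])
        res = ccd_minimize(chain, task, CCDParams(max_moves=5000),
                           np.random.default_rng(3))
        trace = np.array(res.trace)
        assert np.all(np.diff(trace) < 0)     # accepted moves strictly decrease

    def test_bond_geometry_preserved(self):
        chain = _free_chain(10, seed=4)
        task = _point_task(chain, [5.0, 5.0, 0.0])
        n0 = chain.coords[:, SLOT_INDEX["N"]]
        ca0 = chain.coords[:, SLOT_INDEX["CA"]]
        d0 = np.linalg.norm(ca0 - n0, axis=1)
        res = ccd_minimize(chain, task, CCDParams(max_moves=20_000),
                           np.random.default_rng(5))
        n1 = res.chain.coords[:, SLOT_INDEX["N"]]
        ca1 = res.chain.coords[:, SLOT_INDEX["CA"]]
        assert np.max(np.abs(np.linalg.norm(ca1 - n1, axis=1) - d0)) < 1e-9

    def test_toy_point_target_reaches_grid_optimum(self):
        """Final objective within 0.5 A of the exhaustive 5-degree grid optimum."""
        chain, task, grid_opt = make_toy_loop(4, seed=8)
        res = ccd_minimize(chain, task, CCDParams(max_moves=60_000),
                           np.random.default_rng(9),
                           rotatable=toy_rotatable(4))
        assert res.final_objective <= grid_opt + 0.5

    def test_plane_mode_converges_from_above(self):
        """Effectors starting 15 A above the plane end within the 5 A criterion."""
        rng = np.random.default_rng(12)
        chain = build_chain("A" * 20, random_dihedrals(20, rng))
        chain.anchored_end = "N"
        plane = MembranePlane(z0=float(chain.coords[..., 2].max() + 15.0))
        # pull the last three CA atoms up to the plane height
        eff = tuple(EffectorAtom("chain", r, "CA") for r in (18, 19, 20))
        task = AnchorTask("plane", eff, plane)
        res = ccd_minimize(chain, task, CCDParams(max_moves=100_000),
                           np.random.default_rng(13))
        assert res.converged
        za = np.array([res.chain.atom(r, "CA")[2] for r in (18, 19, 20)])
        assert np.all(np.abs(za - plane.z0) <= 5.0)

    def test_determinism(self):
        chain = _free_chain(6, seed=6)
        task = _point_task(chain, [2.0, 2.0, 2.0])
        a = ccd_minimize(chain, task, CCDParams(max_moves=2000),
                         np.random.default_rng(42))
        b = ccd_minimize(chain, task, CCDParams(max_moves=2000),
                         np.random.default_rng(42))
        assert np.array_equal(a.chain.coords, b.chain.coords, equal_nan=True)
        assert a.trace == b.trace


class TestAlignmentClose:
    def test_identical_true(self, rng):
        pts = rng.normal(size=(4, 3))
        assert alignment_close(pts, pts, 0.6)

    def test_uniform_offset_one_angstrom_false(self, rng):
        pts = rng.normal(size=(4, 3))
        assert not alignment_close(pts, pts + np.array([1.0, 0.0, 0.0]), 0.6)

    @pytest.mark.parametrize("r", [0.3, 0.59, 0.61, 1.2])
    def test_constructed_rmsd_thresholding(self, r, rng):
        pts = rng.normal(size=(6, 3))
        d = rng.normal(size=(6, 3))
        d *= r / np.sqrt(np.mean(np.sum(d ** 2, axis=1)))
        assert alignment_close(pts, pts + d, 0.6) == (r < 0.6)

    def test_shape_mismatch_raises(self):
        from ulktether.geometry import GeometryError
        with pytest.raises(GeometryError):
            alignment_close(np.zeros((3, 3)), np.zeros((4, 3)))


class TestToyLoopOracle:
    def test_grid_matches_forward_kinematics(self):
        """The vectorized grid oracle agrees with actual hinge rotations."""
        chain, task, _ = make_toy_loop(3, seed=2)
        rot = toy_rotatable(3)
        rng = np.random.default_rng(4)
        for _ in range(5):
            deltas = rng.uniform(0, 360, len(rot)) // 5 * 5
            test = chain.copy()
            for (r, kind), d in zip(rot, deltas):
                test.rotate_dihedral(r, kind, float(d))
            from ulktether.fixtures import _grid_optimum
            last = int(chain.resids[-1])
            point = test.atom(last, "C")
            # a grid containing exactly this combination finds a distance of 0
            opt = _grid_optimum(chain, rot, (last, "C"), point, step=5.0)
            assert opt < 1e-6

    def test_unreachable_target_gap(self):
        chain, task, grid_opt = make_toy_loop(2, target=np.array([500.0, 0.0, 0.0]),
                                              seed=0)
        ca = chain.atom(1, "CA")
        assert grid_opt >= 500.0 - np.linalg.norm(ca) - 20.0
        assert grid_opt > 480.0

    def test_fixture_deterministic(self):
        a = make_toy_loop(3, seed=5)
        b = make_toy_loop(3, seed=5)
        assert np.array_equal(a[0].coords, b[0].coords, equal_nan=True)
        assert a[2] == b[2]
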