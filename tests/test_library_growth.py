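"""Dihedral library sampling and hierarchical self-avoiding chain growth."""

import numpy as np
import pytest

from ulktether.clash import ClashModel, build_view, has_cross_clash, view_of_chain
from ulktether.fixtures import fjc_chains, make_kd_fixture, KdSpec
from ulktether.geometry import MembranePlane, SLOT_INDEX, Transform, build_chain, superpose
from ulktether.growth import (AttachmentClashError, GrowthPolicy, SegmentSpec,
                              attach_rigid_body, grow_ensemble,
                              hierarchical_assemble, sample_fragment)
from ulktether.library import DihedralLibrary, VirtualBondLibrary, residue_class


class TestLibrary:
    def test_weights_normalized(self, library):
        for cls, w in library.weights.items():
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_residue_classes(self):
        assert residue_class("P", "A") == "pro"
        assert residue_class("A", "P") == "prepro"
        assert residue_class("G", "A") == "gly"
        assert residue_class("L", None) == "generic"

    def test_gly_segment_draws_from_gly_class(self, library, rng):
        """Angles drawn for all-Gly segments come from the Gly basin set."""
        centres = library.angles["gly"]
        hits = 0
        draws = library.sample("G" * 1000, rng, jitter_deg=0.0)
        for phi, psi in draws[:, :2]:
            if np.any((np.abs(centres[:, 0] - phi) < 1e-9)
                      & (np.abs(centres[:, 1] - psi) < 1e-9)):
                hits += 1
        assert hits == 1000

    def test_sample_angle_range(self, library, rng):
        d = library.sample("ACDEFGHIKLMNPQRSTVWY" * 5, rng)
        assert np.all(d[:, :2] > -180.0) and np.all(d[:, :2] <= 180.0)


class TestSampleFragment:
    def test_deterministic_under_seed(self, library):
        a = sample_fragment("ASDFG", range(1, 6), library, np.random.default_rng(3))
        b = sample_fragment("ASDFG", range(1, 6), library, np.random.default_rng(3))
        assert np.array_equal(a.coords, b.coords, equal_nan=True)

    def test_single_residue(self, library, rng):
        frag = sample_fragment("A", [7], library, rng)
        assert len(frag) == 1 and int(frag.resids[0]) == 7


class TestHierarchicalAssemble:
    def test_short_segment_contiguous(self, library, rng):
        spec = SegmentSpec("ACDEFGHIKLMNPQRSTVWYACDEF" * 2, 101, "seg", "X")
        chain = hierarchical_assemble(spec, library, GrowthPolicy(), rng)
        chain.check_contiguous()
        assert len(chain) == 50
        assert list(chain.resids) == list(range(101, 151))

    def test_membrane_half_space_respected(self, library):
        """With the N terminus pinned above the plane, every accepted atom is above it."""
        anchor = build_chain("A", [(np.nan, 150.0, 180.0)],
                             start_frame=Transform(np.eye(3), np.array([0.0, 0.0, 5.0])))
        target = anchor.backbone(1)
        policy = GrowthPolicy(membrane=MembranePlane(0.0))
        spec = SegmentSpec("ASDGKLEQRT" * 3, 1, "seg", "X", anchor=("N", target))
        ens = grow_ensemble(spec, DihedralLibrary.default(), policy, 25,
                            np.random.default_rng(5))
        for chain in ens:
            assert np.nanmin(chain.coords[..., 2]) > 0.0

    def test_anchor_placement(self, library, rng):
        anchor = build_chain("A", [(np.nan, 150.0, 180.0)],
                             start_frame=Transform(np.eye(3), np.array([3.0, -2.0, 40.0])))
        target = anchor.backbone(1)
        spec = SegmentSpec("ASDGKLEQRT", 1, "seg", "X", anchor=("N", target))
        chain = hierarchical_assemble(spec, library, GrowthPolicy(), rng)
        assert np.allclose(chain.backbone(1), target, atol=1e-8)

    def test_c_anchor_placement(self, library, rng):
        anchor = build_chain("A", [(np.nan, 150.0, 180.0)],
                             start_frame=Transform(np.eye(3), np.array([0.0, 0.0, 30.0])))
        target = anchor.backbone(1)
        spec = SegmentSpec("ASDGKLEQRTYV", 1, "seg", "X", anchor=("C", target))
        chain = hierarchical_assemble(spec, library, GrowthPolicy(), rng)
        assert np.allclose(chain.backbone(12), target, atol=1e-8)


def _attachable_chain(library, seed0=0):
    """A coil draw onto which the kinase-domain fixture grafts cleanly."""
    kd = make_kd_fixture(KdSpec(overlap_resid=50))
    spec = SegmentSpec("ASDGKLEQRT", 50, "seg", "ULK1")
    for seed in range(seed0, seed0 + 40):
        chain = hierarchical_assemble(spec, library, GrowthPolicy(),
                                      np.random.default_rng(seed))
        try:
            att = attach_rigid_body(chain.copy(), kd, (50,))
        except AttachmentClashError:
            continue
        return chain, kd
    raise AssertionError("no attachable coil found")


class TestAttachRigidBody:
    def test_overlap_rmsd_matches_superpose_oracle(self, library):
        chain, kd = _attachable_chain(library)
        att = attach_rigid_body(chain, kd, (50,))
        _, oracle = superpose(kd.overlap_coords((50,)), chain.backbone(50))
        assert att.rmsd == pytest.approx(oracle, abs=1e-6)
        placed = att.body.residue_coords(50, mol="ULK1")
        assert np.allclose(placed, chain.backbone(50), atol=1e-6)
        assert att.rmsd < 1e-6      # ideal-geometry single-residue graft is exact

    def test_rigidity_preserved(self, library):
        chain, kd = _attachable_chain(library)
        att = attach_rigid_body(chain, kd, (50,))
        d0 = np.linalg.norm(kd.coords[:50, None] - kd.coords[None, :50], axis=2)
        d1 = np.linalg.norm(att.body.coords[:50, None] - att.body.coords[None, :50], axis=2)
        assert np.max(np.abs(d1 - d0)) < 1e-9

    def test_engineered_collision_raises(self, library, rng):
        from ulktether.geometry import RigidBody
        spec = SegmentSpec("ASDGKLEQRT" * 5, 41, "seg", "ULK1")
        chain = hierarchical_assemble(spec, library, GrowthPolicy(), rng)
        # body whose overlap coincides with residue 50 but which carries an
        # atom placed right on top of a distant chain residue
        ov = chain.backbone(50)
        intruder = chain.atom(75, "CA") + 0.3
        body = RigidBody("bad", np.vstack([ov, intruder[None, :]]),
                         labels=(("ULK1", 50, "N"), ("ULK1", 50, "CA"),
                                 ("ULK1", 50, "C"), ("Z", 1, "CA")),
                         overlap={50: {"N": 0, "CA": 1, "C": 2}})
        with pytest.raises(AttachmentClashError):
            attach_rigid_body(chain, body, (50,))


class TestGrowEnsemble:
    def test_bit_identical_rerun(self, library):
        spec = SegmentSpec("ASDGKLEQRT" * 4, 1, "seg", "X")
        a = grow_ensemble(spec, library, GrowthPolicy(), 3, np.random.default_rng(9))
        b = grow_ensemble(spec, library, GrowthPolicy(), 3, np.random.default_rng(9))
        for x, y in zip(a, b):
            assert np.array_equal(x.coords, y.coords, equal_nan=True)

    def test_freely_jointed_closed_form(self):
        """Virtual-bond mode reproduces <R^2> = N b^2 within 3 standard errors."""
        n_bonds, n_samples, b = 99, 2000, 3.8
        spec = SegmentSpec("A" * (n_bonds + 1), 1, "fjc", "X")
        ens = grow_ensemble(spec, VirtualBondLibrary(b=b), GrowthPolicy(),
                            n_samples, np.random.default_rng(11))
        r2 = np.array([np.sum((m[-1] - m[0]) ** 2) for m in ens])
        expect = n_bonds * b * b
        se = r2.std(ddof=1) / np.sqrt(n_samples)
        assert abs(r2.mean() - expect) < 3 * se

    def test_excluded_volume_expands_chains(self):
        """Self-avoidance strictly increases <R^2> at N = 100 (one-sided, 99%).

        The CA-trace exclusion spans two neighbours (the virtual-bond analog
        of bonded and 1-3 exclusions); without it the acceptance of a freely
        jointed chain vanishes because next-nearest CA pairs are unbounded
        below.
        """
        model = ClashModel(cutoff=1.5, adjacency=2)
        rng = np.random.default_rng(21)
        free = fjc_chains(100, 2000, rng)
        avoid = fjc_chains(100, 2000, rng, clash_model=model)
        r2f = np.sum((free[:, -1] - free[:, 0]) ** 2, axis=1)
        r2a = np.sum((avoid[:, -1] - avoid[:, 0]) ** 2, axis=1)
        diff = r2a.mean() - r2f.mean()
        se = np.sqrt(r2a.var(ddof=1) / len(r2a) + r2f.var(ddof=1) / len(r2f))
        assert diff > 2.33 * se

    def test_invalid_n(self, library):
        spec = SegmentSpec("ASDF", 1, "seg", "X")
        with pytest.raises(ValueError):
            grow_ensemble(spec, library, GrowthPolicy(), 0, np.random.default_rng(0))
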