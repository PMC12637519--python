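"""Synthetic rigid bodies, sequences and reference systems for the pipeline.

Every stage of the tether pipeline can run without external structure files:
the scaffold core, kinase domain and HORMA dimer are idealized dummy bodies
(helix bundles, spherical shells) carrying the anchor tags and graft stubs
the preset needs.  These are explicit synthetic stand-ins for
structure-prediction models: ensemble statistics of a tethered domain depend
on anchor placement and tether length, not on fold detail, which is why a
dummy body suffices for the polymer-level questions asked here.  Also
provided: freely-jointed reference chains with a closed-form mean squared
end-to-end distance, and small toy closure problems whose exhaustive
grid-search optimum backs the CCD solver in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .ccd import AnchorTask, EffectorAtom
from .geometry import (Chain, GeometryError, RigidBody, SLOT_INDEX, Transform,
                       build_chain, rotation_about_axis)

# Residue-class composition used for the packaged synthetic IDR sequences and
# the composition-matched random generator (disorder-biased frequencies).
IDR_COMPOSITION = {
    "A": 0.070, "R": 0.050, "N": 0.040, "D": 0.060, "C": 0.005, "Q": 0.050,
    "E": 0.090, "G": 0.080, "H": 0.020, "I": 0.030, "L": 0.060, "K": 0.070,
    "M": 0.020, "F": 0.020, "P": 0.100, "S": 0.120, "T": 0.060, "W": 0.005,
    "V": 0.040, "Y": 0.020,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Which fixture to build plus its geometric parameters."""

    kind: str                     # core | kd | horma | bound_pose | toy_loop | fjc_chain
    seed: int = 0
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometric primitives

def _helix_ca(n: int, rise: float = 1.5, radius: float = 2.3,
              twist: float = 100.0) -> np.ndarray:
    """CA trace of an ideal alpha helix with its axis along +x."""
    t = np.radians(twist) * np.arange(n)
    return np.column_stack([rise * np.arange(n),
                            radius * np.cos(t), radius * np.sin(t)])


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _axis_swap_x_to_z(sign: float = 1.0) -> Transform:
    """Rotation mapping +x onto sign*z (used to stand built stubs upright)."""
    if sign > 0:
        rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]]).T
    else:
        rot = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]]).T
    return Transform(rot, np.zeros(3))


def _stub_rows(chain: Chain, mol: str) -> tuple[list[np.ndarray], list[tuple[str, int, str]]]:
    """Flatten a built stub chain into (coords, labels) for a rigid body."""
    coords, labels = [], []
    mask = chain.atom_mask()
    for i, resid in enumerate(chain.resids):
        for name, j in SLOT_INDEX.items():
            if mask[i, j]:
                coords.append(chain.coords[i, j])
                labels.append((mol, int(resid), name))
    return coords, labels


def _body(name: str, parts: list[tuple[np.ndarray, tuple[str, int, str]]],
          tags: dict[str, int], overlap_resids: tuple[int, ...] = ()) -> RigidBody:
    coords = np.array([p[0] for p in parts])
    labels = tuple(p[1] for p in parts)
    overlap: dict[int, dict[str, int]] = {}
    for i, (mol, resid, atom) in enumerate(labels):
        if resid in overlap_resids and atom in ("N", "CA", "C", "O"):
            overlap.setdefault(resid, {})[atom] = i
    return RigidBody(name, coords, labels, tags=tags, overlap=overlap)


def _extended_stub(resids: tuple[int, ...], seq: str) -> Chain:
    dih = [(-120.0, 130.0, 180.0)] * len(seq)
    return build_chain(seq, dih, resids=np.array(resids))


# ---------------------------------------------------------------------------
# rigid-body fixtures


@dataclass(frozen=True)
class CoreSpec:
    """Geometry of the dummy scaffold core (helix bundle + arm + stubs)."""

    bundle_helices: int = 4
    helix_len: int = 40
    arm_len: int = 10
    anchor_sep: float = 15.0       # A between the two sulfur anchors
    anchor_depth: float = -12.0    # local z of the membrane-facing anchors
    tether_height: float = 18.0    # local z of the ULK1-831 graft stub


def make_core_fixture(spec: CoreSpec | None = None) -> RigidBody:
    """Dummy scaffold core carrying two sulfur anchors, an elongated arm tip
    and graft stubs for the ATG13 IDR (residue 363) and the ULK1 tether
    (residue 831)."""
    spec = spec or CoreSpec()
    parts: list[tuple[np.ndarray, tuple[str, int, str]]] = []
    rid = 1
    offsets = [(-6.0, -4.5), (6.0, -4.5), (-6.0, 4.5), (6.0, 4.5)]
    for h in range(spec.bundle_helices):
        ca = _helix_ca(spec.helix_len)
        ca[:, 1] += offsets[h % 4][0]
        ca[:, 2] += offsets[h % 4][1]
        if h % 2:
            ca = ca[::-1]
        for xyz in ca:
            parts.append((xyz, ("FIP200", rid, "CA")))
            rid += 1
    # elongated arm continuing +x, sloping to the anchor plane
    x0 = spec.helix_len * 1.5
    arm_x = x0 + 3.5 * np.arange(1, spec.arm_len + 1)
    arm_z = np.linspace(-6.0, spec.anchor_depth, spec.arm_len)
    for x, z in zip(arm_x, arm_z):
        parts.append((np.array([x, 0.0, z]), ("FIP200", rid, "CA")))
        rid += 1
    tip_row = len(parts) - 1

    # membrane anchor sulfurs (EAT-domain cysteines in author numbering)
    xa = 0.35 * x0
    parts.append((np.array([xa, 2.0, spec.anchor_depth]), ("ULK1", 927, "SG")))
    sg1 = len(parts) - 1
    parts.append((np.array([xa + spec.anchor_sep, -2.0, spec.anchor_depth]),
                  ("ULK1", 1003, "SG")))
    sg2 = len(parts) - 1

    # ATG13 graft stub: overlap residue 363 plus structured continuation
    stub = _extended_stub((363, 364, 365), "AAA")
    stub.transform(Transform(np.diag([-1.0, -1.0, 1.0]), np.zeros(3)))  # point -x
    stub.transform(Transform(np.eye(3), np.array([-4.0, 8.0, 6.0])))
    c, l = _stub_rows(stub, "ATG13")
    atg_start = len(parts)
    parts += list(zip(c, l))

    # ULK1 tether stub: residue 831 on top, continuation descending into core
    tether = _extended_stub((831, 832, 833), "AAA")
    tether.transform(_axis_swap_x_to_z(-1.0))
    tether.transform(Transform(np.eye(3), np.array([30.0, 0.0, spec.tether_height])))
    c, l = _stub_rows(tether, "ULK1")
    parts += list(zip(c, l))

    tags = {"C927:SG": sg1, "C1003:SG": sg2, "FIP200_tip": tip_row}
    body = _body("core", parts, tags, overlap_resids=(363,))
    return body


@dataclass(frozen=True)
class KdSpec:
    """Geometry of the dummy kinase domain (shell + C-terminal graft stub).

    ``overlap_resid`` is the single residue shared with the host IDR chain
    (283 for the full-length preset; movable for tether-length experiments).
    """

    radius: float = 16.0
    n_shell: int = 140
    overlap_resid: int = 283


def make_kd_fixture(spec: KdSpec | None = None) -> RigidBody:
    """Dummy globular kinase domain grafted onto the IDR by its single
    overlap residue at the tip of a short rigid tail (the kinase-domain
    C-terminal residues, author numbering 277-283 by default)."""
    spec = spec or KdSpec()
    parts = []
    shell = _fibonacci_sphere(spec.n_shell, spec.radius)
    ov = spec.overlap_resid
    tail_range = set(range(ov - 6, ov + 1))
    rid = 1
    for xyz in shell:
        while rid in tail_range:
            rid += 1        # keep shell labels distinct from the tail residues
        parts.append((xyz, ("ULK1", rid, "CA")))
        rid += 1
    tail = _extended_stub(tuple(range(ov - 6, ov + 1)), "AAAAAAA")
    tail.transform(Transform(np.eye(3), np.array([spec.radius + 1.5, 0.0, 0.0])))
    c, l = _stub_rows(tail, "ULK1")
    parts += list(zip(c, l))
    parts.append((np.zeros(3), ("ULK1", 0, "XX")))   # virtual centre marker
    tags = {"KD_center": len(parts) - 1}
    return _body("KD", parts, tags, overlap_resids=(ov,))


@dataclass(frozen=True)
class HormaSpec:
    """Geometry of the dummy HORMA dimer and the bound-peptide pose.

    The dimer does not touch the bilayer directly: in the membrane-bound
    scaffold complex it rides on a layer of membrane-inserted WIPI
    beta-propellers, modeled here as a rigid ``pedestal`` stand-off (~ one
    propeller height) between the headgroup plane and the dimer body.
    """

    radius: float = 14.0
    n_shell: int = 120
    pedestal: float = 30.0                 # A, WIPI-layer stand-off
    site_offset: float = 7.0               # A from shell surface to pose

    @property
    def center(self) -> tuple:
        return (0.0, 0.0, self.pedestal + self.radius)


def make_bound_pose_fixture(spec: HormaSpec | None = None,
                            pose_sequence: str | None = None
                            ) -> tuple[RigidBody, RigidBody]:
    """Dummy HORMA dimer plus the ULK1 428-450 bound-peptide pose in its frame.

    The HORMA body carries the ATG13-IDR graft stub (residues 228-230, the
    chain anchor) and a virtual binding-site centroid tag ``HD_site``; the
    pose is a rigid 23-residue backbone segment (author numbering 428-450)
    draped next to the site, with overlap maps on residues 428 (resampling
    anchor) and 450 (truncation junction).
    """
    spec = spec or HormaSpec()
    center = np.asarray(spec.center, dtype=float)
    parts = []
    shell = _fibonacci_sphere(spec.n_shell, spec.radius) + center
    for i, xyz in enumerate(shell):
        parts.append((xyz, ("ATG13", 1 + i, "CA")))
    # IDR anchor stub standing on top of the dimer
    stub = _extended_stub((228, 229, 230), "AAA")
    stub.transform(_axis_swap_x_to_z(1.0))
    stub.transform(Transform(np.eye(3), center + np.array([0.0, 0.0, spec.radius - 2.0])))
    c, l = _stub_rows(stub, "ATG13")
    parts += list(zip(c, l))
    site = center + np.array([spec.radius + spec.site_offset, 0.0, 0.0])
    parts.append((site, ("ATG13", 0, "XX")))
    tags = {"HD_site": len(parts) - 1}
    horma = _body("HORMA", parts, tags)

    if pose_sequence is None:
        pose_sequence = idr_sequences()["ulk1_277_831"][428 - 277:451 - 277]
    if len(pose_sequence) != 23:
        raise GeometryError("bound pose covers residues 428-450 (23 residues)")
    # compact hairpin drape (strand - tight turn - strand) from fixed dihedrals
    dih = []
    for i in range(23):
        if 10 <= i <= 13:
            dih.append((-60.0, -40.0, 180.0))
        else:
            dih.append((-125.0, 135.0, 180.0))
    pose_chain = build_chain(pose_sequence, dih, resids=np.arange(428, 451))
    # orient the hairpin's long axis along y, tangential to the dimer surface
    ca = pose_chain.coords[:, SLOT_INDEX["CA"]]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(axis, ref)
    s = np.linalg.norm(v)
    if s > 1e-9:
        ang = math.degrees(math.atan2(s, float(np.dot(axis, ref))))
        pose_chain.transform(rotation_about_axis(np.zeros(3), v, ang))
    com = pose_chain.flat_coords().mean(axis=0)
    pose_chain.transform(Transform(np.eye(3), site - com))
    # push the drape radially outward until it clears the shell
    radial = (site - center) / np.linalg.norm(site - center)
    for _ in range(40):
        d = np.linalg.norm(pose_chain.flat_coords() - center, axis=1)
        if d.min() > spec.radius + 3.0:
            break
        pose_chain.transform(Transform(np.eye(3), 1.0 * radial))
    c, l = _stub_rows(pose_chain, "ULK1")
    pose = _body("bound_pose", list(zip(c, l)), {}, overlap_resids=(428, 450))
    return horma, pose


def make_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to the matching builder (CLI convenience)."""
    if spec.kind == "core":
        return make_core_fixture(CoreSpec(**spec.params))
    if spec.kind == "kd":
        return make_kd_fixture(KdSpec(**spec.params))
    if spec.kind in ("horma", "bound_pose"):
        return make_bound_pose_fixture(HormaSpec(**spec.params))
    if spec.kind == "toy_loop":
        return make_toy_loop(seed=spec.seed, **spec.params)
    if spec.kind == "fjc_chain":
        rng = np.random.default_rng(spec.seed)
        return fjc_chains(rng=rng, **spec.params)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# polymer reference systems


def fjc_chains(n_res: int, n_samples: int, rng: np.random.Generator,
               b: float = 3.8, clash_model=None) -> np.ndarray:
    """Freely-jointed CA-only chains: (n_samples, n_res, 3) positions.

    Bond directions are uniform on the sphere with fixed length ``b``, so
    the mean squared end-to-end distance is exactly (n_res - 1) * b**2.
    With ``clash_model`` set, chains containing any non-adjacent CA pair
    closer than the cutoff are rejected (self-avoiding variant).
    """
    if n_res < 2 or n_samples < 1:
        raise ValueError("need n_res >= 2 and n_samples >= 1")
    out = np.empty((n_samples, n_res, 3))
    have = 0
    ij_far = None
    while have < n_samples:
        batch = max(n_samples - have, 16) if clash_model is None else 1024
        v = rng.standard_normal((batch, n_res - 1, 3))
        v /= np.linalg.norm(v, axis=2, keepdims=True)
        pos = np.concatenate([np.zeros((batch, 1, 3)), np.cumsum(b * v, axis=1)], axis=1)
        if clash_model is None:
            take = pos[:n_samples - have]
        else:
            if ij_far is None:
                idx = np.arange(n_res)
                sep = np.abs(idx[:, None] - idx[None, :])
                ij_far = sep > clash_model.adjacency
            cut2 = clash_model.cutoff ** 2
            # stage 1: short-range contacts dominate rejection and are cheap
            survivors = np.ones(len(pos), dtype=bool)
            for off in range(clash_model.adjacency + 1, min(clash_model.adjacency + 11, n_res)):
                d2o = np.sum((pos[:, off:] - pos[:, :-off]) ** 2, axis=2)
                survivors &= np.all(d2o > cut2, axis=1)
            pos = pos[survivors]
            if len(pos) == 0:
                continue
            # stage 2: full pairwise check via the Gram matrix (memory-lean)
            g = pos @ pos.transpose(0, 2, 1)
            sq = np.einsum("bii->bi", g)
            d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * g
            ok = np.all(d2[:, ij_far] > cut2, axis=1)
            take = pos[ok][:n_samples - have]
            if len(take) == 0:
                continue
        out[have:have + len(take)] = take
        have += len(take)
    return out


# ---------------------------------------------------------------------------
# toy closure problems with an exhaustive grid oracle


def _grid_optimum(chain: Chain, rotatable: list[tuple[int, str]],
                  effector: tuple[int, str], target: np.ndarray,
                  step: float = 5.0) -> float:
    """Exhaustive grid search over the rotatable dihedrals (oracle).

    Rotations about the original hinge axes are composed outermost (N-most)
    last, which reproduces forward kinematics exactly for a point effector.
    """
    order = sorted(rotatable, key=lambda rk: (chain.pos(rk[0]), 0 if rk[1] == "phi" else 1))
    angles = np.arange(0.0, 360.0, step)
    p = chain.atom(*effector).copy()[None, :]
    for resid, kind in reversed(order):
        i = chain.pos(resid)
        if kind == "phi":
            a = chain.coords[i, SLOT_INDEX["N"]]
            bx = chain.coords[i, SLOT_INDEX["CA"]]
        else:
            a = chain.coords[i, SLOT_INDEX["CA"]]
            bx = chain.coords[i, SLOT_INDEX["C"]]
        rots, ts = [], []
        for ang in angles:
            tr = rotation_about_axis(a, bx - a, float(ang))
            rots.append(tr.rotation)
            ts.append(tr.translation)
        rots = np.array(rots)
        ts = np.array(ts)
        p = (np.einsum("aij,nj->ani", rots, p) + ts[:, None, :]).reshape(-1, 3)
    return float(np.min(np.linalg.norm(p - target, axis=1)))


def make_toy_loop(n_res: int = 3, target: np.ndarray | None = None,
                  seed: int = 0, step: float = 5.0
                  ) -> tuple[Chain, AnchorTask, float]:
    """Small closure problem: chain, point-target task and its grid optimum.

    At most three dihedrals are declared rotatable so the 5-degree grid
    stays exhaustively enumerable; the CCD solver is restricted to the same
    set when checked against the oracle.
    """
    if not 2 <= n_res <= 6:
        raise ValueError("toy loops support 2-6 residues")
    rng = np.random.default_rng(seed)
    dih = np.column_stack([rng.uniform(-150, -50, n_res),
                           rng.uniform(100, 160, n_res),
                           np.full(n_res, 180.0)])
    chain = build_chain("A" * n_res, dih, segment_id="toy", molecule="toy")
    chain.anchored_end = "N"
    rotatable = [(1, "psi"), (2, "phi")]
    if n_res >= 3:
        rotatable.append((2, "psi"))
    last = int(chain.resids[-1])
    effector = (last, "C")
    if target is None:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        target = chain.atom(*effector) + 2.5 * direction
    target = np.asarray(target, dtype=float)
    task = AnchorTask("point", (EffectorAtom("chain", last, "C"),),
                      target[None, :])
    opt = _grid_optimum(chain, rotatable, effector, target, step=step)
    return chain, task, opt


def toy_rotatable(n_res: int) -> list[tuple[int, str]]:
    """Rotatable dihedral set used by toy loops of a given size."""
    base = [(1, "psi"), (2, "phi")]
    if n_res >= 3:
        base.append((2, "psi"))
    return base


# ---------------------------------------------------------------------------
# sequences


def idr_sequences() -> dict[str, str]:
    """Packaged synthetic IDR sequences over the modeled author ranges.

    These are composition-matched random stand-ins, not database sequences
    (see the FASTA headers); the ULK1 positions 433-435 carry the P-V-P
    binding motif.  Keys: ``atg13_230_363``-> 134 aa, ``ulk1_277_831`` ->
    555 aa.
    """
    text = resources.files("ulktether.data").joinpath(
        "idr_sequences_synthetic.fasta").read_text()
    seqs: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    return {"atg13_230_363": seqs["atg13_idr_230_363"],
            "ulk1_277_831": seqs["ulk1_idr_277_831"]}


def random_idr_sequence(length: int, rng: np.random.Generator) -> str:
    """Composition-matched random sequence (same residue frequencies as the
    packaged synthetic IDRs)."""
    aas = list(IDR_COMPOSITION)
    p = np.array([IDR_COMPOSITION[a] for a in aas])
    p = p / p.sum()
    return "".join(rng.choice(aas, size=length, p=p))
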