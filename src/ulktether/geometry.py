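"""Backbone geometry: internal/Cartesian conversion, superposition, hinge rotations.

The disordered segments are represented as kinematic chains of backbone
residues (N, CA, C, O and a pseudo-CB) whose phi/psi dihedrals are the only
degrees of freedom; bond lengths and angles are fixed at ideal values.
Rigid domains (kinase domain, HORMA dimer, scaffold core) are immutable atom
sets grafted onto chains by superposition and carried along by downstream
hinge rotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

# Ideal backbone geometry (Engh-Huber-like constants, Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521

ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
# Torsion CB-CA-N-C fixing L-chirality of the pseudo-CB.
TORSION_CB_CA_N_C = -122.6

# Atom slot layout for chain residues.
ATOM_SLOTS = ("N", "CA", "C", "O", "CB")
SLOT_INDEX = {name: i for i, name in enumerate(ATOM_SLOTS)}
N_SLOTS = len(ATOM_SLOTS)

# Mean CA-CA virtual bond length for trans peptides.
CA_CA_VIRTUAL = 3.8


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear sets, broken chains...)."""


class ChainDiscontinuityError(GeometryError):
    """Raised when consecutive residues are not peptide-bonded (C-N gap > tolerance)."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length vector in frame construction")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to C given internal coordinates (NeRF construction).

    ``bond`` is |C-D|, ``angle_deg`` the D-C-B angle and ``torsion_deg`` the
    D-C-B-A dihedral.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    dx = -bond * math.cos(ang)
    dy = bond * math.sin(ang) * math.cos(tor)
    dz = bond * math.sin(ang) * math.sin(tor)
    # scalar frame construction (hot path: called three times per residue)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    if nb < 1e-12:
        raise GeometryError("zero-length vector in frame construction")
    bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-12:
        raise GeometryError("collinear reference atoms in frame construction")
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    return np.array([c[0] + bcx * dx + mx * dy + nx * dz,
                     c[1] + bcy * dx + my * dy + ny * dz,
                     c[2] + bcz * dx + mz * dy + nz * dz])


def _place_atoms_batch(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                       bond: float, angle_deg: float,
                       torsion_deg: np.ndarray) -> np.ndarray:
    """Vectorized NeRF placement: one new atom per (a, b, c) reference triple."""
    ang = math.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.column_stack([np.full(len(tor), -bond * math.cos(ang)),
                               bond * math.sin(ang) * np.cos(tor),
                               bond * math.sin(ang) * np.sin(tor)])
    bc = c - b
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    return (c + bc * d_local[:, :1] + m * d_local[:, 1:2] + n * d_local[:, 2:3])


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -np.mod(-a + 180.0, 360.0) + 180.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Transform:
    """Proper rigid transform x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("Transform needs a 3x3 rotation and 3-vector")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise GeometryError("rotation is improper (det < 0)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)


def _fast_transform(rotation: np.ndarray, translation: np.ndarray) -> Transform:
    """Construct a Transform without invariant checks (trusted internal paths)."""
    tr = object.__new__(Transform)
    object.__setattr__(tr, "rotation", rotation)
    object.__setattr__(tr, "translation", translation)
    return tr


def rotation_about_axis(point: np.ndarray, axis: np.ndarray, angle_deg: float) -> Transform:
    """Rigid rotation by ``angle_deg`` about the line through ``point`` along ``axis``."""
    u = _unit(np.asarray(axis, dtype=float))
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    ux, uy, uz = u
    k = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    rot = np.eye(3) * c + s * k + (1 - c) * np.outer(u, u)
    point = np.asarray(point, dtype=float)
    return _fast_transform(rot, point - rot @ point)


def superpose(mobile: np.ndarray, reference: np.ndarray,
              allow_collinear: bool = False) -> tuple[Transform, float]:
    """Least-squares rigid superposition of paired points (Kabsch).

    Returns the proper rigid transform minimizing the RMSD of
    ``transform.apply(mobile)`` to ``reference``, and that minimal RMSD.

    Raises
    ------
    GeometryError
        For fewer than 3 points or (near-)collinear point sets, where the
        rotation is underdetermined, unless ``allow_collinear``.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise GeometryError("superpose needs matching (n, 3) arrays")
    if len(mob) < 3:
        raise GeometryError("superpose needs at least 3 paired points")
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mob - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    # Collinear/degenerate sets leave the rotation about the principal axis free.
    scale = max(np.linalg.norm(mob - mc, axis=1).max(),
                np.linalg.norm(ref - rc, axis=1).max(), 1e-12)
    if not allow_collinear and s[1] < 1e-8 * scale * scale:
        raise GeometryError("superpose underdetermined: points are collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = rc - rot @ mc
    tr = _fast_transform(rot, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(mob) - ref) ** 2, axis=1))))
    return tr, rmsd


@dataclass(frozen=True)
class MembranePlane:
    """Horizontal membrane headgroup plane; the allowed half-space is z > z0 (A)."""

    z0: float = 0.0

    def height(self, coords: np.ndarray) -> np.ndarray:
        """Signed height z - z0 per atom; positive inside the allowed half-space."""
        coords = np.asarray(coords, dtype=float)
        return coords[..., 2] - self.z0

    def all_above(self, coords: np.ndarray) -> bool:
        if len(coords) == 0:
            return True
        return bool(np.min(self.height(coords)) > 0.0)


def height_above_plane(atom: np.ndarray, plane: MembranePlane) -> float:
    """Signed height of one atom over the headgroup plane (A)."""
    return float(np.asarray(atom, dtype=float)[2] - plane.z0)


@dataclass(frozen=True)
class RigidBody:
    """Immutable labeled atom set placed only by proper rigid transforms.

    ``labels`` holds one (molecule, residue index, atom name) triple per row of
    ``coords``; ``tags`` names special rows (anchor sulfurs, arm tips, site
    centroids); ``overlap`` maps residue index -> {atom name -> row} for the
    residues shared with a host chain and used for grafting.
    """

    name: str
    coords: np.ndarray
    labels: tuple[tuple[str, int, str], ...]
    tags: dict[str, int] = field(default_factory=dict)
    overlap: dict[int, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        c = np.ascontiguousarray(np.asarray(self.coords, dtype=float))
        c.setflags(write=False)
        object.__setattr__(self, "coords", c)
        if len(self.labels) != len(c):
            raise GeometryError("labels and coords length mismatch")
        for tag, row in self.tags.items():
            if not 0 <= row < len(c):
                raise GeometryError(f"tag {tag!r} row out of range")

    def transformed(self, tr: Transform) -> "RigidBody":
        return replace(self, coords=tr.apply(self.coords))

    def tag_coord(self, tag: str) -> np.ndarray:
        return self.coords[self.tags[tag]]

    def overlap_coords(self, resids: Sequence[int] | None = None,
                       atoms: Sequence[str] = ("N", "CA", "C")) -> np.ndarray:
        """Backbone coordinates of the overlap residues, in resid/atom order."""
        resids = sorted(self.overlap) if resids is None else list(resids)
        rows = []
        for r in resids:
            have = self.overlap[r]
            for a in atoms:
                if a in have:
                    rows.append(have[a])
        return self.coords[rows]

    def residue_coords(self, resid: int, atoms: Sequence[str] = ("N", "CA", "C"),
                       mol: str | None = None) -> np.ndarray:
        """Coordinates of named atoms of one labeled residue (in atom order)."""
        rows = []
        for a in atoms:
            for i, (m, r, nm) in enumerate(self.labels):
                if r == resid and nm == a and (mol is None or m == mol):
                    rows.append(i)
                    break
            else:
                raise GeometryError(f"body {self.name!r}: atom {a} of residue {resid} absent")
        return self.coords[rows]

    def mol_resid_arrays(self) -> tuple[list[str], np.ndarray]:
        mols = [l[0] for l in self.labels]
        resids = np.array([l[1] for l in self.labels], dtype=int)
        return mols, resids


@dataclass
class Attachment:
    """A rigid body grafted onto a chain; moves with the overlap residues."""

    body: RigidBody
    overlap_resids: tuple[int, ...]
    rmsd: float


@dataclass(frozen=True)
class BackboneResidue:
    """Read-only per-residue view used at API edges (hot paths use arrays)."""

    index: int
    aa: str
    atoms: dict[str, np.ndarray]
    phi: float | None
    psi: float | None
    omega: float | None


class Chain:
    """An ordered backbone segment with hinge (phi/psi) degrees of freedom.

    Coordinates are stored as an (n_res, 5, 3) array over the slots
    N, CA, C, O, CB (CB rows are NaN for glycine).  ``anchored_end`` marks
    which terminus is held fixed in the world frame; hinge rotations move the
    opposite side.  Residue indices follow author/UniProt numbering and are
    never renumbered on truncation.
    """

    def __init__(self, resids: np.ndarray, seq: str, coords: np.ndarray,
                 segment_id: str = "", molecule: str = "",
                 anchored_end: str | None = None,
                 attachments: list[Attachment] | None = None):
        self.resids = np.asarray(resids, dtype=int)
        self.seq = seq
        self.coords = np.asarray(coords, dtype=float)
        self.segment_id = segment_id
        self.molecule = molecule or segment_id
        self.anchored_end = anchored_end
        self.attachments: list[Attachment] = attachments or []
        if len(self.resids) != len(seq) or self.coords.shape != (len(seq), N_SLOTS, 3):
            raise GeometryError("inconsistent chain arrays")
        if len(self.resids) > 1 and not np.all(np.diff(self.resids) > 0):
            raise GeometryError("residue indices must be strictly increasing")

    # -- basic introspection ------------------------------------------------

    def __len__(self) -> int:
        return len(self.resids)

    def pos(self, resid: int) -> int:
        i = int(np.searchsorted(self.resids, resid))
        if i >= len(self.resids) or self.resids[i] != resid:
            raise KeyError(f"residue {resid} not in chain {self.segment_id!r}")
        return i

    def atom(self, resid: int, name: str) -> np.ndarray:
        return self.coords[self.pos(resid), SLOT_INDEX[name]]

    def backbone(self, resid: int, atoms: Sequence[str] = ("N", "CA", "C")) -> np.ndarray:
        i = self.pos(resid)
        return self.coords[i, [SLOT_INDEX[a] for a in atoms]]

    def atom_mask(self) -> np.ndarray:
        """(n, 5) mask of slots that exist (CB absent for Gly)."""
        mask = np.ones((len(self), N_SLOTS), dtype=bool)
        mask[:, SLOT_INDEX["CB"]] = np.array([aa != "G" for aa in self.seq])
        return mask

    def flat_coords(self, include_attachments: bool = True) -> np.ndarray:
        """All existing atom coordinates, chain atoms first then attachments."""
        parts = [self.coords[self.atom_mask()]]
        if include_attachments:
            parts += [a.body.coords for a in self.attachments]
        return np.concatenate(parts, axis=0) if len(parts) > 1 else parts[0]

    def residue(self, resid: int) -> BackboneResidue:
        i = self.pos(resid)
        phis, psis, omegas = self.measure_dihedrals()
        atoms = {}
        for name, j in SLOT_INDEX.items():
            xyz = self.coords[i, j]
            if np.all(np.isfinite(xyz)):
                atoms[name] = xyz.copy()
        def _opt(arr):
            v = arr[i]
            return None if not np.isfinite(v) else float(v)
        return BackboneResidue(int(self.resids[i]), self.seq[i], atoms,
                               _opt(phis), _opt(psis), _opt(omegas))

    def copy(self) -> "Chain":
        c = Chain(self.resids.copy(), self.seq, self.coords.copy(),
                  self.segment_id, self.molecule, self.anchored_end,
                  [Attachment(a.body, a.overlap_resids, a.rmsd) for a in self.attachments])
        return c

    # -- dihedrals ----------------------------------------------------------

    def check_contiguous(self, tol: float = 2.0) -> None:
        """Raise ChainDiscontinuityError on any C(i)-N(i+1) gap above ``tol`` A."""
        if len(self) < 2:
            return
        c = self.coords[:-1, SLOT_INDEX["C"]]
        n = self.coords[1:, SLOT_INDEX["N"]]
        gaps = np.linalg.norm(c - n, axis=1)
        bad = np.nonzero(gaps > tol)[0]
        if len(bad):
            r = int(self.resids[bad[0]])
            raise ChainDiscontinuityError(
                f"chain {self.segment_id!r}: peptide bond {r}->{r + 1} broken "
                f"(C-N distance {gaps[bad[0]]:.2f} A)")

    def measure_dihedrals(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-residue (phi, psi, omega) in degrees; NaN where undefined."""
        if len(self) < 2:
            n = len(self)
            nanrow = np.full(n, np.nan)
            return nanrow, nanrow.copy(), nanrow.copy()
        self.check_contiguous()
        n = len(self)
        N = self.coords[:, SLOT_INDEX["N"]]
        CA = self.coords[:, SLOT_INDEX["CA"]]
        C = self.coords[:, SLOT_INDEX["C"]]
        phi = np.full(n, np.nan)
        psi = np.full(n, np.nan)
        omega = np.full(n, np.nan)
        for i in range(n):
            if i > 0:
                phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
                omega[i] = dihedral(CA[i - 1], C[i - 1], N[i], CA[i])
            if i < n - 1:
                psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
        return phi, psi, omega

    # -- kinematics ---------------------------------------------------------

    def movement_keys(self) -> np.ndarray:
        """Per-slot scalar key ordering atoms along the chain for hinge masks.

        For a hinge at residue i: with the N side anchored, a phi rotation
        moves keys > 4i (CB, C, O and everything C-ward) and a psi rotation
        moves keys > 4i + 1 (O and everything C-ward); with the C side
        anchored, phi moves keys < 4i and psi moves keys < 4i + 2.
        """
        pos = np.arange(len(self))
        keys = np.empty((len(self), N_SLOTS), dtype=np.int64)
        keys[:, SLOT_INDEX["N"]] = 4 * pos
        keys[:, SLOT_INDEX["CA"]] = 4 * pos
        keys[:, SLOT_INDEX["CB"]] = 4 * pos + 1
        keys[:, SLOT_INDEX["C"]] = 4 * pos + 1
        keys[:, SLOT_INDEX["O"]] = 4 * pos + 2
        return keys

    def _hinge(self, resid: int, kind: str) -> tuple[np.ndarray, np.ndarray, int]:
        """Axis (point, direction) and hinge position for a phi/psi rotation."""
        i = self.pos(resid)
        if kind == "phi":
            if i == 0 and self.anchored_end != "C":
                raise GeometryError("phi undefined for the first residue")
            a = self.coords[i, SLOT_INDEX["N"]]
            b = self.coords[i, SLOT_INDEX["CA"]]
        elif kind == "psi":
            a = self.coords[i, SLOT_INDEX["CA"]]
            b = self.coords[i, SLOT_INDEX["C"]]
        else:
            raise GeometryError(f"unknown dihedral kind {kind!r}")
        return a, b - a, i

    def moved_mask(self, resid: int, kind: str, keys: np.ndarray | None = None) -> np.ndarray:
        """(n, 5) mask of chain atoms moved by the hinge, given anchored_end."""
        keys = self.movement_keys() if keys is None else keys
        i = self.pos(resid)
        if self.anchored_end == "C":
            thr = 4 * i if kind == "phi" else 4 * i + 2
            return keys < thr
        thr = 4 * i if kind == "phi" else 4 * i + 1
        return keys > thr

    def attachment_moves(self, resid: int, kind: str) -> list[bool]:
        """Whether each attachment moves with the hinge at ``resid``/``kind``."""
        # Side rule: the body sits on the far side of its overlap range, and
        # hinges inside the overlap are never rotated (excluded upstream).
        out = []
        for a in self.attachments:
            lo, hi = min(a.overlap_resids), max(a.overlap_resids)
            if self.anchored_end == "C":
                out.append(hi < resid)
            else:
                out.append(lo > resid)
        return out

    def rotate_dihedral(self, resid: int, kind: str, delta_deg: float) -> None:
        """Rotate the mobile side of the chain about a phi/psi hinge, in place.

        Bond lengths and angles are exactly preserved (pure rigid rotation of
        the moved atom set, including attachments on the moved side).
        """
        if not np.isfinite(delta_deg):
            raise GeometryError("non-finite rotation angle")
        point, axis, _ = self._hinge(resid, kind)
        sign = 1.0 if self.anchored_end != "C" else -1.0
        tr = rotation_about_axis(point, axis, sign * delta_deg)
        mask = self.moved_mask(resid, kind)
        if mask.any():
            flat = self.coords.reshape(-1, 3)
            m = mask.reshape(-1)
            flat[m] = tr.apply(flat[m])
        for moves, att in zip(self.attachment_moves(resid, kind), self.attachments):
            if moves:
                att.body = att.body.transformed(tr)

    def transform(self, tr: Transform) -> None:
        """Rigidly move the whole chain (and attachments), in place."""
        self.coords = tr.apply(self.coords.reshape(-1, 3)).reshape(self.coords.shape)
        for att in self.attachments:
            att.body = att.body.transformed(tr)


def build_chain(sequence: str,
                dihedrals: Sequence[tuple[float, float, float]] | np.ndarray,
                start_frame: Transform | None = None,
                resids: Sequence[int] | None = None,
                segment_id: str = "", molecule: str = "") -> Chain:
    """Build a backbone chain from per-residue (phi, psi, omega) in degrees.

    phi of the first residue is ignored (undefined); omega applies to the
    peptide bond preceding each residue and defaults to 180 (trans) if NaN.
    The first residue's N sits at the origin of ``start_frame``.
    """
    n = len(sequence)
    dih = np.asarray(dihedrals, dtype=float)
    if dih.shape != (n, 3):
        raise GeometryError(f"need {n} (phi, psi, omega) rows, got {dih.shape}")
    if not np.all(np.isfinite(dih[:, 1])) or not np.all(np.isfinite(dih[1:, 0])):
        raise GeometryError("non-finite phi/psi angles")
    omega = np.where(np.isfinite(dih[:, 2]), dih[:, 2], 180.0)
    resids = np.arange(1, n + 1) if resids is None else np.asarray(resids, dtype=int)

    coords = np.full((n, N_SLOTS, 3), np.nan)
    iN, iCA, iC, iO, iCB = (SLOT_INDEX[a] for a in ATOM_SLOTS)
    # First residue in the local frame.
    coords[0, iN] = [0.0, 0.0, 0.0]
    coords[0, iCA] = [BOND_N_CA, 0.0, 0.0]
    ang = math.radians(ANGLE_N_CA_C)
    coords[0, iC] = coords[0, iCA] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        psi_prev = dih[i - 1, 1]
        coords[i, iN] = place_atom(coords[i - 1, iN], coords[i - 1, iCA], coords[i - 1, iC],
                                   BOND_C_N, ANGLE_CA_C_N, psi_prev)
        coords[i, iCA] = place_atom(coords[i - 1, iCA], coords[i - 1, iC], coords[i, iN],
                                    BOND_N_CA, ANGLE_C_N_CA, omega[i])
        coords[i, iC] = place_atom(coords[i - 1, iC], coords[i, iN], coords[i, iCA],
                                   BOND_CA_C, ANGLE_N_CA_C, dih[i, 0])
    # Carbonyl O anti to the next N (torsion psi + 180); pseudo-CB with L-chirality.
    coords[:, iO] = _place_atoms_batch(coords[:, iN], coords[:, iCA], coords[:, iC],
                                       BOND_C_O, ANGLE_CA_C_O, dih[:, 1] + 180.0)
    not_gly = np.array([aa != "G" for aa in sequence])
    if not_gly.any():
        coords[not_gly, iCB] = _place_atoms_batch(
            coords[not_gly, iC], coords[not_gly, iN], coords[not_gly, iCA],
            BOND_CA_CB, ANGLE_N_CA_CB, np.full(int(not_gly.sum()), TORSION_CB_CA_N_C))
    chain = Chain(resids, sequence, coords, segment_id=segment_id, molecule=molecule)
    if start_frame is not None:
        chain.transform(start_frame)
    return chain
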