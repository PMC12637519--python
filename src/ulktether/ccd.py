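"""Stochastic cyclic-coordinate-descent refinement of kinematic chains.

Moves draw a random rotatable residue and a phi/psi kind, rotate the mobile
side of the chain by a small Gaussian angle (sigma defaults to 1 degree),
and are accepted only when the effector objective strictly decreases and no
protein-protein clashes are created.  The membrane is deliberately not part
of the clash test during minimization; only the plane-distance objective
sees it.  Three anchor flavours are supported: point targets, the membrane
headgroup plane (RMS of per-atom |z - z0|), and fixed-frame coordinate
alignment (RMSD without re-superposition) used to close truncation
junctions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .clash import ClashModel, ClashView, view_of_body, view_of_chain
from .geometry import (Chain, GeometryError, MembranePlane, SLOT_INDEX,
                       rotation_about_axis)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CCDParams:
    """Move size, caps and convergence tolerances of the CCD refinement."""

    sigma: float = 1.0               # degrees, Gaussian move width
    max_moves: int = 200_000
    anchor_tolerance: float = 5.0    # A, per-atom plane criterion
    align_threshold: float = 0.6     # A, junction alignment RMSD
    point_tolerance: float = 0.1     # A, point-target convergence
    stall_patience: int = 10_000     # attempts without an accepted move
    progress_epsilon: float = 0.1    # A, min objective gain per patience window
    log_every: int = 10_000

    def __post_init__(self):
        if self.sigma <= 0 or self.anchor_tolerance <= 0 or self.align_threshold <= 0:
            raise ValueError("sigma and tolerances must be positive")


@dataclass(frozen=True)
class EffectorAtom:
    """Reference to a labeled atom on the chain or on an attached rigid body."""

    kind: str                 # "chain" | "body"
    resid: int = 0
    atom: str = "CA"
    body: str = ""            # body name for kind="body"
    tag: str = ""             # tag on that body, e.g. "C927:SG"


@dataclass(frozen=True)
class AnchorTask:
    """Effector atoms plus a point / plane / alignment target."""

    kind: str                                  # "point" | "plane" | "alignment"
    effectors: tuple[EffectorAtom, ...]
    target: object                             # (k,3) array or MembranePlane

    def __post_init__(self):
        if self.kind not in ("point", "plane", "alignment"):
            raise ValueError(f"unknown anchor kind {self.kind!r}")
        if len(self.effectors) < 1:
            raise ValueError("need at least one effector")
        if self.kind == "plane":
            if not isinstance(self.target, MembranePlane):
                raise ValueError("plane task needs a MembranePlane target")
        else:
            t = np.asarray(self.target, dtype=float)
            if t.shape != (len(self.effectors), 3):
                raise ValueError("target must pair one point per effector")


@dataclass
class CCDResult:
    """Outcome of a minimization run; the objective trace is non-increasing."""

    chain: Chain
    converged: bool
    moves_attempted: int
    moves_accepted: int
    trace: list[float]
    final_objective: float

    def to_report(self) -> dict:
        return {"converged": self.converged,
                "moves_attempted": self.moves_attempted,
                "moves_accepted": self.moves_accepted,
                "acceptance_ratio": (self.moves_accepted / self.moves_attempted
                                     if self.moves_attempted else 0.0),
                "final_objective": self.final_objective}

    def to_json(self) -> str:
        return json.dumps(self.to_report())


def alignment_close(chain_overlap: np.ndarray, reference_overlap: np.ndarray,
                    threshold: float = 0.6) -> bool:
    """True iff the fixed-frame RMSD of paired coordinates is below threshold."""
    a = np.asarray(chain_overlap, dtype=float)
    b = np.asarray(reference_overlap, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError("alignment_close needs matching (n, 3) coordinate sets")
    rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    return rmsd < threshold


class _Kinematics:
    """Flat mutable view of a chain plus attachments for fast CCD moves."""

    def __init__(self, chain: Chain, model: ClashModel,
                 env_view: ClashView | None = None,
                 rotatable: Sequence[tuple[int, str]] | None = None):
        self.chain = chain
        self.model = model
        mask = chain.atom_mask()
        self.slot_mask = mask
        n_chain = int(mask.sum())
        rows_per_res = mask.sum(axis=1)
        coords = [chain.coords[mask]]
        mol = [np.full(n_chain, chain.molecule, dtype="<U24")]
        resid = [np.repeat(chain.resids, rows_per_res)]
        body = [np.full(n_chain, "", dtype="<U24")]
        # forward/reverse movement keys (see Chain.movement_keys)
        ckeys = chain.movement_keys()
        rkeys = np.empty_like(ckeys)
        pos = np.arange(len(chain))
        rkeys[:, SLOT_INDEX["N"]] = 4 * pos + 1
        rkeys[:, SLOT_INDEX["CB"]] = 4 * pos + 1
        rkeys[:, SLOT_INDEX["CA"]] = 4 * pos + 3
        rkeys[:, SLOT_INDEX["C"]] = 4 * pos + 3
        rkeys[:, SLOT_INDEX["O"]] = 4 * pos + 3
        fwd = [ckeys[mask]]
        rev = [rkeys[mask]]
        self.att_slices = []
        off = n_chain
        for att in chain.attachments:
            b = att.body
            bmol, bres = b.mol_resid_arrays()
            m = len(b.coords)
            coords.append(np.asarray(b.coords))
            mol.append(np.array(bmol, dtype="<U24"))
            resid.append(bres)
            body.append(np.full(m, b.name, dtype="<U24"))
            lo = chain.pos(min(att.overlap_resids))
            hi = chain.pos(max(att.overlap_resids))
            fwd.append(np.full(m, 4 * lo, dtype=np.int64))
            rev.append(np.full(m, 4 * hi + 3, dtype=np.int64))
            self.att_slices.append((att, slice(off, off + m)))
            off += m
        self.coords = np.concatenate(coords, axis=0)
        self.mol = np.concatenate(mol)
        self.resid = np.concatenate(resid)
        self.body = np.concatenate(body)
        self.fwd = np.concatenate(fwd)
        self.rev = np.concatenate(rev)
        # map chain (res, slot) -> flat row
        self.row_of = np.full(mask.shape, -1, dtype=int)
        self.row_of[mask] = np.arange(n_chain)
        self.env = env_view
        self.env_tree = cKDTree(env_view.coords) if env_view is not None and len(env_view) else None

        overlap_res = set()
        for att in chain.attachments:
            overlap_res.update(att.overlap_resids)
        self.rotatable: list[tuple[int, str]] = []
        if rotatable is not None:
            self.rotatable = list(rotatable)
        else:
            for i, r in enumerate(chain.resids):
                r = int(r)
                if r in overlap_res:
                    continue
                for kind in ("phi", "psi"):
                    if self._hinge_valid(i, kind):
                        self.rotatable.append((r, kind))
        if not self.rotatable:
            raise GeometryError("no rotatable residues available for CCD")
        self.rot_residues = sorted({r for r, _ in self.rotatable})
        self.rot_pairs = set(self.rotatable)

    def _hinge_valid(self, i: int, kind: str) -> bool:
        anchored = self.chain.anchored_end
        if kind == "phi":
            return not (i == 0 and anchored != "C")
        # psi of the C-anchored terminal residue would move its own N off target
        if anchored == "C" and i == len(self.chain) - 1:
            return False
        if anchored in (None, "N") and i == len(self.chain) - 1:
            # psi of the last residue moves only its O; pointless but harmless
            return True
        return True

    def moved_mask(self, resid: int, kind: str) -> np.ndarray:
        i = self.chain.pos(resid)
        if self.chain.anchored_end == "C":
            thr = 4 * i if kind == "phi" else 4 * i + 2
            return self.rev < thr
        thr = 4 * i if kind == "phi" else 4 * i + 1
        return self.fwd > thr

    def hinge_transform(self, resid: int, kind: str, delta_deg: float):
        i = self.chain.pos(resid)
        if kind == "phi":
            a = self.coords[self.row_of[i, SLOT_INDEX["N"]]]
            b = self.coords[self.row_of[i, SLOT_INDEX["CA"]]]
        else:
            a = self.coords[self.row_of[i, SLOT_INDEX["CA"]]]
            b = self.coords[self.row_of[i, SLOT_INDEX["C"]]]
        sign = -1.0 if self.chain.anchored_end == "C" else 1.0
        return rotation_about_axis(a, b - a, sign * delta_deg)

    def effector_rows(self, effectors: Sequence[EffectorAtom]) -> np.ndarray:
        rows = []
        for e in effectors:
            if e.kind == "chain":
                i = self.chain.pos(e.resid)
                row = self.row_of[i, SLOT_INDEX[e.atom]]
                if row < 0:
                    raise GeometryError(f"effector atom {e.atom} absent at {e.resid}")
                rows.append(row)
            elif e.kind == "body":
                for att, sl in self.att_slices:
                    if att.body.name == e.body:
                        rows.append(sl.start + att.body.tags[e.tag])
                        break
                else:
                    raise GeometryError(f"no attached body named {e.body!r}")
            else:
                raise GeometryError(f"bad effector kind {e.kind!r}")
        return np.array(rows, dtype=int)

    def _clash_after_move(self, mask: np.ndarray) -> bool:
        """Any clash between the moved set and the unmoved set or environment.

        Fast path: a vectorized nearest-neighbour query; only atoms with a
        sub-cutoff neighbour (rare) go through exclusion filtering.
        """
        cutoff = self.model.cutoff
        moved_idx = np.nonzero(mask)[0]
        moved = self.coords[moved_idx]
        if self.env_tree is not None:
            d, _ = self.env_tree.query(moved, k=1, distance_upper_bound=cutoff)
            close = np.nonzero(d < cutoff)[0]
            for mi_local in close:
                mi = moved_idx[mi_local]
                for ej in self.env_tree.query_ball_point(moved[mi_local], cutoff):
                    if self._pair_ok(self.mol[mi], self.resid[mi], self.body[mi],
                                     self.env.mol[ej], self.env.resid[ej],
                                     self.env.body[ej]):
                        return True
        un_idx = np.nonzero(~mask)[0]
        if len(un_idx) and len(moved_idx):
            if len(un_idx) <= len(moved_idx):
                tree = cKDTree(self.coords[un_idx])
                query, a_idx, b_source = moved, moved_idx, un_idx
            else:
                tree = cKDTree(moved)
                query, a_idx, b_source = self.coords[un_idx], un_idx, moved_idx
            d, _ = tree.query(query, k=1, distance_upper_bound=cutoff)
            close = np.nonzero(d < cutoff)[0]
            for qi in close:
                ai = a_idx[qi]
                for j in tree.query_ball_point(query[qi], cutoff):
                    bj = b_source[j]
                    if self._pair_ok(self.mol[ai], self.resid[ai], self.body[ai],
                                     self.mol[bj], self.resid[bj], self.body[bj]):
                        return True
        return False

    def _pair_ok(self, mol_a, res_a, body_a, mol_b, res_b, body_b) -> bool:
        """True if the pair counts as a clash (i.e. is not excluded)."""
        if body_a != "" and body_a == body_b:
            return False
        if mol_a == mol_b and abs(int(res_a) - int(res_b)) <= self.model.adjacency:
            return False
        return True

    def writeback(self) -> None:
        """Scatter flat coordinates back into the chain and its attachments."""
        n_chain = int(self.slot_mask.sum())
        self.chain.coords[self.slot_mask] = self.coords[:n_chain]
        for att, sl in self.att_slices:
            from dataclasses import replace as _replace
            att.body = _replace(att.body, coords=self.coords[sl])


def _objective(task: AnchorTask, eff_coords: np.ndarray) -> float:
    if task.kind == "plane":
        dz = eff_coords[:, 2] - task.target.z0
        return float(np.sqrt(np.mean(dz * dz)))
    t = np.asarray(task.target, dtype=float)
    d2 = np.sum((eff_coords - t) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))


def _converged(task: AnchorTask, eff_coords: np.ndarray, params: CCDParams) -> bool:
    if task.kind == "plane":
        return bool(np.max(np.abs(eff_coords[:, 2] - task.target.z0))
                    <= params.anchor_tolerance)
    obj = _objective(task, eff_coords)
    if task.kind == "alignment":
        return obj < params.align_threshold
    return obj <= params.point_tolerance


def ccd_minimize(chain: Chain, task: AnchorTask, params: CCDParams,
                 rng: np.random.Generator,
                 env_view: ClashView | None = None,
                 model: ClashModel = ClashModel(),
                 rotatable: Sequence[tuple[int, str]] | None = None,
                 in_place: bool = False) -> CCDResult:
    """Run stochastic CCD until the convergence criterion or the move cap.

    Non-convergence is reported in the result, never raised.  The input chain
    is left untouched unless ``in_place``.
    """
    work = chain if in_place else chain.copy()
    kin = _Kinematics(work, model, env_view, rotatable=rotatable)
    eff_rows = kin.effector_rows(task.effectors)
    obj = _objective(task, kin.coords[eff_rows])
    trace = [obj]
    attempted = accepted = 0
    converged = _converged(task, kin.coords[eff_rows], params)
    residues = kin.rot_residues
    anchored_c = work.anchored_end == "C"
    # hot-loop precomputation: axis atom rows and per-effector movement keys
    iN, iCA, iC = SLOT_INDEX["N"], SLOT_INDEX["CA"], SLOT_INDEX["C"]
    pos_of = {r: work.pos(r) for r in residues}
    keys = kin.rev if anchored_c else kin.fwd
    eff_keys = keys[eff_rows]
    n_res = len(residues)
    sigma = params.sigma
    last_accept = 0
    checkpoint_obj = obj
    next_checkpoint = params.stall_patience
    while (not converged and attempted < params.max_moves
           and attempted - last_accept < params.stall_patience):
        if attempted >= next_checkpoint:
            # moves may be accepted yet clash-blocked from real progress;
            # give up when a whole window gains less than the epsilon
            if checkpoint_obj - obj < params.progress_epsilon:
                break
            checkpoint_obj = obj
            next_checkpoint = attempted + params.stall_patience
        n_draw = min(4096, params.max_moves - attempted)
        ridx = rng.integers(n_res, size=n_draw)
        kinds = rng.integers(2, size=n_draw)          # 0 = phi, 1 = psi
        deltas = sigma * rng.standard_normal(n_draw)
        for t in range(n_draw):
            attempted += 1
            r = residues[ridx[t]]
            kind = "phi" if kinds[t] == 0 else "psi"
            if (r, kind) not in kin.rot_pairs:
                continue
            i = pos_of[r]
            if anchored_c:
                thr = 4 * i if kind == "phi" else 4 * i + 2
                eff_moving = eff_keys < thr
            else:
                thr = 4 * i if kind == "phi" else 4 * i + 1
                eff_moving = eff_keys > thr
            if not eff_moving.any():
                continue
            if kind == "phi":
                p0 = kin.coords[kin.row_of[i, iN]]
                p1 = kin.coords[kin.row_of[i, iCA]]
            else:
                p0 = kin.coords[kin.row_of[i, iCA]]
                p1 = kin.coords[kin.row_of[i, iC]]
            ang = math.radians(-deltas[t] if anchored_c else deltas[t])
            ux, uy, uz = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
            un = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux, uy, uz = ux / un, uy / un, uz / un
            ca_, sa = math.cos(ang), math.sin(ang)
            oc = 1.0 - ca_
            rot = np.array([
                [ca_ + ux * ux * oc, ux * uy * oc - uz * sa, ux * uz * oc + uy * sa],
                [uy * ux * oc + uz * sa, ca_ + uy * uy * oc, uy * uz * oc - ux * sa],
                [uz * ux * oc - uy * sa, uz * uy * oc + ux * sa, ca_ + uz * uz * oc]])
            trial_eff = kin.coords[eff_rows].copy()
            te = trial_eff[eff_moving]
            trial_eff[eff_moving] = (te - p0) @ rot.T + p0
            new_obj = _objective(task, trial_eff)
            if not new_obj < obj:
                continue
            mask = (keys < thr) if anchored_c else (keys > thr)
            moved_idx = np.nonzero(mask)[0]
            old = kin.coords[moved_idx].copy()
            kin.coords[moved_idx] = (old - p0) @ rot.T + p0
            if kin._clash_after_move(mask):
                kin.coords[moved_idx] = old
                continue
            obj = new_obj
            accepted += 1
            last_accept = attempted
            trace.append(obj)
            converged = _converged(task, kin.coords[eff_rows], params)
            if converged:
                break
            if params.log_every and attempted % params.log_every == 0:
                logger.info("ccd: %d moves, %d accepted, objective %.3f",
                            attempted, accepted, obj)
    kin.writeback()
    return CCDResult(work, converged, attempted, accepted, trace, obj)


def ccd_move(chain: Chain, task: AnchorTask, params: CCDParams,
             rng: np.random.Generator,
             env_view: ClashView | None = None,
             model: ClashModel = ClashModel()) -> tuple[Chain, bool, float]:
    """Attempt a single CCD move; returns (chain', accepted, objective).

    The returned chain is a new object; on rejection its coordinates are
    bit-identical to the input.
    """
    work = chain.copy()
    kin = _Kinematics(work, model, env_view)
    eff_rows = kin.effector_rows(task.effectors)
    obj = _objective(task, kin.coords[eff_rows])
    residues = kin.rot_residues
    r = residues[rng.integers(len(residues))]
    kind = "phi" if rng.integers(2) == 0 else "psi"
    delta = params.sigma * rng.standard_normal()
    if (r, kind) not in kin.rot_pairs:
        return work, False, obj
    mask = kin.moved_mask(r, kind)
    eff_moving = mask[eff_rows]
    if not eff_moving.any():
        return work, False, obj
    tr = kin.hinge_transform(r, kind, delta)
    trial_eff = kin.coords[eff_rows].copy()
    trial_eff[eff_moving] = tr.apply(trial_eff[eff_moving])
    new_obj = _objective(task, trial_eff)
    if not new_obj < obj:
        return work, False, obj
    moved_idx = np.nonzero(mask)[0]
    old = kin.coords[moved_idx].copy()
    kin.coords[moved_idx] = tr.apply(old)
    if kin._clash_after_move(mask):
        kin.coords[moved_idx] = old
        return work, False, obj
    kin.writeback()
    return work, True, new_obj
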