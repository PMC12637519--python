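"""Hierarchical chain growth of self-avoiding disordered segments.

Segments are assembled from short sampled fragments merged pairwise by
superposing the one shared residue of adjacent fragments.  One terminus (the
anchored end) can be pinned to a target backbone frame; merges that extend
the world-placed spine are tested against the clash model, the membrane
half-space and any static environment.  Rigid bodies are grafted at the tree
node that first covers their overlap residues and participate in all
subsequent acceptance tests.

Ensemble generation keeps a pool of accepted conformers at every tree node
and assembles members by drawing random child pairs, which amortizes
fragment sampling across the ensemble the way fragment-library growth does;
single conformations use an independent recursive path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clash import (ClashModel, ClashView, build_view, cross_clash_pairs,
                    has_clash, has_cross_clash, view_of_body, view_of_chain)
from .geometry import (Attachment, Chain, GeometryError, MembranePlane,
                       RigidBody, SLOT_INDEX, build_chain, superpose)
from .library import DihedralLibrary, VirtualBondLibrary


class SamplingFailureError(RuntimeError):
    """The sampler exhausted its retry/attempt budget; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AttachmentClashError(RuntimeError):
    """Grafting a rigid body produced clashes outside the overlap."""


class _MergeExhausted(Exception):
    pass


@dataclass
class GrowthPolicy:
    """Knobs of the fragment-assembly sampler.

    fragment_len: leaf fragment size in residues (merged with 1-residue overlap).
    merge_retries: accepted-product attempts per pool slot / merge before failing.
    attempt_factor: global cap on leaf fragment draws, times the ensemble size.
    pool_size: conformer pool kept per tree node during ensemble growth.
    jitter_deg: override of the library's basin jitter (None = library value).
    """

    fragment_len: int = 5
    merge_retries: int = 30
    clash_model: ClashModel = field(default_factory=ClashModel)
    membrane: MembranePlane | None = None
    attempt_factor: int = 1000
    pool_size: int = 48
    jitter_deg: float | None = None

    def __post_init__(self):
        if self.fragment_len < 1 or self.merge_retries < 1:
            raise ValueError("fragment_len and merge_retries must be >= 1")


@dataclass(frozen=True)
class SegmentSpec:
    """A segment to grow: sequence, author numbering, optional anchor and grafts."""

    sequence: str
    start_resid: int
    segment_id: str = ""
    molecule: str = ""
    # ("N" | "C", (3, 3) backbone N/CA/C target coords of the terminal residue)
    anchor: tuple[str, np.ndarray] | None = None
    attachments: tuple[tuple[RigidBody, tuple[int, ...]], ...] = ()
    next_aa: str | None = None

    @property
    def resids(self) -> np.ndarray:
        return np.arange(self.start_resid, self.start_resid + len(self.sequence))


@dataclass
class Ensemble:
    """Accepted conformations plus per-member provenance metadata."""

    members: list
    meta: list[dict] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def sample_fragment(sequence: str, resids: Sequence[int], library: DihedralLibrary,
                    rng: np.random.Generator, policy: GrowthPolicy | None = None,
                    next_aa: str | None = None, segment_id: str = "",
                    molecule: str = "") -> Chain:
    """Draw one internally clash-free fragment from the dihedral library."""
    policy = policy or GrowthPolicy()
    if not sequence:
        raise ValueError("empty fragment sequence")
    for _ in range(policy.merge_retries):
        dih = library.sample(sequence, rng, next_aa=next_aa, jitter_deg=policy.jitter_deg)
        chain = build_chain(sequence, dih, resids=resids,
                            segment_id=segment_id, molecule=molecule)
        if not has_clash(view_of_chain(chain, policy.clash_model), policy.clash_model):
            return chain
    raise SamplingFailureError(
        f"fragment {resids[0]}-{resids[-1]} of {segment_id!r}: no internally "
        f"clash-free draw in {policy.merge_retries} tries",
        {"segment": segment_id, "resids": (int(resids[0]), int(resids[-1]))})


def attach_rigid_body(chain: Chain, body: RigidBody, overlap: Sequence[int],
                      env_view: ClashView | None = None,
                      model: ClashModel = ClashModel()) -> Attachment:
    """Graft a rigid body onto the chain by overlap-residue superposition.

    The placed body must not clash with the chain (outside the overlap
    neighbourhood) nor with the static environment; on clash the chain is
    left unchanged and AttachmentClashError is raised so callers can
    resample.
    """
    overlap = tuple(int(r) for r in overlap)
    if len(overlap) < 1:
        raise GeometryError("attachment needs at least one overlap residue")
    for r in overlap:
        if r not in body.overlap:
            raise GeometryError(f"body {body.name!r} lacks overlap residue {r}")
    mob = body.overlap_coords(overlap)
    ref = np.concatenate([chain.backbone(r) for r in overlap], axis=0)
    tr, rmsd = superpose(mob, ref)
    placed = body.transformed(tr)
    pv = view_of_body(placed, model)
    cv = view_of_chain(chain, model, include_attachments=True)
    if has_cross_clash(pv, cv, model):
        raise AttachmentClashError(f"body {body.name!r} clashes with chain on attachment")
    if env_view is not None and has_cross_clash(pv, env_view, model):
        raise AttachmentClashError(f"body {body.name!r} clashes with environment")
    att = Attachment(placed, overlap, rmsd)
    chain.attachments.append(att)
    return att


def _leaf_ranges(n: int, frag_len: int) -> list[tuple[int, int]]:
    """Positional [lo, hi] leaf ranges overlapping by one residue."""
    if n <= frag_len:
        return [(0, n - 1)]
    ranges = []
    lo = 0
    while lo < n - 1:
        hi = min(lo + frag_len - 1, n - 1)
        ranges.append((lo, hi))
        lo = hi
    return ranges


class _Budget:
    def __init__(self, cap: int):
        self.cap = cap
        self.leaf_draws = 0
        self.merge_fail = 0
        self.clash_fail = 0
        self.membrane_fail = 0
        self.attach_fail = 0

    def draw(self):
        self.leaf_draws += 1
        if self.leaf_draws > self.cap:
            raise SamplingFailureError(
                f"global attempt cap ({self.cap} leaf draws) exceeded",
                self.diagnostics())

    def diagnostics(self) -> dict:
        return {"leaf_draws": self.leaf_draws, "merge_failures": self.merge_fail,
                "clash_failures": self.clash_fail,
                "membrane_failures": self.membrane_fail,
                "attachment_failures": self.attach_fail}


def _merge(world: Chain, incoming: Chain, spine_end: str) -> Chain:
    """Superpose ``incoming`` onto ``world`` via the shared residue and join."""
    shared = int(world.resids[-1]) if spine_end == "N" else int(world.resids[0])
    tr, _ = superpose(incoming.backbone(shared), world.backbone(shared))
    incoming.transform(tr)
    left, right = (world, incoming) if spine_end == "N" else (incoming, world)
    li = left.pos(shared)
    coords = np.concatenate([left.coords[:li + 1], right.coords[1:]], axis=0)
    # the shared residue's O follows the continuation (right side) psi
    coords[li, SLOT_INDEX["O"]] = right.coords[0, SLOT_INDEX["O"]]
    resids = np.concatenate([left.resids[:li + 1], right.resids[1:]])
    seq = left.seq[:li + 1] + right.seq[1:]
    return Chain(resids, seq, coords, segment_id=world.segment_id,
                 molecule=world.molecule, anchored_end=world.anchored_end,
                 attachments=world.attachments + incoming.attachments)


class _Assembler:
    """Shared machinery for single-shot and pooled hierarchical growth."""

    def __init__(self, spec: SegmentSpec, library: DihedralLibrary,
                 policy: GrowthPolicy, env_view: ClashView | None,
                 budget: _Budget):
        self.spec = spec
        self.library = library
        self.policy = policy
        self.env = env_view
        self.budget = budget
        self.seq = spec.sequence
        self.resids = spec.resids
        self.leaves = _leaf_ranges(len(self.seq), policy.fragment_len)
        self.spine_end = "C" if (spec.anchor and spec.anchor[0] == "C") else "N"
        self.model = policy.clash_model
        # assign each attachment to the smallest node covering its overlap
        self.node_atts: dict[tuple[int, int], list] = {}
        for body, ov in spec.attachments:
            node = self._owning_node(0, len(self.leaves), tuple(int(r) for r in ov))
            self.node_atts.setdefault(node, []).append((body, tuple(int(r) for r in ov)))

    # tree structure -------------------------------------------------------

    def _children(self, i: int, j: int) -> tuple[tuple[int, int], tuple[int, int]]:
        k = (i + j) // 2
        return (i, k), (k, j)

    def _node_resids(self, i: int, j: int) -> tuple[int, int]:
        lo = self.resids[self.leaves[i][0]]
        hi = self.resids[self.leaves[j - 1][1]]
        return int(lo), int(hi)

    def _owning_node(self, i: int, j: int, ov: tuple[int, ...]) -> tuple[int, int]:
        lo, hi = self._node_resids(i, j)
        if not all(lo <= r <= hi for r in ov):
            raise GeometryError(
                f"attachment overlap {ov} outside segment {lo}-{hi}")
        if j - i == 1:
            return (i, j)
        for child in self._children(i, j):
            clo, chi = self._node_resids(*child)
            if all(clo <= r <= chi for r in ov):
                return self._owning_node(*child, ov)
        return (i, j)

    # building blocks ------------------------------------------------------

    def leaf(self, idx: int, rng: np.random.Generator, world: bool) -> Chain:
        lo, hi = self.leaves[idx]
        self.budget.draw()
        nxt = self.seq[hi + 1] if hi + 1 < len(self.seq) else self.spec.next_aa
        chain = sample_fragment(self.seq[lo:hi + 1], self.resids[lo:hi + 1],
                                self.library, rng, self.policy, next_aa=nxt,
                                segment_id=self.spec.segment_id,
                                molecule=self.spec.molecule or self.spec.segment_id)
        chain.anchored_end = self.spine_end if world else None
        if world and self.spec.anchor is not None:
            end, target = self.spec.anchor
            anchor_resid = int(self.resids[0]) if end == "N" else int(self.resids[-1])
            tr, _ = superpose(chain.backbone(anchor_resid), np.asarray(target))
            chain.transform(tr)
        self._node_attach(chain, (idx, idx + 1), world)
        if world and not self._world_ok(view_of_chain(chain, self.model)):
            raise _MergeExhausted
        return chain

    def _node_attach(self, chain: Chain, node: tuple[int, int], world: bool) -> None:
        for body, ov in self.node_atts.get(node, ()):
            attach_rigid_body(chain, body, ov,
                              env_view=self.env if world else None,
                              model=self.model)

    def _world_ok(self, view: ClashView) -> bool:
        if self.env is not None and has_cross_clash(view, self.env, self.model):
            self.budget.clash_fail += 1
            return False
        if self.policy.membrane is not None and not self.policy.membrane.all_above(view.coords):
            self.budget.membrane_fail += 1
            return False
        return True

    def merge_pair(self, spine: Chain, incoming: Chain, node: tuple[int, int],
                   world: bool) -> Chain | None:
        """Merge two child conformers and run the acceptance tests.

        Inputs must be private copies; returns the merged chain or None.
        """
        old_n = len(spine)
        old_atts = len(spine.attachments)
        merged = _merge(spine, incoming, self.spine_end)
        n_new_atts = len(merged.attachments) - old_atts
        new_view = self._part_view(merged, len(merged) - old_n, n_new_atts)
        old_view = build_view(
            [Chain(spine.resids, spine.seq, spine.coords,
                   segment_id=spine.segment_id, molecule=spine.molecule)]
            + [a.body for a in spine.attachments], self.model)
        if has_cross_clash(new_view, old_view, self.model):
            self.budget.clash_fail += 1
            return None
        if world and not self._world_ok(new_view):
            return None
        try:
            self._node_attach(merged, node, world)
        except AttachmentClashError:
            self.budget.attach_fail += 1
            return None
        return merged

    def _part_view(self, chain: Chain, new_count: int, n_new_atts: int) -> ClashView:
        n = len(chain)
        sl = slice(n - new_count, n) if self.spine_end == "N" else slice(0, new_count)
        sub = Chain(chain.resids[sl], chain.seq[sl], chain.coords[sl],
                    segment_id=chain.segment_id, molecule=chain.molecule)
        parts = [view_of_chain(sub, self.model, include_attachments=False)]
        if n_new_atts:
            parts += [view_of_body(a.body, self.model)
                      for a in chain.attachments[-n_new_atts:]]
        return ClashView.concat(parts)

    # single-shot recursive growth ----------------------------------------

    def assemble(self, i: int, j: int, world: bool, rng: np.random.Generator) -> Chain:
        if j - i == 1:
            for _ in range(self.policy.merge_retries):
                try:
                    return self.leaf(i, rng, world)
                except (_MergeExhausted, AttachmentClashError):
                    self.budget.merge_fail += 1
            raise _MergeExhausted
        (li, lj), (ri, rj) = self._children(i, j)
        if self.spine_end == "N":
            spine_rng, inc_rng = (li, lj), (ri, rj)
        else:
            spine_rng, inc_rng = (ri, rj), (li, lj)
        spine = self.assemble(*spine_rng, world, rng)
        for _ in range(self.policy.merge_retries):
            try:
                incoming = self.assemble(*inc_rng, False, rng)
            except (_MergeExhausted, AttachmentClashError):
                self.budget.merge_fail += 1
                continue
            merged = self.merge_pair(spine.copy(), incoming, (i, j), world)
            if merged is not None:
                return merged
            self.budget.merge_fail += 1
        raise _MergeExhausted

    # pooled ensemble growth ----------------------------------------------

    def pools(self, n: int, rng: np.random.Generator) -> list[Chain]:
        # node pools never need to exceed ~2x the requested ensemble size
        pool_size = min(max(2, self.policy.pool_size), max(8, 2 * n))

        def node_pool(i: int, j: int, world: bool, size: int) -> list[Chain]:
            out: list[Chain] = []
            if j - i == 1:
                attempts = 0
                cap = size * self.policy.merge_retries
                while len(out) < size and attempts < cap:
                    attempts += 1
                    try:
                        out.append(self.leaf(i, rng, world))
                    except (_MergeExhausted, AttachmentClashError):
                        self.budget.merge_fail += 1
                if len(out) < size:
                    raise SamplingFailureError(
                        f"leaf pool {self._node_resids(i, j)} starved "
                        f"({len(out)}/{size})", self.budget.diagnostics())
                return out
            (li, lj), (ri, rj) = self._children(i, j)
            if self.spine_end == "N":
                spine_rng, inc_rng = (li, lj), (ri, rj)
            else:
                spine_rng, inc_rng = (ri, rj), (li, lj)
            child_size = pool_size if (j - i) > 2 or size > pool_size else max(size, 8)
            sp = node_pool(*spine_rng, world, min(pool_size, max(child_size, size)))
            ip = node_pool(*inc_rng, False, min(pool_size, max(child_size, size)))
            attempts = 0
            cap = size * self.policy.merge_retries
            while len(out) < size and attempts < cap:
                attempts += 1
                s = sp[rng.integers(len(sp))].copy()
                t = ip[rng.integers(len(ip))].copy()
                merged = self.merge_pair(s, t, (i, j), world)
                if merged is not None:
                    out.append(merged)
                else:
                    self.budget.merge_fail += 1
            if len(out) < size:
                raise SamplingFailureError(
                    f"pool at node {self._node_resids(i, j)} starved "
                    f"({len(out)}/{size} after {attempts} merges)",
                    self.budget.diagnostics())
            return out

        return node_pool(0, len(self.leaves), True, n)


def hierarchical_assemble(spec: SegmentSpec, library: DihedralLibrary,
                          policy: GrowthPolicy, rng: np.random.Generator,
                          env_view: ClashView | None = None,
                          budget: _Budget | None = None) -> Chain:
    """Grow one accepted conformation of a segment by pairwise fragment merging."""
    budget = budget or _Budget(policy.attempt_factor * max(1, len(spec.sequence)))
    asm = _Assembler(spec, library, policy, env_view, budget)
    try:
        chain = asm.assemble(0, len(asm.leaves), True, rng)
    except _MergeExhausted:
        raise SamplingFailureError(
            f"assembly of {spec.segment_id!r} exhausted merge retries",
            budget.diagnostics())
    chain.check_contiguous()
    return chain


def grow_ensemble(spec: SegmentSpec, library, policy: GrowthPolicy, n: int,
                  rng: np.random.Generator, env_view: ClashView | None = None,
                  label: str = "") -> Ensemble:
    """Sample exactly ``n`` accepted conformations of a segment.

    Uses pooled hierarchical growth (one conformer pool per tree node); the
    per-member provenance records the shared root seed and the member index.
    Raises SamplingFailureError with acceptance statistics on starvation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(library, VirtualBondLibrary):
        return _grow_fjc_ensemble(spec, library, policy, n, rng, label)
    budget = _Budget(policy.attempt_factor * max(n, 8) * max(1, len(spec.sequence) // policy.fragment_len))
    asm = _Assembler(spec, library, policy, env_view, budget)
    if n == 1:
        last_err = None
        for _ in range(policy.merge_retries):
            try:
                chain = hierarchical_assemble(spec, library, policy, rng,
                                              env_view, budget)
                return Ensemble([chain], [{"member": 0}], label=label)
            except SamplingFailureError as err:
                last_err = err
        raise last_err
    last_err = None
    for _ in range(3):
        try:
            members = asm.pools(n, rng)
            break
        except SamplingFailureError as err:   # starved pool: rebuild afresh
            last_err = err
    else:
        raise last_err
    for m in members:
        m.check_contiguous()
    meta = [{"member": i, "diagnostics": budget.diagnostics() if i == 0 else None}
            for i in range(n)]
    return Ensemble(members, meta, label=label)


def _grow_fjc_ensemble(spec: SegmentSpec, library: VirtualBondLibrary,
                       policy: GrowthPolicy, n: int, rng: np.random.Generator,
                       label: str) -> Ensemble:
    """Freely-jointed virtual-bond mode: CA-only chains, uniform directions."""
    from .fixtures import fjc_chains
    n_res = len(spec.sequence)
    coords = fjc_chains(n_res, n, rng, b=library.b, clash_model=None)
    members = [coords[i] for i in range(n)]
    meta = [{"member": i, "mode": "virtual_bond"} for i in range(n)]
    return Ensemble(members, meta, label=label)
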