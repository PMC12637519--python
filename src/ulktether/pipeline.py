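"""The staged membrane-tether assembly protocol for the ULK1 complex.

Stage 1 (scaffold): grow the ATG13 IDR (residues 230-363) from its anchor on
the membrane-bound HORMA dimer with the scaffold core grafted at residue
363, keep conformations whose two sulfur anchors lie close to the membrane,
and drive the two sulfurs plus the FIP200 arm tip to within the plane
tolerance by stochastic CCD.

Stage 2 (unbound): from each converged scaffold, grow the ULK1 IDR tethered
at residue 831 with the kinase domain grafted at its N-terminal end, fully
above the membrane and clash-free against the scaffold.

Stage 3 (bound): place the ULK1 428-450 bound-peptide pose by HORMA
superposition, select IDR conformations whose 428-450 stretch approaches the
binding site, truncate residues up to 449, close the junction at residue 450
onto the pose by CCD alignment, and resample the N-terminal stretch
(277-428) with the kinase domain attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ccd import AnchorTask, CCDParams, EffectorAtom, ccd_minimize
from .clash import ClashModel, ClashView, build_view, view_of_chain
from .fixtures import (HormaSpec, KdSpec, CoreSpec, idr_sequences,
                       make_bound_pose_fixture, make_core_fixture,
                       make_kd_fixture)
from .geometry import Chain, MembranePlane, RigidBody, SLOT_INDEX, superpose
from .growth import (Ensemble, GrowthPolicy, SamplingFailureError, SegmentSpec,
                     grow_ensemble)
from .library import DihedralLibrary

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage starved or failed; carries stage diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class Ulk1cPreset:
    """Residue ranges, anchors, thresholds and sizes of the packaged protocol.

    Author/UniProt numbering throughout.  The kinase domain is rigid up to
    residue 283 (graft overlap at 283), so sampled IDR chains span 283-831;
    the rigid 277-282 tail of the domain completes the stated 277-831 range.
    """

    atg13_range: tuple[int, int] = (230, 363)
    ulk1_range: tuple[int, int] = (277, 831)
    kd_overlap: int = 283
    bound_range: tuple[int, int] = (428, 450)
    truncate_through: int = 449          # residues <= this are removed
    resample_range: tuple[int, int] = (277, 428)
    membrane_z0: float = 0.0
    d_mem: float = 20.0                  # A, pre-CCD sulfur-to-plane filter
    d_bind: float = 50.0                 # A, 428-450 CA to site centroid filter
    plane_tolerance: float = 5.0         # A, per-anchor CCD termination
    align_threshold: float = 0.6         # A, junction RMSD termination
    replicas: int = 3
    n_per_condition: int = 200
    scaffold_batch: int = 128            # IDR conformations grown per filter batch
    max_scaffold_batches: int = 40
    bound_pool: int = 6                  # aligned tail candidates per scaffold
    candidate_batch: int = 256
    max_candidate_batches: int = 20
    ccd_moves_scaffold: int = 80_000
    ccd_moves_junction: int = 60_000
    anchor_tags: tuple[str, ...] = ("C927:SG", "C1003:SG", "FIP200_tip")


@dataclass
class TetherSystem:
    """Membrane plane, rigid bodies, sequences and the preset for one run."""

    membrane: MembranePlane
    core: RigidBody
    kd: RigidBody
    horma: RigidBody
    pose: RigidBody                       # bound peptide, in the HORMA frame
    sequences: dict[str, str]
    preset: Ulk1cPreset = field(default_factory=Ulk1cPreset)
    library: DihedralLibrary = field(default_factory=DihedralLibrary.default)
    clash_model: ClashModel = field(default_factory=ClashModel)

    @classmethod
    def default(cls, preset: Ulk1cPreset | None = None) -> "TetherSystem":
        preset = preset or Ulk1cPreset()
        seqs = idr_sequences()
        horma, pose = make_bound_pose_fixture(HormaSpec())
        return cls(membrane=MembranePlane(preset.membrane_z0),
                   core=make_core_fixture(CoreSpec()),
                   kd=make_kd_fixture(KdSpec(overlap_resid=preset.kd_overlap)),
                   horma=horma, pose=pose, sequences=seqs, preset=preset)

    def policy(self, with_membrane: bool = True) -> GrowthPolicy:
        return GrowthPolicy(clash_model=self.clash_model,
                            membrane=self.membrane if with_membrane else None)


@dataclass
class Scaffold:
    """A converged membrane-anchored scaffold (stage 1 output)."""

    chain: Chain                  # ATG13 IDR with the core attached
    replica: int
    seed: int
    anchor_residuals: np.ndarray  # |z - z0| per anchor tag, A
    ccd_report: dict

    @property
    def core_body(self) -> RigidBody:
        return self.chain.attachments[0].body

    def tether_target(self) -> np.ndarray:
        """Backbone target for the ULK1 IDR C-terminal anchor (residue 831)."""
        return self.core_body.residue_coords(831, mol="ULK1")

    def env_view(self, horma: RigidBody, model: ClashModel,
                 extra: list | None = None) -> ClashView:
        return build_view([self.chain, horma] + (extra or []), model)


@dataclass
class Member:
    """One accepted conformation of a tethered-kinase condition."""

    chains: dict[str, Chain]
    bodies: dict[str, RigidBody]
    replica: int
    condition: str                # "unbound" | "bound"
    meta: dict = field(default_factory=dict)

    def kd_body(self) -> RigidBody:
        return self.bodies["KD"]

    def kd_com(self) -> np.ndarray:
        """Mass-unweighted centre of the kinase domain's backbone heavy atoms."""
        b = self.kd_body()
        rows = [i for i, (_, _, atom) in enumerate(b.labels)
                if atom in ("N", "CA", "C", "O")]
        return b.coords[rows].mean(axis=0)

    def all_coords(self) -> np.ndarray:
        parts = [c.flat_coords() for c in self.chains.values()]
        parts += [b.coords for b in self.bodies.values()]
        return np.concatenate(parts, axis=0)

    def grown_coords(self) -> np.ndarray:
        """Atoms subject to the half-space acceptance: the sampled chains and
        their grafted bodies.  Scaffold bodies are environment — their
        membrane anchors legitimately finish within +-5 A of the plane."""
        parts = [c.flat_coords(include_attachments=True)
                 for c in self.chains.values()]
        return np.concatenate(parts, axis=0)


@dataclass
class EnsemblePair:
    """Unbound and bound ensembles over the same membrane frame."""

    unbound: Ensemble
    bound: Ensemble
    scaffolds: list[Scaffold]
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage 1: membrane-anchored scaffold


def build_scaffold(system: TetherSystem, rng: np.random.Generator,
                   replica: int = 0) -> Scaffold:
    """Grow, filter and CCD-anchor one ATG13-IDR/core scaffold.

    Candidates are accepted when both sulfur anchors end within ``d_mem`` of
    the headgroup plane; CCD then minimizes the RMS plane distance of the
    two sulfurs and the arm tip until all three are within the plane
    tolerance.  Candidates that fail to converge are discarded in order.
    """
    p = system.preset
    lo, hi = p.atg13_range
    seq = system.sequences["atg13_230_363"]
    if len(seq) != hi - lo + 1:
        raise StageError("ATG13 sequence length does not match its range")
    anchor_target = system.horma.residue_coords(lo, mol="ATG13")
    spec = SegmentSpec(seq, lo, segment_id="atg13_idr", molecule="ATG13",
                       anchor=("N", anchor_target),
                       attachments=((system.core, (hi,)),))
    env = build_view([system.horma], system.clash_model)
    policy = system.policy()
    seed = int(rng.integers(2**31 - 1))
    task = AnchorTask("plane",
                      tuple(EffectorAtom("body", body="core", tag=t)
                            for t in p.anchor_tags),
                      system.membrane)
    params = CCDParams(anchor_tolerance=p.plane_tolerance,
                       max_moves=p.ccd_moves_scaffold, log_every=0)
    grown = tried = 0
    for _ in range(p.max_scaffold_batches):
        ens = grow_ensemble(spec, system.library, policy, p.scaffold_batch,
                            np.random.default_rng(int(rng.integers(2**31 - 1))),
                            env_view=env, label=f"scaffold-candidates-r{replica}")
        grown += len(ens)
        for cand in ens:
            core = cand.attachments[0].body
            sg = np.array([core.tag_coord("C927:SG"), core.tag_coord("C1003:SG")])
            if np.any(np.abs(sg[:, 2] - system.membrane.z0) > p.d_mem):
                continue
            tried += 1
            res = ccd_minimize(cand, task, params,
                               np.random.default_rng(int(rng.integers(2**31 - 1))),
                               env_view=env, model=system.clash_model)
            if res.converged:
                core = res.chain.attachments[0].body
                anchors = np.array([core.tag_coord(t) for t in p.anchor_tags])
                residuals = np.abs(anchors[:, 2] - system.membrane.z0)
                logger.info("scaffold %d converged after %d CCD candidates "
                            "(%d grown)", replica, tried, grown)
                return Scaffold(res.chain, replica, seed, residuals, res.to_report())
    raise StageError(
        f"no scaffold converged (replica {replica}): {tried} candidates "
        f"passed the {p.d_mem} A sulfur filter out of {grown}",
        {"candidates": grown, "filter_passed": tried})


# ---------------------------------------------------------------------------
# stage 2: unbound ULK1 IDR with kinase domain


def sample_unbound(system: TetherSystem, scaffold: Scaffold, n: int,
                   rng: np.random.Generator, start_resid: int | None = None,
                   kd: RigidBody | None = None) -> Ensemble:
    """Grow ``n`` ULK1-IDR conformations tethered at residue 831 with the
    kinase domain attached and no HORMA engagement."""
    p = system.preset
    kd = kd or system.kd
    start = p.kd_overlap if start_resid is None else start_resid
    seq_all = system.sequences["ulk1_277_831"]
    seq = seq_all[start - p.ulk1_range[0]:]
    spec = SegmentSpec(seq, start, segment_id="ulk1_idr", molecule="ULK1",
                       anchor=("C", scaffold.tether_target()),
                       attachments=((kd, (start,)),))
    env = scaffold.env_view(system.horma, system.clash_model)
    ens = grow_ensemble(spec, system.library, system.policy(), n, rng,
                        env_view=env, label=f"unbound-r{scaffold.replica}")
    members = []
    for i, chain in enumerate(ens):
        members.append(Member(chains={"ULK1_IDR": chain},
                              bodies={"KD": chain.attachments[0].body,
                                      "core": scaffold.core_body,
                                      "HORMA": system.horma},
                              replica=scaffold.replica, condition="unbound",
                              meta=ens.meta[i]))
    return Ensemble(members, ens.meta, label=ens.label)


# ---------------------------------------------------------------------------
# stage 3: bound state


def place_bound_pose(system: TetherSystem, scaffold: Scaffold) -> RigidBody:
    """Place the 428-450 peptide pose by superposing the HORMA frame onto the
    scaffold's HORMA dimer (identity for the packaged fixtures)."""
    tr, rmsd = superpose(system.horma.coords, system.horma.coords,
                         allow_collinear=False)
    if rmsd > 1e-6:
        raise StageError(f"HORMA frame superposition rmsd {rmsd:.3f} A")
    return system.pose.transformed(tr)


def _candidate_passes_filter(chain: Chain, site: np.ndarray, p: Ulk1cPreset) -> bool:
    lo, hi = p.bound_range
    mask = (chain.resids >= lo) & (chain.resids <= hi)
    ca = chain.coords[mask, SLOT_INDEX["CA"]]
    if len(ca) == 0:
        return False
    return bool(np.min(np.linalg.norm(ca - site, axis=1)) <= p.d_bind)


def build_bound(system: TetherSystem, scaffold: Scaffold, n: int,
                rng: np.random.Generator) -> Ensemble:
    """Construct ``n`` bound-state members for one scaffold.

    Fresh unbound-style candidates over 428-831 are sampled and filtered by
    the binding-site proximity rule; passing candidates are truncated to
    450-831 and their junction residue 450 is CCD-aligned onto the placed
    pose below the alignment threshold.  Each member then resamples the
    N-terminal stretch with the kinase domain attached against the full
    environment.  Aligned tail candidates are pooled and shared between
    members (the resampled stretch and the kinase placement are drawn
    per member).
    """
    p = system.preset
    pose = place_bound_pose(system, scaffold)
    site = system.horma.tag_coord("HD_site")
    seq_all = system.sequences["ulk1_277_831"]
    cand_start = p.bound_range[0]                       # 428
    seq = seq_all[cand_start - p.ulk1_range[0]:]
    env = scaffold.env_view(system.horma, system.clash_model, extra=[pose])
    spec = SegmentSpec(seq, cand_start, segment_id="ulk1_idr", molecule="ULK1",
                       anchor=("C", scaffold.tether_target()))
    policy = system.policy()

    # --- candidate selection and junction closure --------------------------
    align_task = AnchorTask(
        "alignment",
        tuple(EffectorAtom("chain", 450, a) for a in ("N", "CA", "C", "O")),
        pose.residue_coords(450, atoms=("N", "CA", "C", "O"), mol="ULK1"))
    params = CCDParams(align_threshold=p.align_threshold,
                       max_moves=p.ccd_moves_junction, log_every=0)
    tails: list[tuple[Chain, dict]] = []
    stats = {"candidates": 0, "filter_passed": 0, "ccd_failed": 0}
    for _ in range(p.max_candidate_batches):
        if len(tails) >= p.bound_pool:
            break
        try:
            batch = grow_ensemble(spec, system.library, policy, p.candidate_batch,
                                  np.random.default_rng(int(rng.integers(2**31 - 1))),
                                  env_view=env, label="bound-candidates")
        except SamplingFailureError:
            continue
        for cand in batch:
            stats["candidates"] += 1
            if not _candidate_passes_filter(cand, site, p):
                continue
            stats["filter_passed"] += 1
            # remove residues 1-449 (here: 428-449 of the candidate range)
            keep = cand.resids > p.truncate_through
            tail = Chain(cand.resids[keep], cand.seq[int(np.sum(~keep)):],
                         cand.coords[keep], segment_id="ulk1_tail",
                         molecule="ULK1", anchored_end="C")
            res = ccd_minimize(tail, align_task, params,
                               np.random.default_rng(int(rng.integers(2**31 - 1))),
                               env_view=env, model=system.clash_model)
            if not res.converged:
                stats["ccd_failed"] += 1
                continue
            # CCD never tests the membrane (only clashes); accepted members
            # must still satisfy the half-space, so reject sunk tails here
            if np.min(res.chain.flat_coords()[:, 2]) <= system.membrane.z0:
                stats.setdefault("below_membrane", 0)
                stats["below_membrane"] += 1
                continue
            tails.append((res.chain, res.to_report()))
            if len(tails) >= p.bound_pool:
                break
    if not tails:
        raise StageError(
            f"bound stage starved on replica {scaffold.replica}", stats)

    # --- per-member resampling of the N-terminal stretch -------------------
    re_lo = p.kd_overlap                                 # 283 (KD is rigid below)
    re_hi = p.resample_range[1]                          # 428
    re_seq = seq_all[re_lo - p.ulk1_range[0]: re_hi - p.ulk1_range[0] + 1]
    pose_428 = pose.residue_coords(428, mol="ULK1")
    re_spec = SegmentSpec(re_seq, re_lo, segment_id="ulk1_resampled",
                          molecule="ULK1", anchor=("C", pose_428),
                          attachments=((system.kd, (re_lo,)),))
    members = []
    meta = []
    chunk = max(1, n // len(tails))
    ti = 0
    starved = 0
    while len(members) < n:
        if starved > 4 * len(tails) + 8:
            raise StageError(
                f"bound resampling starved on replica {scaffold.replica}",
                dict(stats, resample_failures=starved))
        tail, tail_report = tails[ti % len(tails)]
        ti += 1
        count = min(chunk, n - len(members))
        member_env = build_view([scaffold.chain, system.horma, pose, tail],
                                system.clash_model)
        try:
            seg = grow_ensemble(re_spec, system.library, policy, count,
                                np.random.default_rng(int(rng.integers(2**31 - 1))),
                                env_view=member_env, label="bound-resample")
        except SamplingFailureError:
            starved += 1
            continue
        junction = tail.backbone(450, atoms=("N", "CA", "C", "O"))
        jr = float(np.sqrt(np.mean(np.sum(
            (junction - np.asarray(align_task.target)) ** 2, axis=1))))
        for chain in seg:
            m = Member(chains={"ULK1_resampled": chain, "ULK1_tail": tail},
                       bodies={"KD": chain.attachments[0].body, "bound_pose": pose,
                               "core": scaffold.core_body, "HORMA": system.horma},
                       replica=scaffold.replica, condition="bound",
                       meta={"member": len(members), "junction_rmsd": jr,
                             "tail_ccd": tail_report})
            members.append(m)
            meta.append(m.meta)
    meta[0] = dict(meta[0], stage_stats=stats)
    return Ensemble(members, meta, label=f"bound-r{scaffold.replica}")


# ---------------------------------------------------------------------------
# full protocol


def run_ulk1c(system: TetherSystem | None = None, seed: int = 0,
              n: int | None = None, replicas: int | None = None) -> EnsemblePair:
    """Run the full staged protocol: R scaffold replicas, each with unbound
    and bound ensembles of size n; returns the pooled pair with provenance."""
    system = system or TetherSystem.default()
    p = system.preset
    n = p.n_per_condition if n is None else n
    replicas = p.replicas if replicas is None else replicas
    root = np.random.SeedSequence(seed)
    unbound_members, unbound_meta = [], []
    bound_members, bound_meta = [], []
    scaffolds = []
    for r, child in enumerate(root.spawn(replicas)):
        # a scaffold can leave the binding site unreachable (clash-blocked
        # junction closure); such replicas restart from a fresh initial
        # ATG13 conformation, mirroring independent protocol iterations
        last_err = None
        for attempt, sub in enumerate(child.spawn(3)):
            s_seed, u_seed, b_seed = sub.spawn(3)
            scaffold = build_scaffold(system, np.random.default_rng(s_seed),
                                      replica=r)
            try:
                bnd = build_bound(system, scaffold, n,
                                  np.random.default_rng(b_seed))
                unb = sample_unbound(system, scaffold, n,
                                     np.random.default_rng(u_seed))
            except (StageError, SamplingFailureError) as err:
                logger.warning("replica %d attempt %d: %s", r, attempt, err)
                last_err = err
                continue
            break
        else:
            raise last_err
        scaffolds.append(scaffold)
        unbound_members += unb.members
        unbound_meta += [dict(m, replica=r) for m in unb.meta]
        bound_members += bnd.members
        bound_meta += [dict(m, replica=r) for m in bnd.meta]
        logger.info("replica %d complete (%d unbound, %d bound)", r, len(unb), len(bnd))
    prov = {"seed": seed, "n_per_condition": n, "replicas": replicas,
            "preset": {k: getattr(p, k) for k in p.__dataclass_fields__
                       if not k.startswith("_")}}
    return EnsemblePair(Ensemble(unbound_members, unbound_meta, "unbound"),
                        Ensemble(bound_members, bound_meta, "bound"),
                        scaffolds, prov)
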