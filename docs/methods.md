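# Methods

`ulktether` builds conformational ensembles of a membrane-tethered,
multidomain kinase complex — the autophagy-initiating ULK1 complex — by
combining three ingredients: fragment-assembly sampling of intrinsically
disordered regions (IDRs), rigid-body grafting of folded domains by
overlap-residue superposition, and a stochastic cyclic-coordinate-descent
(CCD) refinement that drives anchor atoms onto membrane or alignment
targets. The observable of interest is the distribution of the ULK1
kinase-domain (KD) centre of mass over the membrane plane, with and without
the ULK1-IDR peptide engaging the ATG13 HORMA dimer.

## Backbone model

Chains are kinematic chains of backbone residues (N, CA, C, O and a
pseudo-CB; no hydrogens, no side chains beyond CB) with fixed ideal bond
geometry (N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å; N-CA-C 111.0°,
CA-C-N 116.2°, C-N-CA 121.7°). Phi/psi dihedrals are the only degrees of
freedom; omega is fixed trans (180°, no cis-proline). Coordinates are built
from internal coordinates by sequential natural-extension (NeRF) placement;
dihedral measurement is its exact inverse, and the round trip is tested to
1e-6 degrees. The membrane is an implicit half-space: the coordinate frame
is chosen so the headgroup plane is horizontal at z0 (default 0 Å) and the
allowed region is z > z0. All angles are handled in degrees, all lengths in
Å internally; distances are reported in nm.

## Steric model

A clash is any non-excluded heavy-atom pair (N, CA, C, O, CB, anchor SG)
closer than 2.5 Å. Exclusions are intra-rigid-body pairs and same-molecule
pairs within one residue of each other, which at this cutoff is equivalent
to the usual bonded + 1-3 exclusion (the only standard sub-2.5 Å
inter-residue contact, O(i)...N(i+1) at ~2.25 Å, is a 1-3 pair and is
excluded by the rule). Neighbour search uses a k-d tree and is verified
against an all-pairs oracle. The 2.5 Å backbone-level cutoff is
deliberately permissive: the ensembles are coarse polymer models, not
packing models.

## Dihedral library

Fragment sampling draws (phi, psi) pairs from a four-class coil library
(generic, glycine, proline, pre-proline), each class a small set of
weighted Ramachandran basin centres (PPII, extended beta, alpha-R, alpha-L,
bridge) with 12° Gaussian jitter so draws fill the basins. The library is a
deliberately simple, user-replaceable stand-in for an MD-derived fragment
library; the file format (JSON: class -> [phi, psi, weight]) is documented
in `data/coil_library.json`. With this library, free 550-residue chains
have a root-mean-square end-to-end distance of ~20 nm, close to the
empirical scaling R ≈ √6 · 1.927 Å · N^0.588 for disordered proteins —
slightly more compact than MD-derived libraries, which shows up as a
systematic few-percent underestimate of tether extension (see Accuracy).

## Hierarchical chain growth

Segments are grown as trees of 5-residue fragments merged pairwise on a
one-residue overlap (N/CA/C superposition; exact for ideal-geometry
backbones). One terminus may be pinned to a target backbone frame; every
merge extending the world-placed spine is accepted only if it creates no
clash with the already-placed part, the static environment, or the
membrane half-space, and offending sub-fragments are redrawn (30 retries
per merge, global leaf-draw cap). Rigid bodies are grafted at the tree node
that first covers their single overlap residue and participate in all
subsequent acceptance tests, so accepted conformations place both the IDR
and its attachments fully above the membrane.

For ensembles, each tree node keeps a pool of accepted conformers (default
48) and members are assembled by drawing random child pairs, which
amortizes fragment sampling across the ensemble exactly as a finite
fragment library would. Members of one ensemble therefore share sub-chains
with each other; this correlation is immaterial for means and maxima of
large-scale observables but should be kept in mind for tail statistics.

## Stochastic CCD

The refinement repeatedly draws a uniformly random rotatable residue and a
uniformly random dihedral kind, proposes a rotation drawn from a Gaussian
with zero mean and 1° standard deviation, and accepts the move only if the
effector objective strictly decreases and no new protein-protein clash
appears. The membrane is deliberately absent from the CCD clash test; only
the objective sees it. Three anchor flavours share this machinery:

* point — RMS of effector-to-target distances; converged at 0.1 Å,
* plane — RMS of per-atom |z - z0|; converged when every effector is
  within 5 Å of the plane,
* alignment — fixed-frame RMSD of paired backbone heavy atoms (no
  re-superposition); converged below 0.6 Å.

Accepted-move objective sequences are strictly decreasing by construction;
rejected moves leave coordinates bit-identical. Because moves are pure
hinge rotations, bond geometry is preserved to <1e-9 Å over 10^5 moves.
Non-convergence is a reported result, never an exception; the pipeline
simply discards that candidate. Besides the hard move cap (200,000 by
default), a run terminates early when a 10,000-attempt window passes
without an accepted move or without at least 0.1 Å of objective progress —
on clash-obstructed closures, objective-improving moves keep being
proposed and rejected, and the window rule stops such hopeless runs at a
bounded cost. On toy problems with at most
three rotatable dihedrals the solver is verified against an exhaustive
5°-grid search (within 0.5 Å of the grid optimum); the toy set restricts
the rotatable dihedrals precisely so that the grid remains exhaustively
enumerable.

## The staged protocol

1. **Scaffold.** The ATG13 IDR (residues 230-363) grows from its anchor
   stub on the membrane-bound HORMA dimer with the scaffold core grafted at
   residue 363. Candidates whose two sulfur anchors (author numbering C927,
   C1003) end within 20 Å of the plane enter plane-mode CCD over the two
   sulfurs plus the FIP200 arm tip ("it has to lie flat on the bilayer");
   the first candidate with all three anchors within 5 Å becomes the
   replica's scaffold. Replicas differ only in their random stream, giving
   independent initial ATG13 conformations.
2. **Unbound.** The ULK1 IDR (277-831; 283-831 sampled, 277-282 rigid in
   the KD) grows tethered at residue 831 on the core with the KD grafted at
   residue 283, clash-free against the scaffold and fully above the
   membrane; n = 200 members per replica.
3. **Bound.** The ULK1 428-450 peptide pose is placed by HORMA
   superposition. Fresh candidates over 428-831 are filtered by binding-site
   proximity (minimum CA distance of the 428-450 stretch to the site
   centroid ≤ 50 Å — the filter only gates CCD workload; a tighter gate is
   unreachable because the stretch sits at the free chain end ~16 nm RMS
   from its tether), truncated after residue 449, and their junction
   residue 450 is CCD-aligned onto the pose below 0.6 Å RMSD. Aligned
   tails are pooled (6 per scaffold) and shared between members; each
   member independently resamples the 283-428 stretch anchored on the pose
   with the KD attached, against the full environment.

Per-member distances are the mass-unweighted centre of the KD backbone
atoms over the plane, in nm. The root seed fans out to per-replica and
per-stage child streams through `numpy.random.SeedSequence`, so the whole
run is reproducible from one integer. Reproducibility is bit-exact on one
machine; across platforms, differences in BLAS rounding (the superposition
SVD) can flip individual accept/reject decisions and let trajectories
diverge, leaving summary statistics unchanged within their sampling error
— the usual caveat for long accept/reject chains.

## Synthetic study system

No structure files ship with the package; the rigid bodies are idealized
synthetic stand-ins built in `fixtures.py`: a four-helix bundle with an
elongated arm for the scaffold core (anchor sulfurs and arm tip coplanar on
its membrane face, ATG13-363 and ULK1-831 graft stubs), a 16 Å CA shell
for the kinase domain, a 14 Å shell for the HORMA dimer, and a rigid
23-residue hairpin for the bound peptide, draped 4 Å off the dimer
surface. The dimer does not touch the bilayer: in the membrane-bound
scaffold complex it rides on membrane-inserted WIPI β-propellers, modeled
as a rigid 30 Å pedestal (about one propeller height) between the
headgroup plane and the dimer body, so the binding site sits ~4.4 nm over
the membrane. The packaged IDR sequences are composition-matched synthetic
stand-ins (no database access at build time; see the FASTA header), with
the P-V-P motif at ULK1 433-435. Ensemble observables at this coarse level
depend on anchor placement and tether length, not fold detail — which is
what makes dummy bodies adequate — but the compact body sizes and the
single-height pedestal are idealizations that shift absolute distances by
one to two nanometres.

## Accuracy and problem sizes

At the packaged scale (3 replicas × 200 members per condition, seed 1) the
pipeline reproduces the qualitative and quantitative behaviour of the
modeled system: pooled unbound mean ≈ 15.5-17 nm across seeds (reference
19 nm), pooled bound mean ≈ 9.6-9.8 nm (reference 12 nm), bound < unbound
at >99% bootstrap confidence in every replica, and an unbound maximum of
38-46 nm against the 40 nm maximum tether extension (an extreme-value
statistic with seed-to-seed spread of several nm). The consistent
~15-20% underestimate of the means traces to the coil library's mild
compactness relative to MD-derived fragments and to the compact dummy
bodies; both are documented stand-in effects, not fitted quantities. The
full run takes a few minutes on one CPU; the sizes (200 members,
48-conformer pools, 6 bound tails per scaffold) were chosen as the
smallest giving stable means and are plain configuration, not statements
about the reference system.

## Limitations

* Backbone-only chains with a single rotamer-free pseudo-CB; no energetics
  beyond hard-sphere exclusion, no electrostatics, no membrane insertion
  beyond the half-space constraint.
* The coil library is a basin model, not an MD-derived fragment library;
  local sequence-specific structure (polyproline runs, transient helices)
  is only crudely captured.
* Pool-based growth correlates ensemble members; means are robust,
  extreme-value statistics less so.
* The bound-state candidate pool shares aligned 450-831 tails between
  members; diversity in the reported observable comes almost entirely from
  the resampled 283-428 stretch and the kinase placement, which is where
  the tether statistics live.
* Accessible volumes use the hemisphere model V = (2/3)π r_max³; the fold
  change between two extensions is the cube of their ratio and is
  model-independent in the prefactor.
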