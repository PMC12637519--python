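# ulktether

Conformational-ensemble modeling of the membrane-tethered ULK1 autophagy
initiation complex. The ULK1 kinase domain (KD) hangs off a ~550-residue
intrinsically disordered region (IDR) whose other end is anchored, through
the folded ULK1C core and the ATG13 IDR, to the phagophore membrane. The
package asks a polymer question with structural-biology machinery: how far
from the membrane does the KD roam, and how much closer is it held when the
ULK1-IDR peptide (residues 428-450) binds the ATG13 HORMA dimer?

It provides, as a reusable and tested pipeline:

* **Hierarchical chain growth** of self-avoiding IDR conformations from a
  coil dihedral library, with membrane half-space acceptance and rigid-body
  attachment (`growth`),
* **Stochastic cyclic coordinate descent** — small Gaussian hinge rotations
  (σ = 1°) accepted only when the effector objective strictly decreases
  and no clash is created — for anchoring sulfur atoms to the membrane
  plane (within 5 Å) and closing truncation junctions by fixed-frame
  alignment (below 0.6 Å RMSD) (`ccd`),
* the **staged assembly protocol** (scaffold → unbound → bound) with a
  packaged preset and synthetic fixture bodies (`pipeline`, `fixtures`),
* **ensemble observables**: KD-to-membrane distance distributions and the
  hemispherical accessible volume V = (2/3)π·r_max³ with its cube-law fold
  change (r1/r2)³ (`analysis`).

## Worked example

```python
import numpy as np
from ulktether import TetherSystem, run_ulk1c, volume_fold_change
from ulktether.analysis import member_distances, summarize

system = TetherSystem.default()          # synthetic bodies + packaged sequences
pair = run_ulk1c(system, seed=1, n=50, replicas=1)   # small demonstration run

unbound = member_distances(pair.unbound, system.membrane)
bound = member_distances(pair.bound, system.membrane)
print(f"unbound mean {unbound.mean():.1f} nm, max {unbound.max():.1f} nm")
print(f"bound   mean {bound.mean():.1f} nm")
print(f"volume fold change 40->20 nm: {volume_fold_change(40, 20):.1f}")
```

prints (seed 1):

```
unbound mean 15.9 nm, max 29.1 nm
bound   mean 9.9 nm
volume fold change 40->20 nm: 8.0
```

The unbound KD wanders ~16 nm from the membrane on average; engaging the
HORMA site pulls it to ~10 nm, i.e. binding confines the kinase to the
membrane-proximal layer. Halving the maximum tether extension from 40 nm
to 20 nm shrinks the accessible hemisphere 8-fold — equivalently an
order-of-magnitude increase in local KD concentration at the membrane.

The same protocol is available from a shell:

```bash
ulktether preset-ulk1c --seed 1 --n 50 --replicas 1 --out runs/demo
ulktether fixtures --kind core --out runs/fixtures   # inspect a dummy body
```

Each run directory contains multi-model PDBs per condition and replica, a
TSV of per-member distances, a JSON summary and a provenance file that
reproduces the run exactly.

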