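"""Structure and configuration I/O: PDB, FASTA, run configs, provenance.

PDB files are read and written through biotite (fixed-column records,
multi-model via MODEL/ENDMDL); chain identifiers and author residue numbers
are preserved, insertion codes are rejected.  Run configuration is a flat
YAML key set validated against the preset fields; every run emits a
provenance JSON sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import biotite.sequence.io.fasta as fasta

from .clash import ClashModel
from .geometry import Chain, GeometryError, RigidBody, SLOT_INDEX
from .growth import Ensemble
from .pipeline import Member, Ulk1cPreset

MOL_CHAIN_ID = {"ATG13": "B", "ULK1": "A", "FIP200": "F", "HORMA": "H"}


class StructureFormatError(ValueError):
    """Malformed or unsupported structure input."""


# ---------------------------------------------------------------------------
# model assembly -> biotite AtomArray


def _atoms_of_chain(chain: Chain) -> list[tuple]:
    rows = []
    mask = chain.atom_mask()
    cid = MOL_CHAIN_ID.get(chain.molecule, "X")
    for i, resid in enumerate(chain.resids):
        for name, j in SLOT_INDEX.items():
            if mask[i, j]:
                rows.append((cid, int(resid), chain.seq[i], name, chain.coords[i, j]))
    return rows


def _atoms_of_body(body: RigidBody) -> list[tuple]:
    rows = []
    for (mol, resid, name), xyz in zip(body.labels, body.coords):
        if name == "XX":      # virtual markers are not written
            continue
        rows.append((MOL_CHAIN_ID.get(mol, "X"), int(resid), "X", name, xyz))
    return rows


_AA3 = {"A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
        "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
        "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
        "V": "VAL", "Y": "TYR", "X": "UNK"}
_AA1 = {v: k for k, v in _AA3.items()}


def member_to_atom_array(member: Member) -> struc.AtomArray:
    rows = []
    for chain in member.chains.values():
        rows += _atoms_of_chain(chain)
    for body in member.bodies.values():
        rows += _atoms_of_body(body)
    arr = struc.AtomArray(len(rows))
    arr.coord = np.array([r[4] for r in rows])
    arr.chain_id = np.array([r[0] for r in rows])
    arr.res_id = np.array([r[1] for r in rows], dtype=int)
    arr.res_name = np.array([_AA3.get(r[2], "UNK") for r in rows])
    arr.atom_name = np.array([r[3] for r in rows])
    arr.element = np.array(["S" if r[3] == "SG" else r[3][0] for r in rows])
    arr.hetero = np.zeros(len(rows), dtype=bool)
    return arr


def write_ensemble(ensemble: Ensemble, path: str | Path) -> Path:
    """Write an ensemble as a multi-model PDB (MODEL = 1-based member index).

    Byte-stable for identical input; all members must have identical atom
    layout (true for one condition of one replica).
    """
    if len(ensemble) < 1:
        raise ValueError("cannot write an empty ensemble")
    arrays = []
    for m in ensemble:
        arrays.append(member_to_atom_array(m) if isinstance(m, Member)
                      else _chain_atom_array(m))
    stack = struc.stack(arrays)
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    path = Path(path)
    f.write(str(path))
    return path


def _chain_atom_array(chain: Chain) -> struc.AtomArray:
    rows = _atoms_of_chain(chain)
    for att in chain.attachments:
        rows += _atoms_of_body(att.body)
    arr = struc.AtomArray(len(rows))
    arr.coord = np.array([r[4] for r in rows])
    arr.chain_id = np.array([r[0] for r in rows])
    arr.res_id = np.array([r[1] for r in rows], dtype=int)
    arr.res_name = np.array([_AA3.get(r[2], "UNK") for r in rows])
    arr.atom_name = np.array([r[3] for r in rows])
    arr.element = np.array(["S" if r[3] == "SG" else r[3][0] for r in rows])
    arr.hetero = np.zeros(len(rows), dtype=bool)
    return arr


def write_body(body: RigidBody, path: str | Path) -> Path:
    arr_rows = _atoms_of_body(body)
    arr = struc.AtomArray(len(arr_rows))
    arr.coord = np.array([r[4] for r in arr_rows])
    arr.chain_id = np.array([r[0] for r in arr_rows])
    arr.res_id = np.array([r[1] for r in arr_rows], dtype=int)
    arr.res_name = np.full(len(arr_rows), "UNK")
    arr.atom_name = np.array([r[3] for r in arr_rows])
    arr.element = np.array(["S" if r[3] == "SG" else r[3][0] for r in arr_rows])
    arr.hetero = np.zeros(len(arr_rows), dtype=bool)
    f = pdb.PDBFile()
    pdb.set_structure(f, arr)
    path = Path(path)
    f.write(str(path))
    return path


# ---------------------------------------------------------------------------
# reading


def read_structure(path: str | Path, require_backbone: bool = True
                   ) -> dict[str, list[dict]]:
    """Read a (multi-model) PDB into per-model, per-chain residue tables.

    Returns a dict ``chain_id -> list of models``, each model a dict
    ``resid -> {atom_name: xyz}``; author residue numbers preserved.
    Insertion codes are rejected; with ``require_backbone`` (the default for
    chain input), residues lacking the N/CA/C backbone are rejected with an
    error naming them (disable to read rigid-body/CA-trace files).
    """
    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(altloc="first")
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if np.any(stack.ins_code != ""):
        raise StructureFormatError("insertion codes are not supported")
    out: dict[str, list[dict]] = {}
    for model in stack:
        per_chain: dict[str, dict[int, dict[str, np.ndarray]]] = {}
        for at in model:
            per_chain.setdefault(at.chain_id, {}).setdefault(
                int(at.res_id), {})[at.atom_name] = np.asarray(at.coord)
        for cid, residues in per_chain.items():
            if require_backbone:
                missing = [r for r, atoms in sorted(residues.items())
                           if not {"N", "CA", "C"} <= set(atoms)]
                if missing:
                    raise StructureFormatError(
                        f"chain {cid}: residues missing backbone atoms: {missing}")
            out.setdefault(cid, []).append(dict(sorted(residues.items())))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    f = fasta.FastaFile.read(str(path))
    return {name.split()[0]: str(seq) for name, seq in f.items()}


# ---------------------------------------------------------------------------
# run configuration and provenance


_CONFIG_KEYS = {"seed", "n", "replicas", "out_dir", "membrane_z0", "d_mem",
                "d_bind", "plane_tolerance", "align_threshold", "clash_cutoff"}


def load_config(path: str | Path | None) -> dict:
    """Flat YAML config; unknown keys are errors, defaults are materialized."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return raw


def preset_from_config(cfg: dict) -> Ulk1cPreset:
    kwargs = {}
    for key in ("membrane_z0", "d_mem", "d_bind", "plane_tolerance",
                "align_threshold"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    if "n" in cfg:
        kwargs["n_per_condition"] = int(cfg["n"])
    if "replicas" in cfg:
        kwargs["replicas"] = int(cfg["replicas"])
    return Ulk1cPreset(**kwargs)


def write_provenance(out_dir: str | Path, config: dict, seed: int,
                     extra: dict | None = None) -> Path:
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"package_version": __version__, "seed": seed,
               "config": {k: (v if not dataclasses.is_dataclass(v)
                              else dataclasses.asdict(v))
                          for k, v in config.items()},
               **(extra or {})}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def write_distance_table(path: str | Path, distances_nm, meta: list[dict],
                         condition: str) -> Path:
    """TSV of per-member distances plus junction/selection metadata."""
    import pandas as pd
    rows = []
    for i, d in enumerate(distances_nm):
        m = meta[i] if i < len(meta) else {}
        rows.append({"member": i, "condition": condition,
                     "replica": m.get("replica", ""),
                     "kd_membrane_distance_nm": d,
                     "junction_rmsd_A": m.get("junction_rmsd", "")})
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
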