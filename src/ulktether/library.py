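"""Dihedral sampling libraries for coil-like disordered segments.

The packaged default is a four-class (generic / Gly / Pro / pre-Pro) coil
basin library with Gaussian jitter around basin centres; it stands in for an
MD-derived fragment library and can be replaced by any file in the same
JSON layout (class -> list of [phi, psi, weight]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import wrap_angle

CLASSES = ("generic", "gly", "pro", "prepro")


def residue_class(aa: str, next_aa: str | None) -> str:
    """Class of a residue given its identity and the following residue."""
    if aa == "P":
        return "pro"
    if next_aa == "P":
        return "prepro"
    if aa == "G":
        return "gly"
    return "generic"


@dataclass(frozen=True)
class DihedralLibrary:
    """Weighted (phi, psi) basins per residue class, with sampling jitter."""

    angles: dict[str, np.ndarray]    # class -> (k, 2) basin centres, degrees
    weights: dict[str, np.ndarray]   # class -> (k,) probabilities
    jitter_deg: float = 0.0

    def __post_init__(self):
        for cls in CLASSES:
            if cls not in self.angles or cls not in self.weights:
                raise ValueError(f"library missing residue class {cls!r}")
            w = self.weights[cls]
            if abs(float(w.sum()) - 1.0) > 1e-9 or np.any(w < 0):
                raise ValueError(f"weights for class {cls!r} must sum to 1")
            a = self.angles[cls]
            if np.any(a <= -180.0) or np.any(a > 180.0):
                raise ValueError(f"angles for class {cls!r} outside (-180, 180]")
        object.__setattr__(self, "_cumw",
                           {c: np.cumsum(self.weights[c]) for c in CLASSES})

    @classmethod
    def from_dict(cls, payload: dict) -> "DihedralLibrary":
        angles, weights = {}, {}
        for name, rows in payload["classes"].items():
            arr = np.asarray(rows, dtype=float)
            angles[name] = arr[:, :2]
            w = arr[:, 2]
            weights[name] = w / w.sum()
        return cls(angles, weights, float(payload.get("jitter_deg", 0.0)))

    @classmethod
    def from_file(cls, path) -> "DihedralLibrary":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "DihedralLibrary":
        text = resources.files("ulktether.data").joinpath("coil_library.json").read_text()
        return cls.from_dict(json.loads(text))

    def sample(self, sequence: str, rng: np.random.Generator,
               next_aa: str | None = None,
               jitter_deg: float | None = None) -> np.ndarray:
        """Draw (phi, psi, omega) rows for every residue of ``sequence``.

        ``next_aa`` is the residue following the segment (for the pre-Pro
        class of the last residue); omega is always 180 (trans only).
        """
        jit = self.jitter_deg if jitter_deg is None else jitter_deg
        n = len(sequence)
        out = np.empty((n, 3))
        out[:, 2] = 180.0
        classes = [residue_class(aa, sequence[i + 1] if i + 1 < n else next_aa)
                   for i, aa in enumerate(sequence)]
        u = rng.random(n)
        jitter = jit * rng.standard_normal((n, 2)) if jit > 0 else np.zeros((n, 2))
        cumw = self._cumw
        for i, cls in enumerate(classes):
            k = int(np.searchsorted(cumw[cls], u[i]))
            k = min(k, len(self.weights[cls]) - 1)
            out[i, :2] = self.angles[cls][k] + jitter[i]
        out[:, :2] = wrap_angle(out[:, :2])
        return out


@dataclass(frozen=True)
class VirtualBondLibrary:
    """Freely-jointed virtual-bond test mode: CA-only chains with uniformly
    random bond directions of fixed length ``b`` (A).  Used for closed-form
    polymer checks of the sampling machinery, not for protein modeling."""

    b: float = 3.8
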