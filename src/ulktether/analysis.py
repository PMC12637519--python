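"""Ensemble observables: kinase-to-membrane distances, accessible volume.

Distances are measured in Angstrom internally and reported in nm; the
accessible volume of a tethered domain with maximum extension r_max is
modeled as the hemisphere above the membrane, V = (2/3) pi r_max^3, so the
fold change between two maximum extensions is (r1/r2)^3 independent of the
shape prefactor.  The same cube law gives the local-concentration fold
increase near the membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import MembranePlane
from .growth import Ensemble
from .pipeline import Member

A_PER_NM = 10.0


@dataclass(frozen=True)
class DistanceSummary:
    """Per-member kinase-to-membrane distances (nm) with summary statistics."""

    distances: np.ndarray
    mean: float
    sd: float
    maximum: float
    bin_edges: np.ndarray
    counts: np.ndarray
    condition: str = ""
    replica: int | None = None

    def to_dict(self) -> dict:
        return {"condition": self.condition, "replica": self.replica,
                "n": int(len(self.distances)), "mean_nm": self.mean,
                "sd_nm": self.sd, "max_nm": self.maximum,
                "bin_edges_nm": self.bin_edges.tolist(),
                "counts": self.counts.tolist()}


@dataclass(frozen=True)
class VolumeEstimate:
    """Hemispherical accessible volume for a maximum tether extension."""

    r_max: float            # nm
    volume: float           # nm^3
    model: str = "hemisphere"

    def fold_change(self, other: "VolumeEstimate") -> float:
        return self.volume / other.volume


def kd_membrane_distance(member: Member, plane: MembranePlane) -> float:
    """Distance (nm) from the kinase-domain backbone centre to the plane."""
    com = member.kd_com()
    return (float(com[2]) - plane.z0) / A_PER_NM


def member_distances(ensemble: Ensemble, plane: MembranePlane) -> np.ndarray:
    return np.array([kd_membrane_distance(m, plane) for m in ensemble])


def summarize(ensemble: Ensemble, plane: MembranePlane,
              bin_width_nm: float = 1.0, condition: str = "",
              replica: int | None = None) -> DistanceSummary:
    """Mean/SD/max and histogram of kinase-to-membrane distances (nm).

    Deterministic and invariant under member permutation; histogram bins are
    ``bin_width_nm`` wide from 0 to ceil(max) + 1.
    """
    if len(ensemble) < 1:
        raise ValueError("empty ensemble")
    d = member_distances(ensemble, plane)
    top = math.ceil(max(float(d.max()), 0.0)) + 1.0
    edges = np.arange(0.0, top + bin_width_nm / 2, bin_width_nm)
    counts, edges = np.histogram(d, bins=edges)
    return DistanceSummary(np.sort(d), float(d.mean()), float(d.std(ddof=0)),
                           float(d.max()), edges, counts,
                           condition=condition, replica=replica)


def accessible_volume(r_max: float) -> VolumeEstimate:
    """Hemispherical volume (nm^3) explorable with maximum extension r_max (nm)."""
    if not r_max > 0:
        raise ValueError("r_max must be positive")
    return VolumeEstimate(r_max, (2.0 / 3.0) * math.pi * r_max ** 3)


def volume_fold_change(r1: float, r2: float) -> float:
    """Accessible-volume fold change (r1/r2)^3; equals the fold increase in
    local concentration near the membrane when the extension shrinks."""
    if not (r1 > 0 and r2 > 0):
        raise ValueError("extensions must be positive")
    return (r1 / r2) ** 3


def bootstrap_mean_less(a: np.ndarray, b: np.ndarray, n_boot: int = 2000,
                        rng: np.random.Generator | None = None) -> float:
    """One-sided bootstrap confidence that mean(a) < mean(b).

    Returns the fraction of bootstrap resamples in which the mean of ``a``
    is below the mean of ``b``.
    """
    rng = rng or np.random.default_rng(0)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    return float(np.mean(a[ia].mean(axis=1) < b[ib].mean(axis=1)))
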