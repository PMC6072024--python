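"""Extracellular potential by the line-source method.

Each membrane segment carries a uniformly distributed transmembrane
current; the extracellular medium is an infinite homogeneous isotropic
volume conductor of conductivity σ (S/m).  The potential a segment
produces at an electrode site then has a closed form (the potential of a
finite line of uniform current density), and the potential at site m from
one cell is

    Φ_m(t) = Σ_n R_mn I_n(t)

with ``I_n`` the transmembrane current of segment n (nA) and ``R_mn`` the
*transfer resistance* (MΩ, so MΩ · nA = mV).  ``R_mn`` depends only on
geometry and σ, so it is computed once per cell at setup; contributions of
all cells superpose linearly at every electrode.

With Δs the segment length, r the radial distance from the site to the
segment's line (clamped below at the segment radius — an electrode cannot
sit inside the membrane), h the signed longitudinal distance from the
site's projection to the near end and l = h + Δs:

    R = 1/(4πσΔs) · ln| (√(h²+r²) − h) / (√(l²+r²) − l) |

which reduces to the point-source form R = 1/(4πσd) in the far field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .morphology import Segment

__all__ = [
    "ExtracellularMedium", "ElectrodeArray",
    "point_transfer_resistance", "line_transfer_resistance",
    "build_transfer_matrix", "accumulate_lfp",
]

# 1/(4πσ) with σ in S/m and distances in μm yields MΩ directly:
# R[Ω] = 1/(4πσ d[m]) = 1e6/(4πσ d[μm]) Ω = 1/(4πσ d[μm]) MΩ.


@dataclass
class ExtracellularMedium:
    """Homogeneous isotropic volume conductor."""
    sigma: float = 0.3        # S/m

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0 S/m, got {self.sigma}")


@dataclass
class ElectrodeArray:
    """Recording sites: ids plus 3-D positions in μm."""
    ids: np.ndarray
    positions: np.ndarray     # (n_sites, 3)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_sites, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("electrode positions must be finite")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("electrode ids must be unique")
        if len(self.ids) != len(self.positions):
            raise ValueError("ids and positions length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.ids)

    @classmethod
    def from_csv(cls, path: str) -> "ElectrodeArray":
        """Load a layout CSV with columns id, x, y, z (μm)."""
        df = pd.read_csv(path)
        missing = {"id", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(ids=df["id"].to_numpy(),
                   positions=df[["x", "y", "z"]].to_numpy(dtype=float))

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"id": self.ids,
                      "x": self.positions[:, 0],
                      "y": self.positions[:, 1],
                      "z": self.positions[:, 2]}).to_csv(path, index=False)


def point_transfer_resistance(sigma: float, site: Sequence[float],
                              point: Sequence[float]) -> float:
    """Point-source transfer resistance 1/(4πσd) in MΩ (d in μm)."""
    d = float(np.linalg.norm(np.asarray(site, float)
                             - np.asarray(point, float)))
    if d == 0.0:
        raise ValueError("site coincides with the source point")
    return 1.0 / (4.0 * math.pi * sigma * d)


def line_transfer_resistance(sigma: float, a: Sequence[float],
                             b: Sequence[float], site: Sequence[float],
                             radius: float = 0.0) -> float:
    """Uniform-line-source transfer resistance in MΩ.

    ``a``/``b`` are the segment endpoints (μm); the radial distance of the
    site from the segment's line is clamped below at ``radius`` so the
    logarithmic on-axis singularity is never reached.  Symmetric under
    endpoint swap.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    site = np.asarray(site, dtype=float)
    axis = b - a
    ds = float(np.linalg.norm(axis))
    if ds <= 0.0:
        raise ValueError("degenerate segment (zero length)")
    u = axis / ds
    rel = site - a
    proj = float(rel @ u)                 # longitudinal coord of the site
    r2 = float(rel @ rel) - proj * proj
    r = math.sqrt(max(r2, 0.0))
    r = max(r, radius)
    h = -proj                             # site projection -> near end a
    l = h + ds
    num = math.hypot(h, r) - h
    den = math.hypot(l, r) - l
    # rewrite whichever branch is catastrophic (x>0: √(x²+r²)−x ~ r²/2x)
    if h > 0:
        num = r * r / (math.hypot(h, r) + h)
    if l > 0:
        den = r * r / (math.hypot(l, r) + l)
    return abs(math.log(num / den)) / (4.0 * math.pi * sigma * ds)


def build_transfer_matrix(medium: ExtracellularMedium,
                          array: ElectrodeArray,
                          segments: List[Segment]) -> np.ndarray:
    """Transfer matrix R_mn (MΩ), sites × segments, for one placed cell.

    ``segments`` must be in world coordinates (soma position and rotation
    applied).  Computed once per cell at setup; every simulation step then
    costs one matrix-vector product per cell.
    """
    if not segments:
        raise ValueError("cell has no segments")
    R = np.empty((array.n_sites, len(segments)))
    for m, site in enumerate(array.positions):
        for n, seg in enumerate(segments):
            R[m, n] = line_transfer_resistance(
                medium.sigma, seg.a, seg.b, site, radius=seg.radius)
    if not np.all(np.isfinite(R)) or np.any(R <= 0):
        raise FloatingPointError("non-finite or non-positive transfer "
                                 "resistance encountered")
    return R


def accumulate_lfp(phi: np.ndarray, transfer: np.ndarray,
                   i_membrane: np.ndarray) -> np.ndarray:
    """Add one cell's contribution ``R @ I`` (mV) to the running per-site
    potentials ``phi`` for the current step; exact superposition."""
    if transfer.shape[1] != i_membrane.shape[0] or \
            transfer.shape[0] != phi.shape[0]:
        raise ValueError(
            f"shape mismatch: phi {phi.shape}, transfer {transfer.shape}, "
            f"currents {i_membrane.shape}")
    phi += transfer @ i_membrane
    return phi
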