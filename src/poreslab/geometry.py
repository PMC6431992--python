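"""Membrane/pore geometry: region classification and surface distances.

The system is a chain on the cis side (z >= 0) of a membrane of thickness
L pierced by a cylindrical pore of diameter D centered on the z-axis; a
second membrane at z = -(L + R) bounds the laterally unbounded trans slab.
Membranes are modeled as smooth analytic solids (half-space-with-hole and
half-space); distances are true Euclidean distances to the nearest surface
point, so the derived wall energy field is continuous, including at the
pore rim.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import SimParams

__all__ = ["Region", "Conformation", "classify_region", "wall_gap",
           "INSIDE_MATERIAL"]

#: Sentinel returned by :func:`wall_gap` for points inside membrane material.
INSIDE_MATERIAL = -1.0


class Region(enum.Enum):
    """Mutually exclusive, exhaustive labels for any point in space."""

    CIS = "cis"
    PORE = "pore"
    TRANS = "trans"
    MEMBRANE_EXCLUDED = "membrane_excluded"


_CODE_TO_REGION = {
    _kernels.CIS: Region.CIS,
    _kernels.PORE: Region.PORE,
    _kernels.TRANS: Region.TRANS,
    _kernels.MEMBRANE: Region.MEMBRANE_EXCLUDED,
}


@dataclass
class Conformation:
    """Positions of the N+1 monomers; monomer 0 is the leading (head) end."""

    positions: np.ndarray  # shape (N+1, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N+1, 3)")

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def regions(self, params: SimParams) -> list[Region]:
        return [classify_region(p, params) for p in self.positions]


def classify_region(pos, params: SimParams) -> Region:
    """Classify a point as CIS, PORE, TRANS or MEMBRANE_EXCLUDED.

    CIS is the half-space z >= 0; PORE the open cylinder -L < z < 0,
    x^2 + y^2 < (D/2)^2; TRANS the open slab -(L+R) < z <= -L outside
    membrane material; everything else is membrane material.
    """
    x, y, z = (float(v) for v in pos)
    code = _kernels.region_code(x, y, z, params.l_pore, params.r_sep,
                                params.pore_radius)
    return _CODE_TO_REGION[code]


def wall_gap(pos, params: SimParams) -> float:
    """Shortest Euclidean distance from a point to the confining surfaces.

    Returns :data:`INSIDE_MATERIAL` (-1.0) for points inside membrane
    material. On a surface the gap is exactly 0. For points beyond the
    wall interaction range the downstream wall energy is exactly zero.
    """
    x, y, z = (float(v) for v in pos)
    return float(_kernels.wall_gap_open(x, y, z, params.l_pore, params.r_sep,
                                        params.pore_radius))


def straight_chain(params: SimParams, z0: float | None = None) -> Conformation:
    """A straight rod along +z with every bond at l0 (the relax seed state)."""
    if z0 is None:
        z0 = params.z_park
    n1 = params.n_monomers
    pos = np.zeros((n1, 3))
    pos[:, 2] = z0 + params.l0 * np.arange(n1)
    return Conformation(pos)
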