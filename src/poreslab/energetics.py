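"""Potential-energy terms of the bead-spring chain and their increments.

Total energy: U = U_FENE + U_Morse + U_bend + U_wall + U_elec, all in
k_B*T. Bonds are FENE springs confined to (lmin, lmax); excluded volume
between non-bonded monomers (|i-j| > 1) is a Morse potential with minimum
-eps at rmin, truncated at r_cut; bending costs kappa*(1 + cos theta)
with theta the interior angle between consecutive bonds (theta = pi, i.e.
a straight chain, costs nothing); walls repel through the positive branch
of the same Morse form, exactly zero beyond rmin; and a uniform field
inside the pore lowers the potential of each unit charge by q*E*L across
the pore length.

An out-of-range bond or a position inside membrane material is reported
as ``math.inf`` — an infinite-energy sentinel the Metropolis kernel always
rejects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import Conformation, Region
from .params import SimParams

__all__ = ["EnergyBreakdown", "fene_energy", "morse_energy", "bend_energy",
           "wall_energy", "electric_energy", "total_energy", "delta_energy"]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies of one conformation, in k_B*T."""

    u_fene: float
    u_morse: float
    u_bend: float
    u_wall: float
    u_elec: float

    @property
    def u_total(self) -> float:
        return self.u_fene + self.u_morse + self.u_bend + self.u_wall + self.u_elec

    def as_row(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("u_fene", "u_morse", "u_bend", "u_wall", "u_elec")}
        d["u_total"] = self.u_total
        return d


def _to_inf(v: float) -> float:
    # the compiled kernels use a large finite rejection sentinel; the
    # public contract is an infinite-energy sentinel
    return math.inf if v >= 0.5 * _kernels.BIG else float(v)


def fene_energy(l: float, params: SimParams) -> float:
    """FENE bond energy -(k r0^2 / 2) ln(1 - ((l - l0)/r0)^2).

    Zero at the preferred length l0, divergent at the bounds; lengths at
    or outside (lmin, lmax) return the infinite sentinel.
    """
    return _to_inf(_kernels.fene_scalar(l, params.k_spring, params.l0,
                                        params.r0, params.lmin, params.lmax))


def morse_energy(r: float, params: SimParams) -> float:
    """Morse pair energy eps*(e^(-2a(r-rmin)) - 2 e^(-a(r-rmin))).

    Minimum -eps at rmin; truncated to exactly 0 beyond r_cut (where its
    magnitude is < 1e-7 for the default parameters).
    """
    if r >= params.r_cut:
        return 0.0
    return float(_kernels.morse_scalar(r, params.eps_morse, params.alpha_morse,
                                       params.rmin_morse))


def bend_energy(theta: float, kappa: float) -> float:
    """Angle energy kappa*(1 + cos theta).

    theta is the interior angle between consecutive bonds: collinear bonds
    have theta = pi and zero energy; a full backfold (theta = 0) costs
    2*kappa.
    """
    return kappa * (1.0 + math.cos(theta))


def wall_energy(r: float, params: SimParams) -> float:
    """Repulsive wall potential as a function of distance r to a wall monomer.

    Shifted Morse: eps*(e^(-2a(r-rmin)) - 2 e^(-a(r-rmin))) + eps for
    r <= rmin and exactly 0 beyond, continuous (value 0) at r = rmin.
    A negative r (the inside-material sentinel) maps to infinite energy.

    The walls consist of immobile monomers of diameter sigma = rmin whose
    centers sit sigma/2 inside the material surface, so chain energies
    evaluate this at r = wall_gap + wall_offset.
    """
    if r < 0:
        return math.inf
    return float(_kernels.wall_pot_scalar(r, params.eps_morse,
                                          params.alpha_morse,
                                          params.rmin_morse))


def electric_energy(z: float, region: Region | None, params: SimParams) -> float:
    """Electric potential energy of one monomer at axial coordinate z.

    Zero on the cis side, q*E*z across the pore column, constant -q*E*L
    past the pore exit: the field exerts force -q*E only inside the pore,
    and the total drop per monomer over a full passage is q*E*L.
    """
    return float(_kernels.elec_scalar(z, params.q_charge * params.e_field,
                                      params.l_pore))


def total_energy(conf: Conformation, params: SimParams, *,
                 closed_pore: bool = False,
                 skip_wall_first: bool = False) -> EnergyBreakdown:
    """Full per-term energy of a conformation.

    FENE over the N bonds, Morse over all |i-j| > 1 pairs within r_cut,
    bending over the N-1 interior angles, wall and electric terms over all
    monomers. ``closed_pore`` selects the relaxation-phase wall (the full
    z = 0 plane); ``skip_wall_first`` omits the held head monomer's wall
    term during relaxation.
    """
    pos = np.ascontiguousarray(conf.positions, dtype=float)
    u = _kernels.total_energy_terms(
        pos, params.k_spring, params.l0, params.r0, params.lmin, params.lmax,
        params.eps_morse, params.alpha_morse, params.rmin_morse, params.r_cut,
        params.kappa, params.q_charge * params.e_field, params.l_pore,
        params.r_sep, params.pore_radius, params.wall_offset,
        closed_pore, skip_wall_first)
    return EnergyBreakdown(*(_to_inf(v) for v in u))


def delta_energy(conf: Conformation, moved_index: int, trial_pos,
                 params: SimParams, *, closed_pore: bool = False,
                 skip_wall_first: bool = False) -> float:
    """Energy change of moving one monomer to trial_pos.

    Touches only the terms involving the moved monomer (its <= 2 bonds,
    <= 3 angles, its non-bonded pairs within r_cut, its wall and electric
    terms); equals total_energy(after) - total_energy(before) exactly.
    Returns the infinite sentinel for a bond driven out of (lmin, lmax)
    or a trial position inside membrane material.
    """
    n1 = conf.n_monomers
    if not 0 <= moved_index < n1:
        raise IndexError(f"moved_index {moved_index} out of range 0..{n1 - 1}")
    pos = np.ascontiguousarray(conf.positions, dtype=float)
    px, py, pz = (float(v) for v in trial_pos)
    return _to_inf(_kernels.delta_energy_kernel(
        pos, moved_index, px, py, pz, params.k_spring, params.l0, params.r0,
        params.lmin, params.lmax, params.eps_morse, params.alpha_morse,
        params.rmin_morse, params.r_cut, params.kappa,
        params.q_charge * params.e_field, params.l_pore, params.r_sep,
        params.pore_radius, params.wall_offset,
        1 if closed_pore else 0, skip_wall_first))
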