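"""Metropolis dynamic Monte Carlo engine and the translocation protocol.

Protocol per sample: (1) hold the head monomer at the closed pore mouth
and equilibrate the rest of the chain on the cis side; (2) at t = 0
release the head and open the pore; (3) advance single-monomer Metropolis
dynamics — one Monte Carlo step (MCS) is N+1 trial moves and is the time
unit — logging pore occupancy every MCS; (4) if the chain fully retreats
to cis after having engaged the pore, restart from the stored
equilibrated conformation with the clock reset; (5) finish when every
monomer has passed the pore exit plane. The elapsed MCS of the successful
attempt is the translocation time tau.

The hot loops live in :mod:`poreslab._kernels` (numba); this module owns
the typed records, seeding policy, and ensemble aggregation. Samples are
embarrassingly parallel and each is reproducible from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import Conformation
from .params import SimParams

__all__ = ["EngineState", "TranslocationRecord", "EnsembleResult",
           "metropolis_accept", "trial_move", "relax", "run_translocation",
           "run_ensemble", "sample_free_chain"]

_SEED_MOD = 2**31 - 1


def _phase_seeds(seed: int) -> tuple[int, int]:
    # independent streams for the relax and translocation phases,
    # both derived from the single per-sample seed
    return (2 * seed) % _SEED_MOD, (2 * seed + 1) % _SEED_MOD


@dataclass
class EngineState:
    """Mutable state of one Metropolis chain (reference-path API).

    The compiled kernels carry the same state implicitly; this object
    backs the step-by-step Python interface used for validation and
    diagnostics.
    """

    conformation: Conformation
    rng: np.random.Generator
    phase: str = "RELAXING"  # RELAXING | TRANSLOCATING | DONE
    trial_count: int = 0
    accept_count: int = 0

    @property
    def mcs_clock(self) -> int:
        return self.trial_count // self.conformation.n_monomers


@dataclass(frozen=True)
class TranslocationRecord:
    """One successful (or failed) translocation sample."""

    tau: int                    # MCS from release to completion
    waiting: np.ndarray         # per-monomer pore residence time W(s), MCS
    last_exit: np.ndarray       # per-monomer last pore-exit time, MCS
    attempts: int               # withdrawn-and-restarted tries, >= 1
    acceptance_rate: float      # accepted / trial moves over the sample
    final_conformation: Conformation
    seed: int
    success: bool
    relax_mcs_used: int
    snapshots: np.ndarray | None = None   # (n_frames, N+1, 3) if requested
    snapshot_every: int = 0


@dataclass
class EnsembleResult:
    """Aggregate of independent samples at one parameter point."""

    params: SimParams
    records: list[TranslocationRecord]
    n_failed: int = 0

    tau_mean: float = field(init=False)
    tau_se: float = field(init=False)
    w_mean: np.ndarray = field(init=False)
    w_se: np.ndarray = field(init=False)
    acceptance_mean: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("ensemble has no successful records")
        taus = np.array([r.tau for r in self.records], dtype=float)
        self.tau_mean = float(taus.mean())
        n = len(taus)
        self.tau_se = float(taus.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        w = np.stack([r.waiting for r in self.records]).astype(float)
        self.w_mean = w.mean(axis=0)
        self.w_se = (w.std(axis=0, ddof=1) / math.sqrt(n)
                     if n > 1 else np.full(w.shape[1], np.nan))
        self.acceptance_mean = float(
            np.mean([r.acceptance_rate for r in self.records]))

    @property
    def taus(self) -> np.ndarray:
        return np.array([r.tau for r in self.records], dtype=float)

    @property
    def n_success(self) -> int:
        return len(self.records)


def metropolis_accept(delta_u: float, rng: np.random.Generator,
                      kbt: float = 1.0) -> bool:
    """Standard Metropolis acceptance: probability min(1, e^(-dU/kT)).

    The infinite-energy sentinel is always rejected.
    """
    if delta_u <= 0.0:
        return True
    if math.isinf(delta_u):
        return False
    return rng.random() < math.exp(-delta_u / kbt)


def trial_move(state: EngineState, params: SimParams) -> tuple[int, np.ndarray]:
    """Propose one single-monomer move.

    The monomer index is uniform over the movable set (the held head
    monomer is excluded while RELAXING); each coordinate increment is
    uniform on (-step_max, step_max).
    """
    if state.phase == "DONE":
        raise RuntimeError("engine is DONE; no further moves")
    n1 = state.conformation.n_monomers
    lo = 1 if state.phase == "RELAXING" else 0
    i = int(state.rng.integers(lo, n1))
    delta = state.rng.uniform(-params.step_max, params.step_max, size=3)
    return i, state.conformation.positions[i] + delta


def _kernel_args(params: SimParams) -> tuple:
    return (params.k_spring, params.l0, params.r0, params.lmin, params.lmax,
            params.eps_morse, params.alpha_morse, params.rmin_morse,
            params.r_cut, params.kappa, params.q_charge * params.e_field,
            params.l_pore, params.r_sep, params.pore_radius,
            params.wall_offset)


def relax(params: SimParams, seed: int) -> tuple[Conformation, int]:
    """Equilibrate the chain on the cis side with the pore closed.

    Starts from a straight rod (head held at (0, 0, z_park)), freezes the
    head, reflects all other monomers at z = 0, and runs Metropolis until
    the windowed mean total energy of consecutive windows of
    ``relax_window`` MCS agrees to ``relax_tol`` relative (at least
    ``relax_mcs``, at most ``relax_max_mcs`` MCS). Returns the
    conformation and the MCS spent.
    """
    pos, mcs = _kernels.relax_kernel(
        params.n_monomers, *_kernel_args(params), params.step_max,
        params.kbt, params.z_park, params.relax_mcs, params.relax_max_mcs,
        params.relax_window, params.relax_tol, int(seed) % _SEED_MOD)
    return Conformation(pos), int(mcs)


def run_translocation(params: SimParams, seed: int, *,
                      snapshot_every: int = 0,
                      max_snapshots: int = 1000) -> TranslocationRecord:
    """Run one full sample (relax + driven translocation) from one seed.

    Identical seed and params give a bit-identical record. A sample whose
    total MCS (restarts included) exceeds ``max_mcs`` is returned with
    ``success=False`` and is excluded from ensemble statistics.
    """
    s_relax, s_run = _phase_seeds(int(seed))
    conf_eq, relax_used = relax(params, s_relax)
    n1 = params.n_monomers
    n_buf = max_snapshots if snapshot_every > 0 else 0
    snap_buf = np.empty((n_buf, n1, 3))
    (tau, waiting, last_exit, attempts, accepts, trials, pos, status,
     n_snaps) = _kernels.translocate_kernel(
        conf_eq.positions, *_kernel_args(params), params.step_max,
        params.kbt, params.max_mcs, s_run, snapshot_every, snap_buf)
    return TranslocationRecord(
        tau=int(tau),
        waiting=np.asarray(waiting),
        last_exit=np.asarray(last_exit),
        attempts=int(attempts),
        acceptance_rate=float(accepts) / float(trials) if trials else 0.0,
        final_conformation=Conformation(pos),
        seed=int(seed),
        success=(status == _kernels.DONE),
        relax_mcs_used=relax_used,
        snapshots=snap_buf[:n_snaps].copy() if snapshot_every > 0 else None,
        snapshot_every=snapshot_every,
    )


def run_ensemble(params: SimParams, n_samples: int | None = None,
                 base_seed: int | None = None, *,
                 progress: bool = False) -> EnsembleResult:
    """Run independent samples with seeds base_seed + i and aggregate.

    Results depend only on (params, n_samples, base_seed), not on
    execution order. Failed samples (max_mcs exceeded) are counted in
    ``n_failed`` and excluded from tau and W(s) statistics.
    """
    n = params.n_samples if n_samples is None else int(n_samples)
    s0 = params.base_seed if base_seed is None else int(base_seed)
    if n < 1:
        raise ValueError("n_samples must be >= 1")
    records = []
    n_failed = 0
    for i in range(n):
        rec = run_translocation(params, s0 + i)
        if rec.success:
            records.append(rec)
        else:
            n_failed += 1
        if progress and (i + 1) % max(1, n // 10) == 0:
            print(f"  sample {i + 1}/{n}  "
                  f"(failed so far: {n_failed})", flush=True)
    return EnsembleResult(params=params, records=records, n_failed=n_failed)


def sample_free_chain(params: SimParams, n_samples: int, *,
                      sample_every: int = 10, burn_mcs: int = 500,
                      fix_first: bool = False,
                      include_nonbonded: bool = True,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equilibrium samples of an isolated chain (no walls, no field).

    Returns (bond_lengths, cos_angles, end_to_end_sq) arrays of shape
    (n_samples, N), (n_samples, N-1) and (n_samples,); cos_angles uses
    the interior-angle convention (collinear bonds -> -1).
    ``include_nonbonded=False`` drops the |i-j| > 1 Morse pairs, making
    the bond and angle marginals exactly l^2 e^(-U_FENE(l)) and
    e^(-kappa(1+u)) — the closed forms used for Boltzmann validation.
    """
    bonds, cosang, ree2 = _kernels.free_chain_kernel(
        params.n_monomers, params.k_spring, params.l0, params.r0,
        params.lmin, params.lmax, params.eps_morse, params.alpha_morse,
        params.rmin_morse, params.r_cut, params.kappa, params.step_max,
        params.kbt, int(n_samples), int(sample_every), int(burn_mcs),
        fix_first, include_nonbonded, int(seed) % _SEED_MOD)
    nang = params.n_monomers - 2
    return (np.asarray(bonds), np.asarray(cosang)[:, :max(nang, 0)],
            np.asarray(ree2))
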