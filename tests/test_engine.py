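import math

import numpy as np
import pytest
from scipy import stats

from poreslab import (Conformation, SimParams, delta_energy,
                      metropolis_accept, relax, run_ensemble,
                      run_translocation, sample_free_chain, wall_gap)
from poreslab.engine import EngineState, trial_move


class TestMetropolisAccept:
    def test_downhill_and_zero_always_accepted(self, rng):
        assert all(metropolis_accept(-5.0, rng) for _ in range(100))
        assert all(metropolis_accept(0.0, rng) for _ in range(100))

    def test_infinite_sentinel_always_rejected(self, rng):
        assert not any(metropolis_accept(math.inf, rng) for _ in range(100))

    def test_uphill_rate_matches_boltzmann_factor(self, rng):
        # quick version; the high-precision check lives in the acceptance suite
        n = 20_000
        acc = sum(metropolis_accept(1.0, rng) for _ in range(n)) / n
        p = math.exp(-1.0)
        assert abs(acc - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestTrialMove:
    def _state(self, rng, n1=8, phase="TRANSLOCATING"):
        pos = np.zeros((n1, 3))
        pos[:, 2] = 1.0 + 0.7 * np.arange(n1)
        return EngineState(conformation=Conformation(pos), rng=rng, phase=phase)

    def test_increments_bounded_and_centered(self, rng):
        p = SimParams(n_bonds=7)
        st_ = self._state(rng)
        deltas = []
        for _ in range(20_000):
            i, trial = trial_move(st_, p)
            deltas.append(trial - st_.conformation.positions[i])
        d = np.array(deltas)
        assert np.abs(d).max() < p.step_max
        # SD of U(-a, a) is a/sqrt(3); 3.5 sigma since we take the worst
        # of three coordinates
        se = p.step_max / math.sqrt(3 * len(d))
        assert np.abs(d.mean(axis=0)).max() < 3.5 * se

    def test_head_frozen_while_relaxing(self, rng):
        p = SimParams(n_bonds=7)
        st_ = self._state(rng, phase="RELAXING")
        assert all(trial_move(st_, p)[0] != 0 for _ in range(2000))

    def test_index_uniform_over_allowed_set(self, rng):
        p = SimParams(n_bonds=7)
        st_ = self._state(rng)
        counts = np.zeros(8)
        n = 16_000
        for _ in range(n):
            counts[trial_move(st_, p)[0]] += 1
        chi2 = ((counts - n / 8) ** 2 / (n / 8)).sum()
        assert stats.chi2.sf(chi2, df=7) > 1e-3

    def test_done_state_refuses_moves(self, rng):
        st_ = self._state(rng, phase="DONE")
        with pytest.raises(RuntimeError):
            trial_move(st_, SimParams(n_bonds=7))


class TestRelax:
    def test_chain_stays_on_cis_side(self, params_small):
        conf, mcs = relax(params_small, seed=3)
        assert (conf.positions[1:, 2] >= 0).all()
        assert conf.positions[0, 2] == pytest.approx(params_small.z_park)
        assert mcs >= params_small.relax_mcs

    def test_bonds_remain_in_range(self, params_small):
        conf, _ = relax(params_small, seed=4)
        lengths = conf.bond_lengths()
        assert (lengths > params_small.lmin).all()
        assert (lengths < params_small.lmax).all()

    def test_flexible_coil_swells_superlinearly(self):
        """Excluded volume makes the mean-square end-to-end distance of a
        kappa=0 coil grow faster than linearly in N (Flory-type swelling:
        R^2 ~ N^(2*nu) with nu ~ 0.588 > 1/2)."""
        r2 = {}
        for n_bonds in (8, 24):
            p = SimParams(n_bonds=n_bonds, kappa=0.0)
            _, _, ree2 = sample_free_chain(p, 500, sample_every=40,
                                           burn_mcs=4000, seed=11,
                                           include_nonbonded=True)
            r2[n_bonds] = ree2.mean()
        assert r2[24] / r2[8] > 24 / 8


class TestRunTranslocation:
    def test_identical_seed_is_bit_identical(self, params_small):
        a = run_translocation(params_small, seed=123)
        b = run_translocation(params_small, seed=123)
        assert a.tau == b.tau and a.attempts == b.attempts
        assert np.array_equal(a.waiting, b.waiting)
        assert np.array_equal(a.final_conformation.positions,
                              b.final_conformation.positions)

    def test_different_seeds_differ(self, params_small):
        a = run_translocation(params_small, seed=123)
        b = run_translocation(params_small, seed=124)
        assert not np.array_equal(a.final_conformation.positions,
                                  b.final_conformation.positions)

    def test_completion_state_inside_slab(self, params_small, small_ensemble):
        p = params_small
        for rec in small_ensemble.records:
            z = rec.final_conformation.positions[:, 2]
            assert (z < -p.l_pore).all()
            assert (z > -(p.l_pore + p.r_sep)).all()
            for point in rec.final_conformation.positions:
                assert wall_gap(point, p) >= 0

    def test_waiting_vector_complete_and_positive(self, params_small,
                                                  small_ensemble):
        for rec in small_ensemble.records:
            assert len(rec.waiting) == params_small.n_monomers
            assert (rec.waiting > 0).all()
            assert rec.tau > 0 and rec.attempts >= 1

    def test_last_exit_of_slowest_monomer_is_tau(self, small_ensemble):
        for rec in small_ensemble.records:
            assert rec.last_exit.max() == rec.tau

    def test_max_mcs_marks_failure(self, params_small):
        p = params_small.replace(max_mcs=50)
        rec = run_translocation(p, seed=5)
        assert not rec.success

    def test_snapshots_recorded(self, params_small):
        rec = run_translocation(params_small, seed=7, snapshot_every=200)
        assert rec.snapshots is not None and len(rec.snapshots) >= 1
        assert rec.snapshots.shape[1:] == (params_small.n_monomers, 3)


class TestRunEnsemble:
    def test_mean_is_arithmetic_mean(self, small_ensemble):
        taus = [r.tau for r in small_ensemble.records]
        assert small_ensemble.tau_mean == pytest.approx(np.mean(taus))
        assert small_ensemble.tau_se == pytest.approx(
            np.std(taus, ddof=1) / math.sqrt(len(taus)))

    def test_same_base_seed_reproduces(self, params_small):
        a = run_ensemble(params_small, n_samples=3, base_seed=42)
        b = run_ensemble(params_small, n_samples=3, base_seed=42)
        assert a.tau_mean == b.tau_mean
        assert np.array_equal(a.w_mean, b.w_mean)

    def test_failures_counted_not_averaged(self, params_small):
        p = params_small.replace(max_mcs=50)
        with pytest.raises(ValueError):
            run_ensemble(p, n_samples=2, base_seed=0)


class TestFieldDrift:
    def test_single_charge_drifts_down_the_pore(self, rng):
        """A lone charged monomer in the pore feels force -qE and must
        drift toward trans on average."""
        p = SimParams(n_bonds=1, e_field=5.0, kappa=0.0, r_sep=5.0)
        drifts = []
        for rep in range(30):
            pos = np.array([[0.0, 0.0, -1.0]])
            for _ in range(50):
                conf = Conformation(pos)
                trial = pos[0] + rng.uniform(-0.25, 0.25, 3)
                du = delta_energy(conf, 0, trial, p)
                if metropolis_accept(du, rng):
                    pos = np.array([trial])
            drifts.append(pos[0, 2] - (-1.0))
        assert np.mean(drifts) < 0
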