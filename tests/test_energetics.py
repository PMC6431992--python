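import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poreslab import (Conformation, SimParams, bend_energy, delta_energy,
                      electric_energy, fene_energy, morse_energy,
                      total_energy, wall_energy)

P = SimParams(n_bonds=10, kappa=10.0, e_field=5.0, r_sep=5.0)


class TestScalarPotentials:
    @pytest.mark.parametrize("l,expected", [
        (0.7, 0.0),
        (0.55, -0.5 * 20 * 0.3 ** 2 * math.log(1 - 0.25)),  # 0.2589138652
        (0.85, -0.5 * 20 * 0.3 ** 2 * math.log(1 - 0.25)),  # symmetric
    ])
    def test_fene_values(self, l, expected):
        assert fene_energy(l, P) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("l", [0.4, 1.0, 0.2, 1.3])
    def test_fene_out_of_range_is_infinite(self, l):
        assert math.isinf(fene_energy(l, P))

    def test_fene_convex_minimum_at_l0(self):
        ls = np.linspace(0.45, 0.95, 201)
        us = np.array([fene_energy(l, P) for l in ls])
        assert us.min() == pytest.approx(0.0, abs=1e-12)
        assert ls[us.argmin()] == pytest.approx(P.l0, abs=2e-3)
        assert (np.diff(us, 2) > 0).all()  # convex on the open interval

    @pytest.mark.parametrize("r,expected", [
        (0.8, -1.0),
        (0.9, math.exp(-4.8) - 2 * math.exp(-2.4)),   # -0.1732061595
        (0.6, math.exp(9.6) - 2 * math.exp(4.8)),     # 14521.7607
    ])
    def test_morse_values(self, r, expected):
        assert morse_energy(r, P) == pytest.approx(expected, abs=1e-9)

    def test_morse_minimum_and_monotone_tail(self):
        rs = np.linspace(0.8, 1.49, 100)
        us = np.array([morse_energy(r, P) for r in rs])
        assert us[0] == pytest.approx(-1.0, abs=1e-12)
        assert (np.diff(us) > 0).all()

    def test_morse_truncated_beyond_cutoff(self):
        assert morse_energy(P.r_cut, P) == 0.0
        assert morse_energy(5.0, P) == 0.0
        # residual attraction at the cutoff is ~ -2 e^(-alpha(rc-rmin))
        assert abs(morse_energy(P.r_cut - 1e-9, P)) < 2e-7

    @pytest.mark.parametrize("theta,kappa,expected", [
        (math.pi, 10.0, 0.0),      # straight chain is the ground state
        (0.0, 10.0, 20.0),         # full backfold costs 2*kappa
        (math.pi / 2, 10.0, 10.0),
    ])
    def test_bend_values(self, theta, kappa, expected):
        assert bend_energy(theta, kappa) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("r,expected", [
        (0.8, 0.0),                                         # the join
        (2.0, 0.0),                                         # beyond rmin
        (0.7, math.exp(4.8) - 2 * math.exp(2.4) + 1.0),     # 100.464065
    ])
    def test_wall_values(self, r, expected):
        assert wall_energy(r, P) == pytest.approx(expected, abs=1e-9)

    def test_wall_nonnegative_and_diverging(self):
        rs = np.linspace(0.05, 2.0, 200)
        us = np.array([wall_energy(r, P) for r in rs])
        assert (us >= 0).all()
        assert wall_energy(0.05, P) > 1e10
        assert math.isinf(wall_energy(-1.0, P))  # inside-material sentinel

    @pytest.mark.parametrize("z,expected", [
        (0.0, 0.0), (1.0, 0.0),
        (-1.0, -5.0),              # qEz inside the pore column
        (-2.0, -10.0),             # full drop qEL at the exit plane
        (-3.0, -10.0),             # constant past the pore
    ])
    def test_electric_values(self, z, expected):
        assert electric_energy(z, None, P) == pytest.approx(expected, abs=1e-12)

    def test_electric_continuous_and_total_drop(self):
        zs = np.linspace(1, -4, 400)
        us = np.array([electric_energy(z, None, P) for z in zs])
        assert np.abs(np.diff(us)).max() < 0.07  # no jumps on a fine grid
        drop = electric_energy(10.0, None, P) - electric_energy(-10.0, None, P)
        assert drop == pytest.approx(P.q_charge * P.e_field * P.l_pore)


# -- independent whole-chain oracle (plain python, no package internals) ----

def _oracle_total(pos, p: SimParams):
    n1 = len(pos)
    u_f = u_m = u_b = u_w = u_e = 0.0
    for i in range(n1 - 1):
        l = math.dist(pos[i], pos[i + 1])
        x = (l - p.l0) / p.r0
        u_f += (-0.5 * p.k_spring * p.r0 ** 2 * math.log(1 - x * x)
                if abs(x) < 1 else math.inf)
    for i in range(n1 - 2):
        a = np.subtract(pos[i + 1], pos[i])
        b = np.subtract(pos[i + 2], pos[i + 1])
        cosphi = a.dot(b) / (np.linalg.norm(a) * np.linalg.norm(b))
        u_b += p.kappa * (1 - cosphi)
    for i in range(n1):
        for j in range(i + 2, n1):
            r = math.dist(pos[i], pos[j])
            if r < p.r_cut:
                e = math.exp(-p.alpha_morse * (r - p.rmin_morse))
                u_m += p.eps_morse * (e * e - 2 * e)
    for x, y, z in pos:
        # wall gap by cases (chain kept away from the pore in these tests)
        rho = math.hypot(x, y)
        if z >= 0:
            g = z if rho >= p.pore_radius else math.hypot(p.pore_radius - rho, z)
            g = min(g, z + p.l_pore + p.r_sep)
        elif z <= -(p.l_pore + p.r_sep) or (z > -p.l_pore and rho >= p.pore_radius):
            g = -1.0
        elif z > -p.l_pore:
            g = min(p.pore_radius - rho, z + p.l_pore + p.r_sep)
        else:
            d_l = (-p.l_pore - z if rho >= p.pore_radius
                   else math.hypot(p.pore_radius - rho, z + p.l_pore))
            g = min(d_l, z + p.l_pore + p.r_sep)
        if g < 0:
            u_w = math.inf
        else:
            r_wall = g + p.wall_offset
            if r_wall <= p.rmin_morse:
                e = math.exp(-p.alpha_morse * (r_wall - p.rmin_morse))
                u_w += p.eps_morse * (e * e - 2 * e) + p.eps_morse
        qE = p.q_charge * p.e_field
        u_e += 0.0 if z >= 0 else (qE * z if z > -p.l_pore else -qE * p.l_pore)
    return u_f, u_m, u_b, u_w, u_e


def _random_valid_chain(rng, n1, p, z0=3.0, min_sep=0.75):
    """A random self-avoiding chain on the cis side, bonds in range."""
    pos = [np.array([0.0, 0.0, z0])]
    while len(pos) < n1:
        d = rng.normal(size=3)
        d *= (p.l0 + rng.uniform(-0.2, 0.2)) / np.linalg.norm(d)
        cand = pos[-1] + d
        if cand[2] > 0.5 and all(
                np.linalg.norm(cand - q) > min_sep for q in pos[:-1]):
            pos.append(cand)
    return np.array(pos)


class TestTotalEnergy:
    def test_two_bonded_monomers_at_l0_cost_nothing(self):
        conf = Conformation([[0, 0, 5], [0, 0, 5.7]])
        assert total_energy(conf, P).u_total == 0.0

    def test_three_collinear_monomers_cost_only_morse_tail(self):
        # bonds at l0 and a straight angle cost nothing; the end pair at
        # 1.4 still sits just inside the 1.5 cutoff, leaving the ~1e-6
        # Morse tail as the only contribution
        conf = Conformation([[0, 0, 5], [0, 0, 5.7], [0, 0, 6.4]])
        b = total_energy(conf, P)
        assert b.u_fene == pytest.approx(0.0, abs=1e-14)
        assert b.u_bend == pytest.approx(0.0, abs=1e-14)
        assert b.u_total == pytest.approx(morse_energy(1.4, P), rel=1e-9)

    def test_three_collinear_monomers_beyond_cutoff_cost_nothing(self):
        conf = Conformation([[0, 0, 5], [0, 0, 5.8], [0, 0, 6.6]])
        b = total_energy(conf, P)
        assert b.u_morse == 0.0
        assert b.u_total == pytest.approx(2 * fene_energy(0.8, P), rel=1e-12)

    def test_breakdown_sums_to_total(self, rng):
        pos = _random_valid_chain(rng, 11, P)
        b = total_energy(Conformation(pos), P)
        assert b.u_total == pytest.approx(
            b.u_fene + b.u_morse + b.u_bend + b.u_wall + b.u_elec, rel=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(5):
            pos = _random_valid_chain(rng, 10, P)
            b = total_energy(Conformation(pos), P)
            o = _oracle_total(pos, P)
            for got, want in zip(
                    (b.u_fene, b.u_morse, b.u_bend, b.u_wall, b.u_elec), o):
                assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_oracle_agrees_in_pore_and_slab(self, rng):
        # a straight chain threading the pore exercises all regions
        z = np.linspace(1.5, -5.0, 11)
        pos = np.zeros((11, 3))
        pos[:, 2] = z
        b = total_energy(Conformation(pos), P)
        o = _oracle_total(pos, P)
        for got, want in zip(
                (b.u_fene, b.u_morse, b.u_bend, b.u_wall, b.u_elec), o):
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_cutoff_changes_total_negligibly(self, rng):
        pos = _random_valid_chain(rng, 12, P)
        u_cut = total_energy(Conformation(pos), P).u_total
        u_full = total_energy(Conformation(pos), P.replace(r_cut=50.0)).u_total
        assert abs(u_cut - u_full) < 1e-4


class TestDeltaEnergy:
    def test_identity_move_is_zero(self, rng):
        pos = _random_valid_chain(rng, 8, P)
        conf = Conformation(pos)
        assert delta_energy(conf, 3, pos[3], P) == pytest.approx(0.0, abs=1e-12)

    def test_equals_full_recomputation(self, rng):
        pos = _random_valid_chain(rng, 9, P)
        conf = Conformation(pos)
        for _ in range(50):
            i = int(rng.integers(0, 9))
            trial = pos[i] + rng.uniform(-0.25, 0.25, 3)
            du = delta_energy(conf, i, trial, P)
            if math.isinf(du):
                continue
            after = pos.copy()
            after[i] = trial
            du_full = (total_energy(Conformation(after), P).u_total
                       - total_energy(conf, P).u_total)
            assert du == pytest.approx(du_full, rel=1e-9, abs=1e-9)

    def test_bond_violation_is_infinite(self):
        pos = np.array([[0, 0, 5.0], [0, 0, 5.7], [0, 0, 6.4]])
        conf = Conformation(pos)
        assert math.isinf(delta_energy(conf, 2, [0, 0, 6.76], P))  # bond 1.06

    def test_move_into_membrane_is_infinite(self):
        pos = np.array([[0, 0, 0.9], [0, 0, 1.6]])
        conf = Conformation(pos)
        assert math.isinf(delta_energy(conf, 0, [2.0, 0, -1.0], P))

    @given(i=st.integers(0, 7), seed=st.integers(0, 10 ** 6))
    @settings(max_examples=60, deadline=None)
    def test_incremental_equals_global_property(self, i, seed):
        rng = np.random.default_rng(seed)
        pos = _random_valid_chain(rng, 8, P)
        conf = Conformation(pos)
        trial = pos[i] + rng.uniform(-0.2, 0.2, 3)
        du = delta_energy(conf, i, trial, P)
        after = pos.copy()
        after[i] = trial
        u_after = total_energy(Conformation(after), P).u_total
        u_before = total_energy(conf, P).u_total
        if math.isinf(du):
            assert math.isinf(u_after)
        else:
            assert du == pytest.approx(u_after - u_before, abs=1e-9)
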