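"""Numba-compiled core: scalar potentials, geometry, and the MC loops.

Everything here works on plain floats and ndarrays so the hot path stays
inside nopython mode. The public modules (`geometry`, `energetics`,
`engine`) wrap these with typed, documented interfaces.

Sign/geometry conventions: the pore axis is z, the cis half-space is
z >= 0, the left membrane occupies -L <= z <= 0 minus the pore cylinder
of radius D/2, the trans slab is -(L+R) < z < -L, and the right membrane
fills z <= -(L+R). The uniform field acts along -z inside the pore column.

Wall interactions: Eq.-of-state walls are made of immobile monomers of
diameter sigma = rmin whose centers lie sigma/2 inside the material
surface, so the Morse wall potential is evaluated at r = gap + woff with
woff = sigma/2 (a gap is the Euclidean distance to the material surface).
"""

import numpy as np
from numba import njit

INF = np.inf
# finite rejection sentinel used inside fastmath kernels (fastmath assumes
# no infs); the public wrappers map anything >= BIG/2 back to math.inf
BIG = 1.0e30

# region codes
CIS = 0
PORE = 1
TRANS = 2
MEMBRANE = 3

# status codes for a translocation sample
FAILED = 0
DONE = 1


# ---------------------------------------------------------------------------
# scalar potentials
# ---------------------------------------------------------------------------

@njit(cache=True)
def fene_scalar(l, kspring, l0, r0, lmin, lmax):
    if l <= lmin or l >= lmax:
        return BIG
    x = (l - l0) / r0
    return -0.5 * kspring * r0 * r0 * np.log(1.0 - x * x)


@njit(cache=True)
def morse_scalar(r, eps, alpha, rmin):
    e = np.exp(-alpha * (r - rmin))
    return eps * (e * e - 2.0 * e)


@njit(cache=True)
def wall_pot_scalar(r, eps, alpha, rmin):
    # truncated-and-shifted repulsive Morse: 0 beyond rmin, continuous at rmin
    if r > rmin:
        return 0.0
    e = np.exp(-alpha * (r - rmin))
    return eps * (e * e - 2.0 * e) + eps


@njit(cache=True)
def elec_scalar(z, q_e, l_pore):
    # potential energy of one unit charge: 0 in cis, q*E*z in the pore
    # column, -q*E*L past it (force -qE acts only across the pore)
    if z >= 0.0:
        return 0.0
    if z > -l_pore:
        return q_e * z
    return -q_e * l_pore


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@njit(cache=True)
def region_code(x, y, z, l_pore, r_sep, rad):
    if z >= 0.0:
        return CIS
    if z <= -(l_pore + r_sep):
        return MEMBRANE
    if z > -l_pore:
        if x * x + y * y < rad * rad:
            return PORE
        return MEMBRANE
    return TRANS


@njit(cache=True)
def wall_gap_open(x, y, z, l_pore, r_sep, rad):
    """Euclidean distance from a point to the nearest material surface.

    Returns -1.0 if the point is inside membrane material.
    """
    rho = np.sqrt(x * x + y * y)
    zr = l_pore + r_sep  # right membrane face at z = -zr
    if z >= 0.0:
        if rho >= rad:
            g = z
        else:
            # nearest solid point is the cis-side pore rim circle
            g = np.sqrt((rad - rho) ** 2 + z * z)
        return min(g, z + zr)
    if z < -zr:
        return -1.0
    if z > -l_pore:
        if rho > rad:
            return -1.0
        return min(rad - rho, z + zr)
    # trans slab
    d_right = z + zr
    if rho >= rad:
        d_left = -l_pore - z
    else:
        # nearest left-membrane point is the trans-side pore rim circle
        d_left = np.sqrt((rad - rho) ** 2 + (z + l_pore) ** 2)
    return min(d_left, d_right)


@njit(cache=True)
def wall_gap_closed(z):
    # relaxation phase: the pore is closed, so the whole z = 0 plane is wall
    if z < 0.0:
        return -1.0
    return z


# ---------------------------------------------------------------------------
# chain energies
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def total_energy_terms(pos, kspring, l0, r0, lmin, lmax, eps, alpha, rmin,
                       r_cut, kappa, q_e, l_pore, r_sep, rad, woff,
                       closed_pore, skip_wall_first):
    """Return (u_fene, u_morse, u_bend, u_wall, u_elec) of a conformation."""
    n1 = pos.shape[0]
    u_f = 0.0
    u_m = 0.0
    u_b = 0.0
    u_w = 0.0
    u_e = 0.0
    for i in range(n1 - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        u_f += fene_scalar(np.sqrt(dx * dx + dy * dy + dz * dz),
                           kspring, l0, r0, lmin, lmax)
    for i in range(n1 - 2):
        ax = pos[i + 1, 0] - pos[i, 0]
        ay = pos[i + 1, 1] - pos[i, 1]
        az = pos[i + 1, 2] - pos[i, 2]
        bx = pos[i + 2, 0] - pos[i + 1, 0]
        by = pos[i + 2, 1] - pos[i + 1, 1]
        bz = pos[i + 2, 2] - pos[i + 1, 2]
        na = np.sqrt(ax * ax + ay * ay + az * az)
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        cosphi = (ax * bx + ay * by + az * bz) / (na * nb)
        u_b += kappa * (1.0 - cosphi)
    rc2 = r_cut * r_cut
    for i in range(n1):
        for j in range(i + 2, n1):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                u_m += morse_scalar(np.sqrt(r2), eps, alpha, rmin)
    for i in range(n1):
        if closed_pore:
            g = wall_gap_closed(pos[i, 2])
        else:
            g = wall_gap_open(pos[i, 0], pos[i, 1], pos[i, 2],
                              l_pore, r_sep, rad)
        if not (i == 0 and skip_wall_first):
            if g < 0.0:
                u_w = BIG
            else:
                u_w += wall_pot_scalar(g + woff, eps, alpha, rmin)
        u_e += elec_scalar(pos[i, 2], q_e, l_pore)
    return u_f, u_m, u_b, u_w, u_e


@njit(cache=True, fastmath=True)
def _angle_term(ax, ay, az, bx, by, bz, kappa):
    na = np.sqrt(ax * ax + ay * ay + az * az)
    nb = np.sqrt(bx * bx + by * by + bz * bz)
    return kappa * (1.0 - (ax * bx + ay * by + az * bz) / (na * nb))


@njit(cache=True, fastmath=True)
def local_energy(pos, i, px, py, pz, kspring, l0, r0, lmin, lmax, eps, alpha,
                 rmin, r_cut, kappa, q_e, l_pore, r_sep, rad, woff,
                 closed_pore, skip_wall_first, include_nonbonded):
    """Energy of every term touching monomer i, with i placed at (px,py,pz)."""
    n1 = pos.shape[0]
    u = 0.0
    if i > 0:
        dx = px - pos[i - 1, 0]
        dy = py - pos[i - 1, 1]
        dz = pz - pos[i - 1, 2]
        u += fene_scalar(np.sqrt(dx * dx + dy * dy + dz * dz),
                         kspring, l0, r0, lmin, lmax)
        if u >= 0.5 * BIG:
            return BIG
    if i < n1 - 1:
        dx = pos[i + 1, 0] - px
        dy = pos[i + 1, 1] - py
        dz = pos[i + 1, 2] - pz
        u += fene_scalar(np.sqrt(dx * dx + dy * dy + dz * dz),
                         kspring, l0, r0, lmin, lmax)
        if u >= 0.5 * BIG:
            return BIG
    if kappa > 0.0:
        if i >= 2:
            u += _angle_term(pos[i - 1, 0] - pos[i - 2, 0],
                             pos[i - 1, 1] - pos[i - 2, 1],
                             pos[i - 1, 2] - pos[i - 2, 2],
                             px - pos[i - 1, 0],
                             py - pos[i - 1, 1],
                             pz - pos[i - 1, 2], kappa)
        if 1 <= i <= n1 - 2:
            u += _angle_term(px - pos[i - 1, 0],
                             py - pos[i - 1, 1],
                             pz - pos[i - 1, 2],
                             pos[i + 1, 0] - px,
                             pos[i + 1, 1] - py,
                             pos[i + 1, 2] - pz, kappa)
        if i <= n1 - 3:
            u += _angle_term(pos[i + 1, 0] - px,
                             pos[i + 1, 1] - py,
                             pos[i + 1, 2] - pz,
                             pos[i + 2, 0] - pos[i + 1, 0],
                             pos[i + 2, 1] - pos[i + 1, 1],
                             pos[i + 2, 2] - pos[i + 1, 2], kappa)
    if include_nonbonded:
        rc2 = r_cut * r_cut
        for j in range(n1):
            if j < i - 1 or j > i + 1:
                dx = pos[j, 0] - px
                dy = pos[j, 1] - py
                dz = pos[j, 2] - pz
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc2:
                    u += morse_scalar(np.sqrt(r2), eps, alpha, rmin)
    if closed_pore >= 0:
        if not (i == 0 and skip_wall_first):
            if closed_pore == 1:
                g = wall_gap_closed(pz)
            else:
                g = wall_gap_open(px, py, pz, l_pore, r_sep, rad)
            if g < 0.0:
                return BIG
            u += wall_pot_scalar(g + woff, eps, alpha, rmin)
        u += elec_scalar(pz, q_e, l_pore)
    return u


@njit(cache=True, fastmath=True)
def delta_energy_kernel(pos, i, px, py, pz, kspring, l0, r0, lmin, lmax, eps,
                        alpha, rmin, r_cut, kappa, q_e, l_pore, r_sep, rad,
                        woff, closed_pore, skip_wall_first):
    """Single-pass energy difference of moving monomer i to (px,py,pz).

    Each term is differenced individually (new minus old), so the result
    equals total_energy(after) - total_energy(before) to rounding. An
    out-of-range trial bond or a trial position inside membrane material
    returns the BIG rejection sentinel.
    """
    n1 = pos.shape[0]
    ox = pos[i, 0]
    oy = pos[i, 1]
    oz = pos[i, 2]
    du = 0.0
    # bonds (reject early on a bound violation)
    if i > 0:
        dx = px - pos[i - 1, 0]
        dy = py - pos[i - 1, 1]
        dz = pz - pos[i - 1, 2]
        lnew = np.sqrt(dx * dx + dy * dy + dz * dz)
        if lnew <= lmin or lnew >= lmax:
            return BIG
        dx = ox - pos[i - 1, 0]
        dy = oy - pos[i - 1, 1]
        dz = oz - pos[i - 1, 2]
        lold = np.sqrt(dx * dx + dy * dy + dz * dz)
        du += (fene_scalar(lnew, kspring, l0, r0, lmin, lmax)
               - fene_scalar(lold, kspring, l0, r0, lmin, lmax))
    if i < n1 - 1:
        dx = pos[i + 1, 0] - px
        dy = pos[i + 1, 1] - py
        dz = pos[i + 1, 2] - pz
        lnew = np.sqrt(dx * dx + dy * dy + dz * dz)
        if lnew <= lmin or lnew >= lmax:
            return BIG
        dx = pos[i + 1, 0] - ox
        dy = pos[i + 1, 1] - oy
        dz = pos[i + 1, 2] - oz
        lold = np.sqrt(dx * dx + dy * dy + dz * dz)
        du += (fene_scalar(lnew, kspring, l0, r0, lmin, lmax)
               - fene_scalar(lold, kspring, l0, r0, lmin, lmax))
    # wall and electric terms of the moved monomer
    if closed_pore >= 0:
        if not (i == 0 and skip_wall_first):
            if closed_pore == 1:
                gn = wall_gap_closed(pz)
                go = wall_gap_closed(oz)
            else:
                gn = wall_gap_open(px, py, pz, l_pore, r_sep, rad)
                go = wall_gap_open(ox, oy, oz, l_pore, r_sep, rad)
            if gn < 0.0:
                return BIG
            du += (wall_pot_scalar(gn + woff, eps, alpha, rmin)
                   - wall_pot_scalar(go + woff, eps, alpha, rmin))
        du += elec_scalar(pz, q_e, l_pore) - elec_scalar(oz, q_e, l_pore)
    # the <= 3 joint angles touching monomer i
    if kappa > 0.0:
        if i >= 2:
            ax = pos[i - 1, 0] - pos[i - 2, 0]
            ay = pos[i - 1, 1] - pos[i - 2, 1]
            az = pos[i - 1, 2] - pos[i - 2, 2]
            du += (_angle_term(ax, ay, az, px - pos[i - 1, 0],
                               py - pos[i - 1, 1], pz - pos[i - 1, 2], kappa)
                   - _angle_term(ax, ay, az, ox - pos[i - 1, 0],
                                 oy - pos[i - 1, 1], oz - pos[i - 1, 2],
                                 kappa))
        if 1 <= i <= n1 - 2:
            du += (_angle_term(px - pos[i - 1, 0], py - pos[i - 1, 1],
                               pz - pos[i - 1, 2], pos[i + 1, 0] - px,
                               pos[i + 1, 1] - py, pos[i + 1, 2] - pz, kappa)
                   - _angle_term(ox - pos[i - 1, 0], oy - pos[i - 1, 1],
                                 oz - pos[i - 1, 2], pos[i + 1, 0] - ox,
                                 pos[i + 1, 1] - oy, pos[i + 1, 2] - oz,
                                 kappa))
        if i <= n1 - 3:
            bx = pos[i + 2, 0] - pos[i + 1, 0]
            by = pos[i + 2, 1] - pos[i + 1, 1]
            bz = pos[i + 2, 2] - pos[i + 1, 2]
            du += (_angle_term(pos[i + 1, 0] - px, pos[i + 1, 1] - py,
                               pos[i + 1, 2] - pz, bx, by, bz, kappa)
                   - _angle_term(pos[i + 1, 0] - ox, pos[i + 1, 1] - oy,
                                 pos[i + 1, 2] - oz, bx, by, bz, kappa))
    # non-bonded Morse pairs, one pass over the chain
    rc2 = r_cut * r_cut
    for j in range(n1):
        if i - 1 <= j <= i + 1:
            continue
        dx = pos[j, 0] - px
        dy = pos[j, 1] - py
        dz = pos[j, 2] - pz
        r2n = dx * dx + dy * dy + dz * dz
        dx = pos[j, 0] - ox
        dy = pos[j, 1] - oy
        dz = pos[j, 2] - oz
        r2o = dx * dx + dy * dy + dz * dz
        if r2n < rc2:
            du += morse_scalar(np.sqrt(r2n), eps, alpha, rmin)
        if r2o < rc2:
            du -= morse_scalar(np.sqrt(r2o), eps, alpha, rmin)
    return du


# ---------------------------------------------------------------------------
# Monte Carlo loops
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def relax_kernel(n1, kspring, l0, r0, lmin, lmax, eps, alpha, rmin, r_cut,
                 kappa, q_e, l_pore, r_sep, rad, woff, step, kbt, z_park,
                 relax_min_mcs, relax_max_mcs, window, tol, seed):
    """Equilibrate the chain on the cis side with the pore closed.

    Monomer 0 is held at (0, 0, z_park); the z = 0 plane reflects all
    other monomers (closed-pore wall). Starts from a straight rod along
    +z with every bond at l0 (valid by construction). Stops once the mean
    total energy of two consecutive windows agrees to `tol` relative,
    after at least relax_min_mcs and at most relax_max_mcs.
    """
    np.random.seed(seed)
    pos = np.empty((n1, 3))
    for i in range(n1):
        pos[i, 0] = 0.0
        pos[i, 1] = 0.0
        pos[i, 2] = z_park + l0 * i
    mcs = 0
    prev_mean = 1.0e300
    converged = False
    while mcs < relax_max_mcs and not converged:
        esum = 0.0
        for _ in range(window):
            for _ in range(n1):
                i = 1 + int(np.random.random() * (n1 - 1))
                px = pos[i, 0] + (2.0 * np.random.random() - 1.0) * step
                py = pos[i, 1] + (2.0 * np.random.random() - 1.0) * step
                pz = pos[i, 2] + (2.0 * np.random.random() - 1.0) * step
                du = delta_energy_kernel(
                    pos, i, px, py, pz, kspring, l0, r0, lmin, lmax, eps,
                    alpha, rmin, r_cut, kappa, q_e, l_pore, r_sep, rad,
                    woff, 1, True)
                if du < 0.5 * BIG and (
                        du <= 0.0 or np.random.random() < np.exp(-du / kbt)):
                    pos[i, 0] = px
                    pos[i, 1] = py
                    pos[i, 2] = pz
            mcs += 1
            u_f, u_m, u_b, u_w, u_e = total_energy_terms(
                pos, kspring, l0, r0, lmin, lmax, eps, alpha, rmin, r_cut,
                kappa, q_e, l_pore, r_sep, rad, woff, True, True)
            esum += u_f + u_m + u_b + u_w + u_e
        mean = esum / window
        if mcs >= relax_min_mcs and abs(mean - prev_mean) < tol * max(
                abs(prev_mean), 1.0):
            converged = True
        prev_mean = mean
    return pos, mcs


@njit(cache=True, fastmath=True)
def translocate_kernel(pos_eq, kspring, l0, r0, lmin, lmax, eps, alpha, rmin,
                       r_cut, kappa, q_e, l_pore, r_sep, rad, woff, step,
                       kbt, max_mcs, seed, snap_every, snap_buf):
    """Drive one translocation attempt chain until completion or max_mcs.

    The head is released and the pore opened at t = 0. After every MCS the
    pore occupancy is logged; a chain that fully retreats to cis after
    having engaged the pore is restarted from pos_eq with the clock reset.
    Completion: every monomer past the pore exit plane (z < -L).

    Returns (tau, waiting, last_exit, attempts, accepts, trials, pos,
    status, n_snaps).
    """
    np.random.seed(seed)
    n1 = pos_eq.shape[0]
    pos = pos_eq.copy()
    waiting = np.zeros(n1, dtype=np.int64)
    last_exit = np.zeros(n1, dtype=np.int64)
    attempts = 1
    accepts = 0
    trials = 0
    t = 0
    t_total = 0  # never reset by restarts: bounds total work per sample
    # the chain counts as pore-engaged from release if the equilibrated
    # state parks the head inside the pore (the default); otherwise only
    # after it first enters. Without this a chain that slips out right
    # after a restart could wander the unbounded cis side forever.
    rad2 = rad * rad
    engaged0 = False
    for s in range(n1):
        z = pos[s, 2]
        if z < 0.0 and z > -l_pore and (
                pos[s, 0] ** 2 + pos[s, 1] ** 2 < rad2):
            engaged0 = True
    engaged = engaged0
    status = FAILED
    n_snaps = 0
    max_snaps = snap_buf.shape[0]
    while t_total < max_mcs:
        for _ in range(n1):
            i = int(np.random.random() * n1)
            px = pos[i, 0] + (2.0 * np.random.random() - 1.0) * step
            py = pos[i, 1] + (2.0 * np.random.random() - 1.0) * step
            pz = pos[i, 2] + (2.0 * np.random.random() - 1.0) * step
            du = delta_energy_kernel(
                pos, i, px, py, pz, kspring, l0, r0, lmin, lmax, eps, alpha,
                rmin, r_cut, kappa, q_e, l_pore, r_sep, rad, woff, 0, False)
            trials += 1
            if du < 0.5 * BIG and (
                    du <= 0.0 or np.random.random() < np.exp(-du / kbt)):
                pos[i, 0] = px
                pos[i, 1] = py
                pos[i, 2] = pz
                accepts += 1
        t += 1
        t_total += 1
        all_trans = True
        all_cis = True
        any_pore = False
        for s in range(n1):
            z = pos[s, 2]
            if z < 0.0 and z > -l_pore and (
                    pos[s, 0] ** 2 + pos[s, 1] ** 2 < rad2):
                waiting[s] += 1
                last_exit[s] = t + 1
                any_pore = True
            if z >= -l_pore:
                all_trans = False
            if z <= 0.0:
                all_cis = False
        if any_pore:
            engaged = True
        if snap_every > 0 and t % snap_every == 0 and n_snaps < max_snaps:
            snap_buf[n_snaps] = pos
            n_snaps += 1
        if all_trans:
            status = DONE
            break
        if engaged and all_cis and not any_pore:
            # withdrawal: restart from the stored equilibrated conformation
            pos = pos_eq.copy()
            for s in range(n1):
                waiting[s] = 0
                last_exit[s] = 0
            t = 0
            engaged = engaged0
            attempts += 1
    return (t, waiting, last_exit, attempts, accepts, trials, pos, status,
            n_snaps)


@njit(cache=True, fastmath=True)
def free_chain_kernel(n1, kspring, l0, r0, lmin, lmax, eps, alpha, rmin,
                      r_cut, kappa, step, kbt, n_out, sample_every, burn_mcs,
                      fix_first, include_nonbonded, seed):
    """Sample an isolated chain (no walls, no field) at equilibrium.

    Used for Boltzmann-marginal validation: records every bond length and
    every cos(bond-vector angle) once per `sample_every` MCS after a
    burn-in. `include_nonbonded=False` drops the |i-j|>1 Morse pairs so
    the bond and angle marginals factorize into their closed forms.
    """
    np.random.seed(seed)
    pos = np.empty((n1, 3))
    for i in range(n1):
        pos[i, 0] = 0.0
        pos[i, 1] = 0.0
        pos[i, 2] = l0 * i
    nb = n1 - 1
    nang = n1 - 2
    bonds = np.empty((n_out, nb))
    cosang = np.empty((n_out, max(nang, 1)))
    ree2 = np.empty(n_out)
    lo = 1 if fix_first else 0
    nfree = n1 - lo
    for it in range(burn_mcs + n_out * sample_every):
        for _ in range(n1):
            i = lo + int(np.random.random() * nfree)
            px = pos[i, 0] + (2.0 * np.random.random() - 1.0) * step
            py = pos[i, 1] + (2.0 * np.random.random() - 1.0) * step
            pz = pos[i, 2] + (2.0 * np.random.random() - 1.0) * step
            du_new = local_energy(pos, i, px, py, pz, kspring, l0, r0, lmin,
                                  lmax, eps, alpha, rmin, r_cut, kappa, 0.0,
                                  1.0, 1.0, 1.0, 0.0, -1, False,
                                  include_nonbonded)
            if du_new >= 0.5 * BIG:
                continue
            du_old = local_energy(pos, i, pos[i, 0], pos[i, 1], pos[i, 2],
                                  kspring, l0, r0, lmin, lmax, eps, alpha,
                                  rmin, r_cut, kappa, 0.0, 1.0, 1.0, 1.0,
                                  0.0, -1, False, include_nonbonded)
            du = du_new - du_old
            if du <= 0.0 or np.random.random() < np.exp(-du / kbt):
                pos[i, 0] = px
                pos[i, 1] = py
                pos[i, 2] = pz
        k = it - burn_mcs
        if k >= 0 and (k + 1) % sample_every == 0:
            row = (k + 1) // sample_every - 1
            if row < n_out:
                for b in range(nb):
                    dx = pos[b + 1, 0] - pos[b, 0]
                    dy = pos[b + 1, 1] - pos[b, 1]
                    dz = pos[b + 1, 2] - pos[b, 2]
                    bonds[row, b] = np.sqrt(dx * dx + dy * dy + dz * dz)
                for a in range(nang):
                    ax = pos[a + 1, 0] - pos[a, 0]
                    ay = pos[a + 1, 1] - pos[a, 1]
                    az = pos[a + 1, 2] - pos[a, 2]
                    bx = pos[a + 2, 0] - pos[a + 1, 0]
                    by = pos[a + 2, 1] - pos[a + 1, 1]
                    bz = pos[a + 2, 2] - pos[a + 1, 2]
                    na = np.sqrt(ax * ax + ay * ay + az * az)
                    nbn = np.sqrt(bx * bx + by * by + bz * bz)
                    # interior-angle convention: collinear bonds -> cos = -1
                    cosang[row, a] = -(ax * bx + ay * by + az * bz) / (na * nbn)
                dx = pos[n1 - 1, 0] - pos[0, 0]
                dy = pos[n1 - 1, 1] - pos[0, 1]
                dz = pos[n1 - 1, 2] - pos[0, 2]
                ree2[row] = dx * dx + dy * dy + dz * dz
    return bonds, cosang, ree2
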