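"""Numba kernels for event-driven (discontinuous) molecular dynamics.

Reduced units throughout: length in Angstrom, energy in eps_HB, mass in
amu; the time unit follows as A*sqrt(amu/eps_HB).  Velocities are always
current; positions are stored lazily at each bead's `local_t` and
advanced analytically when needed (standard asynchronous DMD).

Scheduling uses one candidate event per bead (its earliest upcoming
discontinuity or cell crossing) kept in a binary heap with per-bead
invalidation counters.  Any velocity change of a bead bumps its counter
and recomputes its candidate, so the globally earliest true event always
has a live heap entry.

Event codes:
    1 core collision        5 bond upper limit
    2 well edge, entering   6 hydrogen-bond well entry (formation try)
    3 well edge, leaving    7 hydrogen-bond well exit (escape try)
    4 bond lower limit      8 cell crossing
"""

import numpy as np
from numba import njit

EV_CORE = 1
EV_WELL_IN = 2
EV_WELL_OUT = 3
EV_BOND_LO = 4
EV_BOND_HI = 5
EV_HB_IN = 6
EV_HB_OUT = 7
EV_CELL = 8

_BIG = 1.0e300
_EDGE_EPS = 1.0e-9  # A^2 tie tolerance at a discontinuity


@njit(cache=True, inline="always", fastmath=True)
def _mic(d, L):
    if d > 0.5 * L:
        return d - L
    elif d < -0.5 * L:
        return d + L
    return d


@njit(cache=True, inline="always", fastmath=True)
def _t_outer(r2, b, a, d2):
    """Time to reach separation^2 d2 going outward (exists for a>0)."""
    disc = b * b + a * (d2 - r2)
    if disc < 0.0:
        disc = 0.0
    return (-b + np.sqrt(disc)) / a


@njit(cache=True, inline="always", fastmath=True)
def _t_inner(r2, b, a, d2):
    """First time separation^2 drops to d2, or -1 if never (needs b<0).

    A pair already at (or, through round-off, marginally inside) the
    threshold while still approaching collides immediately; otherwise it
    could tunnel through the discontinuity.
    """
    if b >= 0.0:
        return -1.0
    if r2 <= d2:
        return 0.0
    disc = b * b - a * (r2 - d2)
    if disc <= 0.0:
        return -1.0
    return (r2 - d2) / (-b + np.sqrt(disc))


@njit(cache=True, inline="always", fastmath=True)
def _pair_geom(pos, vel, local_t, i, j, t, L):
    """Min-image relative position at time t and relative velocity."""
    dti = t - local_t[i]
    dtj = t - local_t[j]
    dx = _mic(pos[i, 0] + vel[i, 0] * dti - pos[j, 0] - vel[j, 0] * dtj, L)
    dy = _mic(pos[i, 1] + vel[i, 1] * dti - pos[j, 1] - vel[j, 1] * dtj, L)
    dz = _mic(pos[i, 2] + vel[i, 2] * dti - pos[j, 2] - vel[j, 2] * dtj, L)
    vx = vel[i, 0] - vel[j, 0]
    vy = vel[i, 1] - vel[j, 1]
    vz = vel[i, 2] - vel[j, 2]
    return dx, dy, dz, vx, vy, vz


@njit(cache=True, inline="always", fastmath=True)
def _pair_event(
    pos, vel, local_t, i, j, t, L,
    itype, kind, chain_id, resix,
    bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2,
    core2, well_edge2, squeeze2,
    hbd2, hb_partner, gmax2,
):
    """Earliest upcoming discontinuity for pair (i, j): (abs time, code)."""
    dx, dy, dz, vx, vy, vz = _pair_geom(pos, vel, local_t, i, j, t, L)
    a = vx * vx + vy * vy + vz * vz
    if a < 1.0e-30:
        return _BIG, 0
    r2 = dx * dx + dy * dy + dz * dz
    b = dx * vx + dy * vy + dz * vz
    # receding and beyond every interaction range: nothing can happen
    if b >= 0.0 and r2 > gmax2:
        return _BIG, 0

    it_i = itype[i]
    it_j = itype[j]
    c2 = core2[it_i, it_j]

    if chain_id[i] == chain_id[j]:
        dres = resix[i] - resix[j]
        if -1 <= dres <= 1:
            # pseudo-bonded: free flight inside the distance window
            for k in range(bnd_ptr[i], bnd_ptr[i + 1]):
                if bnd_idx[k] == j:
                    tin = _t_inner(r2, b, a, bnd_lo2[k])
                    if tin >= 0.0:
                        return t + tin, EV_BOND_LO
                    return t + _t_outer(r2, b, a, bnd_hi2[k]), EV_BOND_HI
            # local non-bonded: reduced hard core only
            tin = _t_inner(r2, b, a, squeeze2 * c2)
            if tin >= 0.0:
                return t + tin, EV_CORE
            return _BIG, 0

    ki = kind[i]
    kj = kind[j]
    # NH-CO: the directional hydrogen-bond well.  Hydrogen bonds are
    # intermolecular only: the strand-forming 11-mers are modeled
    # without the intramolecular (hairpin) channel, which at this
    # system size competes with fibrillization far more than in the
    # full-scale model.
    if (ki == 0 and kj == 2) or (ki == 2 and kj == 0):
        if chain_id[i] == chain_id[j]:
            tin = _t_inner(r2, b, a, c2)
            if tin >= 0.0:
                return t + tin, EV_CORE
            return _BIG, 0
        if hb_partner[i] == j:
            tin = _t_inner(r2, b, a, c2)
            if tin >= 0.0:
                return t + tin, EV_CORE
            return t + _t_outer(r2, b, a, hbd2), EV_HB_OUT
        inside = r2 < hbd2 - _EDGE_EPS or (r2 <= hbd2 + _EDGE_EPS and b < 0.0)
        if inside:
            tin = _t_inner(r2, b, a, c2)
            if tin >= 0.0:
                return t + tin, EV_CORE
            return _BIG, 0
        tin = _t_inner(r2, b, a, hbd2)
        if tin >= 0.0:
            return t + tin, EV_HB_IN
        return _BIG, 0

    # sidechain-sidechain square well
    e2 = well_edge2[it_i, it_j]
    if e2 > 0.0:
        inside = r2 < e2 - _EDGE_EPS or (r2 <= e2 + _EDGE_EPS and b < 0.0)
        if inside:
            tin = _t_inner(r2, b, a, c2)
            if tin >= 0.0:
                return t + tin, EV_CORE
            return t + _t_outer(r2, b, a, e2), EV_WELL_OUT
        tin = _t_inner(r2, b, a, e2)
        if tin >= 0.0:
            return t + tin, EV_WELL_IN
        return _BIG, 0

    # plain hard spheres
    tin = _t_inner(r2, b, a, c2)
    if tin >= 0.0:
        return t + tin, EV_CORE
    return _BIG, 0


@njit(cache=True, inline="always", fastmath=True)
def _cell_cross_time(pos, vel, local_t, i, t, cs, cix, ciy, ciz):
    """Time at which bead i leaves its current cell (axis-aligned)."""
    best = _BIG
    x = pos[i, 0] + vel[i, 0] * (t - local_t[i])
    y = pos[i, 1] + vel[i, 1] * (t - local_t[i])
    z = pos[i, 2] + vel[i, 2] * (t - local_t[i])
    if vel[i, 0] > 0.0:
        dt = ((cix + 1) * cs - x) / vel[i, 0]
        if dt < best:
            best = dt
    elif vel[i, 0] < 0.0:
        dt = (cix * cs - x) / vel[i, 0]
        if dt < best:
            best = dt
    if vel[i, 1] > 0.0:
        dt = ((ciy + 1) * cs - y) / vel[i, 1]
        if dt < best:
            best = dt
    elif vel[i, 1] < 0.0:
        dt = (ciy * cs - y) / vel[i, 1]
        if dt < best:
            best = dt
    if vel[i, 2] > 0.0:
        dt = ((ciz + 1) * cs - z) / vel[i, 2]
        if dt < best:
            best = dt
    elif vel[i, 2] < 0.0:
        dt = (ciz * cs - z) / vel[i, 2]
        if dt < best:
            best = dt
    if best < 0.0:
        best = 0.0
    return t + best


@njit(cache=True, fastmath=True)
def _candidate(
    i, t,
    pos, vel, local_t, L,
    itype, kind, chain_id, resix,
    bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2,
    exc_ptr, exc_idx,
    core2, well_edge2, squeeze2,
    hbd2, hb_partner, gmax2,
    ncell, cs, cell_ix, head, nxt,
    with_crossing=True,
):
    """Bead i's earliest event: (time, partner or -1, code).

    Pseudo-bond partners and local (same/adjacent residue) non-bonded
    partners are iterated directly from their static lists -- they
    dominate the event rate -- and the cell scan covers only non-local
    pairs.
    """
    cix = cell_ix[i, 0]
    ciy = cell_ix[i, 1]
    ciz = cell_ix[i, 2]
    if with_crossing:
        best_t = _cell_cross_time(pos, vel, local_t, i, t, cs, cix, ciy, ciz)
    else:
        best_t = _BIG
    best_j = -1
    best_k = EV_CELL

    # bonded partners: window events always exist
    for k in range(bnd_ptr[i], bnd_ptr[i + 1]):
        j = bnd_idx[k]
        dx, dy, dz, vx, vy, vz = _pair_geom(pos, vel, local_t, i, j, t, L)
        a = vx * vx + vy * vy + vz * vz
        if a < 1.0e-30:
            continue
        r2 = dx * dx + dy * dy + dz * dz
        b = dx * vx + dy * vy + dz * vz
        tin = _t_inner(r2, b, a, bnd_lo2[k])
        if tin >= 0.0:
            te = t + tin
            ke = EV_BOND_LO
        else:
            te = t + _t_outer(r2, b, a, bnd_hi2[k])
            ke = EV_BOND_HI
        if te < best_t:
            best_t = te
            best_j = j
            best_k = ke

    # local non-bonded partners: reduced hard cores only
    for k in range(exc_ptr[i], exc_ptr[i + 1]):
        j = exc_idx[k]
        dx, dy, dz, vx, vy, vz = _pair_geom(pos, vel, local_t, i, j, t, L)
        a = vx * vx + vy * vy + vz * vz
        if a < 1.0e-30:
            continue
        r2 = dx * dx + dy * dy + dz * dz
        b = dx * vx + dy * vy + dz * vz
        tin = _t_inner(r2, b, a, squeeze2 * core2[itype[i], itype[j]])
        if tin >= 0.0 and t + tin < best_t:
            best_t = t + tin
            best_j = j
            best_k = EV_CORE

    chn = chain_id[i]
    ri = resix[i]
    for ox in range(-1, 2):
        cx = (cix + ox) % ncell
        for oy in range(-1, 2):
            cy = (ciy + oy) % ncell
            for oz in range(-1, 2):
                cz = (ciz + oz) % ncell
                c = (cx * ncell + cy) * ncell + cz
                b = head[c]
                while b >= 0:
                    if b != i and not (
                        chain_id[b] == chn and -2 < resix[b] - ri < 2
                    ):
                        te, ke = _pair_event(
                            pos, vel, local_t, i, b, t, L,
                            itype, kind, chain_id, resix,
                            bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2,
                            core2, well_edge2, squeeze2,
                            hbd2, hb_partner, gmax2,
                        )
                        if te < best_t:
                            best_t = te
                            best_j = b
                            best_k = ke
                    b = nxt[b]
    return best_t, best_j, best_k


@njit(cache=True, inline="always", fastmath=True)
def _advance(pos, vel, local_t, i, t):
    dt = t - local_t[i]
    pos[i, 0] += vel[i, 0] * dt
    pos[i, 1] += vel[i, 1] * dt
    pos[i, 2] += vel[i, 2] * dt
    local_t[i] = t


@njit(cache=True)
def _heap_push(hp_t, hp_i, hp_j, hp_k, hp_ci, hp_cj, hp_n, t, i, j, k, ci, cj):
    n = hp_n
    hp_t[n] = t
    hp_i[n] = i
    hp_j[n] = j
    hp_k[n] = k
    hp_ci[n] = ci
    hp_cj[n] = cj
    while n > 0:
        p = (n - 1) >> 1
        if hp_t[p] <= hp_t[n]:
            break
        for arr in (hp_t, ):
            tmp = arr[p]; arr[p] = arr[n]; arr[n] = tmp
        for arr in (hp_i, hp_j, hp_k, hp_ci, hp_cj):
            tmp = arr[p]; arr[p] = arr[n]; arr[n] = tmp
        n = p
    return hp_n + 1


@njit(cache=True)
def _heap_pop(hp_t, hp_i, hp_j, hp_k, hp_ci, hp_cj, hp_n):
    n = hp_n - 1
    t0 = hp_t[0]; i0 = hp_i[0]; j0 = hp_j[0]; k0 = hp_k[0]
    c0 = hp_ci[0]; d0 = hp_cj[0]
    hp_t[0] = hp_t[n]; hp_i[0] = hp_i[n]; hp_j[0] = hp_j[n]
    hp_k[0] = hp_k[n]; hp_ci[0] = hp_ci[n]; hp_cj[0] = hp_cj[n]
    p = 0
    while True:
        l = 2 * p + 1
        if l >= n:
            break
        r = l + 1
        m = l
        if r < n and hp_t[r] < hp_t[l]:
            m = r
        if hp_t[p] <= hp_t[m]:
            break
        tmp = hp_t[p]; hp_t[p] = hp_t[m]; hp_t[m] = tmp
        for arr in (hp_i, hp_j, hp_k, hp_ci, hp_cj):
            tmp2 = arr[p]; arr[p] = arr[m]; arr[m] = tmp2
        p = m
    return t0, i0, j0, k0, c0, d0, n


@njit(cache=True)
def _potential_energy(
    pos, vel, local_t, t, L, N,
    itype, kind, chain_id, resix,
    well_edge2, well_depth,
    hbd2, hb_depth, hb_partner,
):
    """Sum of occupied square-well energies at time t (eps_HB units).

    Only sidechain wells (by distance) and registered hydrogen bonds
    contribute; bonded and locally-excluded pairs carry no well.
    """
    u = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            if chain_id[i] == chain_id[j] and -1 <= resix[i] - resix[j] <= 1:
                continue  # pseudo-bonded or locally excluded: no well
            if hb_partner[i] == j:
                u -= hb_depth
                continue
            e2 = well_edge2[itype[i], itype[j]]
            if e2 <= 0.0:
                continue
            dx, dy, dz, vx, vy, vz = _pair_geom(pos, vel, local_t, i, j, t, L)
            r2 = dx * dx + dy * dy + dz * dz
            b = dx * vx + dy * vy + dz * vz
            if r2 < e2 - _EDGE_EPS or (r2 <= e2 + _EDGE_EPS and b < 0.0):
                u += well_depth[itype[i], itype[j]]
    return u


@njit(cache=True)
def _kinetic_energy(vel, mass):
    ke = 0.0
    for i in range(vel.shape[0]):
        ke += 0.5 * mass[i] * (
            vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
        )
    return ke


@njit(cache=True)
def _aux_ok(pos, vel, local_t, t, L, nh, co, flank1, flank2, aux_min2):
    """Directional constraint: beads flanking NH must stay clear of CO
    and vice versa at formation time."""
    for f in (flank1[nh], flank2[nh]):
        if f >= 0:
            dx, dy, dz, _, _, _ = _pair_geom(pos, vel, local_t, f, co, t, L)
            if dx * dx + dy * dy + dz * dz < aux_min2:
                return False
    for f in (flank1[co], flank2[co]):
        if f >= 0:
            dx, dy, dz, _, _, _ = _pair_geom(pos, vel, local_t, f, nh, t, L)
            if dx * dx + dy * dy + dz * dz < aux_min2:
                return False
    return True


@njit(cache=True, fastmath=True)
def run_core(
    pos, vel, local_t, mass,
    itype, kind, chain_id, resix,
    bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2,
    exc_ptr, exc_idx,
    core2, well_edge2, well_depth, squeeze2,
    hbd2, hb_depth, aux_min2, flank1, flank2, hb_partner,
    L, T_star, ghost_rate_per_bead,
    n_collisions, snapshot_every, count_ghosts,
    seed, t_start,
):
    """Advance the event loop for `n_collisions` velocity-changing events.

    Mutates pos/vel/local_t/hb_partner in place and returns snapshot
    arrays plus counters.  Deterministic for a given seed.
    """
    np.random.seed(seed)
    N = pos.shape[0]
    t = t_start

    # ---- cells -------------------------------------------------------
    max_r2 = hbd2
    for ii in range(well_edge2.shape[0]):
        for jj in range(well_edge2.shape[1]):
            if well_edge2[ii, jj] > max_r2:
                max_r2 = well_edge2[ii, jj]
            if core2[ii, jj] > max_r2:
                max_r2 = core2[ii, jj]
    for k in range(bnd_hi2.shape[0]):
        if bnd_hi2[k] > max_r2:
            max_r2 = bnd_hi2[k]
    max_range = np.sqrt(max_r2)
    gmax2 = max_r2
    ncell = int(L / max_range)
    if ncell < 1:
        ncell = 1
    if ncell > 64:
        ncell = 64
    cs = L / ncell

    head = np.full(ncell * ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(N, -1, dtype=np.int64)
    prv = np.full(N, -1, dtype=np.int64)
    cell_ix = np.empty((N, 3), dtype=np.int64)
    for i in range(N):
        for d in range(3):
            c = int(pos[i, d] / cs)
            if c >= ncell:
                c = ncell - 1
            if c < 0:
                c = 0
            cell_ix[i, d] = c
        c = (cell_ix[i, 0] * ncell + cell_ix[i, 1]) * ncell + cell_ix[i, 2]
        nxt[i] = head[c]
        if head[c] >= 0:
            prv[head[c]] = i
        prv[i] = -1
        head[c] = i

    # ---- heap --------------------------------------------------------
    cap = 64 + 32 * N
    hp_t = np.empty(cap)
    hp_i = np.empty(cap, dtype=np.int64)
    hp_j = np.empty(cap, dtype=np.int64)
    hp_k = np.empty(cap, dtype=np.int64)
    hp_ci = np.empty(cap, dtype=np.int64)
    hp_cj = np.empty(cap, dtype=np.int64)
    hp_n = 0
    # velocity-change counters invalidate pair predictions; crossing
    # epochs only guard against duplicate cell-crossing entries
    counters = np.zeros(N, dtype=np.int64)
    xepoch = np.zeros(N, dtype=np.int64)

    # ---- snapshots ---------------------------------------------------
    if snapshot_every <= 0:
        snapshot_every = n_collisions + 1
    max_snaps = n_collisions // snapshot_every + 3
    snap_t = np.empty(max_snaps)
    snap_pos = np.empty((max_snaps, N, 3))
    snap_hb = np.empty((max_snaps, N), dtype=np.int64)
    snap_ke = np.empty(max_snaps)
    snap_pe = np.empty(max_snaps)
    snap_coll = np.empty(max_snaps, dtype=np.int64)
    n_snap = 0

    # ---- initial candidates -----------------------------------------
    for i in range(N):
        counters[i] += 1
        bt, bj, bk = _candidate(
            i, t, pos, vel, local_t, L, itype, kind, chain_id, resix,
            bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2, exc_ptr, exc_idx,
            core2, well_edge2, squeeze2, hbd2, hb_partner, gmax2,
            ncell, cs, cell_ix, head, nxt,
        )
        cj = xepoch[i] if bk == EV_CELL else counters[bj]
        hp_n = _heap_push(
            hp_t, hp_i, hp_j, hp_k, hp_ci, hp_cj, hp_n,
            bt, i, bj, bk, counters[i], cj,
        )

    # ---- ghost schedule ----------------------------------------------
    total_ghost_rate = ghost_rate_per_bead * N
    if total_ghost_rate > 0.0:
        t_ghost = t + np.random.exponential(1.0 / total_ghost_rate)
    else:
        t_ghost = _BIG

    n_coll = 0
    n_ghost = 0
    n_cross = 0
    n_hb_form = 0
    n_hb_break = 0
    # safety cap: a system with no reachable two-body events (e.g. one
    # bead) must still terminate
    max_iters = 400 * (n_collisions + 1) + 1_000_000
    n_iters = 0
    n_stale_owner = 0
    n_stale_partner = 0
    kind_counts = np.zeros(16, dtype=np.int64)

    # initial snapshot
    for i in range(N):
        dt = t - local_t[i]
        snap_pos[n_snap, i, 0] = pos[i, 0] + vel[i, 0] * dt
        snap_pos[n_snap, i, 1] = pos[i, 1] + vel[i, 1] * dt
        snap_pos[n_snap, i, 2] = pos[i, 2] + vel[i, 2] * dt
        snap_hb[n_snap, i] = hb_partner[i]
    snap_t[n_snap] = t
    snap_ke[n_snap] = _kinetic_energy(vel, mass)
    snap_pe[n_snap] = _potential_energy(
        pos, vel, local_t, t, L, N, itype, kind, chain_id, resix,
        well_edge2, well_depth, hbd2, hb_depth, hb_partner,
    )
    snap_coll[n_snap] = 0
    n_snap += 1

    while n_coll < n_collisions:
        n_iters += 1
        if n_iters > max_iters:
            break
        # heap housekeeping: compact when close to capacity
        if hp_n > cap - 4:
            m = 0
            for q in range(hp_n):
                iq = hp_i[q]
                jq = hp_j[q]
                if hp_ci[q] != counters[iq]:
                    continue
                if hp_k[q] == EV_CELL and hp_cj[q] != xepoch[iq]:
                    continue
                # partner-stale pair entries are kept: popping them
                # triggers the owner's recompute
                if True:
                    hp_t[m] = hp_t[q]; hp_i[m] = iq; hp_j[m] = jq
                    hp_k[m] = hp_k[q]; hp_ci[m] = hp_ci[q]; hp_cj[m] = hp_cj[q]
                    m += 1
            hp_n = m
            # heapify
            for q in range(m // 2 - 1, -1, -1):
                p = q
                while True:
                    l = 2 * p + 1
                    if l >= m:
                        break
                    r = l + 1
                    mm = l
                    if r < m and hp_t[r] < hp_t[l]:
                        mm = r
                    if hp_t[p] <= hp_t[mm]:
                        break
                    tmp = hp_t[p]; hp_t[p] = hp_t[mm]; hp_t[mm] = tmp
                    for arr in (hp_i, hp_j, hp_k, hp_ci, hp_cj):
                        tmp2 = arr[p]; arr[p] = arr[mm]; arr[mm] = tmp2
                    p = mm

        # ghost collision first?
        if hp_n == 0 or t_ghost < hp_t[0]:
            if t_ghost >= _BIG:
                break  # nothing can ever happen again
            t = t_ghost
            g = np.random.randint(0, N)
            _advance(pos, vel, local_t, g, t)
            sig = np.sqrt(T_star / mass[g])
            vel[g, 0] = sig * np.random.normal()
            vel[g, 1] = sig * np.random.normal()
            vel[g, 2] = sig * np.random.normal()
            n_ghost += 1
            counters[g] += 1
            bt, bj, bk = _candidate(
                g, t, pos, vel, local_t, L, itype, kind, chain_id, resix,
                bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2, exc_ptr, exc_idx,
                core2, well_edge2, squeeze2, hbd2, hb_partner, gmax2,
                ncell, cs, cell_ix, head, nxt,
            )
            cj = xepoch[g] if bk == EV_CELL else counters[bj]
            hp_n = _heap_push(
                hp_t, hp_i, hp_j, hp_k, hp_ci, hp_cj, hp_n,
                bt, g, bj, bk, counters[g], cj,
            )
            t_ghost = t + np.random.exponential(1.0 / total_ghost_rate)
            if count_ghosts:
                n_coll += 1
                if n_coll % snapshot_every == 0 and n_snap < max_snaps:
                    for i in range(N):
                        dt = t - local_t[i]
                        snap_pos[n_snap, i, 0] = pos[i, 0] + vel[i, 0] * dt
                        snap_pos[n_snap, i, 1] = pos[i, 1] + vel[i, 1] * dt
                        snap_pos[n_snap, i, 2] = pos[i, 2] + vel[i, 2] * dt
                        snap_hb[n_snap, i] = hb_partner[i]
                    snap_t[n_snap] = t
                    snap_ke[n_snap] = _kinetic_energy(vel, mass)
                    snap_pe[n_snap] = _potential_energy(
                        pos, vel, local_t, t, L, N, itype, kind,
                        chain_id, resix,
                        well_edge2, well_depth, hbd2, hb_depth, hb_partner,
                    )
                    snap_coll[n_snap] = n_coll
                    n_snap += 1
            continue

        te, i, j, ke_code, ci, cj, hp_n = _heap_pop(
            hp_t, hp_i, hp_j, hp_k, hp_ci, hp_cj, hp_n
        )
        if ci != counters[i]:
            n_stale_owner += 1
            continue  # owner has a newer candidate elsewhere in the heap
        if ke_code == EV_CELL and cj != xepoch[i]:
            continue  # duplicate of an already-processed crossing
        if j >= 0 and cj != counters[j]:
            n_stale_partner += 1
            # partner velocity changed since scheduling: recompute the
            # owner's candidate (without bumping its counter -- only
            # velocity changes invalidate predictions) or its true next
            # event would be lost
            bt, bj, bk = _candidate(
                i, t, pos, vel, local_t, L, itype, kind, chain_id, resix,
                bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2, exc_ptr, exc_idx,
                core2, well_edge2, squeeze2, hbd2, hb_partner, gmax2,
                ncell, cs, cell_ix, head, nxt,
            )
            cjn = xepoch[i] if bk == EV_CELL else counters[bj]
            hp_n = _heap_push(
                hp_t, hp_i, hp_j, hp_k, hp_ci, hp_cj, hp_n,
                bt, i, bj, bk, counters[i], cjn,
            )
            continue
        t = te

        if ke_code == EV_CELL:
            _advance(pos, vel, local_t, i, t)
            # which axis boundary was reached? pick nearest boundary axis
            best_d = _BIG
            axis = 0
            direc = 1
            for d in range(3):
                lo = cell_ix[i, d] * cs
                hi = lo + cs
                dd = pos[i, d] - lo
                if dd < best_d:
                    best_d = dd
                    axis = d
                    direc = -1
                dd = hi - pos[i, d]
                if dd < best_d:
                    best_d = dd
                    axis = d
                    direc = 1
            # unlink from old cell
            c = (cell_ix[i, 0] * ncell + cell_ix[i, 1]) * ncell + cell_ix[i, 2]
            if prv[i] >= 0:
                nxt[prv[i]] = nxt[i]
            else:
                head[c] = nxt[i]
            if nxt[i] >= 0:
                prv[nxt[i]] = prv[i]
            # update cell index, wrap position across the box if needed
            newc = cell_ix[i, axis] + direc
            if newc < 0:
                newc = ncell - 1
                pos[i, axis] += L
            elif newc >= ncell:
                newc = 0
                pos[i, axis] -= L
            cell_ix[i, axis] = newc
            c = (cell_ix[i, 0] * ncell + cell_ix[i, 1]) * ncell + cell_ix[i, 2]
            nxt[i] = head[c]
            if head[c] >= 0:
                prv[head[c]] = i
            prv[i] = -1
            head[c] = i
            n_cross += 1
            # bump the crossing epoch (not the velocity counter: pair
            # predictions involving i stay valid) so that duplicate
            # crossing entries cannot re-fire and corrupt the cell index
            xepoch[i] += 1
            bt, bj, bk = _candidate(
                i, t, pos, vel, local_t, L, itype, kind, chain_id, resix,
                bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2, exc_ptr, exc_idx,
                core2, well_edge2, squeeze2, hbd2, hb_partner, gmax2,
                ncell, cs, cell_ix, head, nxt,
            )
            cjn = xepoch[i] if bk == EV_CELL else counters[bj]
            hp_n = _heap_push(
                hp_t, hp_i, hp_j, hp_k, hp_ci, hp_cj, hp_n,
                bt, i, bj, bk, counters[i], cjn,
            )
            continue

        # ---- two-body event ----
        kind_counts[ke_code] += 1
        _advance(pos, vel, local_t, i, t)
        _advance(pos, vel, local_t, j, t)
        dx = _mic(pos[i, 0] - pos[j, 0], L)
        dy = _mic(pos[i, 1] - pos[j, 1], L)
        dz = _mic(pos[i, 2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        rr = np.sqrt(r2)
        nx = dx / rr
        ny = dy / rr
        nz = dz / rr
        vr = (
            (vel[i, 0] - vel[j, 0]) * nx
            + (vel[i, 1] - vel[j, 1]) * ny
            + (vel[i, 2] - vel[j, 2]) * nz
        )
        mi = mass[i]
        mj = mass[j]
        mu = mi * mj / (mi + mj)

        # potential step for crossings: dU = U(after) - U(before)
        reflect = False
        dU = 0.0
        crossing = False
        if ke_code == EV_CORE or ke_code == EV_BOND_LO or ke_code == EV_BOND_HI:
            reflect = True
        elif ke_code == EV_WELL_IN:
            dU = well_depth[itype[i], itype[j]]
            crossing = True
        elif ke_code == EV_WELL_OUT:
            dU = -well_depth[itype[i], itype[j]]
            crossing = True
        elif ke_code == EV_HB_IN:
            nh = i if kind[i] == 0 else j
            co = j if kind[i] == 0 else i
            if (
                hb_partner[nh] < 0
                and hb_partner[co] < 0
                and _aux_ok(pos, vel, local_t, t, L, nh, co,
                            flank1, flank2, aux_min2)
            ):
                dU = -hb_depth
                crossing = True
                hb_partner[nh] = co
                hb_partner[co] = nh
                n_hb_form += 1
            else:
                # transparent crossing: no interaction for this pair now
                crossing = False
                reflect = False
        elif ke_code == EV_HB_OUT:
            dU = hb_depth
            crossing = True

        if crossing:
            need = vr * vr - 2.0 * dU / mu
            if dU > 0.0 and need <= 0.0:
                reflect = True
                if ke_code == EV_HB_OUT:
                    pass  # bond survives the failed escape
            else:
                vr_new = np.sqrt(need) if vr > 0.0 else -np.sqrt(need)
                p = mu * (vr_new - vr)
                vel[i, 0] += p * nx / mi
                vel[i, 1] += p * ny / mi
                vel[i, 2] += p * nz / mi
                vel[j, 0] -= p * nx / mj
                vel[j, 1] -= p * ny / mj
                vel[j, 2] -= p * nz / mj
                if ke_code == EV_HB_OUT:
                    hb_partner[i] = -1
                    hb_partner[j] = -1
                    n_hb_break += 1
        if reflect:
            p = -2.0 * mu * vr
            vel[i, 0] += p * nx / mi
            vel[i, 1] += p * ny / mi
            vel[i, 2] += p * nz / mi
            vel[j, 0] -= p * nx / mj
            vel[j, 1] -= p * ny / mj
            vel[j, 2] -= p * nz / mj

        n_coll += 1
        for bead in (i, j):
            counters[bead] += 1
            bt, bj, bk = _candidate(
                bead, t, pos, vel, local_t, L, itype, kind, chain_id, resix,
                bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2, exc_ptr, exc_idx,
                core2, well_edge2, squeeze2, hbd2, hb_partner, gmax2,
                ncell, cs, cell_ix, head, nxt,
            )
            cjn = xepoch[bead] if bk == EV_CELL else counters[bj]
            hp_n = _heap_push(
                hp_t, hp_i, hp_j, hp_k, hp_ci, hp_cj, hp_n,
                bt, bead, bj, bk, counters[bead], cjn,
            )

        if n_coll % snapshot_every == 0 and n_snap < max_snaps:
            for q in range(N):
                dt = t - local_t[q]
                snap_pos[n_snap, q, 0] = pos[q, 0] + vel[q, 0] * dt
                snap_pos[n_snap, q, 1] = pos[q, 1] + vel[q, 1] * dt
                snap_pos[n_snap, q, 2] = pos[q, 2] + vel[q, 2] * dt
                snap_hb[n_snap, q] = hb_partner[q]
            snap_t[n_snap] = t
            snap_ke[n_snap] = _kinetic_energy(vel, mass)
            snap_pe[n_snap] = _potential_energy(
                pos, vel, local_t, t, L, N, itype, kind, chain_id, resix,
                well_edge2, well_depth, hbd2, hb_depth, hb_partner,
            )
            snap_coll[n_snap] = n_coll
            n_snap += 1

    # final sync: advance everyone to t
    for i in range(N):
        _advance(pos, vel, local_t, i, t)
    if n_snap == 0 or snap_coll[n_snap - 1] != n_coll:
        if n_snap < max_snaps:
            for q in range(N):
                snap_pos[n_snap, q, 0] = pos[q, 0]
                snap_pos[n_snap, q, 1] = pos[q, 1]
                snap_pos[n_snap, q, 2] = pos[q, 2]
                snap_hb[n_snap, q] = hb_partner[q]
            snap_t[n_snap] = t
            snap_ke[n_snap] = _kinetic_energy(vel, mass)
            snap_pe[n_snap] = _potential_energy(
                pos, vel, local_t, t, L, N, itype, kind, chain_id, resix,
                well_edge2, well_depth, hbd2, hb_depth, hb_partner,
            )
            snap_coll[n_snap] = n_coll
            n_snap += 1

    return (
        snap_t[:n_snap].copy(),
        snap_pos[:n_snap].copy(),
        snap_hb[:n_snap].copy(),
        snap_ke[:n_snap].copy(),
        snap_pe[:n_snap].copy(),
        snap_coll[:n_snap].copy(),
        t,
        n_coll,
        n_ghost,
        n_cross,
        n_hb_form,
        n_hb_break,
        n_iters,
        n_stale_owner,
        n_stale_partner,
        kind_counts,
    )


@njit(cache=True, fastmath=True)
def first_event_core(
    pos, vel, local_t,
    itype, kind, chain_id, resix,
    bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2,
    exc_ptr, exc_idx,
    core2, well_edge2, squeeze2,
    hbd2, hb_partner,
    L, t_start, include_crossings,
):
    """Globally earliest two-body/cell event via the cell-list scan.

    Returns (time, i, j, code); j = -1 for a cell crossing.  Used by the
    `next_event` API; the brute-force pair scan in the test-suite oracle
    is independent of this path.
    """
    N = pos.shape[0]
    max_r2 = hbd2
    for ii in range(well_edge2.shape[0]):
        for jj in range(well_edge2.shape[1]):
            if well_edge2[ii, jj] > max_r2:
                max_r2 = well_edge2[ii, jj]
            if core2[ii, jj] > max_r2:
                max_r2 = core2[ii, jj]
    for k in range(bnd_hi2.shape[0]):
        if bnd_hi2[k] > max_r2:
            max_r2 = bnd_hi2[k]
    max_range = np.sqrt(max_r2)
    gmax2 = max_r2
    ncell = int(L / max_range)
    if ncell < 1:
        ncell = 1
    if ncell > 64:
        ncell = 64
    cs = L / ncell
    head = np.full(ncell * ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(N, -1, dtype=np.int64)
    cell_ix = np.empty((N, 3), dtype=np.int64)
    for i in range(N):
        for d in range(3):
            c = int(pos[i, d] / cs)
            if c >= ncell:
                c = ncell - 1
            if c < 0:
                c = 0
            cell_ix[i, d] = c
        c = (cell_ix[i, 0] * ncell + cell_ix[i, 1]) * ncell + cell_ix[i, 2]
        nxt[i] = head[c]
        head[c] = i

    best_t = _BIG
    best_i = -1
    best_j = -1
    best_k = 0
    for i in range(N):
        bt, bj, bk = _candidate(
            i, t_start, pos, vel, local_t, L, itype, kind, chain_id, resix,
            bnd_ptr, bnd_idx, bnd_lo2, bnd_hi2, exc_ptr, exc_idx,
            core2, well_edge2, squeeze2, hbd2, hb_partner, gmax2,
            ncell, cs, cell_ix, head, nxt,
            include_crossings,
        )
        if bt < best_t:
            best_t = bt
            best_i = i
            best_j = bj
            best_k = bk
    return best_t, best_i, best_j, best_k
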