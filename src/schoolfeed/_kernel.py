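"""Compiled fast path for the per-step behavioral loop.

This module mirrors, operation for operation, the reference implementation
in :mod:`schoolfeed.behavior` and :mod:`schoolfeed.feed`, and the test
suite checks the two against each other on identical random streams.  All
selection logic (field-of-view membership, nearest neighbor/boundary/
pellet, tie-breaks, mode gates) follows the same rules and tie orders as
the reference; the neighbor centroid/heading sums may be reassociated for
vectorization, so trajectories agree to floating-point tolerance rather
than bit-for-bit.  All randomness is pre-drawn by the caller (raw wander
vectors, a tie-break uniform pool for contested pellets), so the kernel
itself is purely deterministic.

Pellets never move horizontally, so a CSR cell grid over the feeding square
is built once per day and reused for both the nearest-pellet search
(expanding Chebyshev rings with a conservative distance bound) and the
contact test.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_steps", "build_pellet_grid", "GRID_CELL"]

#: Horizontal cell size (m) of the pellet lookup grid.
GRID_CELL = 0.05


def build_pellet_grid(px: np.ndarray, py: np.ndarray, x0: float, y0: float,
                      side: float, cell: float = GRID_CELL):
    """CSR cell grid over the feeding square for the day's pellets.

    Returns (cell_start, cell_items, ncx, ncy).  Items within a cell are in
    ascending pellet id (stable sort), which keeps tie handling identical
    to the brute-force reference.
    """
    ncx = max(1, int(np.ceil(side / cell)))
    ncy = ncx
    ix = np.clip(((px - x0) / cell).astype(np.int64), 0, ncx - 1)
    iy = np.clip(((py - y0) / cell).astype(np.int64), 0, ncy - 1)
    ci = ix * ncy + iy
    order = np.argsort(ci, kind="stable").astype(np.int64)
    counts = np.bincount(ci, minlength=ncx * ncy)
    cell_start = np.zeros(ncx * ncy + 1, dtype=np.int64)
    np.cumsum(counts, out=cell_start[1:])
    return cell_start, order, ncx, ncy


@njit(cache=True)
def _nearest_pellet(fx, fy, fz, px, py, pz, palive,
                    x0, y0, cell, ncx, ncy, cell_start, cell_items):
    """Nearest live pellet id (or -1), ties to the smallest pellet id."""
    ci = int((fx - x0) / cell)
    if ci < 0:
        ci = 0
    elif ci > ncx - 1:
        ci = ncx - 1
    cj = int((fy - y0) / cell)
    if cj < 0:
        cj = 0
    elif cj > ncy - 1:
        cj = ncy - 1
    best = 1e300
    best_p = -1
    max_r = ncx if ncx > ncy else ncy
    for r in range(max_r + 1):
        if best_p >= 0 and r >= 2:
            bound = (r - 1) * cell
            if bound * bound > best:
                break
        a_lo = ci - r
        a_hi = ci + r
        for a in range(a_lo, a_hi + 1):
            if a < 0 or a >= ncx:
                continue
            if a == a_lo or a == a_hi:
                b_range_lo, b_range_hi, b_step = cj - r, cj + r, 1
            else:
                b_range_lo, b_range_hi, b_step = cj - r, cj + r, 2 * r if r > 0 else 1
            b = b_range_lo
            while b <= b_range_hi:
                if 0 <= b < ncy:
                    c = a * ncy + b
                    for t in range(cell_start[c], cell_start[c + 1]):
                        p = cell_items[t]
                        if palive[p]:
                            dx = px[p] - fx
                            dy = py[p] - fy
                            dz = pz[p] - fz
                            d2 = dx * dx + dy * dy + dz * dz
                            if d2 < best or (d2 == best and p < best_p):
                                best = d2
                                best_p = p
                b += b_step
    return best_p, best


@njit(cache=True, fastmath={"reassoc", "contract", "nsz", "nnan"})
def run_steps(
    # fish state, modified in place
    x, y, z, vx, vy, vz, tl, mass, intake, neaten, smax, feeding,
    # pellet state
    px, py, pz, palive,
    # pellet grid
    gx0, gy0, gcell, ncx, ncy, cell_start, cell_items,
    # pre-drawn randomness
    rand_units, tie_u,
    # parameters
    radius, depth, dt,
    w1, w2, w3, w4, w5, w6, cv_std, cv_feed,
    fov_factor, cos_dead,
    pellet_radius, contact_factor, sink_speed, pellet_mass,
    mass_div, wall_eps,
    step0,
    # event log
    ev_fish, ev_pellet, ev_step,
    # in/out counters: [n_alive, tie_count, ev_count, completion_step]
    state_io,
):
    n = x.shape[0]
    n_steps = rand_units.shape[0]
    n_alive = state_io[0]
    tie_count = state_io[1]
    ev_count = state_io[2]
    completion = state_io[3]
    # scratch allocated here so LLVM knows it does not alias the state
    fxs = np.empty(n)
    fys = np.empty(n)
    fzs = np.empty(n)
    d2buf = np.empty(n)
    wbuf = np.empty(n)
    hadnb = np.zeros(n, dtype=np.uint8)  # had neighbors last step
    pair_cap = 4096 + 16 * n
    pair_p = np.empty(pair_cap, dtype=np.int64)
    pair_f = np.empty(pair_cap, dtype=np.int64)
    cont_f = np.empty(n, dtype=np.int64)
    for k in range(n_steps):
        feed_present = n_alive > 0
        for i in range(n):
            feeding[i] = 1 if (feed_present and intake[i] < smax[i]) else 0
        # ---- forces (synchronous: all read the time-t state) ----
        for i in range(n):
            xi = x[i]
            yi = y[i]
            zi = z[i]
            vxi = vx[i]
            vyi = vy[i]
            vzi = vz[i]
            spd2 = vxi * vxi + vyi * vyi + vzi * vzi
            cd2spd2 = (cos_dead * cos_dead) * spd2
            rview = fov_factor * tl[i]
            r2max = rview * rview
            sx = 0.0
            sy = 0.0
            sz = 0.0
            svx = 0.0
            svy = 0.0
            svz = 0.0
            nn_j = -1
            nn_d2 = 1e300
            # a cheap distance prefilter skips the membership pass for fish
            # with no one in range; fish that had neighbors on the previous
            # step go straight to the membership pass (results identical)
            run_membership = hadnb[i] == 1
            if not run_membership:
                ncf = 0.0
                for j in range(n):
                    dx = x[j] - xi
                    dy = y[j] - yi
                    dz = z[j] - zi
                    d2 = dx * dx + dy * dy + dz * dz
                    ncf += 1.0 if d2 <= r2max else 0.0
                run_membership = ncf > 1.0  # someone besides self in range
            m_cnt = 0
            if run_membership:
                # membership pass: in-view neighbors get weight exactly 1.0
                mcf = 0.0
                for j in range(n):
                    dx = x[j] - xi
                    dy = y[j] - yi
                    dz = z[j] - zi
                    d2 = dx * dx + dy * dy + dz * dz
                    dotb = dx * (-vxi) + dy * (-vyi) + dz * (-vzi)
                    # dead cone, squared form of: dotb > cos_dead * |d| * |v|
                    excl = (spd2 > 0.0 and d2 > 0.0 and dotb > 0.0
                            and dotb * dotb > cd2spd2 * d2)
                    ok = d2 <= r2max and not excl
                    wgt = 1.0 if ok else 0.0
                    wbuf[j] = wgt
                    d2buf[j] = d2 if ok else 1e300
                    mcf += wgt
                mcf -= wbuf[i]  # drop self (in range, never in the cone)
                wbuf[i] = 0.0
                d2buf[i] = 1e300
                m_cnt = int(mcf)
            hadnb[i] = 1 if m_cnt > 0 else 0
            if m_cnt > 0:
                # masked sums (reassociation allowed: vectorizable)
                for j in range(n):
                    wgt = wbuf[j]
                    sx += wgt * x[j]
                    sy += wgt * y[j]
                    sz += wgt * z[j]
                    svx += wgt * vx[j]
                    svy += wgt * vy[j]
                    svz += wgt * vz[j]
                # nearest in-view neighbor: 4-way min reduction, then the
                # first index attaining it (ties to the lowest id)
                mn0 = 1e300
                mn1 = 1e300
                mn2 = 1e300
                mn3 = 1e300
                j = 0
                while j + 3 < n:
                    a = d2buf[j]
                    b = d2buf[j + 1]
                    c = d2buf[j + 2]
                    d = d2buf[j + 3]
                    mn0 = a if a < mn0 else mn0
                    mn1 = b if b < mn1 else mn1
                    mn2 = c if c < mn2 else mn2
                    mn3 = d if d < mn3 else mn3
                    j += 4
                while j < n:
                    v = d2buf[j]
                    mn0 = v if v < mn0 else mn0
                    j += 1
                mn0 = mn0 if mn0 < mn1 else mn1
                mn2 = mn2 if mn2 < mn3 else mn3
                nn_d2 = mn0 if mn0 < mn2 else mn2
                for j in range(n):
                    if d2buf[j] == nn_d2:
                        nn_j = j
                        break
            # normalize the raw wander draw (cube-sampled, per the model)
            rux = rand_units[k, i, 0]
            ruy = rand_units[k, i, 1]
            ruz = rand_units[k, i, 2]
            rnrm = math.sqrt(rux * rux + ruy * ruy + ruz * ruz)
            rux = rux / rnrm
            ruy = ruy / rnrm
            ruz = ruz / rnrm
            # F1 separation (nearest in-view individual)
            if nn_j >= 0:
                ax = xi - x[nn_j]
                ay = yi - y[nn_j]
                az = zi - z[nn_j]
                nrm = math.sqrt(ax * ax + ay * ay + az * az)
                if nrm == 0.0:
                    fx_ = w1 * rux
                    fy_ = w1 * ruy
                    fz_ = w1 * ruz
                else:
                    fx_ = w1 * (ax / nrm)
                    fy_ = w1 * (ay / nrm)
                    fz_ = w1 * (az / nrm)
            else:
                fx_ = 0.0
                fy_ = 0.0
                fz_ = 0.0
            # F2 cohesion (centroid of in-view neighbors)
            if m_cnt > 0:
                ax = sx / m_cnt - xi
                ay = sy / m_cnt - yi
                az = sz / m_cnt - zi
                nrm = math.sqrt(ax * ax + ay * ay + az * az)
                if nrm > 0.0:
                    fx_ += w2 * (ax / nrm)
                    fy_ += w2 * (ay / nrm)
                    fz_ += w2 * (az / nrm)
                # F3 alignment (mean neighbor velocity)
                ax = svx / m_cnt - vxi
                ay = svy / m_cnt - vyi
                az = svz / m_cnt - vzi
                nrm = math.sqrt(ax * ax + ay * ay + az * az)
                if nrm > 0.0:
                    fx_ += w3 * (ax / nrm)
                    fy_ += w3 * (ay / nrm)
                    fz_ += w3 * (az / nrm)
            # F4 boundary (nearest in-view of wall / bottom / surface)
            rxy = math.sqrt(xi * xi + yi * yi)
            bbx = 0.0
            bby = 0.0
            bbz = 0.0
            bfound = False
            bd = 1e300
            if rxy > 0.0:
                dwall = radius - rxy
                if dwall <= rview and dwall < bd:
                    bd = dwall
                    scale = radius / rxy
                    bbx = xi * scale
                    bby = yi * scale
                    bbz = zi
                    bfound = True
            else:
                if radius <= rview:
                    bd = radius
                    bbx = radius
                    bby = 0.0
                    bbz = zi
                    bfound = True
            if zi <= rview and zi < bd:
                bd = zi
                bbx = xi
                bby = yi
                bbz = 0.0
                bfound = True
            if (depth - zi) <= rview and (depth - zi) < bd:
                bd = depth - zi
                bbx = xi
                bby = yi
                bbz = depth
                bfound = True
            if bfound:
                ax = xi - bbx
                ay = yi - bby
                az = zi - bbz
                nrm = math.sqrt(ax * ax + ay * ay + az * az)
                if nrm > 0.0:
                    fx_ += w4 * (ax / nrm)
                    fy_ += w4 * (ay / nrm)
                    fz_ += w4 * (az / nrm)
            # F5 feed attraction (nearest live pellet, no field-of-view limit)
            if feeding[i] == 1 and w5 != 0.0:
                p_near, pd2 = _nearest_pellet(
                    xi, yi, zi, px, py, pz, palive,
                    gx0, gy0, gcell, ncx, ncy, cell_start, cell_items)
                if p_near >= 0:
                    ax = px[p_near] - xi
                    ay = py[p_near] - yi
                    az = pz[p_near] - zi
                    nrm = math.sqrt(ax * ax + ay * ay + az * az)
                    if nrm == 0.0:
                        fx_ += w5 * rux
                        fy_ += w5 * ruy
                        fz_ += w5 * ruz
                    else:
                        fx_ += w5 * (ax / nrm)
                        fy_ += w5 * (ay / nrm)
                        fz_ += w5 * (az / nrm)
            # F6 random wander
            fx_ += w6 * rux
            fy_ += w6 * ruy
            fz_ += w6 * ruz
            fxs[i] = fx_
            fys[i] = fy_
            fzs[i] = fz_
        # ---- integrate (semi-implicit Euler, speed cap, clamp) ----
        for i in range(n):
            m_i = mass[i] / mass_div
            nvx = vx[i] + (fxs[i] / m_i) * dt
            nvy = vy[i] + (fys[i] / m_i) * dt
            nvz = vz[i] + (fzs[i] / m_i) * dt
            cv = cv_feed if feeding[i] == 1 else cv_std
            vmax = cv * tl[i]
            spd = math.sqrt(nvx * nvx + nvy * nvy + nvz * nvz)
            if spd > vmax:
                sc = vmax / spd
                nvx = nvx * sc
                nvy = nvy * sc
                nvz = nvz * sc
            nx = x[i] + nvx * dt
            ny = y[i] + nvy * dt
            nz = z[i] + nvz * dt
            rmax = radius - wall_eps
            rxy = math.sqrt(nx * nx + ny * ny)
            if rxy > rmax:
                s = rmax / rxy
                nx = nx * s
                ny = ny * s
                ux = nx / rmax
                uy = ny / rmax
                vr = nvx * ux + nvy * uy
                if vr > 0.0:
                    nvx = nvx - vr * ux
                    nvy = nvy - vr * uy
            if nz < wall_eps:
                nz = wall_eps
                if nvz < 0.0:
                    nvz = 0.0
            elif nz > depth - wall_eps:
                nz = depth - wall_eps
                if nvz > 0.0:
                    nvz = 0.0
            x[i] = nx
            y[i] = ny
            z[i] = nz
            vx[i] = nvx
            vy[i] = nvy
            vz[i] = nvz
        if n_alive > 0:
            # ---- sink ----
            for p in range(px.shape[0]):
                if palive[p]:
                    zp = pz[p] - sink_speed * dt
                    if zp < 0.0:
                        zp = 0.0
                    pz[p] = zp
            # ---- collect fish-pellet contacts (fish-major, ascending) ----
            n_pairs = 0
            for i in range(n):
                if feeding[i] == 0:
                    continue
                rc = pellet_radius + contact_factor * tl[i]
                rc2 = rc * rc
                a0 = int(np.floor((x[i] - rc - gx0) / gcell))
                a1 = int(np.floor((x[i] + rc - gx0) / gcell))
                b0 = int(np.floor((y[i] - rc - gy0) / gcell))
                b1 = int(np.floor((y[i] + rc - gy0) / gcell))
                if a1 < 0 or a0 >= ncx or b1 < 0 or b0 >= ncy:
                    continue
                if a0 < 0:
                    a0 = 0
                if a1 >= ncx:
                    a1 = ncx - 1
                if b0 < 0:
                    b0 = 0
                if b1 >= ncy:
                    b1 = ncy - 1
                for a in range(a0, a1 + 1):
                    for b in range(b0, b1 + 1):
                        c = a * ncy + b
                        for t in range(cell_start[c], cell_start[c + 1]):
                            p = cell_items[t]
                            if not palive[p]:
                                continue
                            dx = px[p] - x[i]
                            dy = py[p] - y[i]
                            dz = pz[p] - z[i]
                            if dx * dx + dy * dy + dz * dz <= rc2:
                                if n_pairs < pair_cap:
                                    pair_p[n_pairs] = p
                                    pair_f[n_pairs] = i
                                    n_pairs += 1
            # ---- resolve contested pellets in ascending pellet id ----
            while True:
                pmin = -1
                for q in range(n_pairs):
                    if pair_p[q] >= 0 and (pmin < 0 or pair_p[q] < pmin):
                        pmin = pair_p[q]
                if pmin < 0:
                    break
                n_cont = 0
                for q in range(n_pairs):
                    if pair_p[q] == pmin:
                        i = pair_f[q]
                        # live satiation gate: keeps overshoot < one pellet
                        if intake[i] < smax[i]:
                            cont_f[n_cont] = i
                            n_cont += 1
                        pair_p[q] = -1
                if n_cont > 0:
                    u = tie_u[tie_count]
                    tie_count += 1
                    idx = int(u * n_cont)
                    if idx >= n_cont:
                        idx = n_cont - 1
                    i = cont_f[idx]
                    palive[pmin] = False
                    neaten[i] += 1
                    # intake is defined as count x pellet mass (kept exact)
                    intake[i] = neaten[i] * pellet_mass
                    ev_fish[ev_count] = i
                    ev_pellet[ev_count] = pmin
                    ev_step[ev_count] = step0 + k
                    ev_count += 1
                    n_alive -= 1
                    if n_alive == 0 and completion < 0:
                        completion = step0 + k
    state_io[0] = n_alive
    state_io[1] = tie_count
    state_io[2] = ev_count
    state_io[3] = completion
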