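"""Numba kernels: cell-list energies and the Metropolis sweep engine.

All energetic conventions mirror :mod:`patchnet.model` (square-well depth
``-epsilon``, hard core as rejection, both patch states must be closed).
The sweep kernel mutates the coordinate/state arrays in place and keeps the
linked-cell list incrementally up to date; it is seeded explicitly so runs
are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi
THIRD = TWO_PI / 3.0

# counter slots
ATT_TR, ACC_TR, ATT_ROT, ACC_ROT, ATT_FLIP, ACC_FLIP, ATT_CL, ACC_CL, BB_ACC = range(9)
N_COUNTERS = 9


@njit(cache=True, inline="always")
def _mi(d, box):
    return d - box * np.floor(d / box + 0.5)


@njit(cache=True, inline="always")
def _wrap_pi(a):
    return a - TWO_PI * np.floor(a / TWO_PI + 0.5)


_C120 = -0.5
_S120 = 0.8660254037844386


@njit(cache=True, inline="always")
def _pair_e(dx, dy, oi, si0, si1, si2, oj, sj0, sj1, sj2,
            sigma2, rc2, cos_theta, eps):
    """Pair energy from a min-imaged displacement i->j.  inf marks overlap.

    The angular criterion |deviation| < theta_pw is evaluated as
    cos(deviation) > cos(theta_pw); patch directions are generated by
    rotating (cos o, sin o) through 120-degree steps, avoiding arctangents.
    """
    r2 = dx * dx + dy * dy
    if r2 < sigma2:
        return np.inf
    if r2 >= rc2:
        return 0.0
    inv = 1.0 / np.sqrt(r2)
    cphi = dx * inv
    sphi = dy * inv
    ca = np.cos(oi)
    sa = np.sin(oi)
    hit_i = False
    for a in range(3):
        st = si0 if a == 0 else (si1 if a == 1 else si2)
        if st == 1 and ca * cphi + sa * sphi > cos_theta:
            hit_i = True
            break
        ca, sa = ca * _C120 - sa * _S120, sa * _C120 + ca * _S120
    if not hit_i:
        return 0.0
    cb = np.cos(oj)
    sb = np.sin(oj)
    for b in range(3):
        st = sj0 if b == 0 else (sj1 if b == 1 else sj2)
        # j's patch must point along -r_hat
        if st == 1 and -(cb * cphi + sb * sphi) > cos_theta:
            return -eps
        cb, sb = cb * _C120 - sb * _S120, sb * _C120 + cb * _S120
    return 0.0


@njit(cache=True, inline="always")
def _cell_of(xx, yy, cellsz, ncell):
    cx = int(xx / cellsz)
    cy = int(yy / cellsz)
    if cx >= ncell:
        cx = ncell - 1
    if cy >= ncell:
        cy = ncell - 1
    return cy * ncell + cx


@njit(cache=True)
def build_cells(x, y, n, cellsz, ncell, head, nxt):
    for c in range(head.shape[0]):
        head[c] = -1
    for i in range(n):
        c = _cell_of(x[i], y[i], cellsz, ncell)
        nxt[i] = head[c]
        head[c] = i


@njit(cache=True, inline="always")
def _cell_remove(i, c, head, nxt):
    j = head[c]
    if j == i:
        head[c] = nxt[i]
        return
    while nxt[j] != i:
        j = nxt[j]
    nxt[j] = nxt[i]


@njit(cache=True)
def _local_energy(i_skip, xt, yt, ot, st0, st1, st2,
                  x, y, o, s, head, nxt, box, cellsz, ncell,
                  sigma2, rc2, cos_theta, eps):
    """Energy of a (possibly trial) particle against all others.

    Returns (energy, overlap_flag, bond_count).
    """
    e = 0.0
    nb = 0
    if ncell >= 3:
        cx = int(xt / cellsz)
        cy = int(yt / cellsz)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        for dcy in range(-1, 2):
            yy = (cy + dcy) % ncell
            for dcx in range(-1, 2):
                cc = yy * ncell + (cx + dcx) % ncell
                j = head[cc]
                while j >= 0:
                    if j != i_skip:
                        dx = _mi(x[j] - xt, box)
                        dy = _mi(y[j] - yt, box)
                        eij = _pair_e(dx, dy, ot, st0, st1, st2,
                                      o[j], s[j, 0], s[j, 1], s[j, 2],
                                      sigma2, rc2, cos_theta, eps)
                        if eij == np.inf:
                            return 0.0, True, 0
                        if eij < 0.0:
                            nb += 1
                        e += eij
                    j = nxt[j]
    else:
        j = head[0]
        while j >= 0:
            if j != i_skip:
                dx = _mi(x[j] - xt, box)
                dy = _mi(y[j] - yt, box)
                eij = _pair_e(dx, dy, ot, st0, st1, st2,
                              o[j], s[j, 0], s[j, 1], s[j, 2],
                              sigma2, rc2, cos_theta, eps)
                if eij == np.inf:
                    return 0.0, True, 0
                if eij < 0.0:
                    nb += 1
                e += eij
            j = nxt[j]
    return e, False, nb


@njit(cache=True)
def total_energy_cells(x, y, o, s, box, sigma, delta, theta, eps):
    """Cell-list total energy; identical to the O(N^2) unordered-pair sum."""
    n = x.shape[0]
    ncell = int(box / (sigma + delta))
    if ncell < 3:
        ncell = 1
    cellsz = box / ncell
    head = np.full(ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    build_cells(x, y, n, cellsz, ncell, head, nxt)
    sigma2 = sigma * sigma
    rc2 = (sigma + delta) ** 2
    cth = np.cos(theta)
    e = 0.0
    for i in range(n):
        ei, ov, _ = _local_energy(i, x[i], y[i], o[i], s[i, 0], s[i, 1], s[i, 2],
                                  x, y, o, s, head, nxt, box, cellsz, ncell,
                                  sigma2, rc2, cth, eps)
        if ov:
            return np.inf
        e += ei
    return 0.5 * e


@njit(cache=True)
def list_bonds(x, y, o, s, box, sigma, delta, theta):
    """All bonded pairs with their patch indices (brute-force pair scan).

    Returns an (m, 4) int64 array of (i, j, patch_i, patch_j); each pair
    carries the patch combination with the smallest summed angular deviation.
    """
    n = x.shape[0]
    out = np.empty((3 * n // 2 + 3, 4), dtype=np.int64)
    m = 0
    sigma2 = sigma * sigma
    rc2 = (sigma + delta) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mi(x[j] - x[i], box)
            dy = _mi(y[j] - y[i], box)
            r2 = dx * dx + dy * dy
            if r2 < sigma2 or r2 >= rc2:
                continue
            phi = np.arctan2(dy, dx)
            best = 1e30
            ba = -1
            bb = -1
            for a in range(3):
                if s[i, a] != 1:
                    continue
                di = abs(_wrap_pi(o[i] + a * THIRD - phi))
                if di >= theta:
                    continue
                for b in range(3):
                    if s[j, b] != 1:
                        continue
                    dj = abs(_wrap_pi(o[j] + b * THIRD - phi - np.pi))
                    if dj >= theta:
                        continue
                    if di + dj < best:
                        best = di + dj
                        ba = a
                        bb = b
            if ba >= 0:
                if m >= out.shape[0]:
                    tmp = np.empty((out.shape[0] * 2, 4), dtype=np.int64)
                    tmp[:m] = out[:m]
                    out = tmp
                out[m, 0] = i
                out[m, 1] = j
                out[m, 2] = ba
                out[m, 3] = bb
                m += 1
    return out[:m]


@njit(cache=True)
def run_block(x, y, o, s, n, box, sigma, delta, theta, eps, p_open,
              dmax, rmax, cum_tr, cum_rot, cum_flip,
              n_sweeps, seed,
              head, nxt, cellsz, ncell,
              cl_stack, in_cl, ux, uy, wx, wy,
              counters):
    """Run ``n_sweeps`` Metropolis sweeps (n moves each) in place.

    Move type per attempt: translate / rotate / state-flip / cluster with
    cumulative probabilities (cum_tr, cum_rot, cum_flip, 1).  Returns the
    accumulated energy change.  ``counters`` (length 9) collects attempts,
    acceptances and accepted bond-breaking moves.
    """
    np.random.seed(seed)
    sigma2 = sigma * sigma
    rc2 = (sigma + delta) ** 2
    cth = np.cos(theta)
    dE_total = 0.0
    for _ in range(n_sweeps):
        for _ in range(n):
            u = np.random.random()
            if u < cum_tr:
                # ---- translation ----
                counters[ATT_TR] += 1
                i = int(np.random.random() * n)
                xt = x[i] + dmax * (2.0 * np.random.random() - 1.0)
                yt = y[i] + dmax * (2.0 * np.random.random() - 1.0)
                xt -= box * np.floor(xt / box)
                yt -= box * np.floor(yt / box)
                e_new, ov, nb_new = _local_energy(
                    i, xt, yt, o[i], s[i, 0], s[i, 1], s[i, 2],
                    x, y, o, s, head, nxt, box, cellsz, ncell,
                    sigma2, rc2, cth, eps)
                if ov:
                    continue
                e_old, _, nb_old = _local_energy(
                    i, x[i], y[i], o[i], s[i, 0], s[i, 1], s[i, 2],
                    x, y, o, s, head, nxt, box, cellsz, ncell,
                    sigma2, rc2, cth, eps)
                dE = e_new - e_old
                if dE <= 0.0 or np.random.random() < np.exp(-dE):
                    c_old = _cell_of(x[i], y[i], cellsz, ncell)
                    c_new = _cell_of(xt, yt, cellsz, ncell)
                    if c_new != c_old:
                        _cell_remove(i, c_old, head, nxt)
                        nxt[i] = head[c_new]
                        head[c_new] = i
                    x[i] = xt
                    y[i] = yt
                    dE_total += dE
                    counters[ACC_TR] += 1
                    if nb_new < nb_old:
                        counters[BB_ACC] += 1
            elif u < cum_rot:
                # ---- rotation ----
                counters[ATT_ROT] += 1
                i = int(np.random.random() * n)
                ot = o[i] + rmax * (2.0 * np.random.random() - 1.0)
                ot -= TWO_PI * np.floor(ot / TWO_PI)
                e_new, ov, nb_new = _local_energy(
                    i, x[i], y[i], ot, s[i, 0], s[i, 1], s[i, 2],
                    x, y, o, s, head, nxt, box, cellsz, ncell,
                    sigma2, rc2, cth, eps)
                e_old, _, nb_old = _local_energy(
                    i, x[i], y[i], o[i], s[i, 0], s[i, 1], s[i, 2],
                    x, y, o, s, head, nxt, box, cellsz, ncell,
                    sigma2, rc2, cth, eps)
                dE = e_new - e_old
                if dE <= 0.0 or np.random.random() < np.exp(-dE):
                    o[i] = ot
                    dE_total += dE
                    counters[ACC_ROT] += 1
                    if nb_new < nb_old:
                        counters[BB_ACC] += 1
            elif u < cum_flip:
                # ---- patch-state flip ----
                counters[ATT_FLIP] += 1
                i = int(np.random.random() * n)
                k = int(np.random.random() * 3)
                old = s[i, k]
                new = 1 - old
                t0 = new if k == 0 else s[i, 0]
                t1 = new if k == 1 else s[i, 1]
                t2 = new if k == 2 else s[i, 2]
                e_new, _, nb_new = _local_energy(
                    i, x[i], y[i], o[i], t0, t1, t2,
                    x, y, o, s, head, nxt, box, cellsz, ncell,
                    sigma2, rc2, cth, eps)
                e_old, _, nb_old = _local_energy(
                    i, x[i], y[i], o[i], s[i, 0], s[i, 1], s[i, 2],
                    x, y, o, s, head, nxt, box, cellsz, ncell,
                    sigma2, rc2, cth, eps)
                dE = e_new - e_old
                # intrinsic weights: w(open)=p_open, w(closed)=1-p_open
                w_new = p_open if new == 0 else 1.0 - p_open
                w_old = p_open if old == 0 else 1.0 - p_open
                if w_old == 0.0:
                    acc = 1.0
                elif w_new == 0.0:
                    acc = 0.0
                else:
                    acc = (w_new / w_old) * np.exp(-dE)
                if np.random.random() < acc:
                    s[i, k] = new
                    dE_total += dE
                    counters[ACC_FLIP] += 1
                    if nb_new < nb_old:
                        counters[BB_ACC] += 1
            else:
                # ---- rigid cluster move ----
                counters[ATT_CL] += 1
                seed_i = int(np.random.random() * n)
                # size down-weighting (selection probability 1/size): draw u
                # up front so the BFS can abort as soon as the cluster grows
                # past 1/u -- same acceptance law, O(min(size, 1/u)) cost
                u_size = np.random.random()
                size_cap = n + 1.0 if u_size <= 0.0 else 1.0 / u_size
                nc = 1
                cl_stack[0] = seed_i
                in_cl[seed_i] = True
                ux[0] = x[seed_i]
                uy[0] = y[seed_i]
                headp = 0
                # BFS over bonded contacts, unwrapping coordinates
                while headp < nc and nc <= size_cap:
                    t = headp
                    p = cl_stack[t]
                    headp += 1
                    if ncell >= 3:
                        cx = int(x[p] / cellsz)
                        cy = int(y[p] / cellsz)
                        if cx >= ncell:
                            cx = ncell - 1
                        if cy >= ncell:
                            cy = ncell - 1
                        c0 = -1
                        for dcy in range(-1, 2):
                            yy = (cy + dcy) % ncell
                            for dcx in range(-1, 2):
                                cc = yy * ncell + (cx + dcx) % ncell
                                j = head[cc]
                                while j >= 0:
                                    if not in_cl[j]:
                                        dx = _mi(x[j] - x[p], box)
                                        dy = _mi(y[j] - y[p], box)
                                        eij = _pair_e(dx, dy, o[p], s[p, 0], s[p, 1], s[p, 2],
                                                      o[j], s[j, 0], s[j, 1], s[j, 2],
                                                      sigma2, rc2, cth, eps)
                                        if eij < 0.0:
                                            in_cl[j] = True
                                            cl_stack[nc] = j
                                            ux[nc] = ux[t] + dx
                                            uy[nc] = uy[t] + dy
                                            nc += 1
                                    j = nxt[j]
                    else:
                        j = head[0]
                        while j >= 0:
                            if not in_cl[j]:
                                dx = _mi(x[j] - x[p], box)
                                dy = _mi(y[j] - y[p], box)
                                eij = _pair_e(dx, dy, o[p], s[p, 0], s[p, 1], s[p, 2],
                                              o[j], s[j, 0], s[j, 1], s[j, 2],
                                              sigma2, rc2, cth, eps)
                                if eij < 0.0:
                                    in_cl[j] = True
                                    cl_stack[nc] = j
                                    ux[nc] = ux[t] + dx
                                    uy[nc] = uy[t] + dy
                                    nc += 1
                            j = nxt[j]
                # attempt survives iff u < 1/size, i.e. the BFS completed
                # within the cap
                if nc > size_cap or headp < nc:
                    for t in range(nc):
                        in_cl[cl_stack[t]] = False
                    continue
                # rotations require the unwrapped extent to stay below half
                # the box: beyond that, rigid rotation alters minimum-image
                # internal distances (translations are image-safe at any size)
                xmin = ux[0]
                xmax = ux[0]
                ymin = uy[0]
                ymax = uy[0]
                for t in range(1, nc):
                    if ux[t] < xmin:
                        xmin = ux[t]
                    if ux[t] > xmax:
                        xmax = ux[t]
                    if uy[t] < ymin:
                        ymin = uy[t]
                    if uy[t] > ymax:
                        ymax = uy[t]
                span = xmax - xmin
                if ymax - ymin > span:
                    span = ymax - ymin
                rot_ok = span < 0.5 * box - (sigma + delta)
                dtheta = 0.0
                if np.random.random() < 0.5 or not rot_ok:
                    ddx = dmax * (2.0 * np.random.random() - 1.0)
                    ddy = dmax * (2.0 * np.random.random() - 1.0)
                    for t in range(nc):
                        wx[t] = ux[t] + ddx
                        wy[t] = uy[t] + ddy
                else:
                    dtheta = rmax * (2.0 * np.random.random() - 1.0)
                    cx_ = 0.0
                    cy_ = 0.0
                    for t in range(nc):
                        cx_ += ux[t]
                        cy_ += uy[t]
                    cx_ /= nc
                    cy_ /= nc
                    ct = np.cos(dtheta)
                    st = np.sin(dtheta)
                    for t in range(nc):
                        rx = ux[t] - cx_
                        ry = uy[t] - cy_
                        wx[t] = cx_ + ct * rx - st * ry
                        wy[t] = cy_ + st * rx + ct * ry
                # reject on overlap or any new external bond
                ok = True
                for t in range(nc):
                    m_ = cl_stack[t]
                    xt = wx[t] - box * np.floor(wx[t] / box)
                    yt = wy[t] - box * np.floor(wy[t] / box)
                    ot = o[m_] + dtheta
                    if ncell >= 3:
                        cx = int(xt / cellsz)
                        cy = int(yt / cellsz)
                        if cx >= ncell:
                            cx = ncell - 1
                        if cy >= ncell:
                            cy = ncell - 1
                        for dcy in range(-1, 2):
                            yy = (cy + dcy) % ncell
                            for dcx in range(-1, 2):
                                cc = yy * ncell + (cx + dcx) % ncell
                                j = head[cc]
                                while j >= 0:
                                    if not in_cl[j]:
                                        dx = _mi(x[j] - xt, box)
                                        dy = _mi(y[j] - yt, box)
                                        eij = _pair_e(dx, dy, ot, s[m_, 0], s[m_, 1], s[m_, 2],
                                                      o[j], s[j, 0], s[j, 1], s[j, 2],
                                                      sigma2, rc2, cth, eps)
                                        if eij == np.inf or eij < 0.0:
                                            ok = False
                                    j = nxt[j]
                    else:
                        j = head[0]
                        while j >= 0:
                            if not in_cl[j]:
                                dx = _mi(x[j] - xt, box)
                                dy = _mi(y[j] - yt, box)
                                eij = _pair_e(dx, dy, ot, s[m_, 0], s[m_, 1], s[m_, 2],
                                              o[j], s[j, 0], s[j, 1], s[j, 2],
                                              sigma2, rc2, cth, eps)
                                if eij == np.inf or eij < 0.0:
                                    ok = False
                            j = nxt[j]
                    if not ok:
                        break
                if ok:
                    for t in range(nc):
                        m_ = cl_stack[t]
                        xt = wx[t] - box * np.floor(wx[t] / box)
                        yt = wy[t] - box * np.floor(wy[t] / box)
                        c_old = _cell_of(x[m_], y[m_], cellsz, ncell)
                        c_new = _cell_of(xt, yt, cellsz, ncell)
                        if c_new != c_old:
                            _cell_remove(m_, c_old, head, nxt)
                            nxt[m_] = head[c_new]
                            head[c_new] = m_
                        x[m_] = xt
                        y[m_] = yt
                        ot = o[m_] + dtheta
                        o[m_] = ot - TWO_PI * np.floor(ot / TWO_PI)
                    counters[ACC_CL] += 1
                for t in range(nc):
                    in_cl[cl_stack[t]] = False
    return dE_total
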