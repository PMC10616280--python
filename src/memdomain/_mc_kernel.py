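"""Numba kernels for the dynamically triangulated vesicle Monte Carlo.

Mesh representation (fixed-size arrays, counts never change):
  pos  (N,3) float64  vertex coordinates, units of l_min
  nbr  (N,MAXD) int32 neighbour vertex ids per vertex
  enb  (N,MAXD) int32 edge id of each neighbour slot
  deg  (N,) int32     vertex degrees
  ev   (E,2) int32    edge endpoint vertices
  eop  (E,2) int32    the two opposite vertices of each edge (its two faces)

A bond flip rewires one edge in place (edge ids are stable), updating the
opposite-vertex table of the four quad edges.  Keeping explicit opposites
avoids the ambiguity of recovering faces from adjacency alone when non-face
3-cliques appear.

Bending energy: Gompper-Kroll cotangent discretization of the Helfrich
energy with zero spontaneous curvature,
  E_i = (kappa_i/2) A_i |K_i|^2,  K_i = (1/(2A_i)) sum_j (cot a + cot b)(x_i - x_j),
with A_i the barycentric vertex area; |K_i| = c1 + c2 on a smooth surface,
so a sphere integrates to 8 pi kappa.

Self-avoidance: hard-core minimum distance l_min between all non-bonded
vertex pairs, enforced with a linked-cell list of cell size >= l_min.
"""

import numpy as np
from numba import njit

MAXD = 12


@njit(cache=True, fastmath=False)
def _cot(pos, o, i, j):
    """Cotangent of the angle at vertex o in triangle (o, i, j)."""
    ux = pos[i, 0] - pos[o, 0]
    uy = pos[i, 1] - pos[o, 1]
    uz = pos[i, 2] - pos[o, 2]
    vx = pos[j, 0] - pos[o, 0]
    vy = pos[j, 1] - pos[o, 1]
    vz = pos[j, 2] - pos[o, 2]
    dot = ux * vx + uy * vy + uz * vz
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    cr = np.sqrt(cx * cx + cy * cy + cz * cz)
    if cr < 1e-12:
        cr = 1e-12
    return dot / cr


@njit(cache=True, fastmath=False)
def _tri_area(pos, a, b, c):
    ux = pos[b, 0] - pos[a, 0]
    uy = pos[b, 1] - pos[a, 1]
    uz = pos[b, 2] - pos[a, 2]
    vx = pos[c, 0] - pos[a, 0]
    vy = pos[c, 1] - pos[a, 1]
    vz = pos[c, 2] - pos[a, 2]
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    return 0.5 * np.sqrt(cx * cx + cy * cy + cz * cz)


@njit(cache=True, fastmath=False)
def _vertex_eb(pos, nbr, enb, deg, eop, kap, i):
    """Bending energy attributed to vertex i (cotangent scheme)."""
    hx = 0.0
    hy = 0.0
    hz = 0.0
    area6 = 0.0
    xi = pos[i, 0]
    yi = pos[i, 1]
    zi = pos[i, 2]
    for k in range(deg[i]):
        j = nbr[i, k]
        e = enb[i, k]
        o1 = eop[e, 0]
        o2 = eop[e, 1]
        cw = 0.5 * (_cot(pos, o1, i, j) + _cot(pos, o2, i, j))
        hx += cw * (xi - pos[j, 0])
        hy += cw * (yi - pos[j, 1])
        hz += cw * (zi - pos[j, 2])
        area6 += _tri_area(pos, i, j, o1) + _tri_area(pos, i, j, o2)
    a_i = area6 / 6.0
    if a_i < 1e-14:
        a_i = 1e-14
    return 0.5 * kap[i] * (hx * hx + hy * hy + hz * hz) / a_i


@njit(cache=True)
def total_bending(pos, nbr, enb, deg, eop, kap):
    e = 0.0
    for i in range(pos.shape[0]):
        e += _vertex_eb(pos, nbr, enb, deg, eop, kap, i)
    return e


@njit(cache=True)
def fill_eb(pos, nbr, enb, deg, eop, kap, eb):
    for i in range(pos.shape[0]):
        eb[i] = _vertex_eb(pos, nbr, enb, deg, eop, kap, i)


@njit(cache=True)
def count_domain_bonds(ev, vtype):
    c = 0
    for e in range(ev.shape[0]):
        if vtype[ev[e, 0]] == 1 and vtype[ev[e, 1]] == 1:
            c += 1
    return c


@njit(cache=True)
def _is_bonded(nbr, deg, i, j):
    for k in range(deg[i]):
        if nbr[i, k] == j:
            return True
    return False


@njit(cache=True)
def _edge_between(nbr, enb, deg, i, j):
    for k in range(deg[i]):
        if nbr[i, k] == j:
            return enb[i, k]
    return -1


@njit(cache=True)
def _remove_nbr(nbr, enb, deg, i, j):
    for k in range(deg[i]):
        if nbr[i, k] == j:
            last = deg[i] - 1
            nbr[i, k] = nbr[i, last]
            enb[i, k] = enb[i, last]
            deg[i] = last
            return


@njit(cache=True)
def _replace_op(eop, e, old, new):
    if eop[e, 0] == old:
        eop[e, 0] = new
    elif eop[e, 1] == old:
        eop[e, 1] = new


@njit(cache=True)
def apply_flip(nbr, enb, deg, ev, eop, e):
    """Rewire edge e=(a,b) with opposites (c,d) into (c,d) with opposites (a,b).

    Assumes validity was checked.  Applying twice restores the original mesh.
    """
    a = ev[e, 0]
    b = ev[e, 1]
    c = eop[e, 0]
    d = eop[e, 1]
    e_ac = _edge_between(nbr, enb, deg, a, c)
    e_bc = _edge_between(nbr, enb, deg, b, c)
    e_ad = _edge_between(nbr, enb, deg, a, d)
    e_bd = _edge_between(nbr, enb, deg, b, d)
    _remove_nbr(nbr, enb, deg, a, b)
    _remove_nbr(nbr, enb, deg, b, a)
    nbr[c, deg[c]] = d
    enb[c, deg[c]] = e
    deg[c] += 1
    nbr[d, deg[d]] = c
    enb[d, deg[d]] = e
    deg[d] += 1
    _replace_op(eop, e_ac, b, d)
    _replace_op(eop, e_bc, a, d)
    _replace_op(eop, e_ad, b, c)
    _replace_op(eop, e_bd, a, c)
    ev[e, 0] = c
    ev[e, 1] = d
    eop[e, 0] = a
    eop[e, 1] = b


@njit(cache=True)
def _cell_of(x, y, z, lo, inv, dims):
    cx = int((x - lo[0]) * inv)
    cy = int((y - lo[1]) * inv)
    cz = int((z - lo[2]) * inv)
    if cx < 0:
        cx = 0
    if cy < 0:
        cy = 0
    if cz < 0:
        cz = 0
    if cx >= dims[0]:
        cx = dims[0] - 1
    if cy >= dims[1]:
        cy = dims[1] - 1
    if cz >= dims[2]:
        cz = dims[2] - 1
    return (cx * dims[1] + cy) * dims[2] + cz


@njit(cache=True)
def run_sweeps(pos, nbr, enb, deg, ev, eop, vtype, kap, eb, state,
               lmin, lmax, s, w, kT, rb, n_sweeps, seed, energy_trace):
    """Run n_sweeps Monte Carlo sweeps in place.

    state[0] = running total energy (bending + interaction, k_BT)
    state[1] = number of domain-domain bonds
    energy_trace: out array of length n_sweeps (total energy after each sweep).
    Returns (accepted_moves, attempted_moves, accepted_flips, attempted_flips).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_edges = ev.shape[0]
    lmin2 = lmin * lmin
    lmax2 = lmax * lmax
    acc_m = 0
    att_m = 0
    acc_f = 0
    att_f = 0

    # cell-list workspace
    cell = np.empty(n, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    prv = np.empty(n, dtype=np.int32)
    lo = np.empty(3)
    dims = np.empty(3, dtype=np.int32)

    new_eb = np.empty(MAXD + 1)
    touched = np.empty(MAXD + 1, dtype=np.int32)

    for sweep in range(n_sweeps):
        # (re)build the cell list; cell size lmin, one cell of margin
        for ax in range(3):
            m = pos[0, ax]
            for i in range(1, n):
                if pos[i, ax] < m:
                    m = pos[i, ax]
            lo[ax] = m - lmin
        inv = 1.0 / lmin
        for ax in range(3):
            mx = pos[0, ax]
            for i in range(1, n):
                if pos[i, ax] > mx:
                    mx = pos[i, ax]
            d = int((mx - lo[ax]) * inv) + 2
            dims[ax] = d
        ncells = dims[0] * dims[1] * dims[2]
        head = np.full(ncells, -1, dtype=np.int32)
        for i in range(n):
            ci = _cell_of(pos[i, 0], pos[i, 1], pos[i, 2], lo, inv, dims)
            cell[i] = ci
            nxt[i] = head[ci]
            prv[i] = -1
            if head[ci] >= 0:
                prv[head[ci]] = i
            head[ci] = i

        # ---- vertex moves ----
        for v in range(n):
            att_m += 1
            # uniform displacement inside a ball of radius s
            while True:
                dx = s * (2.0 * np.random.random() - 1.0)
                dy = s * (2.0 * np.random.random() - 1.0)
                dz = s * (2.0 * np.random.random() - 1.0)
                if dx * dx + dy * dy + dz * dz <= s * s:
                    break
            px = pos[v, 0] + dx
            py = pos[v, 1] + dy
            pz = pos[v, 2] + dz

            # tether length bounds to all bonded neighbours
            ok = True
            for k in range(deg[v]):
                j = nbr[v, k]
                ddx = px - pos[j, 0]
                ddy = py - pos[j, 1]
                ddz = pz - pos[j, 2]
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 < lmin2 or d2 > lmax2:
                    ok = False
                    break
            if not ok:
                continue

            # self-avoidance: no non-bonded vertex closer than lmin
            ci = _cell_of(px, py, pz, lo, inv, dims)
            ccz = ci % dims[2]
            ccy = (ci // dims[2]) % dims[1]
            ccx = ci // (dims[1] * dims[2])
            for ox in range(-1, 2):
                gx = ccx + ox
                if gx < 0 or gx >= dims[0]:
                    continue
                for oy in range(-1, 2):
                    gy = ccy + oy
                    if gy < 0 or gy >= dims[1]:
                        continue
                    for oz in range(-1, 2):
                        gz = ccz + oz
                        if gz < 0 or gz >= dims[2]:
                            continue
                        u = head[(gx * dims[1] + gy) * dims[2] + gz]
                        while u >= 0:
                            if u != v and not _is_bonded(nbr, deg, v, u):
                                ddx = px - pos[u, 0]
                                ddy = py - pos[u, 1]
                                ddz = pz - pos[u, 2]
                                if ddx * ddx + ddy * ddy + ddz * ddz < lmin2:
                                    ok = False
                                    break
                            u = nxt[u]
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue

            # local bending-energy change
            ntouch = deg[v] + 1
            touched[0] = v
            for k in range(deg[v]):
                touched[k + 1] = nbr[v, k]
            e_before = 0.0
            for t in range(ntouch):
                e_before += eb[touched[t]]
            ox0 = pos[v, 0]
            oy0 = pos[v, 1]
            oz0 = pos[v, 2]
            pos[v, 0] = px
            pos[v, 1] = py
            pos[v, 2] = pz
            e_after = 0.0
            for t in range(ntouch):
                new_eb[t] = _vertex_eb(pos, nbr, enb, deg, eop, kap, touched[t])
                e_after += new_eb[t]
            d_e = e_after - e_before
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e / kT):
                acc_m += 1
                for t in range(ntouch):
                    eb[touched[t]] = new_eb[t]
                state[0] += d_e
                # migrate between cells if needed
                if ci != cell[v]:
                    if prv[v] >= 0:
                        nxt[prv[v]] = nxt[v]
                    else:
                        head[cell[v]] = nxt[v]
                    if nxt[v] >= 0:
                        prv[nxt[v]] = prv[v]
                    cell[v] = ci
                    nxt[v] = head[ci]
                    prv[v] = -1
                    if head[ci] >= 0:
                        prv[head[ci]] = v
                    head[ci] = v
            else:
                pos[v, 0] = ox0
                pos[v, 1] = oy0
                pos[v, 2] = oz0

        # ---- bond flips ----
        nflip = rb * n
        for t in range(nflip):
            att_f += 1
            e = np.random.randint(0, n_edges)
            a = ev[e, 0]
            b = ev[e, 1]
            c = eop[e, 0]
            d = eop[e, 1]
            if deg[a] <= 3 or deg[b] <= 3:
                continue
            if deg[c] >= MAXD or deg[d] >= MAXD:
                continue
            if _is_bonded(nbr, deg, c, d):
                continue
            ddx = pos[c, 0] - pos[d, 0]
            ddy = pos[c, 1] - pos[d, 1]
            ddz = pos[c, 2] - pos[d, 2]
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 < lmin2 or d2 > lmax2:
                continue

            e_before = eb[a] + eb[b] + eb[c] + eb[d]
            apply_flip(nbr, enb, deg, ev, eop, e)
            ea = _vertex_eb(pos, nbr, enb, deg, eop, kap, a)
            ebb = _vertex_eb(pos, nbr, enb, deg, eop, kap, b)
            ec = _vertex_eb(pos, nbr, enb, deg, eop, kap, c)
            ed = _vertex_eb(pos, nbr, enb, deg, eop, kap, d)
            d_bend = (ea + ebb + ec + ed) - e_before
            d_int = 0.0
            if vtype[a] == 1 and vtype[b] == 1:
                d_int += w           # a-b bond removed: lose -w
            if vtype[c] == 1 and vtype[d] == 1:
                d_int -= w           # c-d bond created: gain -w
            d_e = d_bend + d_int
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e / kT):
                acc_f += 1
                eb[a] = ea
                eb[b] = ebb
                eb[c] = ec
                eb[d] = ed
                state[0] += d_e
                if vtype[a] == 1 and vtype[b] == 1:
                    state[1] -= 1
                if vtype[c] == 1 and vtype[d] == 1:
                    state[1] += 1
            else:
                apply_flip(nbr, enb, deg, ev, eop, e)   # undo

        energy_trace[sweep] = state[0]

    return acc_m, att_m, acc_f, att_f
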