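"""Numba-accelerated inner loop of the SBS engine.

Implements the same semantics as the reference numpy path in
``chemistry``: adaptive ladder step from the half-gap criterion,
Gaussian Brownian displacements with periodic wrap, encounter reactions
resolved closest pair first with products at the minimum-image midpoint.
Neighbor search uses a cell-sorted Verlet list rebuilt when accumulated
displacement could invalidate it.  All random numbers are consumed
sequentially from a buffer drawn by the caller's seeded generator, so
results are reproducible from the seed alone.

If numba is unavailable the engine falls back to the reference path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

# Segment return codes
DONE = 0
NEED_NORMALS = 1
SNAP_FULL = 2
PAIRS_FULL = 3
PARTICLES_FULL = 4
LOG_FULL = 5

_MAX_DUE = 4096


@njit(cache=True)
def _rebuild_pairs(pos, kinds, n, box, r_list, pair_i, pair_j):
    """Cell-sorted periodic neighbor search; pairs within r_list.

    Particles are bucketed into cells of side >= r_list; each unordered
    pair of neighboring occupied cells is processed exactly once.
    Returns the number of pairs, or -1 if the pair buffer is too small.
    Dead slots (kinds < 0) are skipped.
    """
    ncx = max(1, int(box[0] / r_list))
    ncy = max(1, int(box[1] / r_list))
    ncz = max(1, int(box[2] / r_list))
    csx = box[0] / ncx
    csy = box[1] / ncy
    csz = box[2] / ncz
    keys = np.empty(n, dtype=np.int64)
    for i in range(n):
        if kinds[i] < 0:
            keys[i] = np.int64(9223372036854775807)  # dead slots sort last
            continue
        cx = min(int(pos[i, 0] / csx), ncx - 1)
        cy = min(int(pos[i, 1] / csy), ncy - 1)
        cz = min(int(pos[i, 2] / csz), ncz - 1)
        keys[i] = (cx * ncy + cy) * ncz + cz
    order = np.argsort(keys)
    skeys = keys[order]
    n_live = n
    for i in range(n):
        if skeys[i] == np.int64(9223372036854775807):
            n_live = i
            break
    # run-length encode occupied cells
    cell_key = np.empty(n_live, dtype=np.int64)
    cell_start = np.empty(n_live + 1, dtype=np.int64)
    n_cells = 0
    i = 0
    while i < n_live:
        cell_key[n_cells] = skeys[i]
        cell_start[n_cells] = i
        while i < n_live and skeys[i] == cell_key[n_cells]:
            i += 1
        n_cells += 1
    cell_start[n_cells] = n_live

    cap = pair_i.shape[0]
    np_pairs = 0
    r2 = r_list * r_list
    nbr = np.empty(26, dtype=np.int64)
    for c in range(n_cells):
        key = cell_key[c]
        lo = cell_start[c]
        hi = cell_start[c + 1]
        # within-cell pairs
        for a_ in range(lo, hi):
            i_ = order[a_]
            for b_ in range(a_ + 1, hi):
                j_ = order[b_]
                ddx = pos[i_, 0] - pos[j_, 0]
                ddx -= box[0] * np.rint(ddx / box[0])
                ddy = pos[i_, 1] - pos[j_, 1]
                ddy -= box[1] * np.rint(ddy / box[1])
                ddz = pos[i_, 2] - pos[j_, 2]
                ddz -= box[2] * np.rint(ddz / box[2])
                if ddx * ddx + ddy * ddy + ddz * ddz <= r2:
                    if np_pairs >= cap:
                        return -1
                    pair_i[np_pairs] = i_
                    pair_j[np_pairs] = j_
                    np_pairs += 1
        # distinct neighbor cells with key > own key
        cz = key % ncz
        cy = (key // ncz) % ncy
        cx = key // (ncz * ncy)
        nn = 0
        for dx in range(-1, 2):
            ax = (cx + dx) % ncx
            for dy in range(-1, 2):
                ay = (cy + dy) % ncy
                for dz in range(-1, 2):
                    if dx == 0 and dy == 0 and dz == 0:
                        continue
                    az = (cz + dz) % ncz
                    nkey = (ax * ncy + ay) * ncz + az
                    if nkey <= key:
                        continue
                    dup = False
                    for q in range(nn):
                        if nbr[q] == nkey:
                            dup = True
                            break
                    if not dup:
                        nbr[nn] = nkey
                        nn += 1
        for q in range(nn):
            nkey = nbr[q]
            d = np.searchsorted(cell_key[:n_cells], nkey)
            if d >= n_cells or cell_key[d] != nkey:
                continue
            lo2 = cell_start[d]
            hi2 = cell_start[d + 1]
            for a_ in range(lo, hi):
                i_ = order[a_]
                for b_ in range(lo2, hi2):
                    j_ = order[b_]
                    ddx = pos[i_, 0] - pos[j_, 0]
                    ddx -= box[0] * np.rint(ddx / box[0])
                    ddy = pos[i_, 1] - pos[j_, 1]
                    ddy -= box[1] * np.rint(ddy / box[1])
                    ddz = pos[i_, 2] - pos[j_, 2]
                    ddz -= box[2] * np.rint(ddz / box[2])
                    if ddx * ddx + ddy * ddy + ddz * ddz <= r2:
                        if np_pairs >= cap:
                            return -1
                        pair_i[np_pairs] = i_
                        pair_j[np_pairs] = j_
                        np_pairs += 1
    return np_pairs


@njit(cache=True)
def _choose_dt(gap, d_max, ladder, dt_min, dt_max):
    if d_max <= 0.0 or gap == np.inf:
        return dt_max
    g = gap if gap > 0.0 else 0.0
    best = -1.0
    smallest = dt_max
    for r in ladder:
        if r < dt_min or r > dt_max:
            continue
        if r < smallest:
            smallest = r
        if np.sqrt(6.0 * d_max * r) <= 0.5 * g and r > best:
            best = r
    if best > 0.0:
        return best
    return smallest


@njit(cache=True)
def run_segment(pos, kinds, state_f, state_i, t_stop, box, d_ps,
                channel_matrix, radius_matrix, prod_flat, prod_off,
                ladder, dt_min, dt_max, r_max, skin,
                normals, snap_t, snap_counts, snap_e, counts,
                pair_i, pair_j, ref,
                log_t, log_ch, log_xyz, log_on):
    """Advance chemistry until t_stop or a buffer runs out.

    state_f = [clock_ps, energy_ev, gap_nm (<0 = stale)]
    state_i = [n_slots, nrm_idx, snap_n, n_pairs, log_n, stale_flag]
    """
    clock = state_f[0]
    gap = state_f[2]
    n = state_i[0]
    nrm = state_i[1]
    snap_n = state_i[2]
    n_pairs = state_i[3]
    log_n = state_i[4]
    stale = state_i[5] != 0 or gap < 0.0
    cap = pos.shape[0]
    d_glob = 0.0
    for k in range(d_ps.shape[0]):
        if d_ps[k] > d_glob:
            d_glob = d_ps[k]
    r_need = r_max + 2.0 * np.sqrt(6.0 * d_glob * dt_max)
    r_list = r_need + skin
    due_p = np.empty(_MAX_DUE, dtype=np.int64)
    due_d = np.empty(_MAX_DUE)

    status = DONE
    while clock < t_stop - 1e-9:
        # fastest diffusion coefficient among species present
        d_max = 0.0
        n_live = 0
        for k in range(counts.shape[0]):
            if counts[k] > 0:
                n_live += counts[k]
                if d_ps[k] > d_max:
                    d_max = d_ps[k]
        if n_live == 0:
            clock = t_stop
            break
        if stale:
            # stable compaction of dead slots, then rebuild the pair list
            w = 0
            for i in range(n):
                if kinds[i] >= 0:
                    if w != i:
                        kinds[w] = kinds[i]
                        pos[w, 0] = pos[i, 0]
                        pos[w, 1] = pos[i, 1]
                        pos[w, 2] = pos[i, 2]
                    w += 1
            n = w
            n_pairs = _rebuild_pairs(pos, kinds, n, box, r_list,
                                     pair_i, pair_j)
            if n_pairs < 0:
                status = PAIRS_FULL
                break
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
            stale = False
            gap = np.inf
            for p in range(n_pairs):
                i_ = pair_i[p]
                j_ = pair_j[p]
                a = kinds[i_]
                b = kinds[j_]
                if a < 0 or b < 0 or channel_matrix[a, b] < 0:
                    continue
                ddx = pos[i_, 0] - pos[j_, 0]
                ddx -= box[0] * np.rint(ddx / box[0])
                ddy = pos[i_, 1] - pos[j_, 1]
                ddy -= box[1] * np.rint(ddy / box[1])
                ddz = pos[i_, 2] - pos[j_, 2]
                ddz -= box[2] * np.rint(ddz / box[2])
                g = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz) \
                    - radius_matrix[a, b]
                if g < gap:
                    gap = g
        eff_gap = gap
        if eff_gap == np.inf:
            # nothing reactive inside the certified list radius
            eff_gap = (r_list - skin) - r_max
        dt = _choose_dt(eff_gap, d_max, ladder, dt_min, dt_max)
        if nrm + 3 * n > normals.shape[0]:
            status = NEED_NORMALS
            break
        if clock + dt >= t_stop - 1e-9:
            dt = t_stop - clock
            clock = t_stop
        else:
            clock += dt
        # Brownian displacements with periodic wrap
        for i in range(n):
            k = kinds[i]
            if k < 0:
                nrm += 3
                continue
            s = np.sqrt(2.0 * d_ps[k] * dt)
            for ax in range(3):
                x = pos[i, ax] + s * normals[nrm]
                nrm += 1
                pos[i, ax] = x % box[ax]
        # Verlet-list validity: actual max displacement since rebuild
        max_d2 = 0.0
        for i in range(n):
            if kinds[i] < 0:
                continue
            ddx = pos[i, 0] - ref[i, 0]
            ddx -= box[0] * np.rint(ddx / box[0])
            ddy = pos[i, 1] - ref[i, 1]
            ddy -= box[1] * np.rint(ddy / box[1])
            ddz = pos[i, 2] - ref[i, 2]
            ddz -= box[2] * np.rint(ddz / box[2])
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > max_d2:
                max_d2 = d2
        if 2.0 * np.sqrt(max_d2) > skin:
            stale = True
        # recompute cached pair distances; collect due reactions
        n_due = 0
        gap = np.inf
        for p in range(n_pairs):
            i_ = pair_i[p]
            j_ = pair_j[p]
            a = kinds[i_]
            b = kinds[j_]
            if a < 0 or b < 0:
                continue
            ch = channel_matrix[a, b]
            if ch < 0:
                continue
            ddx = pos[i_, 0] - pos[j_, 0]
            ddx -= box[0] * np.rint(ddx / box[0])
            ddy = pos[i_, 1] - pos[j_, 1]
            ddy -= box[1] * np.rint(ddy / box[1])
            ddz = pos[i_, 2] - pos[j_, 2]
            ddz -= box[2] * np.rint(ddz / box[2])
            d = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            r = radius_matrix[a, b]
            if d <= r:
                if n_due < _MAX_DUE:
                    due_p[n_due] = p
                    due_d[n_due] = d
                    n_due += 1
                # beyond capacity: the pair reacts on a later step
            else:
                g = d - r
                if g < gap:
                    gap = g
        if n_due > 0:
            # stable insertion sort, closest first
            for a_ in range(1, n_due):
                kp = due_p[a_]
                kd = due_d[a_]
                b_ = a_ - 1
                while b_ >= 0 and due_d[b_] > kd:
                    due_p[b_ + 1] = due_p[b_]
                    due_d[b_ + 1] = due_d[b_]
                    b_ -= 1
                due_p[b_ + 1] = kp
                due_d[b_ + 1] = kd
            n_rx = 0
            for q in range(n_due):
                p = due_p[q]
                i_ = pair_i[p]
                j_ = pair_j[p]
                a = kinds[i_]
                b = kinds[j_]
                if a < 0 or b < 0:
                    continue
                ch = channel_matrix[a, b]
                ddx = pos[i_, 0] - pos[j_, 0]
                ddx -= box[0] * np.rint(ddx / box[0])
                ddy = pos[i_, 1] - pos[j_, 1]
                ddy -= box[1] * np.rint(ddy / box[1])
                ddz = pos[i_, 2] - pos[j_, 2]
                ddz -= box[2] * np.rint(ddz / box[2])
                mx = (pos[i_, 0] - 0.5 * ddx) % box[0]
                my = (pos[i_, 1] - 0.5 * ddy) % box[1]
                mz = (pos[i_, 2] - 0.5 * ddz) % box[2]
                kinds[i_] = -1
                kinds[j_] = -1
                counts[a] -= 1
                counts[b] -= 1
                n_rx += 1
                for t in range(prod_off[ch], prod_off[ch + 1]):
                    if n >= cap:
                        status = PARTICLES_FULL
                        stale = True
                        break
                    kinds[n] = prod_flat[t]
                    counts[prod_flat[t]] += 1
                    pos[n, 0] = mx
                    pos[n, 1] = my
                    pos[n, 2] = mz
                    ref[n, 0] = mx
                    ref[n, 1] = my
                    ref[n, 2] = mz
                    n += 1
                if status == PARTICLES_FULL:
                    break
                if log_on != 0:
                    if log_n >= log_t.shape[0]:
                        status = LOG_FULL
                        stale = True
                        break
                    log_t[log_n] = clock
                    log_ch[log_n] = ch
                    log_xyz[log_n, 0] = mx
                    log_xyz[log_n, 1] = my
                    log_xyz[log_n, 2] = mz
                    log_n += 1
            if status != DONE:
                break
            if n_rx > 0:
                stale = True  # products need fresh neighbor lists
                if snap_n >= snap_t.shape[0]:
                    status = SNAP_FULL
                    break
                snap_t[snap_n] = clock
                for k in range(counts.shape[0]):
                    snap_counts[snap_n, k] = counts[k]
                snap_e[snap_n] = state_f[1]
                snap_n += 1
    state_f[0] = clock
    state_f[2] = -1.0 if stale else gap
    state_i[0] = n
    state_i[1] = nrm
    state_i[2] = snap_n
    state_i[3] = n_pairs
    state_i[4] = log_n
    state_i[5] = 1 if stale else 0
    return status
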