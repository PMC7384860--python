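"""Numba-compiled inner loop of the Gillespie simulation.

The kernel advances the three lattice layers event by event: it recomputes
the fifteen propensities from the current population counts (O(1)), draws an
exponential waiting time and an event index, and dispatches the attempt.
Attempts use the paper-style null-event semantics: eligibility predicates
are evaluated on the pre-attempt state and an ineligible attempt leaves the
state unchanged (but still consumes the waiting time).

The python layer owns initialisation, fixed events and checkpointing; it
calls :func:`run_chunk` repeatedly with stopping conditions (a domain-length
threshold and/or a time horizon).  All randomness inside the kernel comes
from numba's own RNG, seeded explicitly per chunk, so runs are reproducible
event-for-event.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# cell codes (must match lattice.CellKind)
M, X, XB, ID, IL = 1, 2, 3, 4, 5

# event indices
EV_MOVE_M, EV_MOVE_X, EV_MOVE_ID, EV_MOVE_IL = 0, 1, 2, 3
EV_PRO_XB, EV_PRO_X, EV_PRO_ID, EV_PRO_IL = 4, 5, 6, 7
EV_DIFF_M, EV_DIFF_XB, EV_DIE_M = 8, 9, 10
EV_D2L, EV_L2D, EV_GROW_H, EV_GROW_V = 11, 12, 13, 14
N_EVENTS = 15

EVENT_LABELS = (
    "move-M", "move-X", "move-Id", "move-Il",
    "proliferate-Xb", "proliferate-X", "proliferate-Id", "proliferate-Il",
    "differentiate-M", "differentiate-Xb", "die-M",
    "transition-Id-Il", "transition-Il-Id", "grow-horizontal", "grow-vertical",
)

# kernel parameter-vector indices
(R_MOVE_M, R_MOVE_X, R_MOVE_I, R_PRO_XB, R_PRO_X, R_PRO_ID, R_PRO_IL,
 R_DIFF_M_CAP, B_0, B_I, B_X, B_LOC, R_DIFF_XB, R_DEATH_M, R_D2L, R_L2D,
 R_GROW_H, R_GROW_V, BETA, S_M_FROM_X, S_M_TO_XB, S_X_TO_M, S_ID_TO_X,
 S_IL_FROM_IL, THETA_XL, THETA_XS, R_DIFF_XB_SOLO,
 K_DIFF_PER_ID, K_DIFF_PER_X, R_DIFF_SOLO, R_DIFF_XB_AUTO,
 THETA_XB_ID) = range(32)
N_PRM = 32

# toggle-vector indices
(T_HAS_M, T_H2, T_H4, T_D2L_NO_XLONG, T_D2L_NO_XSHORT,
 T_L2D_NO_MSHORT, T_L2D_NO_XSHORT) = range(7)
N_TOG = 7

# chunk exit statuses
ST_STOP_LEN, ST_STOP_T, ST_STALLED, ST_MAX_EVENTS, ST_CAPACITY = 0, 1, 2, 3, 4

# the eight compass directions and their unit vectors
_D = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)], dtype=np.int64)
DIR_R = _D[:, 0].copy()
DIR_C = _D[:, 1].copy()
_n = np.sqrt((_D ** 2).sum(axis=1).astype(np.float64))
DIR_UY = (_D[:, 0] / _n).copy()
DIR_UX = (_D[:, 1] / _n).copy()


@njit(cache=True, inline="always")
def _count(g, nrows, ncols, bi, bj, sten, kind, limit):
    """Count sites g[bi+dr, bj+dc] == kind over a stencil, clipped at the
    domain boundary, early-exiting once ``limit`` is reached."""
    n = 0
    for k in range(sten.shape[0]):
        a = bi + sten[k, 0]
        b = bj + sten[k, 1]
        if 0 <= a < nrows and 0 <= b < ncols and g[a, b] == kind:
            n += 1
            if n >= limit:
                return n
    return n


@njit(cache=True, inline="always")
def _bias(g, nrows, ncols, bi, bj, sten, uv, kind, s, B):
    for k in range(sten.shape[0]):
        a = bi + sten[k, 0]
        b = bj + sten[k, 1]
        if 0 <= a < nrows and 0 <= b < ncols and g[a, b] == kind:
            B[0] += s * uv[k, 0]
            B[1] += s * uv[k, 1]


@njit(cache=True, inline="always")
def _bias_wall(g, nrows, ncols, bi, bj, sten, uv, kind, s, B):
    # as _bias, but sites beyond the domain boundary act as occupied, so a
    # repelled agent is also pushed away from the wall instead of piling up
    for k in range(sten.shape[0]):
        a = bi + sten[k, 0]
        b = bj + sten[k, 1]
        if 0 <= a < nrows and 0 <= b < ncols:
            if g[a, b] == kind:
                B[0] += s * uv[k, 0]
                B[1] += s * uv[k, 1]
        else:
            B[0] += s * uv[k, 0]
            B[1] += s * uv[k, 1]


@njit(cache=True, inline="always")
def _sample_dir(By, Bx, beta):
    zmax = -1e300
    z = np.empty(8)
    for d in range(8):
        z[d] = beta * (By * DIR_UY[d] + Bx * DIR_UX[d])
        if z[d] > zmax:
            zmax = z[d]
    tot = 0.0
    for d in range(8):
        z[d] = np.exp(z[d] - zmax)
        tot += z[d]
    u = np.random.random() * tot
    acc = 0.0
    for d in range(8):
        acc += z[d]
        if u <= acc:
            return d
    return 7


@njit(cache=True, inline="always")
def _pick(g, nrows, ncols, kind):
    while True:
        r = np.random.randint(0, nrows)
        c = np.random.randint(0, ncols)
        if g[r, c] == kind:
            return r, c


@njit(cache=True)
def _insert_line(g, nlines, width, k, step, vertical):
    """Insert ``step`` empty rows (or columns) at index ``k``."""
    if vertical:
        for r in range(nlines + step - 1, k + step - 1, -1):
            for c in range(width):
                g[r, c] = g[r - step, c]
        for r in range(k, k + step):
            for c in range(width):
                g[r, c] = 0
    else:
        for r in range(width):
            for c in range(nlines + step - 1, k + step - 1, -1):
                g[r, c] = g[r, c - step]
            for c in range(k, k + step):
                g[r, c] = 0


@njit(cache=True)
def run_chunk(mg, xg, ig, dims, counts, tvec, prm, tog,
              cc_s, cf_s, cf_s_uv, cf_l, cf_l_uv,
              fc_s, fc_s_len, fc_s_uv,
              ff_s, ff_s_uv, ff_l,
              stop_cols, stop_t, max_events, seed,
              ev_att, ev_fire):
    np.random.seed(seed)
    rows = dims[0]
    cols = dims[1]
    nM = counts[0]
    nX = counts[1]
    nXb = counts[2]
    nId = counts[3]
    nIl = counts[4]
    t = tvec[0]
    cap_rows = mg.shape[0]
    theta_xl = int(prm[THETA_XL])
    theta_xs = int(prm[THETA_XS])
    status = ST_MAX_EVENTS
    B = np.empty(2)
    a = np.empty(N_EVENTS)

    if cols >= stop_cols:
        return ST_STOP_LEN
    if t >= stop_t:
        return ST_STOP_T

    for _ev in range(max_events):
        r2 = 2 * rows
        c2 = 2 * cols
        a[EV_MOVE_M] = nM * prm[R_MOVE_M]
        a[EV_MOVE_X] = nX * prm[R_MOVE_X]
        a[EV_MOVE_ID] = nId * prm[R_MOVE_I]
        a[EV_MOVE_IL] = nIl * prm[R_MOVE_I]
        a[EV_PRO_XB] = nXb * prm[R_PRO_XB]
        a[EV_PRO_X] = nX * prm[R_PRO_X]
        a[EV_PRO_ID] = nId * prm[R_PRO_ID]
        a[EV_PRO_IL] = nIl * prm[R_PRO_IL]
        # melanophore differentiation: the overall rate scales with the
        # domain totals of dense S-iridophores and xanthophores; the
        # spontaneous term acts only when no other pigment cells exist.
        solo = 1.0 if (nX + nXb + nId + nIl) == 0 else 0.0
        a[EV_DIFF_M] = (prm[K_DIFF_PER_ID] * nId + prm[K_DIFF_PER_X] * nX
                        + prm[R_DIFF_SOLO] * (rows * cols - nM) * solo) \
            * tog[T_HAS_M]
        a[EV_DIFF_XB] = nXb * max(prm[R_DIFF_XB], prm[R_DIFF_XB_AUTO])
        a[EV_DIE_M] = nM * prm[R_DEATH_M]
        a[EV_D2L] = nId * prm[R_D2L]
        a[EV_L2D] = nIl * prm[R_L2D]
        a[EV_GROW_H] = prm[R_GROW_H]
        a[EV_GROW_V] = prm[R_GROW_V]

        a0 = 0.0
        for k in range(N_EVENTS):
            a0 += a[k]
        if a0 <= 0.0:
            status = ST_STALLED
            break

        tau = -np.log(np.random.random()) / a0
        if t + tau > stop_t:
            t = stop_t
            status = ST_STOP_T
            break
        t += tau

        u = np.random.random() * a0
        ev = 0
        acc = a[0]
        while acc < u and ev < N_EVENTS - 1:
            ev += 1
            acc += a[ev]
        ev_att[ev] += 1

        # ------------------------------------------------ movement
        if ev == EV_MOVE_M:
            r, c = _pick(mg, rows, cols, M)
            B[0] = 0.0
            B[1] = 0.0
            if prm[S_M_FROM_X] != 0.0:
                _bias(xg, r2, c2, 2 * r, 2 * c, cf_s, cf_s_uv, X,
                      prm[S_M_FROM_X], B)
            if prm[S_M_TO_XB] != 0.0:
                _bias(xg, r2, c2, 2 * r, 2 * c, cf_l, cf_l_uv, XB,
                      prm[S_M_TO_XB], B)
            d = _sample_dir(B[0], B[1], prm[BETA])
            rr = r + DIR_R[d]
            cc = c + DIR_C[d]
            if 0 <= rr < rows and 0 <= cc < cols and mg[rr, cc] == 0:
                mg[r, c] = 0
                mg[rr, cc] = M
                ev_fire[ev] += 1
        elif ev == EV_MOVE_X or ev == EV_MOVE_ID or ev == EV_MOVE_IL:
            if ev == EV_MOVE_X:
                g = xg
                kind = X
            elif ev == EV_MOVE_ID:
                g = ig
                kind = ID
            else:
                g = ig
                kind = IL
            i, j = _pick(g, r2, c2, kind)
            B[0] = 0.0
            B[1] = 0.0
            if ev == EV_MOVE_X:
                if prm[S_X_TO_M] != 0.0:
                    p = 2 * (i & 1) + (j & 1)
                    np_ = fc_s_len[p]
                    _bias(mg, rows, cols, i >> 1, j >> 1,
                          fc_s[p, :np_], fc_s_uv[p, :np_], M,
                          prm[S_X_TO_M], B)
            elif ev == EV_MOVE_ID:
                if prm[S_ID_TO_X] != 0.0:
                    _bias(xg, r2, c2, i, j, ff_s, ff_s_uv, X,
                          prm[S_ID_TO_X], B)
            else:
                if prm[S_IL_FROM_IL] != 0.0:
                    _bias_wall(ig, r2, c2, i, j, ff_s, ff_s_uv, IL,
                               prm[S_IL_FROM_IL], B)
            d = _sample_dir(B[0], B[1], prm[BETA])
            ii = i + DIR_R[d]
            jj = j + DIR_C[d]
            if 0 <= ii < r2 and 0 <= jj < c2 and g[ii, jj] == 0:
                g[i, j] = 0
                g[ii, jj] = kind
                ev_fire[ev] += 1

        # ------------------------------------------------ proliferation
        elif ev == EV_PRO_XB or ev == EV_PRO_X or ev == EV_PRO_ID or ev == EV_PRO_IL:
            if ev == EV_PRO_XB:
                g = xg
                kind = XB
            elif ev == EV_PRO_X:
                g = xg
                kind = X
            elif ev == EV_PRO_ID:
                g = ig
                kind = ID
            else:
                g = ig
                kind = IL
            i, j = _pick(g, r2, c2, kind)
            nempty = 0
            for d in range(8):
                ii = i + DIR_R[d]
                jj = j + DIR_C[d]
                if 0 <= ii < r2 and 0 <= jj < c2 and g[ii, jj] == 0:
                    nempty += 1
            if nempty > 0:
                pickn = np.random.randint(0, nempty)
                seen = 0
                for d in range(8):
                    ii = i + DIR_R[d]
                    jj = j + DIR_C[d]
                    if 0 <= ii < r2 and 0 <= jj < c2 and g[ii, jj] == 0:
                        if seen == pickn:
                            g[ii, jj] = kind
                            break
                        seen += 1
                ev_fire[ev] += 1
                if ev == EV_PRO_XB:
                    nXb += 1
                elif ev == EV_PRO_X:
                    nX += 1
                elif ev == EV_PRO_ID:
                    nId += 1
                else:
                    nIl += 1

        # ------------------------------------------------ differentiation
        elif ev == EV_DIFF_M:
            r, c = _pick(mg, rows, cols, 0)
            ok = True
            if tog[T_H4] == 0:
                if _count(ig, r2, c2, 2 * r, 2 * c, cf_s, ID, 1) > 0:
                    ok = False   # local dense S-iridophores veto differentiation
            if ok:
                if solo > 0.0:
                    w = prm[R_DIFF_M_CAP]   # no signals: spontaneous fate
                else:
                    w = prm[B_0]
                    if prm[B_I] > 0.0 and _count(ig, r2, c2, 2 * r, 2 * c,
                                                 cf_l, ID, 1) > 0:
                        w += prm[B_I]
                    if prm[B_X] > 0.0 and _count(xg, r2, c2, 2 * r, 2 * c,
                                                 cf_l, X, 1) > 0:
                        w += prm[B_X]
                    if prm[B_LOC] > 0.0:
                        if (_count(ig, r2, c2, 2 * r, 2 * c, cf_s, IL, 1) > 0
                                and _count(xg, r2, c2, 2 * r, 2 * c,
                                           cf_s, X, 1) == 0):
                            w += prm[B_LOC]
                if np.random.random() * prm[R_DIFF_M_CAP] < w:
                    mg[r, c] = M
                    nM += 1
                    ev_fire[ev] += 1
        elif ev == EV_DIFF_XB:
            i, j = _pick(xg, r2, c2, XB)
            # xanthophores colonise consolidated dense-S-iridophore
            # territory within reach (short disk or long annulus) of the
            # existing xanthophore field; isolated seeding over dense
            # sheets is much rarer, and with no S-iridophores on the
            # domain at all an autonomous programme takes over, gated on
            # the absence of nearby melanophores
            theta_xb = int(prm[THETA_XB_ID])
            cap = max(prm[R_DIFF_XB], prm[R_DIFF_XB_AUTO])
            r = 0.0
            if (nId + nIl) == 0:
                p = 2 * (i & 1) + (j & 1)
                np_ = fc_s_len[p]
                if _count(mg, rows, cols, i >> 1, j >> 1,
                          fc_s[p, :np_], M, 1) == 0:
                    r = prm[R_DIFF_XB_AUTO]
            elif _count(ig, r2, c2, i, j, ff_s, ID, theta_xb) >= theta_xb:
                if (_count(xg, r2, c2, i, j, ff_s, X, 1) > 0
                        or _count(xg, r2, c2, i, j, ff_l, X, 1) > 0):
                    r = prm[R_DIFF_XB]
                else:
                    r = prm[R_DIFF_XB_SOLO]
            ok = np.random.random() * cap < r
            if ok:
                xg[i, j] = X
                nXb -= 1
                nX += 1
                ev_fire[ev] += 1

        # ------------------------------------------------ melanophore death
        elif ev == EV_DIE_M:
            r, c = _pick(mg, rows, cols, M)
            die = _count(ig, r2, c2, 2 * r, 2 * c, cf_s, ID, 1) > 0
            if not die:
                if _count(xg, r2, c2, 2 * r, 2 * c, cf_s, X, 1) > 0:
                    if tog[T_H2] == 1:
                        die = True
                    else:
                        die = _count(mg, rows, cols, r, c, cc_s, M, 1) == 0
            if die:
                mg[r, c] = 0
                nM -= 1
                ev_fire[ev] += 1

        # ------------------------------------------------ shape transitions
        elif ev == EV_D2L:
            i, j = _pick(ig, r2, c2, ID)
            p = 2 * (i & 1) + (j & 1)
            np_ = fc_s_len[p]
            flip = _count(mg, rows, cols, i >> 1, j >> 1,
                          fc_s[p, :np_], M, 1) > 0
            if not flip and tog[T_D2L_NO_XLONG] == 0:
                gate = True
                if tog[T_D2L_NO_XSHORT] == 0:
                    gate = _count(xg, r2, c2, i, j, ff_s, X, 1) == 0
                if gate:
                    flip = _count(xg, r2, c2, i, j, ff_l, X,
                                  theta_xl) >= theta_xl
            if flip:
                ig[i, j] = IL
                nId -= 1
                nIl += 1
                ev_fire[ev] += 1
        elif ev == EV_L2D:
            i, j = _pick(ig, r2, c2, IL)
            gate = True
            if tog[T_L2D_NO_MSHORT] == 0:
                p = 2 * (i & 1) + (j & 1)
                np_ = fc_s_len[p]
                gate = _count(mg, rows, cols, i >> 1, j >> 1,
                              fc_s[p, :np_], M, 1) == 0
            flip = False
            if gate:
                if tog[T_L2D_NO_XSHORT] == 0:
                    flip = _count(xg, r2, c2, i, j, ff_s, X,
                                  theta_xs) >= theta_xs
                if not flip:
                    flip = _count(xg, r2, c2, i, j, ff_l, X, 1) == 0
            if flip:
                ig[i, j] = ID
                nIl -= 1
                nId += 1
                ev_fire[ev] += 1

        # ------------------------------------------------ domain growth
        elif ev == EV_GROW_H:
            if cols + 1 > mg.shape[1]:
                status = ST_CAPACITY
                break
            k = np.random.randint(0, cols + 1)
            _insert_line(mg, cols, rows, k, 1, False)
            _insert_line(xg, c2, r2, 2 * k, 2, False)
            _insert_line(ig, c2, r2, 2 * k, 2, False)
            cols += 1
            ev_fire[ev] += 1
            if cols >= stop_cols:
                status = ST_STOP_LEN
                break
        else:  # EV_GROW_V
            if rows + 1 > cap_rows:
                status = ST_CAPACITY
                break
            k = np.random.randint(0, rows + 1)
            _insert_line(mg, rows, cols, k, 1, True)
            _insert_line(xg, r2, c2, 2 * k, 2, True)
            _insert_line(ig, r2, c2, 2 * k, 2, True)
            rows += 1
            ev_fire[ev] += 1

    dims[0] = rows
    dims[1] = cols
    counts[0] = nM
    counts[1] = nX
    counts[2] = nXb
    counts[3] = nId
    counts[4] = nIl
    tvec[0] = t
    return status
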