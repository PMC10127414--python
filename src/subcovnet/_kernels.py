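"""Compiled kernels for binary-graph metrics and the permutation engine.

Graphs live on at most 32 nodes and are stored as one ``uint32`` adjacency
bitmask per node, which makes breadth-first searches and Maslov-Sneppen
double-edge swaps a handful of bit operations each.  The permutation test
recomputes the full chain (Pearson correlation -> negative zeroing ->
sparsity binarization -> metrics -> random-network normalization -> AUC)
for every relabeling, so these kernels are deliberately allocation-free in
their inner loops.

Randomness uses an explicit xorshift64* state so results are a pure
function of the seed; index draws use Lemire multiply-shift reduction.

All kernels are cross-checked in the test suite against plain
numpy/networkx implementations and brute-force oracles.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# 16-bit popcount table; uint32 popcount = two lookups.
_POP16 = np.array([bin(i).count("1") for i in range(1 << 16)], dtype=np.uint8)

_M32 = np.uint64(0xFFFFFFFF)
_U1 = np.uint32(1)

# metric indices in the global-curve arrays
CP, LP, GAMMA, LAMBDA, SIGMA, EGLOB, ELOC = range(7)
N_GLOBAL_METRICS = 7
GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Gamma", "Lambda", "Sigma", "Eglobal", "Elocal")

NODAL_EFFICIENCY, BETWEENNESS, DEGREE = range(3)
NODAL_METRIC_NAMES = ("nodal_efficiency", "betweenness", "degree")


@njit(cache=True, inline="always")
def _xorshift(state):
    x = state[0]
    x ^= x << np.uint64(13)
    x ^= x >> np.uint64(7)
    x ^= x << np.uint64(17)
    state[0] = x
    return x * np.uint64(0x2545F4914F6CDD1D)


def seed_state(seed: int) -> np.ndarray:
    """Initialise an xorshift64* state from a small integer seed."""
    s = np.uint64((int(seed) * 6364136223846793005 + 1442695040888963407) % (1 << 64))
    state = np.empty(1, dtype=np.uint64)
    state[0] = s | np.uint64(1)
    return state


@njit(cache=True, inline="always")
def _popcount32(x):
    return _POP16[x & np.uint32(0xFFFF)] + _POP16[(x >> np.uint32(16)) & np.uint32(0xFFFF)]


# ---------------------------------------------------------------------------
# correlation and edge ordering
# ---------------------------------------------------------------------------


@njit(cache=True)
def corr_rplus(X):
    """Pearson correlation of columns of X with negatives zeroed.

    Returns the N x N matrix with unit diagonal replaced by zero (the
    diagonal never enters edge selection).  Columns with (numerically)
    zero variance get zero correlation to every other node.
    """
    n, p = X.shape
    Z = np.empty((n, p))
    ok = np.empty(p, dtype=np.bool_)
    for j in range(p):
        m = 0.0
        for i in range(n):
            m += X[i, j]
        m /= n
        ss = 0.0
        for i in range(n):
            d = X[i, j] - m
            Z[i, j] = d
            ss += d * d
        if ss <= 1e-300:
            ok[j] = False
        else:
            ok[j] = True
            inv = 1.0 / np.sqrt(ss)
            for i in range(n):
                Z[i, j] *= inv
    R = Z.T @ Z
    for a in range(p):
        for b in range(p):
            if a == b or not ok[a] or not ok[b]:
                R[a, b] = 0.0
            elif R[a, b] < 0.0:
                R[a, b] = 0.0
            elif R[a, b] > 1.0:
                R[a, b] = 1.0
    return R


@njit(cache=True)
def sorted_edges(Rp):
    """Upper-triangle edges of Rp sorted by descending weight.

    Ties are broken by lexicographic (i, j) pair order via a stable
    mergesort on the pair-enumeration index.  Returns (eu, ev, n_pos)
    where n_pos counts strictly positive weights.
    """
    n = Rp.shape[0]
    m = n * (n - 1) // 2
    w = np.empty(m)
    pu = np.empty(m, dtype=np.int64)
    pv = np.empty(m, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            w[k] = Rp[i, j]
            pu[k] = i
            pv[k] = j
            k += 1
    order = np.argsort(-w, kind="mergesort")
    eu = np.empty(m, dtype=np.int64)
    ev = np.empty(m, dtype=np.int64)
    n_pos = 0
    for t in range(m):
        o = order[t]
        eu[t] = pu[o]
        ev[t] = pv[o]
        if w[o] > 0.0:
            n_pos += 1
    return eu, ev, n_pos


# ---------------------------------------------------------------------------
# per-graph metrics on bitmask rows
# ---------------------------------------------------------------------------


@njit(cache=True)
def clustering_bitset(rows, n):
    """Mean clustering coefficient; nodes with degree < 2 contribute 0."""
    total = 0.0
    for i in range(n):
        mask = rows[i]
        d = _popcount32(mask)
        if d < 2:
            continue
        t2 = 0
        m = mask
        while m:
            lsb = m & (~m + _U1)
            j = 0
            v = lsb
            while v > _U1:
                v >>= _U1
                j += 1
            t2 += _popcount32(rows[j] & mask)
            m ^= lsb
        # t2 double-counts each neighbour-neighbour edge
        total += t2 / (d * (d - 1))
    return total / n


@njit(cache=True)
def path_stats(rows, n):
    """Lp over finite ordered pairs, unreachable unordered pairs, Eglobal,
    and per-node efficiency.

    Lp is the mean shortest path over ordered pairs with finite distance;
    Eglobal and nodal efficiency treat 1/infinity as 0.
    """
    nodal_eff = np.zeros(n)
    total_d = 0.0
    n_finite = 0
    total_inv = 0.0
    full = (np.uint32(1) << np.uint32(n)) - _U1 if n < 32 else np.uint32(0xFFFFFFFF)
    for s in range(n):
        visited = _U1 << np.uint32(s)
        frontier = visited
        d = 0
        inv = 0.0
        while frontier:
            d += 1
            newf = np.uint32(0)
            m = frontier
            while m:
                lsb = m & (~m + _U1)
                i = 0
                v = lsb
                while v > _U1:
                    v >>= _U1
                    i += 1
                newf |= rows[i]
                m ^= lsb
            newf &= full
            newf &= ~visited
            if newf == np.uint32(0):
                break
            c = _popcount32(newf)
            total_d += d * c
            n_finite += c
            inv += c / d
            visited |= newf
            frontier = newf
        nodal_eff[s] = inv / (n - 1) if n > 1 else 0.0
        total_inv += inv
    n_pairs = n * (n - 1)
    lp = total_d / n_finite if n_finite > 0 else np.nan
    eglob = total_inv / n_pairs if n_pairs > 0 else 0.0
    unreachable = (n_pairs - n_finite) // 2
    return lp, eglob, nodal_eff, unreachable


@njit(cache=True)
def local_efficiency_bitset(rows, n):
    """Mean over all nodes of the global efficiency of each node's
    neighbour-induced subgraph (0 for degree < 2)."""
    total = 0.0
    for i in range(n):
        sub = rows[i]
        d = _popcount32(sub)
        if d < 2:
            continue
        sub_inv = 0.0
        m = sub
        while m:
            lsb = m & (~m + _U1)
            s = 0
            v = lsb
            while v > _U1:
                v >>= _U1
                s += 1
            m ^= lsb
            # BFS from s restricted to sub
            visited = lsb
            frontier = lsb
            dd = 0
            while frontier:
                dd += 1
                newf = np.uint32(0)
                mm = frontier
                while mm:
                    l2 = mm & (~mm + _U1)
                    j = 0
                    v2 = l2
                    while v2 > _U1:
                        v2 >>= _U1
                        j += 1
                    newf |= rows[j]
                    mm ^= l2
                newf &= sub
                newf &= ~visited
                if newf == np.uint32(0):
                    break
                sub_inv += _popcount32(newf) / dd
                visited |= newf
                frontier = newf
        total += sub_inv / (d * (d - 1))
    return total / n


@njit(cache=True)
def betweenness_bitset(rows, n):
    """Brandes betweenness on an unweighted undirected graph, normalized
    by (n-1)(n-2)/2."""
    bc = np.zeros(n)
    sigma = np.zeros(n)
    dist = np.zeros(n, dtype=np.int64)
    delta = np.zeros(n)
    order = np.zeros(n, dtype=np.int64)
    for s in range(n):
        for i in range(n):
            sigma[i] = 0.0
            dist[i] = -1
            delta[i] = 0.0
        sigma[s] = 1.0
        dist[s] = 0
        head = 0
        tail = 0
        order[tail] = s
        tail += 1
        while head < tail:
            v = order[head]
            head += 1
            m = rows[v]
            while m:
                lsb = m & (~m + _U1)
                w = 0
                vv = lsb
                while vv > _U1:
                    vv >>= _U1
                    w += 1
                m ^= lsb
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    order[tail] = w
                    tail += 1
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        for t in range(tail - 1, 0, -1):
            w = order[t]
            m = rows[w]
            coef = (1.0 + delta[w]) / sigma[w]
            while m:
                lsb = m & (~m + _U1)
                v = 0
                vv = lsb
                while vv > _U1:
                    vv >>= _U1
                    v += 1
                m ^= lsb
                if dist[v] == dist[w] - 1:
                    delta[v] += sigma[v] * coef
            if w != s:
                bc[w] += delta[w]
    # each unordered pair counted twice; normalize to [0, 1]
    if n > 2:
        norm = 1.0 / ((n - 1) * (n - 2))
        for i in range(n):
            bc[i] *= norm
    else:
        for i in range(n):
            bc[i] = 0.0
    return bc


@njit(cache=True)
def degrees_bitset(rows, n):
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        out[i] = _popcount32(rows[i])
    return out


# ---------------------------------------------------------------------------
# Maslov-Sneppen rewiring
# ---------------------------------------------------------------------------


@njit(cache=True)
def rewire(rows, eu, ev, n_edges, n_swaps, max_attempts, state):
    """Degree-preserving double-edge swaps in place.

    ``eu/ev[:n_edges]`` is the live edge list, kept consistent with the
    bitmask rows.  Returns the number of successful swaps (may fall short
    of ``n_swaps`` if ``max_attempts`` is exhausted).
    """
    if n_edges < 2:
        return 0
    E = np.uint64(n_edges)
    swaps = 0
    att = 0
    while swaps < n_swaps and att < max_attempts:
        att += 1
        r = _xorshift(state)
        r1 = (r >> np.uint64(32)) & _M32
        r2 = r & _M32
        e1 = np.int64((r1 * E) >> np.uint64(32))
        e2 = np.int64((r2 * E) >> np.uint64(32))
        if e1 == e2:
            continue
        a = eu[e1]
        b = ev[e1]
        c = eu[e2]
        d = ev[e2]
        if (r1 ^ r2) & np.uint64(1):
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        if (rows[a] >> np.uint32(d)) & _U1:
            continue
        if (rows[c] >> np.uint32(b)) & _U1:
            continue
        rows[a] ^= _U1 << np.uint32(b)
        rows[b] ^= _U1 << np.uint32(a)
        rows[c] ^= _U1 << np.uint32(d)
        rows[d] ^= _U1 << np.uint32(c)
        rows[a] |= _U1 << np.uint32(d)
        rows[d] |= _U1 << np.uint32(a)
        rows[c] |= _U1 << np.uint32(b)
        rows[b] |= _U1 << np.uint32(c)
        eu[e1] = a
        ev[e1] = d
        eu[e2] = c
        ev[e2] = b
        swaps += 1
    return swaps


@njit(cache=True)
def adjacency_to_rows(adj):
    n = adj.shape[0]
    rows = np.zeros(n, dtype=np.uint32)
    for i in range(n):
        for j in range(n):
            if adj[i, j] != 0 and i != j:
                rows[i] |= _U1 << np.uint32(j)
    return rows


@njit(cache=True)
def rows_to_adjacency(rows, n):
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(n):
            if (rows[i] >> np.uint32(j)) & _U1:
                adj[i, j] = 1
    return adj


# ---------------------------------------------------------------------------
# curve engine
# ---------------------------------------------------------------------------


@njit(cache=True)
def _largest_component_rows(rows, n):
    """Mask of the largest connected component."""
    best = np.uint32(0)
    best_size = 0
    seen = np.uint32(0)
    for s in range(n):
        bit = _U1 << np.uint32(s)
        if seen & bit:
            continue
        comp = bit
        frontier = bit
        while frontier:
            newf = np.uint32(0)
            m = frontier
            while m:
                lsb = m & (~m + _U1)
                i = 0
                v = lsb
                while v > _U1:
                    v >>= _U1
                    i += 1
                newf |= rows[i]
                m ^= lsb
            newf &= ~comp
            if newf == np.uint32(0):
                break
            comp |= newf
            frontier = newf
        seen |= comp
        size = _popcount32(comp)
        if size > best_size:
            best_size = size
            best = comp
    return best


@njit(cache=True)
def global_curves(X, ks, n_random, swap_mult, att_mult, state, nested):
    """Global metric curves over the sparsity grid for one group.

    X: subjects x nodes volume matrix.  ks: target edge counts per grid
    point (ascending).  Returns (curves[7, n_k], achieved[n_k],
    unreachable[n_k], swap_deficit) where curves rows follow
    GLOBAL_METRIC_NAMES and Gamma/Lambda/Sigma are NaN when n_random == 0.

    The rewired ensemble is either rebuilt independently at every grid
    point or, in the nested scheme, carried up the grid: the edges added
    to the real graph are added to each null graph, followed by
    swap_mult x (new edge count) additional successful swaps, keeping the
    cumulative swap budget at swap_mult x E at every level.
    """
    n = X.shape[1]
    nk = ks.shape[0]
    Rp = corr_rplus(X)
    eu, ev, n_pos = sorted_edges(Rp)
    m = eu.shape[0]

    curves = np.full((N_GLOBAL_METRICS, nk), np.nan)
    achieved = np.zeros(nk, dtype=np.int64)
    unreachable = np.zeros(nk, dtype=np.int64)
    swap_deficit = 0

    rows = np.zeros(n, dtype=np.uint32)
    # null-ensemble state (nested scheme)
    ens_rows = np.zeros((n_random, n), dtype=np.uint32)
    ens_eu = np.zeros((n_random, m), dtype=np.int64)
    ens_ev = np.zeros((n_random, m), dtype=np.int64)
    ens_ne = np.zeros(n_random, dtype=np.int64)

    e_done = 0
    for t in range(nk):
        k = min(ks[t], n_pos)
        achieved[t] = k
        while e_done < k:
            a = eu[e_done]
            b = ev[e_done]
            rows[a] |= _U1 << np.uint32(b)
            rows[b] |= _U1 << np.uint32(a)
            e_done += 1
        cp = clustering_bitset(rows, n)
        lp, eglob, _ne, unr = path_stats(rows, n)
        eloc = local_efficiency_bitset(rows, n)
        curves[CP, t] = cp
        curves[LP, t] = lp
        curves[EGLOB, t] = eglob
        curves[ELOC, t] = eloc
        unreachable[t] = unr

        if n_random > 0:
            cp_sum = 0.0
            lp_sum = 0.0
            n_ok = 0
            for j in range(n_random):
                fresh = True
                if nested and t > 0:
                    # top up this null graph with the edges newly added to
                    # the real graph, preserving the exact degree sequence
                    fresh = False
                    prev = ens_ne[j]
                    for e in range(prev, k):
                        a = eu[e]
                        b = ev[e]
                        if (ens_rows[j, a] >> np.uint32(b)) & _U1:
                            # (a, b) already present: degree-matched repair.
                            # Remove a random edge (x, y) disjoint from
                            # {a, b} and add (a, x), (b, y) instead.
                            repaired = False
                            for _try in range(256):
                                r = _xorshift(state)
                                e3 = np.int64(
                                    (((r >> np.uint64(32)) & _M32) * np.uint64(ens_ne[j]))
                                    >> np.uint64(32)
                                )
                                x = ens_eu[j, e3]
                                y = ens_ev[j, e3]
                                if r & np.uint64(1):
                                    x, y = y, x
                                if x == a or x == b or y == a or y == b:
                                    continue
                                if (ens_rows[j, a] >> np.uint32(x)) & _U1:
                                    continue
                                if (ens_rows[j, b] >> np.uint32(y)) & _U1:
                                    continue
                                ens_rows[j, x] ^= _U1 << np.uint32(y)
                                ens_rows[j, y] ^= _U1 << np.uint32(x)
                                ens_rows[j, a] |= _U1 << np.uint32(x)
                                ens_rows[j, x] |= _U1 << np.uint32(a)
                                ens_rows[j, b] |= _U1 << np.uint32(y)
                                ens_rows[j, y] |= _U1 << np.uint32(b)
                                ens_eu[j, e3] = a
                                ens_ev[j, e3] = x
                                ens_eu[j, ens_ne[j]] = b
                                ens_ev[j, ens_ne[j]] = y
                                ens_ne[j] += 1
                                repaired = True
                                break
                            if not repaired:
                                fresh = True  # rebuild this member from scratch
                                break
                        else:
                            ens_rows[j, a] |= _U1 << np.uint32(b)
                            ens_rows[j, b] |= _U1 << np.uint32(a)
                            ens_eu[j, ens_ne[j]] = a
                            ens_ev[j, ens_ne[j]] = b
                            ens_ne[j] += 1
                    if not fresh:
                        budget = swap_mult * (k - prev)
                        got = rewire(
                            ens_rows[j], ens_eu[j], ens_ev[j], ens_ne[j],
                            budget, att_mult * budget + 64, state,
                        )
                        swap_deficit += budget - got
                if fresh:
                    for i in range(n):
                        ens_rows[j, i] = rows[i]
                    for e in range(k):
                        ens_eu[j, e] = eu[e]
                        ens_ev[j, e] = ev[e]
                    ens_ne[j] = k
                    budget = swap_mult * k
                    got = rewire(
                        ens_rows[j], ens_eu[j], ens_ev[j], k,
                        budget, att_mult * budget + 64, state,
                    )
                    swap_deficit += budget - got
                rcp = clustering_bitset(ens_rows[j], n)
                rlp, _rg, _rne, _ru = path_stats(ens_rows[j], n)
                if not np.isnan(rlp):
                    cp_sum += rcp
                    lp_sum += rlp
                    n_ok += 1
            if n_ok > 0 and cp_sum > 0.0 and lp_sum > 0.0:
                curves[GAMMA, t] = cp / (cp_sum / n_ok)
                curves[LAMBDA, t] = lp / (lp_sum / n_ok)
                curves[SIGMA, t] = curves[GAMMA, t] / curves[LAMBDA, t]
    return curves, achieved, unreachable, swap_deficit


@njit(cache=True)
def nodal_curves(X, ks):
    """Nodal metric curves (nodal efficiency, betweenness, degree) over
    the sparsity grid for one group: array [3, n_nodes, n_k]."""
    n = X.shape[1]
    nk = ks.shape[0]
    Rp = corr_rplus(X)
    eu, ev, n_pos = sorted_edges(Rp)
    out = np.zeros((3, n, nk))
    rows = np.zeros(n, dtype=np.uint32)
    e_done = 0
    for t in range(nk):
        k = min(ks[t], n_pos)
        while e_done < k:
            a = eu[e_done]
            b = ev[e_done]
            rows[a] |= _U1 << np.uint32(b)
            rows[b] |= _U1 << np.uint32(a)
            e_done += 1
        _lp, _eg, ne, _unr = path_stats(rows, n)
        bc = betweenness_bitset(rows, n)
        dg = degrees_bitset(rows, n)
        for i in range(n):
            out[NODAL_EFFICIENCY, i, t] = ne[i]
            out[BETWEENNESS, i, t] = bc[i]
            out[DEGREE, i, t] = dg[i]
    return out


@njit(cache=True)
def trap_auc(grid, values):
    s = 0.0
    for i in range(grid.shape[0] - 1):
        s += 0.5 * (values[i] + values[i + 1]) * (grid[i + 1] - grid[i])
    return s


@njit(cache=True)
def step_auc(grid, values, step):
    s = 0.0
    for i in range(grid.shape[0]):
        s += values[i] * step
    return s


@njit(cache=True)
def _aucs_from_curves(curves, grid, auc_rule, step):
    nmet = curves.shape[0]
    out = np.empty(nmet)
    for q in range(nmet):
        if auc_rule == 0:
            out[q] = trap_auc(grid, curves[q])
        else:
            out[q] = step_auc(grid, curves[q], step)
    return out


@njit(cache=True)
def _shuffle(idx, state):
    n = idx.shape[0]
    for i in range(n - 1, 0, -1):
        r = _xorshift(state)
        j = np.int64((((r >> np.uint64(32)) & _M32) * np.uint64(i + 1)) >> np.uint64(32))
        tmp = idx[i]
        idx[i] = idx[j]
        idx[j] = tmp
    return idx


@njit(cache=True)
def two_group_global_perm(
    XA, XB, grid, ks, n_random, swap_mult, att_mult, n_perm, seed, nested, auc_rule, step
):
    """Observed per-group global AUCs and the permutation null of A-B
    differences.

    Returns (auc_A[7], auc_B[7], null[n_perm, 7]).  Every permutation
    pools the subjects, reassigns them preserving group sizes, and reruns
    the whole chain with a fresh deterministic random-network stream.
    """
    nA = XA.shape[0]
    nB = XB.shape[0]
    p = XA.shape[1]
    pool = np.empty((nA + nB, p))
    pool[:nA] = XA
    pool[nA:] = XB
    state = np.empty(1, dtype=np.uint64)
    state[0] = (
        np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    ) | np.uint64(1)

    cA, _a1, _u1, _s1 = global_curves(XA, ks, n_random, swap_mult, att_mult, state, nested)
    cB, _a2, _u2, _s2 = global_curves(XB, ks, n_random, swap_mult, att_mult, state, nested)
    auc_A = _aucs_from_curves(cA, grid, auc_rule, step)
    auc_B = _aucs_from_curves(cB, grid, auc_rule, step)

    null = np.empty((n_perm, N_GLOBAL_METRICS))
    idx = np.arange(nA + nB)
    for r in range(n_perm):
        _shuffle(idx, state)
        PA = pool[idx[:nA]]
        PB = pool[idx[nA:]]
        c1, _x1, _y1, _z1 = global_curves(PA, ks, n_random, swap_mult, att_mult, state, nested)
        c2, _x2, _y2, _z2 = global_curves(PB, ks, n_random, swap_mult, att_mult, state, nested)
        a1 = _aucs_from_curves(c1, grid, auc_rule, step)
        a2 = _aucs_from_curves(c2, grid, auc_rule, step)
        for q in range(N_GLOBAL_METRICS):
            null[r, q] = a1[q] - a2[q]
    return auc_A, auc_B, null


@njit(cache=True)
def two_group_nodal_perm(XA, XB, grid, ks, metric_id, n_perm, seed, auc_rule, step):
    """Observed nodal AUCs per group and permutation null of differences
    for one nodal metric: returns (auc_A[n], auc_B[n], null[n_perm, n])."""
    nA = XA.shape[0]
    nB = XB.shape[0]
    p = XA.shape[1]
    pool = np.empty((nA + nB, p))
    pool[:nA] = XA
    pool[nA:] = XB
    state = np.empty(1, dtype=np.uint64)
    state[0] = (
        np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    ) | np.uint64(1)

    def _nodal_aucs(X):
        c = nodal_curves(X, ks)
        out = np.empty(p)
        for i in range(p):
            if auc_rule == 0:
                out[i] = trap_auc(grid, c[metric_id, i])
            else:
                out[i] = step_auc(grid, c[metric_id, i], step)
        return out

    auc_A = _nodal_aucs(XA)
    auc_B = _nodal_aucs(XB)
    null = np.empty((n_perm, p))
    idx = np.arange(nA + nB)
    for r in range(n_perm):
        _shuffle(idx, state)
        a1 = _nodal_aucs(pool[idx[:nA]])
        a2 = _nodal_aucs(pool[idx[nA:]])
        for i in range(p):
            null[r, i] = a1[i] - a2[i]
    return auc_A, auc_B, null
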