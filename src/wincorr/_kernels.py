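"""Numba-compiled dynamic-programming kernels.

Two hot loops live here: local alignment of a sequence against a partial
order graph (a generalization of Smith-Waterman over all paths of the
DAG), and a banded unit-cost edit-distance alignment with operation
traceback used by the evaluator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def poa_align_kernel(labels, topo, pred_indptr, pred_idx, query,
                     match, mismatch, gap):
    """Local alignment of ``query`` to a DAG.

    ``labels`` holds one base code per node; ``topo`` lists node ids in
    topological order; predecessors of each node are given CSR-style and
    must be pre-sorted by topological rank (traceback tie order: diagonal
    over vertical over horizontal, earliest predecessor first).

    Returns (score, op_nodes, op_qpos): parallel arrays where
    (v, j) is an aligned pair, (v, -1) a node skipped by the query and
    (-1, j) a query base inserted relative to the graph.
    """
    V = labels.size
    Q = query.size
    H = np.zeros((V, Q + 1), np.int32)
    best = np.int32(0)
    bv = -1
    bj = 0
    for ti in range(V):
        v = topo[ti]
        lv = labels[v]
        p0 = pred_indptr[v]
        p1 = pred_indptr[v + 1]
        row = H[v]
        for j in range(1, Q + 1):
            s = match if lv == query[j - 1] else mismatch
            h = s  # fresh local start feeding the diagonal
            for pi in range(p0, p1):
                p = pred_idx[pi]
                d = H[p, j - 1] + s
                if d > h:
                    h = d
                g = H[p, j] + gap
                if g > h:
                    h = g
            g2 = row[j - 1] + gap
            if g2 > h:
                h = g2
            if h < 0:
                h = 0
            row[j] = h
            if h > best:
                best = h
                bv = v
                bj = j

    cap = V + Q + 2
    ops_n = np.empty(cap, np.int32)
    ops_q = np.empty(cap, np.int32)
    cnt = 0
    v = bv
    j = bj
    while v != -1 and j > 0:
        h = H[v, j]
        if h <= 0:
            break
        s = match if labels[v] == query[j - 1] else mismatch
        p0 = pred_indptr[v]
        p1 = pred_indptr[v + 1]
        moved = False
        for pi in range(p0, p1):
            p = pred_idx[pi]
            if H[p, j - 1] + s == h:
                ops_n[cnt] = v
                ops_q[cnt] = j - 1
                cnt += 1
                v = p
                j -= 1
                moved = True
                break
        if moved:
            continue
        if s == h:
            ops_n[cnt] = v
            ops_q[cnt] = j - 1
            cnt += 1
            break
        for pi in range(p0, p1):
            p = pred_idx[pi]
            if H[p, j] + gap == h:
                ops_n[cnt] = v
                ops_q[cnt] = -1
                cnt += 1
                v = p
                moved = True
                break
        if moved:
            continue
        if H[v, j - 1] + gap == h:
            ops_n[cnt] = -1
            ops_q[cnt] = j - 1
            cnt += 1
            j -= 1
            continue
        break
    return best, ops_n[:cnt][::-1].copy(), ops_q[:cnt][::-1].copy()


@njit(cache=True)
def topo_csr_kernel(n, eu, ev):
    """Topological order, ranks and rank-sorted predecessor CSR for a DAG
    given as parallel edge arrays."""
    E = eu.size
    indptr = np.zeros(n + 1, np.int32)
    for e in range(E):
        indptr[ev[e] + 1] += 1
    for v in range(n):
        indptr[v + 1] += indptr[v]
    pred_idx = np.empty(E, np.int32)
    fill = indptr[:-1].copy()
    for e in range(E):
        v = ev[e]
        pred_idx[fill[v]] = eu[e]
        fill[v] += 1
    # successor CSR for Kahn
    sptr = np.zeros(n + 1, np.int32)
    for e in range(E):
        sptr[eu[e] + 1] += 1
    for v in range(n):
        sptr[v + 1] += sptr[v]
    succ_idx = np.empty(E, np.int32)
    sfill = sptr[:-1].copy()
    for e in range(E):
        u = eu[e]
        succ_idx[sfill[u]] = ev[e]
        sfill[u] += 1
    indeg = np.zeros(n, np.int32)
    for e in range(E):
        indeg[ev[e]] += 1
    topo = np.empty(n, np.int32)
    head = 0
    tail = 0
    for v in range(n):
        if indeg[v] == 0:
            topo[tail] = v
            tail += 1
    while head < tail:
        v = topo[head]
        head += 1
        for si in range(sptr[v], sptr[v + 1]):
            s = succ_idx[si]
            indeg[s] -= 1
            if indeg[s] == 0:
                topo[tail] = s
                tail += 1
    rank = np.empty(n, np.int32)
    for r in range(tail):
        rank[topo[r]] = r
    # insertion-sort each (tiny) predecessor list by rank
    for v in range(n):
        lo = indptr[v]
        hi = indptr[v + 1]
        for a in range(lo + 1, hi):
            key = pred_idx[a]
            kr = rank[key]
            b = a - 1
            while b >= lo and rank[pred_idx[b]] > kr:
                pred_idx[b + 1] = pred_idx[b]
                b -= 1
            pred_idx[b + 1] = key
    return tail, topo, indptr, pred_idx


@njit(cache=True)
def anchor_compat_kernel(P, k):
    """Pairwise anchor compatibility over the position matrix P
    (candidate x sequence, -1 when absent).  Upper triangle only:
    order_ok[i, j] holds when anchor i ends at least k bases before
    anchor j starts in every sequence containing both; co[i, j] counts
    the co-containing sequences."""
    n, S = P.shape
    order_ok = np.zeros((n, n), np.bool_)
    co = np.zeros((n, n), np.int32)
    for i in range(n):
        for j in range(i + 1, n):
            c = 0
            viol = 0
            for s in range(S):
                pi = P[i, s]
                pj = P[j, s]
                both = (pi >= 0) and (pj >= 0)
                c += 1 if both else 0
                viol += 1 if (both and pj < pi + k) else 0
            order_ok[i, j] = viol == 0
            co[i, j] = c
    return order_ok, co


# edit operation codes emitted by banded_edit_kernel
OP_SUB = 1
OP_DEL = 2   # base of `a` missing from `b`
OP_INS = 3   # extra base of `b`, attributed to the gap position on `a`


@njit(cache=True)
def banded_edit_kernel(a, b, w):
    """Global unit-cost alignment of ``b`` against ``a`` within band ``w``.

    The result is exact whenever the returned distance is <= w (indel
    drift along an optimal path never exceeds the distance itself).
    Returns (distance, positions_on_a, op_kinds).
    """
    n = a.size
    m = b.size
    if w < abs(n - m):
        w = abs(n - m)
    width = 2 * w + 1
    INF = np.int32(1 << 28)
    H = np.full((n + 1, width), INF, np.int32)
    for c in range(width):
        j = c - w
        if 0 <= j <= m:
            H[0, c] = j
    for i in range(1, n + 1):
        lo = i - w
        if lo < 0:
            lo = 0
        hi = i + w
        if hi > m:
            hi = m
        for j in range(lo, hi + 1):
            c = j - i + w
            best = INF
            if c + 1 < width:
                v = H[i - 1, c + 1] + 1          # deletion of a[i-1]
                if v < best:
                    best = v
            if j >= 1:
                d = H[i - 1, c]
                if a[i - 1] == b[j - 1]:
                    v = d
                else:
                    v = d + 1
                if v < best:
                    best = v
            if j >= 1 and c - 1 >= 0:
                v = H[i, c - 1] + 1              # insertion of b[j-1]
                if v < best:
                    best = v
            H[i, c] = best
    dist = H[n, m - n + w]

    pos = np.empty(n + m + 1, np.int32)
    kind = np.empty(n + m + 1, np.int8)
    cnt = 0
    i = n
    j = m
    while i > 0 or j > 0:
        c = j - i + w
        h = H[i, c]
        if i > 0 and j > 0:
            d = H[i - 1, c]
            if a[i - 1] == b[j - 1] and d == h:
                i -= 1
                j -= 1
                continue
            if a[i - 1] != b[j - 1] and d + 1 == h:
                pos[cnt] = i - 1
                kind[cnt] = OP_SUB
                cnt += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and c + 1 < width and H[i - 1, c + 1] + 1 == h:
            pos[cnt] = i - 1
            kind[cnt] = OP_DEL
            cnt += 1
            i -= 1
            continue
        if j > 0 and c - 1 >= 0 and H[i, c - 1] + 1 == h:
            pos[cnt] = i
            kind[cnt] = OP_INS
            cnt += 1
            j -= 1
            continue
        break
    return dist, pos[:cnt][::-1].copy(), kind[:cnt][::-1].copy()
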