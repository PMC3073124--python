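"""Low-level search kernels on flat tree arrays.

Trees are stored as neighbour tables: ``nbr`` is int32[N, 3] (-1 padded) and
``deg`` int32[N], with leaves 0..n-1 and internal nodes n..N-1.  Leaf state
sets are uint8 bitmasks, one byte per character.

The TBR scan uses edge-rooted directional Fitch sets: for a bisection into
subtrees T1 and T2, the length of the tree obtained by reconnecting at edges
(e1, e2) is ``len(T1) + len(T2) + #characters whose root sets at e1 and e2 are
disjoint``.  This makes a whole reconnection row an O(C) bit scan instead of a
full rescore.

Kernels are compiled with numba when available and degrade to pure Python
otherwise (identical semantics, usable for small problems and as a safety
net).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def tree_length(nbr, deg, n, X):
    """Unrooted Fitch length of the tree over the leaves present (deg > 0)."""
    N = nbr.shape[0]
    C = X.shape[1]
    anchor = -1
    for v in range(n):
        if deg[v] > 0:
            anchor = v
            break
    if anchor < 0 or deg[anchor] == 0:
        return 0
    root = nbr[anchor, 0]
    if root < n and deg[root] == 1:  # two-leaf tree
        total = 0
        for c in range(C):
            if X[anchor, c] & X[root, c] == 0:
                total += 1
        return total

    parent = np.full(N, -1, dtype=np.int32)
    order = np.empty(N, dtype=np.int32)
    stack = np.empty(N, dtype=np.int32)
    sets = np.empty((N, C), dtype=np.uint8)
    parent[root] = anchor
    sp = 0
    stack[0] = root
    cnt = 0
    while sp >= 0:
        v = stack[sp]
        sp -= 1
        order[cnt] = v
        cnt += 1
        for t in range(deg[v]):
            w = nbr[v, t]
            if w != parent[v]:
                parent[w] = v
                sp += 1
                stack[sp] = w
    total = 0
    for idx in range(cnt - 1, -1, -1):
        v = order[idx]
        if v < n:
            for c in range(C):
                sets[v, c] = X[v, c]
        else:
            first = -1
            for t in range(deg[v]):
                w = nbr[v, t]
                if w == parent[v]:
                    continue
                if first < 0:
                    first = w
                    for c in range(C):
                        sets[v, c] = sets[w, c]
                else:
                    for c in range(C):
                        x = sets[v, c] & sets[w, c]
                        if x == 0:
                            total += 1
                            sets[v, c] = sets[v, c] | sets[w, c]
                        else:
                            sets[v, c] = x
    for c in range(C):
        if sets[root, c] & X[anchor, c] == 0:
            total += 1
    return total


@njit(cache=True)
def attach_scores(nbr, deg, n, X, leaf, out_u, out_v, out_s):
    """Length of the tree after attaching ``leaf`` on each edge.

    Fills out_u/out_v with edge endpoints and out_s with resulting lengths;
    returns (number of edges, current length).
    """
    N = nbr.shape[0]
    C = X.shape[1]
    anchor = -1
    for v in range(n):
        if v != leaf and deg[v] > 0:
            anchor = v
            break
    root = nbr[anchor, 0]
    parent = np.full(N, -1, dtype=np.int32)
    order = np.empty(N, dtype=np.int32)
    stack = np.empty(N, dtype=np.int32)
    D = np.empty((N, C), dtype=np.uint8)
    U = np.empty((N, C), dtype=np.uint8)
    parent[root] = anchor
    sp = 0
    stack[0] = root
    cnt = 0
    while sp >= 0:
        v = stack[sp]
        sp -= 1
        order[cnt] = v
        cnt += 1
        for t in range(deg[v]):
            w = nbr[v, t]
            if w != parent[v]:
                parent[w] = v
                sp += 1
                stack[sp] = w
    L = 0
    for idx in range(cnt - 1, -1, -1):
        v = order[idx]
        if v < n:
            for c in range(C):
                D[v, c] = X[v, c]
        else:
            first = -1
            for t in range(deg[v]):
                w = nbr[v, t]
                if w == parent[v]:
                    continue
                if first < 0:
                    first = w
                    for c in range(C):
                        D[v, c] = D[w, c]
                else:
                    for c in range(C):
                        x = D[v, c] & D[w, c]
                        if x == 0:
                            L += 1
                            D[v, c] = D[v, c] | D[w, c]
                        else:
                            D[v, c] = x
    for c in range(C):
        if D[root, c] & X[anchor, c] == 0:
            L += 1
    # upward sets: U[v] = state set of everything on the parent side of v
    for c in range(C):
        U[root, c] = X[anchor, c]
    for idx in range(cnt):
        v = order[idx]
        if v < n:
            continue
        for t in range(deg[v]):
            w = nbr[v, t]
            if w == parent[v]:
                continue
            # sibling set = combine of other children and U[v]
            for c in range(C):
                s = U[v, c]
                for t2 in range(deg[v]):
                    w2 = nbr[v, t2]
                    if w2 == parent[v] or w2 == w:
                        continue
                    x = s & D[w2, c]
                    if x == 0:
                        s = s | D[w2, c]
                    else:
                        s = x
                U[w, c] = s
    E = 0
    for idx in range(cnt):
        v = order[idx]
        extra = 0
        for c in range(C):
            x = D[v, c] & U[v, c]
            if x == 0:
                x = D[v, c] | U[v, c]
            if x & X[leaf, c] == 0:
                extra += 1
        out_u[E] = parent[v]
        out_v[E] = v
        out_s[E] = L + extra
        E += 1
    return E, L


@njit(cache=True)
def tbr_scan(
    nbr, deg, n, X, ea, eb, cur_best, mode, collect_all,
    out_imp, out_eq, rng_seed,
):
    """Scan TBR (mode 0) or SPR (mode 1) moves over the given bisection edges.

    A move is recorded as (a, b, u1, v1, u2, v2, length): remove edge a-b,
    reattach the a-side by subdividing (u1, v1) and the b-side at (u2, v2)
    (u == v marks a single-leaf side).  Improving moves (< cur_best) go to
    ``out_imp``; equal-length moves are reservoir-sampled into ``out_eq``
    (seeded, so a scan is reproducible), keeping the drift step's choice of
    sideways move unbiased across the whole neighbourhood.  With
    collect_all == 0 the scan returns at the first improving move.
    Returns (n_improving, n_equal) where n_equal counts *recorded* moves.
    """
    np.random.seed(rng_seed)
    N = nbr.shape[0]
    C = X.shape[1]
    parent = np.full(N, -1, dtype=np.int32)
    order = np.empty(N, dtype=np.int32)
    stack = np.empty(N, dtype=np.int32)
    D = np.empty((N, C), dtype=np.uint8)
    U = np.empty((N, C), dtype=np.uint8)
    R = np.empty((2, N, C), dtype=np.uint8)
    candu = np.empty((2, N), dtype=np.int32)
    candv = np.empty((2, N), dtype=np.int32)
    E = np.zeros(2, dtype=np.int64)
    L = np.zeros(2, dtype=np.int64)
    n_imp = 0
    n_eq = 0
    n_eq_seen = 0
    cap_imp = out_imp.shape[0]
    cap_eq = out_eq.shape[0]

    for eidx in range(ea.shape[0]):
        a = ea[eidx]
        b = eb[eidx]
        for side in range(2):
            root = a if side == 0 else b
            block = b if side == 0 else a
            if root < n:
                E[side] = 1
                L[side] = 0
                candu[side, 0] = root
                candv[side, 0] = root
                for c in range(C):
                    R[side, 0, c] = X[root, c]
                continue
            # DFS from root, not crossing the removed edge
            parent[root] = block
            sp = 0
            stack[0] = root
            cnt = 0
            while sp >= 0:
                v = stack[sp]
                sp -= 1
                order[cnt] = v
                cnt += 1
                for t in range(deg[v]):
                    w = nbr[v, t]
                    if w != parent[v]:
                        parent[w] = v
                        sp += 1
                        stack[sp] = w
            Lc = 0
            for idx in range(cnt - 1, 0, -1):
                v = order[idx]
                if v < n:
                    for c in range(C):
                        D[v, c] = X[v, c]
                else:
                    c1 = -1
                    c2 = -1
                    for t in range(deg[v]):
                        w = nbr[v, t]
                        if w != parent[v]:
                            if c1 < 0:
                                c1 = w
                            else:
                                c2 = w
                    for c in range(C):
                        x = D[c1, c] & D[c2, c]
                        if x == 0:
                            Lc += 1
                            D[v, c] = D[c1, c] | D[c2, c]
                        else:
                            D[v, c] = x
            rc1 = -1
            rc2 = -1
            for t in range(deg[root]):
                w = nbr[root, t]
                if w != block:
                    if rc1 < 0:
                        rc1 = w
                    else:
                        rc2 = w
            for c in range(C):
                if D[rc1, c] & D[rc2, c] == 0:
                    Lc += 1
            L[side] = Lc
            # upward sets within the component
            for c in range(C):
                U[rc1, c] = D[rc2, c]
                U[rc2, c] = D[rc1, c]
            for idx in range(cnt):
                v = order[idx]
                if v == root or v < n:
                    continue
                for t in range(deg[v]):
                    w = nbr[v, t]
                    if w == parent[v]:
                        continue
                    s2 = -1
                    for t2 in range(deg[v]):
                        w2 = nbr[v, t2]
                        if w2 != parent[v] and w2 != w:
                            s2 = w2
                    for c in range(C):
                        x = U[v, c] & D[s2, c]
                        if x == 0:
                            U[w, c] = U[v, c] | D[s2, c]
                        else:
                            U[w, c] = x
            # candidate reconnection edges; index 0 = merged original edge
            candu[side, 0] = rc1
            candv[side, 0] = rc2
            for c in range(C):
                x = D[rc1, c] & D[rc2, c]
                if x == 0:
                    x = D[rc1, c] | D[rc2, c]
                R[side, 0, c] = x
            mcount = 1
            for idx in range(cnt):
                v = order[idx]
                if v == root or v == rc1 or v == rc2:
                    continue
                candu[side, mcount] = parent[v]
                candv[side, mcount] = v
                for c in range(C):
                    x = D[v, c] & U[v, c]
                    if x == 0:
                        x = D[v, c] | U[v, c]
                    R[side, mcount, c] = x
                mcount += 1
            E[side] = mcount

        limit = cur_best - L[0] - L[1]
        if limit < 0:
            continue
        for i in range(E[0]):
            for j in range(E[1]):
                if mode == 1 and i != 0 and j != 0:
                    continue
                cnt2 = 0
                ok = True
                for c in range(C):
                    if R[0, i, c] & R[1, j, c] == 0:
                        cnt2 += 1
                        if cnt2 > limit:
                            ok = False
                            break
                if not ok:
                    continue
                length = L[0] + L[1] + cnt2
                if length < cur_best:
                    if n_imp < cap_imp:
                        out_imp[n_imp, 0] = a
                        out_imp[n_imp, 1] = b
                        out_imp[n_imp, 2] = candu[0, i]
                        out_imp[n_imp, 3] = candv[0, i]
                        out_imp[n_imp, 4] = candu[1, j]
                        out_imp[n_imp, 5] = candv[1, j]
                        out_imp[n_imp, 6] = length
                        n_imp += 1
                    if collect_all == 0:
                        return n_imp, n_eq
                else:
                    if n_eq < cap_eq:
                        slot = n_eq
                        n_eq += 1
                    else:
                        slot = np.random.randint(0, n_eq_seen + 1)
                    n_eq_seen += 1
                    if slot < cap_eq:
                        out_eq[slot, 0] = a
                        out_eq[slot, 1] = b
                        out_eq[slot, 2] = candu[0, i]
                        out_eq[slot, 3] = candv[0, i]
                        out_eq[slot, 4] = candu[1, j]
                        out_eq[slot, 5] = candv[1, j]
                        out_eq[slot, 6] = length
    return n_imp, n_eq
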