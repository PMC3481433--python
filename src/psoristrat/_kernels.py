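"""Numba kernels for the deterministic CART/Gini tree ensemble.

All randomness flows through a splitmix64 counter passed in as per-tree
64-bit seeds, so fitted forests are bit-identical across platforms and
independent of execution order. Trees are stored in flat preallocated
arrays (one row per tree): ``feature < 0`` marks a leaf.
"""

import numpy as np
from numba import njit

U64 = np.uint64

_SM_GAMMA = U64(0x9E3779B97F4A7C15)
_SM_MUL1 = U64(0xBF58476D1CE4E5B9)
_SM_MUL2 = U64(0x94D049BB133111EB)


@njit(inline="always")
def _next_u64(state):
    state[0] = state[0] + _SM_GAMMA
    z = state[0]
    z = (z ^ (z >> U64(30))) * _SM_MUL1
    z = (z ^ (z >> U64(27))) * _SM_MUL2
    return z ^ (z >> U64(31))


@njit(inline="always")
def _rand_below(state, n):
    # modulo bias is ~n/2^64: irrelevant at these sizes
    return np.int64(_next_u64(state) % U64(n))


@njit(inline="always")
def _gini(counts, n, n_classes):
    s = 0.0
    for c in range(n_classes):
        f = counts[c] / n
        s += f * f
    return 1.0 - s


@njit(cache=True)
def _shuffle(arr, m, state):
    # Fisher-Yates on arr[:m]
    for i in range(m - 1, 0, -1):
        j = _rand_below(state, i + 1)
        tmp = arr[i]
        arr[i] = arr[j]
        arr[j] = tmp


@njit(cache=True)
def _grow_tree(X, y, n_classes, bag, nb, mtry, min_node_size, state,
               feat_t, thr_t, left_t, right_t, pred_t, gini_acc,
               idx, perm, swaps, sel, vbuf, ibuf, counts, lcounts,
               stack_s, stack_e, stack_n):
    """Grow one tree on the in-bag samples ``bag[:nb]``; returns node count."""
    n_total, p = X.shape
    for i in range(nb):
        idx[i] = bag[i]
    node_count = 1
    sp = 0
    stack_s[0] = 0
    stack_e[0] = nb
    stack_n[0] = 0
    sp = 1
    while sp > 0:
        sp -= 1
        start = stack_s[sp]
        end = stack_e[sp]
        nid = stack_n[sp]
        nsz = end - start
        for c in range(n_classes):
            counts[c] = 0
        for i in range(start, end):
            counts[y[idx[i]]] += 1
        imp = _gini(counts, nsz, n_classes)
        best_c = 0
        for c in range(1, n_classes):
            if counts[c] > counts[best_c]:
                best_c = c
        pred_t[nid] = best_c
        if imp <= 1e-15 or nsz < 2 or nsz < 2 * min_node_size:
            feat_t[nid] = -1
            continue

        # draw mtry distinct features: partial Fisher-Yates with undo
        for j in range(mtry):
            r = j + _rand_below(state, p - j)
            swaps[j] = r
            tmp = perm[j]
            perm[j] = perm[r]
            perm[r] = tmp
            sel[j] = perm[j]
        for j in range(mtry - 1, -1, -1):
            r = swaps[j]
            tmp = perm[j]
            perm[j] = perm[r]
            perm[r] = tmp
        # ascending feature order so the lowest index wins ties
        for a in range(1, mtry):
            v = sel[a]
            b = a - 1
            while b >= 0 and sel[b] > v:
                sel[b + 1] = sel[b]
                b -= 1
            sel[b + 1] = v

        best_dec = 1e-12
        best_f = -1
        best_thr = 0.0
        for j in range(mtry):
            f = sel[j]
            for i in range(nsz):
                s = idx[start + i]
                vbuf[i] = X[s, f]
                ibuf[i] = s
            # insertion sort by value (node sizes are small)
            for a in range(1, nsz):
                v = vbuf[a]
                w = ibuf[a]
                b = a - 1
                while b >= 0 and vbuf[b] > v:
                    vbuf[b + 1] = vbuf[b]
                    ibuf[b + 1] = ibuf[b]
                    b -= 1
                vbuf[b + 1] = v
                ibuf[b + 1] = w
            if vbuf[0] == vbuf[nsz - 1]:
                continue
            for c in range(n_classes):
                lcounts[c] = 0
            ln = 0
            for i in range(nsz - 1):
                lcounts[y[ibuf[i]]] += 1
                ln += 1
                if vbuf[i] < vbuf[i + 1]:
                    rn = nsz - ln
                    gl = 0.0
                    gr = 0.0
                    for c in range(n_classes):
                        fl = lcounts[c] / ln
                        fr = (counts[c] - lcounts[c]) / rn
                        gl += fl * fl
                        gr += fr * fr
                    dec = imp - (ln * (1.0 - gl) + rn * (1.0 - gr)) / nsz
                    if dec > best_dec:
                        best_dec = dec
                        best_f = f
                        best_thr = 0.5 * (vbuf[i] + vbuf[i + 1])
        if best_f < 0:
            feat_t[nid] = -1
            continue

        gini_acc[best_f] += (nsz / nb) * best_dec
        # partition idx[start:end] by X[., best_f] <= best_thr
        lo = start
        hi = end - 1
        while lo <= hi:
            if X[idx[lo], best_f] <= best_thr:
                lo += 1
            else:
                tmp = idx[lo]
                idx[lo] = idx[hi]
                idx[hi] = tmp
                hi -= 1
        lchild = node_count
        rchild = node_count + 1
        node_count += 2
        feat_t[nid] = best_f
        thr_t[nid] = best_thr
        left_t[nid] = lchild
        right_t[nid] = rchild
        stack_s[sp] = start
        stack_e[sp] = lo
        stack_n[sp] = lchild
        sp += 1
        stack_s[sp] = lo
        stack_e[sp] = end
        stack_n[sp] = rchild
        sp += 1
    return node_count


@njit(inline="always")
def _leaf_of(Xq, i, feat_t, thr_t, left_t, right_t):
    nid = 0
    while feat_t[nid] >= 0:
        if Xq[i, feat_t[nid]] <= thr_t[nid]:
            nid = left_t[nid]
        else:
            nid = right_t[nid]
    return nid


@njit(cache=True)
def fit_forest(X, y, n_classes, n_trees, frac, bootstrap, mtry,
               min_node_size, seeds):
    """Fit the ensemble; stratified per-class subsampling (or bootstrap).

    Returns tree arrays, per-tree node counts, in-bag counts, summed Gini
    decreases (divide by n_trees for the importance) and OOB vote counts.
    """
    n, p = X.shape
    max_nodes = 2 * n + 3
    feat = np.full((n_trees, max_nodes), -1, np.int32)
    thr = np.zeros((n_trees, max_nodes), np.float64)
    left = np.full((n_trees, max_nodes), -1, np.int32)
    right = np.full((n_trees, max_nodes), -1, np.int32)
    pred = np.zeros((n_trees, max_nodes), np.int16)
    n_nodes = np.zeros(n_trees, np.int32)
    inbag = np.zeros((n_trees, n), np.int16)
    gini_sum = np.zeros(p, np.float64)
    oob_votes = np.zeros((n, n_classes), np.int32)

    cls_start = np.zeros(n_classes + 1, np.int64)
    for i in range(n):
        cls_start[y[i] + 1] += 1
    for c in range(n_classes):
        cls_start[c + 1] += cls_start[c]
    cls_idx = np.empty(n, np.int64)
    fill = cls_start[:n_classes].copy()
    for i in range(n):
        c = y[i]
        cls_idx[fill[c]] = i
        fill[c] += 1

    bag = np.empty(n, np.int64)
    idx = np.empty(n, np.int64)
    perm = np.arange(p)
    swaps = np.empty(p, np.int64)
    sel = np.empty(p, np.int64)
    vbuf = np.empty(n, np.float64)
    ibuf = np.empty(n, np.int64)
    counts = np.empty(n_classes, np.int64)
    lcounts = np.empty(n_classes, np.int64)
    stack_s = np.empty(max_nodes, np.int64)
    stack_e = np.empty(max_nodes, np.int64)
    stack_n = np.empty(max_nodes, np.int64)
    shuf = np.empty(n, np.int64)
    state = np.empty(1, np.uint64)

    for t in range(n_trees):
        state[0] = seeds[t]
        nb = 0
        for c in range(n_classes):
            c0 = cls_start[c]
            c1 = cls_start[c + 1]
            nc = c1 - c0
            m = np.int64(frac * nc)
            if m < 1:
                m = 1
            if m > nc:
                m = nc
            if bootstrap:
                for _ in range(nc):
                    bag[nb] = cls_idx[c0 + _rand_below(state, nc)]
                    nb += 1
            else:
                for i in range(nc):
                    shuf[i] = cls_idx[c0 + i]
                _shuffle(shuf, nc, state)
                for i in range(m):
                    bag[nb] = shuf[i]
                    nb += 1
        for i in range(nb):
            inbag[t, bag[i]] += 1
        nn = _grow_tree(X, y, n_classes, bag, nb, mtry, min_node_size, state,
                        feat[t], thr[t], left[t], right[t], pred[t], gini_sum,
                        idx, perm, swaps, sel, vbuf, ibuf, counts, lcounts,
                        stack_s, stack_e, stack_n)
        n_nodes[t] = nn
        for i in range(n):
            if inbag[t, i] == 0:
                nid = _leaf_of(X, i, feat[t], thr[t], left[t], right[t])
                oob_votes[i, pred[t, nid]] += 1
    return feat, thr, left, right, pred, n_nodes, inbag, gini_sum, oob_votes


@njit(cache=True)
def predict_votes(Xq, feat, thr, left, right, pred, n_classes):
    n_trees = feat.shape[0]
    nq = Xq.shape[0]
    votes = np.zeros((nq, n_classes), np.int32)
    for t in range(n_trees):
        for i in range(nq):
            nid = _leaf_of(Xq, i, feat[t], thr[t], left[t], right[t])
            votes[i, pred[t, nid]] += 1
    return votes


@njit(cache=True)
def apply_leaves(Xq, feat, thr, left, right):
    n_trees = feat.shape[0]
    nq = Xq.shape[0]
    leaves = np.empty((n_trees, nq), np.int32)
    for t in range(n_trees):
        for i in range(nq):
            leaves[t, i] = _leaf_of(Xq, i, feat[t], thr[t], left[t], right[t])
    return leaves


@njit(cache=True)
def proximity_all(leaves):
    n_trees, n = leaves.shape
    P = np.zeros((n, n), np.float64)
    for t in range(n_trees):
        for i in range(n):
            li = leaves[t, i]
            for j in range(i, n):
                if leaves[t, j] == li:
                    P[i, j] += 1.0
    P /= n_trees
    for i in range(n):
        for j in range(i + 1, n):
            P[j, i] = P[i, j]
        P[i, i] = 1.0
    return P


@njit(cache=True)
def proximity_oob(leaves, inbag):
    """Pair counts restricted to trees where both samples are out-of-bag.

    Entries for pairs never jointly OOB are NaN (flagged missing).
    """
    n_trees, n = leaves.shape
    P = np.zeros((n, n), np.float64)
    denom = np.zeros((n, n), np.float64)
    for t in range(n_trees):
        for i in range(n):
            if inbag[t, i] != 0:
                continue
            li = leaves[t, i]
            for j in range(i, n):
                if inbag[t, j] != 0:
                    continue
                denom[i, j] += 1.0
                if leaves[t, j] == li:
                    P[i, j] += 1.0
    for i in range(n):
        for j in range(i, n):
            if denom[i, j] > 0:
                P[i, j] /= denom[i, j]
            else:
                P[i, j] = np.nan
            P[j, i] = P[i, j]
        P[i, i] = 1.0
    return P


@njit(cache=True)
def mda_importance(X, y, n_classes, feat, thr, left, right, pred, n_nodes,
                   inbag, seeds):
    """Mean decrease in accuracy, global and per class.

    For each tree, OOB accuracy is compared with accuracy after permuting a
    feature's OOB values (seeded per tree+feature). Features a tree never
    splits on contribute exactly zero for that tree.
    """
    n_trees = feat.shape[0]
    n, p = X.shape
    per_class_sum = np.zeros((p, n_classes), np.float64)
    global_sum = np.zeros(p, np.float64)
    class_tree_count = np.zeros(n_classes, np.int64)
    used = np.zeros(p, np.uint8)
    used_list = np.empty(p, np.int64)
    oob = np.empty(n, np.int64)
    base_ok = np.empty(n, np.uint8)
    vperm = np.empty(n, np.float64)
    posbuf = np.empty(n, np.int64)
    state = np.empty(1, np.uint64)
    ctot = np.empty(n_classes, np.int64)
    cbase = np.empty(n_classes, np.int64)
    cperm = np.empty(n_classes, np.int64)

    for t in range(n_trees):
        n_oob = 0
        for i in range(n):
            if inbag[t, i] == 0:
                oob[n_oob] = i
                n_oob += 1
        if n_oob == 0:
            continue
        for c in range(n_classes):
            ctot[c] = 0
            cbase[c] = 0
        for j in range(n_oob):
            i = oob[j]
            ctot[y[i]] += 1
            nid = _leaf_of(X, i, feat[t], thr[t], left[t], right[t])
            ok = 1 if pred[t, nid] == y[i] else 0
            base_ok[j] = ok
            cbase[y[i]] += ok
        for c in range(n_classes):
            if ctot[c] > 0:
                class_tree_count[c] += 1
        nu = 0
        for nd in range(n_nodes[t]):
            f = feat[t, nd]
            if f >= 0 and used[f] == 0:
                used[f] = 1
                used_list[nu] = f
                nu += 1
        tot_base = 0
        for c in range(n_classes):
            tot_base += cbase[c]
        for u in range(nu):
            f = used_list[u]
            state[0] = seeds[t] ^ (U64(0x5851F42D4C957F2D) * U64(f + 1))
            for j in range(n_oob):
                posbuf[j] = j
            _shuffle(posbuf, n_oob, state)
            for j in range(n_oob):
                vperm[j] = X[oob[posbuf[j]], f]
            for c in range(n_classes):
                cperm[c] = 0
            for j in range(n_oob):
                i = oob[j]
                nid = 0
                while feat[t, nid] >= 0:
                    ff = feat[t, nid]
                    xv = vperm[j] if ff == f else X[i, ff]
                    if xv <= thr[t, nid]:
                        nid = left[t, nid]
                    else:
                        nid = right[t, nid]
                if pred[t, nid] == y[i]:
                    cperm[y[i]] += 1
            tot_perm = 0
            for c in range(n_classes):
                tot_perm += cperm[c]
                if ctot[c] > 0:
                    per_class_sum[f, c] += (cbase[c] - cperm[c]) / ctot[c]
            global_sum[f] += (tot_base - tot_perm) / n_oob
        for u in range(nu):
            used[used_list[u]] = 0
    per_class = np.zeros((p, n_classes), np.float64)
    for c in range(n_classes):
        if class_tree_count[c] > 0:
            for f in range(p):
                per_class[f, c] = per_class_sum[f, c] / class_tree_count[c]
    return global_sum / n_trees, per_class, class_tree_count
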