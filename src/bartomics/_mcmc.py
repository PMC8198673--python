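"""Numba kernels for the sum-of-trees probit sampler.

Trees live in flat per-tree slot arrays (capacity ``_CAP`` nodes): an internal
node stores a split feature index and threshold ("go left if value <=
threshold"), a leaf stores its probit-scale contribution.  The backfitting
sweep updates one tree at a time against the partial residuals of the latent
probit variables, using grow / prune / change Metropolis-Hastings proposals
under the depth-penalised structure prior

    P(node at depth d splits) = alpha * (1 + d) ** (-beta)

with split rules drawn uniformly over the features that still vary inside the
node and uniformly over the observed unique values of the chosen feature
(excluding the maximum, so both children are non-empty).  Leaf values are
conjugate-normal draws with prior N(0, sigma_mu^2); the residual variance is
fixed at 1 under the probit convention.

All randomness goes through numba's internal Mersenne-Twister state, seeded
once per chain, so runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LEAF = -1
UNUSED = -2
_CAP = 1024  # per-tree node-slot capacity; grow proposals beyond it are rejected


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def _log_node_marginal(n, S, sm2):
    """Node-dependent part of the log marginal likelihood (sigma = 1).

    Constant terms that are shared between a node and any re-partition of the
    same samples cancel in every MH ratio, so only these two terms are kept.
    """
    t = 1.0 + n * sm2
    return -0.5 * np.log(t) + 0.5 * sm2 * S * S / t


@njit(cache=True)
def _rtnorm_pos(mu):
    """Draw from N(mu, 1) truncated to (0, inf).

    Plain rejection when the untruncated mass above 0 is at least ~1/3;
    Robert's translated-exponential rejection in the tail.  Avoids inverse-CDF
    evaluation entirely, so no precision cliff for extreme mu.
    """
    a = -mu  # lower bound on the standardised scale
    if a <= 0.45:
        while True:
            t = np.random.normal()
            if t > a:
                return mu + t
    else:
        lam = 0.5 * (a + np.sqrt(a * a + 4.0))
        while True:
            t = a + np.random.exponential() / lam
            d = t - lam
            if np.log(np.random.random()) <= -0.5 * d * d:
                return mu + t


@njit(cache=True)
def _grow_logratio(nleaves, w2star, d, nP, SP, nL, SL, nR, SR,
                   alpha, beta, sm2, p_grow, p_prune, lik_on):
    """Log MH ratio of a grow move (rule prior cancels the rule proposal)."""
    ad = alpha * (1.0 + d) ** (-beta)
    ad1 = alpha * (2.0 + d) ** (-beta)
    lp = np.log(ad) + 2.0 * np.log(1.0 - ad1) - np.log(1.0 - ad)
    lt = np.log(p_prune) - np.log(p_grow) + np.log(nleaves) - np.log(w2star)
    ll = 0.0
    if lik_on:
        ll = (_log_node_marginal(nL, SL, sm2)
              + _log_node_marginal(nR, SR, sm2)
              - _log_node_marginal(nP, SP, sm2))
    return lp + lt + ll


# ---------------------------------------------------------------------------
# tree bookkeeping
# ---------------------------------------------------------------------------

@njit(cache=True)
def _alloc(meta, freelist):
    # meta: [0]=high-water slot count, [1]=free-stack top, [2]=n_active
    if meta[1] > 0:
        meta[1] -= 1
        return freelist[meta[1]]
    s = meta[0]
    meta[0] += 1
    return s


@njit(cache=True)
def _count_leaves(feat, nslots):
    k = 0
    for s in range(nslots):
        if feat[s] == LEAF:
            k += 1
    return k


@njit(cache=True)
def _count_singly(feat, left, right, nslots):
    """Internal nodes whose two children are both leaves."""
    k = 0
    for s in range(nslots):
        if feat[s] >= 0 and feat[left[s]] == LEAF and feat[right[s]] == LEAF:
            k += 1
    return k


@njit(cache=True)
def _kth_leaf(feat, nslots, k):
    c = 0
    for s in range(nslots):
        if feat[s] == LEAF:
            if c == k:
                return s
            c += 1
    return -1


@njit(cache=True)
def _kth_singly(feat, left, right, nslots, k):
    c = 0
    for s in range(nslots):
        if feat[s] >= 0 and feat[left[s]] == LEAF and feat[right[s]] == LEAF:
            if c == k:
                return s
            c += 1
    return -1


@njit(cache=True)
def _gather_pair(leaf_of, a, b, n, sidx):
    ns = 0
    for i in range(n):
        l = leaf_of[i]
        if l == a or l == b:
            sidx[ns] = i
            ns += 1
    return ns


@njit(cache=True)
def _feature_varies(X, sidx, ns, j):
    v0 = X[sidx[0], j]
    for q in range(1, ns):
        if X[sidx[q], j] != v0:
            return True
    return False


@njit(cache=True)
def _count_valid_features(X, sidx, ns):
    p = X.shape[1]
    padj = 0
    for j in range(p):
        if _feature_varies(X, sidx, ns, j):
            padj += 1
    return padj


@njit(cache=True)
def _kth_valid_feature(X, sidx, ns, k):
    p = X.shape[1]
    c = 0
    for j in range(p):
        if _feature_varies(X, sidx, ns, j):
            if c == k:
                return j
            c += 1
    return -1


@njit(cache=True)
def _unique_cut(X, sidx, ns, j, pick):
    """Number of candidate cutpoints for feature j inside the node, and the
    value of the ``pick``-th one (unique sorted values, maximum excluded)."""
    vals = np.empty(ns, np.float64)
    for q in range(ns):
        vals[q] = X[sidx[q], j]
    vals.sort()
    nun = 1
    for q in range(1, ns):
        if vals[q] != vals[q - 1]:
            nun += 1
    ncut = nun - 1
    if ncut == 0:
        return 0, 0.0
    if pick < 0:
        return ncut, 0.0
    c = 0
    cval = vals[0]
    if pick > 0:
        for q in range(1, ns):
            if vals[q] != vals[q - 1]:
                c += 1
                if c == pick:
                    cval = vals[q]
                    break
    return ncut, cval


# ---------------------------------------------------------------------------
# one Metropolis-Hastings tree move
# ---------------------------------------------------------------------------

@njit(cache=True)
def _tree_move(feat, thresh, val, left, right, parent, dep, meta, freelist,
               leaf_of, X, r, alpha, beta, sm2, p_grow, p_prune, min_node,
               lik_on):
    """Propose and (maybe) apply one grow/prune/change move.

    Returns (accepted, log_ratio, move_type) with move_type 0=grow, 1=prune,
    2=change.  Degenerate proposals are rejected with log_ratio = -inf.
    """
    n = X.shape[0]
    u = np.random.random()
    if u < p_grow:
        mtype = 0
    elif u < p_grow + p_prune:
        mtype = 1
    else:
        mtype = 2

    if mtype == 0:
        # ------------------------------------------------------------- GROW
        nleaves = _count_leaves(feat, meta[0])
        L = _kth_leaf(feat, meta[0], np.random.randint(0, nleaves))
        sidx = np.empty(n, np.int64)
        ns = _gather_pair(leaf_of, L, -99, n, sidx)
        if ns < 2 * min_node:
            return 0, -np.inf, 0
        padj = _count_valid_features(X, sidx, ns)
        if padj == 0:
            return 0, -np.inf, 0
        j = _kth_valid_feature(X, sidx, ns, np.random.randint(0, padj))
        ncut, _ = _unique_cut(X, sidx, ns, j, -1)
        _, cval = _unique_cut(X, sidx, ns, j, np.random.randint(0, ncut))
        nL = 0
        SL = 0.0
        SP = 0.0
        for q in range(ns):
            i = sidx[q]
            SP += r[i]
            if X[i, j] <= cval:
                nL += 1
                SL += r[i]
        nR = ns - nL
        if nL < min_node or nR < min_node:
            return 0, -np.inf, 0
        if meta[1] + (_CAP - meta[0]) < 2:
            return 0, -np.inf, 0
        d = dep[L]
        w2 = _count_singly(feat, left, right, meta[0])
        par = parent[L]
        if par >= 0:
            sib = right[par] if left[par] == L else left[par]
            w2star = w2 + 1 - (1 if feat[sib] == LEAF else 0)
        else:
            w2star = w2 + 1
        logr = _grow_logratio(nleaves, w2star, d, ns, SP, nL, SL, nR, SP - SL,
                              alpha, beta, sm2, p_grow, p_prune, lik_on)
        if np.log(np.random.random()) < logr:
            cl = _alloc(meta, freelist)
            cr = _alloc(meta, freelist)
            feat[L] = j
            thresh[L] = cval
            left[L] = cl
            right[L] = cr
            for ch in (cl, cr):
                feat[ch] = LEAF
                val[ch] = 0.0
                left[ch] = -1
                right[ch] = -1
                parent[ch] = L
                dep[ch] = d + 1
            for q in range(ns):
                i = sidx[q]
                leaf_of[i] = cl if X[i, j] <= cval else cr
            meta[2] += 2
            return 1, logr, 0
        return 0, logr, 0

    if mtype == 1:
        # ------------------------------------------------------------ PRUNE
        w2 = _count_singly(feat, left, right, meta[0])
        if w2 == 0:
            return 0, -np.inf, 1
        P = _kth_singly(feat, left, right, meta[0], np.random.randint(0, w2))
        cl = left[P]
        cr = right[P]
        ns = 0
        nL = 0
        SP = 0.0
        SL = 0.0
        for i in range(n):
            l = leaf_of[i]
            if l == cl:
                ns += 1
                nL += 1
                SP += r[i]
                SL += r[i]
            elif l == cr:
                ns += 1
                SP += r[i]
        nleaves = _count_leaves(feat, meta[0])
        d = dep[P]
        logr = -_grow_logratio(nleaves - 1, w2, d, ns, SP, nL, SL,
                               ns - nL, SP - SL, alpha, beta, sm2,
                               p_grow, p_prune, lik_on)
        if np.log(np.random.random()) < logr:
            feat[P] = LEAF
            val[P] = 0.0
            left[P] = -1
            right[P] = -1
            for ch in (cl, cr):
                feat[ch] = UNUSED
                freelist[meta[1]] = ch
                meta[1] += 1
            for i in range(n):
                l = leaf_of[i]
                if l == cl or l == cr:
                    leaf_of[i] = P
            meta[2] -= 2
            return 1, logr, 1
        return 0, logr, 1

    # ---------------------------------------------------------------- CHANGE
    w2 = _count_singly(feat, left, right, meta[0])
    if w2 == 0:
        return 0, -np.inf, 2
    P = _kth_singly(feat, left, right, meta[0], np.random.randint(0, w2))
    cl = left[P]
    cr = right[P]
    sidx = np.empty(n, np.int64)
    ns = _gather_pair(leaf_of, cl, cr, n, sidx)
    padj = _count_valid_features(X, sidx, ns)
    if padj == 0:
        return 0, -np.inf, 2
    j = _kth_valid_feature(X, sidx, ns, np.random.randint(0, padj))
    ncut, _ = _unique_cut(X, sidx, ns, j, -1)
    _, cval = _unique_cut(X, sidx, ns, j, np.random.randint(0, ncut))
    nLn = 0
    SLn = 0.0
    nLo = 0
    SLo = 0.0
    S = 0.0
    for q in range(ns):
        i = sidx[q]
        ri = r[i]
        S += ri
        if X[i, j] <= cval:
            nLn += 1
            SLn += ri
        if leaf_of[i] == cl:
            nLo += 1
            SLo += ri
    if nLn < min_node or ns - nLn < min_node:
        return 0, -np.inf, 2
    logr = 0.0
    if lik_on:
        logr = (_log_node_marginal(nLn, SLn, sm2)
                + _log_node_marginal(ns - nLn, S - SLn, sm2)
                - _log_node_marginal(nLo, SLo, sm2)
                - _log_node_marginal(ns - nLo, S - SLo, sm2))
    if np.log(np.random.random()) < logr:
        feat[P] = j
        thresh[P] = cval
        for q in range(ns):
            i = sidx[q]
            leaf_of[i] = cl if X[i, j] <= cval else cr
        return 1, logr, 2
    return 0, logr, 2


@njit(cache=True)
def _draw_leaf_values(feat, val, nslots, leaf_of, r, n, sm2, prior_only):
    """Conjugate Gibbs draw of every leaf value (prior draw in prior mode)."""
    if prior_only:
        sd = np.sqrt(sm2)
        for s in range(nslots):
            if feat[s] == LEAF:
                val[s] = np.random.normal() * sd
        return
    cnt = np.zeros(nslots, np.float64)
    S = np.zeros(nslots, np.float64)
    for i in range(n):
        l = leaf_of[i]
        cnt[l] += 1.0
        S[l] += r[i]
    inv_sm2 = 1.0 / sm2
    for s in range(nslots):
        if feat[s] == LEAF:
            prec = cnt[s] + inv_sm2
            val[s] = S[s] / prec + np.random.normal() / np.sqrt(prec)


# ---------------------------------------------------------------------------
# the full backfitting chain
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_chain(X, y, m, n_burn, n_post, alpha, beta, sm2, p_grow, p_prune,
               min_node, offset, seed, prior_only, keep_draws):
    """Run the probit backfitting sampler; return serialized post-burn draws.

    Returns (node_feature, node_threshold, node_value, node_left, node_right,
    tree_offsets, split_counts, total_internal).  Node indices in the
    serialized arrays are local to each tree block (root at local index 0);
    tree_offsets has length n_post * m + 1.
    """
    np.random.seed(seed)
    n, p = X.shape

    feat = np.full((m, _CAP), UNUSED, np.int32)
    thresh = np.zeros((m, _CAP), np.float64)
    val = np.zeros((m, _CAP), np.float64)
    left = np.full((m, _CAP), -1, np.int32)
    right = np.full((m, _CAP), -1, np.int32)
    parent = np.full((m, _CAP), -1, np.int32)
    dep = np.zeros((m, _CAP), np.int32)
    meta = np.zeros((m, 3), np.int64)
    freelist = np.zeros((m, _CAP), np.int32)
    leaf_of = np.zeros((m, n), np.int32)
    for t in range(m):
        feat[t, 0] = LEAF
        meta[t, 0] = 1  # high-water
        meta[t, 2] = 1  # active nodes

    tfit = np.zeros((m, n), np.float64)
    f = np.zeros(n, np.float64)
    zc = np.zeros(n, np.float64)
    r = np.zeros(n, np.float64)

    split_counts = np.zeros(p, np.int64)
    total_internal = 0

    offsets = np.zeros(n_post * m + 1, np.int64)
    cap = 4096
    out_feat = np.empty(cap, np.int32)
    out_thresh = np.empty(cap, np.float64)
    out_val = np.empty(cap, np.float64)
    out_left = np.empty(cap, np.int32)
    out_right = np.empty(cap, np.int32)
    pos = 0
    locmap = np.full(_CAP, -1, np.int32)
    stack = np.empty(_CAP, np.int32)

    total_iters = n_burn + n_post
    for it in range(total_iters):
        if not prior_only:
            for i in range(n):
                mu = f[i] + offset
                if y[i] == 1:
                    z = _rtnorm_pos(mu)
                else:
                    z = -_rtnorm_pos(-mu)
                zc[i] = z - offset
        for t in range(m):
            if not prior_only:
                for i in range(n):
                    r[i] = zc[i] - f[i] + tfit[t, i]
            _tree_move(feat[t], thresh[t], val[t], left[t], right[t],
                       parent[t], dep[t], meta[t], freelist[t], leaf_of[t],
                       X, r, alpha, beta, sm2, p_grow, p_prune, min_node,
                       not prior_only)
            _draw_leaf_values(feat[t], val[t], meta[t, 0], leaf_of[t], r, n,
                              sm2, prior_only)
            if not prior_only:
                for i in range(n):
                    nv = val[t, leaf_of[t, i]]
                    f[i] += nv - tfit[t, i]
                    tfit[t, i] = nv

        if it >= n_burn:
            dnum = it - n_burn
            for t in range(m):
                nslots = meta[t, 0]
                for s in range(nslots):
                    if feat[t, s] >= 0:
                        split_counts[feat[t, s]] += 1
                        total_internal += 1
                if keep_draws:
                    need = meta[t, 2]
                    if pos + need > cap:
                        newcap = cap * 2
                        while newcap < pos + need:
                            newcap *= 2
                        nf2 = np.empty(newcap, np.int32)
                        nf2[:pos] = out_feat[:pos]
                        out_feat = nf2
                        nt2 = np.empty(newcap, np.float64)
                        nt2[:pos] = out_thresh[:pos]
                        out_thresh = nt2
                        nv2 = np.empty(newcap, np.float64)
                        nv2[:pos] = out_val[:pos]
                        out_val = nv2
                        nl2 = np.empty(newcap, np.int32)
                        nl2[:pos] = out_left[:pos]
                        out_left = nl2
                        nr2 = np.empty(newcap, np.int32)
                        nr2[:pos] = out_right[:pos]
                        out_right = nr2
                        cap = newcap
                    # preorder traversal: assign local ids, then write
                    top = 0
                    stack[top] = 0
                    top += 1
                    nloc = 0
                    while top > 0:
                        top -= 1
                        s = stack[top]
                        locmap[s] = nloc
                        nloc += 1
                        if feat[t, s] >= 0:
                            stack[top] = right[t, s]
                            top += 1
                            stack[top] = left[t, s]
                            top += 1
                    # second pass in the same preorder
                    top = 0
                    stack[top] = 0
                    top += 1
                    while top > 0:
                        top -= 1
                        s = stack[top]
                        w = pos + locmap[s]
                        out_feat[w] = feat[t, s]
                        out_thresh[w] = thresh[t, s]
                        out_val[w] = val[t, s]
                        if feat[t, s] >= 0:
                            out_left[w] = locmap[left[t, s]]
                            out_right[w] = locmap[right[t, s]]
                            stack[top] = right[t, s]
                            top += 1
                            stack[top] = left[t, s]
                            top += 1
                        else:
                            out_left[w] = -1
                            out_right[w] = -1
                    pos += need
                offsets[dnum * m + t + 1] = pos

    return (out_feat[:pos], out_thresh[:pos], out_val[:pos],
            out_left[:pos], out_right[:pos], offsets, split_counts,
            total_internal)


# ---------------------------------------------------------------------------
# evaluation kernels over serialized posteriors
# ---------------------------------------------------------------------------

@njit(cache=True)
def _predict_forest(nf, nth, nv, nl, nr, offsets, n_draws, m, X, offset):
    nX = X.shape[0]
    out = np.empty((n_draws, nX), np.float64)
    for d in range(n_draws):
        for i in range(nX):
            s = offset
            for t in range(m):
                base = offsets[d * m + t]
                node = 0
                while nf[base + node] >= 0:
                    j = nf[base + node]
                    if X[i, j] <= nth[base + node]:
                        node = nl[base + node]
                    else:
                        node = nr[base + node]
                s += nv[base + node]
            out[d, i] = s
    return out


@njit(cache=True)
def _pd_average(nf, nth, nv, nl, nr, offsets, n_draws, m, X, f0, f1, fvals,
                offset):
    """Partial-dependence kernel: for each evaluation point, clamp feature f0
    (and f1 if >= 0) to the point's values in every training row, then average
    the probit prediction over rows within each posterior draw."""
    nX = X.shape[0]
    n_pts = fvals.shape[0]
    out = np.empty((n_pts, n_draws), np.float64)
    for pt in range(n_pts):
        v0 = fvals[pt, 0]
        v1 = fvals[pt, 1] if f1 >= 0 else 0.0
        for d in range(n_draws):
            acc = 0.0
            for i in range(nX):
                s = 0.0
                for t in range(m):
                    base = offsets[d * m + t]
                    node = 0
                    while nf[base + node] >= 0:
                        j = nf[base + node]
                        if j == f0:
                            xv = v0
                        elif j == f1:
                            xv = v1
                        else:
                            xv = X[i, j]
                        if xv <= nth[base + node]:
                            node = nl[base + node]
                        else:
                            node = nr[base + node]
                    s += nv[base + node]
                acc += s
            out[pt, d] = acc / nX + offset
    return out


@njit(cache=True)
def _depth_split_stats(nf, nl, nr, offsets, n_trees, max_d):
    """Per-depth (number of internal nodes, number of nodes) over all trees."""
    splits = np.zeros(max_d + 1, np.int64)
    nodes = np.zeros(max_d + 1, np.int64)
    snode = np.empty(4096, np.int64)
    sdep = np.empty(4096, np.int64)
    for k in range(n_trees):
        base = offsets[k]
        top = 0
        snode[top] = 0
        sdep[top] = 0
        top += 1
        while top > 0:
            top -= 1
            node = snode[top]
            dpt = sdep[top]
            if dpt <= max_d:
                nodes[dpt] += 1
            if nf[base + node] >= 0:
                if dpt <= max_d:
                    splits[dpt] += 1
                snode[top] = nl[base + node]
                sdep[top] = dpt + 1
                top += 1
                snode[top] = nr[base + node]
                sdep[top] = dpt + 1
                top += 1
    return splits, nodes


# ---------------------------------------------------------------------------
# single-move entry points (used by the Python-level move API and tests)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _single_move(feat, thresh, val, left, right, parent, dep, meta, freelist,
                 leaf_of, X, r, alpha, beta, sm2, p_grow, p_prune, min_node,
                 lik_on, seed):
    np.random.seed(seed)
    return _tree_move(feat, thresh, val, left, right, parent, dep, meta,
                      freelist, leaf_of, X, r, alpha, beta, sm2, p_grow,
                      p_prune, min_node, lik_on)


@njit(cache=True)
def _gibbs_leaves(feat, val, nslots, leaf_of, r, n, sm2, n_draws, seed):
    """Repeated conjugate leaf draws on a frozen tree; returns draws for every
    active leaf slot (columns ordered by slot index among leaves)."""
    np.random.seed(seed)
    nleaf = 0
    for s in range(nslots):
        if feat[s] == LEAF:
            nleaf += 1
    out = np.empty((n_draws, nleaf), np.float64)
    for d in range(n_draws):
        _draw_leaf_values(feat, val, nslots, leaf_of, r, n, sm2, False)
        c = 0
        for s in range(nslots):
            if feat[s] == LEAF:
                out[d, c] = val[s]
                c += 1
    return out
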