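"""Numba kernel for the BART backfitting sampler.

Trees live in flat heap arrays: slot 0 is the root, slot ``i`` has children
``2i+1``/``2i+2``; ``var[i] == -1`` marks a terminal node, ``-2`` an unused
slot, and ``var[i] >= 0`` the splitting covariate of an internal node.  One
Metropolis-Hastings move (grow / prune / change / swap) is attempted per tree
per sweep, with the terminal-node values integrated out of the acceptance
ratio; leaf values are then redrawn from their conjugate normal posteriors.

Everything here operates on primitive arrays so the whole sweep loop compiles
to machine code; the user-facing wrappers are in :mod:`ebcobart.sampler`.
"""

import numpy as np
from numba import njit

TERMINAL = np.int32(-1)
UNUSED = np.int32(-2)

GROW, PRUNE, CHANGE, SWAP = 0, 1, 2, 3


@njit(cache=True)
def depth_of(idx):
    d = 0
    n = idx + 1
    while n > 1:
        n >>= 1
        d += 1
    return d


@njit(cache=True)
def _route(var_t, split_t, X, i):
    node = 0
    while var_t[node] >= 0:
        if X[i, var_t[node]] <= split_t[node]:
            node = 2 * node + 1
        else:
            node = 2 * node + 2
    return node


@njit(cache=True)
def _route_from(var_t, split_t, X, i, start):
    node = start
    while var_t[node] >= 0:
        if X[i, var_t[node]] <= split_t[node]:
            node = 2 * node + 1
        else:
            node = 2 * node + 2
    return node


@njit(cache=True)
def _collect(var_t, internals, leaves, prunable, stack):
    """DFS over occupied heap slots; fills node lists, returns their counts."""
    ni = 0
    nl = 0
    npr = 0
    sp = 0
    stack[sp] = 0
    sp += 1
    while sp > 0:
        sp -= 1
        node = stack[sp]
        v = var_t[node]
        if v == TERMINAL:
            leaves[nl] = node
            nl += 1
        else:
            internals[ni] = node
            ni += 1
            l = 2 * node + 1
            r = 2 * node + 2
            if var_t[l] == TERMINAL and var_t[r] == TERMINAL:
                prunable[npr] = node
                npr += 1
            stack[sp] = r
            sp += 1
            stack[sp] = l
            sp += 1
    return ni, nl, npr


@njit(cache=True)
def _collect_sub(var_t, start, leaves, stack):
    """Leaves of the subtree rooted at ``start``."""
    nl = 0
    sp = 0
    stack[sp] = start
    sp += 1
    while sp > 0:
        sp -= 1
        node = stack[sp]
        if var_t[node] == TERMINAL:
            leaves[nl] = node
            nl += 1
        else:
            stack[sp] = 2 * node + 2
            sp += 1
            stack[sp] = 2 * node + 1
            sp += 1
    return nl


@njit(cache=True)
def _is_descendant(node, anc):
    """True if heap slot ``node`` lies in the subtree rooted at ``anc``."""
    n = node + 1
    a = anc + 1
    while n > a:
        n >>= 1
    return n == a


@njit(cache=True)
def leaf_term(n, s, sigma2, sig2mu):
    """Structure-dependent part of the integrated leaf log likelihood.

    The full marginal is  -(n/2)log(2*pi*sigma2) + 0.5*log(sigma2/(sigma2+n*sig2mu))
    - sum r^2/(2 sigma2) + sig2mu*s^2/(2 sigma2 (sigma2+n*sig2mu)); the first and
    third terms sum to a constant over any leaf partition of the same
    observations, so MH ratios only need the two terms kept here.
    """
    if n == 0:
        return 0.0
    denom = sigma2 + n * sig2mu
    return 0.5 * np.log(sigma2 / denom) + sig2mu * s * s / (2.0 * sigma2 * denom)


@njit(cache=True)
def sample_trunc_normal(mu, positive):
    """Draw from N(mu, 1) truncated to (0, inf) if positive else (-inf, 0]."""
    if positive:
        a = -mu
    else:
        a = mu
    # sample z ~ N(0,1) truncated to [a, inf)
    if a < 0.45:
        while True:
            z = np.random.normal()
            if z >= a:
                break
    else:
        # Robert (1995) exponential rejection for the tail
        alpha = 0.5 * (a + np.sqrt(a * a + 4.0))
        while True:
            z = a - np.log(np.random.random()) / alpha
            d = z - alpha
            if np.random.random() <= np.exp(-0.5 * d * d):
                break
    if positive:
        return mu + z
    return mu - z


@njit(cache=True)
def _draw_categorical(cumS):
    u = np.random.random()
    lo = 0
    hi = cumS.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if cumS[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    if lo >= cumS.shape[0]:
        lo = cumS.shape[0] - 1
    return lo


@njit(cache=True)
def _cuts_between(cuts_flat, s, e, mmin, mmax):
    """Index range [lo, hi) of cuts strictly inside (mmin, mmax).

    Candidate cuts are midpoints of consecutive distinct observed values, so
    a cut never coincides with an observed value and the comparisons below
    are unambiguous.
    """
    lo = s
    hi = e
    while lo < hi:
        mid = (lo + hi) // 2
        if cuts_flat[mid] < mmin:
            lo = mid + 1
        else:
            hi = mid
    lo_idx = lo
    hi = e
    while lo < hi:
        mid = (lo + hi) // 2
        if cuts_flat[mid] < mmax:
            lo = mid + 1
        else:
            hi = mid
    return lo_idx, lo


@njit(cache=True)
def _valid_cut_range(X, j, leaf_assign, slot_a, slot_b, cuts_flat, cuts_off):
    """Cuts of covariate j that split the members of one or two leaves
    non-trivially: those strictly between the members' min and max of x_j.
    Both the splitting-value prior and the proposal are uniform on this set
    (the data-driven cut convention of the standard samplers), so their
    ratio cancels except where the set itself changes."""
    mmin = np.inf
    mmax = -np.inf
    for i in range(X.shape[0]):
        la = leaf_assign[i]
        if la == slot_a or la == slot_b:
            v = X[i, j]
            if v < mmin:
                mmin = v
            if v > mmax:
                mmax = v
    if mmax <= mmin:
        return 0, 0
    return _cuts_between(cuts_flat, cuts_off[j], cuts_off[j + 1], mmin, mmax)


@njit(cache=True)
def _subtree_log_cut_prior(var_t, split_t, top, internals, ni, assign,
                           X, cuts_flat, cuts_off):
    """Sum of log(1/n_valid) over internal nodes of the subtree at ``top``,
    -inf if any rule no longer splits its members non-trivially.  ``assign``
    maps observations to their terminal slots under the tree being scored."""
    total = 0.0
    for k in range(ni):
        nd = internals[k]
        if not _is_descendant(nd, top):
            continue
        j = var_t[nd]
        a = split_t[nd]
        mmin = np.inf
        mmax = -np.inf
        for i in range(X.shape[0]):
            la = assign[i]
            if la >= 0 and _is_descendant(la, nd):
                v = X[i, j]
                if v < mmin:
                    mmin = v
                if v > mmax:
                    mmax = v
        if not (mmin < a < mmax):
            return -np.inf
        lo, hi = _cuts_between(cuts_flat, cuts_off[j], cuts_off[j + 1],
                               mmin, mmax)
        if hi <= lo:
            return -np.inf
        total -= np.log(float(hi - lo))
    return total


@njit(cache=True)
def _log_select_prob(p_move, ni, move_probs):
    """Log probability that the resampling scheme selects a given move type.

    Moves are drawn from the nominal mixture and redrawn (up to 10 times) when
    the type has no legal instance in the current tree: PRUNE/CHANGE need an
    internal node with two terminal children (one exists iff ni >= 1), SWAP a
    parent-child internal pair (iff ni >= 2).  The effective selection
    probability is p_move * (1 - F^10) / (1 - F) with F the illegal mass, and
    it enters the MH asymmetry term so the resampling stays balanced.
    """
    Z = move_probs[GROW]
    if ni >= 1:
        Z += move_probs[PRUNE] + move_probs[CHANGE]
    if ni >= 2:
        Z += move_probs[SWAP]
    F = 1.0 - Z
    trunc = 1.0 - F ** 10 if F > 0.0 else 1.0
    return np.log(p_move) + np.log(trunc) - np.log(Z)


@njit(cache=True)
def _update_tree(var_t, split_t, mu_t, X, pr, leaf_assign,
                 internals, leaves, prunable, stack, cnt, ssum,
                 cnt2, ssum2, subleaves, assign2,
                 cuts_flat, cuts_off, cumS, alpha, beta,
                 sigma2, sig2mu, max_depth, move_probs, min_node):
    """One MH structure move + conjugate leaf redraw for a single tree.

    ``pr`` holds the partial residuals with this tree's fit removed.
    ``leaf_assign`` must hold this tree's current observation->leaf routing
    on entry (it is maintained incrementally across sweeps) and holds the
    updated routing on exit.  Returns 1 if the move was accepted, else 0.
    """
    N = X.shape[0]
    ni, nl, npr = _collect(var_t, internals, leaves, prunable, stack)
    for k in range(nl):
        cnt[leaves[k]] = 0
        ssum[leaves[k]] = 0.0
    for i in range(N):
        l = leaf_assign[i]
        cnt[l] += 1
        ssum[l] += pr[i]

    # pick a legal move type, resampling up to 10 times
    move = -1
    for _attempt in range(10):
        u = np.random.random()
        m = 0
        acc = move_probs[0]
        while u > acc and m < 3:
            m += 1
            acc += move_probs[m]
        if m == GROW:
            move = m
            break
        if (m == PRUNE or m == CHANGE) and npr > 0:
            move = m
            break
        # every non-root internal node pairs with its (internal) parent
        if m == SWAP and ni >= 2:
            move = m
            break
    accepted = 0
    if move == GROW:
        li = leaves[np.random.randint(nl)]
        d = depth_of(li)
        if d < max_depth:
            j = _draw_categorical(cumS)
            clo, chi = _valid_cut_range(X, j, leaf_assign, li, -1,
                                        cuts_flat, cuts_off)
            ncuts = chi - clo
            if ncuts > 0:
                a = cuts_flat[clo + np.random.randint(ncuts)]
                nT = cnt[li]
                sT = ssum[li]
                nL = 0
                sL = 0.0
                for i in range(N):
                    if leaf_assign[i] == li and X[i, j] <= a:
                        nL += 1
                        sL += pr[i]
                nR = nT - nL
                sR = sT - sL
                if nL >= min_node and nR >= min_node:
                    pa = alpha * (1.0 + d) ** (-beta)
                    pc = alpha * (2.0 + d) ** (-beta)
                    logprior = np.log(pa) + 2.0 * np.log1p(-pc) - np.log1p(-pa)
                    npr_new = npr + 1
                    if li > 0:
                        sib = li - 1 if li % 2 == 0 else li + 1
                        if var_t[sib] == TERMINAL:
                            npr_new -= 1
                    logprop = (_log_select_prob(move_probs[PRUNE], ni + 1, move_probs)
                               - _log_select_prob(move_probs[GROW], ni, move_probs)
                               + np.log(float(nl)) - np.log(float(npr_new)))
                    dll = (leaf_term(nL, sL, sigma2, sig2mu)
                           + leaf_term(nR, sR, sigma2, sig2mu)
                           - leaf_term(nT, sT, sigma2, sig2mu))
                    if np.log(np.random.random()) < dll + logprior + logprop:
                        var_t[li] = j
                        split_t[li] = a
                        var_t[2 * li + 1] = TERMINAL
                        var_t[2 * li + 2] = TERMINAL
                        mu_t[2 * li + 1] = 0.0
                        mu_t[2 * li + 2] = 0.0
                        for i in range(N):
                            if leaf_assign[i] == li:
                                if X[i, j] <= a:
                                    leaf_assign[i] = 2 * li + 1
                                else:
                                    leaf_assign[i] = 2 * li + 2
                        accepted = 1
    elif move == PRUNE:
        g = prunable[np.random.randint(npr)]
        l = 2 * g + 1
        r = 2 * g + 2
        nT = cnt[l] + cnt[r]
        sT = ssum[l] + ssum[r]
        d = depth_of(g)
        pa = alpha * (1.0 + d) ** (-beta)
        pc = alpha * (2.0 + d) ** (-beta)
        logprior = -(np.log(pa) + 2.0 * np.log1p(-pc) - np.log1p(-pa))
        logprop = (_log_select_prob(move_probs[GROW], ni - 1, move_probs)
                   - _log_select_prob(move_probs[PRUNE], ni, move_probs)
                   + np.log(float(npr)) - np.log(float(nl - 1)))
        dll = (leaf_term(nT, sT, sigma2, sig2mu)
               - leaf_term(cnt[l], ssum[l], sigma2, sig2mu)
               - leaf_term(cnt[r], ssum[r], sigma2, sig2mu))
        if np.log(np.random.random()) < dll + logprior + logprop:
            var_t[g] = TERMINAL
            var_t[l] = UNUSED
            var_t[r] = UNUSED
            for i in range(N):
                la = leaf_assign[i]
                if la == l or la == r:
                    leaf_assign[i] = g
            accepted = 1
    elif move == CHANGE:
        # redraw the rule of a uniformly chosen internal node, keeping the
        # subtree below it; members are rerouted and the move is vetoed if a
        # leaf empties or a descendant rule loses its valid-cut support
        g = internals[np.random.randint(ni)]
        j_old = var_t[g]
        a_old = split_t[g]
        # valid cuts at g are computed from the members of g's subtree
        mmin = np.inf
        mmax = -np.inf
        j = _draw_categorical(cumS)
        for i in range(N):
            if _is_descendant(leaf_assign[i], g):
                v = X[i, j]
                if v < mmin:
                    mmin = v
                if v > mmax:
                    mmax = v
        if mmax > mmin:
            clo, chi = _cuts_between(cuts_flat, cuts_off[j], cuts_off[j + 1],
                                     mmin, mmax)
            ncuts = chi - clo
        else:
            ncuts = 0
        if ncuts > 0:
            a = cuts_flat[clo + np.random.randint(ncuts)]
            lp_old = _subtree_log_cut_prior(var_t, split_t, g, internals, ni,
                                            leaf_assign, X,
                                            cuts_flat, cuts_off)
            # reverse-proposal cut count for the old rule at g
            mmin2 = np.inf
            mmax2 = -np.inf
            for i in range(N):
                if _is_descendant(leaf_assign[i], g):
                    v = X[i, j_old]
                    if v < mmin2:
                        mmin2 = v
                    if v > mmax2:
                        mmax2 = v
            rlo, rhi = _cuts_between(cuts_flat, cuts_off[j_old],
                                     cuts_off[j_old + 1], mmin2, mmax2)
            var_t[g] = j
            split_t[g] = a
            nsub = _collect_sub(var_t, g, subleaves, stack)
            for k in range(nsub):
                cnt2[subleaves[k]] = 0
                ssum2[subleaves[k]] = 0.0
            for i in range(N):
                if _is_descendant(leaf_assign[i], g):
                    nleaf = _route_from(var_t, split_t, X, i, g)
                    cnt2[nleaf] += 1
                    ssum2[nleaf] += pr[i]
                    assign2[i] = nleaf
                else:
                    assign2[i] = -1
            ok = True
            for k in range(nsub):
                if cnt2[subleaves[k]] < min_node:
                    ok = False
                    break
            dll = -np.inf
            if ok:
                lp_new = _subtree_log_cut_prior(var_t, split_t, g, internals,
                                                ni, assign2, X,
                                                cuts_flat, cuts_off)
                ok = np.isfinite(lp_new)
                if ok:
                    # the proposal's 1/n_valid cut factors at g cancel the
                    # corresponding prior factors inside lp_new/lp_old
                    dll = (lp_new - lp_old
                           + np.log(float(ncuts)) - np.log(float(rhi - rlo)))
                    for k in range(nsub):
                        sl = subleaves[k]
                        dll += (leaf_term(cnt2[sl], ssum2[sl], sigma2, sig2mu)
                                - leaf_term(cnt[sl], ssum[sl], sigma2,
                                            sig2mu))
            if ok and np.log(np.random.random()) < dll:
                for i in range(N):
                    if assign2[i] >= 0:
                        leaf_assign[i] = assign2[i]
                accepted = 1
            else:
                var_t[g] = j_old
                split_t[g] = a_old
    elif move == SWAP:
        # pairs are (parent, child) with the child any non-root internal node
        pick = np.random.randint(ni - 1)
        child = -1
        for k in range(ni):
            nd = internals[k]
            if nd > 0:
                if pick == 0:
                    child = nd
                    break
                pick -= 1
        parent = (child - 1) // 2
        # swap the rules; topology (hence the leaf slot set) is unchanged.
        # The uniform-cut prior factors over the subtree do not cancel here
        # (the valid-cut sets shift with the members), so they enter the
        # ratio, and a rule losing its valid-cut support vetoes the move.
        lp_old = _subtree_log_cut_prior(var_t, split_t, parent, internals, ni,
                                        leaf_assign, X, cuts_flat, cuts_off)
        jv = var_t[parent]
        sv = split_t[parent]
        var_t[parent] = var_t[child]
        split_t[parent] = split_t[child]
        var_t[child] = jv
        split_t[child] = sv
        nsub = _collect_sub(var_t, parent, subleaves, stack)
        for k in range(nsub):
            cnt2[subleaves[k]] = 0
            ssum2[subleaves[k]] = 0.0
        for i in range(N):
            if _is_descendant(leaf_assign[i], parent):
                nleaf = _route_from(var_t, split_t, X, i, parent)
                cnt2[nleaf] += 1
                ssum2[nleaf] += pr[i]
                assign2[i] = nleaf
            else:
                assign2[i] = -1
        ok = True
        for k in range(nsub):
            if cnt2[subleaves[k]] < min_node:
                ok = False
                break
        lp_new = -np.inf
        if ok:
            lp_new = _subtree_log_cut_prior(var_t, split_t, parent, internals,
                                            ni, assign2, X,
                                            cuts_flat, cuts_off)
            ok = np.isfinite(lp_new)
        dll = 0.0
        if ok:
            dll = lp_new - lp_old
            for k in range(nsub):
                sl = subleaves[k]
                dll += (leaf_term(cnt2[sl], ssum2[sl], sigma2, sig2mu)
                        - leaf_term(cnt[sl], ssum[sl], sigma2, sig2mu))
        if ok and np.log(np.random.random()) < dll:
            for i in range(N):
                if assign2[i] >= 0:
                    leaf_assign[i] = assign2[i]
            accepted = 1
        else:
            # undo the swap
            jv = var_t[parent]
            sv = split_t[parent]
            var_t[parent] = var_t[child]
            split_t[parent] = split_t[child]
            var_t[child] = jv
            split_t[child] = sv

    # an accepted move changed the leaf set: refresh node lists and stats
    if accepted == 1:
        ni, nl, npr = _collect(var_t, internals, leaves, prunable, stack)
        for k in range(nl):
            cnt[leaves[k]] = 0
            ssum[leaves[k]] = 0.0
        for i in range(N):
            l = leaf_assign[i]
            cnt[l] += 1
            ssum[l] += pr[i]
    for k in range(nl):
        l = leaves[k]
        denom = sigma2 + cnt[l] * sig2mu
        post_mean = sig2mu * ssum[l] / denom
        post_var = sigma2 * sig2mu / denom
        mu_t[l] = post_mean + np.sqrt(post_var) * np.random.normal()
    return accepted


@njit(cache=True)
def run_chain(X, y, is_binary, ybin, cuts_flat, cuts_off, cumS,
              alpha, beta, sigma_mu, nu, lam, mu0, K,
              n_iter, burn_in, seed, max_depth, move_probs, min_node,
              fixed_sigma2, snap_cap0):
    """Run one MCMC chain; returns kept fits, sigma^2 draws and tree snapshots.

    Snapshots store, per kept draw and tree, the occupied heap slots with
    their (slot, var, split, mu) fields; offsets index the flat node arrays
    by draw*K + tree.
    """
    np.random.seed(seed)
    N, p = X.shape
    H = 2 ** (max_depth + 1)
    var = np.full((K, H), UNUSED, dtype=np.int32)
    split = np.zeros((K, H))
    muh = np.zeros((K, H))
    for t in range(K):
        var[t, 0] = TERMINAL
    tree_fit = np.zeros((K, N))
    sig2mu = sigma_mu * sigma_mu

    if is_binary:
        sigma2 = 1.0
    elif fixed_sigma2 > 0.0:
        sigma2 = fixed_sigma2
    else:
        m = 0.0
        for i in range(N):
            m += y[i]
        m /= N
        v = 0.0
        for i in range(N):
            v += (y[i] - m) ** 2
        sigma2 = v / (N - 1)

    target = np.empty(N)
    if is_binary:
        for i in range(N):
            target[i] = sample_trunc_normal(mu0, ybin[i] == 1)
    else:
        for i in range(N):
            target[i] = y[i]
    r = np.empty(N)
    for i in range(N):
        r[i] = target[i] - mu0

    # workspaces; per-tree routing is cached and updated incrementally
    tree_assign = np.zeros((K, N), dtype=np.int32)
    internals = np.empty(H, dtype=np.int32)
    leaves = np.empty(H, dtype=np.int32)
    prunable = np.empty(H, dtype=np.int32)
    stack = np.empty(H, dtype=np.int32)
    subleaves = np.empty(H, dtype=np.int32)
    assign2 = np.empty(N, dtype=np.int32)
    cnt = np.zeros(H, dtype=np.int64)
    ssum = np.zeros(H)
    cnt2 = np.zeros(H, dtype=np.int64)
    ssum2 = np.zeros(H)
    pr = np.empty(N)

    n_kept = n_iter - burn_in
    fits = np.empty((n_kept, N))
    sigma2s = np.empty(n_kept)
    n_accept = 0

    snap_cap = snap_cap0
    snap_slot = np.empty(snap_cap, dtype=np.int32)
    snap_var = np.empty(snap_cap, dtype=np.int32)
    snap_split = np.empty(snap_cap)
    snap_mu = np.empty(snap_cap)
    snap_off = np.zeros(n_kept * K + 1, dtype=np.int64)
    pos = 0

    for it in range(n_iter):
        for t in range(K):
            for i in range(N):
                pr[i] = r[i] + tree_fit[t, i]
            n_accept += _update_tree(
                var[t], split[t], muh[t], X, pr, tree_assign[t],
                internals, leaves, prunable, stack, cnt, ssum,
                cnt2, ssum2, subleaves, assign2,
                cuts_flat, cuts_off, cumS, alpha, beta,
                sigma2, sig2mu, max_depth, move_probs, min_node)
            for i in range(N):
                nf = muh[t, tree_assign[t, i]]
                r[i] += tree_fit[t, i] - nf
                tree_fit[t, i] = nf
        if is_binary:
            for i in range(N):
                f = target[i] - r[i]
                z = sample_trunc_normal(f, ybin[i] == 1)
                r[i] += z - target[i]
                target[i] = z
        elif fixed_sigma2 <= 0.0:
            ssr = 0.0
            for i in range(N):
                ssr += r[i] * r[i]
            shape = 0.5 * (nu + N)
            rate = 0.5 * (nu * lam + ssr)
            sigma2 = rate / np.random.gamma(shape, 1.0)
        if it >= burn_in:
            q = it - burn_in
            for i in range(N):
                fits[q, i] = target[i] - r[i]
            sigma2s[q] = sigma2
            for t in range(K):
                ni, nl, npr = _collect(var[t], internals, leaves, prunable,
                                       stack)
                need = pos + ni + nl
                if need > snap_cap:
                    new_cap = snap_cap * 2
                    while new_cap < need:
                        new_cap *= 2
                    ns = np.empty(new_cap, dtype=np.int32)
                    nv = np.empty(new_cap, dtype=np.int32)
                    nsp = np.empty(new_cap)
                    nm = np.empty(new_cap)
                    ns[:pos] = snap_slot[:pos]
                    nv[:pos] = snap_var[:pos]
                    nsp[:pos] = snap_split[:pos]
                    nm[:pos] = snap_mu[:pos]
                    snap_slot = ns
                    snap_var = nv
                    snap_split = nsp
                    snap_mu = nm
                    snap_cap = new_cap
                for k in range(ni):
                    nd = internals[k]
                    snap_slot[pos] = nd
                    snap_var[pos] = var[t, nd]
                    snap_split[pos] = split[t, nd]
                    snap_mu[pos] = 0.0
                    pos += 1
                for k in range(nl):
                    nd = leaves[k]
                    snap_slot[pos] = nd
                    snap_var[pos] = TERMINAL
                    snap_split[pos] = 0.0
                    snap_mu[pos] = muh[t, nd]
                    pos += 1
                snap_off[q * K + t + 1] = pos
    return (fits, sigma2s, snap_off, snap_slot[:pos].copy(),
            snap_var[:pos].copy(), snap_split[:pos].copy(),
            snap_mu[:pos].copy(), n_accept)


@njit(cache=True)
def predict_snapshots(snap_off, snap_slot, snap_var, snap_split, snap_mu,
                      K, mu0, X):
    """Per-draw sum-of-trees predictions on new rows X -> (n_draws, M)."""
    n_draws = (snap_off.shape[0] - 1) // K
    M = X.shape[0]
    out = np.full((n_draws, M), mu0)
    for q in range(n_draws):
        for t in range(K):
            lo = snap_off[q * K + t]
            hi = snap_off[q * K + t + 1]
            for i in range(M):
                node = 0
                while True:
                    # linear scan for the slot within this tree's record
                    kpos = -1
                    for k in range(lo, hi):
                        if snap_slot[k] == node:
                            kpos = k
                            break
                    v = snap_var[kpos]
                    if v < 0:
                        out[q, i] += snap_mu[kpos]
                        break
                    if X[i, v] <= snap_split[kpos]:
                        node = 2 * node + 1
                    else:
                        node = 2 * node + 2
    return out
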