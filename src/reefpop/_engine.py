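"""Numba kernels for the event-driven structured coalescent.

Time runs backward in generations; a pair of lineages in a deme of diploid
size N coalesces at rate 1/(2N), and each lineage emigrates at total rate m,
split uniformly over its neighbor set (all other demes in the island model;
the 2-4 lattice neighbors in the stepping-stone model). At ``T_col`` every
lineage enters one panmictic pool of size ``N_anc``.

A genealogy is returned as the (n-1) coalescence events in time order:
``times[e]`` plus the two child node ids ``c1[e], c2[e]``. Leaves are nodes
``0..n-1``; the internal node created by event ``e`` is ``n + e``.

Exact accelerations
-------------------
Naively, most events are migration steps of lineages that sit alone in their
demes, and (at high Nm) repeated meet-and-separate cycles of lineage pairs.
Two exact shortcuts remove almost all of them:

* scattered phase (every deme holds at most one lineage): no coalescence is
  possible, so the migration steps form a pure jump chain; their total
  duration is Gamma(#steps, 1/(k m)). The stepping-stone walk is simulated
  step by step (lattice geometry matters) but without per-step clock draws.
* island model: deme labels are exchangeable, so the meet/separate cycle is
  iid and the number of failed cycles before a coalescence (or a rarer
  multi-lineage configuration change) is geometric; the aggregate number of
  walk steps is negative-binomial (drawn as a gamma-Poisson mixture) and the
  aggregate duration is gamma. Migrations of a lone lineage into an empty
  deme never change the exchangeable configuration and are thinned away.

``_gen_struct_naive`` keeps the plain one-event-at-a-time loop as an
independent in-repo oracle for distributional tests.

Kernels re-seed numba's global RNG stream on entry, so every exported call
is a pure function of its arguments.
"""

import numpy as np
from numba import njit

_NB = dict(cache=True, nogil=True)


@njit(inline="always")
def _randint(k):
    # uniform integer in [0, k); one double draw, bias < 2^-50 for k <= 2^20
    return int(np.random.random() * k)


@njit(inline="always")
def _exp_time(rate):
    return -np.log1p(-np.random.random()) / rate


@njit(**_NB)
def _coalesce_pool(k, t, N, nodes, times, c1, c2, e, nxt):
    """Finish the genealogy in a single panmictic pool of diploid size N."""
    while k > 1:
        rate = k * (k - 1) / (4.0 * N)
        t += _exp_time(rate)
        i = _randint(k)
        j = _randint(k - 1)
        if j >= i:
            j += 1
        lo, hi = (i, j) if i < j else (j, i)
        times[e] = t
        c1[e] = nodes[lo]
        c2[e] = nodes[hi]
        nodes[lo] = nxt
        nodes[hi] = nodes[k - 1]
        nxt += 1
        k -= 1
        e += 1


@njit(**_NB)
def _gen_ns(n, N_mod, N_anc, T_c, times, c1, c2):
    """Panmictic coalescent with an instantaneous size switch at T_c."""
    nodes = np.arange(n, dtype=np.int64)
    k = n
    t = 0.0
    e = 0
    nxt = n
    while k > 1:
        Ncur = N_mod if t < T_c else N_anc
        rate = k * (k - 1) / (4.0 * Ncur)
        dt = _exp_time(rate)
        if t < T_c and t + dt >= T_c:
            t = T_c  # memoryless: redraw under the ancestral size
            continue
        t += dt
        i = _randint(k)
        j = _randint(k - 1)
        if j >= i:
            j += 1
        lo, hi = (i, j) if i < j else (j, i)
        times[e] = t
        c1[e] = nodes[lo]
        c2[e] = nodes[hi]
        nodes[lo] = nxt
        nodes[hi] = nodes[k - 1]
        nxt += 1
        k -= 1
        e += 1


@njit(**_NB)
def _nb_plus_r(r, p):
    """Sum of r iid Geometric(p) variables (support >= 1 each)."""
    if r <= 0:
        return 0
    if r < 8:
        tot = 0
        for _ in range(r):
            tot += np.random.geometric(p)
        return tot
    lam = np.random.gamma(r, (1.0 - p) / p)
    return r + np.random.poisson(lam)


@njit(**_NB)
def _gen_lattice(init_deme, d, N, m, T_col, nbr_idx, nbr_cnt, times, c1, c2):
    """Stepping-stone phase of the structured coalescent (up to T_col).

    The event rates (coalescence C = sumpair/(4N), migration M = k m) are
    constant between configuration changes, so migration hops of lineages
    that are alone in their deme and land in an empty deme are applied in a
    tight inner loop with a single uniform draw each; the segment duration
    is drawn once as Gamma(#events, 1/(C+M)). Exact.

    Returns (k_remaining, t, e, nxt) packed as a tuple of ints/floats.
    """
    n = init_deme.shape[0]
    nodes = np.arange(n, dtype=np.int64)
    deme = init_deme.copy()
    cnt = np.zeros(d, dtype=np.int64)
    for i in range(n):
        cnt[deme[i]] += 1
    sumpair = 0
    for dd in range(d):
        c = cnt[dd]
        sumpair += c * (c - 1)
    k = n
    t = 0.0
    e = 0
    nxt = n
    rc = 1.0 / (2.0 * N)
    while k > 1 and t < T_col:
        C = sumpair * rc / 2.0
        M = k * m
        tot = C + M
        if tot <= 0.0:
            t = T_col
            break
        G = 0
        coal = False
        mi = -1
        msrc = -1
        mdst = -1
        while True:
            G += 1
            u = np.random.random() * tot
            if u < C:
                coal = True
                break
            w = (u - C) / M * k
            i = int(w)
            if i >= k:  # guard against roundoff at the upper edge
                i = k - 1
            s = deme[i]
            j = nbr_idx[s, int((w - i) * nbr_cnt[s])]
            if cnt[s] > 1 or cnt[j] > 0:
                mi = i
                msrc = s
                mdst = j
                break
            cnt[s] = 0
            cnt[j] = 1
            deme[i] = j
        elapsed = np.random.gamma(G, 1.0 / tot) if G > 1 else _exp_time(tot)
        if t + elapsed >= T_col:
            t = T_col
            break
        t += elapsed
        if coal:
            r = np.random.random() * sumpair
            acc = 0.0
            target = -1
            for dd in range(d):
                c = cnt[dd]
                if c > 1:
                    acc += c * (c - 1)
                    if r < acc:
                        target = dd
                        break
            c = cnt[target]
            a = _randint(c)
            b = _randint(c - 1)
            if b >= a:
                b += 1
            ia = -1
            ib = -1
            seen = 0
            for idx in range(k):
                if deme[idx] == target:
                    if seen == a:
                        ia = idx
                    if seen == b:
                        ib = idx
                    seen += 1
            lo, hi = (ia, ib) if ia < ib else (ib, ia)
            times[e] = t
            c1[e] = nodes[lo]
            c2[e] = nodes[hi]
            nodes[lo] = nxt
            nodes[hi] = nodes[k - 1]
            deme[hi] = deme[k - 1]
            nxt += 1
            k -= 1
            e += 1
            sumpair -= 2 * (c - 1)
            cnt[target] = c - 1
        else:
            cs = cnt[msrc]
            sumpair -= 2 * (cs - 1)
            cnt[msrc] = cs - 1
            cd = cnt[mdst]
            sumpair += 2 * cd
            cnt[mdst] = cd + 1
            deme[mi] = mdst
    return k, t, e, nxt, nodes


@njit(**_NB)
def _gen_island(init_deme, d, N, m, T_col, times, c1, c2):
    """Island-model phase of the structured coalescent (up to T_col)."""
    n = init_deme.shape[0]
    nodes = np.arange(n, dtype=np.int64)
    deme = init_deme.copy()
    cnt = np.zeros(d, dtype=np.int64)
    for i in range(n):
        cnt[deme[i]] += 1
    sumpair = 0
    occ = 0
    s1 = 0
    for dd in range(d):
        c = cnt[dd]
        sumpair += c * (c - 1)
        if c > 0:
            occ += 1
        if c == 1:
            s1 += 1
    k = n
    t = 0.0
    e = 0
    nxt = n
    rc = 1.0 / (2.0 * N)
    while k > 1 and t < T_col:
        if sumpair == 0:
            # iid meet/separate cycles; compress the failures exactly
            if m <= 0.0:
                t = T_col
                break
            p_meet = (k - 1) / (d - 1.0)
            r_rep = 2.0 * m * (d - k + 1.0) / (d - 1.0)  # pair member -> empty deme
            r_p2s = 2.0 * m * (k - 2.0) / (d - 1.0)      # pair member -> a singleton
            r_s2p = m * (k - 2.0) / (d - 1.0)            # singleton joins the pair
            r_s2s = m * (k - 2.0) * (k - 3.0) / (d - 1.0)  # two singletons meet
            R = rc + r_rep + r_p2s + r_s2p + r_s2s
            p_exit = 1.0 - r_rep / R
            F = np.random.geometric(p_exit)
            M = _nb_plus_r(F, p_meet)
            elapsed = np.random.gamma(M, 1.0 / (k * m)) + np.random.gamma(F, 1.0 / R)
            if t + elapsed >= T_col:
                t = T_col
                break
            t += elapsed
            # final meeting pair is uniform (membership refreshes each cycle)
            a = _randint(k)
            b = _randint(k - 1)
            if b >= a:
                b += 1
            u = np.random.random() * (R - r_rep)
            if u < rc:
                # exit: the meeting pair coalesces; survivors stay scattered
                lo, hi = (a, b) if a < b else (b, a)
                times[e] = t
                c1[e] = nodes[lo]
                c2[e] = nodes[hi]
                nodes[lo] = nxt
                nodes[hi] = nodes[k - 1]
                deme[hi] = deme[k - 1]
                nxt += 1
                k -= 1
                e += 1
                for dd in range(d):
                    cnt[dd] = 0
                for i in range(k):
                    deme[i] = i
                    cnt[i] = 1
                occ = k
                s1 = k
                sumpair = 0
                continue
            u -= rc
            # remaining exits create one or two co-occupied demes; lay the
            # configuration out on fresh deme labels (exchangeable)
            for dd in range(d):
                cnt[dd] = 0
            if u < r_p2s:
                # a pair member jumps onto a singleton: new pair + old partner alone
                mover = a if np.random.random() < 0.5 else b
                s = _randint(k - 2)
                idx = -1
                seen = 0
                for i in range(k):
                    if i != a and i != b:
                        if seen == s:
                            idx = i
                            break
                        seen += 1
                deme[mover] = 0
                deme[idx] = 0
                nd = 1
                for i in range(k):
                    if i != mover and i != idx:
                        deme[i] = nd
                        nd += 1
                cnt[0] = 2
                for dd in range(1, nd):
                    cnt[dd] = 1
                occ = nd
                s1 = nd - 1
                sumpair = 2
            elif u < r_p2s + r_s2p:
                # a singleton joins the meeting pair: triple
                s = _randint(k - 2)
                idx = -1
                seen = 0
                for i in range(k):
                    if i != a and i != b:
                        if seen == s:
                            idx = i
                            break
                        seen += 1
                deme[a] = 0
                deme[b] = 0
                deme[idx] = 0
                nd = 1
                for i in range(k):
                    if i != a and i != b and i != idx:
                        deme[i] = nd
                        nd += 1
                cnt[0] = 3
                for dd in range(1, nd):
                    cnt[dd] = 1
                occ = nd
                s1 = nd - 1
                sumpair = 6
            else:
                # two other singletons meet: two pairs
                s = _randint(k - 2)
                q = _randint(k - 3)
                if q >= s:
                    q += 1
                i1 = -1
                i2 = -1
                seen = 0
                for i in range(k):
                    if i != a and i != b:
                        if seen == s:
                            i1 = i
                        if seen == q:
                            i2 = i
                        seen += 1
                deme[a] = 0
                deme[b] = 0
                deme[i1] = 1
                deme[i2] = 1
                nd = 2
                for i in range(k):
                    if i != a and i != b and i != i1 and i != i2:
                        deme[i] = nd
                        nd += 1
                cnt[0] = 2
                cnt[1] = 2
                for dd in range(2, nd):
                    cnt[dd] = 1
                occ = nd
                s1 = nd - 2
                sumpair = 4
            continue
        # mixed phase: at least one deme holds >= 2 lineages; migrations of
        # lone lineages into empty demes are thinned away (exchangeability)
        coal_rate = sumpair * rc / 2.0
        km = k - s1
        r_multi = m * km
        r_single = m * s1 * (occ - 1.0) / (d - 1.0)
        total = coal_rate + r_multi + r_single
        dt = _exp_time(total)
        if t + dt >= T_col:
            t = T_col
            break
        t += dt
        u = np.random.random() * total
        if u < coal_rate:
            r = np.random.random() * sumpair
            acc = 0.0
            target = -1
            for dd in range(d):
                c = cnt[dd]
                if c > 1:
                    acc += c * (c - 1)
                    if r < acc:
                        target = dd
                        break
            c = cnt[target]
            a = _randint(c)
            b = _randint(c - 1)
            if b >= a:
                b += 1
            ia = -1
            ib = -1
            seen = 0
            for idx in range(k):
                if deme[idx] == target:
                    if seen == a:
                        ia = idx
                    if seen == b:
                        ib = idx
                    seen += 1
            lo, hi = (ia, ib) if ia < ib else (ib, ia)
            times[e] = t
            c1[e] = nodes[lo]
            c2[e] = nodes[hi]
            nodes[lo] = nxt
            nodes[hi] = nodes[k - 1]
            deme[hi] = deme[k - 1]
            nxt += 1
            k -= 1
            e += 1
            sumpair -= 2 * (c - 1)
            cnt[target] = c - 1
            if c == 2:
                s1 += 1
        elif u < coal_rate + r_multi:
            # emigration out of a multi-occupancy deme
            r = np.random.random() * km
            acc = 0.0
            src = -1
            for dd in range(d):
                c = cnt[dd]
                if c > 1:
                    acc += c
                    if r < acc:
                        src = dd
                        break
            a = _randint(cnt[src])
            idx = -1
            seen = 0
            for i in range(k):
                if deme[i] == src:
                    if seen == a:
                        idx = i
                        break
                    seen += 1
            dst = -1
            if np.random.random() * (d - 1.0) < d - occ:
                for dd in range(d):
                    if cnt[dd] == 0:
                        dst = dd
                        break
            else:
                r2 = _randint(occ - 1)
                seen = 0
                for dd in range(d):
                    if cnt[dd] > 0 and dd != src:
                        if seen == r2:
                            dst = dd
                            break
                        seen += 1
            cs = cnt[src]
            sumpair -= 2 * (cs - 1)
            cnt[src] = cs - 1
            if cs == 2:
                s1 += 1
            cd = cnt[dst]
            sumpair += 2 * cd
            cnt[dst] = cd + 1
            if cd == 0:
                occ += 1
                s1 += 1
            elif cd == 1:
                s1 -= 1
            deme[idx] = dst
        else:
            # a lone lineage lands on another occupied deme
            r = _randint(s1)
            src = -1
            seen = 0
            for dd in range(d):
                if cnt[dd] == 1:
                    if seen == r:
                        src = dd
                        break
                    seen += 1
            idx = -1
            for i in range(k):
                if deme[i] == src:
                    idx = i
                    break
            r2 = _randint(occ - 1)
            dst = -1
            seen = 0
            for dd in range(d):
                if cnt[dd] > 0 and dd != src:
                    if seen == r2:
                        dst = dd
                        break
                    seen += 1
            cnt[src] = 0
            occ -= 1
            s1 -= 1
            cd = cnt[dst]
            sumpair += 2 * cd
            cnt[dst] = cd + 1
            if cd == 1:
                s1 -= 1
            deme[idx] = dst
    return k, t, e, nxt, nodes


@njit(**_NB)
def _gen_struct(init_deme, d, N, m, T_col, N_anc, nbr_idx, nbr_cnt, island, times, c1, c2):
    """Structured coalescent on d demes collapsing to one pool at T_col."""
    if island:
        k, t, e, nxt, nodes = _gen_island(init_deme, d, N, m, T_col, times, c1, c2)
    else:
        k, t, e, nxt, nodes = _gen_lattice(init_deme, d, N, m, T_col, nbr_idx, nbr_cnt, times, c1, c2)
    _coalesce_pool(k, t, N_anc, nodes, times, c1, c2, e, nxt)


@njit(**_NB)
def _gen_struct_naive(init_deme, d, N, m, T_col, N_anc, nbr_idx, nbr_cnt, island, times, c1, c2):
    """Plain one-event-at-a-time reference loop (oracle for the fast kernel)."""
    n = init_deme.shape[0]
    nodes = np.arange(n, dtype=np.int64)
    deme = init_deme.copy()
    cnt = np.zeros(d, dtype=np.int64)
    for i in range(n):
        cnt[deme[i]] += 1
    sumpair = 0
    for dd in range(d):
        sumpair += cnt[dd] * (cnt[dd] - 1)
    k = n
    t = 0.0
    e = 0
    nxt = n
    while k > 1 and t < T_col:
        coal_rate = sumpair / (4.0 * N)
        mig_rate = k * m
        total = coal_rate + mig_rate
        if total <= 0.0:
            t = T_col
            break
        dt = np.random.exponential(1.0 / total)
        if t + dt >= T_col:
            t = T_col
            break
        t += dt
        if np.random.random() * total < coal_rate:
            r = np.random.random() * sumpair
            acc = 0.0
            target = -1
            for dd in range(d):
                c = cnt[dd]
                if c > 1:
                    acc += c * (c - 1)
                    if r < acc:
                        target = dd
                        break
            c = cnt[target]
            a = np.random.randint(c)
            b = np.random.randint(c - 1)
            if b >= a:
                b += 1
            ia = -1
            ib = -1
            seen = 0
            for idx in range(k):
                if deme[idx] == target:
                    if seen == a:
                        ia = idx
                    if seen == b:
                        ib = idx
                    seen += 1
            lo, hi = (ia, ib) if ia < ib else (ib, ia)
            times[e] = t
            c1[e] = nodes[lo]
            c2[e] = nodes[hi]
            nodes[lo] = nxt
            nodes[hi] = nodes[k - 1]
            deme[hi] = deme[k - 1]
            nxt += 1
            k -= 1
            e += 1
            sumpair -= 2 * (c - 1)
            cnt[target] = c - 1
        else:
            idx = np.random.randint(k)
            src = deme[idx]
            if island:
                dst = np.random.randint(d - 1)
                if dst >= src:
                    dst += 1
            else:
                dst = nbr_idx[src, np.random.randint(nbr_cnt[src])]
            cs = cnt[src]
            sumpair -= 2 * (cs - 1)
            cnt[src] = cs - 1
            cd = cnt[dst]
            sumpair += 2 * cd
            cnt[dst] = cd + 1
            deme[idx] = dst
    _coalesce_pool(k, t, N_anc, nodes, times, c1, c2, e, nxt)


@njit(**_NB)
def _class_lengths(n, times, c1, c2, out):
    """Total branch length subtended by i sampled leaves, for i = 1..n-1.

    out has length n; out[i] receives class i. Root branch carries nothing.
    """
    ndesc = np.zeros(2 * n - 1, dtype=np.int64)
    btime = np.zeros(2 * n - 1)
    for i in range(n):
        ndesc[i] = 1
    for e in range(n - 1):
        t = times[e]
        u = c1[e]
        v = c2[e]
        out[ndesc[u]] += t - btime[u]
        out[ndesc[v]] += t - btime[v]
        w = n + e
        ndesc[w] = ndesc[u] + ndesc[v]
        btime[w] = t


@njit(**_NB)
def sim_genealogy_ns(n, N_mod, N_anc, T_c, seed):
    np.random.seed(seed)
    times = np.empty(n - 1)
    c1 = np.empty(n - 1, dtype=np.int64)
    c2 = np.empty(n - 1, dtype=np.int64)
    _gen_ns(n, N_mod, N_anc, T_c, times, c1, c2)
    return times, c1, c2


@njit(**_NB)
def sim_genealogy_struct(init_deme, d, N, m, T_col, N_anc, nbr_idx, nbr_cnt, island, seed, naive=False):
    np.random.seed(seed)
    n = init_deme.shape[0]
    times = np.empty(n - 1)
    c1 = np.empty(n - 1, dtype=np.int64)
    c2 = np.empty(n - 1, dtype=np.int64)
    if naive:
        _gen_struct_naive(init_deme, d, N, m, T_col, N_anc, nbr_idx, nbr_cnt, island, times, c1, c2)
    else:
        _gen_struct(init_deme, d, N, m, T_col, N_anc, nbr_idx, nbr_cnt, island, times, c1, c2)
    return times, c1, c2


@njit(**_NB)
def sim_sfs_ns(n, N_mod, N_anc, T_c, mu_len, n_loci, seed):
    """Aggregate unfolded mutation counts xi[0..n-2] over independent loci."""
    np.random.seed(seed)
    xi = np.zeros(n - 1, dtype=np.int64)
    times = np.empty(n - 1)
    c1 = np.empty(n - 1, dtype=np.int64)
    c2 = np.empty(n - 1, dtype=np.int64)
    cl = np.empty(n)
    for _ in range(n_loci):
        _gen_ns(n, N_mod, N_anc, T_c, times, c1, c2)
        cl[:] = 0.0
        _class_lengths(n, times, c1, c2, cl)
        for i in range(1, n):
            lam = mu_len * cl[i]
            if lam > 0.0:
                xi[i - 1] += np.random.poisson(lam)
    return xi


@njit(**_NB)
def sim_sfs_ns_batch(n, N_mod, N_anc, T_c, mu_len, n_loci, n_datasets, seed):
    """Many independent NS datasets; row i is the unfolded xi of dataset i."""
    np.random.seed(seed)
    out = np.zeros((n_datasets, n - 1), dtype=np.int64)
    times = np.empty(n - 1)
    c1 = np.empty(n - 1, dtype=np.int64)
    c2 = np.empty(n - 1, dtype=np.int64)
    cl = np.empty(n)
    for r in range(n_datasets):
        for _ in range(n_loci):
            _gen_ns(n, N_mod, N_anc, T_c, times, c1, c2)
            cl[:] = 0.0
            _class_lengths(n, times, c1, c2, cl)
            for i in range(1, n):
                lam = mu_len * cl[i]
                if lam > 0.0:
                    out[r, i - 1] += np.random.poisson(lam)
    return out


@njit(**_NB)
def sim_sfs_struct(init_deme, d, N, m, T_col, N_anc, nbr_idx, nbr_cnt, island, mu_len, n_loci, seed):
    np.random.seed(seed)
    n = init_deme.shape[0]
    xi = np.zeros(n - 1, dtype=np.int64)
    times = np.empty(n - 1)
    c1 = np.empty(n - 1, dtype=np.int64)
    c2 = np.empty(n - 1, dtype=np.int64)
    cl = np.empty(n)
    for _ in range(n_loci):
        _gen_struct(init_deme, d, N, m, T_col, N_anc, nbr_idx, nbr_cnt, island, times, c1, c2)
        cl[:] = 0.0
        _class_lengths(n, times, c1, c2, cl)
        for i in range(1, n):
            lam = mu_len * cl[i]
            if lam > 0.0:
                xi[i - 1] += np.random.poisson(lam)
    return xi


@njit(**_NB)
def sim_two_pop_branch_counts(
    init_deme, nA, d, N, m, T_col, N_anc, nbr_idx, nbr_cnt, island, mu_len, n_loci, seed
):
    """Joint genealogy of two samples; per-branch mutation counts.

    Leaves 0..nA-1 belong to population A, the rest to B. Returns flat arrays
    (one entry per non-root branch per locus): number of A-descendants,
    B-descendants, and the Poisson mutation count on that branch.
    """
    np.random.seed(seed)
    n = init_deme.shape[0]
    nb = n_loci * 2 * (n - 1)
    aA = np.empty(nb, dtype=np.int64)
    aB = np.empty(nb, dtype=np.int64)
    nm = np.empty(nb, dtype=np.int64)
    times = np.empty(n - 1)
    c1 = np.empty(n - 1, dtype=np.int64)
    c2 = np.empty(n - 1, dtype=np.int64)
    descA = np.zeros(2 * n - 1, dtype=np.int64)
    descB = np.zeros(2 * n - 1, dtype=np.int64)
    btime = np.zeros(2 * n - 1)
    p = 0
    for _ in range(n_loci):
        _gen_struct(init_deme, d, N, m, T_col, N_anc, nbr_idx, nbr_cnt, island, times, c1, c2)
        for i in range(n):
            descA[i] = 1 if i < nA else 0
            descB[i] = 0 if i < nA else 1
            btime[i] = 0.0
        for e in range(n - 1):
            t = times[e]
            for child in (c1[e], c2[e]):
                aA[p] = descA[child]
                aB[p] = descB[child]
                lam = mu_len * (t - btime[child])
                nm[p] = np.random.poisson(lam) if lam > 0.0 else 0
                p += 1
            w = n + e
            descA[w] = descA[c1[e]] + descA[c2[e]]
            descB[w] = descB[c1[e]] + descB[c2[e]]
            btime[w] = t
    return aA, aB, nm
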