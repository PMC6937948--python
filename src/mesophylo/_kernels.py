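"""Numba-compiled inner loop for hierarchical-ABC pair simulations.

The co-divergence test needs millions of two-population coalescent + HKY
replicates; this module provides a jit kernel equivalent in distribution to
the general event-list engine in :mod:`mesophylo.coalsim` restricted to a
single split (a test asserts the agreement).  The kernel uses numba's
per-thread legacy NumPy RNG: call :func:`seed_kernel` once per run for
reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "seed_kernel",
    "pair_stats",
    "batch_pair_stats",
    "N_PAIR_STATS",
    "PAIR_STAT_NAMES",
]

N_PAIR_STATS = 7
PAIR_STAT_NAMES = (
    "pi_total",
    "pi_within_1",
    "pi_within_2",
    "pi_net",
    "theta_w",
    "tajima_d_1",
    "tajima_d_2",
)


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _tajima_d(n, S, k):
    if S == 0 or n < 2:
        return 0.0
    a1 = 0.0
    a2 = 0.0
    for i in range(1, n):
        a1 += 1.0 / i
        a2 += 1.0 / (i * i)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0.0:
        return 0.0
    return (k - S / a1) / denom


@njit(cache=True)
def pair_stats(n1, n2, t_split, N1, N2, Na, kappa, fA, fC, fG, fT, u, L):
    """Simulate one two-population split and return its 7 summary statistics.

    Populations of haploid sizes N1/N2 merge into an ancestor of size Na at
    ``t_split`` generations; HKY mutation at per-site rate ``u``; statistics
    are per-site: (π_total, π_w1, π_w2, π_net, θ_W, D1, D2) with Tajima's D
    reported as 0 where undefined.
    """
    n = n1 + n2
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    # active lineage ids per population
    act1 = np.empty(n, dtype=np.int64)
    act2 = np.empty(n, dtype=np.int64)
    c1 = n1
    c2 = n2
    for i in range(n1):
        act1[i] = i
    for i in range(n2):
        act2[i] = n1 + i
    nxt = n
    t = 0.0
    # phase 1: two isolated populations until t_split
    while True:
        r1 = c1 * (c1 - 1) / 2.0 / (2.0 * N1) if c1 >= 2 else 0.0
        r2 = c2 * (c2 - 1) / 2.0 / (2.0 * N2) if c2 >= 2 else 0.0
        tot = r1 + r2
        if tot == 0.0:
            break
        wait = np.random.exponential(1.0 / tot)
        if t + wait >= t_split:
            break
        t += wait
        if np.random.random() * tot < r1:
            i = np.random.randint(c1)
            j = np.random.randint(c1 - 1)
            if j >= i:
                j += 1
            a = act1[i]
            b = act1[j]
            lo = i if i < j else j
            hi = j if i < j else i
            act1[lo] = nxt
            act1[hi] = act1[c1 - 1]
            c1 -= 1
        else:
            i = np.random.randint(c2)
            j = np.random.randint(c2 - 1)
            if j >= i:
                j += 1
            a = act2[i]
            b = act2[j]
            lo = i if i < j else j
            hi = j if i < j else i
            act2[lo] = nxt
            act2[hi] = act2[c2 - 1]
            c2 -= 1
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        nxt += 1
    # phase 2: merged ancestral population
    t = t_split
    act = np.empty(c1 + c2, dtype=np.int64)
    for i in range(c1):
        act[i] = act1[i]
    for i in range(c2):
        act[c1 + i] = act2[i]
    c = c1 + c2
    while c > 1:
        rate = c * (c - 1) / 2.0 / (2.0 * Na)
        t += np.random.exponential(1.0 / rate)
        i = np.random.randint(c)
        j = np.random.randint(c - 1)
        if j >= i:
            j += 1
        a = act[i]
        b = act[j]
        lo = i if i < j else j
        hi = j if i < j else i
        act[lo] = nxt
        act[hi] = act[c - 1]
        c -= 1
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        nxt += 1

    # HKY generator, uniformization
    freqs = np.empty(4)
    freqs[0] = fA
    freqs[1] = fC
    freqs[2] = fG
    freqs[3] = fT
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            ts = (i == 0 and j == 2) or (i == 2 and j == 0) or (
                i == 1 and j == 3
            ) or (i == 3 and j == 1)
            q[i, j] = freqs[j] * (kappa if ts else 1.0)
    mean_rate = 0.0
    for i in range(4):
        rowsum = 0.0
        for j in range(4):
            if j != i:
                rowsum += q[i, j]
        q[i, i] = -rowsum
        mean_rate += freqs[i] * rowsum
    if mean_rate > 0.0 and u > 0.0:
        scale = u / mean_rate
        for i in range(4):
            for j in range(4):
                q[i, j] *= scale
    lam = 0.0
    for i in range(4):
        if -q[i, i] > lam:
            lam = -q[i, i]
    cum_b = np.zeros((4, 4))
    for i in range(4):
        acc = 0.0
        for j in range(4):
            bij = q[i, j] / lam if lam > 0.0 else 0.0
            if i == j:
                bij += 1.0
            acc += bij
            cum_b[i, j] = acc
        cum_b[i, 3] = 1.0

    # evolve sequences root -> tips
    seqs = np.empty((n_nodes, L), dtype=np.int8)
    root = n_nodes - 1
    cumf = np.empty(4)
    acc = 0.0
    for i in range(4):
        acc += freqs[i]
        cumf[i] = acc
    cumf[3] = 1.0
    for s in range(L):
        r = np.random.random()
        st = 0
        while cumf[st] < r:
            st += 1
        seqs[root, s] = st
    order = np.argsort(-node_time)
    for oi in range(n_nodes):
        node = order[oi]
        if node == root:
            continue
        p = parent[node]
        for s in range(L):
            seqs[node, s] = seqs[p, s]
        if lam > 0.0:
            blen = node_time[p] - node_time[node]
            n_ev = np.random.poisson(lam * blen * L)
            for _ in range(n_ev):
                s = np.random.randint(L)
                r = np.random.random()
                st = seqs[node, s]
                new = 0
                while cum_b[st, new] < r:
                    new += 1
                seqs[node, s] = new

    # variable sites among tips
    var_sites = np.empty(L, dtype=np.int64)
    n_var = 0
    for s in range(L):
        ref = seqs[0, s]
        for i in range(1, n):
            if seqs[i, s] != ref:
                var_sites[n_var] = s
                n_var += 1
                break

    # pairwise difference counts on variable sites
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cnt = 0.0
            for v in range(n_var):
                s = var_sites[v]
                if seqs[i, s] != seqs[j, s]:
                    cnt += 1.0
            d[i, j] = cnt
            d[j, i] = cnt

    inv_l = 1.0 / L
    tot_sum = 0.0
    tot_n = 0
    w1_sum = 0.0
    w1_n = 0
    w2_sum = 0.0
    w2_n = 0
    b_sum = 0.0
    b_n = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot_sum += d[i, j]
            tot_n += 1
            if i < n1 and j < n1:
                w1_sum += d[i, j]
                w1_n += 1
            elif i >= n1 and j >= n1:
                w2_sum += d[i, j]
                w2_n += 1
            else:
                b_sum += d[i, j]
                b_n += 1
    pi_total = tot_sum / tot_n * inv_l
    pi_w1 = (w1_sum / w1_n * inv_l) if w1_n > 0 else 0.0
    pi_w2 = (w2_sum / w2_n * inv_l) if w2_n > 0 else 0.0
    pi_b = (b_sum / b_n * inv_l) if b_n > 0 else 0.0
    pi_net = pi_b - 0.5 * (pi_w1 + pi_w2)
    a1 = 0.0
    for i in range(1, n):
        a1 += 1.0 / i
    theta_w = n_var / a1 * inv_l

    # per-population S and k for Tajima's D
    s1 = 0
    s2 = 0
    for v in range(n_var):
        s = var_sites[v]
        ref = seqs[0, s]
        for i in range(1, n1):
            if seqs[i, s] != ref:
                s1 += 1
                break
        ref = seqs[n1, s]
        for i in range(n1 + 1, n):
            if seqs[i, s] != ref:
                s2 += 1
                break
    k1 = (w1_sum / w1_n) if w1_n > 0 else 0.0
    k2 = (w2_sum / w2_n) if w2_n > 0 else 0.0
    d1 = _tajima_d(n1, s1, k1)
    d2 = _tajima_d(n2, s2, k2)

    out = np.empty(7)
    out[0] = pi_total
    out[1] = pi_w1
    out[2] = pi_w2
    out[3] = pi_net
    out[4] = theta_w
    out[5] = d1
    out[6] = d2
    return out


@njit(cache=True)
def batch_pair_stats(n1, n2, t_splits, N1s, N2s, Nas, kappa, fA, fC, fG, fT, u, L, out):
    """Fill ``out[s]`` with :func:`pair_stats` for each simulated draw s."""
    for s in range(t_splits.shape[0]):
        out[s] = pair_stats(
            n1, n2, t_splits[s], N1s[s], N2s[s], Nas[s],
            kappa, fA, fC, fG, fT, u, L,
        )
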