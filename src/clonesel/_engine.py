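"""Numba kernel for the forward clonal Wright-Fisher simulation.

The population is stored as a mutation tree: every node is one mutation
(the root is the mutation-free founder genotype) and a cell's genotype is
the path from its node to the root.  This clone-compressed representation
is exact for asexual, non-recombining populations and keeps the state
small: only nodes ancestral to at least one live cell are retained.

Per generation:

1. offspring counts are drawn multinomially with clone weights
   count x fitness, where fitness is the product of (1 + s) over the
   clone's mutations (floored at 0);
2. each offspring cell mutates with probability 1 - exp(-mu_genome);
   a mutating cell receives a zero-truncated Poisson(mu_genome) number
   of new mutations, each creating a child node.

The kernel uses numba's own Mersenne-Twister state, seeded per call, so
results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DEGENERATE = 1  # total fitness-weighted mass reached zero
STATUS_OVERFLOW = 2    # node capacity exhausted; caller retries larger

# fitness_class codes
FC_NEUTRAL = 0
FC_BENEFICIAL = 1
FC_DELETERIOUS = 2


@njit(cache=True)
def _zt_poisson(lam: float) -> int:
    """Zero-truncated Poisson sample (k >= 1) by inversion."""
    if lam <= 0.0:
        return 1
    u = np.random.random()
    p0 = np.exp(-lam)
    denom = 1.0 - p0
    pk = lam * p0 / denom
    c = pk
    k = 1
    while u > c and k < 500:
        k += 1
        pk *= lam / k
        c += pk
    return k


@njit(cache=True)
def _simulate(N, generations, mu_genome, frac_nonsyn, p_ben,
              shape_p, scale_p, shape_n, scale_n,
              driver_frac, vaf_min, seed, cap):
    np.random.seed(seed)

    parent = np.full(cap, -1, np.int64)
    s_arr = np.zeros(cap, np.float64)
    fit = np.zeros(cap, np.float64)
    count = np.zeros(cap, np.int64)
    syn = np.zeros(cap, np.uint8)
    fclass = np.zeros(cap, np.int8)
    driver = np.zeros(cap, np.uint8)
    origin = np.zeros(cap, np.int32)

    n_nodes = 1          # root: founder genotype, no mutation
    fit[0] = 1.0
    count[0] = N

    live = np.empty(N, np.int64)
    live[0] = 0
    n_live = 1
    live_next = np.empty(N, np.int64)

    p_mut = 1.0 - np.exp(-mu_genome)
    # worst-case new nodes in one generation (loose bound used to decide
    # when pruning is needed before the capacity is hit)
    margin = int(N * (mu_genome + 5.0)) + 1000
    prune_every = 64

    for gen in range(1, generations + 1):
        # --- multinomial resampling with weights count * fitness ---
        wtot = 0.0
        for j in range(n_live):
            wtot += count[live[j]] * fit[live[j]]
        if wtot <= 0.0:
            return (STATUS_DEGENERATE, n_nodes, parent, s_arr, count, syn,
                    fclass, driver, origin)
        remaining = N
        wrem = wtot
        last_pos = -1
        for j in range(n_live):
            i = live[j]
            w = count[i] * fit[i]
            if remaining <= 0 or wrem <= 0.0:
                count[i] = 0
                continue
            if w > 0.0:
                last_pos = i
            if w >= wrem:
                c = remaining
            else:
                pr = w / wrem
                if pr < 0.0:
                    pr = 0.0
                elif pr > 1.0:
                    pr = 1.0
                c = np.random.binomial(remaining, pr)
            count[i] = c
            remaining -= c
            wrem -= w
        if remaining > 0 and last_pos >= 0:
            # float underflow in the running weight can strand offspring;
            # assign them to the last clone with positive weight
            count[last_pos] += remaining

        # --- mutation ---
        n_live_next = 0
        for j in range(n_live):
            i = live[j]
            c = count[i]
            if c == 0:
                continue
            m = np.random.binomial(c, p_mut) if p_mut > 0.0 else 0
            count[i] = c - m
            if c - m > 0:
                live_next[n_live_next] = i
                n_live_next += 1
            for _ in range(m):
                k = _zt_poisson(mu_genome)
                par = i
                for _kk in range(k):
                    node = n_nodes
                    if node >= cap:
                        return (STATUS_OVERFLOW, n_nodes, parent, s_arr,
                                count, syn, fclass, driver, origin)
                    # draw the mutation
                    if np.random.random() >= frac_nonsyn:
                        sv = 0.0
                        sy = 1
                        fc = FC_NEUTRAL
                        dr = 1 if np.random.random() < driver_frac else 0
                    elif p_ben > 0.0 and np.random.random() < p_ben:
                        sv = np.random.gamma(shape_p, scale_p) if shape_p > 0.0 else 0.0
                        sy = 0
                        fc = FC_BENEFICIAL if sv > 0.0 else FC_NEUTRAL
                        dr = 1
                    else:
                        sv = -np.random.gamma(shape_n, scale_n) if shape_n > 0.0 else 0.0
                        sy = 0
                        fc = FC_DELETERIOUS if sv < 0.0 else FC_NEUTRAL
                        dr = 1 if np.random.random() < driver_frac else 0
                    parent[node] = par
                    s_arr[node] = sv
                    f = fit[par] * (1.0 + sv)
                    fit[node] = f if f > 0.0 else 0.0
                    count[node] = 0
                    syn[node] = sy
                    fclass[node] = fc
                    driver[node] = dr
                    origin[node] = gen
                    n_nodes += 1
                    par = node
                count[par] = 1
                live_next[n_live_next] = par
                n_live_next += 1

        tmp = live
        live = live_next
        live_next = tmp
        n_live = n_live_next

        # --- prune extinct subtrees ---
        if gen % prune_every == 0 or n_nodes > cap - margin:
            mark = np.zeros(n_nodes, np.uint8)
            mark[0] = 1
            for j in range(n_live):
                i = live[j]
                while i >= 0 and mark[i] == 0:
                    mark[i] = 1
                    i = parent[i]
            new_idx = np.full(n_nodes, -1, np.int64)
            nn = 0
            for i in range(n_nodes):
                if mark[i] == 1:
                    new_idx[i] = nn
                    pi = parent[i]
                    parent[nn] = new_idx[pi] if pi >= 0 else -1
                    s_arr[nn] = s_arr[i]
                    fit[nn] = fit[i]
                    count[nn] = count[i]
                    syn[nn] = syn[i]
                    fclass[nn] = fclass[i]
                    driver[nn] = driver[i]
                    origin[nn] = origin[i]
                    nn += 1
            for j in range(n_live):
                live[j] = new_idx[live[j]]
            n_nodes = nn
            if n_nodes > cap - margin:
                return (STATUS_OVERFLOW, n_nodes, parent, s_arr, count, syn,
                        fclass, driver, origin)

    return (STATUS_OK, n_nodes, parent, s_arr, count, syn, fclass, driver,
            origin)


@njit(cache=True)
def _descendant_counts(n_nodes, parent, count):
    desc = count[:n_nodes].copy()
    for i in range(n_nodes - 1, 0, -1):
        desc[parent[i]] += desc[i]
    return desc


def run_engine(N, generations, mu_genome, frac_nonsyn, p_ben,
               gamma_pos, gamma_neg, driver_frac, vaf_min, seed):
    """Run the kernel and return segregating mutations as plain arrays.

    Returns dict of arrays: vaf, s, synonymous, fitness_class, driver,
    origin_gen -- one entry per segregating (non-fixed) mutation with
    vaf >= vaf_min.  Raises RuntimeError on a degenerate population.
    """
    shape_p, rate_p = gamma_pos
    shape_n, rate_n = gamma_neg
    scale_p = 1.0 / rate_p if rate_p > 0 else 0.0
    scale_n = 1.0 / rate_n if rate_n > 0 else 0.0

    exp_events = generations * N * mu_genome
    cap = int(1.2 * exp_events + 8.0 * np.sqrt(exp_events + 1.0)) + 50_000
    while True:
        out = _simulate(N, generations, mu_genome, frac_nonsyn, p_ben,
                        shape_p, scale_p, shape_n, scale_n,
                        driver_frac, vaf_min, seed, cap)
        status = out[0]
        if status != STATUS_OVERFLOW:
            break
        cap *= 2
        if cap > 500_000_000:  # pragma: no cover
            raise MemoryError("simulation node capacity exceeded all bounds")
    if status == STATUS_DEGENERATE:
        raise RuntimeError(
            "degenerate population: total clone fitness reached zero"
        )
    (_, n_nodes, parent, s_arr, count, syn, fclass, driver, origin) = out
    desc = _descendant_counts(n_nodes, parent, count)
    idx = np.arange(1, n_nodes)
    d = desc[1:n_nodes]
    vaf = d / N
    keep = (d > 0) & (d < N) & (vaf >= vaf_min)
    sel = idx[keep]
    return {
        "vaf": vaf[keep],
        "s": s_arr[sel].copy(),
        "synonymous": syn[sel].astype(bool),
        "fitness_class": fclass[sel].copy(),
        "driver": driver[sel].astype(bool),
        "origin_gen": origin[sel].copy(),
    }
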