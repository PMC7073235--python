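"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by direct enumeration, independently of
the library code paths it cross-checks.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from scipy.stats import rankdata


def brute_nsr_tfp(edges, de_genes, mirnas, tf_genes):
    """Naive per-miRNA NSR / TF count / TFP by scanning the edge list."""
    de = set(de_genes)
    mset = set(mirnas)
    kept = [(m, g) for m, g in edges if m in mset and g in de]
    reg = Counter(g for _, g in kept)
    out = {}
    for m in mirnas:
        targets = {g for mm, g in kept if mm == m}
        nsr = sum(1 for g in targets if reg[g] == 1)
        tf_count = len(targets & set(tf_genes))
        tfp = tf_count / len(targets) if targets else 0.0
        out[m] = (len(targets), nsr, tf_count, tfp)
    return out


def brute_signed_rank_greater(diffs):
    """Exact one-sided signed-rank p by enumerating all 2^m sign vectors.

    Zero differences are dropped first (the Wilcoxon reduction); each of the
    2^m sign assignments of the non-zero differences is equally likely under
    the null, and ties are handled with midranks.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=m):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= observed - 1e-9:
            count += 1
    return count / 2**m


def brute_betweenness(nodes, edges):
    """Normalized betweenness by enumerating every shortest path.

    For each ordered pair (s, t) all shortest paths are generated by
    depth-first search over the BFS predecessor structure; each interior
    node of each path gets credit 1/(number of shortest s-t paths).
    """
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    score = {n: 0.0 for n in nodes}
    nodes = list(nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            # BFS distances from s
            dist = {s: 0}
            frontier = [s]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            if t not in dist:
                continue
            paths = []

            def extend(path):
                u = path[-1]
                if u == t:
                    paths.append(path)
                    return
                for v in adj[u]:
                    if dist.get(v, -1) == dist[u] + 1 and dist[v] <= dist[t]:
                        extend(path + [v])

            extend([s])
            for path in paths:
                for mid in path[1:-1]:
                    score[mid] += 1.0 / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    return {k: v / norm for k, v in score.items()}


def brute_bh(pvals):
    """Benjamini-Hochberg adjusted p-values, direct step-down enforcement."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def brute_km(times, events):
    """Product-limit estimator over event times, naive accumulation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = [(0.0, 1.0)]
    for t in np.unique(times):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        if d > 0:
            s *= 1.0 - d / at_risk
        out.append((float(t), s))
    return out
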