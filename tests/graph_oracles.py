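"""Independent brute-force graph-metric oracles (loops only, no reuse
of the implementation under test)."""

import numpy as np


def brute_clustering(adj):
    """Triangle enumeration by triple loop."""
    n = adj.shape[0]
    per = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        d = len(nbrs)
        if d < 2:
            continue
        tri = 0
        for a in range(d):
            for b in range(a + 1, d):
                if adj[nbrs[a], nbrs[b]]:
                    tri += 1
        per[i] = 2 * tri / (d * (d - 1))
    return per, per.mean()


def brute_distances(adj):
    """Floyd-Warshall with explicit loops."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj.astype(bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_char_path(adj):
    d = brute_distances(adj)
    vals = [d[i, j] for i in range(len(d)) for j in range(len(d))
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def brute_global_eff(adj):
    d = brute_distances(adj)
    n = len(d)
    total = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(d[i, j]))
    return total / (n * (n - 1)) if n > 1 else 0.0


def brute_local_eff(adj):
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += brute_global_eff(sub)
    return total / n


def random_adj(rng, n, p):
    a = rng.random((n, n)) < p
    a = np.triu(a, k=1)
    a = a | a.T
    return a


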