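"""Independent brute-force oracles used by the acceptance script."""

import numpy as np


def bh_oracle(p):
    """Literal Benjamini-Hochberg step-up rule: adj_(k) = min over j >= k of
    m * p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj[order[rank - 1]] = min(1.0, running)
    return adj


def naive_cast(S, t):
    """Straight-line reimplementation of the CAST add/remove scheme."""
    n = len(S)
    pool = list(range(n))
    clusters = []
    while pool:
        best, best_tot = None, -np.inf
        for x in pool:
            tot = sum(S[x][y] for y in pool)
            if tot > best_tot:
                best, best_tot = x, tot
        cluster = [best]
        pool.remove(best)
        while True:
            moved = False
            while pool:
                cand, cand_mean = None, -np.inf
                for x in pool:
                    mean = sum(S[x][y] for y in cluster) / len(cluster)
                    if mean > cand_mean:
                        cand, cand_mean = x, mean
                if cand_mean >= t:
                    cluster.append(cand)
                    pool.remove(cand)
                    moved = True
                else:
                    break
            while len(cluster) > 1:
                worst, worst_mean = None, np.inf
                for x in cluster:
                    mean = sum(S[x][y] for y in cluster) / len(cluster)
                    if mean < worst_mean:
                        worst, worst_mean = x, mean
                if worst_mean < t:
                    cluster.remove(worst)
                    pool.append(worst)
                    pool.sort()
                    moved = True
                else:
                    break
            if not moved:
                break
        clusters.append(sorted(cluster))
    return clusters
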