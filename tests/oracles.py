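"""Naive brute-force reimplementations used as independent oracles.

Everything here is written as plain double/triple loops straight from the
definitions, deliberately ignoring the vectorized implementations under
test.
"""

from __future__ import annotations

import math
from itertools import combinations


def shannon_brute(counts) -> float:
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def bray_curtis_brute(u, v) -> float:
    num = sum(abs(a - b) for a, b in zip(u, v))
    den = sum(a + b for a, b in zip(u, v))
    return num / den


def levins_brute(row) -> float:
    total = sum(row)
    return 1.0 / sum((c / total) ** 2 for c in row)


def simper_brute(rel_a_cols, rel_b_cols):
    """Mean per-taxon contribution over all between-group pairs.

    rel_*_cols: list of per-sample relative-abundance vectors.
    """
    n_taxa = len(rel_a_cols[0])
    contrib = [0.0] * n_taxa
    n_pairs = 0
    for a in rel_a_cols:
        for b in rel_b_cols:
            den = sum(x + y for x, y in zip(a, b))
            for k in range(n_taxa):
                contrib[k] += abs(a[k] - b[k]) / den
            n_pairs += 1
    return [c / n_pairs for c in contrib]


def bmntd_brute(weights_k, weights_l, dist) -> float:
    """weights_*: taxon -> relative abundance within the community (only
    present taxa); dist: (taxon, taxon) -> distance."""
    def half(src, dst):
        s = 0.0
        for i, w in src.items():
            s += w * min(dist[(i, j)] if i != j else 0.0 for j in dst)
        return s

    return 0.5 * (half(weights_k, weights_l) + half(weights_l, weights_k))


def zi_pi_brute(edges, modules):
    """edges: iterable of (u, v); modules: node -> module id."""
    nodes = set(modules)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    kin = {v: sum(1 for u in adj[v] if modules[u] == modules[v]) for v in nodes}
    zi = {}
    for m in set(modules.values()):
        members = [v for v in nodes if modules[v] == m]
        vals = [kin[v] for v in members]
        mean = sum(vals) / len(vals)
        var = sum((x - mean) ** 2 for x in vals) / len(vals)
        sd = math.sqrt(var)
        for v in members:
            zi[v] = (kin[v] - mean) / sd if sd > 0 else 0.0
    pi = {}
    for v in nodes:
        k = len(adj[v])
        if k == 0:
            pi[v] = 0.0
            continue
        per = {}
        for u in adj[v]:
            per[modules[u]] = per.get(modules[u], 0) + 1
        pi[v] = 1.0 - sum((c / k) ** 2 for c in per.values())
    return zi, pi


def modularity_brute(edges, modules) -> float:
    """Q = sum_m (e_mm - a_m^2) on an unweighted undirected graph."""
    m_edges = len(edges)
    mods = set(modules.values())
    e_mm = {m: 0 for m in mods}
    deg_sum = {m: 0 for m in mods}
    for u, v in edges:
        if modules[u] == modules[v]:
            e_mm[modules[u]] += 1
        deg_sum[modules[u]] += 1
        deg_sum[modules[v]] += 1
    q = 0.0
    for m in mods:
        q += e_mm[m] / m_edges - (deg_sum[m] / (2 * m_edges)) ** 2
    return q


def permanova_f_brute(d, labels):
    """Pseudo-F from raw pairwise distances (Anderson's direct formula)."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_t = sum(d[i][j] ** 2 for i, j in combinations(range(n), 2)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(d[i][j] ** 2 for i, j in combinations(idx, 2)) / len(idx)
    ss_a = ss_t - ss_w
    a = len(groups)
    return (ss_a / (a - 1)) / (ss_w / (n - a))
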