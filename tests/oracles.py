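"""Independent brute-force reference implementations used as oracles.

Everything here is written straight from the mathematical definitions,
with plain Python loops and exact combinatorics, deliberately sharing no
code with the package under test.
"""

from __future__ import annotations

import math


def brute_connectivity(dist, labels, L):
    """Sum of reciprocal neighbor ranks for neighbors outside the cluster."""
    n = len(labels)
    L = min(L, n - 1)
    total = 0.0
    for i in range(n):
        others = sorted((j for j in range(n) if j != i),
                        key=lambda j: (dist[i][j], j))
        for rank, j in enumerate(others[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def brute_dunn(dist, labels):
    """min between-cluster distance / max within-cluster diameter."""
    clusters = sorted(set(labels))
    max_diam = 0.0
    for c in clusters:
        idx = [i for i, l in enumerate(labels) if l == c]
        for a in idx:
            for b in idx:
                max_diam = max(max_diam, dist[a][b])
    min_inter = math.inf
    for ca in clusters:
        for cb in clusters:
            if ca >= cb:
                continue
            for a in (i for i, l in enumerate(labels) if l == ca):
                for b in (i for i, l in enumerate(labels) if l == cb):
                    min_inter = min(min_inter, dist[a][b])
    if max_diam == 0:
        return math.inf
    return min_inter / max_diam


def brute_silhouette(dist, labels):
    """Mean of (b - a)/max(a, b); singletons contribute 0."""
    n = len(labels)
    clusters = sorted(set(labels))
    widths = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i]]
        if len(own) == 1:
            widths.append(0.0)
            continue
        a = sum(dist[i][j] for j in own if j != i) / (len(own) - 1)
        b = math.inf
        for c in clusters:
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(dist[i][j] for j in members) / len(members))
        widths.append((b - a) / max(a, b))
    return sum(widths) / n


def brute_bh(p_values):
    """Benjamini–Hochberg step-up from the definition:
    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1, in input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q[i] = min(running, 1.0)
    return q


def brute_hypergeom_tail(n_universe, n_set, n_input, n_overlap):
    """P[X >= n_overlap] by exact enumeration of all overlap counts."""
    total = math.comb(n_universe, n_input)
    acc = 0
    for x in range(n_overlap, min(n_set, n_input) + 1):
        if n_input - x > n_universe - n_set:
            continue
        acc += math.comb(n_set, x) * math.comb(n_universe - n_set, n_input - x)
    return acc / total


def brute_pathway_edges(genes_of, edge_min):
    """All-pairs scan for overlap-fraction edges between gene sets."""
    ids = sorted(genes_of)
    edges = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            smaller = min(len(genes_of[a]), len(genes_of[b]))
            if smaller == 0:
                continue
            if len(genes_of[a] & genes_of[b]) / smaller >= edge_min:
                edges.add(frozenset((a, b)))
    return edges


def brute_module_edges(input_genes, edges, kind, confidence_min):
    """Edge filter for induced modules, straight from the induction rule."""
    inp = set(input_genes)
    kept = []
    for e in edges:
        if e.kind != kind or e.confidence < confidence_min:
            continue
        if kind == "ppi":
            if e.source in inp and e.target in inp:
                kept.append((e.source, e.target))
        else:
            if e.target in inp:
                kept.append((e.source, e.target))
    return kept
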