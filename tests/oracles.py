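"""Independent reference implementations used to cross-check the package.

These are deliberately written with different structures (plain Python
loops, union-find, saturation iteration) than the implementations they
verify.
"""

import math


def brute_force_labels(genes, hits, seeds, params):
    """Saturate the within-window weak-hit relation with no ordering
    assumptions; returns the set of labeled protein ids."""
    eligible = {h.protein_id for h in hits if h.e_value <= params.weak_e_max}
    index = {g.protein_id: (g.replicon_id, g.gene_index) for g in genes}
    labeled = set(seeds)
    changed = True
    while changed:
        changed = False
        for g in genes:
            if g.protein_id in labeled or g.protein_id not in eligible:
                continue
            rid, gi = index[g.protein_id]
            for q in labeled:
                qrid, qi = index[q]
                if qrid == rid and abs(qi - gi) <= params.window:
                    labeled.add(g.protein_id)
                    changed = True
                    break
    return labeled


def naive_mcl(graph, inflation=1.4, prune=1e-5, conv=1e-8, max_iter=100):
    """Reference Markov clustering with plain Python list matrices."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    pos = {v: i for i, v in enumerate(nodes)}
    mat = [[0.0] * n for _ in range(n)]
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        mat[pos[a]][pos[b]] = w
        mat[pos[b]][pos[a]] = w
    for i in range(n):
        col = [mat[r][i] for r in range(n)]
        mat[i][i] = max(col) if max(col) > 0 else 1.0
    for i in range(n):
        total = sum(mat[r][i] for r in range(n))
        for r in range(n):
            mat[r][i] /= total
    for _ in range(max_iter):
        sq = [[sum(mat[r][k] * mat[k][c] for k in range(n)) for c in range(n)]
              for r in range(n)]
        infl = [[sq[r][c] ** inflation for c in range(n)] for r in range(n)]
        for r in range(n):
            for c in range(n):
                if infl[r][c] < prune:
                    infl[r][c] = 0.0
        for c in range(n):
            total = sum(infl[r][c] for r in range(n)) or 1.0
            for r in range(n):
                infl[r][c] /= total
        delta = max(abs(infl[r][c] - mat[r][c]) for r in range(n) for c in range(n))
        mat = infl
        if delta < conv:
            break
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for r in range(n):
        for c in range(n):
            if mat[r][c] > prune:
                parent[find(r)] = find(c)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(nodes[i])
    return sorted(groups.values(), key=lambda s: sorted(s)[0])


def partition_key(clusters):
    return sorted(tuple(sorted(c)) for c in clusters)
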