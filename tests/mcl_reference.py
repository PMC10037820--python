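"""Independent dense Markov-clustering reference for cross-checking.

Same algorithm definition as the package implementation (self-loops at
each vertex's maximum incident weight, expansion by matrix squaring,
entrywise inflation, pruning, attractor-based cluster reading with the
same tie rules) but written from scratch in plain Python lists so that
a bug in the numpy implementation cannot hide in its oracle.
"""

from __future__ import annotations


def _normalize_columns(M, n):
    for j in range(n):
        s = sum(M[i][j] for i in range(n))
        if s == 0.0:
            M[j][j] = 1.0
            s = 1.0
        for i in range(n):
            M[i][j] /= s


def mcl_reference(nodes, edges, inflation=2.0, eps=1e-6, max_iter=100, tol=1e-8):
    """Cluster an undirected weighted graph by plain-Python MCL.

    nodes: iterable of hashable vertex labels.
    edges: mapping (u, v) -> weight (one direction suffices).
    Returns a set of frozensets partitioning the vertices.
    """
    order = sorted(nodes)
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    A = [[0.0] * n for _ in range(n)]
    for (u, v), w in edges.items():
        if u == v:
            continue
        A[idx[u]][idx[v]] = A[idx[v]][idx[u]] = float(w)
    for i in range(n):
        mx = max(A[j][i] for j in range(n))
        A[i][i] = mx if mx > 0 else 1.0

    M = [row[:] for row in A]
    _normalize_columns(M, n)
    for _ in range(max_iter):
        # expansion: one matrix squaring
        M2 = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)] for i in range(n)]
        # inflation + pruning
        for i in range(n):
            for j in range(n):
                x = M2[i][j] ** inflation
                M2[i][j] = x if x >= eps else 0.0
        _normalize_columns(M2, n)
        delta = max(abs(M2[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = M2
        if delta < tol:
            break

    attractors = [i for i in range(n) if M[i][i] > eps]
    if not attractors:
        attractors = sorted({max(range(n), key=lambda i: M[i][j]) for j in range(n)})
    att_set = set(attractors)

    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # attractor systems join through attractor columns only; overlapping
    # non-attractor vertices are resolved by the flow rule below
    for j in attractors:
        support = [a for a in attractors if M[a][j] > eps]
        for a, b in zip(support, support[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    clusters = {}
    for j in range(n):
        flows = {}
        for a in attractors:
            if M[a][j] > 0.0:
                key = find(a)
                flows[key] = flows.get(key, 0.0) + M[a][j]
        if not flows:
            best_row = max(range(n), key=lambda i: M[i][j])
            flows = {find(best_row) if best_row in att_set else -(j + 1): 1.0}
        top = max(flows.values())
        key = min(k for k, v in flows.items() if v >= top - 1e-9)
        clusters.setdefault(key, set()).add(order[j])
    return {frozenset(c) for c in clusters.values()}
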