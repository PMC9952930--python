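"""Independent dense Markov-clustering reference, written without numpy.

Used as the second route of a dual-route check of the package's MCL: plain
dict/list matrix arithmetic, same algorithm definition (expansion by matrix
power, inflation by elementwise power with column renormalization, pruning,
attractor extraction with largest-flow assignment and lexicographic ties).
"""

from __future__ import annotations


def _matmul(A: list[list[float]], B: list[list[float]]) -> list[list[float]]:
    n = len(A)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        Ai = A[i]
        for k in range(n):
            a = Ai[k]
            if a == 0.0:
                continue
            Bk = B[k]
            Oi = out[i]
            for j in range(n):
                Oi[j] += a * Bk[j]
    return out


def reference_mcl(
    nodes: list[str],
    edges: list[tuple[str, str, float]],
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 200,
    prune: float = 1e-6,
) -> list[list[str]]:
    order = sorted(set(nodes) | {x for e in edges for x in e[:2]}, key=str)
    if not order:
        return []
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    W = [[0.0] * n for _ in range(n)]
    for a, b, w in edges:
        if a == b or w <= 0:
            continue
        i, j = idx[a], idx[b]
        W[i][j] = max(W[i][j], float(w))
        W[j][i] = max(W[j][i], float(w))
    for i in range(n):
        m = max(W[i])
        W[i][i] = m if m > 0 else 1.0

    # column-normalize
    def normalize(M):
        for j in range(n):
            s = sum(M[i][j] for i in range(n))
            if s == 0:
                M[j][j] = 1.0
                s = 1.0
            for i in range(n):
                M[i][j] /= s
        return M

    M = normalize([row[:] for row in W])
    for _ in range(max_iter):
        prev = [row[:] for row in M]
        # expansion: matrix power of the current flow matrix
        R = prev
        for _ in range(expansion - 1):
            R = _matmul(R, prev)
        M = R
        for i in range(n):
            for j in range(n):
                M[i][j] = M[i][j] ** inflation
        M = normalize(M)
        # prune relative to the renormalized column, then renormalize again
        for i in range(n):
            for j in range(n):
                if M[i][j] < prune:
                    M[i][j] = 0.0
        M = normalize(M)
        delta = max(abs(M[i][j] - prev[i][j]) for i in range(n) for j in range(n))
        if delta < 1e-8:
            break

    attractors = [i for i in range(n) if M[i][i] > prune]
    if not attractors:
        attractors = list(range(n))
    clusters: dict[int, list[str]] = {}
    for j in range(n):
        best = max(M[i][j] for i in attractors)
        if best <= 0:
            owner = j
        else:
            tied = [i for i in attractors if M[i][j] >= best - 1e-12]
            owner = min(tied, key=lambda i: str(order[i]))
        clusters.setdefault(owner, []).append(order[j])
    return [sorted(clusters[a]) for a in sorted(clusters, key=lambda i: str(order[i]))]
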