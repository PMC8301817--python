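"""Independent reference implementations used as test oracles.

Deliberately written with plain dense numpy and explicit loops, sharing
no code with the package implementations they check.
"""

import numpy as np


def dense_mcl_oracle(nodes, weighted_edges, inflation, expansion=2,
                     prune=1e-6, eps=1e-8, max_iter=200):
    """Dense-matrix MCL reference: returns a node -> cluster map.

    Same canonical update (self-loops = max incident weight, column
    normalization, expansion by matrix power, entrywise inflation,
    pruning) coded independently against numpy arrays.
    """
    nodes = sorted(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b, w in weighted_edges:
        A[index[a], index[b]] = w
        A[index[b], index[a]] = w
    loops = A.max(axis=1)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(A, loops)

    def colnorm(M):
        s = M.sum(axis=0)
        s[s == 0] = 1.0
        return M / s

    M = colnorm(A)
    for _ in range(max_iter):
        prev = M.copy()
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        M[M < prune] = 0.0
        M = colnorm(M)
        if np.abs(M - prev).max() < eps:
            break

    cluster_of = {}
    next_cluster = 0
    for i in range(n):
        if M[i, i] <= prune:
            continue
        members = [j for j in range(n) if M[i, j] > 0]
        taken = [cluster_of[nodes[j]] for j in members
                 if nodes[j] in cluster_of]
        fresh = [j for j in members if nodes[j] not in cluster_of]
        if not fresh:
            continue
        cid = min(taken) if taken else next_cluster
        if not taken:
            next_cluster += 1
        for j in fresh:
            cluster_of[nodes[j]] = cid
    for j in range(n):
        if nodes[j] in cluster_of:
            continue
        col = M[:, j]
        if col.max() > 0 and nodes[int(col.argmax())] in cluster_of:
            cluster_of[nodes[j]] = cluster_of[nodes[int(col.argmax())]]
        else:
            cluster_of[nodes[j]] = next_cluster
            next_cluster += 1
    return cluster_of


def ari_contingency_oracle(labels_a, labels_b):
    """Adjusted Rand index from the contingency-table closed form."""
    from math import comb
    a_classes = sorted(set(labels_a))
    b_classes = sorted(set(labels_b))
    table = np.zeros((len(a_classes), len(b_classes)), dtype=int)
    for x, y in zip(labels_a, labels_b):
        table[a_classes.index(x), b_classes.index(y)] += 1
    sum_ij = sum(comb(int(v), 2) for v in table.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    n = len(labels_a)
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def partitions_equivalent(map_a, map_b):
    """True iff two cluster maps induce the same set partition."""
    def blocks(m):
        out = {}
        for k, v in m.items():
            out.setdefault(v, set()).add(k)
        return {frozenset(s) for s in out.values()}
    return blocks(map_a) == blocks(map_b)
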