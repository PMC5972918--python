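"""Independent brute-force reference implementations used only by tests.

Deliberately written as plain nested loops over Python sets and floats,
sharing no code with the package, so agreement is a meaningful check.
"""

import math


def brute_distance(row_i, row_j, metric="euclidean", p=2.0):
    if metric == "euclidean":
        p = 2.0
    elif metric == "manhattan":
        p = 1.0
    total = 0.0
    for a, b in zip(row_i, row_j):
        total += abs(a - b) ** p
    return total ** (1.0 / p)


def brute_neighborhoods(matrix, beta, metric="euclidean", p=2.0):
    n = len(matrix)
    nbrs = []
    for i in range(n):
        s = set()
        for j in range(n):
            if brute_distance(matrix[i], matrix[j], metric, p) <= beta:
                s.add(j)
        nbrs.append(s)
    return nbrs


def brute_regions(matrix, labels, beta, metric="euclidean", p=2.0):
    """Lower/upper approximations and all derived measures, by enumeration."""
    n = len(matrix)
    nbrs = brute_neighborhoods(matrix, beta, metric, p)
    classes = sorted(set(labels), key=str)
    lower, upper = {}, {}
    for c in classes:
        members = {i for i in range(n) if labels[i] == c}
        lower[c] = {i for i in range(n) if nbrs[i] <= members}
        upper[c] = {i for i in range(n) if nbrs[i] & members}
    pos = set().union(*lower.values())
    upper_union = set().union(*upper.values())
    boundary = upper_union - pos
    rho = len(pos) / len(upper_union)
    r = 1.0 - rho
    K = r * len(pos) / n
    return {
        "lower": lower, "upper": upper, "pos": pos, "boundary": boundary,
        "negative": set(range(n)) - upper_union,
        "rho": rho, "roughness": r, "K": K, "K_classic": len(pos) / n,
    }


def brute_dependency(matrix, labels, cols, beta, metric="euclidean", p=2.0,
                     variant="paper"):
    """K(B, D) for the attribute subset given as 0-based column positions."""
    if not cols:
        return 0.0
    sub = [[row[c] for c in cols] for row in matrix]
    res = brute_regions(sub, labels, beta, metric, p)
    return res["K"] if variant == "paper" else res["K_classic"]


def brute_total_scatter(matrix):
    """Total scatter Sum_j (x_j - mu)(x_j - mu)^T as nested lists."""
    n = len(matrix)
    T = len(matrix[0])
    mu = [sum(row[t] for row in matrix) / n for t in range(T)]
    S = [[0.0] * T for _ in range(T)]
    for row in matrix:
        d = [row[t] - mu[t] for t in range(T)]
        for a in range(T):
            for b in range(T):
                S[a][b] += d[a] * d[b]
    return S
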