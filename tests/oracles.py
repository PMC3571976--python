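"""Independent straight-line reference implementations used as test oracles.

Everything here is deliberately scalar pure Python (loops, no numpy
vectorization) and shares no code path with the package internals.
"""

from __future__ import annotations

import itertools


def mismatch(x, h) -> int:
    assert len(x) == len(h)
    return sum(1 for a, b in zip(x, h) if a != b)


def membership_column(distances, alpha):
    """Fuzzy membership of one object against k centers, from its k
    distances.  Zero distance wins outright (lowest index on ties)."""
    k = len(distances)
    if any(d == 0 for d in distances):
        winner = min(l for l in range(k) if distances[l] == 0)
        return [1.0 if l == winner else 0.0 for l in range(k)]
    exp = 1.0 / (alpha - 1.0)
    col = []
    for l in range(k):
        denom = sum((distances[l] / distances[z]) ** exp for z in range(k))
        col.append(1.0 / denom)
    return col


def membership(distance_matrix, alpha):
    """k x n membership as list of columns transposed back to rows."""
    k = len(distance_matrix)
    n = len(distance_matrix[0])
    cols = [membership_column([distance_matrix[l][i] for l in range(k)], alpha)
            for i in range(n)]
    return [[cols[i][l] for i in range(n)] for l in range(k)]


def dominant(w):
    k, n = len(w), len(w[0])
    d = [[0.5] * n for _ in range(k)]
    for i in range(n):
        best = max(range(k), key=lambda l: (w[l][i], -l))
        d[best][i] = 1.0
    return d


def cost(w, d):
    total = 0.0
    for row_w, row_d in zip(w, d):
        for a, b in zip(row_w, row_d):
            total += a * b
    return total


def set_cost(values, centroid_rows, alpha):
    """Full model cost of a centroid set given raw token rows."""
    dmat = [[mismatch(values[i], h) for i in range(len(values))]
            for h in centroid_rows]
    w = membership(dmat, alpha)
    return cost(w, dominant(w))


def exhaustive_best(values, k, alpha):
    """Max cost over every size-k subset of objects used as centers;
    returns (best_cost, best_indices)."""
    best_cost, best_idx = -1.0, None
    for idx in itertools.combinations(range(len(values)), k):
        c = set_cost(values, [values[i] for i in idx], alpha)
        if c > best_cost:
            best_cost, best_idx = c, idx
    return best_cost, best_idx


def exhaustive_labels(values, k, alpha):
    """Crisp labels under the exhaustive-best centroid set."""
    _, idx = exhaustive_best(values, k, alpha)
    dmat = [[mismatch(values[i], values[c]) for i in range(len(values))]
            for c in idx]
    w = membership(dmat, alpha)
    return [max(range(k), key=lambda l: (w[l][i], -l))
            for i in range(len(values))]
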