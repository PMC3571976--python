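"""Mathematical core of the k-AMH model.

The model scores a set of k candidate centers (Approximate Modal
Haplotypes, always actual data objects) against all n objects through
four pieces, applied in order:

1. simple-matching distance between objects and centers;
2. a fuzzy partition matrix W (k x n) — the standard Fuzzy-k-Modes
   membership with fuzziness exponent alpha > 1;
3. a dominant-weighting matrix D (k x n) giving each object weight 1.0
   in its best cluster and 0.5 in every other;
4. the cost P = sum(W * D), which the search procedure *maximizes*.

All matrices are row-major k x n.  Every argmax tie breaks to the
lowest cluster index, everywhere, so results are deterministic.
"""

from __future__ import annotations

import numpy as np


def mismatch_distance(x, h) -> int:
    """Simple-matching distance: number of marker positions at which two
    haplotypes carry different allele tokens.  Symmetric, in [0, m]."""
    x = np.asarray(x)
    h = np.asarray(h)
    if x.shape != h.shape or x.ndim != 1:
        raise ValueError(f"haplotype length mismatch: {x.shape} vs {h.shape}")
    return int(np.sum(x != h))


def pairwise_mismatch(codes: np.ndarray, chunk: int = 512) -> np.ndarray:
    """n x n matrix of simple-matching distances between all object pairs.

    ``codes`` is the integer-encoded n x m token matrix.  Computed in row
    chunks to bound the broadcast temporary on large n.
    """
    n = codes.shape[0]
    out = np.empty((n, n), dtype=np.int32)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        out[start:stop] = (
            codes[start:stop, None, :] != codes[None, :, :]
        ).sum(axis=2)
    return out


def distances_to_centroids(codes: np.ndarray, centroid_codes: np.ndarray) -> np.ndarray:
    """k x n distance matrix from integer-encoded rows to k centroid rows."""
    return (centroid_codes[:, None, :] != codes[None, :, :]).sum(axis=2)


def membership_matrix(distances: np.ndarray, alpha: float) -> np.ndarray:
    """Fuzzy partition matrix W from a k x n distance matrix.

    For an object i with all distances positive,

        W[l, i] = 1 / sum_z (d[l, i] / d[z, i]) ** (1 / (alpha - 1)),

    so each column sums to 1 and smaller distance means larger
    membership.  An object at distance zero from some center gets
    membership 1 there and 0 elsewhere; if several centers carry
    identical tokens, the lowest-index zero-distance cluster wins.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2:
        raise ValueError("distances must be a k x n matrix")
    if not alpha > 1:
        raise ValueError(f"alpha must be > 1, got {alpha}")
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")

    k, n = d.shape
    exponent = 1.0 / (alpha - 1.0)
    with np.errstate(divide="ignore"):
        inv = d ** (-exponent)          # inf where d == 0
    zero_cols = np.isinf(inv).any(axis=0)
    w = np.empty_like(d)
    if (~zero_cols).any():
        cols = ~zero_cols
        w[:, cols] = inv[:, cols] / inv[:, cols].sum(axis=0)
    if zero_cols.any():
        w[:, zero_cols] = 0.0
        first_zero = np.argmax(d[:, zero_cols] == 0, axis=0)
        w[first_zero, np.nonzero(zero_cols)[0]] = 1.0
    return w


def dominant_matrix(w: np.ndarray) -> np.ndarray:
    """Dominant-weighting matrix D: per object column, 1.0 for the cluster
    with maximal membership (ties to the lowest index), 0.5 elsewhere.
    Every column sums to (k + 1) / 2."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2:
        raise ValueError("membership must be a k x n matrix")
    k, n = w.shape
    d = np.full((k, n), 0.5)
    d[np.argmax(w, axis=0), np.arange(n)] = 1.0
    return d


def cost(w: np.ndarray, d: np.ndarray, exponent: float | None = None) -> float:
    """Cost P = sum over clusters and objects of W * D (maximized by the
    search).  ``exponent`` optionally raises W to a power first — a
    sensitivity handle, off by default."""
    w = np.asarray(w, dtype=float)
    d = np.asarray(d, dtype=float)
    if w.shape != d.shape:
        raise ValueError(f"shape mismatch: W {w.shape} vs D {d.shape}")
    if exponent is not None:
        w = w ** exponent
    return float((w * d).sum())


def crisp_assign(w: np.ndarray) -> np.ndarray:
    """Crisp labels: per object, the cluster of maximal membership
    (ties to the lowest cluster index)."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2:
        raise ValueError("membership must be a k x n matrix")
    return np.argmax(w, axis=0)


def derive_seeds(seed: int | None, count: int) -> list[int]:
    """Derive ``count`` independent 31-bit child seeds from a master seed."""
    state = np.random.SeedSequence(seed).generate_state(count, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]
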