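"""Hard k-Modes and Fuzzy k-Modes baselines.

Both algorithms alternate a partition update with a per-column mode
(most frequent token) update, minimizing the total simple-matching
dissimilarity between objects and their cluster modes.  They are the
classical references that the medoid-style k-AMH search is benchmarked
against: their constructed modes need not be any observed haplotype,
which is exactly what makes them fragile on tables full of nearly
identical rows (non-unique centroids, empty clusters, local minima).

Mode ties break to the lexicographically smallest token and assignment
ties to the lowest cluster index, so runs are deterministic given a seed.
"""

from __future__ import annotations

import logging

import numpy as np

from .algorithm import ClusteringResult, init_centroids
from .core import crisp_assign, distances_to_centroids, membership_matrix
from .ystr_io import HaplotypeDataset

logger = logging.getLogger(__name__)


def _weighted_modes(
    codes: np.ndarray,
    weights: np.ndarray,
    domain_sizes: list[int],
) -> np.ndarray:
    """Per cluster and column, the token code with maximal total weight.

    ``weights`` is k x n.  np.argmax returns the first (smallest) code on
    ties; codes are in lexicographic token order, so ties break to the
    lexicographically smallest token.
    """
    k = weights.shape[0]
    m = codes.shape[1]
    modes = np.empty((k, m), dtype=np.int64)
    for l in range(k):
        for j in range(m):
            counts = np.bincount(codes[:, j], weights=weights[l],
                                 minlength=domain_sizes[j])
            modes[l, j] = int(np.argmax(counts))
    return modes


def _decode_modes(dataset: HaplotypeDataset, mode_codes: np.ndarray) -> np.ndarray:
    """Map mode code rows back to token strings."""
    domains = dataset.token_domains
    return np.array(
        [[domains[j][mode_codes[l, j]] for j in range(len(domains))]
         for l in range(mode_codes.shape[0])],
        dtype=object,
    )


def kmodes_fit(
    dataset: HaplotypeDataset,
    k: int,
    seed: int | None = None,
    max_iter: int = 100,
) -> ClusteringResult:
    """Hard k-Modes: crisp assignment to the nearest mode, then per-column
    plurality mode update, until labels stop changing.

    The within-cluster cost is non-increasing across iterations except
    when an emptied cluster is re-seeded from the worst-fit object
    (logged when it happens).
    """
    n = dataset.n_objects
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    codes = dataset.codes
    domain_sizes = [len(d) for d in dataset.token_domains]
    modes = codes[list(init_centroids(dataset, k, rng).indices)].copy()

    labels = None
    objective = np.inf
    trace: list[float] = []
    for iteration in range(1, max_iter + 1):
        dist = distances_to_centroids(codes, modes)
        new_labels = np.argmin(dist, axis=0)
        per_object = dist[new_labels, np.arange(n)]
        for l in range(k):
            if not (new_labels == l).any():
                worst = int(np.argmax(per_object))
                logger.warning("k-Modes: cluster %d empty, re-seeding from "
                               "worst-fit object %d", l, worst)
                modes[l] = codes[worst]
                new_labels[worst] = l
                per_object[worst] = 0
        objective = float(per_object.sum())
        trace.append(objective)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        onehot = np.zeros((k, n))
        onehot[labels, np.arange(n)] = 1.0
        modes = _weighted_modes(codes, onehot, domain_sizes)

    membership = np.zeros((k, n))
    membership[labels, np.arange(n)] = 1.0
    return ClusteringResult(
        labels=labels,
        membership=membership,
        final_cost=objective,
        seed=seed,
        algorithm="kmodes",
        modes=_decode_modes(dataset, modes),
        n_iter=iteration,
        cost_trace=trace,
        ids=dataset.ids,
    )


def fuzzy_kmodes_fit(
    dataset: HaplotypeDataset,
    k: int,
    alpha: float = 1.5,
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> ClusteringResult:
    """Fuzzy k-Modes: alternate the fuzzy membership update with a
    w**alpha-weighted per-column mode update until the objective
    P(W, Z) = sum w**alpha * d stops decreasing.

    The objective sequence is non-increasing; iteration stops when the
    decrease falls below ``tol`` or ``max_iter`` is reached.  A cluster
    whose total membership weight collapses to zero is re-seeded from
    the worst-fit object (logged).
    """
    n = dataset.n_objects
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if not alpha > 1:
        raise ValueError(f"alpha must be > 1, got {alpha}")
    rng = np.random.default_rng(seed)
    codes = dataset.codes
    domain_sizes = [len(d) for d in dataset.token_domains]
    modes = codes[list(init_centroids(dataset, k, rng).indices)].copy()

    previous = np.inf
    trace: list[float] = []
    w = None
    for iteration in range(1, max_iter + 1):
        dist = distances_to_centroids(codes, modes)
        w = membership_matrix(dist, alpha)
        weights = w ** alpha
        objective = float((weights * dist).sum())
        trace.append(objective)
        if previous - objective < tol:
            break
        previous = objective
        row_weight = weights.sum(axis=1)
        if (row_weight == 0).any():
            per_object = dist.min(axis=0)
            for l in np.nonzero(row_weight == 0)[0]:
                worst = int(np.argmax(per_object))
                logger.warning("Fuzzy k-Modes: cluster %d has zero weight, "
                               "re-seeding from object %d", l, worst)
                modes[l] = codes[worst]
                per_object[worst] = 0
            continue
        modes = _weighted_modes(codes, weights, domain_sizes)

    return ClusteringResult(
        labels=crisp_assign(w),
        membership=w,
        final_cost=trace[-1],
        seed=seed,
        algorithm="fuzzy-kmodes",
        alpha=alpha,
        modes=_decode_modes(dataset, modes),
        n_iter=iteration,
        cost_trace=trace,
        ids=dataset.ids,
    )
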