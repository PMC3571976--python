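"""The k-AMH driver: greedy medoid-style search maximizing the cost P.

k initial centers are drawn at random from the data, then every
non-center object is tried, one by one, as a replacement for each
cluster's center.  A candidate is accepted iff it strictly increases
the cost, so the sequence of accepted costs is strictly increasing and
the procedure cannot cycle.  The scan is cluster-major with the inner
loop in dataset order; one full sweep performs exactly k*(n-k)
candidate evaluations when nothing is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    cost,
    crisp_assign,
    derive_seeds,
    distances_to_centroids,
    dominant_matrix,
    membership_matrix,
    pairwise_mismatch,
)
from .ystr_io import HaplotypeDataset


@dataclass(frozen=True)
class CentroidSet:
    """k distinct object indices plus copies of their token vectors."""

    indices: tuple[int, ...]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("centroid indices must be distinct")
        if len(self.indices) < 1:
            raise ValueError("need at least one centroid")

    @property
    def k(self) -> int:
        return len(self.indices)


@dataclass
class ClusteringResult:
    """Output of one clustering run (any algorithm in this package)."""

    labels: np.ndarray
    membership: np.ndarray
    final_cost: float
    seed: int | None
    algorithm: str
    alpha: float | None = None
    centroid_indices: tuple[int, ...] | None = None
    modes: np.ndarray | None = None
    replacements: int = 0
    sweeps_run: int = 0
    n_iter: int = 0
    initial_cost: float | None = None
    cost_trace: list[float] = field(default_factory=list)
    candidate_evaluations: int = 0
    ids: tuple[str, ...] | None = None

    @property
    def k(self) -> int:
        return self.membership.shape[0]


def init_centroids(
    dataset: HaplotypeDataset, k: int, rng: np.random.Generator
) -> CentroidSet:
    """Draw k distinct objects uniformly without replacement."""
    n = dataset.n_objects
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    indices = tuple(int(i) for i in rng.choice(n, size=k, replace=False))
    return CentroidSet(indices=indices, haplotypes=dataset.values[list(indices)])


def _cost_from_rows(
    pairwise: np.ndarray,
    indices: np.ndarray,
    alpha: float,
    cost_exponent: float | None,
) -> float:
    w = membership_matrix(pairwise[indices], alpha)
    return cost(w, dominant_matrix(w), exponent=cost_exponent)


def evaluate_candidate(
    dataset: HaplotypeDataset,
    centroids: CentroidSet,
    cluster: int,
    candidate: int,
    alpha: float = 1.5,
    cost_exponent: float | None = None,
) -> float:
    """Full cost of the centroid set with cluster ``cluster``'s center
    provisionally replaced by object ``candidate``.

    Distances, memberships and dominant weights are recomputed over all
    k clusters and n objects.  The candidate must not currently serve as
    any cluster's center.
    """
    if candidate in centroids.indices:
        raise ValueError(f"object {candidate} is already a centroid")
    if not 0 <= cluster < centroids.k:
        raise ValueError(f"cluster index {cluster} out of range")
    indices = list(centroids.indices)
    indices[cluster] = candidate
    codes = dataset.codes
    d = distances_to_centroids(codes, codes[indices])
    w = membership_matrix(d, alpha)
    return cost(w, dominant_matrix(w), exponent=cost_exponent)


def fit_kamh(
    dataset: HaplotypeDataset,
    k: int,
    alpha: float = 1.5,
    seed: int | None = None,
    max_sweeps: int = 1,
    init_indices: tuple[int, ...] | None = None,
    cost_exponent: float | None = None,
) -> ClusteringResult:
    """Run k-AMH once and return labels, memberships and run metadata.

    ``max_sweeps`` caps how many full (cluster, object) passes are made;
    the default single sweep matches the O(km(n-k)) complexity of the
    base procedure.  Extra sweeps stop early once a sweep accepts no
    replacement.  ``init_indices`` overrides the random initial draw
    (used by exhaustive-initialization studies).
    """
    n = dataset.n_objects
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    if init_indices is None:
        indices = np.asarray(init_centroids(dataset, k, rng).indices)
    else:
        if len(set(init_indices)) != k:
            raise ValueError("init_indices must be k distinct object indices")
        indices = np.asarray(init_indices, dtype=np.int64)

    pw = pairwise_mismatch(dataset.codes)
    is_centroid = np.zeros(n, dtype=bool)
    is_centroid[indices] = True

    current = _cost_from_rows(pw, indices, alpha, cost_exponent)
    initial_cost = current
    trace = [current]
    replacements = 0
    evaluations = 0
    sweeps_run = 0

    for _ in range(max_sweeps):
        sweeps_run += 1
        accepted_this_sweep = False
        for l in range(k):
            for i in range(n):
                if is_centroid[i]:
                    continue
                evaluations += 1
                candidate = indices.copy()
                candidate[l] = i
                value = _cost_from_rows(pw, candidate, alpha, cost_exponent)
                if value > current:
                    is_centroid[indices[l]] = False
                    is_centroid[i] = True
                    indices = candidate
                    current = value
                    trace.append(value)
                    replacements += 1
                    accepted_this_sweep = True
        if not accepted_this_sweep:
            break

    w = membership_matrix(pw[indices], alpha)
    final_cost = cost(w, dominant_matrix(w), exponent=cost_exponent)
    return ClusteringResult(
        labels=crisp_assign(w),
        membership=w,
        final_cost=final_cost,
        seed=seed,
        algorithm="kamh",
        alpha=alpha,
        centroid_indices=tuple(int(i) for i in indices),
        replacements=replacements,
        sweeps_run=sweeps_run,
        initial_cost=initial_cost,
        cost_trace=trace,
        candidate_evaluations=evaluations,
        ids=dataset.ids,
    )


def multi_restart(
    dataset: HaplotypeDataset,
    k: int,
    alpha: float = 1.5,
    n_restarts: int = 1,
    seed: int | None = None,
    **fit_kwargs,
) -> tuple[ClusteringResult, list[ClusteringResult]]:
    """Run k-AMH ``n_restarts`` times from independent derived seeds.

    Returns the run with maximal final cost (ties to the earliest run)
    together with the full run list, so callers can both pick a best
    partition and average accuracies across runs.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    runs = [
        fit_kamh(dataset, k, alpha=alpha, seed=child, **fit_kwargs)
        for child in derive_seeds(seed, n_restarts)
    ]
    best = max(runs, key=lambda r: r.final_cost)
    return best, runs
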