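"""Clustering accuracy, multi-run benchmarking and the scale harness.

Accuracy follows the misclassification-matrix convention: build the
k x c cluster-by-class contingency table, match clusters to classes
one-to-one so that the total matched count is maximal (Hungarian
assignment; unmatched clusters contribute nothing when k != c), and
report r = matched / n.  A simpler greedy majority-vote matching is
available for comparison; being one-to-one as well, it never beats the
optimal matching.

The benchmarking protocol repeats fit-and-score over many runs, each on
a freshly shuffled copy of the dataset with its own derived seed, and
summarizes the per-run accuracies (mean, SD, 95% CI, min, max).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress

from .algorithm import fit_kamh
from .baselines import fuzzy_kmodes_fit, kmodes_fit
from .core import derive_seeds
from .synthetic import generate_surname_like
from .ystr_io import HaplotypeDataset


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy r plus the contingency matrix and mapping behind it."""

    r: float
    contingency: np.ndarray
    cluster_ids: tuple
    class_names: tuple
    mapping: dict

    def __float__(self) -> float:
        return self.r


def _contingency(labels_pred, labels_true):
    pred = np.asarray(labels_pred)
    true = np.asarray(labels_true)
    clusters, pred_idx = np.unique(pred, return_inverse=True)
    classes, true_idx = np.unique(true, return_inverse=True)
    table = np.zeros((len(clusters), len(classes)), dtype=np.int64)
    np.add.at(table, (pred_idx, true_idx), 1)
    return table, tuple(clusters.tolist()), tuple(classes.tolist())


def accuracy(
    labels_pred,
    labels_true,
    mapping: str = "optimal",
) -> AccuracyReport:
    """Misclassification-matrix clustering accuracy.

    ``mapping="optimal"`` matches clusters to classes by maximum-weight
    one-to-one assignment; ``"greedy"`` lets clusters claim their
    majority class one at a time, each class at most once.
    """
    pred = np.asarray(labels_pred)
    true = np.asarray(labels_true)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-d and equal length: "
            f"{pred.shape} vs {true.shape}"
        )
    table, clusters, classes = _contingency(pred, true)
    n = int(table.sum())
    if mapping == "optimal":
        rows, cols = linear_sum_assignment(table, maximize=True)
        matched = int(table[rows, cols].sum())
        assignment = {clusters[r]: classes[c] for r, c in zip(rows, cols)}
    elif mapping == "greedy":
        # clusters claim their majority class one at a time (largest
        # majority first), each class usable once; never beats "optimal"
        order = np.argsort(-table.max(axis=1), kind="stable")
        free = set(range(table.shape[1]))
        matched = 0
        assignment = {}
        for r in order:
            if not free:
                break
            c = max(free, key=lambda j: (table[r, j], -j))
            matched += int(table[r, c])
            assignment[clusters[r]] = classes[c]
            free.remove(c)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return AccuracyReport(
        r=matched / n,
        contingency=table,
        cluster_ids=clusters,
        class_names=classes,
        mapping=assignment,
    )


@dataclass(frozen=True)
class RunSummary:
    """Descriptive statistics of per-run accuracies for one algorithm."""

    algorithm: str
    n_runs: int
    mean: float
    std: float
    ci_lower: float
    ci_upper: float
    min: float
    max: float
    best_run: float
    accuracies: tuple[float, ...]


def summarize(algorithm: str, accuracies) -> RunSummary:
    acc = np.asarray(list(accuracies), dtype=float)
    if acc.size == 0:
        raise ValueError("need at least one run")
    mean = float(acc.mean())
    std = float(acc.std(ddof=1)) if acc.size > 1 else 0.0
    half = 1.96 * std / np.sqrt(acc.size)
    return RunSummary(
        algorithm=algorithm,
        n_runs=int(acc.size),
        mean=mean,
        std=std,
        ci_lower=mean - half,
        ci_upper=mean + half,
        min=float(acc.min()),
        max=float(acc.max()),
        best_run=float(acc.max()),
        accuracies=tuple(acc.tolist()),
    )


#: Registry of fit callables usable by name in run_experiment / the CLI.
ALGORITHMS = {
    "kamh": lambda ds, k, alpha, seed: fit_kamh(ds, k, alpha=alpha, seed=seed),
    "kmodes": lambda ds, k, alpha, seed: kmodes_fit(ds, k, seed=seed),
    "fuzzy-kmodes": lambda ds, k, alpha, seed: fuzzy_kmodes_fit(
        ds, k, alpha=alpha, seed=seed),
}


def run_experiment(
    dataset: HaplotypeDataset,
    algorithms,
    n_runs: int = 100,
    seed: int | None = None,
    alpha: float = 1.5,
    k: int | None = None,
    mapping: str = "optimal",
) -> dict[str, RunSummary]:
    """Repeated fit-and-score benchmark on a labeled dataset.

    For each run the object order is reshuffled with a derived seed, the
    algorithm is fit with that same seed, and accuracy against the true
    labels is recorded.  All algorithms see identical shuffles, so their
    summaries are paired.
    """
    if dataset.labels is None:
        raise ValueError("run_experiment needs a dataset with class labels")
    if isinstance(algorithms, str):
        algorithms = [algorithms]
    for name in algorithms:
        if name not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {name!r}; "
                             f"choose from {sorted(ALGORITHMS)}")
    if k is None:
        k = len(set(dataset.labels))

    run_seeds = derive_seeds(seed, n_runs)
    scores: dict[str, list[float]] = {name: [] for name in algorithms}
    for run_seed in run_seeds:
        order = np.random.default_rng(run_seed).permutation(dataset.n_objects)
        shuffled = dataset.take(order)
        for name in algorithms:
            result = ALGORITHMS[name](shuffled, k, alpha, run_seed)
            report = accuracy(result.labels, shuffled.labels, mapping=mapping)
            scores[name].append(report.r)
    return {name: summarize(name, acc) for name, acc in scores.items()}


def summary_table(summaries: dict[str, RunSummary]) -> pd.DataFrame:
    """Benchmark summaries as a table (N, Mean, Std. Dev., CI, Min, Max)."""
    rows = [
        {
            "Algorithm": s.algorithm,
            "N": s.n_runs,
            "Mean": s.mean,
            "Std. Dev.": s.std,
            "CI Lower": s.ci_lower,
            "CI Upper": s.ci_upper,
            "Min": s.min,
            "Max": s.max,
        }
        for s in summaries.values()
    ]
    return pd.DataFrame(rows)


def scale_benchmark(
    n_grid,
    k_grid,
    m: int = 25,
    seed: int | None = None,
    alpha: float = 1.5,
) -> tuple[pd.DataFrame, dict]:
    """Measure candidate-evaluation counts and wall time across problem sizes.

    For every (n, k) in the grid product a synthetic surname-like dataset
    is generated and a single-sweep fit is timed.  Least-squares lines
    are fit to counts versus n (at the smallest k) and counts versus k
    (at the largest n); a sweep costs k*(n-k) evaluations plus a handful
    more after accepted replacements, so both relations are linear.
    """
    n_grid = list(n_grid)
    k_grid = list(k_grid)
    if not n_grid or not k_grid:
        raise ValueError("n_grid and k_grid must be nonempty")
    records = []
    cell_seeds = iter(derive_seeds(seed, len(n_grid) * len(k_grid)))
    for n in n_grid:
        for k in k_grid:
            cell_seed = next(cell_seeds)
            sizes = [n // k] * k
            sizes[0] += n - sum(sizes)
            data = generate_surname_like(k, sizes, m=m, seed=cell_seed)
            start = time.perf_counter()
            result = fit_kamh(data, k, alpha=alpha, seed=cell_seed,
                              max_sweeps=1)
            elapsed = time.perf_counter() - start
            records.append({
                "n": n, "k": k, "m": m,
                "evaluations": result.candidate_evaluations,
                "seconds": elapsed,
                "replacements": result.replacements,
            })
    table = pd.DataFrame(records)

    def _fit(x, y):
        if len(set(x)) < 2:
            return None
        reg = linregress(x, y)
        return {"slope": float(reg.slope), "intercept": float(reg.intercept),
                "r_squared": float(reg.rvalue ** 2)}

    vs_n = table[table["k"] == k_grid[0]]
    vs_k = table[table["n"] == n_grid[-1]]
    fits = {
        "evaluations_vs_n": _fit(vs_n["n"], vs_n["evaluations"]),
        "evaluations_vs_k": _fit(vs_k["k"], vs_k["evaluations"]),
        "seconds_vs_n": _fit(vs_n["n"], vs_n["seconds"]),
        "seconds_vs_k": _fit(vs_k["k"], vs_k["seconds"]),
    }
    return table, fits
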