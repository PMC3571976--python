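# Methods

## Model and procedure

k-AMH partitions n categorical objects (Y-STR haplotypes: vectors of
allele tokens over m markers) into k clusters whose centers are actual
data objects, not constructed modes. The pieces, in the order the
method runs:

1. **Distance.** Simple matching: `d(x, h)` counts marker positions
   where the tokens differ. Tokens are opaque, whitespace-trimmed
   strings; `"38.2"` and `"38"` simply differ. No stepwise/ordinal STR
   distance is offered — the model is purely categorical.
2. **Membership.** Given centers `H_1…H_k`, the fuzzy partition matrix
   is the standard fuzzy-k-modes membership
   `W_li = 1 / Σ_z (d_li/d_zi)^(1/(α−1))`; an object at distance 0 from
   some center has membership 1 there and 0 elsewhere. Columns sum to 1
   by construction. When duplicate token vectors make several centers
   distance-0 from an object, the lowest-index one takes the full
   membership, preserving normalization.
3. **Dominant weighting.** `D_li = 1.0` where cluster l holds object
   i's maximal membership, `0.5` otherwise; each column sums to
   `(k+1)/2`. All argmax ties — here, in crisp assignment and in the
   baselines — break to the lowest cluster index so that every run is
   a deterministic function of its seed.
4. **Cost and search.** `P = Σ W_li·D_li` is maximized by greedy
   first-improvement replacement: for each cluster in ascending order,
   each non-center object in dataset order is provisionally swapped in
   and kept iff the full recomputed cost strictly increases. Strict
   acceptance makes the accepted-cost sequence strictly increasing
   (hence no cycling) and means equal-cost candidates never displace an
   incumbent. Objects currently serving as any cluster's center are
   skipped; an object displaced mid-run becomes eligible again. A
   quiet sweep therefore performs exactly `k·(n−k)` candidate
   evaluations, and the per-sweep work is `O(k·m·(n−k))`.
5. **Output.** Labels are the per-object membership argmax; the result
   records centers, cost trace, replacement count and seed.

`W` enters the cost linearly. The membership expression already
carries the fuzziness exponent internally, and the search's
monotonicity argument operates on that form; an optional
`cost_exponent` can additionally raise `W` to a power inside the cost
for sensitivity checks, and is off by default.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | required | number of clusters; assumed known (no model selection) |
| `alpha` | 1.5 | fuzziness exponent, sensible in [1.1, 2.0]; larger values flatten memberships. 1.5 is the midpoint of that conventional range |
| `max_sweeps` | 1 | full (cluster, object) passes; the base procedure is a single pass, extra sweeps stop at the first quiet one |
| `n_restarts` | 1 | independent seeded restarts; the best-cost run is returned along with all runs |
| `seed` | None | master seed; restart and benchmark-run seeds are derived 31-bit children via `numpy.random.SeedSequence` |

## Baselines

Hard k-Modes and Fuzzy k-Modes minimize `Σ w_li^α d(X_i, Z_l)` by
alternating the partition update with a per-column (weighted) plurality
mode update. Both initialize from k random distinct objects, like
k-AMH, so comparisons isolate the center mechanism rather than the
initialization. Weighted-mode ties break to the lexicographically
smallest token. An emptied cluster (hard) or zero-weight cluster
(fuzzy) is re-seeded from the worst-fit object and logged; this is the
non-unique-centroid failure mode in action, and the only point where
the objective may momentarily rise. Frequency-spread ("diverse")
initialization variants from the wider k-Modes literature are out of
scope.

## Accuracy

`accuracy()` builds the k×c cluster-by-class contingency matrix and
matches clusters to classes **one-to-one** so the matched total is
maximal (Hungarian assignment, `scipy.optimize.linear_sum_assignment`);
unmatched clusters contribute 0 when k ≠ c, and `r = matched/n`. The
"corresponding class" of a cluster is not otherwise well defined; the
optimal matching is label-permutation invariant, which a plain
majority vote is not. A greedy one-to-one matching (largest majority
first) is available for comparison and is provably never better.
`run_experiment` repeats shuffle → fit → score with per-run derived
seeds (fresh object order *and* fresh centers each run) and reports
mean, sample SD, a normal-approximation 95% CI (`mean ± 1.96·sd/√runs`),
min and max. Inferential comparisons (ANOVA etc.) are out of scope.

## Synthetic data

The generators emulate the structure of real Y-STR project tables
rather than any mutational process:

- **surname-like**: k modal haplotypes at pairwise distance ≥
  `min_separation` (default m//2), each member mutated at j markers,
  j ~ `mismatch_probs` (default 0:0.4, 1:0.3, 2:0.2, 3:0.1 — most
  members match the modal haplotype exactly or at 1–3 markers);
- **haplogroup-like**: looser classes (default mismatch spread up to 5),
  optional sparse sub-lineages per class (sub-modes offset by
  ~divergence/3 markers), and skew expressed through `sizes` — e.g.
  sizes (24, 20, 200, 32, 475) put ~63% of objects in one class;
- **worked-example fixtures**: two tiny frozen tables. The first (9
  objects, 3 attributes, 3 classes) has globally dominant attributes
  that make plurality modes collide across classes; the second (8
  objects, classes sized 6 and 2) has a class holding 75% of objects.
  The underlying pictures are not machine-readable as data, so the
  token matrices are constructed once to satisfy every stated
  structural constraint (class modes, dominant attributes, sizes) and
  frozen, rather than sampled per run.

Tokens are integers-as-strings in a plausible allele range (8–40);
cosmetic only. What the generators do **not** reproduce: stepwise
mutation kinetics, marker-specific mutation rates, missing values, and
real inter-class distance profiles. Passing recovery tests on this
synthetic data therefore demonstrates correctness of the algorithms
under the modeled distance structure, not field accuracy on any real
project table (the original web-scraped tables have no accessions and
are not redistributable, so they are out of scope here).

## Numerical and design notes

- Distances are small integers; memberships use
  `d^(−1/(α−1))` normalized per column, with the zero-distance case
  handled exactly (no epsilon fudging).
- `evaluate_candidate` recomputes the full k×n membership and cost per
  candidate; `fit_kamh` precomputes the n×n pairwise distance matrix
  once (centers are data objects, so every candidate's distance row is
  a lookup). The n×n matrix is built in row chunks; memory is the
  practical ceiling (~4·n² bytes).
- Benchmark problem sizes in the tests (e.g. skewed 150-object tables,
  scale grids up to a few hundred objects) were chosen so the whole
  suite runs in seconds while still exercising hundreds of runs; the
  harness itself handles arbitrary sizes.
- CSV/TSV I/O goes through pandas with all cells read as strings;
  membership values are written with 10-decimal rounding so per-row
  sums still verify to 1e-9 on re-read.

## Known limitations

- Greedy first-improvement is order-dependent: permuting the dataset
  can change which local maximum a single run reaches (multi-restart
  exists for exactly this reason). What *is* order-invariant is the
  cost of any fixed center set, and labels under fixed-by-value
  centers permute with the rows.
- k is fixed a priori; there is no cluster-count selection.
- No missing-data model: incomplete rows are rejected (or dropped with
  `--drop-incomplete`).
- With k=1 every membership is 1 and all center choices tie, so the
  initial random center is retained by strict acceptance.
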