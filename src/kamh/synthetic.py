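"""Seeded generators for synthetic Y-STR-like categorical datasets.

Real Y-STR project tables have a characteristic shape: each class
(surname family group or haplogroup) clusters tightly around a modal
haplotype, most members matching it exactly or at 1-3 markers'
difference; class sizes are often heavily skewed (one haplogroup can
hold ~63-75% of a table); and surname tables are small with many
classes.  These generators reproduce that distance structure — modal
haplotypes with a controlled pairwise separation, per-object mismatch
counts drawn from an explicit distribution — without modelling the
mutational process itself (no stepwise mutation, no phylogeny).

Tokens are integers-as-strings in a plausible allele-repeat range
(8-40), purely cosmetic: every algorithm here treats them as opaque
categories.
"""

from __future__ import annotations

import numpy as np

from .core import mismatch_distance
from .ystr_io import CANONICAL_MARKERS, HaplotypeDataset

_ALLELE_LOW, _ALLELE_HIGH = 8, 41  # half-open; tokens are str(int)

#: Default per-object mismatch distribution for surname-like classes:
#: members match the modal haplotype at 0-3 markers, most at 0-1.
SURNAME_MISMATCH_PROBS = {0: 0.4, 1: 0.3, 2: 0.2, 3: 0.1}

#: Haplogroup-like classes are looser: similar, almost-similar and some
#: quite distant members.
HAPLOGROUP_MISMATCH_PROBS = {0: 0.2, 1: 0.2, 2: 0.2, 3: 0.15, 4: 0.15, 5: 0.1}


def _marker_names(m: int) -> tuple[str, ...]:
    if m <= len(CANONICAL_MARKERS):
        return CANONICAL_MARKERS[:m]
    return CANONICAL_MARKERS + tuple(
        f"M{j}" for j in range(len(CANONICAL_MARKERS), m)
    )


def _random_haplotype(m: int, rng: np.random.Generator) -> np.ndarray:
    return np.array(
        [str(v) for v in rng.integers(_ALLELE_LOW, _ALLELE_HIGH, size=m)],
        dtype=object,
    )


def _separated_haplotypes(
    count: int, m: int, min_separation: int, rng: np.random.Generator,
    max_tries: int = 2000,
) -> list[np.ndarray]:
    """Sample ``count`` haplotypes with pairwise distance >= min_separation."""
    if min_separation > m:
        raise ValueError(f"separation {min_separation} exceeds {m} markers")
    if min_separation < 1:
        raise ValueError("modal haplotypes must be distinct (separation >= 1)")
    modes: list[np.ndarray] = []
    for _ in range(max_tries):
        candidate = _random_haplotype(m, rng)
        if all(mismatch_distance(candidate, mode) >= min_separation
               for mode in modes):
            modes.append(candidate)
            if len(modes) == count:
                return modes
    raise ValueError(
        f"could not place {count} modal haplotypes at pairwise distance "
        f">= {min_separation} on {m} markers"
    )


def _mutate(
    haplotype: np.ndarray, n_mutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Copy with ``n_mutations`` distinct positions changed to new tokens."""
    out = haplotype.copy()
    positions = rng.choice(len(haplotype), size=n_mutations, replace=False)
    for j in positions:
        while True:
            token = str(rng.integers(_ALLELE_LOW, _ALLELE_HIGH))
            if token != haplotype[j]:
                out[j] = token
                break
    return out


def _normalize_probs(probs: dict[int, float], m: int) -> tuple[np.ndarray, np.ndarray]:
    counts = np.array(sorted(probs), dtype=np.int64)
    p = np.array([probs[c] for c in counts], dtype=float)
    if (counts < 0).any() or counts.max(initial=0) > m:
        raise ValueError("mismatch counts must lie in [0, m]")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("mismatch probabilities must sum to 1")
    return counts, p / p.sum()


def _build(
    class_modes: list[np.ndarray],
    class_names: list[str],
    sizes,
    probs: dict[int, float],
    m: int,
    rng: np.random.Generator,
    submodes_per_class: list[list[np.ndarray]] | None = None,
) -> HaplotypeDataset:
    counts, p = _normalize_probs(probs, m)
    values, labels, ids = [], [], []
    for c, (name, size) in enumerate(zip(class_names, sizes)):
        anchors = (submodes_per_class[c] if submodes_per_class
                   else [class_modes[c]])
        for member in range(size):
            anchor = anchors[int(rng.integers(len(anchors)))]
            j = int(rng.choice(counts, p=p))
            values.append(_mutate(anchor, j, rng))
            labels.append(name)
            ids.append(f"{name}_{member + 1}")
    return HaplotypeDataset(
        ids=tuple(ids),
        markers=_marker_names(m),
        values=np.array(values, dtype=object),
        labels=tuple(labels),
    )


def generate_surname_like(
    k: int,
    sizes,
    m: int = 25,
    mismatch_probs: dict[int, float] | None = None,
    seed: int | None = None,
    min_separation: int | None = None,
) -> HaplotypeDataset:
    """Labeled dataset mimicking a surname project table.

    Each of the k classes is built around a modal haplotype; class modes
    are resampled until pairwise separation >= ``min_separation``
    (default m // 2, comfortably above the 0-3 marker within-class
    spread so classes cannot overlap).  Each object mutates its class
    mode at j markers, j drawn from ``mismatch_probs``.
    """
    if len(sizes) != k:
        raise ValueError(f"expected {k} class sizes, got {len(sizes)}")
    if any(s < 1 for s in sizes):
        raise ValueError("class sizes must be >= 1")
    rng = np.random.default_rng(seed)
    if mismatch_probs is None:
        mismatch_probs = SURNAME_MISMATCH_PROBS
    if min_separation is None:
        min_separation = max(1, m // 2)
    modes = _separated_haplotypes(k, m, min_separation, rng)
    names = [f"G{c + 1}" for c in range(k)]
    return _build(modes, names, sizes, mismatch_probs, m, rng)


def generate_haplogroup_like(
    k: int,
    sizes,
    m: int = 25,
    divergence: int | None = None,
    subclass_count: int = 2,
    mismatch_probs: dict[int, float] | None = None,
    seed: int | None = None,
) -> HaplotypeDataset:
    """Labeled dataset mimicking a haplogroup table.

    Class modes sit at pairwise distance >= ``divergence`` (default
    m // 2).  Each class optionally contains ``subclass_count`` sparse
    sub-lineages: sub-modes offset from the class mode by about
    divergence // 3 markers, with objects scattered around whichever
    sub-mode they draw.  Skewed class sizes (one class holding 63-75%
    of objects) are expressed through ``sizes``.  ``subclass_count=1``
    reduces to surname-like generation with the looser haplogroup
    mismatch spread.
    """
    if len(sizes) != k:
        raise ValueError(f"expected {k} class sizes, got {len(sizes)}")
    if any(s < 1 for s in sizes):
        raise ValueError("class sizes must be >= 1")
    if subclass_count < 1:
        raise ValueError("subclass_count must be >= 1")
    rng = np.random.default_rng(seed)
    if divergence is None:
        divergence = max(1, m // 2)
    if divergence < 1:
        raise ValueError("divergence must be >= 1: class modes must differ")
    if mismatch_probs is None:
        mismatch_probs = HAPLOGROUP_MISMATCH_PROBS
    modes = _separated_haplotypes(k, m, divergence, rng)
    offset = max(1, divergence // 3)
    submodes = [
        [mode] + [_mutate(mode, offset, rng) for _ in range(subclass_count - 1)]
        for mode in modes
    ]
    names = [f"H{c + 1}" for c in range(k)]
    return _build(modes, names, sizes, mismatch_probs, m, rng,
                  submodes_per_class=submodes)


# --- frozen worked-example fixtures -------------------------------------
#
# Two tiny datasets built to exhibit the pathologies that break
# mode-based centroids.  The token matrices are frozen constructions
# satisfying every stated structural constraint (class modes, dominant
# shared attributes, class sizes), not samples from a generator.

# 9 objects, 3 attributes, 3 tight classes whose modes are
# [a1,a2,a3], [a1,b2,c3], [b1,c2,d4]; attributes a1, a2 and c3 are
# globally dominant, so plurality modes collide across classes.
_EXAMPLE_I_ROWS = [
    ("A1", "A", ["a1", "a2", "a3"]),
    ("A2", "A", ["a1", "a2", "a3"]),
    ("A3", "A", ["a1", "a2", "c3"]),
    ("B1", "B", ["a1", "b2", "c3"]),
    ("B2", "B", ["a1", "b2", "c3"]),
    ("B3", "B", ["a1", "a2", "c3"]),
    ("C1", "C", ["b1", "c2", "d4"]),
    ("C2", "C", ["b1", "c2", "d4"]),
    ("C3", "C", ["a1", "c2", "c3"]),
]

# 8 objects in two classes sized 6 and 2 (the large class holds 75% of
# the data); class modes [a1,a2,b3] and [a1,b2,c3]/[a1,b2,d3].  The
# extreme size skew makes fuzzy modes split the large class.
_EXAMPLE_II_ROWS = [
    ("A1", "A", ["a1", "a2", "a3"]),
    ("A2", "A", ["a1", "a2", "a3"]),
    ("A3", "A", ["a1", "a2", "b3"]),
    ("A4", "A", ["a1", "a2", "b3"]),
    ("A5", "A", ["a1", "a2", "b3"]),
    ("A6", "A", ["a1", "a2", "b3"]),
    ("B1", "B", ["a1", "b2", "c3"]),
    ("B2", "B", ["a1", "b2", "d3"]),
]


def _fixture(rows) -> HaplotypeDataset:
    return HaplotypeDataset(
        ids=tuple(r[0] for r in rows),
        markers=("M1", "M2", "M3"),
        values=np.array([r[2] for r in rows], dtype=object),
        labels=tuple(r[1] for r in rows),
    )


def make_example_fixtures(
    seed: int | None = None,
) -> tuple[HaplotypeDataset, HaplotypeDataset]:
    """The two frozen worked-example datasets (small/many-classes and
    extreme-skew).  ``seed`` is accepted for interface uniformity but
    unused: the fixtures are deterministic constructions."""
    return _fixture(_EXAMPLE_I_ROWS), _fixture(_EXAMPLE_II_ROWS)
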