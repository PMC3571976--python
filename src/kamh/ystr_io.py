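"""Reading and writing Y-STR haplotype tables and clustering results.

Y-STR project tables are plain spreadsheets: one row per individual, one
column per named STR marker, each cell holding an allele value (a repeat
count such as ``"14"``, or a microvariant such as ``"38.2"``).  Allele
values are treated as opaque categorical tokens end to end — they are
never coerced to numbers, because the clustering distance is simple
matching (match/mismatch), not a numeric difference.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised when an input table cannot be parsed into a dataset."""


#: Canonical 25-marker Y-STR panel used by surname/haplogroup web projects.
#: The quadruplicated DYS464 locus is spelled out as a–d.
CANONICAL_MARKERS: tuple[str, ...] = (
    "DYS393", "DYS390", "DYS19", "DYS391", "DYS385a", "DYS385b", "DYS426",
    "DYS388", "DYS439", "DYS389I", "DYS392", "DYS389II", "DYS458",
    "DYS459a", "DYS459b", "DYS455", "DYS454", "DYS447", "DYS437",
    "DYS448", "DYS449", "DYS464a", "DYS464b", "DYS464c", "DYS464d",
)


@dataclass(frozen=True)
class HaplotypeDataset:
    """A rectangular table of categorical allele tokens.

    Parameters
    ----------
    ids
        ``n`` unique object identifiers.
    markers
        ``m`` ordered marker (column) names.
    values
        ``n x m`` array of whitespace-trimmed allele tokens (strings).
    labels
        Optional ``n`` ground-truth class labels, used only for evaluation.
    """

    ids: tuple[str, ...]
    markers: tuple[str, ...]
    values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=object)
        object.__setattr__(self, "values", values)
        n, m = len(self.ids), len(self.markers)
        if n < 1 or m < 1:
            raise ValueError("dataset needs at least one object and one marker")
        if values.shape != (n, m):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{n} ids x {m} markers"
            )
        if self.labels is not None and len(self.labels) != n:
            raise ValueError(f"expected {n} labels, got {len(self.labels)}")
        if len(set(self.ids)) != n:
            raise ValueError("object ids must be unique")

    @property
    def n_objects(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @cached_property
    def codes(self) -> np.ndarray:
        """``n x m`` integer codes; per column, codes follow the
        lexicographic order of the distinct tokens observed there."""
        n, m = self.values.shape
        codes = np.empty((n, m), dtype=np.int64)
        for j in range(m):
            _, codes[:, j] = np.unique(self.values[:, j].astype(str),
                                       return_inverse=True)
        return codes

    @cached_property
    def token_domains(self) -> tuple[np.ndarray, ...]:
        """Per column, the sorted distinct tokens (DOM of each marker)."""
        return tuple(np.unique(self.values[:, j].astype(str))
                     for j in range(self.n_markers))

    def take(self, order: Sequence[int]) -> "HaplotypeDataset":
        """Return a new dataset with rows reordered/subset by ``order``."""
        order = np.asarray(order)
        return HaplotypeDataset(
            ids=tuple(self.ids[i] for i in order),
            markers=self.markers,
            values=self.values[order],
            labels=None if self.labels is None
            else tuple(self.labels[i] for i in order),
        )


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path: str | Path,
    id_column: str | None = None,
    label_column: str | None = None,
    drop_incomplete: bool = False,
    delimiter: str | None = None,
) -> HaplotypeDataset:
    """Read a haplotype table from a delimited text file.

    The first row is a header.  ``id_column`` defaults to the first
    column; every column other than the id and label columns is a marker,
    kept in file order.  Rows with any empty marker cell are rejected, or
    dropped when ``drop_incomplete`` is set.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                            na_values=[], engine="python")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no columns found")

    frame = frame.map(lambda s: s.strip() if isinstance(s, str) else s)
    columns = list(frame.columns)
    id_col = columns[0] if id_column is None else id_column
    if id_col not in columns:
        raise ParseError(f"{path}: id column {id_col!r} not in header")
    if label_column is not None and label_column not in columns:
        raise ParseError(f"{path}: label column {label_column!r} not in header")
    marker_cols = [c for c in columns if c != id_col and c != label_column]
    if not marker_cols:
        raise ParseError(f"{path}: no marker columns")

    # pandas renders short/ragged rows as NaN; treat those as empty cells
    markers_frame = frame[marker_cols]
    incomplete = markers_frame.isna().any(axis=1) | (markers_frame == "").any(axis=1)
    if incomplete.any():
        bad = frame.index[incomplete].tolist()
        if drop_incomplete:
            frame = frame[~incomplete]
            if frame.empty:
                raise ParseError(f"{path}: all rows incomplete")
        else:
            raise ParseError(
                f"{path}: empty marker cell in data row(s) "
                f"{', '.join(str(i + 2) for i in bad[:10])} "
                "(use drop_incomplete to skip them)"
            )

    ids = tuple(frame[id_col].astype(str))
    if len(set(ids)) != len(ids):
        dupes = frame[id_col][frame[id_col].duplicated()].unique()
        raise ParseError(f"{path}: duplicate ids: {', '.join(map(str, dupes[:5]))}")
    labels = (tuple(frame[label_column].astype(str))
              if label_column is not None else None)
    values = frame[marker_cols].to_numpy(dtype=object)
    return HaplotypeDataset(ids=ids, markers=tuple(marker_cols),
                            values=values, labels=labels)


def write_dataset(
    dataset: HaplotypeDataset,
    path: str | Path,
    id_column: str = "id",
    label_column: str = "group",
    delimiter: str | None = None,
) -> None:
    """Write a dataset as a delimited table with a header row."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    frame = pd.DataFrame(dataset.values, columns=list(dataset.markers))
    frame.insert(0, id_column, list(dataset.ids))
    if dataset.labels is not None:
        frame[label_column] = list(dataset.labels)
    frame.to_csv(path, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL)


def write_result(result, path: str | Path, precision: int = 10) -> None:
    """Write cluster assignments and a sidecar metadata file.

    The assignments CSV has columns ``id``, ``cluster`` and one
    membership column per cluster (``w_c1`` ... ``w_ck``), rounded to
    ``precision`` decimals.  Metadata (k, alpha, seed, cost, ...) goes to
    ``<path>.meta`` as flat ``key=value`` lines.
    """
    path = Path(path)
    w = np.asarray(result.membership, dtype=float)
    k, n = w.shape
    ids = result.ids if result.ids is not None else [str(i) for i in range(n)]
    frame = pd.DataFrame({"id": list(ids), "cluster": np.asarray(result.labels)})
    for l in range(k):
        frame[f"w_c{l + 1}"] = np.round(w[l], precision)
    frame.to_csv(path, index=False)

    meta = {
        "algorithm": result.algorithm,
        "k": k,
        "n": n,
        "alpha": result.alpha,
        "seed": result.seed,
        "cost": repr(result.final_cost),
        "replacements": result.replacements,
        "sweeps_run": result.sweeps_run,
        "centroid_indices": (
            ",".join(map(str, result.centroid_indices))
            if result.centroid_indices is not None else ""
        ),
    }
    meta_path = path.with_name(path.name + ".meta")
    meta_path.write_text(
        "".join(f"{key}={value}\n" for key, value in meta.items()),
        encoding="utf-8",
    )


def read_result(path: str | Path) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Read an assignments CSV back; returns (ids, labels, membership k x n)."""
    frame = pd.read_csv(path, dtype={"id": str})
    ids = tuple(frame["id"])
    labels = frame["cluster"].to_numpy(dtype=np.int64)
    w_cols = [c for c in frame.columns if c.startswith("w_c")]
    membership = frame[w_cols].to_numpy(dtype=float).T
    return ids, labels, membership
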