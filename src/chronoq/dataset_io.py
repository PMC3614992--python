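"""Tab-delimited readers and writers for matrices, times and orderings.

Formats
-------
* Expression matrix: TSV, genes as rows; first row holds sample ids, first
  column gene ids. Missing entries are an empty cell or a configurable
  token (default ``NA``).
* Sample metadata: two-column TSV ``sample_id <TAB> time`` (survival days
  or known sampling time).
* Similarity matrix: square TSV with matching row/column ids; diagonal
  cells may hold a placeholder since self-similarity is never used.
* Ordering result: TSV of ``rank, sample_id[, time]`` plus a JSON summary
  side-car (overall similarity, validity, SMD when times are known).

The sample order of the expression-matrix header defines the 0-based
index used by every downstream module.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .similarity import SimilarityMatrix, check_permutation

__all__ = [
    "ExpressionMatrix",
    "SampleTimes",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_times",
    "write_sample_times",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "write_ordering",
    "read_ordering",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix; NaN marks a missing measurement."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError(
                f"value shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleTimes:
    """Per-sample nonnegative time (survival days or sampling time).

    ``unit`` is a free-form tag (``"days"``, ``"min"``, ``"h"``); every
    computation only uses the relative order and differences of the values.
    """

    times: "pd.Series"
    unit: str = "days"

    def __post_init__(self) -> None:
        self.times = pd.Series(self.times, dtype=float)
        self.times.index = self.times.index.map(str)
        if self.times.index.has_duplicates:
            raise FormatError("duplicate sample ids in times table")
        vals = self.times.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise FormatError("non-finite time value")
        if np.any(vals < 0):
            raise FormatError("negative time value")

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, sample_id: str) -> float:
        return float(self.times[str(sample_id)])

    def vector_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Times aligned to ``sample_ids``; missing samples raise InputError."""
        missing = [s for s in sample_ids if str(s) not in self.times.index]
        if missing:
            raise InputError(f"no time recorded for samples: {missing}")
        return self.times.loc[[str(s) for s in sample_ids]].to_numpy()


def _read_rows(path) -> list[list[str]]:
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t")]
    return [r for r in rows if r and not all(c.strip() == "" for c in r)]


def read_expression_matrix(path, missing_token: str = "NA") -> ExpressionMatrix:
    """Read a genes x samples TSV; ``missing_token`` or empty cells become NaN."""
    rows = _read_rows(path)
    if not rows:
        raise InputError(f"{path}: empty expression matrix file")
    header = rows[0]
    sample_ids = [c.strip() for c in header[1:]]
    if len(sample_ids) < 2:
        raise InputError(f"{path}: need at least 2 samples, found {len(sample_ids)}")
    gene_ids: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, got {len(row)}"
            )
        gene_ids.append(row[0].strip())
        vals = []
        for cell in row[1:]:
            cell = cell.strip()
            if cell == "" or cell == missing_token:
                vals.append(math.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric cell {cell!r}") from exc
        data.append(vals)
    return ExpressionMatrix(gene_ids, sample_ids, np.asarray(data, dtype=float))


def write_expression_matrix(matrix: ExpressionMatrix, path, missing_token: str = "NA") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", *matrix.sample_ids])
        for gid, row in zip(matrix.gene_ids, matrix.values):
            w.writerow([gid, *(missing_token if math.isnan(v) else repr(float(v)) for v in row)])


def read_sample_times(path, unit: str = "days") -> SampleTimes:
    """Read a two-column ``sample_id <TAB> time`` TSV."""
    rows = _read_rows(path)
    # tolerate (and skip) a header line announcing the columns
    if rows and rows[0] and rows[0][0].strip().lower() in {"sample_id", "sample", "id"}:
        rows = rows[1:]
    if not rows:
        raise InputError(f"{path}: empty times file")
    ids: list[str] = []
    vals: list[float] = []
    for lineno, row in enumerate(rows, start=1):
        if len(row) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
        ids.append(row[0].strip())
        try:
            vals.append(float(row[1]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric time {row[1]!r}") from exc
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample ids")
    return SampleTimes(pd.Series(vals, index=ids), unit=unit)


def write_sample_times(times: SampleTimes, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for sid, t in times.times.items():
            w.writerow([sid, repr(float(t))])


_DIAGONAL_PLACEHOLDERS = {"", "-", "–", "—", "NA", "nan"}


def read_similarity_matrix(path) -> SimilarityMatrix:
    """Read a square similarity TSV; diagonal placeholders are ignored."""
    rows = _read_rows(path)
    if not rows:
        raise InputError(f"{path}: empty similarity file")
    header = [c.strip() for c in rows[0][1:]]
    n = len(header)
    if len(rows) - 1 != n:
        raise FormatError(f"{path}: matrix is not square ({len(rows) - 1} rows, {n} columns)")
    sim = np.full((n, n), np.nan)
    row_ids: list[str] = []
    for i, row in enumerate(rows[1:]):
        if len(row) != n + 1:
            raise FormatError(f"{path}: row {i + 2} has {len(row)} columns, expected {n + 1}")
        row_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if i == j and cell in _DIAGONAL_PLACEHOLDERS:
                continue
            try:
                sim[i, j] = float(cell)
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell {cell!r}") from exc
    if row_ids != header:
        raise FormatError(f"{path}: row ids do not match column ids")
    # symmetry is an input contract, not a format one
    off = ~np.eye(n, dtype=bool)
    if not np.allclose(sim[off], sim.T[off], atol=1e-9, rtol=0.0, equal_nan=True):
        raise InputError(f"{path}: similarity matrix is asymmetric beyond 1e-9")
    return SimilarityMatrix(header, sim)


def write_similarity_matrix(S: SimilarityMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["similarity", *S.sample_ids])
        for i, sid in enumerate(S.sample_ids):
            cells = ["-" if i == j else repr(float(S.sim[i, j])) for j in range(S.n)]
            w.writerow([sid, *cells])


def write_ordering(
    ordering: Sequence[int],
    sample_ids: Sequence[str],
    path,
    times: SampleTimes | None = None,
    summary: Mapping | None = None,
) -> None:
    """Write ``rank, sample_id[, time]`` rows plus a JSON summary side-car.

    The side-car is written next to ``path`` with a ``.json`` suffix and
    carries whatever run summary the caller provides (overall similarity,
    validity flag, SMD, training metadata).
    """
    perm = check_permutation(ordering, len(sample_ids))
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["rank", "sample_id"] + (["time"] if times is not None else [])
        w.writerow(header)
        for rank, idx in enumerate(perm, start=1):
            row = [rank, sample_ids[idx]]
            if times is not None:
                row.append(repr(times[sample_ids[idx]]))
            w.writerow(row)
    if summary is not None:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(dict(summary), fh, indent=2, default=float)
            fh.write("\n")


def read_ordering(path, sample_ids: Sequence[str]) -> tuple[int, ...]:
    """Read an ordering file back into a permutation of 0-based indices."""
    rows = _read_rows(path)
    if rows and rows[0] and rows[0][0].strip().lower() == "rank":
        rows = rows[1:]
    index_of = {str(s): i for i, s in enumerate(sample_ids)}
    try:
        perm = tuple(index_of[row[1].strip()] for row in rows)
    except KeyError as exc:
        raise InputError(f"{path}: unknown sample id {exc}") from exc
    return check_permutation(perm, len(sample_ids))
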