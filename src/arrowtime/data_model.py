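"""Containers and I/O for parcellated multivariate time series.

The central objects are :class:`SubjectSeries` (one regions x time matrix per
recording) and :class:`CohortSeries` (the concatenation of several subjects
along time, with the positions of the junctions recorded so that downstream
model fits can exclude transition pairs that straddle two subjects).

Matrices are oriented regions-in-rows, time-in-columns, matching the R x 1
state-vector convention of first-order vector autoregressive modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectSeries",
    "CohortSeries",
    "LabelTable",
    "concatenate_subjects",
    "load_cohort",
    "zscore_regions",
    "time_reverse",
    "read_label_table",
    "read_overlap_counts",
    "write_subject_tsv",
]


def _default_region_ids(n: int) -> list[str]:
    return [f"r{i:03d}" for i in range(n)]


@dataclass
class SubjectSeries:
    """A single subject's regions x time matrix.

    Parameters
    ----------
    data:
        Real matrix of shape (n_regions, n_time); must be finite.
    subject_id:
        Identifier carried through concatenation bookkeeping.
    region_ids:
        Ordered region identifiers; generated as ``r000, r001, ...`` when
        omitted.
    """

    data: np.ndarray
    subject_id: str = "subject"
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(
                f"subject {self.subject_id!r}: expected a 2-D regions x time "
                f"matrix, got shape {self.data.shape}"
            )
        if self.data.shape[1] < 2:
            raise ValueError(
                f"subject {self.subject_id!r}: need at least 2 time points, "
                f"got {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values present")
        if not self.region_ids:
            self.region_ids = _default_region_ids(self.data.shape[0])
        if len(self.region_ids) != self.data.shape[0]:
            raise ValueError(
                f"subject {self.subject_id!r}: {len(self.region_ids)} region ids "
                f"for {self.data.shape[0]} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortSeries:
    """Concatenation of subject series along time with junction bookkeeping.

    ``boundaries[k]`` is the column index at which the k-th subject block
    starts; the first boundary is always 0.  Transition pairs straddling a
    boundary do not belong to any subject and are excluded by model fits.
    """

    data: np.ndarray
    boundaries: np.ndarray
    subject_order: list[str]
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("cohort data must be 2-D (regions x time)")
        if self.boundaries.size == 0 or self.boundaries[0] != 0:
            raise ValueError("boundaries must start at 0")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.boundaries[-1] >= self.data.shape[1]:
            raise ValueError("last boundary lies beyond the data")
        if len(self.subject_order) != self.boundaries.size:
            raise ValueError("subject_order and boundaries disagree in length")
        if not self.region_ids:
            self.region_ids = _default_region_ids(self.data.shape[0])

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.boundaries.size

    def blocks(self) -> Iterator[tuple[int, int]]:
        """Yield (start, stop) column ranges of each subject block."""
        stops = np.append(self.boundaries[1:], self.n_time)
        for start, stop in zip(self.boundaries, stops):
            yield int(start), int(stop)

    def split(self) -> list[SubjectSeries]:
        """Recover the per-subject series (bit-exact inverse of concatenation)."""
        return [
            SubjectSeries(self.data[:, a:b].copy(), sid, list(self.region_ids))
            for (a, b), sid in zip(self.blocks(), self.subject_order)
        ]

    def truncate(self, n_samples: int) -> "CohortSeries":
        """Keep the first ``n_samples`` concatenated time points.

        A subject block cut mid-way is kept as a partial block; blocks that
        fall entirely beyond the cut are dropped.
        """
        if n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if n_samples > self.n_time:
            raise ValueError(
                f"n_samples={n_samples} exceeds cohort length {self.n_time}"
            )
        keep = self.boundaries < n_samples
        return CohortSeries(
            self.data[:, :n_samples],
            self.boundaries[keep].copy(),
            [s for s, k in zip(self.subject_order, keep) if k],
            list(self.region_ids),
        )


@dataclass
class LabelTable:
    """Region -> category labels, optionally backed by overlap vote counts."""

    labels: dict[str, str]
    label_order: list[str] = field(default_factory=list)
    overlap_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.label_order:
            seen: list[str] = []
            for v in self.labels.values():
                if v not in seen:
                    seen.append(v)
            self.label_order = seen

    def label_of(self, region_id: str) -> str:
        if region_id not in self.labels:
            raise KeyError(f"region {region_id!r} has no label")
        return self.labels[region_id]


def concatenate_subjects(
    subjects: Sequence[SubjectSeries], order: Sequence[int] | None = None
) -> CohortSeries:
    """Concatenate subjects along time, recording block boundaries.

    ``order`` is an optional permutation of subject indices (the fold scheme
    draws one per fold); by default subjects are concatenated as given.
    """
    if not subjects:
        raise ValueError("no subjects to concatenate")
    n_regions = subjects[0].n_regions
    region_ids = subjects[0].region_ids
    for s in subjects:
        if s.n_regions != n_regions:
            raise ValueError(
                f"subject {s.subject_id!r} has {s.n_regions} regions, "
                f"expected {n_regions}"
            )
    idx = list(range(len(subjects))) if order is None else list(order)
    picked = [subjects[i] for i in idx]
    lengths = [s.n_time for s in picked]
    boundaries = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    data = np.concatenate([s.data for s in picked], axis=1)
    return CohortSeries(data, boundaries, [s.subject_id for s in picked], list(region_ids))


def zscore_regions(s: SubjectSeries) -> SubjectSeries:
    """Standardize every region's time course to mean 0, sd 1 (ddof=1).

    Applied per subject, before any concatenation.  Raises on zero-variance
    regions, naming the offender.
    """
    sd = s.data.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"subject {s.subject_id!r}: zero-variance region "
            f"{s.region_ids[bad[0]]!r} cannot be z-scored"
        )
    z = (s.data - s.data.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(s, data=z)


def time_reverse(c: CohortSeries) -> CohortSeries:
    """Reverse each subject block in time; subject order is preserved.

    An involution: applying it twice returns the original exactly.
    """
    out = np.empty_like(c.data)
    for a, b in c.blocks():
        out[:, a:b] = c.data[:, a:b][:, ::-1]
    return CohortSeries(out, c.boundaries.copy(), list(c.subject_order), list(c.region_ids))


def _read_delimited(path: Path, delimiter: str) -> tuple[np.ndarray, list[str] | None]:
    with open(path) as fh:
        first = fh.readline()
    tokens = first.rstrip("\n").split(delimiter)

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens if t != "")
    df = pd.read_csv(path, sep=delimiter, header=0 if has_header else None)
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {r + 1 + int(has_header)}, "
            f"column {c + 1}: {df.iat[r, c]!r}"
        )
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at row {r + 1}, column {c + 1}")
    header = [str(c) for c in df.columns] if has_header else None
    return coerced.to_numpy(dtype=float), header


def load_cohort(
    paths: Iterable[str | Path],
    format: str = "delimited",
    regions_in_rows: bool = True,
    delimiter: str = "\t",
) -> tuple[CohortSeries, list[SubjectSeries]]:
    """Load one matrix file per subject and concatenate them.

    ``delimited`` files are TSV/CSV with an optional header row of region ids
    (header applies when regions are in columns); ``binary`` files are ``.npy``
    dense arrays.  All subjects must agree on the region count; the offending
    file is named otherwise.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files")
    subjects: list[SubjectSeries] = []
    n_regions: int | None = None
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(str(p))
        if format == "delimited":
            mat, header = _read_delimited(p, delimiter)
        elif format == "binary":
            mat, header = np.asarray(np.load(p), dtype=float), None
        else:
            raise ValueError(f"unknown format {format!r}")
        if not regions_in_rows:
            mat = mat.T
            region_ids = header
        else:
            region_ids = None
        if n_regions is None:
            n_regions = mat.shape[0]
        elif mat.shape[0] != n_regions:
            raise ValueError(
                f"{p}: {mat.shape[0]} regions, but earlier files have {n_regions}"
            )
        subjects.append(
            SubjectSeries(mat, subject_id=p.stem, region_ids=list(region_ids or []))
        )
    return concatenate_subjects(subjects), subjects


def write_subject_tsv(s: SubjectSeries, path: str | Path, header: bool = False) -> None:
    """Write a subject matrix as TSV (regions in rows, no index column)."""
    df = pd.DataFrame(s.data)
    df.to_csv(path, sep="\t", header=False, index=False)
    if header:  # header row of region ids only makes sense time-in-rows
        pd.DataFrame(s.data.T, columns=s.region_ids).to_csv(
            path, sep="\t", index=False
        )


def read_label_table(path: str | Path, delimiter: str = "\t") -> LabelTable:
    """Read a two-column (region_id, label) table."""
    df = pd.read_csv(path, sep=delimiter, header=None, names=["region_id", "label"])
    return LabelTable({str(r): str(l) for r, l in zip(df.region_id, df.label)})


def read_overlap_counts(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a region x label nonnegative count matrix (first column = region id)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    counts = df.to_numpy()
    if (counts < 0).any():
        raise ValueError(f"{path}: negative overlap counts")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError(f"{path}: overlap counts must be integers")
    return df
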