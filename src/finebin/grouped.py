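"""Core containers for interval-grouped count data.

Grouped counts are histograms over contiguous half-open intervals
``[edges[i], edges[i+1])`` — typically 5-year age classes of death or
disease-onset counts, possibly ending in a wide interval (a closed
"85+" group) and/or a zero-count closing interval that anchors the
right tail. Every ungrouping method in this package consumes a
:class:`GroupedCounts` and produces an :class:`UngroupedEstimate` on a
single-year :class:`FineGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GroupedCounts",
    "FineGrid",
    "UngroupedEstimate",
    "read_grouped",
    "append_closing_interval",
    "group_sample",
    "histogram_density",
    "cumulative_knots",
    "write_fine",
]


class GroupedDataError(ValueError):
    """Structural problem in grouped input (gaps, overlaps, bad counts)."""


@dataclass(frozen=True)
class GroupedCounts:
    """Counts observed on contiguous half-open intervals.

    Parameters
    ----------
    edges
        Strictly increasing interval boundaries in years, length ``I + 1``.
    counts
        Non-negative counts per interval, length ``I``.
    """

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1 or edges.size != counts.size + 1:
            raise GroupedDataError(
                f"need len(edges) == len(counts) + 1, got {edges.size} and {counts.size}"
            )
        if counts.size < 1:
            raise GroupedDataError("at least one interval is required")
        if not np.all(np.diff(edges) > 0):
            raise GroupedDataError("interval edges must be strictly increasing")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise GroupedDataError("counts must be finite and non-negative")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def nbins(self) -> int:
        return self.counts.size

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def total_n(self) -> float:
        return float(self.counts.sum())

    @property
    def support(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])


@dataclass(frozen=True)
class FineGrid:
    """Single-year estimation grid: unit bins ``[start, start+1), ...``.

    ``points`` are the left edges of the ``J = stop - start`` unit bins.
    """

    start: int
    stop: int

    def __post_init__(self) -> None:
        if int(self.start) != self.start or int(self.stop) != self.stop:
            raise ValueError("grid bounds must be whole years")
        if self.stop <= self.start:
            raise ValueError("grid stop must exceed start")
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "stop", int(self.stop))

    @property
    def J(self) -> int:
        return self.stop - self.start

    @property
    def points(self) -> np.ndarray:
        return np.arange(self.start, self.stop, dtype=float)

    @classmethod
    def spanning(cls, gc: GroupedCounts) -> "FineGrid":
        """Smallest unit grid covering the grouped support."""
        lo, hi = gc.support
        return cls(int(np.floor(lo)), int(np.ceil(hi)))

    def covers(self, gc: GroupedCounts) -> bool:
        lo, hi = gc.support
        return self.start <= lo and hi <= self.stop


@dataclass(frozen=True)
class UngroupedEstimate:
    """Expected counts per unit bin, produced by one ungrouping method."""

    grid: FineGrid
    gamma: np.ndarray
    total_n: float
    method_tag: str
    settings: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gamma = np.asarray(self.gamma, dtype=float)
        if gamma.size != self.grid.J:
            raise ValueError(f"gamma length {gamma.size} != grid J {self.grid.J}")
        if np.any(gamma < 0):
            raise ValueError("gamma must be non-negative")
        object.__setattr__(self, "gamma", gamma)

    @property
    def density(self) -> np.ndarray:
        """gamma / total_n — per-unit-bin probability mass."""
        return self.gamma / self.total_n


_DEFAULT_COLUMNS = {"age_low": "age_low", "age_high": "age_high", "count": "count"}


def read_grouped(path, dialect: Mapping[str, str] | None = None) -> GroupedCounts:
    """Read a grouped count table from delimited text (CSV with header).

    Expects columns ``age_low, age_high, count`` (remappable through
    ``dialect``, e.g. ``{"age_low": "from"}``). Rows are sorted by lower
    bound and must tile the support contiguously. Open-ended labels like
    ``"85+"`` are rejected: close the interval explicitly (e.g. at 115)
    before fitting.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise GroupedDataError(f"missing columns {missing} in {path}")
    for key in ("age_low", "age_high", "count"):
        col = cols[key]
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise GroupedDataError(
                f"non-numeric value in column '{col}' at row {row} "
                "(open-ended labels like '85+' need an explicit upper bound)"
            )
        df[col] = vals
    df = df.sort_values(cols["age_low"]).reset_index(drop=True)
    lo = df[cols["age_low"]].to_numpy(dtype=float)
    hi = df[cols["age_high"]].to_numpy(dtype=float)
    counts = df[cols["count"]].to_numpy(dtype=float)
    if np.any(counts < 0):
        row = int(np.flatnonzero(counts < 0)[0])
        raise GroupedDataError(f"negative count at row {row}")
    for i in range(len(lo) - 1):
        if hi[i] != lo[i + 1]:
            raise GroupedDataError(
                f"intervals not contiguous at row {i + 1}: "
                f"[{lo[i]}, {hi[i]}) followed by [{lo[i + 1]}, {hi[i + 1]})"
            )
    edges = np.append(lo, hi[-1])
    return GroupedCounts(edges=edges, counts=counts)


def append_closing_interval(gc: GroupedCounts, upper: float) -> GroupedCounts:
    """Extend ``gc`` with a zero-count interval ``[last edge, upper)``.

    The closing interval encodes the assumption that no events occur
    beyond the last observed age; it anchors the right tail of every
    ungrouping method without changing the total count.
    """
    if upper <= gc.edges[-1]:
        raise ValueError(
            f"closing upper bound {upper} must exceed last edge {gc.edges[-1]}"
        )
    return GroupedCounts(
        edges=np.append(gc.edges, float(upper)),
        counts=np.append(gc.counts, 0.0),
    )


def group_sample(values, edges) -> GroupedCounts:
    """Bin continuous observations into half-open intervals.

    ``counts[i]`` = number of values in ``[edges[i], edges[i+1])``; a
    value on a boundary belongs to the upper interval. Values outside
    ``[edges[0], edges[-1])`` raise — samplers are expected to resample
    out-of-support draws rather than drop them.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise GroupedDataError("edges must be strictly increasing")
    if values.size:
        if values.min() < edges[0] or values.max() >= edges[-1]:
            raise ValueError("value outside the grouping support")
    idx = np.searchsorted(edges, values, side="right") - 1
    counts = np.bincount(idx, minlength=edges.size - 1).astype(float)
    return GroupedCounts(edges=edges, counts=counts)


def histogram_density(gc: GroupedCounts) -> np.ndarray:
    """Piecewise-constant density heights, one per coarse interval.

    Height on interval i is ``counts[i] / (n * width_i)``, so the step
    function integrates to exactly 1 over the support.
    """
    if gc.total_n <= 0:
        raise ValueError("histogram density undefined for total count 0")
    return gc.counts / (gc.total_n * gc.widths)


def cumulative_knots(gc: GroupedCounts) -> tuple[np.ndarray, np.ndarray]:
    """Knots ``(x_i, Y_i)`` of the cumulative count function.

    ``Y_0 = 0`` at the first edge; differencing consecutive ``Y`` values
    recovers the coarse counts exactly.
    """
    return gc.edges.copy(), np.concatenate([[0.0], np.cumsum(gc.counts)])


def write_fine(estimate: UngroupedEstimate, path) -> None:
    """Write an estimate as CSV: one row per unit bin (age, count, density).

    Header comment lines record the method tag and its settings.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={estimate.method_tag}\n")
        for key, val in estimate.settings.items():
            fh.write(f"# {key}={val}\n")
        pd.DataFrame(
            {
                "age": estimate.grid.points,
                "count": estimate.gamma,
                "density": estimate.density,
            }
        ).to_csv(fh, index=False)
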