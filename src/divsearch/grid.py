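"""Discretized drug-concentration search space and response-surface oracles.

A drug cocktail is an n-vector of integer concentration indices, one per
drug, each running 0..T.  The search space is therefore a lattice of
(T+1)**n points.  A :class:`ResponseSurface` wraps a dense tensor of
sensitivities in [0, 1] over that lattice and counts every oracle query,
which is the cost unit of a sequential drug-screening experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GridPoint = tuple[int, ...]
"""A lattice point: an n-tuple of integer concentration indices in [0, T]."""


@dataclass(frozen=True)
class SearchGrid:
    """The discretized concentration lattice for ``n`` drugs at levels 0..T.

    Parameters
    ----------
    n : number of drugs (dimensions).
    T : maximum discretization index per drug; each axis has T+1 levels.
    bounds : per-drug (low, high) real concentration interval used only for
        the affine index-to-concentration view; the search itself lives on
        the integer lattice.
    """

    n: int
    T: int
    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"number of drugs must be >= 1, got {self.n}")
        if self.T < 1:
            raise ValueError(f"discretization index T must be >= 1, got {self.T}")
        if len(self.bounds) != self.n:
            raise ValueError(
                f"expected {self.n} bound pairs, got {len(self.bounds)}"
            )
        for i, (lo, hi) in enumerate(self.bounds):
            if not lo < hi:
                raise ValueError(f"bounds for drug {i} must satisfy low < high")

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.T + 1,) * self.n

    @property
    def size(self) -> int:
        return (self.T + 1) ** self.n

    def contains(self, point: Sequence[int]) -> bool:
        return len(point) == self.n and all(0 <= v <= self.T for v in point)

    def validate_point(self, point: Sequence[int]) -> GridPoint:
        pt = tuple(int(v) for v in point)
        if not self.contains(pt):
            raise ValueError(f"point {pt} outside grid (n={self.n}, T={self.T})")
        return pt

    def concentrations(self, point: Sequence[int]) -> np.ndarray:
        """Real concentrations for a lattice point (affine per-drug map)."""
        pt = self.validate_point(point)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return lo + (hi - lo) * np.asarray(pt) / self.T

    def iter_points(self) -> Iterable[GridPoint]:
        for idx in np.ndindex(*self.shape):
            yield idx


def make_grid(
    n: int, T: int, bounds: Sequence[tuple[float, float]] | None = None
) -> SearchGrid:
    """Build a :class:`SearchGrid`; ``bounds`` defaults to (0, 1) per drug."""
    if bounds is None:
        if n < 1:
            raise ValueError(f"number of drugs must be >= 1, got {n}")
        bounds = ((0.0, 1.0),) * n
    return SearchGrid(n=int(n), T=int(T), bounds=tuple(tuple(b) for b in bounds))


@dataclass
class ResponseSurface:
    """Sensitivity oracle f: lattice -> [0, 1] with query accounting.

    ``values`` holds the full dense tensor; ``query`` is the only method
    that increments the experiment counter, so algorithms are charged one
    unit of cost per point they actually test.  The optimum set is computed
    once by exhaustive enumeration at construction.
    """

    grid: SearchGrid
    values: np.ndarray
    n_queries: int = 0
    optima: frozenset[GridPoint] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value tensor shape {self.values.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("sensitivities must lie in [0, 1]")
        top = self.values.max()
        self.optima = frozenset(
            tuple(idx) for idx in np.argwhere(self.values == top)
        )

    @property
    def max_value(self) -> float:
        return float(self.values.max())

    def query(self, point: Sequence[int]) -> float:
        """Run one 'experiment': return f(point) and count the query."""
        pt = self.grid.validate_point(point)
        self.n_queries += 1
        return float(self.values[pt])

    def peek(self, point: Sequence[int]) -> float:
        """Read a value without charging an experiment (analysis only)."""
        return float(self.values[self.grid.validate_point(point)])

    def reset_counter(self) -> None:
        self.n_queries = 0


def _index_mesh(grid: SearchGrid) -> np.ndarray:
    """(size, n) array of all lattice points in C order."""
    return np.indices(grid.shape).reshape(grid.n, -1).T


def make_hill_surface(
    grid: SearchGrid,
    hills: Sequence[tuple[Sequence[int], float, float]],
    floor: float = 0.0,
) -> ResponseSurface:
    """Synthetic multi-hill surface: a floor plus Gaussian bumps.

    Each hill is (center, width, height) with the center on the lattice,
    width in index units and height in (0, 1].  The sensitivity at a point
    is min(1, floor + sum_h height_h * exp(-||x - c_h||_2^2 / width_h^2)).
    Hill count and width control how many near-optimal points exist, which
    is the regime knob for single-peak versus multi-peak test problems.
    """
    if len(hills) == 0:
        raise ValueError("at least one hill is required")
    pts = _index_mesh(grid).astype(float)
    total = np.full(grid.size, float(floor))
    for center, width, height in hills:
        c = grid.validate_point(center)
        if not 0 < height <= 1:
            raise ValueError(f"hill height must be in (0, 1], got {height}")
        if width <= 0:
            raise ValueError(f"hill width must be positive, got {width}")
        d2 = ((pts - np.asarray(c, dtype=float)) ** 2).sum(axis=1)
        total += height * np.exp(-d2 / width**2)
    vals = np.minimum(1.0, total).reshape(grid.shape)
    return ResponseSurface(grid=grid, values=vals)


def make_inverted_sphere_surface(
    grid: SearchGrid, center: Sequence[int]
) -> ResponseSurface:
    """Unimodal quadratic test surface with its unique maximum 1 at ``center``.

    Sensitivity is 1 - d2/d2_max where d2 is the squared Euclidean index
    distance to the center and d2_max the largest such distance on the grid,
    so the farthest corner scores exactly 0.
    """
    c = grid.validate_point(center)
    pts = _index_mesh(grid).astype(float)
    d2 = ((pts - np.asarray(c, dtype=float)) ** 2).sum(axis=1)
    vals = (1.0 - d2 / d2.max()).reshape(grid.shape)
    return ResponseSurface(grid=grid, values=vals)


def load_tabulated_surface(path: str | Path, grid: SearchGrid) -> ResponseSurface:
    """Read a tabulated response surface from a delimited text file.

    Two layouts are accepted:

    * dense matrix (n=2 only): (T+1) x (T+1) numeric cells, rows indexed by
      drug 1 ascending and columns by drug 2 ascending, no header;
    * long format: header ``d1,...,dn,sensitivity`` followed by one row per
      lattice point.

    Values are rescaled to [0, 1] by dividing by the file maximum whenever
    any value exceeds 1 (raw inhibition percentages are a common case).
    """
    path = Path(path)
    sep = r"\s+|,|;|\t"
    first = path.read_text().lstrip().splitlines()[0] if path.stat().st_size else ""
    tokens = [t for t in pd.Series([first]).str.split(sep).iloc[0] if t]
    has_header = any(not _is_number(t) for t in tokens)

    if has_header:
        # cells kept as strings: float() is correctly rounded, so a
        # save -> load round trip is bit-exact
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
        if df.shape[1] != grid.n + 1:
            raise ValueError(
                f"long-format file must have {grid.n} index columns plus one "
                f"value column, found {df.shape[1]} columns"
            )
        if len(df) != grid.size:
            raise ValueError(
                f"expected {grid.size} rows, found {len(df)}"
            )
        vals = np.full(grid.shape, np.nan)
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            entries = list(row)
            try:
                idx = tuple(int(v) for v in entries[: grid.n])
                v = float(entries[-1])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"non-numeric cell at line {row_no}") from exc
            if not grid.contains(idx):
                raise ValueError(f"index {idx} at line {row_no} outside grid")
            vals[idx] = v
        if np.isnan(vals).any():
            raise ValueError("file does not cover every grid point exactly once")
    else:
        if grid.n != 2:
            raise ValueError("dense matrix layout is only defined for n=2")
        df = pd.read_csv(path, sep=sep, engine="python", header=None, dtype=str)
        arr = df.to_numpy()
        if arr.shape != grid.shape:
            raise ValueError(
                f"matrix shape {arr.shape} does not match grid shape {grid.shape}"
            )
        try:
            vals = arr.astype(float)
        except ValueError as exc:
            bad = [
                i + 1
                for i in range(arr.shape[0])
                if not all(_is_number(str(x)) for x in arr[i])
            ]
            raise ValueError(f"non-numeric cell in row(s) {bad}") from exc

    if np.any(vals < 0):
        bad_rows = np.unique(np.argwhere(vals < 0)[:, 0]) + 1
        raise ValueError(f"negative sensitivities in row(s) {bad_rows.tolist()}")
    if vals.max() > 1:
        vals = vals / vals.max()
    return ResponseSurface(grid=grid, values=vals)


def save_surface(surface: ResponseSurface, path: str | Path) -> None:
    """Write a surface in long format (``d1..dn,sensitivity``), full precision."""
    grid = surface.grid
    idx = _index_mesh(grid)
    df = pd.DataFrame(idx, columns=[f"d{i + 1}" for i in range(grid.n)])
    df["sensitivity"] = surface.values.reshape(-1)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def points_within_fraction(
    surface: ResponseSurface, fraction: float
) -> set[GridPoint]:
    """All lattice points with sensitivity >= fraction * max sensitivity.

    With fraction 0.95 this counts the near-optimal cocktails — the
    denominator of how hard a surface is to search.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    cut = fraction * surface.max_value
    return {tuple(i) for i in np.argwhere(surface.values >= cut)}


def l1_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """L1 (taxicab) distance between two lattice points."""
    return int(np.abs(np.asarray(a) - np.asarray(b)).sum())


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
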