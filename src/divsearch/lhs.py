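"""Maximin Latin-hypercube initialization (the parallel phase of the search).

The first ``m`` experiments are placed by drawing a Latin-hypercube sample
in the continuous unit cube, improving it under the maximin criterion
(maximize the minimum pairwise distance), and snapping the points to the
nearest lattice cells.  Stratified-but-spread placement buys a reasonable
first sketch of the response surface for a fixed experimental budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.spatial.distance import pdist

from .grid import GridPoint, SearchGrid


@dataclass
class LhsConfig:
    """Initial-design settings.

    m : number of initial experiments (Latin-hypercube points).
    max_iterations : budget of candidate column swaps for the maximin
        improvement loop; each accepted swap strictly increases the minimum
        pairwise distance, so the objective is monotone in the budget.
    seed : RNG seed; ``None`` means the caller supplies a Generator.
    """

    m: int = 10
    max_iterations: int = 1000
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


def default_m(grid: SearchGrid) -> int:
    """Initial-design size used by default: 10 points for 3-5 drugs,
    5 for a synthetic two-drug grid, 3 for small tabulated two-drug grids."""
    if grid.n >= 3:
        return 10
    return 3 if grid.size <= 100 else 5


def min_pairwise_distance(points: np.ndarray) -> float:
    """Exact minimum Euclidean distance over all point pairs."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("min_pairwise_distance needs at least 2 points")
    return float(pdist(points).min())


def generate_maximin_lhs(
    config: LhsConfig, n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw an (m, n) Latin-hypercube sample and improve its maximin score.

    Each column is a random permutation of the m strata with uniform jitter
    inside each stratum, so every dimension keeps exactly one point per
    stratum.  Improvement proposes swaps of two entries within one column
    (which preserves the stratification) and accepts a swap iff the minimum
    pairwise distance strictly increases.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.m
    sample = np.empty((m, n))
    for j in range(n):
        sample[:, j] = (rng.permutation(m) + rng.random(m)) / m
    if m < 2:
        return sample

    best = min_pairwise_distance(sample)
    for _ in range(config.max_iterations):
        j = int(rng.integers(n))
        a, b = rng.choice(m, size=2, replace=False)
        sample[[a, b], j] = sample[[b, a], j]
        score = min_pairwise_distance(sample)
        if score > best:
            best = score
        else:
            sample[[a, b], j] = sample[[b, a], j]  # revert
    return sample


def snap_to_grid(points: np.ndarray, grid: SearchGrid) -> list[GridPoint]:
    """Map continuous unit-cube points to the nearest lattice points.

    Coordinate x snaps to round(x * T).  When two continuous points land in
    the same cell the later one is moved to the nearest unoccupied cell
    (L1-nearest, ties broken lexicographically) so that the initial design
    still spends its full budget on distinct experiments.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != grid.n:
        raise ValueError(
            f"points have dimension {points.shape[1]}, grid has {grid.n}"
        )
    snapped: list[GridPoint] = []
    occupied: set[GridPoint] = set()
    for x in points:
        pt = tuple(int(v) for v in np.clip(np.rint(x * grid.T), 0, grid.T))
        if pt in occupied:
            pt = _nearest_free_cell(pt, occupied, grid)
            if pt is None:
                continue  # grid full: cannot place more distinct points
        occupied.add(pt)
        snapped.append(pt)
    return snapped


def _nearest_free_cell(
    start: GridPoint, occupied: set[GridPoint], grid: SearchGrid
) -> GridPoint | None:
    """Closest unoccupied lattice cell by L1 distance, lexicographic ties."""
    max_radius = grid.n * grid.T
    for radius in range(1, max_radius + 1):
        ring = sorted(
            pt
            for pt in _l1_ring(start, radius, grid)
            if pt not in occupied
        )
        if ring:
            return ring[0]
    return None


def _l1_ring(center: GridPoint, radius: int, grid: SearchGrid):
    """All lattice points at exact L1 distance ``radius`` from ``center``."""
    offsets_per_axis = range(-radius, radius + 1)
    for offsets in product(offsets_per_axis, repeat=grid.n):
        if sum(abs(o) for o in offsets) != radius:
            continue
        pt = tuple(c + o for c, o in zip(center, offsets))
        if all(0 <= v <= grid.T for v in pt):
            yield pt
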