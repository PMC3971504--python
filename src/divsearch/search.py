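"""Diverse stochastic search: sequential dose-finding on a lattice oracle.

The run has two phases.  The parallel phase spends m experiments on a
maximin Latin-hypercube design.  The iterative phase then repeats:

1. min-max normalize the measured sensitivities and raise them to the
   (n-1)th power, which sharpens peaks relative to average terrain;
2. inpaint the full surface from the measured cells (DCT-penalized least
   squares);
3. with probability ``p_focus`` run a *focused* step — walk the surface
   values from the top and test the first estimated (untested) cell that
   does not sit on an already "discovered" hill — otherwise run a
   *diverse* step — treat the estimate as an unnormalized PMF, Gibbs
   sample from it, and test one of the sampled untested cells.

Hill bookkeeping keeps the focused path from circling one peak: tested
points are labeled by the hill (steepest-ascent basin) they belong to; a
hill whose top xi points have all been tested is "discovered" and its
cells are skipped.  If the focused walk inspects ~1% of the grid without
finding a candidate, the estimates inside a small sphere around the
current top are zeroed (archived, restorable) and the iteration restarts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln

from .grid import GridPoint, ResponseSurface, SearchGrid
from .lhs import LhsConfig, generate_maximin_lhs, snap_to_grid
from .smoothing import SmootherProblem, estimate_surface

logger = logging.getLogger(__name__)

Path_ = Literal["init", "focused", "diverse"]


@dataclass
class SearchParams:
    """Tunable parameters of the iterative phase.

    Fields left at ``None`` are resolved per grid by :meth:`resolve`:
    power_exponent -> n - 1; cluster_threshold -> 2n - 1 if n < 5 else 7;
    cluster_break -> ceil(1% of grid points); gibbs_points -> twice the
    grid size when the grid has fewer than 7500 points, else 15000.
    """

    p_focus: float = 0.3
    power_exponent: int | None = None
    cluster_threshold: int | None = None
    cluster_break: int | None = None
    cluster_sphere_fraction: float = 1.0 / 500.0
    gibbs_points: int | None = None
    gibbs_burn_in: int = 10
    smoothing_s: float = 1e-3
    smoothing_iters: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_focus <= 1:
            raise ValueError(f"p_focus must be in [0, 1], got {self.p_focus}")
        if not 0 < self.cluster_sphere_fraction < 1:
            raise ValueError("cluster_sphere_fraction must be in (0, 1)")

    def resolve(self, grid: SearchGrid) -> "SearchParams":
        """Fill grid-dependent defaults; returns a new fully specified copy."""
        n, size = grid.n, grid.size
        return SearchParams(
            p_focus=self.p_focus,
            power_exponent=(
                self.power_exponent if self.power_exponent is not None
                else max(1, n - 1)
            ),
            cluster_threshold=(
                self.cluster_threshold if self.cluster_threshold is not None
                else (2 * n - 1 if n < 5 else 7)
            ),
            cluster_break=(
                self.cluster_break if self.cluster_break is not None
                else math.ceil(0.01 * size)
            ),
            cluster_sphere_fraction=self.cluster_sphere_fraction,
            gibbs_points=(
                self.gibbs_points if self.gibbs_points is not None
                else (2 * size if size < 7500 else 15000)
            ),
            gibbs_burn_in=self.gibbs_burn_in,
            smoothing_s=self.smoothing_s,
            smoothing_iters=self.smoothing_iters,
            seed=self.seed,
        )


class ExperimentRecord(NamedTuple):
    iteration: int  # 1-based oracle-query index
    point: GridPoint
    sensitivity: float
    path: Path_


@dataclass
class SuppressionSphere:
    """A zeroed L2 ball around an over-explored peak, with archived values."""

    center: GridPoint
    radius: float
    archived: dict[GridPoint, float]


@dataclass
class SearchState:
    """Full trajectory and bookkeeping of one search run."""

    grid: SearchGrid
    experiments: list[ExperimentRecord] = field(default_factory=list)
    estimate: np.ndarray | None = None
    hill_labels: dict[GridPoint, tuple[GridPoint, int]] = field(
        default_factory=dict
    )
    discovered_hills: set[GridPoint] = field(default_factory=set)
    suppressions: list[SuppressionSphere] = field(default_factory=list)
    rng: np.random.Generator = field(
        default_factory=np.random.default_rng
    )

    @property
    def tested(self) -> set[GridPoint]:
        return {rec.point for rec in self.experiments}

    @property
    def points(self) -> list[GridPoint]:
        return [rec.point for rec in self.experiments]

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([rec.sensitivity for rec in self.experiments])

    def best(self) -> ExperimentRecord:
        return max(self.experiments, key=lambda r: r.sensitivity)


class ClusterBreak(NamedTuple):
    """Signal that the focused walk gave up and zeroed a sphere."""

    sphere: SuppressionSphere


def normalize_and_power(values: Sequence[float], n: int) -> np.ndarray:
    """Min-max normalize measured values to [0,1], then raise to power n-1.

    The monotone transform preserves the ranking while emphasizing peaks.
    An all-equal input carries no ranking information and maps to all ones
    (a flat, uniform sampling weight).
    """
    if n < 2:
        raise ValueError(f"power rule needs n >= 2 drugs, got n={n}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one measured value")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values)
    return ((values - lo) / (hi - lo)) ** (n - 1)


def choose_path(
    rng: np.random.Generator, p_focus: float
) -> Literal["focused", "diverse"]:
    """Bernoulli(p_focus) draw deciding the character of this iteration."""
    return "focused" if rng.random() < p_focus else "diverse"


def _axis_neighbors(point: GridPoint, grid: SearchGrid):
    for axis in range(grid.n):
        for step in (-1, 1):
            v = point[axis] + step
            if 0 <= v <= grid.T:
                yield point[:axis] + (v,) + point[axis + 1:]


def ascent_path(
    estimate: np.ndarray, grid: SearchGrid, start: GridPoint
) -> GridPoint:
    """Steepest-ascent terminal among axis neighbors on the estimate.

    Moves to the highest strictly-better axis neighbor until none exists;
    ties among equally-best improving neighbors break to the
    lexicographically smallest index vector, so the walk is deterministic.
    """
    current = start
    while True:
        best_val = estimate[current]
        best_pt = None
        for nb in _axis_neighbors(current, grid):
            v = estimate[nb]
            if v > best_val or (v == best_val and best_pt is not None and nb < best_pt):
                best_val = v
                best_pt = nb
        if best_pt is None:
            return current
        current = best_pt


def _hill_of(
    point: GridPoint,
    estimate: np.ndarray,
    grid: SearchGrid,
    cache: dict[GridPoint, GridPoint],
) -> GridPoint:
    """Hill identity = ascent terminal; memoized along the walked path."""
    path = []
    cur = point
    while cur not in cache:
        path.append(cur)
        nxt = _ascent_step(estimate, grid, cur)
        if nxt is None:
            cache[cur] = cur
            break
        cur = nxt
    terminal = cache[cur]
    for p in path:
        cache[p] = terminal
    return terminal


def _ascent_step(
    estimate: np.ndarray, grid: SearchGrid, point: GridPoint
) -> GridPoint | None:
    best_val = estimate[point]
    best_pt = None
    for nb in _axis_neighbors(point, grid):
        v = estimate[nb]
        if v > best_val or (v == best_val and best_pt is not None and nb < best_pt):
            best_val = v
            best_pt = nb
    return best_pt


def cluster_sphere_radius(grid: SearchGrid, volume_fraction: float) -> float:
    """Radius of the L2 ball covering ``volume_fraction`` of the lattice.

    Solves c_n * r**n = volume_fraction * (T+1)**n with c_n the unit
    n-ball volume coefficient pi^(n/2) / Gamma(n/2 + 1).
    """
    n = grid.n
    c_n = math.exp((n / 2) * math.log(math.pi) - gammaln(n / 2 + 1))
    return (volume_fraction * grid.size / c_n) ** (1.0 / n)


def focused_step(
    state: SearchState, params: SearchParams, estimate: np.ndarray
) -> GridPoint | ClusterBreak:
    """One pass of the focused (path a) walk over the sorted surface values.

    Walks cells from highest to lowest estimated sensitivity (ties broken
    by lexicographic cell order).  Tested cells met along the way are
    labeled with the hill they ascend to; once a hill has accumulated
    ``cluster_threshold`` tested points it counts as discovered and its
    cells are skipped.  The first untested cell on an undiscovered hill is
    the next experiment.  If ``cluster_break`` cells are inspected without
    finding one, the walk gives up: estimates inside the cluster sphere
    around the current top cell are archived and zeroed, and a
    :class:`ClusterBreak` is returned so the iteration can restart.
    """
    grid = state.grid
    flat = estimate.reshape(-1)
    order = np.lexsort((np.arange(flat.size), -flat))
    tested = state.tested
    cache: dict[GridPoint, GridPoint] = {}
    hill_counts: dict[GridPoint, int] = {}
    limit = min(params.cluster_break, flat.size)

    for rank in range(limit):
        point = tuple(
            int(v) for v in np.unravel_index(order[rank], grid.shape)
        )
        hill = _hill_of(point, estimate, grid, cache)
        if point in tested:
            count = hill_counts.get(hill, 0) + 1
            hill_counts[hill] = count
            state.hill_labels[point] = (hill, count)
            if count >= params.cluster_threshold:
                state.discovered_hills.add(hill)
            continue
        if hill in state.discovered_hills:
            continue
        return point

    # Give up on this neighborhood: zero a small sphere around the top cell.
    top = tuple(int(v) for v in np.unravel_index(order[0], grid.shape))
    radius = cluster_sphere_radius(grid, params.cluster_sphere_fraction)
    archived: dict[GridPoint, float] = {}
    for offsets in np.ndindex(*(2 * int(radius) + 1,) * grid.n):
        pt = tuple(
            t + o - int(radius) for t, o in zip(top, offsets)
        )
        if not grid.contains(pt):
            continue
        if sum((a - b) ** 2 for a, b in zip(pt, top)) <= radius**2:
            archived[pt] = float(estimate[pt])
    sphere = SuppressionSphere(center=top, radius=radius, archived=archived)
    state.suppressions.append(sphere)
    return ClusterBreak(sphere=sphere)


def gibbs_sample(
    pmf: np.ndarray,
    count: int,
    burn_in: int,
    rng: np.random.Generator,
) -> list[GridPoint]:
    """Systematic-scan Gibbs sampler on a discrete grid distribution.

    Each sweep redraws every coordinate from its exact 1-D conditional
    (the normalized slice of the tensor through the current state); one
    sample is recorded per sweep after ``burn_in`` sweeps.
    """
    pmf = np.asarray(pmf, dtype=float)
    if np.any(pmf < 0):
        raise ValueError("pmf entries must be non-negative")
    total = pmf.sum()
    if total <= 0:
        raise ValueError("pmf must have at least one positive entry")
    n = pmf.ndim
    # start at a random positive cell so every conditional slice has mass
    positive = np.argwhere(pmf > 0)
    state = list(positive[rng.integers(len(positive))])
    # per-axis cumulative sums: every 1-D conditional CDF is a slice view
    cums = [np.cumsum(pmf, axis=a) for a in range(n)]
    uniforms = rng.random((burn_in + count, n))
    samples: list[GridPoint] = []
    for sweep in range(burn_in + count):
        for axis in range(n):
            index = tuple(
                slice(None) if a == axis else state[a] for a in range(n)
            )
            cum = cums[axis][index]
            # inverse-CDF draw from the exact 1-D conditional
            state[axis] = int(
                np.searchsorted(
                    cum, uniforms[sweep, axis] * cum[-1], side="right"
                )
            )
        if sweep >= burn_in:
            samples.append(tuple(state))
    return samples


def diverse_step(
    state: SearchState, params: SearchParams, estimate: np.ndarray
) -> GridPoint:
    """One diverse (path b) step: sample the estimate as a distribution.

    Draws ``gibbs_points`` Gibbs samples from the (non-negative) estimate
    and picks one uniformly among those not yet tested; if every sample is
    already tested, falls back to a uniform draw over untested cells.
    """
    grid = state.grid
    pmf = np.clip(estimate, 0.0, None)
    if pmf.sum() <= 0:
        pmf = np.ones_like(pmf)
    samples = gibbs_sample(
        pmf, params.gibbs_points, params.gibbs_burn_in, state.rng
    )
    tested = state.tested
    fresh = [pt for pt in samples if pt not in tested]
    if fresh:
        return fresh[int(state.rng.integers(len(fresh)))]
    untested = [pt for pt in state.grid.iter_points() if pt not in tested]
    if not untested:
        raise RuntimeError("every grid point has already been tested")
    logger.debug("all Gibbs samples already tested; uniform fallback")
    return untested[int(state.rng.integers(len(untested)))]


def _suppressed_estimate(state: SearchState, estimate: np.ndarray) -> np.ndarray:
    out = estimate.copy()
    for sphere in state.suppressions:
        for pt in sphere.archived:
            out[pt] = 0.0
    return out


def restore_suppressions(state: SearchState, point: GridPoint) -> None:
    """Lift any suppression sphere that the newly tested point falls inside.

    Archived estimates are only masks on recomputed surfaces, so lifting a
    sphere restores the original values exactly.
    """
    kept = []
    for sphere in state.suppressions:
        d2 = sum((a - b) ** 2 for a, b in zip(point, sphere.center))
        if d2 <= sphere.radius**2:
            logger.debug("restoring suppression sphere at %s", sphere.center)
            continue
        kept.append(sphere)
    state.suppressions = kept


def dss_iterate(
    oracle: ResponseSurface,
    lhs: LhsConfig,
    params: SearchParams,
    max_steps: int,
    stop_value: float | None = None,
) -> SearchState:
    """Run the full search: LHS phase then focused/diverse iterations.

    Up to ``max_steps`` oracle queries are made (the first ``lhs.m`` by
    the initial design), each logged in order; no grid point is ever
    queried twice.  All randomness flows from one seeded generator in a
    fixed order (LHS, then per-iteration path choice and sampling), so a
    run is bit-reproducible from ``params.seed``.  If ``stop_value`` is
    given, the run ends as soon as a measured sensitivity reaches it —
    the screening-protocol stop once a good-enough cocktail is in hand;
    otherwise exactly ``max_steps`` queries are spent.
    """
    grid = oracle.grid
    params = params.resolve(grid)
    if max_steps < lhs.m:
        raise ValueError(
            f"max_steps ({max_steps}) must cover the initial design (m={lhs.m})"
        )
    if max_steps > grid.size:
        raise ValueError("max_steps cannot exceed the number of grid points")
    rng = np.random.default_rng(params.seed)
    state = SearchState(grid=grid, rng=rng)

    # Phase 1: maximin Latin-hypercube design, snapped to distinct cells.
    design = snap_to_grid(generate_maximin_lhs(lhs, grid.n, rng=rng), grid)
    for pt in design:
        value = oracle.query(pt)
        state.experiments.append(
            ExperimentRecord(len(state.experiments) + 1, pt, value, "init")
        )
    if stop_value is not None and state.sensitivities.max() >= stop_value:
        return state

    consecutive_breaks = 0
    while len(state.experiments) < max_steps:
        weights = normalize_and_power(state.sensitivities, grid.n)
        y = np.zeros(grid.shape)
        w = np.zeros(grid.shape)
        for pt, wt in zip(state.points, weights):
            y[pt] = wt
            w[pt] = 1.0
        est = estimate_surface(
            SmootherProblem(
                y=y, weights=w, s=params.smoothing_s,
                n_iters=params.smoothing_iters,
            )
        ).values
        est = np.clip(est, 0.0, None)
        est = _suppressed_estimate(state, est)
        state.estimate = est

        path = choose_path(rng, params.p_focus)
        candidate: GridPoint | None = None
        if path == "focused":
            result = focused_step(state, params, est)
            if isinstance(result, ClusterBreak):
                consecutive_breaks += 1
                if consecutive_breaks < 5:
                    continue  # restart the iteration with the sphere zeroed
                logger.warning(
                    "repeated cluster breaks; falling through to diverse step"
                )
                path = "diverse"
            else:
                candidate = result
        if candidate is None:
            candidate = diverse_step(state, params, est)
            path = "diverse"
        consecutive_breaks = 0

        if candidate in state.tested:  # defensive: contract of both paths
            raise RuntimeError(f"candidate {candidate} already tested")
        value = oracle.query(candidate)
        state.experiments.append(
            ExperimentRecord(len(state.experiments) + 1, candidate, value, path)
        )
        restore_suppressions(state, candidate)
        if stop_value is not None and value >= stop_value:
            break
    return state
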