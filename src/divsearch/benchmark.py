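"""Repeated seeded evaluation: cost, success rate and distance trajectories.

Cost is the number of oracle queries (experiments) until the first tested
point reaches ``threshold`` (default 0.95) times the surface maximum,
counting the initial Latin-hypercube queries.  Success rate is the
fraction of runs that get there within a fixed query budget.  A uniform
sampling-without-replacement baseline provides the control: on a surface
with q qualifying points out of N its expected cost is (N+1)/(q+1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .grid import GridPoint, ResponseSurface, l1_distance, points_within_fraction
from .lhs import LhsConfig
from .search import SearchParams, SearchState, dss_iterate

SurfaceFactory = Callable[[int], ResponseSurface]


@dataclass
class BenchmarkResult:
    """Aggregate metrics over repeated seeded runs."""

    cost: float
    std: float
    worst_case: float
    success_rate: float
    n_runs: int
    threshold: float
    budget: int
    first_passages: list[int | None] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cost": self.cost,
            "std": self.std,
            "worst_case": self.worst_case,
            "success_rate": self.success_rate,
            "n_runs": self.n_runs,
            "threshold": self.threshold,
            "budget": self.budget,
            "first_passages": self.first_passages,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def first_passage(
    trajectory: Sequence[tuple[GridPoint, float]],
    threshold: float,
    max_value: float,
) -> int | None:
    """1-based index of the first experiment reaching threshold*max, if any."""
    cut = threshold * max_value
    for i, (_, value) in enumerate(trajectory, start=1):
        if value >= cut:
            return i
    return None


def _summarize(
    passages: list[int | None], n_runs: int, threshold: float, budget: int
) -> BenchmarkResult:
    reached = [p for p in passages if p is not None]
    return BenchmarkResult(
        cost=float(np.mean(reached)) if reached else float("nan"),
        std=float(np.std(reached, ddof=1)) if len(reached) > 1 else 0.0,
        worst_case=float(max(reached)) if reached else float("nan"),
        success_rate=len(reached) / n_runs,
        n_runs=n_runs,
        threshold=threshold,
        budget=budget,
        first_passages=passages,
    )


def run_trials(
    surface: ResponseSurface | SurfaceFactory,
    lhs: LhsConfig,
    params: SearchParams,
    n_runs: int = 100,
    budget: int | None = None,
    threshold: float = 0.95,
    base_seed: int = 0,
    keep_states: bool = False,
) -> BenchmarkResult | tuple[BenchmarkResult, list[SearchState]]:
    """Run the search ``n_runs`` times with seeds base_seed..base_seed+n-1.

    ``surface`` may be a fixed :class:`ResponseSurface` (its query counter
    is reset per run) or a callable mapping a run seed to a fresh surface,
    which models per-run randomized problem instances.  Cost counts every
    oracle query including the initial design.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    passages: list[int | None] = []
    states: list[SearchState] = []
    for i in range(n_runs):
        seed = base_seed + i
        surf = surface(seed) if callable(surface) else surface
        if budget is None:
            run_budget = min(surf.grid.size, 10 * (surf.grid.T + 1) * surf.grid.n)
        else:
            run_budget = budget
        if not callable(surface):
            surf.reset_counter()
        run_params = SearchParams(**{**params.__dict__, "seed": seed})
        state = dss_iterate(
            surf, lhs, run_params, max_steps=run_budget,
            stop_value=threshold * surf.max_value,
        )
        trajectory = [(r.point, r.sensitivity) for r in state.experiments]
        passages.append(first_passage(trajectory, threshold, surf.max_value))
        if keep_states:
            states.append(state)
    result = _summarize(
        passages, n_runs, threshold,
        run_budget if budget is None else budget,
    )
    return (result, states) if keep_states else result


def min_distance_trajectory(
    points: Sequence[GridPoint], optima: Sequence[GridPoint] | frozenset
) -> np.ndarray:
    """Running minimum L1 distance from tested points to any optimum.

    Element t is the minimum over the first t+1 tested points and all
    optima; the sequence is non-increasing by construction.
    """
    optima = list(optima)
    if not points or not optima:
        raise ValueError("need at least one tested point and one optimum")
    out = np.empty(len(points))
    best = np.inf
    for i, pt in enumerate(points):
        best = min(best, min(l1_distance(pt, opt) for opt in optima))
        out[i] = best
    return out


def expected_cost_without_replacement(n_points: int, n_qualifying: int) -> float:
    """Closed-form mean draws to hit one of q marked points out of N
    when sampling uniformly without replacement: (N + 1) / (q + 1)."""
    if n_qualifying < 1 or n_qualifying > n_points:
        raise ValueError("need 1 <= n_qualifying <= n_points")
    return (n_points + 1) / (n_qualifying + 1)


def random_search_baseline(
    surface: ResponseSurface,
    n_runs: int = 100,
    budget: int | None = None,
    threshold: float = 0.95,
    seed: int = 0,
) -> BenchmarkResult:
    """Uniform sampling without replacement, same metrics as run_trials."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    grid = surface.grid
    if budget is None:
        budget = grid.size
    qualifying = points_within_fraction(surface, threshold)
    flat_ok = np.zeros(grid.size, dtype=bool)
    for pt in qualifying:
        flat_ok[np.ravel_multi_index(pt, grid.shape)] = True
    rng = np.random.default_rng(seed)
    passages: list[int | None] = []
    for _ in range(n_runs):
        order = rng.permutation(grid.size)[:budget]
        hits = np.nonzero(flat_ok[order])[0]
        passages.append(int(hits[0]) + 1 if hits.size else None)
    return _summarize(passages, n_runs, threshold, budget)
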