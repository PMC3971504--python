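import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from divsearch import (
    LhsConfig,
    SearchParams,
    ascent_path,
    choose_path,
    diverse_step,
    dss_iterate,
    focused_step,
    gibbs_sample,
    make_grid,
    make_inverted_sphere_surface,
    normalize_and_power,
)
from divsearch.search import ClusterBreak, ExperimentRecord, SearchState


def make_state(grid, tested=(), values=None, seed=0):
    state = SearchState(grid=grid, rng=np.random.default_rng(seed))
    values = values or [0.5] * len(tested)
    for i, (pt, v) in enumerate(zip(tested, values), start=1):
        state.experiments.append(ExperimentRecord(i, tuple(pt), v, "init"))
    return state


class TestNormalizeAndPower:
    def test_minmax_then_power(self):
        np.testing.assert_allclose(
            normalize_and_power([2, 4, 6], n=2), [0.0, 0.5, 1.0]
        )
        np.testing.assert_allclose(
            normalize_and_power([0.0, 0.5, 1.0], n=3), [0.0, 0.25, 1.0]
        )

    def test_constant_input_maps_to_flat_weights(self):
        np.testing.assert_array_equal(
            normalize_and_power([0.4, 0.4, 0.4], n=4), [1.0, 1.0, 1.0]
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=2, max_size=12,
        ),
        n=st.integers(min_value=2, max_value=6),
    )
    def test_ranking_preserved(self, values, n):
        out = normalize_and_power(values, n)
        order_in = np.argsort(values, kind="stable")
        assert np.all(np.diff(np.asarray(out)[order_in]) >= -1e-12)


class TestChoosePath:
    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(0)
        assert all(choose_path(rng, 0.0) == "diverse" for _ in range(20))
        assert all(choose_path(rng, 1.0) == "focused" for _ in range(20))

    def test_frequency_matches_bernoulli(self):
        rng = np.random.default_rng(7)
        draws = sum(choose_path(rng, 0.3) == "focused" for _ in range(10_000))
        sigma = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(draws / 10_000 - 0.3) < 3 * sigma


class TestAscentPath:
    def test_local_max_stays_put(self):
        grid = make_grid(2, 4)
        est = np.zeros(grid.shape)
        est[2, 2] = 1.0
        assert ascent_path(est, grid, (2, 2)) == (2, 2)

    def test_monotone_ramp_reaches_top(self):
        grid = make_grid(1, 9)
        est = np.linspace(0, 1, 10)
        assert ascent_path(est, grid, (0,)) == (9,)

    def test_matches_brute_force_climb(self, rng):
        grid = make_grid(2, 5)
        for _ in range(10):
            est = rng.random(grid.shape)
            start = tuple(rng.integers(0, 6, 2))
            assert ascent_path(est, grid, start) == _oracle_climb(est, grid, start)


def _oracle_climb(est, grid, point):
    while True:
        neighbors = []
        for axis in range(grid.n):
            for step in (-1, 1):
                v = point[axis] + step
                if 0 <= v <= grid.T:
                    neighbors.append(point[:axis] + (v,) + point[axis + 1:])
        better = [nb for nb in neighbors if est[nb] > est[point]]
        if not better:
            return point
        top = max(est[nb] for nb in better)
        point = sorted(nb for nb in better if est[nb] == top)[0]


class TestFocusedStep:
    def params(self, **kw):
        defaults = dict(cluster_threshold=3, cluster_break=100)
        defaults.update(kw)
        return SearchParams(**defaults).resolve(make_grid(1, 6))

    def test_top_estimated_point_returned_immediately(self):
        grid = make_grid(1, 6)
        est = np.linspace(0, 1, 7)
        state = make_state(grid)
        assert focused_step(state, self.params(), est) == (6,)

    def test_same_hill_candidate_below_tested_points(self):
        # ramp: the top two cells are tested, the third is the candidate
        grid = make_grid(1, 6)
        est = np.linspace(0, 1, 7)
        state = make_state(grid, tested=[(6,), (5,)])
        assert focused_step(state, self.params(), est) == (4,)
        assert state.hill_labels[(6,)] == ((6,), 1)
        assert state.hill_labels[(5,)] == ((6,), 2)

    def test_discovered_hill_is_skipped(self):
        # two hills; the dominant one has its top-xi cells tested, so the
        # next candidate must come from the second hill
        grid = make_grid(1, 6)
        est = np.array([0.1, 0.9, 1.0, 0.8, 0.2, 0.55, 0.7])
        state = make_state(grid, tested=[(2,), (1,)])
        params = self.params(cluster_threshold=2)
        candidate = focused_step(state, params, est)
        assert (2,) in state.discovered_hills
        assert candidate == (6,)  # peak of the undiscovered hill

    def test_exhausted_walk_triggers_cluster_break(self):
        grid = make_grid(1, 6)
        est = np.linspace(0, 1, 7)
        state = make_state(grid, tested=[(6,), (5,), (4,)])
        params = self.params(cluster_threshold=10, cluster_break=3)
        result = focused_step(state, params, est)
        assert isinstance(result, ClusterBreak)
        sphere = result.sphere
        assert sphere.center == (6,)
        # archived values restore the original estimates exactly
        for pt, original in sphere.archived.items():
            assert est[pt] == original
        assert state.suppressions == [sphere]


class TestGibbsSample:
    def test_point_mass_always_sampled(self):
        pmf = np.zeros((5, 5))
        pmf[3, 1] = 1.0
        rng = np.random.default_rng(0)
        samples = gibbs_sample(pmf, 50, 5, rng)
        assert set(samples) == {(3, 1)}

    def test_uniform_frequencies_within_binomial_bound(self):
        pmf = np.ones((11, 11))
        rng = np.random.default_rng(1)
        samples = gibbs_sample(pmf, 10_000, 10, rng)
        counts = np.zeros((11, 11))
        for pt in samples:
            counts[pt] += 1
        p = 1 / 121
        sigma = np.sqrt(p * (1 - p) / 10_000)
        assert np.abs(counts / 10_000 - p).max() < 4 * sigma

    def test_two_hill_mass_ratio(self):
        from divsearch import make_hill_surface

        grid = make_grid(2, 8)
        surf = make_hill_surface(
            grid, [((2, 2), 2.0, 1.0), ((6, 6), 2.0, 0.6)], floor=0.05
        )
        pmf = surf.values
        # hill membership: nearer center (ties impossible off-diagonal)
        near_a = np.zeros(grid.shape, dtype=bool)
        for pt in grid.iter_points():
            near_a[pt] = (
                sum((a - b) ** 2 for a, b in zip(pt, (2, 2)))
                < sum((a - b) ** 2 for a, b in zip(pt, (6, 6)))
            )
        true_ratio = pmf[near_a].sum() / pmf[~near_a].sum()
        samples = gibbs_sample(pmf, 10_000, 10, np.random.default_rng(2))
        hits_a = sum(near_a[pt] for pt in samples)
        emp_ratio = hits_a / (len(samples) - hits_a)
        assert abs(emp_ratio - true_ratio) / true_ratio < 0.10

    def test_degenerate_pmf_rejected(self):
        with pytest.raises(ValueError):
            gibbs_sample(np.zeros((3, 3)), 10, 1, np.random.default_rng(0))


class TestDiverseStep:
    def test_concentrated_estimate_returns_its_peak(self):
        grid = make_grid(2, 4)
        est = np.zeros(grid.shape)
        est[1, 3] = 1.0
        state = make_state(grid)
        params = SearchParams().resolve(grid)
        assert diverse_step(state, params, est) == (1, 3)

    def test_never_repeats_a_tested_point(self):
        grid = make_grid(2, 2)
        est = np.zeros(grid.shape)
        est[1, 1] = 1.0  # point mass sits on an already tested cell
        state = make_state(grid, tested=[(1, 1)])
        params = SearchParams().resolve(grid)
        for _ in range(10):
            assert diverse_step(state, params, est) != (1, 1)

    def test_candidate_frequency_tracks_estimate_height(self):
        grid = make_grid(2, 4)
        rng = np.random.default_rng(3)
        est = rng.random(grid.shape) ** 3
        params = SearchParams(gibbs_points=50).resolve(grid)
        counts = {}
        for seed in range(300):
            state = make_state(grid, seed=seed)
            pt = diverse_step(state, params, est)
            counts[pt] = counts.get(pt, 0) + 1
        pts = list(grid.iter_points())
        rho, _ = spearmanr(
            [est[pt] for pt in pts], [counts.get(pt, 0) for pt in pts]
        )
        assert rho > 0.3


class TestFullRun:
    def test_query_accounting_and_uniqueness(self, sphere2d):
        state = dss_iterate(
            sphere2d, LhsConfig(m=5), SearchParams(seed=11), max_steps=40
        )
        assert sphere2d.n_queries == 40 == len(state.experiments)
        points = state.points
        assert len(points) == len(set(points))
        assert [r.iteration for r in state.experiments] == list(range(1, 41))

    def test_bit_reproducible_under_seed(self, grid2d):
        runs = []
        for _ in range(2):
            surf = make_inverted_sphere_surface(grid2d, (4, 16))
            runs.append(
                dss_iterate(
                    surf, LhsConfig(m=5), SearchParams(seed=77), max_steps=25
                ).experiments
            )
        assert runs[0] == runs[1]

    def test_min_distance_is_nonincreasing(self, sphere2d):
        from divsearch import min_distance_trajectory

        state = dss_iterate(
            sphere2d, LhsConfig(m=5), SearchParams(seed=5), max_steps=30
        )
        traj = min_distance_trajectory(state.points, sphere2d.optima)
        assert np.all(np.diff(traj) <= 0 + 1e-12)

    def test_budget_below_design_size_rejected(self, sphere2d):
        with pytest.raises(ValueError):
            dss_iterate(sphere2d, LhsConfig(m=10), SearchParams(), max_steps=5)

    def test_stop_value_halts_early(self, sphere2d):
        state = dss_iterate(
            sphere2d, LhsConfig(m=5), SearchParams(seed=2), max_steps=200,
            stop_value=0.95,
        )
        assert state.sensitivities.max() >= 0.95
        assert len(state.experiments) < 200
        # no sequential experiment is spent after the target is reached
        # (the initial design is a parallel batch and is never truncated)
        sequential = [r for r in state.experiments if r.path != "init"]
        assert all(r.sensitivity < 0.95 for r in sequential[:-1])
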