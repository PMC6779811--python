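"""Exhaustive/heuristic/GA search strategies and Pareto machinery."""

import itertools
import math

import numpy as np
import pytest

from ictonet.icto import calibrate_k
from ictonet.netgen import GeneratorConfig, Network, generate_network
from ictonet.optsearch import (ExhaustiveBudgetError, GAConfig, SICache,
                               _log_allocation, _ni_order, crowding_distance,
                               delta_si, fast_nondominated_sort,
                               ground_truth_search, nsga2_search,
                               optimal_set_extraction, random_search,
                               recurrent_ordering, simple_ordering,
                               StrategyResult)
from ictonet.thetadyn import ThetaParams


@pytest.fixture(scope="module")
def searched8(net8):
    """Shared cache + ground truth (sizes 1-3) on the 8-node fixture."""
    params = ThetaParams(k=30.0, n_steps=10_000, n_realizations=1, seed=17)
    cache = SICache(net8, 30.0, params)
    gt = ground_truth_search(net8, 30.0, 3, params, cache=cache)
    return net8, params, cache, gt


class TestGroundTruth:
    def test_enumeration_counts(self, searched8):
        net, params, cache, gt = searched8
        assert gt.n_evaluations == sum(math.comb(8, k) for k in (1, 2, 3))

    def test_three_node_network_enumerates_seven_sets(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = 1.0
        net = Network(weights=w, directed=True)
        params = ThetaParams(k=10.0, n_steps=2_000, seed=1)
        gt = ground_truth_search(net, 10.0, 3, params)
        assert gt.n_evaluations == 7

    def test_refusal_reports_exact_candidate_count(self, net8):
        params = ThetaParams(k=30.0, n_steps=1_000, seed=0)
        big = generate_network(
            GeneratorConfig("random_regular_directed", 20, 2.0, seed=0))
        with pytest.raises(ExhaustiveBudgetError) as exc:
            ground_truth_search(big, 30.0, 10, params, budget_ceiling=1000)
        assert exc.value.n_sets == 616_665  # sum C(20, n), n = 1..10

    def test_per_size_maximum_dominates_heuristics(self, searched8):
        net, params, cache, gt = searched8
        simple = simple_ordering(net, 30.0, params, cache=cache)
        rec = recurrent_ordering(net, 30.0, params, cache=cache)
        rnd = random_search(net, 30.0, 40, 3, params, seed=4, cache=cache)
        for other in (simple, rec, rnd):
            for size, gap in delta_si(gt, other).items():
                assert gap >= 0.0


class TestOrderings:
    def test_ni_ranking_order(self):
        assert list(_ni_order(np.array([0.1, 0.9, 0.4]))) == [1, 2, 0]

    def test_ni_ties_broken_by_lower_index(self):
        assert list(_ni_order(np.array([0.5, 0.9, 0.9, 0.1]))) == [1, 2, 0, 3]

    def test_first_pick_agrees_between_orderings(self, searched8):
        net, params, cache, _ = searched8
        simple = simple_ordering(net, 30.0, params, cache=cache)
        rec = recurrent_ordering(net, 30.0, params, cache=cache)
        assert simple.best_sets(1) == rec.best_sets(1)

    def test_star_ordering_picks_hub_first(self, star_net):
        params = ThetaParams(k=20.0, n_steps=20_000, seed=17)
        simple = simple_ordering(star_net, 20.0, params)
        assert simple.best_sets(1) == [frozenset({0})]

    def test_recurrent_tends_to_beat_simple(self):
        """Median over an ensemble: re-ranking NI after each removal gives
        solutions at least as good as the one-shot ranking."""
        gaps = []
        for seed in range(8):
            net = generate_network(
                GeneratorConfig("scale_free_static", 10, 2.0, 3.0, True,
                                seed=40 + seed))
            params = ThetaParams(n_steps=10_000, n_realizations=1, seed=7)
            try:
                cal = calibrate_k(net, params, tol=0.1)
            except Exception:
                continue
            cache = SICache(net, cal.k_star, params)
            simple = simple_ordering(net, cal.k_star, params, cache=cache)
            rec = recurrent_ordering(net, cal.k_star, params, cache=cache)
            common = set(simple.best) & set(rec.best)
            gaps.extend(rec.best_si(s) - simple.best_si(s) for s in common)
        assert np.median(gaps) >= 0.0


class TestRandomSearch:
    def test_allocation_sums_exactly_to_budget(self):
        for budget in (100, 317, 5000):
            alloc = _log_allocation(40, 20, budget)
            assert sum(alloc) == budget
            assert all(a >= 1 for a in alloc)

    def test_allocation_reproducible_and_denser_at_small_sizes(self):
        a1 = _log_allocation(40, 10, 1000)
        assert a1 == _log_allocation(40, 10, 1000)
        # log C(40, n) grows with n up to n = 20, so allocation does too
        assert a1[0] < a1[-1]

    def test_full_enumeration_when_allocation_covers_size(self, searched8):
        net, params, cache, _ = searched8
        res = random_search(net, 30.0, 60, 2, params, seed=1, cache=cache)
        # the 60-sample allocation covers C(8,1) = 8 and C(8,2) = 28 fully,
        # so both strata are enumerated exhaustively instead of sampled
        assert res.n_evaluations == 8 + 28
        assert res.sizes() == [1, 2]

    def test_budget_below_sizes_rejected(self, searched8):
        net, params, cache, _ = searched8
        with pytest.raises(ValueError):
            random_search(net, 30.0, 2, 3, params, cache=cache)

    def test_same_seed_same_result(self, searched8):
        net, params, cache, _ = searched8
        a = random_search(net, 30.0, 50, 3, params, seed=9, cache=cache)
        b = random_search(net, 30.0, 50, 3, params, seed=9, cache=cache)
        assert a.best == b.best


class TestNonDominatedSort:
    def test_worked_example(self):
        pts = [(1, 0.5), (2, 0.1), (2, 0.6), (3, 0.05)]
        fronts = fast_nondominated_sort(pts)
        assert fronts[0] == [0, 1, 3]
        assert fronts[1] == [2]

    def test_identical_points_share_front(self):
        assert fast_nondominated_sort([(1.0, 1.0)] * 5) == [[0, 1, 2, 3, 4]]

    def test_single_and_empty(self):
        assert fast_nondominated_sort([(3, 4)]) == [[0]]
        assert fast_nondominated_sort([]) == []

    def test_front_k_dominated_only_by_lower_fronts(self):
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 6, size=(30, 2)).astype(float)
        fronts = fast_nondominated_sort(pts)
        ranks = np.empty(len(pts), dtype=int)
        for k, front in enumerate(fronts):
            ranks[front] = k
        for i in range(len(pts)):
            for j in range(len(pts)):
                dominates = (np.all(pts[i] <= pts[j])
                             and np.any(pts[i] < pts[j]))
                if dominates:
                    assert ranks[i] < ranks[j]

    def test_crowding_boundaries_infinite(self):
        pts = [(1, 5.0), (2, 3.0), (3, 2.0), (4, 1.0)]
        d = crowding_distance(pts, [0, 1, 2, 3])
        assert np.isinf(d[0]) and np.isinf(d[3])
        assert np.isfinite(d[1]) and np.isfinite(d[2])


@pytest.fixture(scope="module")
def ga_run(net8):
    params = ThetaParams(k=30.0, n_steps=10_000, n_realizations=1, seed=17)
    cache = SICache(net8, 30.0, params)
    cfg = GAConfig(population_size=20, generations=12, n_runs=2,
                   size_cap=4, forbidden_nodes=frozenset({2}), seed=31)
    return nsga2_search(net8, 30.0, cfg, params, cache=cache)


class TestNSGA2:
    def test_forbidden_node_never_returned(self, ga_run):
        for _, _, members in ga_run.front.members:
            assert 2 not in members
        for size in ga_run.result.sizes():
            for s in ga_run.result.best_sets(size):
                assert 2 not in s

    def test_size_cap_respected(self, ga_run):
        assert all(size <= 4 for size, _, _ in ga_run.front.members)
        assert all(size <= 4 for size in ga_run.result.sizes())

    def test_front_is_mutually_nondominated(self, ga_run):
        pts = [(s, o) for s, o, _ in ga_run.front.members]
        for a, b in itertools.combinations(pts, 2):
            assert not (a[0] <= b[0] and a[1] < b[1])
            assert not (b[0] <= a[0] and b[1] < a[1])

    def test_running_best_is_monotone_per_run(self, ga_run):
        for history in ga_run.convergence.best_si_history:
            for earlier, later in zip(history, history[1:]):
                for size, si in earlier.items():
                    assert later[size] >= si

    def test_independent_runs_converge_on_fixture(self, ga_run):
        """With cached common-seed SI values, independent runs agree on the
        best SI per size: the across-run spread stays within 0.05."""
        report = ga_run.convergence
        assert report.converged
        assert all(v <= 0.05 for v in report.spread_per_size.values())
        assert all(h >= 0.0 for h in report.hypervolumes)

    def test_all_penalized_raises(self, net8):
        params = ThetaParams(k=30.0, n_steps=1_000, seed=0)
        cfg = GAConfig(population_size=8, generations=2, n_runs=1,
                       forbidden_nodes=frozenset(range(8)), seed=0)
        with pytest.raises(RuntimeError):
            nsga2_search(net8, 30.0, cfg, params)

    def test_ga_matches_ground_truth_on_shared_cache(self, searched8):
        net, params, cache, gt = searched8
        cfg = GAConfig(population_size=24, generations=15, n_runs=2,
                       size_cap=3, seed=5)
        ga = nsga2_search(net, 30.0, cfg, params, cache=cache)
        gaps = delta_si(gt, ga.result)
        assert all(g <= 0.02 for g in gaps.values())


class TestDeltaSIAndExtraction:
    def test_delta_si_identical_is_zero(self, searched8):
        _, _, _, gt = searched8
        assert all(v == 0.0 for v in delta_si(gt, gt).values())

    def test_delta_si_simple_arithmetic(self):
        ref = StrategyResult("a", {2: (1.0, [frozenset({0, 1})])}, 0)
        oth = StrategyResult("b", {2: (0.8, [frozenset({2, 3})])}, 0)
        assert delta_si(ref, oth) == {2: pytest.approx(0.2)}

    def test_delta_si_warns_on_missing_size(self):
        ref = StrategyResult("a", {1: (0.5, [frozenset({0})]),
                                   2: (0.9, [frozenset({0, 1})])}, 0)
        oth = StrategyResult("b", {1: (0.4, [frozenset({1})])}, 0)
        with pytest.warns(UserWarning, match="size 2 missing"):
            out = delta_si(ref, oth)
        assert list(out) == [1]

    def test_extraction_picks_smallest_above_threshold(self):
        res = StrategyResult("x", {
            1: (0.7, [frozenset({0})]),
            2: (0.995, [frozenset({0, 1})]),
            3: (1.0, [frozenset({0, 1, 2})]),
        }, 0)
        opt = optimal_set_extraction(res, 0.99)
        assert opt.status == "ok"
        assert opt.size == 2
        assert opt.sets == [frozenset({0, 1})]

    def test_extraction_keeps_co_optimal_sets(self):
        res = StrategyResult("x", {
            2: (0.995, [frozenset({0, 1}), frozenset({2, 3})]),
        }, 0)
        opt = optimal_set_extraction(res, 0.99)
        assert len(opt.sets) == 2

    def test_extraction_empty_with_diagnostic(self):
        res = StrategyResult("x", {1: (0.4, [frozenset({0})]),
                                   2: (0.6, [frozenset({0, 1})])}, 0)
        opt = optimal_set_extraction(res, 0.99)
        assert opt.status == "none_above_threshold"
        assert opt.sets == [] and opt.size is None
        assert opt.max_si == pytest.approx(0.6)


def test_gaconfig_validation():
    with pytest.raises(ValueError):
        GAConfig(population_size=15)  # odd
    with pytest.raises(ValueError):
        GAConfig(generations=0)
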