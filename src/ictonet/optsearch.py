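"""Search strategies for minimal, maximally ictogenic node sets.

The problem: among all subsets of network nodes, find the smallest sets
whose virtual resection drives Set Ictogenicity (SI) towards 1.  Exhaustive
enumeration is the ground truth but scales as sum_n C(N, n); heuristics
(simple/recurrent NI ordering, stratified random search) and a constrained
two-objective NSGA-II (minimize set size and 1 - SI simultaneously) make
larger networks tractable.  All strategies on one network share a single
SI-evaluation cache keyed by node set, so their comparison (Delta-SI) is
paired: identical sets always receive identical SI values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .icto import SIResult, evaluate_sets_si
from .netgen import Network
from .thetadyn import ClassifierConfig, ThetaParams

__all__ = [
    "SICache",
    "StrategyResult",
    "GAConfig",
    "ParetoFront",
    "ConvergenceReport",
    "NSGAResult",
    "OptimalSets",
    "ExhaustiveBudgetError",
    "ground_truth_search",
    "simple_ordering",
    "recurrent_ordering",
    "random_search",
    "fast_nondominated_sort",
    "crowding_distance",
    "nsga2_search",
    "delta_si",
    "optimal_set_extraction",
]


class ExhaustiveBudgetError(RuntimeError):
    def __init__(self, n_sets: int, budget: int):
        self.n_sets = n_sets
        self.budget = budget
        super().__init__(
            f"exhaustive search would evaluate {n_sets} candidate sets, "
            f"exceeding the budget ceiling of {budget}"
        )


class SICache:
    """Shared, batched SI evaluator with memoization by node set.

    One instance per (network, K, seed protocol); every strategy run
    against it sees identical SI values for identical sets.
    """

    def __init__(self, net: Network, k_star: float, params: ThetaParams,
                 cfg: ClassifierConfig | None = None, chunk: int = 1024):
        self.net = net
        self.k_star = k_star
        self.params = params
        self.cfg = cfg
        self.chunk = chunk
        self._table: dict[frozenset, SIResult] = {}
        self.n_requests = 0
        self.n_simulated = 0

    def evaluate(self, sets: Sequence[Iterable[int]]) -> list[SIResult]:
        keys = [frozenset(int(i) for i in x) for x in sets]
        self.n_requests += len(keys)
        missing = sorted(
            {k for k in keys if k not in self._table},
            key=lambda k: tuple(sorted(k)),
        )
        if missing:
            res = evaluate_sets_si(self.net, [tuple(sorted(k)) for k in missing],
                                   self.k_star, self.params, self.cfg,
                                   chunk=self.chunk)
            for k, r in zip(missing, res):
                self._table[k] = r
            self.n_simulated += len(missing)
        return [self._table[k] for k in keys]

    def si(self, x: Iterable[int]) -> float:
        return self.evaluate([x])[0].si

    def __len__(self):
        return len(self._table)


@dataclass
class StrategyResult:
    """Best set(s) found per resection size by one search strategy."""

    strategy: str
    best: dict[int, tuple[float, list[frozenset]]]  # size -> (si, co-optimal sets)
    n_evaluations: int
    seeds: tuple = ()

    def sizes(self) -> list[int]:
        return sorted(self.best)

    def best_si(self, size: int) -> float:
        return self.best[size][0]

    def best_sets(self, size: int) -> list[frozenset]:
        return self.best[size][1]

    def _record(self, res: SIResult) -> None:
        n = len(res.x)
        if n == 0:
            return
        if n not in self.best or res.si > self.best[n][0]:
            self.best[n] = (res.si, [res.x])
        elif res.si == self.best[n][0] and res.x not in self.best[n][1]:
            self.best[n][1].append(res.x)
            self.best[n][1].sort(key=lambda s: tuple(sorted(s)))


def _count_sets(n: int, max_size: int) -> int:
    return sum(math.comb(n, k) for k in range(1, max_size + 1))


def ground_truth_search(net: Network, k_star: float, max_size: int,
                        params: ThetaParams,
                        cache: SICache | None = None,
                        budget_ceiling: int = 2_000_000) -> StrategyResult:
    """Exhaustive SI of every set up to ``max_size`` (the ground truth).

    Refuses — reporting the exact candidate count — when the enumeration
    exceeds ``budget_ceiling``; e.g. a full 40-node search would require
    2**40 - 1 evaluations.
    """
    n = net.n_nodes
    total = _count_sets(n, max_size)
    if total > budget_ceiling:
        raise ExhaustiveBudgetError(total, budget_ceiling)
    if cache is None:
        cache = SICache(net, k_star, params)
    out = StrategyResult("ground_truth", {}, 0)
    for size in range(1, max_size + 1):
        combos = [c for c in itertools.combinations(range(n), size)]
        for res in cache.evaluate(combos):
            out._record(res)
        out.n_evaluations += len(combos)
    return out


def _ni_order(ni: np.ndarray) -> np.ndarray:
    # descending NI, ties broken by lower node index
    return np.lexsort((np.arange(len(ni)), -ni))


def simple_ordering(net: Network, k_star: float, params: ThetaParams,
                    stop_si: float = 0.99,
                    cache: SICache | None = None) -> StrategyResult:
    """Rank nodes once by NI and add them greedily until SI > ``stop_si``."""
    if cache is None:
        cache = SICache(net, k_star, params)
    n = net.n_nodes
    singles = cache.evaluate([(i,) for i in range(n)])
    ni = np.array([r.si for r in singles])
    order = _ni_order(ni)
    out = StrategyResult("simple_ordering", {}, n)
    current: list[int] = []
    for node in order:
        current.append(int(node))
        res = cache.evaluate([tuple(current)])[0]
        out._record(res)
        out.n_evaluations += 1
        if res.si > stop_si:
            break
    return out


def recurrent_ordering(net: Network, k_star: float, params: ThetaParams,
                       stop_si: float = 0.99,
                       cache: SICache | None = None) -> StrategyResult:
    """Greedy ordering that re-ranks remaining nodes after every removal.

    At each step the node whose addition gives the largest SI of the
    cumulative set is appended (equivalently: the node with the highest NI
    in the perturbed network); SI is always referenced to the intact
    network's BNI.
    """
    if cache is None:
        cache = SICache(net, k_star, params)
    n = net.n_nodes
    out = StrategyResult("recurrent_ordering", {}, 0)
    current: list[int] = []
    remaining = list(range(n))
    while remaining:
        candidates = [tuple(current + [j]) for j in remaining]
        res = cache.evaluate(candidates)
        out.n_evaluations += len(candidates)
        sis = np.array([r.si for r in res])
        pick = int(np.lexsort((np.array(remaining), -sis))[0])
        current.append(remaining[pick])
        del remaining[pick]
        best = res[pick]
        out._record(best)
        if best.si > stop_si:
            break
    return out


def _log_allocation(n: int, max_size: int, budget: int) -> list[int]:
    """Per-size sample counts proportional to log C(N, n), summing to budget."""
    weights = np.array([math.log(math.comb(n, k))
                        for k in range(1, max_size + 1)])
    weights = np.where(weights <= 0, 1e-9, weights)
    raw = budget * weights / weights.sum()
    alloc = np.floor(raw).astype(int)
    remainder = raw - alloc
    short = budget - alloc.sum()
    for idx in np.argsort(-remainder)[:short]:
        alloc[idx] += 1
    # every size gets at least one sample, borrowed from the largest bucket
    for i in range(len(alloc)):
        if alloc[i] == 0:
            alloc[int(np.argmax(alloc))] -= 1
            alloc[i] = 1
    return alloc.tolist()


def random_search(net: Network, k_star: float, budget: int, max_size: int,
                  params: ThetaParams, seed: int = 0,
                  cache: SICache | None = None) -> StrategyResult:
    """Stratified random sampling of sets, log-proportional across sizes.

    Sizes whose full enumeration fits the allocation are enumerated
    exhaustively; otherwise distinct sets are drawn uniformly without
    replacement.
    """
    if budget < max_size:
        raise ValueError(f"budget {budget} < number of sizes {max_size}")
    if cache is None:
        cache = SICache(net, k_star, params)
    n = net.n_nodes
    alloc = _log_allocation(n, max_size, budget)
    rng = np.random.default_rng(seed)
    out = StrategyResult("random_search", {}, 0, seeds=(seed,))
    for size, n_samples in zip(range(1, max_size + 1), alloc):
        total = math.comb(n, size)
        if total <= n_samples:
            combos = list(itertools.combinations(range(n), size))
        else:
            seen: set[tuple] = set()
            while len(seen) < n_samples:
                pick = tuple(sorted(rng.choice(n, size=size, replace=False).tolist()))
                seen.add(pick)
            combos = sorted(seen)
        for res in cache.evaluate(combos):
            out._record(res)
        out.n_evaluations += len(combos)
    return out


# ---------------------------------------------------------------------------
# NSGA-II
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    generations: int = 100
    n_runs: int = 8
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1/N
    size_cap: int | None = None         # default floor(N/2)
    penalty_size: float | None = None   # default N + 1
    penalty_obj: float = 2.0            # penalty on the 1 - SI objective
    forbidden_nodes: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if self.generations < 1 or self.n_runs < 1:
            raise ValueError("generations and n_runs must be >= 1")


@dataclass
class ParetoFront:
    """Non-dominated (size, 1 - SI) trade-off, pooled across runs."""

    members: list[tuple[int, float, frozenset]]  # sorted by size
    per_run_members: list[list[tuple[int, float, frozenset]]] = field(
        default_factory=list)

    def sizes(self) -> list[int]:
        return [m[0] for m in self.members]


@dataclass
class ConvergenceReport:
    hypervolumes: list[float]
    spread_per_size: dict[int, float]
    converged: bool
    best_si_history: list[list[dict[int, float]]] = field(default_factory=list)


@dataclass
class NSGAResult:
    front: ParetoFront
    convergence: ConvergenceReport
    result: StrategyResult


def fast_nondominated_sort(points: Sequence[Sequence[float]]) -> list[list[int]]:
    """Partition objective vectors (minimization) into non-dominated fronts."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return []
    # dominates[i, j]: i dominates j (<= in all objectives, < in at least one)
    le = np.all(pts[:, None, :] <= pts[None, :, :], axis=2)
    lt = np.any(pts[:, None, :] < pts[None, :, :], axis=2)
    dominates = le & lt
    dom_count = dominates.sum(axis=0)
    fronts: list[list[int]] = []
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        current = np.nonzero((dom_count == 0) & ~assigned)[0]
        fronts.append(current.tolist())
        assigned[current] = True
        dom_count = dom_count - dominates[current].sum(axis=0)
    return fronts


def crowding_distance(points: Sequence[Sequence[float]],
                      front: Sequence[int]) -> np.ndarray:
    """NSGA-II crowding distance of the members of one front."""
    m = len(front)
    dist = np.zeros(m)
    if m <= 2:
        dist[:] = np.inf
        return dist
    pts = np.asarray(points, dtype=float)[np.asarray(front, dtype=int)]
    for obj in range(pts.shape[1]):
        order = np.argsort(pts[:, obj], kind="stable")
        lo, hi = pts[order[0], obj], pts[order[-1], obj]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi > lo:
            for k in range(1, m - 1):
                dist[order[k]] += (pts[order[k + 1], obj]
                                   - pts[order[k - 1], obj]) / (hi - lo)
    return dist


def _objectives(masks: np.ndarray, sis: np.ndarray, cap: int,
                penalty_size: float, penalty_obj: float,
                forbidden: np.ndarray) -> np.ndarray:
    sizes = masks.sum(axis=1)
    obj = np.column_stack([sizes.astype(float), 1.0 - sis])
    bad = (sizes > cap) | (masks[:, forbidden].any(axis=1) if forbidden.size else False)
    obj[bad, 0] = penalty_size
    obj[bad, 1] = penalty_obj
    return obj


def nsga2_search(net: Network, k_star: float, cfg: GAConfig,
                 params: ThetaParams,
                 cache: SICache | None = None) -> NSGAResult:
    """Constrained NSGA-II over node subsets.

    Individuals are binary membership vectors; the two minimized objectives
    are the set size and 1 - SI.  Candidates larger than the size cap or
    containing forbidden nodes receive large penalty objectives and are
    never simulated.  ``cfg.n_runs`` independent runs are pooled into one
    Pareto front; SI values are cached across runs.
    """
    n = net.n_nodes
    cap = cfg.size_cap if cfg.size_cap is not None else n // 2
    penalty_size = cfg.penalty_size if cfg.penalty_size is not None else n + 1
    p_mut = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / n
    forbidden = np.array(sorted(int(i) for i in cfg.forbidden_nodes), dtype=int)
    if np.any((forbidden < 0) | (forbidden >= n)):
        raise ValueError("forbidden_nodes outside the node range")
    allowed = np.setdiff1d(np.arange(n), forbidden)
    if allowed.size == 0 or cap < 1:
        raise RuntimeError(
            "every candidate would be penalized (forbidden set covers the "
            "network or size cap < 1)"
        )
    if cache is None:
        cache = SICache(net, k_star, params)

    def eval_sis(masks: np.ndarray) -> np.ndarray:
        sizes = masks.sum(axis=1)
        ok = (sizes > 0) & (sizes <= cap)
        if forbidden.size:
            ok &= ~masks[:, forbidden].any(axis=1)
        sis = np.zeros(len(masks))
        idx = np.nonzero(ok)[0]
        if idx.size:
            sets = [tuple(np.nonzero(masks[i])[0].tolist()) for i in idx]
            res = cache.evaluate(sets)
            for i, r in zip(idx, res):
                sis[i] = r.si
                strategy._record(r)
        return sis

    strategy = StrategyResult("nsga2", {}, 0, seeds=(cfg.seed,))
    per_run_fronts: list[list[tuple[int, float, frozenset]]] = []
    histories: list[list[dict[int, float]]] = []
    hypervolumes: list[float] = []

    for run in range(cfg.n_runs):
        rng = np.random.default_rng((cfg.seed, run))
        pop = np.zeros((cfg.population_size, n), dtype=bool)
        for i in range(cfg.population_size):
            size = int(rng.integers(1, min(cap, allowed.size) + 1))
            pop[i, rng.choice(allowed, size=size, replace=False)] = True
        sis = eval_sis(pop)
        strategy.n_evaluations += len(pop)
        obj = _objectives(pop, sis, cap, penalty_size, cfg.penalty_obj, forbidden)
        if np.all(obj[:, 0] == penalty_size):
            raise RuntimeError("all initial candidates penalized")
        history: list[dict[int, float]] = []
        running_best: dict[int, float] = {}

        for gen in range(cfg.generations):
            fronts = fast_nondominated_sort(obj)
            rank = np.empty(len(pop), dtype=int)
            crowd = np.empty(len(pop))
            for fi, front in enumerate(fronts):
                rank[front] = fi
                crowd[front] = crowding_distance(obj, front)
            # binary tournament -> offspring
            children = np.empty_like(pop)
            for i in range(0, cfg.population_size, 2):
                parents = []
                for _ in range(2):
                    a, b = rng.integers(0, cfg.population_size, size=2)
                    if (rank[a], -crowd[a]) <= (rank[b], -crowd[b]):
                        parents.append(pop[a])
                    else:
                        parents.append(pop[b])
                c1, c2 = parents[0].copy(), parents[1].copy()
                if rng.random() < cfg.crossover_prob:
                    swap = rng.random(n) < 0.5
                    c1[swap], c2[swap] = parents[1][swap], parents[0][swap]
                for c in (c1, c2):
                    flip = rng.random(n) < p_mut
                    c ^= flip
                children[i] = c1
                children[i + 1] = c2
            child_sis = eval_sis(children)
            strategy.n_evaluations += len(children)
            child_obj = _objectives(children, child_sis, cap, penalty_size,
                                    cfg.penalty_obj, forbidden)
            # elitist (mu + lambda) survival
            union = np.vstack([pop, children])
            union_sis = np.concatenate([sis, child_sis])
            union_obj = np.vstack([obj, child_obj])
            fronts = fast_nondominated_sort(union_obj)
            keep: list[int] = []
            for front in fronts:
                if len(keep) + len(front) <= cfg.population_size:
                    keep.extend(front)
                else:
                    cd = crowding_distance(union_obj, front)
                    order = np.argsort(-cd, kind="stable")
                    need = cfg.population_size - len(keep)
                    keep.extend(np.asarray(front)[order[:need]].tolist())
                    break
            keep = np.asarray(keep)
            pop, sis, obj = union[keep], union_sis[keep], union_obj[keep]
            for mask, s in zip(pop, sis):
                sz = int(mask.sum())
                if 0 < sz <= cap and s >= running_best.get(sz, -1.0):
                    running_best[sz] = max(running_best.get(sz, 0.0), s)
            history.append(dict(running_best))

        histories.append(history)
        # final per-run front (valid, nonempty candidates only)
        sizes = pop.sum(axis=1)
        valid = np.nonzero((sizes > 0) & (obj[:, 0] < penalty_size))[0]
        pairs = {(int(sizes[i]), float(1.0 - sis[i]),
                  frozenset(np.nonzero(pop[i])[0].tolist())) for i in valid}
        pairs = sorted(pairs, key=lambda t: (t[0], t[1], tuple(sorted(t[2]))))
        fr = fast_nondominated_sort([[p[0], p[1]] for p in pairs])
        run_front = [pairs[i] for i in fr[0]] if fr else []
        run_front.sort(key=lambda t: (t[0], t[1]))
        per_run_fronts.append(run_front)
        hypervolumes.append(_hypervolume(run_front, cap))

    pooled = {m for front in per_run_fronts for m in front}
    pooled = sorted(pooled, key=lambda t: (t[0], t[1], tuple(sorted(t[2]))))
    fr = fast_nondominated_sort([[p[0], p[1]] for p in pooled])
    members = sorted(({pooled[i] for i in fr[0]} if fr else set()),
                     key=lambda t: (t[0], t[1], tuple(sorted(t[2]))))
    # drop co-located duplicates dominated at equal coordinates, keep co-optima
    front = ParetoFront(members=members, per_run_members=per_run_fronts)

    spread: dict[int, float] = {}
    for size in sorted({s for h in histories for s in h[-1]}):
        vals = [h[-1].get(size) for h in histories if size in h[-1]]
        if len(vals) > 1:
            spread[size] = float(np.subtract(*np.percentile(vals, [75, 25])))
        else:
            spread[size] = 0.0
    converged = all(v <= 0.05 for v in spread.values()) if spread else True
    report = ConvergenceReport(hypervolumes=hypervolumes,
                               spread_per_size=spread,
                               converged=converged,
                               best_si_history=histories)
    return NSGAResult(front=front, convergence=report, result=strategy)


def _hypervolume(front: list[tuple[int, float, frozenset]], cap: int) -> float:
    """2-D hypervolume of a front w.r.t. reference point (cap + 1, 1.1)."""
    if not front:
        return 0.0
    ref1, ref2 = cap + 1.0, 1.1
    best: dict[int, float] = {}
    for size, one_minus_si, _ in front:
        if size not in best or one_minus_si < best[size]:
            best[size] = one_minus_si
    pts = sorted(best.items())
    hv = 0.0
    for k, (f1, f2) in enumerate(pts):
        nxt = pts[k + 1][0] if k + 1 < len(pts) else ref1
        if f2 < ref2:
            hv += (ref2 - f2) * (nxt - f1)
    return hv


def delta_si(reference: StrategyResult, other: StrategyResult) -> dict[int, float]:
    """Per-size SI gap, reference minus other; negative when the reference loses."""
    out: dict[int, float] = {}
    for size in reference.sizes():
        if size not in other.best:
            warnings.warn(f"size {size} missing from {other.strategy}; skipped")
            continue
        out[size] = reference.best_si(size) - other.best_si(size)
    return out


@dataclass
class OptimalSets:
    sets: list[frozenset]
    size: int | None
    si: float | None
    status: str            # "ok" or "none_above_threshold"
    max_si: float | None = None


def optimal_set_extraction(result: StrategyResult | ParetoFront,
                           threshold: float = 0.99) -> OptimalSets:
    """All sets of minimal size whose SI exceeds ``threshold``.

    Multiple co-optimal sets of the minimal size are preserved.  When no
    candidate reaches the threshold the result is empty, with the maximal
    observed SI as a diagnostic.
    """
    if isinstance(result, ParetoFront):
        per_size: dict[int, tuple[float, list[frozenset]]] = {}
        for size, one_minus_si, members in result.members:
            si = 1.0 - one_minus_si
            if size not in per_size or si > per_size[size][0]:
                per_size[size] = (si, [members])
            elif si == per_size[size][0]:
                per_size[size][1].append(members)
    else:
        per_size = result.best
    max_si = max((v[0] for v in per_size.values()), default=None)
    for size in sorted(per_size):
        si, sets = per_size[size]
        if si > threshold:
            winners = sorted({s for s in sets}, key=lambda s: tuple(sorted(s)))
            return OptimalSets(sets=winners, size=size, si=si, status="ok",
                               max_si=max_si)
    return OptimalSets(sets=[], size=None, si=None,
                       status="none_above_threshold", max_si=max_si)
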