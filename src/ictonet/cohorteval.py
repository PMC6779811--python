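"""Cohort-level evaluation of model-suggested resections.

For each patient case the model suggestion (one or more co-optimal node
sets from the search) is compared with the actually resected channels:
the overlap is the percentage of suggested nodes that fall inside the
resection.  Good-outcome (Engel I) and poor-outcome (Engel IV) groups are
compared by a one-sided exact Wilcoxon rank-sum test, and the overlap is
assessed as an outcome classifier via ROC/AUC (Mann-Whitney concordance).
A per-case random baseline repeats the overlap with uniformly random node
sets of the suggested size.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .icto import calibrate_k
from .netgen import Network
from .optsearch import GAConfig, SICache, nsga2_search, optimal_set_extraction
from .thetadyn import ThetaParams

__all__ = [
    "PatientCase",
    "OverlapResult",
    "overlap",
    "random_baseline",
    "rank_sum_test",
    "roc_analysis",
    "evaluate_cohort",
    "CohortReport",
]


@dataclass
class PatientCase:
    """One unit of cohort evaluation: network, actual resection, outcome."""

    case_id: str
    network: Network
    resected: frozenset
    outcome: str                      # "good" (Engel I) or "poor" (Engel IV)
    suggested_sets: list[frozenset] = field(default_factory=list)
    planted_set: frozenset | None = None   # ground truth on synthetic cohorts

    def __post_init__(self):
        if self.outcome not in ("good", "poor"):
            raise ValueError("outcome must be 'good' or 'poor'")
        n = self.network.n_nodes
        self.resected = frozenset(int(i) for i in self.resected)
        if any(not (0 <= i < n) for i in self.resected):
            raise ValueError("resected nodes outside the network")


@dataclass
class OverlapResult:
    case_id: str
    outcome: str
    max_overlap_pct: float
    min_overlap_pct: float
    baseline_mean: float
    baseline_se: float


def overlap(suggested: Iterable[int], resected: Iterable[int]) -> float:
    """Percentage of the suggested set that lies inside the actual resection."""
    s = frozenset(suggested)
    if not s:
        raise ValueError("suggested set is empty")
    r = frozenset(resected)
    return 100.0 * len(s & r) / len(s)


def random_baseline(n_nodes: int, suggested_size: int,
                    resected: Iterable[int], n_samples: int = 100,
                    seed: int = 0) -> tuple[float, float]:
    """Mean and standard error of the overlap of random same-size sets."""
    if suggested_size > n_nodes:
        raise ValueError("suggested size exceeds the number of nodes")
    r = frozenset(resected)
    if not r:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    vals = np.empty(n_samples)
    for i in range(n_samples):
        pick = rng.choice(n_nodes, size=suggested_size, replace=False)
        vals[i] = 100.0 * len(set(pick.tolist()) & r) / suggested_size
    se = float(vals.std(ddof=1) / math.sqrt(n_samples)) if n_samples > 1 else 0.0
    return float(vals.mean()), se


# ---------------------------------------------------------------------------
# Rank-sum test (exact enumeration with midranks) and ROC
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float],
                  side: str = "greater",
                  exact_limit: int = 25) -> float:
    """One-sided Wilcoxon rank-sum p-value: is ``group_a`` shifted vs ``group_b``?

    Exact when the combined sample is small (full enumeration of group
    assignments over midranks); otherwise the normal approximation with
    tie correction.  ``side='greater'`` tests whether a tends to exceed b.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    if side == "less":
        return rank_sum_test(b, a, "greater", exact_limit)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both groups")
    ranks = _midranks(pooled)
    n1, n = len(a), len(pooled)
    w_obs = ranks[:n1].sum()
    if n <= exact_limit:
        count = 0
        total = 0
        # enumerate all C(n, n1) assignments of ranks to group a
        for combo in itertools.combinations(range(n), n1):
            w = ranks[list(combo)].sum()
            if w >= w_obs - 1e-9:
                count += 1
            total += 1
        return count / total
    # normal approximation with tie correction
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 0.5
    z = (w_obs - mu - 0.5) / math.sqrt(var)  # continuity correction
    from scipy.stats import norm
    return float(norm.sf(z))


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    sensitivity: float
    specificity: float
    threshold: float


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC of a score against binary labels; AUC by Mann-Whitney concordance.

    The reported operating point maximizes Youden's J = sensitivity +
    specificity - 1.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    # concordance: ties count 1/2
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    auc = (gt + 0.5 * eq) / (len(pos) * len(neg))
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    j = tpr - fpr
    best = int(np.argmax(j))
    return ROCResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thresholds,
                     sensitivity=float(tpr[best]),
                     specificity=float(1.0 - fpr[best]),
                     threshold=float(thresholds[best]))


# ---------------------------------------------------------------------------
# End-to-end cohort pipeline
# ---------------------------------------------------------------------------


@dataclass
class CohortReport:
    per_case: list[OverlapResult]
    p_value: float
    auc: float
    sensitivity: float
    specificity: float


def _suggest_sets(case: PatientCase, params: ThetaParams, ga: GAConfig,
                  threshold_si: float) -> list[frozenset]:
    cal = calibrate_k(case.network, params, tol=0.05)
    cache = SICache(case.network, cal.k_star, params)
    res = nsga2_search(case.network, cal.k_star, ga, params, cache=cache)
    opt = optimal_set_extraction(res.result, threshold=threshold_si)
    if opt.sets:
        return opt.sets
    # nothing crossed the SI threshold: fall back to the highest-SI set
    best_size = max(res.result.best, key=lambda s: res.result.best[s][0])
    return res.result.best_sets(best_size)


def evaluate_cohort(cases: Sequence[PatientCase],
                    params: ThetaParams | None = None,
                    ga: GAConfig | None = None,
                    threshold_si: float = 0.99,
                    n_baseline: int = 100,
                    seed: int = 0) -> CohortReport:
    """Suggest resections per case, score overlaps, and test group separation.

    Cases without precomputed ``suggested_sets`` get them from a calibrated
    NSGA-II search at the given (reduced-fidelity) simulation settings.
    """
    params = params or ThetaParams(n_steps=30_000, n_realizations=2)
    per_case: list[OverlapResult] = []
    for idx, case in enumerate(cases):
        if not case.suggested_sets:
            ga_cfg = ga or GAConfig(population_size=24, generations=20,
                                    n_runs=2, seed=seed * 1009 + idx)
            case.suggested_sets = _suggest_sets(case, replace(params, seed=seed + idx),
                                                ga_cfg, threshold_si)
        overlaps = [overlap(s, case.resected) for s in case.suggested_sets]
        size = len(case.suggested_sets[0])
        base_mean, base_se = random_baseline(case.network.n_nodes, size,
                                             case.resected, n_baseline,
                                             seed=seed + 1000 + idx)
        per_case.append(OverlapResult(
            case_id=case.case_id, outcome=case.outcome,
            max_overlap_pct=max(overlaps), min_overlap_pct=min(overlaps),
            baseline_mean=base_mean, baseline_se=base_se,
        ))
    good = [r.max_overlap_pct for r in per_case if r.outcome == "good"]
    poor = [r.max_overlap_pct for r in per_case if r.outcome == "poor"]
    p = rank_sum_test(good, poor, side="greater")
    roc = roc_analysis([r.max_overlap_pct for r in per_case],
                       [1 if r.outcome == "good" else 0 for r in per_case])
    return CohortReport(per_case=per_case, p_value=p, auc=roc.auc,
                        sensitivity=roc.sensitivity,
                        specificity=roc.specificity)
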