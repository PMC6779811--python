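"""Synthetic fixtures: network ensembles, coupled signals, and patient cohorts.

Three generators back the test surface end to end:

* ensembles of artificial networks (the exemplar topologies);
* multichannel signal blocks simulated from the theta model on a known
  network, so that functional-network inference can be validated against
  planted couplings;
* synthetic surgical cohorts, where each case carries a planted ictogenic
  set (a dense driver clique), a resection mask, and an outcome label:
  good-outcome resections contain the planted set, poor-outcome resections
  miss at least half of it.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohorteval import PatientCase
from .netgen import GeneratorConfig, Network, generate_network
from .netinfer import Recording
from .thetadyn import ThetaParams, _trace_only, fixed_points

__all__ = [
    "CohortSpec",
    "make_network_ensemble",
    "make_coupled_signals",
    "make_cohort",
    "make_planted_network",
]


@dataclass(frozen=True)
class CohortSpec:
    """Shape and effect settings of a synthetic surgical cohort."""

    n_good: int = 13
    n_poor: int = 7
    n_nodes: int = 16
    planted_size_range: tuple = (3, 4)
    extra_resection_range: tuple = (1, 3)   # good cases: nodes beyond planted
    w_in: float = 1.0       # weight inside the planted driver clique
    w_out: float = 0.6      # weight of clique -> network driving edges
    w_background: float = 0.1
    background_density: float = 0.15
    label_flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_good < 1 or self.n_poor < 1:
            raise ValueError("need at least one case per outcome group")
        if self.planted_size_range[1] >= self.n_nodes / 2:
            raise ValueError("planted set must be smaller than half the network")


def make_network_ensemble(config: GeneratorConfig,
                          n_realizations: int = 10) -> list[Network]:
    """Independent realizations of one topology from derived sub-seeds."""
    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_realizations)
    return [generate_network(replace(config, seed=int(s))) for s in sub_seeds]


def make_planted_network(n_nodes: int, planted: tuple, w_in: float,
                         w_out: float, w_background: float,
                         background_density: float,
                         rng: np.random.Generator) -> Network:
    """Directed network with a mutually coupled driver clique wired into it.

    The planted nodes form a complete subgraph of weight ``w_in`` and send
    ``w_out`` edges to a random half of the remaining nodes; a sparse
    random background of weak edges connects everything else.  Removing
    the planted set disconnects the dominant drive and collapses
    epileptiform activity.
    """
    w = np.zeros((n_nodes, n_nodes))
    others = np.setdiff1d(np.arange(n_nodes), planted)
    # weak random background among non-planted nodes
    for i in others:
        for j in others:
            if i != j and rng.random() < background_density:
                w[i, j] = w_background
    for i in planted:
        for j in planted:
            if i != j:
                w[i, j] = w_in
    n_targets = max(1, len(others) // 2)
    for i in planted:
        targets = rng.choice(others, size=n_targets, replace=False)
        w[i, targets] = w_out
    return Network(weights=w, directed=True)


def make_coupled_signals(net: Network, duration: float, rate: float,
                         noise_level: float = 0.05, seed: int = 0,
                         k: float | None = None,
                         dt: float = 0.01) -> Recording:
    """Simulate theta dynamics on ``net`` and emit an observable per node.

    The observable is the spike-like amplitude 1 - cos(theta - theta_s)
    plus independent Gaussian sensor noise, sampled at ``rate``; connected
    node pairs co-fluctuate, disconnected ones do not.  ``k`` defaults to
    a super-critical coupling that keeps the network active.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    n_samples = int(round(duration * rate))
    if n_samples < 2:
        raise ValueError("degenerate duration/rate")
    if k is None:
        k = 20.0 * net.n_nodes / max(1.0, net.weights.sum())
    params = ThetaParams(k=k, dt=dt, n_steps=n_samples, seed=seed)
    # one integration step per output sample: the sampling rate fixes dt
    theta = _trace_only(net, params, realization=0, trace_step=1)
    fp = fixed_points(params.i_o)
    obs = 1.0 - np.cos(theta - fp.theta_stable)
    rng = np.random.default_rng(seed + 0x5EED)
    obs = obs.T + noise_level * rng.standard_normal((net.n_nodes, n_samples))
    return Recording(samples=obs, rate=rate)


def make_cohort(spec: CohortSpec) -> list[PatientCase]:
    """Synthetic 13-good / 7-poor cohort with planted ictogenic sets.

    Good-outcome resections are supersets of the planted set; poor-outcome
    resections contain strictly fewer than half of the planted nodes (the
    drive survives the surgery).
    """
    rng = np.random.default_rng(spec.seed)
    cases: list[PatientCase] = []
    outcomes = ["good"] * spec.n_good + ["poor"] * spec.n_poor
    for idx, outcome in enumerate(outcomes):
        n = spec.n_nodes
        p_size = int(rng.integers(spec.planted_size_range[0],
                                  spec.planted_size_range[1] + 1))
        planted = tuple(sorted(rng.choice(n, size=p_size, replace=False).tolist()))
        net = make_planted_network(n, planted, spec.w_in, spec.w_out,
                                   spec.w_background, spec.background_density,
                                   rng)
        others = np.setdiff1d(np.arange(n), planted)
        if outcome == "good":
            extra = int(rng.integers(spec.extra_resection_range[0],
                                     spec.extra_resection_range[1] + 1))
            resected = set(planted) | set(
                rng.choice(others, size=extra, replace=False).tolist())
        else:
            # keep at most floor((p-1)/2) planted nodes: under half survive removal
            n_hit = int(rng.integers(0, max(1, (p_size - 1) // 2) + 1))
            n_hit = min(n_hit, (p_size - 1) // 2)
            hit = rng.choice(np.array(planted), size=n_hit, replace=False)
            n_miss = int(rng.integers(2, 5))
            miss = rng.choice(others, size=n_miss, replace=False)
            resected = set(hit.tolist()) | set(miss.tolist())
        if spec.label_flip_prob > 0 and rng.random() < spec.label_flip_prob:
            outcome = "poor" if outcome == "good" else "good"
        cases.append(PatientCase(
            case_id=f"case{idx + 1:02d}",
            network=net,
            resected=frozenset(int(i) for i in resected),
            outcome=outcome,
            planted_set=frozenset(planted),
        ))
    return cases
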