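"""Noisy theta-model dynamics on weighted networks.

Each node is a theta neuron sitting close to a saddle-node-on-invariant-
circle (SNIC) bifurcation:

    dtheta_j = [(1 - cos theta_j) + (1 + cos theta_j) I_j] dt

with input current I_j = I_o + xi_j + (K/N) sum_i a_ij [1 - cos(theta_i -
theta_s)].  For mean input I_o < 0 the node has a stable resting phase
theta_s and a saddle theta_u; Gaussian input fluctuations occasionally push
the phase over the saddle, producing a spike (one full rotation), and
network coupling can turn rare spikes into sustained epileptiform firing.

Integration is Euler-Maruyama.  Noise is generated by a counter-based
splitmix64 + Box-Muller stream keyed on (node seed, step), which makes
trajectories reproducible, permutation-equivariant under per-node seeding,
and lets a whole batch of virtually-resected variants of one network share
identical noise (common random numbers).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit, uint64

from .netgen import Network

__all__ = [
    "ThetaParams",
    "FixedPoints",
    "ClassifierConfig",
    "SimulationResult",
    "fixed_points",
    "simulate",
    "classify_epileptiform",
    "batch_fractions",
    "node_seed_array",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ThetaParams:
    """Parameters of the network SDE and its integration."""

    i_o: float = -1.2
    noise_sd: float = 0.6
    k: float = 0.0
    dt: float = 0.01
    n_steps: int = 4_000_000
    seed: int = 0
    n_realizations: int = 1
    # per-step-sigma reading of the noise amplitude (no sqrt(dt) scaling);
    # default is the SDE-intensity reading implied by Euler-Maruyama.
    per_step_noise: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.noise_sd < 0 or self.k < 0:
            raise ValueError("noise_sd and k must be nonnegative")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


@dataclass(frozen=True)
class FixedPoints:
    theta_stable: float
    theta_unstable: float
    exists: bool


@dataclass(frozen=True)
class ClassifierConfig:
    """How per-sample phases are labelled normal vs epileptiform.

    ``saddle_crossing`` (default): a node turns epileptiform when its phase
    crosses the saddle theta_u in the increasing direction, and returns to
    normal once the phase has settled within ``settle_delta`` radians of the
    resting phase for ``smooth_window`` consecutive steps.  The settle
    window distinguishes a rotation passing through the resting phase
    (stays epileptiform) from an actual return to rest.

    ``amplitude_threshold``: epileptiform when the moving average (window
    ``smooth_window``) of the amplitude 1 - cos(theta - theta_s) exceeds
    ``amp_threshold``.
    """

    method: str = "saddle_crossing"
    amp_threshold: float = 0.9
    smooth_window: int = 100
    settle_delta: float = 0.6

    def __post_init__(self):
        if self.method not in ("saddle_crossing", "amplitude_threshold"):
            raise ValueError(f"unknown classifier method {self.method!r}")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not (0 < self.amp_threshold < 2):
            raise ValueError("amp_threshold must lie in (0, 2)")


@dataclass(frozen=True)
class SimulationResult:
    seizure_fraction: np.ndarray
    params: ThetaParams
    seed: int
    phases: np.ndarray | None = None
    trace_step: int = 1


def fixed_points(i: float) -> FixedPoints:
    """Resting and saddle phases of an uncoupled theta node at input ``i``.

    Setting the flow to zero gives cos(theta) = (1 + i)/(1 - i); when this
    is outside [-1, 1] no fixed point exists and the node rotates forever.
    """
    if not np.isfinite(i):
        raise ValueError("input current must be finite")
    if i == 1.0:
        raise ValueError("input current i = 1 is degenerate (1 - i = 0)")
    c = (1.0 + i) / (1.0 - i)
    if abs(c) > 1.0:
        return FixedPoints(theta_stable=math.nan, theta_unstable=math.nan,
                           exists=False)
    theta_u = math.acos(c)
    return FixedPoints(theta_stable=-theta_u, theta_unstable=theta_u, exists=True)


# ---------------------------------------------------------------------------
# Counter-based noise + integration kernels
# ---------------------------------------------------------------------------

_GOLD = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0x6A09E667F3BCC909)
_INV53 = 2.0 ** -53


@njit(cache=True, inline="always")
def _mix(x):
    z = uint64(x)
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    return z ^ (z >> uint64(31))


@njit(cache=True, inline="always")
def _gauss(h, t):
    base = uint64(h) + uint64(t) * _GOLD
    r1 = _mix(base)
    r2 = _mix(r1 ^ _C2)
    u1 = (float(r1 >> uint64(11)) + 0.5) * _INV53
    u2 = (float(r2 >> uint64(11)) + 0.5) * _INV53
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(TWO_PI * u2)


@njit(cache=True, fastmath=True)
def _run_batch(n, edge_i, edge_j, w_eff, k_over_n, io, sig_amp, dt, n_steps,
               theta_s, theta_u, hnode, delta, settle, frac_out):
    """Integrate S virtually-resected variants of one network in lockstep.

    ``w_eff[s, e]`` is the (possibly zeroed) weight of edge e in variant s;
    all variants share the same per-(node, step) noise stream.  Writes the
    per-node epileptiform-time fraction into ``frac_out[s, :]``.
    """
    S = w_eff.shape[0]
    E = edge_i.shape[0]
    cs = math.cos(theta_s)
    ss = math.sin(theta_s)
    pi = math.pi
    theta = np.full((S, n), theta_s)
    flag = np.zeros((S, n), np.uint8)
    settle_ct = np.zeros((S, n), np.int32)
    count = np.zeros((S, n), np.int64)
    noise = np.empty(n)
    cth = np.empty(n)
    drive = np.empty(n)
    coup = np.empty(n)
    for t in range(n_steps):
        for j in range(n):
            noise[j] = _gauss(hnode[j], t) * sig_amp
        for s in range(S):
            for i in range(n):
                c = math.cos(theta[s, i])
                si = math.sin(theta[s, i])
                cth[i] = c
                drive[i] = 1.0 - (c * cs + si * ss)
                coup[i] = 0.0
            for e in range(E):
                coup[edge_j[e]] += w_eff[s, e] * drive[edge_i[e]]
            for j in range(n):
                c = cth[j]
                cur = io + k_over_n * coup[j]
                old = theta[s, j]
                new = old + ((1.0 - c) + (1.0 + c) * cur) * dt \
                    + (1.0 + c) * noise[j]
                if new > old and old < theta_u and new >= theta_u:
                    flag[s, j] = 1
                    settle_ct[s, j] = 0
                if new > pi:
                    new -= TWO_PI
                elif new <= -pi:
                    new += TWO_PI
                theta[s, j] = new
                if flag[s, j] == 1:
                    d = new - theta_s
                    if d > pi:
                        d -= TWO_PI
                    elif d <= -pi:
                        d += TWO_PI
                    if -delta < d < delta:
                        settle_ct[s, j] += 1
                        if settle_ct[s, j] >= settle:
                            flag[s, j] = 0
                            settle_ct[s, j] = 0
                    else:
                        settle_ct[s, j] = 0
                    count[s, j] += flag[s, j]
    for s in range(S):
        for j in range(n):
            frac_out[s, j] = count[s, j] / n_steps


@njit(cache=True, fastmath=True)
def _run_trace(weights, k, io, sig_amp, dt, n_steps, theta_s, hnode,
               record_every, out_theta):
    """Single-network integration recording the phase every ``record_every`` steps."""
    n = weights.shape[0]
    cs = math.cos(theta_s)
    ss = math.sin(theta_s)
    pi = math.pi
    theta = np.full(n, theta_s)
    drive = np.empty(n)
    k_over_n = k / n
    rec = 0
    for t in range(n_steps):
        for i in range(n):
            drive[i] = 1.0 - (math.cos(theta[i]) * cs + math.sin(theta[i]) * ss)
        for j in range(n):
            coup = 0.0
            for i in range(n):
                coup += weights[i, j] * drive[i]
            c = math.cos(theta[j])
            cur = io + k_over_n * coup
            new = theta[j] + ((1.0 - c) + (1.0 + c) * cur) * dt \
                + (1.0 + c) * _gauss(hnode[j], t) * sig_amp
            if new > pi:
                new -= TWO_PI
            elif new <= -pi:
                new += TWO_PI
            theta[j] = new
        if (t + 1) % record_every == 0 and rec < out_theta.shape[0]:
            for j in range(n):
                out_theta[rec, j] = theta[j]
            rec += 1


def node_seed_array(seed: int, realization: int, n: int) -> np.ndarray:
    """Derive one independent noise-stream key per node.

    Keys depend only on (master seed, realization index, node index), so
    permuting nodes together with their keys permutes trajectories exactly.
    """
    mask = (1 << 64) - 1
    base = (int(seed) * 0xD1342543DE82EF95
            + int(realization) * 0xAF251AF3B0F025B5) & mask
    out = np.empty(n, dtype=np.uint64)
    for j in range(n):
        out[j] = _mix(np.uint64((base + j * 0x9E3779B97F4A7C15 + 1) & mask))
    return out


def _noise_amplitude(params: ThetaParams) -> float:
    if params.noise_sd == 0:
        return 0.0
    if params.per_step_noise:
        return params.noise_sd
    return params.noise_sd * math.sqrt(params.dt)


def batch_fractions(net: Network, removed_sets: Sequence[Sequence[int]],
                    params: ThetaParams,
                    cfg: ClassifierConfig | None = None,
                    realization: int = 0,
                    node_seeds: np.ndarray | None = None) -> np.ndarray:
    """Per-node epileptiform fractions for many virtual resections at once.

    Returns an (S, N) array, one row per removed set (the empty set gives
    the unperturbed network).  All sets share the same noise, so rows are
    directly comparable.  Removed nodes keep running (they still receive
    noise) but exchange no coupling, matching the definition of resection
    as zeroing connections.
    """
    cfg = cfg or ClassifierConfig()
    if cfg.method != "saddle_crossing":
        raise ValueError("batch_fractions supports the saddle_crossing classifier")
    fp = fixed_points(params.i_o)
    if not fp.exists:
        raise ValueError(
            "no resting fixed point for i_o = %g; every node oscillates" % params.i_o
        )
    n = net.n_nodes
    src, dst = np.nonzero(net.weights)
    edge_i = src.astype(np.int64)
    edge_j = dst.astype(np.int64)
    base_w = net.weights[src, dst]
    S = len(removed_sets)
    active = np.ones((S, n), dtype=bool)
    for s, x in enumerate(removed_sets):
        for i in x:
            if not (0 <= int(i) < n):
                raise IndexError(f"node index {i} out of range")
            active[s, int(i)] = False
    w_eff = (base_w[None, :]
             * active[:, edge_i].astype(float)
             * active[:, edge_j].astype(float))
    if node_seeds is None:
        node_seeds = node_seed_array(params.seed, realization, n)
    frac = np.empty((S, n))
    _run_batch(n, edge_i, edge_j, np.ascontiguousarray(w_eff),
               params.k / n, params.i_o, _noise_amplitude(params),
               params.dt, params.n_steps, fp.theta_stable, fp.theta_unstable,
               node_seeds, cfg.settle_delta, cfg.smooth_window, frac)
    if not np.all(np.isfinite(frac)):
        raise FloatingPointError("theta integration produced non-finite output")
    return frac


def simulate(net: Network, params: ThetaParams,
             cfg: ClassifierConfig | None = None,
             return_trace: bool = False,
             trace_step: int = 1) -> SimulationResult:
    """Simulate the theta model on ``net`` and classify epileptiform time.

    Averages the per-node fractions over ``params.n_realizations``
    independent noise realizations.  With ``return_trace`` the (decimated)
    phase trajectory of the first realization is attached.
    """
    cfg = cfg or ClassifierConfig()
    fp = fixed_points(params.i_o)
    if not fp.exists:
        warnings.warn("no resting fixed point: whole run classified epileptiform")
        frac = np.ones(net.n_nodes)
        trace = None
        if return_trace:
            trace = _trace_only(net, params, 0, trace_step)
        return SimulationResult(seizure_fraction=frac, params=params,
                                seed=params.seed, phases=trace,
                                trace_step=trace_step)
    fracs = []
    for r in range(params.n_realizations):
        if cfg.method == "saddle_crossing":
            fracs.append(batch_fractions(net, [()], params, cfg, realization=r)[0])
        else:
            theta = _trace_only(net, params, r, 1)
            states = classify_epileptiform(theta, params.i_o, cfg)
            fracs.append(states.mean(axis=0))
    frac = np.mean(fracs, axis=0)
    trace = _trace_only(net, params, 0, trace_step) if return_trace else None
    return SimulationResult(seizure_fraction=frac, params=params,
                            seed=params.seed, phases=trace,
                            trace_step=trace_step)


def _trace_only(net: Network, params: ThetaParams, realization: int,
                trace_step: int) -> np.ndarray:
    fp = fixed_points(params.i_o)
    theta_s = fp.theta_stable if fp.exists else 0.0
    n_rec = params.n_steps // trace_step
    out = np.empty((n_rec, net.n_nodes))
    hnode = node_seed_array(params.seed, realization, net.n_nodes)
    _run_trace(np.ascontiguousarray(net.weights), params.k, params.i_o,
               _noise_amplitude(params), params.dt, params.n_steps,
               theta_s, hnode, trace_step, out)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("theta integration produced non-finite phases")
    return out


# ---------------------------------------------------------------------------
# Stand-alone classifier (works on any phase trace)
# ---------------------------------------------------------------------------


def _wrap(x: np.ndarray) -> np.ndarray:
    return (x + math.pi) % TWO_PI - math.pi


def classify_epileptiform(trace: np.ndarray, i_o: float,
                          cfg: ClassifierConfig | None = None) -> np.ndarray:
    """Binary per-sample epileptiform state of a phase trace.

    ``trace`` has shape (T,) or (T, N); returns the same shape in uint8.
    Mirrors the inline classifier of the integration kernel for the
    saddle_crossing method.
    """
    cfg = cfg or ClassifierConfig()
    arr = np.asarray(trace, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    fp = fixed_points(i_o)
    if not fp.exists:
        warnings.warn("no resting fixed point: whole trace classified epileptiform")
        out = np.ones(arr.shape, dtype=np.uint8)
        return out[:, 0] if squeeze else out

    if cfg.method == "amplitude_threshold":
        amp = 1.0 - np.cos(arr - fp.theta_stable)
        w = cfg.smooth_window
        kernel = np.ones(w) / w
        out = np.empty(arr.shape, dtype=np.uint8)
        for j in range(arr.shape[1]):
            sm = np.convolve(amp[:, j], kernel, mode="full")[: arr.shape[0]]
            # rescale the warm-up so early samples average over what exists
            sm[: w - 1] *= w / np.arange(1, w, dtype=float)[: w - 1]
            out[:, j] = sm > cfg.amp_threshold
        return out[:, 0] if squeeze else out

    theta_s, theta_u = fp.theta_stable, fp.theta_unstable
    T, N = arr.shape
    out = np.zeros((T, N), dtype=np.uint8)
    for j in range(N):
        flag = 0
        settle = 0
        prev = arr[0, j]
        for t in range(T):
            cur = arr[t, j]
            if t > 0:
                step = _wrap(np.array([cur - prev]))[0]
                if step > 0 and prev < theta_u <= prev + step:
                    flag = 1
                    settle = 0
            if flag:
                d = _wrap(np.array([cur - theta_s]))[0]
                if -cfg.settle_delta < d < cfg.settle_delta:
                    settle += 1
                    if settle >= cfg.smooth_window:
                        flag = 0
                        settle = 0
                else:
                    settle = 0
            out[t, j] = flag
            prev = cur
    return out[:, 0] if squeeze else out
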