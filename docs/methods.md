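# Methods

## Model

Each network node is a theta neuron, the normal form of a saddle-node-on-
invariant-circle (SNIC) bifurcation. The phase of node *j* obeys

    dθ_j/dt = (1 − cos θ_j) + (1 + cos θ_j) · I_j(t)
    I_j(t)  = I_o + ξ_j(t) + (K/N) Σ_i a_ij [1 − cos(θ_i − θ_s)]

with mean input `I_o = −1.2`, white Gaussian input fluctuations ξ_j of
standard deviation `σ = 0.6`, global coupling scale `K`, and adjacency
`a_ij` (weight of the edge from *i* to *j*). For `I_o < 0` an uncoupled
node has a stable resting phase θ_s and a saddle θ_u with
`cos θ = (1 + I_o)/(1 − I_o)`; noise occasionally pushes the phase over
the saddle, producing a spike (one full rotation), and network input —
each active neighbour contributes `1 − cos(θ_i − θ_s)` ∈ [0, 2] — can
sustain repeated firing. Integration is Euler–Maruyama with step
`dt = 0.01` (dimensionless time); the noise increment is
`(1 + cos θ) · σ · √dt · η` with η ~ N(0,1), i.e. σ is read as the SDE
noise intensity (a per-step reading is available via
`ThetaParams.per_step_noise`; the K calibration absorbs the constant
either way). Phases are wrapped to (−π, π] each step. All nodes start at
θ_s, the "normal activity" baseline.

### Noise streams

Noise is generated inside the integration kernel by a counter-based
generator (splitmix64 hashing of (node key, step index) followed by
Box–Muller). Consequences:

* trajectories are exactly reproducible from (seed, realization, node);
* permuting node labels together with their keys permutes trajectories
  exactly (tested);
* a whole batch of virtually resected variants of one network shares one
  noise stream per (node, step) — common random numbers — so SI
  differences between candidate sets are paired comparisons, and the
  noise cost is amortized over the batch.

## Epileptiform-state classification

The fraction of time each node spends in epileptiform dynamics is the
basic observable. The default `saddle_crossing` rule is a hysteresis
state machine:

* a node **enters** the epileptiform state when its phase crosses the
  saddle θ_u in the increasing direction (wrap-aware);
* it **returns to normal** once the phase has remained within
  `settle_delta = 0.6` rad of θ_s for `smooth_window = 100` consecutive
  steps (one time unit).

The settle window is what distinguishes a rotation that merely *passes
through* the resting phase (it transits the neighbourhood in far fewer
than 100 steps and stays flagged) from an actual return to rest. It also
handles the marginal case of a phase that pokes just past θ_u and
retreats without completing a rotation: such a node un-flags after it
settles, rather than staying flagged until an eventual later spike. The
0.6 rad neighbourhood is ≈ 2.3 stationary standard deviations of the
resting phase under the default noise (linearizing the flow at θ_s gives
an Ornstein–Uhlenbeck fluctuation scale of ≈ 0.26 rad), so a resting
node settles within a few windows with high probability.

An alternative `amplitude_threshold` rule flags samples where the moving
average (window 100) of the spike amplitude `1 − cos(θ − θ_s)` exceeds
0.9. Both rules agree on the regimes that matter (rest ↔ sustained
firing); the calibration of K absorbs residual differences in the
absolute time fractions.

If no resting fixed point exists (`I_o ≥ 0` side of the SNIC), every
node rotates perpetually and the whole trace is classified epileptiform
with a warning.

## BNI, calibration, SI

* **BNI** = mean over nodes of the per-node epileptiform time fraction,
  averaged over `n_realizations` independent noise realizations.
* **Calibration**: bisection on K, evaluating every K with the *same*
  noise realizations so BNI(K) is effectively monotone. The bracket is
  found by doubling from `K = 1`; after bracketing, six refinement steps
  are always taken and the evaluated K closest to the target is
  returned, so the operating point typically lands within ~0.01 of the
  0.5 target rather than at the edge of the ±0.05 acceptance tolerance.
  An explicit `CalibrationError` reports networks whose BNI saturates
  below the target (e.g. edgeless networks, where BNI does not depend
  on K at all).
* **SI** of a node set X: the network with X's rows and columns zeroed
  is re-simulated at the *unperturbed* network's K\* (recalibrating
  would nullify the statistic) under the same noise realizations, and
  `SI = max(0, (BNI⁰ − BNI^X)/BNI⁰)`. Removed nodes keep running (they
  still receive noise and count towards BNI) but exchange no coupling —
  resection means disconnection, not deletion.

SI is computed from realization-averaged BNIs (the ratio of means, not
the mean of per-realization ratios). The two definitions differ only at
second order in the per-realization fluctuations; the ratio-of-means
form keeps the identity `si == max(0, (bni_ref − bni_pert)/bni_ref)`
exact in the reported result. Under common random numbers SI(∅) is
exactly 0 and the NI of a fully isolated node is exactly 0.

Desk-scale defaults used throughout the tests and the acceptance script
are 2×10⁵ steps / 4 realizations for calibration-grade estimates and
10⁵ steps / 2 realizations for search-grade estimates (the full-fidelity
4×10⁶-step setting remains available through `ThetaParams`); these sizes
were chosen once as the smallest at which the BNI estimate's spread is
well inside the ±0.05 calibration tolerance.

## Search strategies

All strategies on one network share an `SICache` keyed by node set, so
identical sets always receive identical SI values and between-strategy
gaps (ΔSI) are paired.

* **Ground truth**: exhaustive enumeration of all sets up to a size cap;
  refuses, with the exact candidate count, when Σ C(N,n) exceeds a
  budget ceiling (a full 40-node search would be 2⁴⁰ − 1 sets).
* **Simple ordering**: rank nodes once by NI, add greedily, stop when
  SI > 0.99. Ties rank the lower node index first.
* **Recurrent ordering**: after each removal, re-rank the remaining
  nodes by the SI of (current set + node) — equivalently the NI within
  the perturbed network — always referencing the intact network's BNI⁰.
* **Random search**: per-size sample counts proportional to
  log C(N, n), rounded by largest remainder to sum exactly to the
  budget (each size gets at least one sample); sizes whose stratum fits
  the allocation are enumerated exhaustively, otherwise distinct sets
  are drawn without replacement.
* **NSGA-II**: binary membership encoding; objectives (|X|, 1 − SI),
  both minimized; binary tournament on (rank, crowding distance);
  uniform crossover with probability 0.9; per-bit mutation 1/N; elitist
  (μ+λ) survival. Candidates larger than the size cap (default ⌊N/2⌋)
  or containing forbidden nodes receive penalty objectives (N+1, 2) and
  are never simulated. Initial individuals draw a size uniformly from
  1..cap and then a uniform random set of that size from the allowed
  nodes. Independent runs (default 8; 4 at desk scale) are pooled into
  one Pareto front. The per-size running best is tracked from all
  evaluated candidates (an archive), which is the quantity compared
  against ground truth; it is monotone across generations by
  construction.

Convergence is reported as (a) each run's 2-D hypervolume w.r.t. the
reference point (size_cap + 1, 1.1) and (b) the across-run interquartile
range of the best SI per size, with `converged` meaning every spread
≤ 0.05. These are proxies with the same intent as spread-based MOGA
convergence metrics — fully specified here rather than imported.

## Functional-network inference

Preprocessing follows standard intracranial-EEG practice: polyphase
anti-aliased resampling to 512 Hz, subtraction of the per-sample median
of the artifact-free channels (so any common signal cancels exactly),
and a zero-phase (forward–backward) 4th-order Butterworth band-pass at
0.5–150 Hz. Bad channels are an input mask; they are excluded from the
reference and isolated in the output network.

Edge weights are surrogate-corrected mutual information:

* plug-in MI (nats) on a 2-D histogram over per-channel equiquantile
  bins, `n_bins = ⌊√(n/5)⌋` capped at 32 — invariant under monotone
  amplitude rescaling of either channel;
* null distribution from 99 circular time shifts (minimum shift 5% of
  the window) of one channel, which preserve each channel's marginal
  distribution and autocorrelation exactly while destroying
  cross-channel alignment;
* weight = max(0, MI_observed − 95th percentile of the null), giving an
  undirected network in which ≥ 95% of truly independent pairs clamp to
  exactly zero by construction.

## Synthetic data

The generators define the study conditions for everything the tests
assert:

* **Ensembles**: ten realizations per topology; directed scale-free
  networks use the static model (node weights ∝ i^(−1/(γ−1)) applied
  independently to source and target draws, edges added until
  N·mean_degree exist) with γ = 3 and mean in/out degree 2 at N = 20;
  the Barabási–Albert generator is available as the undirected (and an
  in-degree-preferential directed) alternative; random directed
  networks are exactly 2-regular digraphs (configuration-model pairing
  with rejection of self-loops and multi-edges).
* **Coupled signals**: theta dynamics on a known network at a
  super-critical coupling (default K = 20·N/Σa, chosen once so that
  directly coupled pairs fire together without global synchrony), with
  observable `1 − cos(θ − θ_s)` per node plus 5% Gaussian sensor noise.
  The planted-dependency validation fixture uses disjoint strongly
  coupled channel pairs, the cleanest realization of "planted pairwise
  dependencies".
* **Cohorts**: 13 good-outcome + 7 poor-outcome cases. Each case is a
  16-node directed network with a planted driver clique (internal
  weight 1.0) that sends weight-0.6 edges to half of the remaining
  nodes over a weak (0.1) random background. Good-outcome resections
  contain the planted set plus 1–3 extra nodes; poor-outcome resections
  contain strictly fewer than half of the planted nodes. Labels are
  deterministic given the masks (an optional flip probability exists
  for robustness experiments).

What the synthetic cohort does *not* emulate: electrode geometry,
volume conduction, artifacts, seizure morphology, inter-patient
variability in network size (real implantations span ~24–98 channels),
or diagnostic uncertainty in the outcome labels. Passing the cohort
test therefore shows that the pipeline recovers planted drivers and
that the overlap statistic separates construction-level outcome groups;
it does not validate clinical performance.

## Numerical choices and degenerate inputs

* Eigenvector centrality: power iteration on the symmetric adjacency
  with a diagonal shift (max row sum) so bipartite spectra (±λ pairs)
  converge; tolerance 1e−10, ≤ 10⁴ iterations; undirected networks
  only — it is undefined for directed networks here.
* Weighted betweenness converts affinity weights to distances as 1/w;
  absent paths contribute zero. Directed clustering is the Fagiolo-style
  generalization (networkx on DiGraph).
* Exact rank-sum p-values enumerate all C(n₁+n₂, n₁) group assignments
  over midranks when n₁+n₂ ≤ 25; larger samples use the normal
  approximation with tie correction and continuity correction. All-tied
  input is flagged and returns the midrank value (≥ 0.5).
* MI of a constant channel is defined as 0 (with a warning); MI is made
  bitwise symmetric by canonicalizing the argument order.
* SI ties between co-optimal sets are all kept, sorted by lexicographic
  node order. Node indices are 0-based everywhere; file formats declare
  their conventions in headers.
* Seeds: one master seed; module seeds derived by stable integer
  hashing so adding a pipeline step never shifts other streams; all
  derived seeds stay below 2³¹.

## Known limitations

* The epileptiform-time rule is a package design choice (the underlying
  time-fraction observable is only defined up to such a rule); the K
  calibration makes BNI/SI comparisons robust to it, but absolute time
  fractions are rule-dependent.
* BNI saturates below 1 on networks with zero-in-degree nodes (they
  never receive coupling), which is why calibration reports failure
  rather than looping when the target is unreachable.
* NSGA-II hyperparameters are standard rather than tuned; on desk-scale
  problems the search space is small enough that the pooled runs cover
  the optimum, which is what the ground-truth comparison checks.
* The cohort pipeline's runtime scales linearly in cases × distinct GA
  candidates; the shipped reduced-fidelity defaults (16-node networks,
  3×10⁴ steps, population 24, 20 generations, 2 runs) were chosen once
  to keep a 20-case evaluation at desk scale.
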