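# Methods

This note documents the models, conventions and parameter choices behind
`epispread`, and what the synthetic-data experiments do and do not show.

## Networks and thresholding

A patient network is a symmetric matrix of weights w_ij in [0, 1] over an
atlas (natively 246 ROIs), with zero diagonal. Proportional thresholding at
density θ keeps the round(θ·N(N−1)/2) strongest links and zeroes the rest
without binarizing; ties at the boundary are broken by (smaller i, smaller j)
lexicographic edge order so retained edge sets are deterministic and nested
across the density grid. The reported mean connectivity is the bookkeeping
value κ = θN (the exact graph mean degree θ(N−1) is exposed separately as
`mean_degree_exact`). Loading enforces symmetry to 1e-9 (symmetrized by
averaging below that; an error above it) and zeroes the diagonal.

The density grid is non-uniform — 0.01, 0.02, 0.04, 0.06, 0.08, 0.10, then
steps of 0.05 up to 0.50 — because the dynamics are most sensitive to
connectivity changes at low density.

The exponential-distance-rule (EDR) surrogate sets w_ij = exp(−λ·d_ij)·ε_ij
with Euclidean centroid distances in mm and symmetric multiplicative
lognormal noise of median 1 (ε = 1 when noise_sigma = 0), clipped to [0, 1].
λ defaults to the literature value 0.188/mm; a coarser-parcellation refit
around 0.05/mm is more appropriate at 246-ROI resolution (see the synthetic
generator below). `edr_lambda_scan` provides a generic correlation scan over
decay exponents; no claim is made that it replicates any particular published
refit procedure.

## SI dynamics

Susceptible–Infected dynamics with synchronous updates: a susceptible node j
becomes infected at step t+1 with probability 1 − Π_{i infected at t}(1 − β·w_ij).
The Monte-Carlo simulator (default N_R = 10⁴ runs) aggregates the
first-infection probability map p_i(t), the infection curve I(t) (seed
included), and expected first-infection times. Runs are vectorized in chunks
with a single master seed driving deterministic per-chunk streams, so results
are reproducible at any chunking.

Mean infection times are computed as the expectation of the first-infection
step, censored at the horizon T (default 10·N so censoring is negligible on
connected networks), with the per-ROI censored fraction reported. The naive
sum Σ_t p_i(t) is a total infection probability (≤ 1), not a time; it is kept
as `printed_time_sum` for audit only.

Density control: for resection experiments β is always derived from
βθ = 4·10⁻⁴ at the network's density (β = 0.01 at θ = 0.04), and propagation
is measured at t₀ = 50 steps. On a complete uniform-weight 246-node network
with a 4-node seed this yields roughly two thirds of the nodes infected at
t₀. Note that the stochastic process systematically lags the deterministic
logistic mean-field curve by up to ~0.06 (absolute fraction) in mid-growth —
an expected small-seed fluctuation effect, not a simulation artifact; the
tests bound the deviation accordingly.

The slow-propagation (β → 0) limit infects exactly one node per step, chosen
with probability proportional to its total link weight to the infected set;
the per-ROI mean activation step over runs is the first-passage activation
ordering used for fitting. Nodes disconnected from the seed are flagged
unreachable (infinite order). The inner loop is a numba kernel; a brute-force
sequence-enumeration oracle validates its order statistics exactly on small
graphs.

Propagation extents count infected nodes *outside the original seed* divided
by (N − |seed|). This makes complete seed disconnection yield exactly
I_R(t₀) = 0, which would be impossible if the still-formally-infected seed
counted. Figure-style curves I(t) include the seed; the extent convention is
used for all resection measures.

## Clinical and model patterns, density fitting

Contact points (CPs) are assigned to the nearest ROI centroid (ties to the
smaller ROI id); CPs sharing an ROI are merged with the earliest activation
step (seizure-onset semantics). Sampled ROIs that never activate are simply
absent from the pattern and are excluded from both rankings. Activation
steps are converted to midpoint-tie ranks; the model ranks the same ROIs by
mean slow-propagation activation step (seed ROIs rank first at time 0;
unreachable ROIs rank last, tied).

The correlation C is Pearson on the two rank vectors — equivalently
tie-corrected Spearman; population vs sample moments cancel in the ratio.
Significance uses a two-sided permutation test (default 10⁴ permutations of
one rank vector, add-one corrected). A rank-based U test cannot test a
correlation directly, so the permutation test is the primary significance
machinery here.

Density selection: C(θ) curves typically rise steeply and then flatten or dip;
the scientifically meaningful fit is the lowest-density maximum, which keeps
only the fundamental connections needed to reproduce the propagation.
Formally: scan θ ascending; a grid point is a local maximum if C is ≥ both
neighbours (boundary points compare to one neighbour); the selected point is
the lowest-θ local maximum that is significant (p < 0.05) *and* within 5% of
the global maximum (`FitConfig.prominence`). The prominence condition is
essential in practice: without it, Monte-Carlo wiggles on the rising shoulder
(e.g. C ≈ 0.6 at θ = 0.01 against a clear peak of 0.98 at θ = 0.10) get
selected. If no local maximum qualifies, the global maximum is reported with
`significant=False`.

The fully-connected baseline exploits exchangeability: on a uniform complete
graph all non-seed nodes have identical expected activation times, so the
model ranking is computed analytically (seed at 0, everything else tied). If
no seed ROI is sampled the ranking is constant and C is reported as 0 with a
degenerate flag.

## Virtual resections

A resection zeroes all links of the chosen nodes; network size is unchanged.
The search for the optimal size-S resection has four steps: (1) candidates
are the seed plus its first and second unweighted-hop neighbours; (2)
simulated annealing over size-S subsets maximizes a structural surrogate;
(3) the top-k (default 10) surrogate sets are evaluated with full SI
simulations of the post-resection extent; (4) the extent-minimal set wins
(ties by surrogate rank, then lexicographic ROI order).

The surrogate is the mean effective distance from the seed. Per-link lengths
are d_ij = 1 − ln(P_ij) with P_ij = w_ij/Σ_k w_ik row-normalized on the
*intact* network; node distances are multi-source shortest paths. This
construction of the effective-distance metric is a reconstruction — it follows
the standard effective-distance literature, and its averaging conventions are
this package's own choices. Two such choices matter:

* **Frozen link lengths.** Resections delete nodes from the fixed
  effective-length graph; surviving transition probabilities are *not*
  re-normalized. Re-normalizing would let the removal of a neighbour increase
  P (and shorten distances) elsewhere, so that resecting more could look
  worse — with frozen lengths the objective is provably non-decreasing as the
  resection grows, which is what a containment score should do.
* **Cap for unreachable nodes.** The mean runs over all non-seed nodes;
  resected and disconnected nodes contribute a finite cap (intact d-graph
  diameter + 1), so disconnection is strictly rewarded and the objective
  stays finite.

The annealer swaps one member with one non-member per proposal, calibrates
the initial temperature so ~80% of downhill moves are accepted on a short
random walk, cools geometrically (0.95) every |pool| proposals, runs
200·|pool| proposals per restart with 3 restarts (all configurable), and
returns the top-k distinct sets. On every tested instance with ≤ 12
candidates and S ≤ 3 it matches exhaustive search.

Resection curves scan S upward, seeding each size with the previous best set
plus the best single surrogate addition (monotone hull: a larger resection
never spreads more; residual Monte-Carlo inversions are clamped), adding the
trivial full-seed resection at S = S_RA, and stop at the first size with zero
non-seed infections in every run (R100; verified to stay zero when
re-simulated at 10× the runs). R90 is the smallest size with i_R ≤ 0.1 —
because the full-seed resection always achieves i_R = 0, R90 and R100 always
exist with S ≤ S_RA.

## Synthetic patients

The generator emulates the statistical structure the pipeline assumes:
centroids uniform in a 140×170×120 mm box; EDR weights with λ = 0.052/mm and
lognormal noise σ = 0.5; a compact seed (the S_RA = 4 ROIs nearest a random
focus, regenerated if not connected at the planted density); N_SR = 40
sampled ROIs drawn without replacement with probability ∝ exp(−d_seed/30 mm)
(seed included); and a clinical pattern obtained by simulating the
slow-propagation ordering at θ* = 0.10 and coarsening mean orders into 6
equal-count activation steps. Defaults mirror the clinical cohort ranges
(seeds 3–12 ROIs, 30–60 sampled ROIs, ~6 propagation steps); the published
per-patient implantation table in `pipeline.COHORT_TABLE` can parameterize
realistic cohorts.

The λ = 0.052 default (the coarse-parcellation refit, not the literature
0.188) is deliberate: at steep decay the weights span many orders of
magnitude, links added at higher density are dynamically irrelevant, C(θ)
saturates instead of peaking, and no density is identifiable. Compressed
weights — as functional-connectivity matrices actually have — are what make
the density a recoverable parameter. Under the default conditions the fitted
density lands within one grid step of the planted θ* in ≳80% of replicates
(at 10³ slow-propagation runs per grid point), and fits on step-permuted
control patterns are non-significant in the large majority.

What passing these experiments does *not* show: real AEC matrices have
richer structure than distance decay plus independent noise (hubs, community
structure, hemispheric asymmetries), clinical activation steps carry
observation noise beyond coarsening, and true seizure dynamics include
inhibition that the SI abstraction omits. Synthetic recovery validates the
machinery, not the clinical model itself.

## Numerical choices and limitations

* Test-scale networks default to N = 90 (atlas-scale 246 is used where the
  quantity depends on it); simulation sizes in the test and acceptance
  suites (10³–10⁴ runs, 5–20 synthetic patients) were chosen as the smallest
  that give stable statistics.
* The SI simulator uses float32 log-survival accumulation; probabilities are
  exact to well below Monte-Carlo noise.
* Degenerate inputs: fully tied rankings yield C = 0 with a flag rather than
  an error inside fits; a fully resected seed yields extent 0; isolated
  nodes are unreachable, not errors.
* SIS/SIR recovery dynamics, post-resection plasticity, eloquent-cortex
  constraints (the API accepts an exclusion set but applies no clinical
  logic) and seed inference from patterns are out of scope.
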