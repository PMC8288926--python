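# Methods

## The generational percolation process

A multiplex network is a single set of `N` nodes carrying `L ≥ 2` layers of
undirected links (default and theory case: two layers, A and B). The
process is deterministic given the layers:

* `C^0` is the universal configuration — all nodes in one cluster.
* Generation `n` uses layer `(n−1) mod L`. An edge of the active layer
  survives only if its endpoints belong to the same cluster of `C^{n−1}`;
  the connected components of the surviving edges form `C^n`.

Generation 1 is therefore the plain component structure of layer A, and
every generation *refines* the previous partition. Since a partition of a
finite set can refine at most `N−1` times, a steady state is always
reached; we write `n_c` for the last generation that changed anything
(`C^{n_c+1} = C^{n_c}`). The narrative convention "the generation where no
new clusters appear" is `n_c + 1`; both are derivable from the trace.

Applying one layer is idempotent, so at `L = 2` a single application that
leaves the partition unchanged certifies the steady state (the next
application of the *other* layer reproduces the partition it already
produced). This is only valid once the partition was itself produced by a
layer, so detection starts at generation 2; for `L > 2` a full unchanged
cycle of `L` applications is required. A `max_generations` cap
(default 10⁴) bounds the loop defensively.

The engine rebuilds components from scratch each generation with the
compiled union-find/BFS in `scipy.sparse.csgraph.connected_components`
applied to the filtered edge list — `O(M α(N))` per generation, entirely
adequate at the sizes studied (`N ≤ 2^18`). Partitions are canonicalized
(cluster label = smallest member id) so equality tests are `O(N)` array
comparisons.

The order parameter is `ψ^n`, the largest cluster's node fraction at
generation `n`; `N₂` is the second-largest cluster's node count, whose peak
across a control sweep locates the finite-size pseudo-critical point.

## Control parameters

Two ways to drive the transition:

* **Degree control** (`z`): generate fresh layers at average degree `z`.
  ER layers use the fixed-edge-count ensemble `G(N, M)` with
  `M = round(zN/2)` — the control parameter is pinned exactly, removing
  ensemble noise in `z`; the difference from `G(N, p)` vanishes as N grows.
* **Occupation control** (`p`): fix the layers and retain each link
  independently with probability `p`. For sweeps, each edge carries a
  single uniform mark and the occupied set is `{mark < p}`, so occupied
  sets are nested across `p` (coupled dilution). This makes every
  realization's sweep monotone in `p` and is the default; independent
  redraws per grid point are available (`coupled=False`) for checking that
  ensemble averages are unaffected.

## Generators

* **ER**: uniform simple graph with exactly `M` edges, by vectorized
  rejection sampling of distinct unordered pairs.
* **Truncated power law** (configuration model): degrees sampled i.i.d.
  from `p_k ∝ k^(−γ)` on `{m, …, K}`, `K` defaulting to `floor(√N)`.
  Normalization is numeric (the closed form `c ≈ (γ−1)m^(γ−1)` is only the
  large-K limit). If the degree sum is odd, the last node's degree is
  resampled until even — unbiased for all but one node. Stubs are paired
  uniformly and the multigraph is *erased* to a simple graph (self-loops
  dropped, multi-edges collapsed); at `γ = 2.5`, `K = √N`, `N ≥ 2^14` the
  edge loss is below 2% and is asserted in the tests.
* **Top-weight thresholding**: given a symmetric weight matrix, keep
  exactly the `M = round(zN/2)` largest upper-triangle weights; ties break
  deterministically by (weight descending, then (i,j) lexicographic). This
  is the standard construction for turning weighted connectome matrices
  into sparse layers at a target density.
* **Synthetic weighted bilayer**: upper-triangle entries of two matrices
  jointly Gaussian with correlation `ρ`, plus an optional additive
  within-community boost. It emulates the *statistical* structure of a
  functional/morphological matrix pair — tunable inter-layer weight
  correlation, hence tunable thresholded-layer overlap, and block
  community structure. It does **not** emulate spatial embedding,
  hemispheric symmetry, distance-dependent connectivity, or the heavy
  tails of empirical similarity measures; conclusions drawn from it
  concern the percolation machinery, not brain biology.

RNG policy: every stochastic routine takes a seed or `numpy` Generator;
ensemble drivers spawn independent child streams per realization from one
master `SeedSequence`, so any single realization is reproducible from
(master seed, index).

## Mean-field theory

`F(x)` is the giant-cluster fraction of a layer ensemble restricted to a
random usable node fraction `x`, measured relative to the used nodes. The
recursion alternates layers:

    S^n   = S^0 · F_{A or B}(S^{n−1}),   ψ^n = S^{n−1} · F(S^{n−1}),

with `S^0 = 1` for degree control. Bond dilution at occupation `p`
replaces `F(x)` by `F(px)`; initial node removal would set `S^0 = p`
(implemented for completeness, not used by the standard protocols).

* ER: `F(x)` is the largest root `u` of `u = 1 − exp(−z·x·u)`, zero for
  `zx ≤ 1`; solved by bracketed Brent to 10⁻¹⁰.
* Configuration model: generating-function self-consistency
  `u = (1−x) + x·G1(u)`, `F = 1 − G0(u)`; verified to reduce to the ER
  form for Poisson degrees. The scale-free theory is used with finite
  truncation `K` and reports threshold-vs-K trends (the threshold in `x`
  decreases as `K` grows for `2 < γ < 3`); asymptotic exponents are out of
  scope.

Finite-generation thresholds come from bisection on the control value for
the smallest value with `ψ^n > 10⁻⁸` (numerical meaning of "nonzero").
For ER this gives `z_c¹ = 1`, `z_c² ≈ 1.582` (the root of `z·S(z) = 1`
with `S` the classical giant-component fraction), increasing toward the
infinite-generation value.

The infinite-generation limit satisfies `S = S^0·F(S)`. For identical ER
layers at `S^0 = 1` this is `S = 1 − exp(−zS²)`. The nonzero solution is
born in a tangent (saddle-node) bifurcation, so the steady-state
transition is *discontinuous*: at the critical degree the order parameter
jumps from 0 to `ψ_c = S_c²`. Numerically the fixed point is found by
locating the interior minimum of `g(S) = S − S^0·F(S)` (coarse grid plus
bounded scalar minimization — plain sign-scanning misses the dip, which
shrinks to a point at tangency) and bisecting the largest root; the
critical control value is bisected to 10⁻⁹ because `S(c)` departs from
`S_c` like `sqrt(c − c_c)`, so a loose control tolerance would bias the
reported `S_c` upward. The closed-form cross-check solves the tangency
system directly: `−2(1−S)ln(1−S)/S = 1`, giving `z_c ≈ 2.4554`,
`S_c ≈ 0.7153`, `ψ_c ≈ 0.5117`, and satisfying
`S_c = (1 + sqrt(1 − 2/z_c))/2`. (A variant of this expression sometimes
quoted with `1 − z_c/2` under the root is dimensionally impossible at
`z_c ≈ 2.455`; the form above is the one consistent with the tangency
condition and with the value 0.715.)

Near-tangency convergence of the plain recursion is slow (critical
slowing down); the bisection-based fixed point and the iterated recursion
are cross-checked against each other in the tests wherever both converge.

## Monte Carlo protocols and finite-size scaling

* **Sweeps**: `R` independent realizations per grid point; degree control
  regenerates layers per point, occupation control dilutes one fixed
  multiplex per realization with coupled marks. Sample arrays are retained
  so both averaging conventions are available: over *all* realizations
  (finite-generation scaling) and over *percolating* realizations only
  (discontinuous-transition extrapolation).
* **Bimodal classification**: at the steady-state critical point the
  per-realization `ψ` distribution is bimodal — a near-zero mode
  (non-percolating) and a macroscopic mode. The splitter takes the deepest
  histogram valley between the two most populated modes, requires the
  valley to be at most half as populated as the lesser mode *and* the
  lower group's mean to sit well below the upper group's (scale
  separation), and otherwise falls back to the cutoff `5·N^(−1/3)` (the
  continuous-transition finite-size scale). The guards keep unimodal
  samples from being split on histogram noise.
* **Pseudo-critical point**: the grid value maximizing the ensemble-mean
  `N₂`, refined by quadratic interpolation through the argmax and its
  neighbours; a peak on the grid boundary raises an error rather than
  returning a biased value.
* **Power fit** `value ∝ N^(−ε)`: least squares on log–log, ε reported
  positive for decay, with standard error from the residuals.
* **Offset fit** `value(N) = c0 + a·N^(−ε)`: grid search over
  ε ∈ (0, 1) in steps of 10⁻³ with a linear least-squares subproblem for
  `(c0, a)` at each ε — immune to the initialization sensitivity of a
  joint nonlinear fit. For a nonnegative observable decaying toward its
  limit, the extrapolated offset is additionally constrained to the
  admissible band `0 ≤ c0 ≤ min(values)`; over a narrow size window the
  small-ε part of the grid is nearly collinear with the intercept, and
  without the constraint it can win the residual race with wildly
  extrapolated offsets. Even so, `(c0, ε)` remain strongly correlated on
  few-octave windows: point estimates of `c0` carry an uncertainty of a
  few times the per-point noise, which the reduced-scale protocols here
  cannot fully suppress. Both fitters are validated on synthetic data with
  known exponents before being trusted on simulation output.
* **Cluster-size distribution**: pooled histogram at a given generation,
  log-binned (base 1.3), normalized per node and per unit size.

## Problem sizes

The default verification protocols use: steady-state ER runs at
`z = z_c^∞` for `N ∈ {2^12 … 2^16}` with replications graded by per-size
cost (600/450/300/220/200, all at least 200 per size) for the offset fit
of the percolating-realization mean and the percolating fraction at
`N = 2^16`; generation-1 ER runs at `z = 1` for `N ∈ {2^12 … 2^18}` with
100 realizations per size (continuous-transition exponent ε = 1/3); the
theory–simulation overlay at `N = 2^16` with 20 realizations per degree;
and scale-free generation-3 sweeps at `γ = 2.5, m = 2, K = √N` for
`N ∈ {2^12 … 2^17}` with graded replications (250/200/150/100/70/50) on
the refined grid (pseudo-critical decay exponent α). The pseudo-critical
grids are chosen adaptively: a coarse scan locates the `N₂` peak, a
refined grid (step 0.01, half-width 0.05) around it feeds the quadratic
interpolation; the fit window is reported with the fit. The α ≈ 0.075
exponent is small and known to be sensitive to the size window; the
reported value should be read together with that window. On the
steady-state offset extrapolation specifically, the few-octave window
carries little curvature: the per-size means decay nearly linearly in
`ln N` at the attainable noise level, so the extrapolated `c0` has a wide
statistical equivalence region and its point estimate at this scale
should be treated as indicative, not conclusive (see the offset-fit
discussion above).

## Known limitations

* The mean-field recursion and fixed point are implemented for two
  layers; the engine itself accepts any `L ≥ 2`.
* The occupation-control theory treats dilution through `F(px)`, which is
  exact for ER ensembles and a degree-distribution approximation for the
  erased configuration model (simplification slightly distorts the
  realized degrees at finite N).
* No weighted or directed percolation; no site-dilution simulations.
* The synthetic bilayer is a statistical stand-in for connectome-style
  data, as discussed above.
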