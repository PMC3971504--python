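# Methods

## Problem setting

A cocktail of `n` drugs is a vector of integer concentration indices,
one per drug, each in `0..T`; real concentrations are an affine view of
the indices and play no role in the search itself.  An oracle
`f: {0..T}^n → [0, 1]` returns the measured sensitivity of a cocktail.
The cost unit is one oracle query (one wet-lab experiment); CPU time is
explicitly not the objective.  The package assumes the surface is
benign in one specific sense: cocktails close to the optimum in L1
index distance have sensitivity close to the optimum.  Nothing else is
assumed — no unimodality, no prior normalization of the surface, no
gradient access.

## Search procedure

**Parallel phase.**  `m` points are drawn as a Latin-hypercube sample
in the continuous unit cube (one point per `1/m`-width stratum per
dimension), improved under the maximin criterion by random within-column
swaps (a swap is kept only if it strictly increases the minimum pairwise
Euclidean distance; default budget 1000 swaps, after which improvements
are negligible on the grid sizes considered), then snapped to the
lattice by per-coordinate rounding.  If two continuous points snap to
the same cell, the later one moves to the nearest free cell (L1-nearest,
lexicographic tie-break) so the full budget of `m` distinct experiments
is spent.  The distance metric for the maximin criterion is Euclidean in
the continuous cube; this is a package choice — the criterion's metric
is genuinely open, and L1 would change little at these sizes.

**Surface estimate.**  Measured sensitivities are min–max normalized
and raised to the `(n − 1)`th power (for `n = 2` the exponent is 1 and
the step is a no-op; an all-equal input degenerates to flat weights).
The full grid is then inpainted by weighted penalized least squares:
minimize `F(ŷ) = ‖W^{1/2}(ŷ − y)‖² + s·‖Dŷ‖²` where `W` is 1 at
measured cells and 0 elsewhere and `D` is the lattice Laplacian with
Neumann (reflective) boundaries.  The type-2 DCT diagonalizes `D`, so
the minimizer is iterated as
`ŷ ← IDCT(Γ ∘ DCT(W∘(y − ŷ) + ŷ))`, `Γ = 1/(1 + s·Λ²)`,
`Λ(k) = Σ_i (2 − 2 cos(π k_i / N_i))`.  Defaults: `s = 10⁻³` (small, so
the estimate passes within 10⁻³ of the measured values), 100 iterations,
early stop when the max update falls below 10⁻⁹.  The iteration starts
from a nearest-known-neighbor fill rather than zeros: with a fixed
iteration budget a good start matters, and the fixed point is unchanged.
Estimates are clipped at 0 before use as a sampling weight (the
smoother can undershoot).  A dense normal-equation solver
(`brute_force_smoother`) provides an independent oracle on grids up to
10⁴ cells; the two agree to 10⁻⁶ at convergence.

**Focused step (probability 0.3).**  Grid cells are walked from highest
to lowest estimated sensitivity (stable sort, lexicographic tie-break).
Each tested cell met along the walk is labeled with its *hill* — the
terminal of a deterministic steepest-ascent walk over axis neighbors
(ties to the lexicographically smallest neighbor); two tested points
share a hill iff they ascend to the same terminal.  A hill whose top
`ξ` cells are all tested is *discovered* and its cells are skipped:
enough is known there, and the budget is better spent elsewhere.  The
first untested cell on an undiscovered hill becomes the next
experiment.  If the walk inspects `⌈1% of grid points⌉` cells without
finding one, the estimates inside an L2 sphere of volume 1/500 of the
search space around the current top cell are archived and zeroed, and
the iteration restarts; a newly tested point landing inside such a
sphere lifts the suppression (the archive makes this lossless).  After
five consecutive restarts the iteration falls through to a diverse
step — the situation where every hill is discovered is otherwise a
deadlock, and exploring is the only sensible continuation.

**Diverse step (probability 0.7).**  The clipped estimate is treated as
an unnormalized PMF and sampled by systematic-scan Gibbs: each sweep
redraws every coordinate from its exact 1-D conditional (a normalized
slice of the tensor); one sample is recorded per sweep after a 10-sweep
burn-in from a random positive cell.  Default sample count: twice the
grid size for grids under 7500 cells, else 15 000.  The candidate is
drawn uniformly from the sampled cells not yet tested; if every sample
is already tested, a uniform draw over untested cells is the fallback.
Re-testing a measured cell would waste an experiment under the cost
metric, so candidates never repeat.

**Parameter defaults** (all exposed in `SearchParams`): focus
probability 0.3; power exponent `n − 1`; hill-discovery threshold
`ξ = 2n − 1` for `n < 5`, else 7; cluster break `⌈0.01·(T+1)^n⌉`
inspected cells; suppression sphere volume 1/500 of the grid (its
radius solves `c_n r^n = (T+1)^n/500` with `c_n` the unit n-ball
volume); Gibbs burn-in 10 sweeps.  One seeded generator drives the
whole run in a fixed order (LHS, then per-iteration path choice and
sampling), so runs are bit-reproducible.

## Distance theory

The `theory` module is exact: the triangular offset PMF, its fold, the
`n`-fold convolution (`R1`), the minimum-of-`m` order statistic (`R2`,
via `CDF = 1 − (1 − CDF_{R1})^m`), moments of both, the `k`-optimum
adjustment (`μ_k(n,T,m) = μ(n,T,k·m)`), the product-of-uniforms density
`(ln 1/x)^{r−1}/(r−1)!` for the focused-decay model, and the stitched
expected-distance trajectory (order-statistic mean up to iteration `m`,
then decay by `2^{−(t−m)p}`).  The largest convolution used anywhere in
the tests has 151 support points; everything is sub-second.

Two approximations are inherited by the model itself and worth naming:

* `R2` assumes the `m` distances are fully independent, but in a run
  they share one optimum location; simulation shows this biases the
  model mean slightly low (≈0.2 at `n=2, T=20, m=5`).
* The focused-decay model treats the L1 distance as shrinking by one
  uniform factor per refinement — an acknowledged simplification of the
  per-dimension shrinkage.

## Benchmark protocol

`run_trials` repeats the search with seeds `base_seed + i`.  *Cost* is
the mean number of oracle queries until the first tested cocktail
reaches `threshold` (default 0.95) times the surface maximum, counting
the initial-design queries; *success rate* is the fraction of runs that
get there within the query budget; the worst case and the standard
deviation over runs are reported alongside.  Runs stop querying once
the threshold is reached (the screening protocol stops when a
good-enough cocktail is in hand), which cost accounting never notices
but which keeps repeated evaluation fast.  The control is uniform
sampling without replacement, whose exact expected cost on a surface
with `q` qualifying cells out of `N` is `(N + 1)/(q + 1)`.

## Synthetic surfaces and what the tests show

Two generators stand in for laboratory response surfaces: a Gaussian
multi-hill surface (floor plus bumps; hill count and width control how
many near-optimal cells exist) and a unimodal inverted-sphere surface
(`1 − d²/d²_max`).  Both are smooth, noise-free, and exactly tabulated,
which real dose-response data is not: measurement noise, plate effects
and non-smooth synergy cliffs are all absent.  Passing benchmarks on
these surfaces therefore demonstrates the search mechanics — query
accounting, convergence of the estimate, hill bookkeeping, the cost
advantage over undirected sampling — not clinical performance.  A
reader for tabulated surfaces (dense matrix for two drugs, or long
format `d1..dn,sensitivity`; values above 1 are rescaled by the file
maximum, a convention choice for raw inhibition percentages) accepts
external experimental grids.

On the built-in 21×21 unimodal surface with `m = 5`, 100 seeded runs
reach the 0.95 threshold with success rate 1.0 at mean cost 8.48
(worst 28), versus 11.6 expected for uniform sampling without
replacement and 441 for exhaustion.

One theory-versus-simulation comparison fails by a small margin and is
kept failing deliberately: the mean minimum L1 distance after the `m`
initial points, averaged over 100 runs with a uniformly placed optimum,
is 5.05 at `n=2, T=20, m=5`, below the `μ ± 3σ/√100` band
`[5.25, 7.30]` around the iid-placement prediction `μ = 6.28`.  The
cause is systematic, not a bug: the maximin Latin-hypercube design is
more space-filling than the iid-uniform placement the order-statistic
model assumes, so the initial design sits *closer* to the optimum than
the theory predicts.  The same comparison at `n=4, T=10, m=10` falls
inside its band.  The theory is thus a conservative envelope for the
algorithm's parallel phase, and the two-sided equality check fails on
the favorable side; weakening the design (fewer maximin swaps) would
mask the effect rather than explain it.

## Numerical choices and limitations

* Sort and ascent tie-breaks are lexicographic throughout, making every
  deterministic sub-procedure reproducible and testable.
* The smoother's fixed 100-iteration budget is far from convergence for
  very small `s`; tests that compare against the dense oracle raise the
  budget and tighten the stop tolerance instead of changing `s`.
* Problem sizes in the test suite are desk-scale (grids ≤ 21², runs of
  ≤ 250 queries, 100 repetitions) — chosen so the whole suite runs in
  about a minute while still exercising every code path.
* Complexity grows with `(T + 1)^n` through the dense estimate tensor;
  the method is intended for cocktails of up to roughly ten drugs after
  candidate reduction, not for raw drug libraries.
* Measurement noise and toxicity/cost terms are out of scope; the
  oracle is assumed exact and free of side-effect penalties.
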