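# Methods

## Model

`graphmm` tests, at every vertex `v` of a known undirected graph
`G = (V, E)`, the null hypothesis that the group means agree,
`H_{0,v}: mu_{X,v} = mu_{Y,v}`, from two-group data `X` (N × M_X) and `Y`
(N × M_Y).  Instead of reducing each vertex to a univariate statistic, the
model places a discrete mixture over *graph-respecting partitions* of a
small subgraph around `v` — partitions in which every block induces a
connected subgraph — together with a per-block shift indicator
`Delta_k = 1[delta_k != 0]`.  Vertices in the same block share a base mean
`phi_k` in group 1 and `phi_k + delta_k Delta_k` in group 2, so spatially
coherent signal at neighbors sharpens the test at `v`.

Graph restriction is what keeps the discrete state space tractable: the
3×3 lattice has 1434 graph-respecting partitions against 21 147 = B(9)
unrestricted set partitions, and the local star graphs are smaller still.
Enumeration grows the block containing the smallest unassigned vertex over
all connected supersets (bitmask frontier expansion), recursing on the
remainder; results are cached per subgraph shape.

### Likelihood

Per group the sampling model is multivariate Gaussian with unknown
covariance carrying a conjugate inverse-Wishart prior, `U ~ IW(A, df)` and
`W ~ IW(B, df)`.  Integrating the covariances analytically gives a
matrix-T marginal

    f(X, Y | mu_X, mu_Y) = C |A|^{df/2} |B|^{df/2}
                           / ( |A~|^{(df+M_X)/2} |B~|^{(df+M_Y)/2} ),

with `A~ = A + (M_X - 1) S1 + M_X (Xbar - mu_X)(Xbar - mu_X)'` and `B~`
analogous.  The constant `C` (a ratio of multivariate gamma functions per
group) is implemented in full, so the value is an absolute log density and
unit tests can check it against numerical integration of the
Normal × inverse-Wishart model; it would cancel across mixture components
otherwise.  The likelihood deliberately allows general covariance among
vertices: it is *not* a product-partition model, because independence
across blocks is not defensible for imaging data.

### Marginalizing the free means

Block base-means carry priors `phi_k ~ N(mu0, tau2)` and active shifts
`delta_k ~ N(delta0, sigma2)`.  The marginal of one configuration
`(Psi, Delta)` integrates these `d = K + #active` parameters out by a
Laplace approximation around the posterior mode.  By the matrix
determinant lemma the data term reduces to
`const - a_X log(1 + M_X q_X) - a_Y log(1 + M_Y q_Y)` with `q_X, q_Y`
quadratic forms in the parameters, so the gradient and Hessian are
closed-form and the mode is found by a damped (Levenberg-style) Newton
ascent started from block means of the observed data, typically
converging in under ten iterations.  We use the analytic derivatives
rather than finite differences: they are exact, faster, and the whole
construction is validated end-to-end against integration oracles (below).
If the negative Hessian at the mode is not positive definite — possible in
principle far from concentration — a minimal ridge is added before taking
its log-determinant.

Configurations are weighted by a uniform prior over the enumerated
partitions of the local subgraph times iid Bernoulli block nulls
(`P(Delta_k = 0) = p0`), normalized by log-sum-exp; all mixture arithmetic
stays in log space because weights span hundreds of log units.  The local
FDR is `l_v = sum of posterior weights of configurations in which v's
block is unshifted`.

### Accuracy of the Laplace step

With `M = 4` samples per group and `df = 6` the matrix-T is heavy-tailed
and the Gaussian approximation is at its weakest; on all 18 configurations
of a 3-vertex path the config posterior still agrees with an
importance-sampling integration oracle within 0.05 total variation, and at
`M = 30` (the simulation suite) the approximation error is negligible
relative to Monte-Carlo noise.  The single-block marginal agrees with 1D
adaptive quadrature within 0.3% relative log density.

## Whole-lattice engine

Each vertex is scored from its local subgraph only: the 3×3 in-slice
lattice window (`lattice3x3`), the 4-neighbor in-slice star (`star2d`), or
the 6-neighbor 3D star (`star3d`).  Windows are clipped at lattice borders
— never padded — and the model runs on whatever connected subgraph
remains, with the globally estimated scale matrices subset to the present
window slots (principal submatrices).  Vertices sharing a window shape are
processed as one numpy batch; the arithmetic is identical to the
single-graph API (verified to ~1e-9) and independent of vertex order.  A
vertex whose local computation fails is reported conservatively with
`l_v = 1` and a warning, never dropped.

Discoveries are `L(c) = {v : l_v <= c}`.  The *controlled* FDR of a list
is the mean of its `l_v` — a data-computable bound on the expected false
discovery proportion; in simulations the *empirical* FDR and TPR count the
latent null indicators.

The full 3×3 window mixes over roughly 26 000 configurations per vertex
(seconds per vertex); the star windows mix over 162 (milliseconds per
vertex).  The bundled simulation suites therefore run the star2d window on
a 20×25 slice — small enough for routine testing, large enough for stable
rate estimates — while `lattice3x3` remains available for production runs
where minutes per slice are acceptable.

## Empirical-Bayes hyperparameters

Estimated once from the whole graph, moment-based, each estimator
swappable via `EstimatorConfig`:

| parameter | default estimator | notes |
|---|---|---|
| mu0, tau2 | mean / variance over vertices of pooled per-vertex means | tau2 floored at 1e-6 |
| delta0 | 0 | symmetric two-sided testing |
| sigma2 | var over vertices of (Ybar_v − Xbar_v) minus mean sampling variance | floored at 1e-6 |
| df | window order + 2 | smallest integer df with a finite IW mean |
| A, B | (df − n_w − 1) × average full-window sample covariance, 50% shrunk to its diagonal | IW mean equals the shrunk covariance |
| p0 | Storey's estimator at lambda = 0.5 on per-vertex Welch t-test p-values | floored at 1/n, capped at 1 |

`p0` is estimated marginally per vertex but enters the prior as the
block-level null probability; when blocks of nulls and non-nulls have
similar sizes the two coincide, and under-estimating `p0` is the
conservative direction for FDR.  The moment estimator for `sigma2`
averages over null vertices and so understates the shift variance of the
truly shifted blocks; this over-shrinks `delta` and again errs
conservative.  Fewer than 50 vertices triggers wide defaults
(tau2, sigma2 >= 1) and a warning.

Preprocessing utilities mirror a standard imaging pipeline: a per-vertex
rank-based normal-scores transform (midranks; Phi^{-1}((r − 0.5)/M) over
the pooled samples) and a low-marginal-SD vertex filter at a quantile
threshold.

## Toy system

The two-pair toy model isolates the blocking phenomenon: latent means are
standard normal across the system; a unit is null with probability `p0`
(tested pair shares its mean) and blocked with probability `p_block`
(second variable duplicates both means); observation noise has known
variance `sigma2`.  `lfdr1` uses only (x1, y1); `lfdr2` mixes over the
four (null × blocked) states of a 4-variate normal whose component
covariances are built as `sigma2 I + Z Z'` from the unit-to-mean incidence
`Z` — no hand-entered matrices.  With `p_block = 0`, `lfdr2` reduces to
`lfdr1` exactly.  The mis-specification experiment generates with one
blocking rate and scores with another: under-stating the rate preserves
FDR control, over-stating it (over-regularizing) can lose it.

## Synthetic scenarios

Scenario data emulate a single coronal slice: a contiguous partition of
the lattice with block-constant base means `N(mu0 = 0, tau2 = 1)`, a
fraction of blocks shifted by ±`shift_magnitude` noise-SDs (sign random),
and unit-variance Gaussian noise per sample, independent by default or
with an optional Gaussian-kernel spatial correlation.  Five preset shapes
vary the block-size law and the shift regime: (1) blocks of 12–14 voxels,
(2) small blocks of 2–4, (3) large blocks of 20–25 — all with
shift fraction 0.2 and magnitude 0.6 — and mean-4-voxel blocks with
(4) fewer, stronger shifts (0.1, 1.0) and (5) more frequent, weaker ones
(0.4, 0.35).  Default group sizes are M_X = M_Y = 30 on a 20×25 slice,
the sizes at which the bundled rate suites run.

Blocks are consecutive segments of a serpentine (boustrophedon) traversal
of the lattice.  This guarantees contiguity and *exact* compliance with
the block-size law (a random composition of N with all parts in the law's
support), at the cost of elongated, anisotropic block shapes; real
atrophy clusters are blobbier, so the suite if anything understates the
advantage a compact-window model has on compact signal.  Setting
`graph_respecting=False` then reassigns 20% of vertices to random
non-adjacent blocks: latent means stay clustered and low-dimensional but
are no longer contiguous, reproducing the robustness regime in which FDR
control should survive model violation.

Two permutation experiments complete the harness: re-splitting the pooled
sample columns (destroys all group signal; every discovery is false) and
applying one random vertex permutation to all samples (preserves
per-vertex marginals, destroys spatial structure; detections should
thin out).  On the second, note that the lfdr *distributions* cross:
permutation empties the low tail — the detections — while the upper bulk
moves slightly down, so the correct check is depletion of small lfdrs,
not global stochastic ordering.

## What the synthetic suites do and do not show

The generator matches the model family closely (Gaussian noise,
block-level shifts); passing rate tests therefore demonstrates internal
calibration and the blocking power mechanism, not robustness to the
artifacts of real structural MRI (registration error, intensity
non-normality, long-range covariance).  The non-contiguous-truth scenario
and the fixed ±magnitude shifts (which violate the Gaussian shift prior)
are deliberate, mild mis-specifications in the conservative direction.
Real-data runs should apply the normal-scores transform and the
low-variance filter first, as the preprocessing utilities do.

## Numerical choices

- Newton ascent: gradient tolerance 1e-8 (scaled), max 80 iterations,
  backtracking with an absolute slack of 1e-9 to absorb float noise in an
  objective of magnitude ~10^2; Levenberg ridge grows 10× on a stuck step
  and decays 2× otherwise.
- `A + (M_X − 1) S1` must be positive definite; if not, a trace-scaled
  ridge `1e-8 · tr/n` is added (growing 10×, with a warning).
- Ties in ranking: discovery lists sort by `l_v` then vertex id;
  normal scores use midranks.
- Degenerate inputs: constant rows get p = 1 in Welch tests (warning),
  zero-variance rows are flagged by the filter; `p0` at the 0/1 boundary
  is handled as a prior limit (configurations with vanishing mass are
  dropped at `-inf`).
- Reproducibility: every stochastic entry point takes a seed;
  `numpy.random.default_rng` throughout.

## Known limitations

- Exhaustive enumeration caps the local window at ~12 vertices; larger
  neighborhoods would need sampling over partitions, which is out of
  scope.
- The Laplace error grows with the number of free parameters when sample
  sizes are very small (M ≲ 4); the quadrature cross-checks bound it at
  0.05 total variation there.
- Serpentine blocks are anisotropic; block-shape realism is traded for
  exact size-law control.
- A single global `p0` is shared across the volume; slice-specific nulls
  are not modeled.
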