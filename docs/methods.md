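# Methods notes

## The complexity model

The alpha shape of a point set at radius α is the union of Delaunay
tetrahedra whose circumsphere radius is at most α. The family over α is
nested: the kept set only grows with α, so the enclosed volume is exactly
non-decreasing and reaches the convex hull in the α → ∞ limit. We
parameterize the family by the dimensionless refinement coefficient
k = α / l_ref, where l_ref is the mean distance from each point of the
down-sampled interior cloud to its 100 nearest neighbors. Because l_ref
scales linearly with the specimen, k is scale-free; the package asserts
invariance of the final score under ×10 scaling (exact up to floating
point, since fill candidates are generated as unit variates mapped into
the bounding box) and under rigid motion (sampling noise only, ~0.5% in
practice).

A specimen's characteristic curve is alpha-shape volume as a percent of
the source mesh volume across 200 k values log-spaced on [0.1, 10⁴].
Concave specimens exceed 100% at coarse k (the near-hull fit bridges
their concavities); the optimal refinement k_opt is where the curve
crosses 100%, and alpha complexity is 1/k_opt. Convex specimens never
cross: the hull of n interior samples undershoots a smooth convex body by
O(n^(-2/3)) (≈3% at 20k points, ≈1.4% at 100k), so they are flagged
out-of-range and reported at the grid boundary (complexity 10⁻⁴) — the
correct qualitative answer (minimal complexity) with an explicit flag.

### Numerical choices

- **Circumradii** come from the linear circumcenter system
  (v_i − a)·(c − a) = |v_i − a|²/2, solved in batch. Near-flat
  tetrahedra (|det| < 1e-14·edge³) get radius ∞ and are never kept; their
  volume is numerically zero by the same determinant.
- **The coarsest grid endpoint maps to α = ∞** (exactly the hull).
  Delaunay triangulations of interior-filled clouds contain tetrahedra
  with near-cocircular vertices whose circumradius can exceed k_max·l_ref
  by orders of magnitude while carrying ~10⁻⁵ of the total volume; a
  finite cutoff at the top of a family meant to "span to the convex hull"
  would therefore undershoot the hull. Fits at any finite α remain the
  pure circumradius filter.
- **Optimal k** is found by locating the first grid value with fraction
  ≥ 100% and bisecting the bracketing interval in log₁₀ k until the
  fraction is within 0.1 percentage points of 100% or the bracket is
  narrower than 10⁻³ in log₁₀ k. The objective is exactly monotone
  (cumulative sums over radius-sorted tetrahedra), so bisection is
  deterministic, derivative-free, and immune to the flat 0%-volume region
  that defeats simplex-type optimizers.
- **Tie-break at the filter boundary** is inclusive (circumradius ≤ α).
- **Point-in-polyhedron** casts +z rays against triangles bucketed on a
  2D grid; barycentric coordinates within 1e-10 of an edge, near-vertical
  triangles under the query, or crossings within 1e-11·diag of the query
  height mark the query degenerate, and it is re-cast from a jittered
  position (1e-8·diag) with fresh randomness — the standard robust
  treatment for parity tests.
- **l_ref** is the mean of per-point means; with a fixed neighbor count
  this equals the pooled mean, so the two readings of "average distance
  of all points to their 100 nearest neighbors" coincide.

## Heatmaps

Each cloud point receives the coarsest (largest) grid k at which it is a
vertex of the alpha-shape boundary at that k; boundary membership is not
monotone in k, so the grid is scanned from the coarse end and the first
hit wins. Convex-hull vertices therefore always carry k_max. Points never
on any boundary keep a NaN sentinel and are excluded from face averages
(an all-NaN face inherits its edge-neighbors' mean). Values are rendered
on the optimal fit's boundary through a red→blue ramp on log₁₀ k built so
that warmth (R − B) is strictly monotone decreasing in k — hot regions
are the ones only tight fits resolve, i.e. the drivers of complexity.
Off-the-shelf diverging colormaps darken at their extremes and would
break the monotone-warmth contract the tests assert.

## Morphospace

Profiles are the curve's fractions at the 6 grid points nearest (in
log k) to {0.1, 1, 10, 100, 1000, 10⁴} — the unique log-equally-spaced
six-point set spanning the grid. PCA standardizes columns (zero mean,
unit variance) and eigendecomposes the correlation matrix; component
signs are fixed by making each component's largest-magnitude loading
positive. Phylogenetic PCA estimates a single Pagel λ for the profile
matrix by pooled ML, eigendecomposes the evolutionary correlation matrix
R = (X − a)ᵀ V(λ)⁻¹ (X − a)/(n − 1) (a = phylogenetic means), and scores
standardized residuals from a; with λ → 0 or a star tree this reduces
exactly to ordinary correlation PCA.

## Comparative statistics

All procedures operate on the Brownian tip covariance C (C_ij = shared
root-to-MRCA path length). Pagel's λ multiplies the off-diagonal of C.

- **λ signal test**: profile ML over λ ∈ [0, 1] (bounded scalar
  minimization with endpoint checks), p from χ²₁ on the likelihood ratio
  against λ = 0.
- **Ancestral states**: GLS/ML Brownian estimates
  â_j = μ̂ + c_jᵀ C⁻¹ (x − μ̂1), with c_j the node-to-tip shared path
  vector; the root equals the GLS grand mean. Verified against the
  re-rooting route on fixtures.
- **PGLS**: λ estimated by ML jointly with coefficients; standard errors
  use the unbiased residual variance and t has n − p degrees of freedom
  (λ not counted, matching GLS convention). At λ = 0 on an ultrametric
  tree this is numerically identical to OLS.
- **Phylogenetic ANOVA/MANOVA**: the classical F (or Wilks' Λ with Rao's
  F approximation) on the observed data, referenced to a null
  distribution of the same statistic over Brownian simulations on the
  tree, with the (co)variance estimated from the data by ML/GLS;
  p = (1 + #{more extreme}) / (n_sim + 1). Default n_sim = 1000.
- Degrees of branch-length freedom: all statistics are invariant to
  multiplying every branch by a constant (asserted to 1e-8).

Species missing a variable are dropped from that model only; an optional
cetaceans-only subset switch reruns all models on the restricted clade.

## Synthetic data

The tube generator emulates lumen endocasts at the level relevant to the
method: radius field r(θ, z) = R(z)·(1 − Σ dents) + texture, where R(z)
tapers linearly, each fold is a raised-cosine dent of angular half-width
`fold_width` whose locus may spiral along the axis, dents fade over the
terminal 15% of the axis so end caps stay clean, and texture is
band-limited harmonic noise (angular/axial modes 14–24 by default) fading
at the ends. Total dent depth is capped at 0.95 of the local radius;
fold_depth ≥ 1 is rejected as self-intersecting. Meshes are closed with
triangle-fan caps and always pass watertight/winding validation; the
fold-free, noise-free tube has a closed-form volume used as an oracle.

Two design points matter for what passing tests mean:

- **Gross folds are few and wide** (defaults 3 folds, half-width 1.1 rad).
  The radius of the sphere that bridges a fold mouth is capped by the
  tube radius, so narrow folds would be resolved at the same fine scales
  as surface texture; wide folds keep the gross-concavity signal in the
  coarse sampled scales and let PC1 (gross) and PC2 (texture) separate —
  the separation the cohort tests assert exists by construction.
- **Texture is band-limited at scales below the fold-mouth scale**, so
  the two knobs move different parts of the characteristic curve.

Comparative data are simulated on pure-birth (Yule) trees (dendropy;
terminal branches extended by the exponential waiting time to the next
speciation so that stopping at the n-th birth event does not leave a
zero-length cherry). Predictors evolve as unit-depth Brownian motion;
the response adds known slopes and a Pagel-λ-structured residual. The
cohort generator mirrors the study's composition (19 species / 40
specimens; ~14 "cetaceans", 4 "pinnipeds", 1 "sirenian") with
within-species jitter on shape parameters smaller than between-species
spread by construction.

What the generator does **not** emulate: real photogrammetry artifacts
(holes, non-manifold patches, remeshing noise), anatomically realistic
fold geometry (real vaginal folds are flaps, not radial dents), allometry
between size and complexity, and measurement error in trait tables.
Passing tests therefore demonstrate correctness and calibration of the
machinery, not field realism of any biological conclusion.

## Problem sizes

Package defaults are the study protocol (fill ≥ 250,000 points,
down-sample to 100,000, 100 neighbors, 200 grid values, n_sim = 1000).
The test suite and acceptance script run the same pipeline at desk scale
— 20,000-point clouds (12,000 for the 12-specimen cohort), (96, 160)
mesh resolution, n_sim = 199 inside calibration loops with 500 outer
replicates — chosen so the whole suite completes in a few minutes while
keeping every property comfortably measurable at its stated tolerance.

## Known limitations

- Sub-percent volume deficits of sampled hulls mean convex specimens
  report the boundary value 10⁻⁴ rather than a "true" tiny complexity;
  ranking among convex specimens is not meaningful.
- The coarsest-contribution map is defined on the computed grid family;
  boundary membership between grid values is not interpolated.
- PGLS p-values use the t reference, not a λ-uncertainty-adjusted one;
  with few species λ̂ is noisy (as in the cited tooling).
- Phylogenetic MANOVA simulates under multivariate Brownian motion with
  the ML evolutionary covariance; very small cohorts make that estimate
  unstable.
- The ray caster assumes a consistently-oriented closed surface; it is
  not a general mesh-repair tool (non-watertight input is rejected
  upstream by design).
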