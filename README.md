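# alphamorph

Landmark-free quantification of 3D shape complexity for anatomical
structures, built around alpha shapes, with phylogenetic comparative
statistics for relating complexity to ecological and sexual-selection
predictors.

Many biological structures — vaginal lumina, bacula, endocasts of any
internal cavity — lack the homologous landmarks that classical geometric
morphometrics requires. This package implements an alternative: fit a
*family* of alpha shapes to points filling the structure's interior,
ranging from tight "shrink-wraps" to the convex hull, and ask how refined
a fit must be before its volume matches the structure's true volume.
Structures with deep invaginations, spirals and folds need tight fits;
simple convex structures do not. The package was designed for marine
mammal vaginal endocasts (cetaceans, pinnipeds, sirenians) but applies to
any closed surface mesh.

## The method

For a watertight triangulated surface mesh with volume `V_mesh`:

1. **Interior fill.** Sample uniform random points in the bounding box and
   keep those inside the surface (ray-parity test) until ≥ 250,000 points;
   down-sample to 100,000.
2. **Reference length.** `l_ref` = mean distance from each point to its
   100 nearest neighbors. All alpha radii are expressed as `α = k · l_ref`
   with dimensionless refinement coefficient `k`, making the analysis
   scale-free.
3. **Alpha-shape family.** For 200 values of `k` log-spaced on
   `[0.1, 10⁴]`, the alpha shape is the union of Delaunay tetrahedra with
   circumradius ≤ α (the coarsest grid value is the convex hull). The
   **characteristic curve** is alpha-shape volume as % of `V_mesh`
   against `k`; it is exactly non-decreasing.
4. **Alpha complexity.** The optimal refinement `k_opt` is the `k` whose
   alpha-shape volume equals `V_mesh` (located by monotone bracketing and
   bisection in `log₁₀ k`); **alpha complexity = 1 / k_opt**. Higher
   values mean more complex shapes.
5. **Heatmaps.** Each point is assigned the *coarsest* `k` at which it
   lies on an alpha-shape boundary; mapped onto the optimal fit's surface
   (warm = low k = complex region), this localizes where complexity
   resides.
6. **Morphospace.** Volume fractions at 6 log-spaced `k` values
   (`0.1 … 10⁴`) summarize each specimen across scales; PCA (and
   phylogenetic PCA) of these profiles separates gross concavity from
   fine surface texture.
7. **Comparative tests.** Pagel's λ (ML, likelihood-ratio test), GLS
   ancestral states, PGLS regression with a Pagel correlation structure
   (λ estimated jointly by ML), and simulation-based phylogenetic
   ANOVA/MANOVA — all re-implemented on the Brownian-motion tip
   covariance matrix, reducing exactly to their classical counterparts on
   a star phylogeny.

Because no real specimen meshes ship with the package, a synthetic
generator produces endocast-like tubes with controllable invaginations
(count, depth, width, spiral), taper and band-limited surface texture,
plus comparative datasets simulated under known λ and regression slopes —
every stage of the pipeline is testable against ground truth.

## Worked example

```python
import alphamorph as am

spec = am.SyntheticShapeSpec(n_folds=3, fold_depth=0.6, fold_width=1.1,
                             spiral_turns=1.0, resolution=(96, 160), seed=7)
mesh = am.make_tube(spec)
cfg = am.RunConfig(fill_min=30_000, downsample_target=20_000, seed=1)
res = am.run_specimen(mesh, cfg, out_dir="out/demo")
print(res.complexity.optimal_k, res.complexity.alpha_complexity)
```

prints (reduced 20k-point sampling for speed):

```
specimen:        tube_d0.6_n3_s7
mesh volume:     9.089
l_ref:           0.1783
optimal k:       1.666
alpha complexity: 0.600
profile (% of mesh volume at k = 0.1 ... 10000):
     0.0    92.2   156.6   163.4   165.4   165.9
```

Reading this: the tube's three deep spiral folds are bridged by coarse
fits, which span ~166% of the true volume near the hull end; only at
`k ≈ 1.7` does the fit tighten to the true volume, giving alpha
complexity 0.60. A convex sphere processed the same way never exceeds
its own volume (the hull of interior samples slightly undershoots it),
is flagged as out-of-range at the grid boundary, and scores ~10⁻⁴ —
far below any folded tube. Outputs written per specimen: the
characteristic curve (CSV), multi-scale profile (CSV), result + seeds +
config hash (JSON), and the heatmap (colored PLY + scalar sidecar CSV).

Cohort-level runs (`am.run_cohort` or `alphamorph cohort`) add species
means, PCA/pPCA morphospaces, the λ signal test, ancestral states, PGLS
models for the standard predictor sets (relative neonate length, relative
testes mass, sexual size dimorphism) and phylogenetic ANOVA/MANOVA over
penis-tip categories, as CSV/JSON tables.

There is also a CLI:

```bash
alphamorph synth tube --spec tube.cfg --out shapes/
alphamorph specimen shapes/tube_d0.6_n3_s7.ply --seed 1 --out out/
alphamorph cohort manifest.csv --tree tree.nwk --traits traits.csv --out out/
```

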