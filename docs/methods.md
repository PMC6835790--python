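# Methods

## The problem

Consumer tests of food products collect two kinds of numbers per
consumer and product: an overall-liking grade on the 9-point hedonic
scale (1 = dislike extremely … 9 = like extremely) and perceived
attribute intensities on 5-point just-about-right (JAR) scales, coded
−2 (far too little) … 0 (just about right) … +2 (far too much).  With P
products and A attributes every consumer is a point x_i ∈ R^d,
d = P·(A+1), far too many dimensions to look at.  The liking product
landscape (LPL) method turns this into a family of 2-D maps: consumers
are embedded in a plane so that similar raters sit together, the
consumer distribution is drawn as a kernel-density layer, and one
regression landscape per evaluation (each product's liking, each
product × attribute JAR) is superimposed, made transparent wherever no
consumers sit.  Because every map of an analysis shares the same
embedding, a reader can trace one consumer cloud across maps and ask
*why* a segment likes or dislikes a product.

## Pipeline

1. **Consumer map.**  Three techniques, selectable per run:
   - *PCA*: scores on the first two principal components of the
     column-centered n × d consumer matrix.  Columns are centered, not
     standardized — hedonic and signed JAR values already live on
     comparable ranges — but a `standardize` flag exists for mixing
     heterogeneous scales.
   - *IPM variant*: classic internal preference mapping.  PCA is run on
     the P × n products-by-consumers overall-liking matrix (consumers
     as variables); products become points (component scores), and each
     consumer's position is its loading on the first two components
     multiplied by the per-component variance of the product scores.
     The scaling phrase is ambiguous in the literature (variance vs
     standard deviation, per-component vs total); we use per-component
     variance and record the choice in the embedding metadata.
   - *MDS*: metric multidimensional scaling of the Euclidean distance
     matrix, minimized by SMACOF majorization from a classical
     (Torgerson) scaling start.  The classical start removes nearly all
     seed sensitivity; the seed only perturbs exactly degenerate
     starts.  Raw squared-error stress Σ_{i<j}(d_ij − d̂_ij)² is the
     optimization target (the Guttman transform decreases it
     monotonically, which the test suite asserts per iteration);
     Kruskal stress-1, √(Σ(d_ij − d̂_ij)²/Σd_ij²), is reported.
   All embeddings are brought to a canonical orientation (principal
   axes of the final coordinates, each axis sign-fixed so its
   largest-magnitude entry is positive) so repeated runs and adjacent
   figures are directly comparable.  Data modes: OL (d = P), JAR
   (d = P·A), OLJAR (d = P·(A+1)); IPM is defined on OL only.

2. **Distribution map.**  Bivariate Gaussian KDE,
   p(x) = 1/(2πnh²) · Σ_i exp(−‖x − x_i*‖²/(2h²)), with the bivariate
   Scott bandwidth h = n^(−1/6) applied to the raw (unstandardized) map
   coordinates.  Note the Scott rule matches the usual per-dimension
   prescription only when the coordinate variance is near 1; we apply
   it literally and report h in every output.  A non-normalized legacy
   variant dividing the exponent by 2h instead of 2h² is available
   behind `as_printed=True` for fidelity comparisons only.  The default
   evaluation grid is 200 × 200 over the consumer bounding box expanded
   by 15% per side — finer than any figure raster, and shared between
   the density and acceptance layers so they superimpose exactly.

3. **Acceptance map.**  One evaluation's grades g_i are regressed on
   the 2-D coordinates with either
   - *QUA*: the quadratic response surface
     f = α₀ + α₁d₁ + α₂d₂ + α₃d₁² + α₄d₂² + α₅d₁d₂, fitted by ordinary
     least squares (requires ≥ 6 non-collinear points), or
   - *SVM*: ε-insensitive support-vector regression with RBF kernel.
     Defaults C = 1, ε = 0.1, γ = "scale" (the sklearn convention,
     1/(2·total coordinate variance)); the γ default matters — a much
     smoother kernel (e.g. 1/(2·mean pairwise squared distance),
     available as `gamma="pairwise"`) makes SVR indistinguishable from
     the quadratic on two-cluster panels and inverts the SVM-vs-QUA
     error ordering.  A small deterministic grid-search helper exists
     but is never used by default, so results are reproducible.
   Fit quality is the **percentage error**, 100·MAE/n_points, with
   MAE = (1/n)Σ|f(x_i*) − g_i| and n_points the count of scale
   categories (9 hedonic, 5 JAR; a scale-range denominator variant is
   available behind a flag).  It is computed on the training points —
   a descriptive measure of how faithfully the landscape depicts the
   panel, not a generalization estimate.

4. **Composition.**  Per-node opacity is the density normalized by its
   own maximum: empty regions are pure white, the densest point fully
   opaque (the only mapping that guarantees both stated endpoint
   behaviors).  Density contours use evenly spaced levels
   max·k/(L+1), k = 1…L.  Hedonic surfaces use a diverging blue→red
   ramp over [1, 9]; JAR surfaces interpolate five anchors (−2 dark
   blue, −1 blue, 0 green, +1 yellow, +2 red).  Each JAR figure carries
   a bar of category proportions and the percent of consumers at 0;
   each hedonic figure carries the mean grade; all annotations are
   recomputed from the raw table (asserted to 1e−9).  SVG export is
   byte-deterministic (fixed hash salt, stripped date metadata).

## The synthetic panel

The built-in generator emulates a designed two-segment tasting study:
50 "women" and 50 "men", five wines, overall liking plus five JAR
attributes, each rating drawn as segment profile mean + N(0, σ²).  The
profile means ship as a packaged CSV (60 cells).  Defaults:

| parameter        | default | rationale                                      |
|------------------|---------|------------------------------------------------|
| noise_sd σ       | 0.5     | keeps the designed segments separable (profile gaps are 1–5 scale units) while giving visible within-segment spread; exposed as a parameter |
| clip             | true    | guarantees every draw is a valid panel          |
| round_to_scale   | false   | landscapes stay smooth; rounding available for discreteness-realism studies |

Draw order is consumer-major, then product, then measure, all
lexicographic, from one RNG stream seeded per call — a seed pins the
exact table.  Clipping biases cells whose profile mean sits on a scale
bound (e.g. a designed mean of 9 on the hedonic scale); recovery tests
therefore check interior cells only, and the bias is a documented
property, not hidden.

What the generator does **not** emulate: correlated noise across
attributes, consumer-specific scale usage, discreteness (by default),
non-Gaussian response styles.  Passing tests therefore demonstrate
correctness of the machinery and recoverability of a clean two-segment
structure; they do not certify behavior on messy real panels.

One observed consequence: the designed overall-liking profiles alone
differ by 2–5 hedonic points per wine, so even the OL-only IPM map
separates the two segments about as cleanly as the OLJAR-fed PCA/MDS
maps under this generator (median silhouettes ≈ 0.90 vs 0.89 at
σ = 0.5).  The often-cited advantage of feeding attribute perceptions
into the map should be expected on panels whose segments agree on
liking but disagree on attributes — not on this design.

## Benchmark

Fourteen combinations ({IPM_OL, PCA_OL, PCA_JAR, PCA_OLJAR, MDS_OL,
MDS_JAR, MDS_OLJAR} × {QUA, SVM}) are each scored on every evaluation;
errors are averaged per evaluation first, then per family
(overall-liking / JAR), then the two family means are averaged —
ranking is ascending on that average with lexicographic tie-breaks.
On the synthetic panel (median over 10 seeds at σ = 0.5) every SVM
combination scores at or below its QUA twin and MDS_OLJAR_SVM sits
below the 14-combo median, the method's two robust ordinal claims; the
absolute per-combo error values depend on σ and are not meaningful
beyond a given generator setting.

Segment validation uses agglomerative Ward clustering on Euclidean
distances of the flattened vectors; the cluster count is chosen by
maximizing the mean silhouette over k ∈ [2, min(8, n−1)] — an
algorithmic, testable replacement for visual dendrogram inspection.

## Numerical choices and degenerate inputs

- PCA/IPM sign convention: largest-|loading| entry of each component
  positive; duplicates map to identical coordinates.
- SMACOF: tolerance 1e−9 relative stress decrease, cap 300 iterations.
- Zero-variance inputs, all-identical vectors, < 3 consumers, < 3
  products (IPM), < 6 points or collinear coordinates (QUA) raise
  typed domain errors rather than returning garbage.
- Rank-deficient designs are reported with the deficiency named.
- Identical consumer vectors in clustering return a single cluster.
- All orderings (consumers, products, measures, vector columns) are
  lexicographic, so every matrix and every run is bit-reproducible.

## Problem sizes

Default analyses operate on the 100-consumer, 5-product, 6-measure
panel (3 000 cells, d = 30); the benchmark suite uses 10 simulation
draws and the clustering validation 20, with 200 × 200 evaluation
grids.  These sizes were chosen to match the designed study and keep a
full benchmark under a minute on a laptop core.

## Known limitations

- Product points cannot be shown on PCA/MDS consumer maps (only the
  IPM view places products); this is inherent to embedding consumers
  rather than products.
- The percentage error is a training-fit measure; model comparison by
  it rewards flexibility and should not be read as predictive skill.
- Scott's h = n^(−1/6) ignores the coordinate spread; maps with very
  large or very small coordinate scales over- or under-smooth.
- External (real-panel) CSVs may code JAR as 1–5; the reader flag
  `jar_coded_1_to_5` recenters, but the choice must be supplied by the
  user — it cannot be inferred reliably from data.
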