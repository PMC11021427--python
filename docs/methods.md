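# Methods

## Scope and design

`habscape` implements an integrated landscape-ecology workflow: synthetic
land-cover generation, land-change estimation and projection, an
InVEST-style habitat-quality (HQ) model, landscape-pattern metrics, and
the tile-level correlation between HQ and pattern. Real classified
imagery is deliberately out of scope; the synthetic generator stands in
for it so that every downstream stage has a fully specified, seeded
input and every claim the test suite makes is checkable.

## Habitat-quality model

Degradation at cell *x* with land-cover class *j* is

D_x = Σ_r Σ_y (w_r / Σ_r w_r) · r_y · i(d_xy) · β_x · S_jr

where *r* indexes threat factors, *y* their presence cells (binary
rasters, r_y ∈ {0,1}), β_x is an optional accessibility raster
(default 1), S_jr the class sensitivity, and i(d) the decay kernel.
Distances are Euclidean between cell centres in metres.

- **Decay kernels.** Linear: i = 1 − d/d_rmax. Exponential:
  i = exp(−2.99·d/d_rmax). Both are clamped to 0 beyond d_rmax: the
  exponential alone never reaches zero, and d_rmax is specified as a
  *maximum effective* distance, so influence past it is cut. The
  clamp's largest discarded value is exp(−2.99) ≈ 0.05.
- **Evaluation.** The inner sum over threat cells is a convolution of
  the binary threat raster with the kernel, computed by FFT
  (`scipy.signal.fftconvolve`). This is algebraically identical to the
  double sum; the tests compare it to a literal quadruple-loop
  implementation on seeded fixtures and require 1e-6 relative
  agreement (observed: ~1e-15).
- **Border convention.** No padding: threats outside the raster do not
  exist, so degradation near the border is underestimated — the
  standard clipped-watershed caveat of regional applications.
- **Quality transform.** Q = H_j(1 − D^z/(D^z + K^z)). The exponent
  z defaults to 2.5 (the conventional InVEST scaling) and the
  half-saturation constant K defaults to "auto" = half the maximum
  observed degradation, the usual recommendation when no calibration
  target exists; both are exposed as parameters. With "auto" K in a
  multi-date scenario, the pipeline resolves a single K from the
  pooled maximum over all dates so that quality is comparable across
  dates; a per-date K would rescale each map to its own threat load.
  On a degradation-free landscape K falls back to 0.5 and Q = H.
- **Parameter tables.** The shipped defaults cover seven threats
  (agriculture 8 km/0.82/linear, grazing 6/0.72/linear, urban
  8/0.31/exponential, rural 8/0.51/exponential, mining
  10/0.69/exponential, main roads 7/0.50/linear, minor roads
  5/0.50/linear) and a seven-class sensitivity table in which forest
  and good rangeland are full habitat (H = 1), fair/poor rangeland and
  water are partial (0.8/0.6/0.5), agriculture is marginal (0.2) and
  built-up is non-habitat (0). Users can override either with a CSV of
  the same schema.
- **Classification.** Six levels: exactly 0 → "No habitat"; then
  half-open bands (0, 0.2] Poor, (0.2, 0.4] Relatively poor,
  (0.4, 0.6] Moderate, (0.6, 0.8] Relatively good, (0.8, 1] Good.

## Land change

- **Estimation.** Transition counts are the cross-tabulation of two
  dated maps over jointly valid cells; probabilities are row-normalized
  counts. A class absent at the first date receives an identity row
  (persistence by convention) rather than NaN.
- **Projection.** Demand is the composition times the n-th matrix
  power; one 30-year step projects the third date from the
  second (matrix annualization by roots is ill-posed for general
  stochastic matrices and is not attempted).
- **Allocation.** Neural transition-potential modelling is replaced by
  a deterministic, seeded stand-in: per donor class, integer transition
  targets come from largest-remainder rounding of expected counts (so
  the achieved composition matches demand to within one cell per
  transition); the cells that convert are those ranked highest by the
  transition's suitability surface (min–max-normalized weighted linear
  combination of covariates; uniform by default, ties broken by a
  seeded shuffle). Infeasible demand converts all available donors.
- **Driver screening.** Continuous covariates are decile-binned and
  crosstabbed against the binary change mask; Cramer's V above 0.15
  flags a driver as influential. The decile rule is our determinism
  choice; no continuity correction is applied to the chi-square.
- **Map agreement.** Overall accuracy (trace/total) and Cohen's kappa
  ((P0 − Pe)/(1 − Pe)); kappa is signalled as undefined when chance
  agreement is 1.

## Landscape metrics

FRAGSTATS default conventions, both exposed as arguments: patches are
8-connected same-class components (nodata splits patches); contagion
adjacencies are 4-connected cell pairs counted once in each direction,
with pairs touching nodata excluded. PD is NP per 100 ha of valid
area. SHDI is −Σ P_i ln P_i in nats. CONTAG is
100·[1 + Σ_ik p_ik ln p_ik / (2 ln m)] with p_ik = P_i·g_ik/Σ_k g_ik
over the m classes present, and is undefined (NaN, by design not 100)
when m = 1.

A property worth noting: with the row marginals of p_ik fixed at the
class proportions, the entropy term is bounded below by −Σ P_i ln P_i,
so at equal proportions *both* a checkerboard and perfectly aggregated
half-planes sit at CONTAG = 50; values near 100 require a single
dominant class as well as aggregation. CONTAG therefore confounds
composition with configuration, which is exactly why the correlation
analysis pairs it with SHDI and NP.

## Synthetic landscapes

The generator emulates the statistical structure the analysis needs,
not real geomorphology:

- **Land cover.** Seeded white noise smoothed with a Gaussian kernel
  (sigma = `clumping`, in cells), classes assigned by rank-order
  quantile slices, which matches target class proportions to within one
  cell. `clumping = 0` gives spatially independent cells; larger values
  give larger patches. An optional second value turns the field into a
  west-to-east fragmentation gradient (linear blend of two smoothed
  fields, each standardized first).
- **Default composition** (first date): forest 0.14, rangeland
  good/fair/poor 0.28/0.22/0.18, water 0.02, agriculture 0.12,
  built-up 0.04 — habitat classes ≈ 82% of the area, the regime the
  default transition rows then erode by roughly a quarter of each
  habitat class per 30-year step toward agriculture and built-up.
- **Threats.** Agriculture and grazing layers are the agriculture and
  rangeland cells themselves; built-up splits into urban (largest
  8-connected component) and rural (the rest); mines are seeded random
  cells outside water; roads are seeded random boundary-to-boundary
  polylines rasterized one cell wide.
- **Evolution.** Per-cell multinomial sampling from the transition
  row; an optional contagion bias multiplies the probability of moving
  into class c by (1 + bias · neighbor fraction in c), renormalized,
  producing aggregated rather than salt-and-pepper growth.
- **NDVI.** Rangeland cells draw from truncated Gaussians (good 0.22,
  fair 0.145, poor 0.06; sd 0.01) confined to their condition band
  (good > 0.17, fair 0.12–0.17, poor 0.01–0.12; lower bounds
  inclusive, good open above — the touching printed intervals need a
  convention, fixed here for determinism), so thresholding recovers the
  generating class; non-rangeland is NaN.

What passing tests on these landscapes do **not** show: realistic patch
geometry (quantile slicing yields banded class adjacency), terrain- or
climate-conditioned land cover, observation error in classification, or
threat persistence errors. Conclusions about the *method* (kernel
behavior, conservation, sign structure) transfer; numeric levels (mean
HQ values, metric magnitudes) do not.

## Scenario scale and the correlation analysis

Study-scale scenarios run on 128×128 grids with 500 m cells (≈64 km
across, ≈410 000 ha), so the km-scale maximum effective distances of
the threat tables remain physically meaningful relative to landscape
extent; the generator's default cell size elsewhere is 30 m, the usual
satellite-product pixel. The correlation unit is the 16×16-cell tile
(64 tiles per date, 192 pooled over three dates); tiles with undefined
CONTAG are dropped for CONTAG pairs and the remaining count reported.
Significance is reported at 0.05 with no multiple-testing correction —
four planned comparisons. Per-date and pooled-over-dates correlations
are both written; the pooled table is the headline because it spans the
fragmentation range the scenario creates.

The sign-recovery experiment runs 20 seeds of the gradient scenario and
asks only for the qualitative pattern (CONTAG positive, NP negative,
monotone mean-HQ decline); observed recovery is 20/20. Correlation
*magnitudes* on synthetic tiles are not comparable to field studies and
are not targets.

## Numerical choices and degenerate inputs

- FFT convolution output is clipped at 0 to remove negative round-off.
- Min–max normalization of a constant covariate contributes a uniform
  0.5; an all-zero-weight suitability is a uniform 0.5 surface.
- Cramer's V drops all-zero rows/columns before the chi-square;
  a constant covariate screens to V = 0.
- Zero-variance inputs to Pearson correlation return NaN markers
  rather than raising, so bulk reports survive constant columns.
- All generators and the pipeline derive per-stage seeds from the
  master seed (CRC32 of the stage name), keeping every stage
  independently reproducible; two runs with one seed produce
  byte-identical CSVs.
- Rasters are single-band GeoTIFFs (int32 or float32) written via
  tifffile with ModelPixelScale/ModelTiepoint/GDAL_NODATA tags and a
  JSON legend in ImageDescription; alignment (shape + transform) is
  enforced on every multi-raster operation.

## Known limitations

- The allocation rule is a transparent stand-in, not a calibrated
  land-change model; it reproduces demand exactly but places change by
  suitability rank only.
- Border truncation biases degradation low within one d_rmax of the
  edge (up to 16 cells at study scale).
- The livestock-grazing threat is proxied by rangeland presence; real
  grazing pressure maps would differ.
- Habitat rarity scoring and monetary valuation are intentionally
  absent.
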