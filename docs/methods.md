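# Methods

## Problem and pipeline

`cyclecover` asks whether a migratory species' habitat is represented in
protected areas (PAs) in *every* season of its annual cycle, not just
overall. The pipeline has five stages, all operating on one shared
equal-area lattice of square cells (default cell area 21.625 km²,
≈4.65-km sides):

1. **Occurrence cleaning** (`occurrences`). Presence-only records are
   filtered by a fixed rule sequence — missing coordinates, (0, 0)
   coordinates, coordinate uncertainty above 10 km, exact duplicates, then
   unparseable dates — each removal audited once, so
   raw = retained + Σ removed per species. Records are split by calendar
   month into four seasons (Dec–Feb, Mar–May, Jun–Aug, Sep–Nov; a single
   global calendar, ignoring hemisphere), snapped to grid cells and
   deduplicated per cell. "Unique occurrence records" means unique occupied
   cells, which makes the retention threshold scale-consistent. A
   species–season needs ≥30 unique cells to be modelled; a species needs
   ≥2 surviving seasons to stay in the analysis (seasonal comparison is the
   point). Whether the ≥30 rule is applied before or after per-cell
   deduplication is not forced by the method's description; it is applied
   after, and the cleaning audit makes this order visible.
2. **Niche modelling** (`enm`), described below.
3. **Protection layer** (`protection`). PA records mixing polygons and
   point-plus-reported-area entries are filtered (biosphere-reserve
   designations; proposed / not-reported / unknown statuses, both
   configurable deny-lists), points are buffered to circles of radius
   √(area/π) (64-segment polygons; area low by ~0.16%), and the dissolved
   union is rasterized to a per-cell protected fraction. A cell is
   protected iff its fraction is *strictly* greater than 0.5; the tie at
   exactly 0.5 goes to "not protected", computed at double precision. An
   exact polygon-overlay coverage mode
   (100 × area(range ∩ PA)/area(range)) backs a resolution sensitivity
   analysis.
4. **Gap scoring** (`gaps`). The representation target is 100% of the range
   for ranges under 1,000 km², 16% (the current global terrestrial PA
   share) above 250,000 km², and linear in log₁₀(area) between — continuous
   at both knots; e.g. the log-midpoint area ≈15,811 km² gets 58%. Coverage
   is the percentage of suitable cells whose protected flag is set;
   gap = target − coverage (negative when a species overshoots);
   "meets target" is the weak inequality coverage ≥ target. Gap classes are
   mutually exclusive per record (>10%, >5%, 1–5%, <1%), while the summary
   table reports the cumulative counts (>5% includes >10%) usual in gap
   tables.
5. **Country summaries** (`countries`). Countries are cell sets partitioning
   the grid. A species occurs in a country when ≥1 suitable cell falls
   there; national attainment is judged on the clipped range with the
   target recomputed from the *within-country* area (default), so a small
   national range demands a high national target. The alternative —
   applying the global-range target percentage nationally — is available
   via `target_mode="global"`; which semantics a national report should use
   is genuinely open, so both are implemented and the default documented.

## The niche model

The model is the Gibbs/maxnet formulation of MaxEnt: over the background
cells, P(cell) ∝ exp(η(x)) with η(x) = Σⱼ βⱼ fⱼ(x), fitted by minimizing

  −mean_presence(η) + log Σ_background e^η + Σⱼ λⱼ |βⱼ|,

a convex problem solved by FISTA with backtracking and adaptive restarts
(tolerance 1e-6 on the objective change, at most 10,000 iterations;
non-convergence raises with diagnostics). Penalties follow the Maxent
convention λⱼ = multiplier × s_class(j) × sdⱼ/√m (sd over background, m
presences) with base scalars L/Q/P = 1.0, H = 0.5, T = 2.0 — a coarse
analogue of Maxent's feature-class defaults, configurable. Features with
zero variance over the training background are pinned at β = 0: their
penalty vanishes and the likelihood can otherwise grow without bound along
them.

Feature classes operate on covariates min–max standardized to [0, 1] by the
training-background bounds (new values are clamped to the bounds and the
clamp count audited — clamping, not extrapolation): L identity, Q squares,
P pairwise products, H forward/reverse hinges and T step indicators at 10
equally spaced interior knots per covariate (fewer than Maxent's 50, for
desk-scale speed; configurable).

Candidate models are the cross of feature-class combinations
(L, LQ, H, LQH, LQHP, LQHPT) and regularization multipliers (0.5–4.0 in
steps of 0.5). Each candidate is scored by its mean held-out AUC
(rank-based, ties ½) over the four bins of a two-level spatial
checkerboard: fine parity on f₁×f₁ blocks, coarse parity on f₁f₂×f₁f₂
blocks (default factors (2, 2)). The four checkerboard bins *are* the CV
folds; folds with no held-out presences or background are skipped. Ties are
broken toward fewer feature classes, then larger multiplier — the smoother
model. The winner is refit on all data.

Background: up to 10,000 valid cells within a 100-km buffer of the
occurrences, drawn uniformly without replacement (seeded); species with
small buffered regions simply get fewer background points. Presence cells
are excluded from the background by default (avoids label noise in the
held-out AUC); the inclusive variant is a flag.

Continuous suitability is the cloglog transform
s(x) = 1 − exp(−exp(η(x) − H)) with H the entropy of the normalized Gibbs
distribution over background. Any strictly increasing transform gives the
same binary maps (the thresholding is rank-based, an invariant the tests
check), so downstream results do not depend on this choice.

Binarization searches the unique presence scores τ under the rule
"score ≥ τ ⇒ presence", maximizing sensitivity + specificity (max SSS),
ties to the smallest τ; the *stored* threshold is the largest observed
score strictly below the winning τ, so the conventional strict rule
"value > threshold ⇒ presence" reproduces the identical partition.

## The synthetic world

`synthworld` generates every input with known truth, on a flat Cartesian
km plane (the record columns named longitude/latitude carry plane
coordinates; all cleaning rules treat them identically — this removes
projection machinery from the test path while the planar operations remain
exactly what real-data use would apply after projecting to equal-area /
equidistant frames).

- **Climate**: per layer, iid Gaussian noise blurred with a Gaussian filter
  (σ = 6 cells), then exactly decorrelated (QR) and re-mixed through the
  Cholesky factor of the requested correlation matrix, so target pairwise
  correlations are realized in-sample; a non-positive-definite request
  errors. Default 8 layers, matching the number of retained bioclim
  covariates in real-data use.
- **Protected areas**: random circles (radius 2–6 cell sides) accumulate
  until their union covers the requested area fraction (default 0.16, the
  global terrestrial share); the final circle is shrunk by bisection so the
  realized fraction lands on target (observed error ≪ the 0.05 calibration
  bound). A 9% share of records (the point-only share of the global PA
  inventory) is stored as point + reported area; buffering reconstructs the
  same circle.
- **Countries**: Voronoi cells of seed points drawn on the lattice —
  exhaustive and disjoint by construction.
- **Species**: per-season truth suitability is the inverse logit of a
  linear predictor on named climate layers; the truth range is
  suitability > 0.5. Clean records sample cells proportionally to
  suitability, jitter uniformly within the cell, carry dates inside the
  season window and lognormal uncertainties (median 300 m, log-sd 1, capped
  below 10 km). A contamination fraction of each season's records is
  corrupted — equal shares of missing coordinates, (0, 0) coordinates,
  coarse uncertainty (10–100 km) and exact duplicates, so every cleaning
  rule is exercised — and appended after the clean rows.

What the generator does *not* emulate: real observation bias (roads,
cities, PA-biased recording), spatial clumping of effort, taxonomic error,
or non-climate drivers of distributions. Passing recovery tests therefore
show the estimator chain is correct under its own assumptions, not that
real-data inference is unbiased.

## Experiment sizes and numerical choices

The seeded experiments (`experiments`, also run by
`scripts/acceptance.py`) use a 100×100-cell world, 10 species × 2 seasons,
150 records per species–season, 5,000 background points, and a reduced
candidate grid (L and LQ × multipliers 0.5 and 2.0) — the planted niches
are logistic-linear, so linear/quadratic features span the useful model
space at a fraction of the full search cost; the full default grid is
exercised separately. The raster-vs-exact comparison uses a 64×64 world
and a 2× lattice refinement (exact subdivision, so range polygons are
identical at both resolutions). The oracle comparison for the fitted
optimum is a two-stage dense grid search (step 0.1, then 0.004 around the
coarse optimum) over the two-coefficient penalized objective.

Tie-breaks and degenerate inputs are fixed deterministically throughout:
collinearity filtering drops the member of the worst pair with the larger
mean |r| (ties by layer-name order) and may reduce to a single layer;
constant climate layers, degenerate covariates, empty ranges, empty
background regions and all-identical score sets raise immediately rather
than propagating NaNs.

## Known limitations

- The two alternatives left open above (year-round = union vs. mean of
  seasonal coverages — both are computed and reported; national targets
  from within-country vs. global range area) can change headline numbers
  on real data; defaults are documented, alternatives are flags.
- The L1 path is optimized per candidate from a cold start; warm-starting
  across multipliers would be faster but is unnecessary at these sizes.
- Point-PA buffering assumes circular sites; real site shapes are unknown
  for point records, and this is the standard convention.
- The raster coverage rule is evaluated per cell; species ranging over very
  few cells inherit the full granularity error of the >50% rule, which the
  exact-overlay mode exists to quantify.
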