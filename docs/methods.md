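# Methods

## The estimation protocol

The package implements the Cologne Protocol, a geostatistical procedure for
estimating prehistoric hunter-gatherer population size and density from
archaeological site distributions. The study window (the *Total Area of
Calculation*, TAC) is partitioned into zones of high activity — *Core
Areas* — and zones of little or no activity. The procedure has four stages:

1. **Largest-Empty-Circle (LEC) field.** For a point pattern of sites, every
   Voronoi vertex carries the radius of the largest circle centred there that
   contains no site. This radius is an inverse density measure: small radii
   mean dense occupation. Samples are also taken where Voronoi edges cross
   the window boundary, and at the window vertices themselves, so that
   coastal/edge density is measured rather than extrapolated (a constrained
   LEC centre can only be a Voronoi vertex, an edge–boundary crossing, or a
   window corner).
2. **Interpolation.** The scattered LEC radii are interpolated to a regular
   grid by inverse-distance weighting with power 2. IDW was chosen over
   kriging because it is deterministic, parameter-light and exactly
   reproducible; the interpolator is a pluggable stage, so a kriging variant
   can be substituted without touching the rest of the pipeline. A grid cell
   centre coinciding with a sample takes the sample value exactly. Values
   are extrapolated one cell ring beyond the window so that isopleths cross
   the boundary smoothly before being clipped back to it.
3. **Isopleths and the optimally describing isoline (ODI).** For an
   ascending ladder of radius levels, the sub-level set {interpolated radius
   ≤ L} is polygonised by marching squares (linear cell-edge interpolation)
   and clipped to the window; its area (km²) and the fraction of sites it
   contains ("capture") form the areal-increase curve. The ODI is selected
   from that curve (below), and its interior is the Core Area. The level
   ladder defaults to 1-km steps up to the 95th percentile of sample radii.
4. **Demography.** For a region with Core-Area size `A` km² and raw-material
   catchment quartiles `Q1 ≤ Q2 ≤ Q3`,

       N_groups(q) = A / q
       N_people(q) = N_groups(q) × group size   (42.5 persons per group)
       D(q)        = N_people(q) / A            (persons/km²)

   `Q2` gives the mean estimate, `Q1`/`Q3` the maximum/minimum bracket
   (smaller catchments ⇒ more, larger ⇒ fewer groups). The TAC density
   divides total people by the full window area (2.6 M km² in the
   reproduction fixture).

## The ODI selection rule

The protocol's descriptive rule — "the first peak or plateau of areal
increase that still encircles about 70% or more of all sites" — needs a
numeric criterion. This package uses a *stall* test on the increment
sequence `ΔA(L)`: level `L_i` is a candidate when the next increment does
not exceed the current one by more than `plateau_tol` (default 0.10,
relative), i.e. the areal-increase curve has locally peaked or flattened.
The ODI is the smallest candidate whose capture is at least `min_capture`
(default 0.70). If the increments are still rising wherever capture is
sufficient, the smallest level reaching the capture threshold is returned
and flagged `fallback`; if capture never reaches the threshold, selection
fails with an error.

Two alternative operationalisations were evaluated on simulated clustered
patterns and rejected:

- *Plateau relative to the global maximum increment.* Whenever a large late
  increment exists (the sub-level set expanding into near-empty background),
  almost every low level counts as a plateau and selection collapses onto
  the bare capture threshold, systematically under-delineating clusters.
- *Prominence thresholds / smoothing filters on the increments.* These
  either skip the genuine cluster peak (when the global maximum lies in the
  late background expansion) or do not improve recovery.

A consequence worth noting: on a homogeneous Poisson pattern (no density
structure at all) the rule selects a genuine stall past the capture
threshold rather than flagging a fallback — the resulting "Core Area" is
non-informative, enclosing roughly half the window. Tests assert exactly
that signature.

Whether a site lying exactly on the isoline counts as captured is not
decidable from the published material; this package counts it as inside.

## Raw-material catchments (RMCA)

An RMCA is the convex hull of a 5-km-radius buffer around the site
(discretised at 360 vertices; area error < 0.005% of the true disc) and the
site's raw-material source locations. Before hull construction, raw-material
records representing less than 1% of an assemblage, or documented by single
pieces, are removed. Catchments with only one distinct source-to-site
distance (distances compared at 1 m resolution, so one source and several
equidistant sources are treated alike) or smaller than 500 km² are excluded,
in that order of precedence; every catchment ends up in exactly one status
class. Quartiles of the kept catchment sizes are taken per region *block*
(groups of estimate regions sharing one quartile set — the adjacency
transfer used where some Core Areas lack raw-material data), using
sorted-order linear interpolation. The quartile estimator is deliberately
explicit because the choice materially changes Q1/Q3 for small samples and
the original estimator is not documented; this is a known reproduction
limit.

Records attributed generically to both phases contribute to both phase
selections; records from sites attributed only generically contribute to no
phase-specific quartile.

## Rounding and the table fixture

Display rounding is half-up throughout: groups to 1 decimal, people to the
nearest integer of the *unrounded* groups × 42.5, densities to 3 decimals.
Totals are computed from unrounded row values and rounded once — this is
what makes the warm-phase mean total 8126 rather than the 8128 obtained by
summing pre-rounded cells. Headline prose totals round people to the
nearest hundred.

The packaged fixture carries the printed per-region inputs (ODI areas,
quartiles) and the printed derived cells. Because the printed quartiles are
whole km², each carries ±0.5 km² print precision; the reproduction diff
accepts a printed cell when it is attainable under that input uncertainty.
This resolves five cells that sit within one rounding ulp of the printed
value (one warm-phase Q1 group/people pair whose unrounded value lies
5 × 10⁻⁵ below a rounding tie, three cold-phase Q1 people cells, and the
cold-phase Q3 people sum). Two italic whole-window Q1/Q3 densities printed
in the warm-phase table are internally inconsistent with their own
numerators (14 262 / 2.6 M = 0.005485 → 0.005, printed 0.006; 4 839 / 2.6 M
= 0.001861 → 0.002, printed 0.001); no input-precision perturbation can
bridge them, so they are excluded from the diff and recorded here.

## Synthetic data

The generator draws site patterns from a Thomas process: Poisson parents
(or fixed parent locations for controlled experiments), Poisson(μ)
offspring per parent displaced by an isotropic Gaussian of spread σ, plus a
homogeneous Poisson background, all clipped to the window. Ground truth for
recovery experiments is the disc of radius 3σ per parent (≈99% of offspring
mass). Attribution flags are drawn i.i.d. per record from a configurable
mix; there is no temporal or spatial autocorrelation in the attributions.
Raw-material assemblages receive 1–k sources at exponential-tailed distances
with Dirichlet share percentages; a configurable fraction of assemblages
gets one forced sub-1% trace material, and a configurable fraction of
sources is flagged as single pieces, to exercise the share filter.

What the generator does *not* emulate: taphonomic loss, survey and research
bias, coastline geometry, non-Gaussian cluster shapes, and spatially
correlated chronological attribution. Passing recovery tests therefore
show that the pipeline recovers clean clustered structure at realistic
densities, not that it reproduces the published maps.

### Recovery experiment

The standing recovery experiment places two cluster parents 283 km apart in
a 500 × 500 km window: μ = 120 offspring, σ = 15 km, background
3 × 10⁻⁴ sites/km² (peak cluster intensity ≈ 280 × background; ~85% of
sites belong to clusters), analysed with a 5-km grid cell and 1-km level
ladder. Across 100 pilot replicates the Core Areas matched the truth discs
with Jaccard ≥ 0.5 in 93% of runs (median ≈ 0.7); the acceptance test
requires ≥ 80% of 20 seeded replicates. The whole experiment runs in a few
seconds.

## Numerical choices and degenerate inputs

- Coordinates are metres in one equal-area projection; all areas are true
  km². No reprojection happens inside the package.
- Fewer than three distinct sites, or a collinear site set, in any
  calibration region is a hard error naming the region.
- Exact duplicate coordinates are kept in tables but deduplicated before
  the Voronoi stage; the count is reported.
- Isopleth levels must ascend; a level tie at a constant field is broken
  toward inclusion (a site or cell exactly at the level is inside).
- Default grid cell is 10 km for continental-scale windows (the fixture's
  2.6 M km²), 5 km in the synthetic experiments; halving the cell changes
  smooth-field isopleth areas by well under 5%.
- Rounding ties are half-up (away from zero), matching every printed cell
  checked.

## Known limitations

- The published Core-Area maps, per-region ODI levels and RMCA filter
  yields (53/108 and 39/97) depend on the study's site database and
  supplementary catchment tables and are not reproducible from the printed
  material; the property-based tests above stand in for them.
- The original interpolation method and level ladder are not documented;
  results on real data may differ from any re-implementation even with
  identical inputs.
- Quartile estimation for n < ~10 catchments is estimator-sensitive (see
  above).
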