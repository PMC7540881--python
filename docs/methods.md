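# Methods

This note documents the models, the numerical conventions, the synthetic
world the tests run on, and the design decisions taken where several
reasonable choices existed. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The niche model and its assumptions

A language group's eco-linguistic niche (ELN) is treated exactly like a
species niche in presence-only distribution modelling: village localities
inside the group's territory are presences; no absences exist; the model
must score every grid cell of the accessible area M in [0, 1]. The central
assumption is that the environmental conditions at occupied villages are a
sample from the conditions the group can occupy — occupied territory is
taken as an estimate of the (realized) niche, and the model's geographic
projection may legitimately extend beyond the territory.

### Algorithms

Three deterministic algorithm families stand behind one `fit`/`predict`
interface:

* **bioclim** — the classic climate envelope. Suitability 1.0 where every
  variable lies within mean ± `sd_cutoff`·sd of the training values, 0.5
  within the training min–max envelope, 0.0 outside. Default
  `sd_cutoff = 0.674` (the central-half envelope of a normal variable).
* **envelope_score** — the fraction of variables whose value lies within
  the training min–max range; a graded envelope.
* **env_distance** — variables rescaled to [0, 1] by their study-area
  range; suitability decays linearly from 1 at distance 0 to 0 at
  `max_distance_fraction` × the metric's maximum distance. Metrics:
  euclidean (max √p), gower = mean absolute difference (max 1), chebyshev =
  max absolute difference (max 1), and Mahalanobis with the training
  covariance (ridge-regularized by 1e-6·trace/p when singular). Mahalanobis
  has no finite theoretical maximum in normalized space, so its reference
  maximum is the largest observed distance over the study-area cells —
  data-driven but deterministic. `n_nearest_points` selects the reference
  point: the mean of the n nearest training points, with `0` meaning the
  training centroid and the default `1` the single nearest occurrence.

Determinism is a feature, not a simplification of convenience: the
consensus machinery only needs several independent [0, 1] predictions with
evaluation scores, and exact algorithms make every downstream contract
testable to machine precision.

### The default ensemble

The default six-member ensemble uses environmental distance to the
**training centroid** (`n_nearest_points = 0`) under euclidean and gower
metrics at two decay scales, chebyshev, and Mahalanobis. The envelope
algorithms are deliberately not in the default ensemble: any model that is
an exact interpolator of its training set (bioclim and envelope_score score
every training occurrence at their maximum; nearest-occurrence distance
gives them distance 0) makes the occurrence-score distribution degenerate
at the top of the scale, and the fixed-sensitivity omission threshold —
an order statistic of exactly those scores — then cuts deep into the niche
instead of trimming its margin. Centroid-distance models give occurrences
the same score distribution as the surrounding niche cells, which is the
exchangeability the threshold rule implicitly assumes. Both envelope
algorithms remain fully implemented, unit-tested and available through
`AlgorithmConfig`.

### Evaluation and consensus

Presence-only models are scored against `10 × n_presence` random background
cells (capped at 10,000), excluding presence cells. Statistics: overall
accuracy at a threshold (default 0.5), rank-based AUC (ties count ½), and
the bootstrap partial-ROC ratio — the mean over 100 bootstraps (each
resampling 50 % of the presences with replacement) of the model's partial
AUC over the region with sensitivity ≥ 1 − E (E = 0.10), divided by the
area under the diagonal over the same span; the ROC curve is interpolated
linearly to the exact sensitivity bound.

The weighted elitist consensus ranks models by AUC on a held-out occurrence
split (default split fraction 0.5; ties broken by partial-ROC ratio, then
model id), keeps the top half (rounded up), weights them proportionally to
their AUC (or equally), and adds the weighted maps. The models entering the
consensus are refitted on all occurrences — evaluate-on-split,
calibrate-on-everything, as ensemble SDM platforms commonly do.

The omission threshold τ is the (k+1)-th smallest consensus suitability at
the training occurrences with k = ⌊s·n⌋ (default sensitivity s = 0.10), an
exact order statistic with no interpolation, so at most a fraction s of
occurrences fall strictly below τ; cells below τ are set to zero.

## Ecological space, overlap, patterns

The PCA standardizes each variable to zero mean and unit variance over all
valid study-area cells (a correlation-matrix PCA — the 26 variables mix
°C, mm, m, degrees and codes) and is fitted once on the full environment;
niches are *projected* into this common space as the cells with
suitability > 0.9. The sign convention makes the largest-magnitude loading
of each component positive. The inertia ellipse scales the sample
covariance of a score cloud by the χ²(2 df) quantile at the coverage level
(default 0.61), so it contains about that fraction of a Gaussian cloud.

Overlap statistics normalize the two suitability surfaces to probability
distributions over the shared valid cells: D = 1 − ½ Σ|p̂₁ − p̂₂|,
I = 1 − ½ Σ(√p̂₁ − √p̂₂)². Both are invariant to positive rescaling of a
map. I ≥ D is *not* asserted anywhere — it is not a theorem. Clustering is
complete linkage on Euclidean distances between the rows of the 1 − D
matrix (scipy's implementation; merge heights are monotone).

Patterns (ELPs) are formalized as connected components of the graph joining
group pairs with geographic Jaccard ≥ `g_min` (default 0.4) **and**
Schoener's D ≥ `d_min` (default 0.6). The published analysis identified
patterns by expert inspection; a reproducible pipeline needs an explicit
rule, and thresholded graph components are the simplest one consistent with
"high geographical overlap and high paired overlap scores". Components are
transitive closures: a chain A–B, B–C joins A and C even if A–C is weak.
Raising either threshold can only refine the partition. Accessibility
filtering keeps the 8-connected range components that intersect the group's
territory, plus — for maritime (Austronesian) families — components
touching sea cells.

## Potentials, growing season, risk

The family potential is the cellwise arithmetic mean over *all* of a
family's niches (the divisor is the family's total group count, so a group
finding a cell unsuitable pulls the mean down); ΔELN is the TNG mean minus
the Austronesian mean, bounded in [−1, 1] and antisymmetric under swapping
the families. The growing season counts months with mean temperature
strictly above 6 °C and precipitation strictly above twice the temperature,
evaluated multiplicatively (`prec > 2·tmean`) so freezing months need no
division; monthly mean temperature defaults to (tmin + tmax)/2 when true
monthly means are absent. Ecological risk is 1 / (mean GS over the region),
flagged undefined where the mean is zero.

## Numerical conventions

* Grids are north-up geographic lon/lat; rows run north → south; all
  sampling uses cell centers. On-disk rasters are ESRI ASCII grids written
  with 17 significant digits, so float64 values round-trip bit-exactly.
* Bioclim quarters are any 3 consecutive months and wrap across the year
  boundary; quarter ties take the lowest starting month. bio4/bio15 use
  the sample (ddof = 1) standard deviation, as in dismo::biovars; bio3 is
  defined 0 where the annual range is 0, bio15 is 0 where mean monthly
  precipitation is 0.
* Terrain: Horn 8-neighbour finite differences; aspect is the azimuth of
  steepest descent, clockwise from north, 0 for flat cells; flow direction
  uses ESRI D8 codes with diagonal drops divided by √2 and 0 for pits;
  border cells and windows touching nodata are masked. All derivatives are
  invariant under adding a constant to the DEM.
* Boundary points of territory polygons count as inside; a point claimed by
  several polygons goes to the smallest by area (a deterministic tie rule).
* One global seed drives everything; per-stage seeds are derived from it by
  hashing the stage name, so stages are independently reproducible.

## The synthetic world

The generator produces a New-Guinea-like island at 200 × 200 cells
(0.05° ≈ 5 km cells; the real analysis used 30 arc-second grids — the
resolution is configurable and the default keeps the full pipeline within
seconds) with eight groups in five planted strata: three groups sharing a
highland stratum, two sharing a mid-elevation stratum, and three coastal
singletons (one warm-foothill TNG group and the Austronesian wet- and
dry-coast groups).

What it emulates, and why these features matter:

* **Stepped hypsometry.** The island is a massif of four plateaus
  (coastal plain, foothill, montane, highland at ~4 °C spacing in annual
  mean temperature) joined by short steep scarps, with scarp positions at
  fixed quantiles of the land hypsometry so plateau areas are stable across
  seeds, plus an unassigned alpine summit belt. Real large tropical islands
  have exactly this intermontane-plateau structure, and discrete eco-zones
  with narrow transitions are what makes "a group's niche" a meaningful,
  recoverable object; a purely continuous elevation gradient leaves every
  niche with a broad halo of partially-suitable transition cells that no
  presence-only method can delimit.
* **Climate from smooth elevation.** Temperature lapses at 6.5 °C/km off
  the smooth (plateau) elevation with a weak latitudinal trend and ~1.3 °C
  seasonal amplitude; the DEM itself carries additional fine-scale
  ruggedness. This mirrors interpolated climate products, which follow
  broad station-calibrated elevation rather than fine terrain, and it keeps
  aspect and the other terrain derivatives locally mixed instead of
  flank-coherent.
* **A windward/leeward rain shadow.** The coastal plain is wet north of
  the divide and dry south of it with a sharp transition, giving coastal
  precipitation a bimodal distribution; the wet/dry strata are split at the
  gap between the modes. Upland precipitation keeps only a mild gradient.
* **Interleaved territories.** Groups sharing a stratum receive interleaved
  longitude stripes of it, so each territory samples the stratum's full
  environmental breadth — the defining property of a multi-group pattern is
  that its groups are environmentally exchangeable.
* **Geographically sampled villages.** Villages are uniform in territory
  area, not in environmental space, so occurrence sampling carries the same
  spatial bias as real gazetteers. Climate noise is smooth at a ~5-cell
  length scale with small amplitudes (0.1 °C temperature, a few mm
  precipitation), the texture every territory samples.

What it does **not** emulate: interpolation artefacts and station-density
gradients of real climate surfaces; digitization error and enclaves in
territory polygons; population-density bias in gazetteers; coastline
complexity and offshore islands beyond what the noise field produces; any
historical process (expansion, contact, language shift). Passing the
recovery tests therefore shows the pipeline is *correct and internally
consistent* — that it recovers niches and patterns where clean ground truth
exists — not that its inferences on real, messier geodata would be as
accurate.

## Known limitations

* Presence-only evaluation against random background caps AUC at roughly
  1 − prevalence/2; groups whose niches cover large fractions of the study
  area are structurally limited to modest AUC regardless of model quality.
* The deterministic algorithm family cannot learn variable relevance from
  presence/background contrast the way regression or machine-learning SDMs
  do; with many uninformative variables its distances dilute, which is the
  main accuracy cost of exact testability.
* Pattern identification depends on the two thresholds `g_min`, `d_min`;
  both are reported in every output and configurable, but no automatic
  selection is attempted.
* The growing-season rule uses monthly climatologies; it cannot express
  within-month variability or drought spells.
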