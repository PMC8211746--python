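# Methods

## Expected phylogenetic diversity

All scores derive from one quantity.  Let a rooted tree have branches
`b` with lengths `L_b` (Ma) and descendant leaf sets `S_b`, and let
`p_i ∈ [0,1]` be the probability that species `i` is extinct at the end
of the horizon, with extinctions independent across species.  A branch's
history survives iff at least one descendant survives, so

    expPD(p) = Σ_b L_b (1 − Π_{i∈S_b} p_i).

The species scores are single-coordinate finite differences of `expPD`:
HEDGE sets `p_i → 0` (securing), LEDGE sets `p_i → 1` (loss).  Both
collapse to closed per-branch forms —
`HEDGE_i = Σ_{b∋i} L_b Π_{j∈S_b} p_j` and
`LEDGE_i = Σ_{b∋i} L_b (1−p_i) Π_{j∈S_b, j≠i} p_j` —
which the implementation uses, but the contract is the two-evaluation
definition and the test suite enforces their equality to 1e−10 Ma on
random trees, alongside a brute-force oracle that enumerates all `2^n`
survival outcomes on tiny trees.  The cell scores GexpPD and LexpPD are
the same differences applied to all species present in a grid cell at
once; GexpPD likewise reduces to a per-branch sum over branches with at
least one descendant in the cell, while LexpPD needs the in-cell /
out-of-cell product split and is evaluated cell-by-cell over occupied
cells.

Products `Π p_j` are computed as exponentials of sparse-matrix log-sums
with an explicit zero count per branch, so `p = 0` and `p = 1` are exact
rather than epsilon-approximated; the no-extinction and
certain-extinction limits (`expPD = total PD`, `expPD = 0`) hold to
machine equality.

## PD convention

PD is rooted: the PD of a leaf subset is the summed length of all
branches on its paths to the root of the full tree, and a root edge
above the basal split is ignored.  This makes single-species PD the
species' root-path length, makes fair-proportion ED sum exactly to total
PD, and matches the behaviour of the standard community-PD tooling the
spatial scores are benchmarked against conceptually.  Polytomies are
accepted as-is and zero-length branches are allowed.

## Extinction probabilities and Red List handling

The default category → probability map, `IUCN50` (LC 0.0009, NT 0.0071,
VU 0.0513, EN 0.4276, CR 0.9688 over 50 years), is the standard
projection of the Red List criteria thresholds to a common 50-year
horizon.  It ships as a named, editable configuration entry: any
strictly increasing LC→CR table is accepted, because every expected-PD
statistic is conditional on this choice.

Data-deficient species must be imputed before scoring.  The default rule
is quantile matching on log range size: the non-DD species define a
log-range distribution and a category composition; a DD species at
range-size quantile `u` receives the category occupying quantile `u` of
the composition ordered CR → LC (small range ⇒ severe category).  This
encodes only the documented range-size dependence of threat, is
idempotent, and is pluggable (`impute_dd(table, rule=...)`).  Extinct /
Extinct-in-the-Wild categories are input errors: the analysis concerns
extant species.

## Reference grid

The grid is a cylindrical equal-area (Behrmann, standard parallels
30°N/S) raster computed on the WGS84 ellipsoid with Snyder's authalic
`q` function.  Column count rounds the world width at the standard
parallel divided by the cell size; row count rounds the projected height
of the latitude band.  With 96.5 km cells between 90°N and 60°S this
gives 360 × 142 = 51,120 cells, the dimensions of the distributed mammal
range rasters; the ellipsoidal width (34,735 km → 359.95 cells) is what
forces 360 columns — a spherical (authalic-radius) width of 34,667 km
would round to 359.  Cells are exact `cell_size²` squares in the
projected plane, ids row-major from the north-west corner.

## Spatial scores

The presence matrix is sparse boolean (cells × species).  Richness-type
scores are single sparse mat-vecs.  The phylogeny-based scores use a
cells × branches incidence built by one sparse product (a branch is in a
cell iff any descendant is), from which PD-type scores, phylogenetic
endemism (PWR: each branch's length divided by its occupied-cell count)
and GexpPD are again mat-vecs.  Two conservation identities are enforced
in tests at study scale (1,000 species on the full 51,120-cell grid):
Σ_cells SWR equals the number of occurring species, and Σ_cells PWR
equals the total PD of occurring branches.

Conventions: "rare" means range size strictly below the median range
size over all species (mid-point median for even counts); proportion
maps mask cells with zero denominator rather than scoring them 0;
hotspots are the `floor(0.025 × n_defined)` highest cells with ties
broken by (value descending, cell id ascending) and a warning when the
cut splits a tie block; the TOP-species rule is the same floor-and-
deterministic-ties rule at fraction 0.25.  Medians over even-sized tree
ensembles are the mean of the two central values.  EDGE is applied once
to the median ED (the GE weight is tree-independent); HEDGE/LEDGE and
all phylogeny-based cell scores are computed per tree and
median-aggregated.

## Protected-area processing

Records are filtered before geometry work: status "Not Reported" or
"Proposed", designation "UNESCO-MAB Biosphere Reserve", and points
without a reported area are excluded; points with a reported area are
replaced by a circle of exactly that area drawn in the equal-area plane
(radius `√(A/π)`, 64 segments per quadrant ⇒ area error ≈ 0.01%, within
the 0.5% tolerance the areal approximation is held to).  Invalid
polygons are repaired (`make_valid`, then zero-width buffer; an
unrepairable geometry raises naming the record), everything is dissolved
into one union so overlapping designations are not double-counted, and
per-cell coverage is the intersection area over the cell area, in
percent.  Because cells are equal-area, the overall protected percent of
a hotspot set is the unweighted mean of its cell coverages.  The
three-way classification uses 0% = "not protected" and ≥50% = "heavily
protected" by default; the 50% cut is a parameter, as no canonical value
exists.

## Synthetic inputs

The generators emulate the statistical structure the analysis assumes,
not mammal biogeography:

* **Trees**: pure-birth (Yule) ensembles at rate 1/Ma, conditioned on
  the tip count — the simplest ultrametric model that exercises every
  score; tested against the closed-form expected depth Σ_{k=2..n} 1/k.
  Real posterior samples share topology information across trees;
  independent Yule draws do not, which makes the robustness analysis
  conservative.
* **Statuses**: i.i.d. draws from a configurable composition, default
  LC .56 / NT .07 / VU .09 / EN .08 / CR .05 / DD .15, the approximate
  Red List composition of extant mammals including its ~14% DD fraction.
* **Ranges**: spreading-dye growth (uniform frontier sampling,
  4-connectivity, no wrap-around) to a log-normal target size, default
  median 20 cells and log-sd 1.5 — contiguous, heavy-tailed ranges of
  the kind gridded range maps exhibit.  No cohesion between phylogeny
  and geography is simulated, so spatial phylogenetic clustering in real
  data is *not* represented; tests passing here show the machinery is
  correct, not that real mammal hotspots would look alike.
* **Protection**: sums of random rectangular blobs with exponential side
  lengths, rescaled (multiplicatively, with an additive floor-lift if
  clipping at 100% makes the rescaling stall) until the global mean is
  within ±2 points of the target, default 15% — the order of the
  terrestrial protected fraction.

All generators are pure functions of (config, seed); the pipeline's
outputs are byte-reproducible, which the suite asserts file-by-file.

## Problem sizes

The shipped analysis drivers use 500 species, 25 trees (10 for the
cell-score stage) and the full 51,120-cell grid — sizes chosen so each
driver completes in seconds while every code path, including the full
grid, is exercised; the species count scales linearly and the method has
no parameter that changes behaviour with n.  Oracle-based tests use
trees of ≤ 12 leaves where two-evaluation checks are cheap, and ≤ 6
leaves where the 2^n enumeration oracle is used.

## Known limitations

* Extinctions are independent across species; correlated threats (shared
  drivers within regions or clades) would change expected PD and are out
  of scope of the `expPD` model itself.
* Priorities are marginal (per species / per cell), not complementary:
  the scores value each unit in isolation and do not seek the optimum
  *set* that jointly maximises expected PD.
* The DD imputation rule is an approximation driven by range size alone.
* Coverage overlay works on the rasterised percent-protected field;
  sub-cell protection quality, connectivity and management categories
  are not modelled.
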