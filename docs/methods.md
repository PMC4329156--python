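# Methods

## Scope and units

`buffercost` evaluates riparian buffer-zone allocations for phosphorus
mitigation at sub-catchment resolution. It takes baseline P transports
as inputs — it does not re-derive them from leaching simulations — and
covers everything downstream: eligibility delineation, reduction
accounting, annualized costs, scenario comparison, and cost-optimal
targeting. Units are fixed package-wide: areas ha, lengths m, costs
€ yr⁻¹, transports kg P yr⁻¹; conversions happen only in the readers.

## Reduction model

A buffer of width *w* (one of 2, 6, 10, 15, 20 m) on land of slope
class *s* intercepts a fixed fraction *f(s, w)* of the no-buffer
baseline P transport of its impact area. The default fraction table
(packaged as `data/reduction_table.csv`) spans 0.13 (gentlest slope,
2 m) to 0.72 (steepest slope, 20 m) and is strictly increasing in both
arguments; it derives from leaching-model estimates parameterized for
one crop type and one climate region, so it is a replaceable input, not
a constant of the package.

Assumptions worth making explicit:

* **Linearity.** Reduction is proportional to the baseline transport of
  the impact area. This makes existing-buffer removal an exact inverse
  (`baseline = observed / (1 − f)`) and global calibration a single
  scale factor.
* **Impact-area attribution.** The fraction applies to the transport of
  the buffer's impact area (the strip of cropped land within the 60 m
  corridor), never to whole-sub-catchment transport.
* **Pro-rata partial enrolment.** Enrolling area *a* of the potential
  *A(w)* scales the sub-catchment's reduction by *a/A(w)* — uniform
  thinning across its impact areas. Real programs enrol whole strips;
  partial enrolment is a modelling extension and reports flag it
  implicitly through fractional areas.

The sub-catchment CSV column `baseline_p_transport_kg` holds the
*no-buffer* baseline. Callers holding transports observed behind an
existing buffer must back-correct them with `strip_existing_buffers`
before building a bundle.

## Delineation

The vector stage reproduces the national mapping procedure on planar
metric GeoJSON layers:

1. each watercourse centerline is assigned a 15 m channel width and
   dilated to its two edge lines;
2. a block qualifies against a watercourse when its boundary runs along
   the watercourse edge for ≥ 30 m; adjacency is measured by snapping
   the edge to the block boundary within 1 m and taking the 1-D
   intersection length, so flush-digitized geometry yields the exact
   shared length;
3. pasture, undefined-crop and minor-crop blocks are excluded (only
   cropped blocks are buffer-eligible);
4. the impact area is the block clipped to the centerline dilated by
   60 m. The 60 m corridor is measured from the *centerline* (the
   literal reading; 7.5 m half-channel + 50 m would give 57.5 m), and
   is configurable via `--impact-buffer`;
5. the enrollable strip at width *w* is accounted as a rectangle,
   frontage × *w* — consistent with per-hectare subsidy accounting —
   so potential area is exactly linear in width.

Geometric predicates use a 1e-6 m tolerance; polygons must be valid on
input (no repair is attempted). Degenerate inputs (zero-length
centerlines, self-intersecting polygons) raise naming the feature.

## Costs

Annual cost per hectare = regional 90th-percentile leasing price + €17
establishment/maintenance, both € ha⁻¹ yr⁻¹; the packaged schedule
covers the eight PO8 production regions (€95 … €719 totals). The 90th
percentile (linear interpolation between order statistics) rather than
the mean reflects that a buffer payment competes with continued
production: a median-level payment would compensate only half the
landowners. Everything is annual over the 5-year commitment — no
discounting. Cost efficiency (€ kg⁻¹) raises on zero reduction rather
than returning infinity.

Report rounding mirrors program-table conventions: costs to whole €,
average reduction to 2 decimals, percentage deltas to whole percent;
ties round away from zero (206.75 → 207). Unrounded values are kept
internally and exposed via `--precision full`; deltas are always
computed from unrounded totals.

## Scenarios and the allocator

* `EXISTING`: per-sub-catchment enrolled areas accounted at a nominal
  width, default 10 m (subsidy records hold areas, not widths; 10 m is
  the national load-compilation convention).
* `UNIFORM_WIDTH`: full potential area everywhere at one width.
* `COST_OPTIMAL`: greedy over whole (sub-catchment, width) options at
  full potential area, sorted by average cost (€ per kg reduced) with
  deterministic tie-breaks (ascending average cost, then descending
  reduction, then sub-catchment id, then width); options are admitted —
  at most one width per sub-catchment — until the cumulative reduction
  reaches the target, and the crossing option is taken whole. A
  `nearest` flag stops at whichever side of the target is closer.

The greedy rule is a heuristic for the underlying knapsack-like
problem. With equal per-option reductions and distinct costs it is
exactly optimal; in general it can overshoot. `exhaustive_allocation`
enumerates every whole-option assignment and is the verification oracle
for small instances (≲ 8 sub-catchments, ≤ 2 candidate widths); the
test suite compares the two routes and the CLI exposes
`--verify-exhaustive`.

Because option cost grows linearly in width while *f* grows
sublinearly, narrow widths always dominate per kg — so a greedy chain
restricted to one width per sub-catchment can stall below a target that
wider buffers could reach. The reporting layer therefore selects, for
the targeted scenario, the *narrowest single candidate width whose
full-coverage reduction meets the target*
(`narrowest_attainable_width`), which is also the cheapest attainable
single-width program. On the demo data this selects 10 m; on catchments
where 6 m full coverage exceeds the existing program's reduction it
selects 6 m.

## Synthetic catchment generator

`synthetic.generate` emulates the structure of the Svärta River
catchment, the demo system: 13 sub-catchments in region "Svealands
slättbygder", soil-P class split 11 high / 1 mid / 1 low, slope class
split 11 steep / 2 middle / 0 gentle, 9 000 ha agricultural land with
7 500 ha cropped. Defaults chosen once as study conditions:

* total eligible frontage 183 333.3 m, so the full 6 m potential area
  is exactly 110 ha (the reported uniform-program area);
* 162 ha of existing 10 m buffers spread pro rata by frontage (the real
  2008 distribution is unpublished; an explicit allocation CSV can
  override);
* per-sub-catchment frontages drawn U(8 000, 22 000) m then rescaled to
  the fixed total; impact-strip export intensities drawn
  U(0.1, 0.3) kg P ha⁻¹ yr⁻¹ — a realistic range for high-P clay soils
  near watercourses — which lands uncalibrated reductions within a
  factor ~2 of the anchor, keeping the calibration factor tame (it is
  logged).

`calibrate` rescales every baseline transport by one global factor so a
reference allocation (default: the existing 162 ha at 10 m) reproduces
a reference reduction (default 97.2 kg yr⁻¹) exactly; linearity makes
this exact to round-off and preserves all ratios.

**What the generator does not emulate.** Real per-sub-catchment
transports and the actual spatial distribution of the 2008 buffers are
unpublished. Under the pro-rata default the existing program covers
88 % of the 10 m potential with uniform efficiency, so a uniform 6 m
program removes at most (0.46/0.58)/0.884 ≈ 90 % of the anchored
baseline reduction — on synthetic data the uniform scenario reduces
*less* than the existing program, whereas a real catchment with
unevenly placed existing buffers can show the opposite. Catchment-level
anchored quantities (areas, costs, the baseline reduction and every
ratio identity downstream of them) are meaningful on synthetic bundles;
absolute reductions of the other scenarios are not, and passing tests
on them demonstrate arithmetic consistency, not real-world transfer.

The geometry fixtures place metre-aligned rectangular blocks along a
straight 15 m watercourse, flush with the channel edge or fully outside
the 60 m corridor, recording construction-time adjacency ground truth.
Metre alignment mirrors cadastral digitization precision and makes the
1 m-raster area cross-check sharp.

## Numerical choices

* Slope class boundaries: [0, 1.99), [1.99, 3.26], (3.26, ∞) — touching
  boundaries belong to the middle class, consistent with the steepest
  class being strictly above 3.26 %.
* Allocation validation allows a 1e-9 relative slack against potential
  areas to survive CSV round-trips.
* The raster area oracle counts 1 m cell centers; the vector–raster
  agreement tolerance is 1 %.
* Greedy determinism is guaranteed by the four-level tie-break above;
  generator determinism by `numpy.random.default_rng(seed)` throughout.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
demo scale (13 sub-catchments, single-digit numbers of geometry
fixtures per seed, 50 seeds for the raster cross-check) and verify the
allocator exhaustively at 5–8 sub-catchments with up to two candidate
widths; the whole suite completes in a few seconds on one core.

## Known limitations

* One reduction-fraction table at a time; no mixing coefficient sets
  across regions in a single run.
* No CRS handling: geometry must arrive in planar metric coordinates.
* The greedy allocator does not split options; `nearest` mode and
  partial enrolment exist but whole-option admission is the default and
  the only mode the exhaustive verifier covers.
* No uptake/participation modelling and no transaction-cost
  quantification: costs are land and establishment only.
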