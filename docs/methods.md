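# Methods

## Model

A river network is a set of pre-segmented channel *sequences* (polylines in
a planar metric CRS) stitched into an undirected multigraph by unifying
segment endpoints within a snapping tolerance (single-linkage clustering;
default 1.0 m — generous against digitizing slack yet far below any
realistic sequence length; 0 demands exact coincidence). Sequence
granularity is taken as given: state hydrography data arrive pre-segmented,
and the package never re-splits geometries.

Each non-restored sequence is scored on four criteria worth 0–2 points
each — barrier presence (yes 2 / no 0; the barrier criterion deliberately
has no 1-point middle level), ecomorphological condition (natural 0 /
semi-natural 1 / artificial 2; the five-level field scheme High/Good/
Moderate/Poor/Bad collapses to these three on input), and the two species
criteria (NPS, HDAS): a flagged sequence scores 0 because it needs
protection rather than restoration, an absent one scores 1, and an absent
one *adjacent* to a flagged sequence scores 2, because restoring next door
extends habitat and spawning grounds for an existing population.
Presence dominates adjacency: a flagged sequence scores 0 even when it
also neighbors another flagged sequence.

Adjacency uses a 500 m threshold measured along the network from nearest
point to nearest point: the distance between two sequences is the shortest
path between their closest endpoints over the node graph (a shared node is
distance 0), computed with one multi-source Dijkstra pass per flag.
Species migrate along the channel, so network distance is the default; a
Euclidean mode (`adjacency.mode: euclidean`) covers the corridor reading
of the threshold for sensitivity analysis.

The total score is `4 · Σ w_c p_c / Σ w_c`, i.e. the weighted mean of
points rescaled so the range is always [0, 8] and equal weights reproduce
the integer point sum exactly. Weights default to 25% each; they are a
configuration hook for stakeholder-elicited weights, not something the
package estimates. Scores are binned un-rounded by a real-valued bin map.
Only the scale's extremes are fixed by the model definition (8 →
very_high; 0–1 → very_low); the interior edges default to 1, 3, 5, 7,
giving the two middle categories two-point spans, and are configurable.
Category precedence is: restored → `already_restored`; any unknown
criterion → `unknown`; otherwise the score's bin. "Unknown" is an explicit
attribute level so this precedence is testable, and in practice missing
connectivity (barrier) data is what feeds the unknown category.

## Landscape metrics

Metrics are class-level and fully vector-based. Patches are maximal groups
of contiguous same-class polygons; contiguity defaults to *queen* (any
boundary contact, including a single corner point, merges — such a patch's
geometry is a MultiPolygon of point-touching parts), with *rook* (shared
edge of positive length) as the alternative. NP, MPS (ha), ED (m/ha),
MNND (m, edge-to-edge via an STRtree nearest query, checked against an
exhaustive O(n²) oracle in the tests) and MSI (perimeter over the
perimeter of the equal-area circle; ≥ 1 by the isoperimetric inequality)
follow the standard class-level definitions. Hole boundaries count toward
perimeter. ED includes perimeter lying on the study-area boundary by
default; a boundary-exclusion variant is available because raster
implementations differ on this point. MNND is undefined (reported blank),
not 0, when a class has a single patch.

Change tables difference per-class areas between two epochs and print at
the precision conventional for such tables: km² at 2 dp, percentage points
at 1 dp, rounding half away from zero (banker's rounding would disagree
with printed references on ties). The same half-away rule at 1 dp applies
to all report output. `change_table` accepts either full maps or per-class
area tables, so printed summary tables can be differenced directly.

## Riparian buffers

The study area is the union of a 60 m buffer on the main stem and 40 m
buffers on the side network — the zone most relevant for intercepting
nutrient runoff. Buffers are planar with round caps at 64 quadrant
segments (cap area within ~0.01% of the true circle; flat caps available).
Buffer composition intersects each priority category's buffered member
segments with the land-cover mosaic and reports each class's share of the
buffered area. Categories are computed independently, so overlapping
buffers contribute to both rows; buffer area outside the mosaic is
reported as an explicit `uncovered` share rather than silently
renormalized.

## Reporting

Length-by-category reports use the full network length — including
`unknown` and `already_restored` — as the percentage denominator, so the
seven categories sum to 100 up to rounding; per-state reports use each
state's own total. Output is deterministic and byte-identical for
identical inputs.

## Synthetic data

`make_network` grows a random tree of segments (branching probability
0.25) or, in grid mode, a ditch grid like a drained agricultural plain.
Defaults emulate the study conditions the model targets: 200 segments of
100–800 m (a network of roughly 85–90 km), three administrative states
assigned as contiguous bands, P(restored) = 0.10, P(barrier data
missing) = 0.13 (missingness concentrated on connectivity data), barrier
P(yes) = 0.35, EC mixture 0.2/0.3/0.5 natural/semi-natural/artificial
(about half of lowland channels in non-natural condition), and species
flags at 15% prevalence. `make_mosaic` fills a grid of square cells (10 m
default, so every cell clears the 50 m² minimum mapping unit) with classes
drawn from a farmland-dominated mixture (69% Farmland, 12% EI, 9% TI,
7.5% Settlement, 2.8% Forest); a clustering parameter copies a neighbor's
class with probability 0.5, which creates coherent patches while
preserving the marginal mixture. One numpy Generator seeded from a single
integer drives all randomness.

What the generators do **not** emulate: real channel sinuosity and drainage
geometry, spatial autocorrelation between criteria (e.g. barriers
clustering in urban reaches), non-convex land-cover polygons, and the
historical digitizing process. Passing tests therefore demonstrate the
correctness of the algorithms and arithmetic on data with the right
structure and marginals, not calibration against any real river system.

## Numerical choices and limitations

- Geometry predicates and overlays delegate to GEOS via shapely 2; overlap
  detection in the land-cover validator tolerates slivers below 1e-9 m².
- Node ids are assigned by sorted cluster centroid, so topology is
  reproducible and independent of segment order.
- Geographic-looking input (bounding box inside ±180/±90) is rejected at
  the I/O layer instead of being reprojected; `assume_planar` overrides
  the heuristic for legitimately small planar extents.
- Problem sizes in the test suite and acceptance script (100 oracle
  networks of ≤ 50 segments; one 10,000-segment end-to-end run) were
  chosen as comfortable desk-scale checks of correctness and scaling.
- Scoring treats the segment, not the meter, as the unit: a very long
  flagged segment makes *all* its neighbors adjacent from its nearest
  endpoint, which matches the sequence-based data model but means results
  depend on how the source data segment the channel.
- No CRS transformation, raster ecomorphology ingestion, AHP/MCDA weight
  elicitation, or landscape-level (cross-class) metrics; GeoJSON is the
  only geospatial file format read or written.
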