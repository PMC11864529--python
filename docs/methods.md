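# Methods

This note records the modelling assumptions behind `aedsim`, the
parameters that matter, what the synthetic scenes do and do not emulate,
and the numerical choices a maintainer should know about.

## Routing model

Streets form a planar graph in projected meters; geographic coordinates
must be projected by the caller, which is adequate at single-city scale.
Edge traversal time is `length / speed` with a constant per-edge speed —
no turn penalties, signal delays, or traffic variation. Four modes are
defined: walk (10 km/h), bicycle (15 km/h), car (40 km/h), ambulance
(50 km/h). Walk and ambulance speeds are the standardized values of the
study design this package replicates (10 km/h is a brisk running pace
for a lay responder; 50 km/h an urban ambulance average); bicycle and
car are urban-plausible defaults, exposed for sensitivity analysis.
Pedestrians may traverse every street in both directions; vehicular
modes respect one-way restrictions. Per-edge `maxspeed_<mode>` overrides
take precedence over the mode default.

Points are snapped to the **nearest node**, not the nearest point on an
edge: simpler and exactly testable, with ties broken to the lowest node
id. The synthetic generator keeps blocks ≤ 200 m, so snapping moves a
point at most half a block diagonal (~141 m), i.e. a bounded ≤ ~51 s
one-way walking error at 10 km/h. Unreachable pairs are `+inf`, never a
sentinel. Shortest times come from Dijkstra on the mode-specific
directed graph; parallel segments collapse to the fastest.

## Response models and coverage

- **Ambulance**: one-way vehicular time from the (nearest) station to
  the scene. Dispatch, chute, and on-scene intervals are deliberately
  excluded; the model is station→scene travel only, a standardized basis
  for comparison rather than a full response-time model.
- **Bystander round trip**: the victim's companion runs to the nearest
  AED and back while CPR continues, so the response time is the full
  round trip at walking speed. Because pedestrian traversal is
  undirected, the return leg equals the outbound leg and the round trip
  is computed as exactly `2 ×` the one-way matrix (a second shortest-path
  pass would be mathematically identical but reintroduce floating-point
  re-association). The two-leg sum is kept for any future directed mode.

Coverage applies the budget to the **total** round trip (≤ 300 s,
boundary inclusive — "within" reads as ≤). Under symmetric walking this
coincides with the per-stretch reading of 150 s each way; the total form
generalizes. The per-stretch limit is retained as informational metadata.

## MCLP

The coverage relation aᵢⱼ (candidate j covers demand i within the
budget) feeds a maximal covering location problem with unit demand
weights by default. Two solvers:

- **Greedy**: repeatedly open the site covering the largest uncovered
  weight; ties to the lowest candidate index; stops early when no site
  adds coverage, so the number of opened sites can be below the budget
  p (Σxⱼ ≤ p, not = p — opening useless sites serves nothing and the
  report says how many were actually used). Carries the classical
  (1 − 1/e) guarantee for submodular maximization, asserted against the
  exact optimum in tests.
- **Exact**: bounded exhaustive search over candidate subsets of size
  1..p in ascending size, then lexicographic order, keeping the first
  strictly better objective — the returned optimum is therefore the
  smallest, lexicographically least optimal site set, which makes tests
  exact. The subset count is capped (default 10⁶); beyond it the solver
  refuses and points to greedy. No commercial-solver dependency.

`min_facilities_for_target` searches the smallest p whose objective
reaches a target coverage fraction, reporting the best attainable with a
flag when the target is out of reach. It supports the two readings of a
fixed published site count: imposed a priori (fixed p) or the minimal
budget for an achieved coverage; the replication config documents the
ambiguity and defaults to fixed p = 18.

## Statistics

- **Wilcoxon signed-rank** on paired per-point times (both arms are
  computed on the identical demand set, in identical order). Zero
  differences are dropped (Wilcoxon's convention; Pratt's zero-ranking
  is available), absolute differences ranked with midranks. The
  two-sided p is exact — dynamic programming over the 2ⁿ sign-flip null
  of the positive-rank sum — when the sample is tie-free, zero-free and
  n ≤ 25 (configurable); otherwise a tie-corrected normal approximation
  is used. A z statistic is reported in both regimes; the continuity
  correction defaults off (z conventions differ across packages).
  Infinite (unreachable) times must be excluded upstream; the pipeline
  reports the exclusion count. A rank-sum (independent-samples) variant
  is available behind an explicit function for sensitivity analysis.
  Note the exact/approx discrepancy can exceed 0.01 at large p values
  unless the continuity correction is applied; the agreement test uses
  the corrected form.
- **Shapiro–Wilk** gatekeeps normality per arm via Royston's published
  approximation (scipy's implementation), valid for 3 ≤ n ≤ 5000;
  constant samples are rejected with a zero-variance error.
- **Summaries**: mean, median, n−1 sd; the 95% CI of the mean defaults
  to Student-t, with a seeded percentile bootstrap (default B = 10 000)
  as an alternative — published CIs of this kind often come from
  unstated methods, so both are exposed rather than reverse-engineered.
- **Cronbach's alpha** = k/(k−1) · (1 − Σ item variances / total-score
  variance), n−1 denominators, no missing cells; Likert CSVs are
  validated to integer 1..7.

## Synthetic scenes

The generator emulates a planned, grid-like city center: a rows × cols
node lattice with uniform jitter (≤ 15 m default) on node coordinates,
exact Euclidean edge lengths, and a fraction of full streets one-way
with direction alternating by street parity (the familiar alternating
one-way pattern, which avoids vehicular traps). Strong connectivity
under the car mode is verified; on the rare failure the scene is
regenerated from a deterministically derived seed, so output remains a
pure function of config + seed. Demand is sampled uniformly over the
concentric central sub-rectangle of the bounding box (continuous space,
snapped downstream), emulating random point plotting over a dense city
center. Candidate AED sites are a seeded sample of street corners,
standing in for a registry of public, non-residential establishments;
the station sits at a chosen corner, the centroid, or an explicit node.

**Replication scene** (`configs/replication.yaml`): 25 × 25 grid of
200 m blocks (~4.8 km square — city-center scale), 50 demand points in
the central half, one corner station, 300 s budget, walk 10 km/h,
ambulance 50 km/h, AED budget p = 18 (greedy solver). The candidate
density (150 corners, roughly every fourth intersection) is chosen so
that the registry — like a real city-center registry of public
establishments — is dense enough that the optimizer, not candidate
scarcity, limits coverage; at the 300 s round-trip budget a site covers
a ~417 m network-walk radius, and ~18 sites is about the packing number
of the central region at that radius. City size and candidate count are
synthetic choices, not published values.

**What the scenes do not emulate**: population-density-weighted demand,
land-use structure, real street irregularity, AED opening hours,
distributed ambulance fleets, or traffic variation. Passing tests show
the pipeline's internal contracts and the directional conclusion on
grid-like scenes; they do not validate absolute response times for any
real city.

## Numerical choices

- Routing-oracle comparisons use rtol 1e-12 / atol 1e-9: Dijkstra and
  Floyd–Warshall associate edge-weight sums differently, so bitwise
  equality is not meaningful for float times; the tolerance is far below
  physical resolution.
- Exact coverage boundary tests use speed/length pairs whose times are
  exactly representable (e.g. 500 m at 12 km/h → 150.0 s) so the
  inclusive-≤ rule is pinned without float ambiguity.
- Matrix CSVs write `inf` for unreachable; JSON artifacts are written
  with sorted keys and the pipeline is byte-reproducible for a fixed
  config + seed (asserted in tests).
- Problem sizes in the test and acceptance runs (≤ 50-node oracle
  graphs, 2 000-replicate calibration at n = 50, ten replication seeds
  on the 625-node scene) keep the full suite under ~10 s while leaving
  every contract exercised at meaningful scale.

## Known limitations

- Nearest-node snapping biases walk times slightly downward for points
  mid-block; nearest-point-on-edge snapping is a listed extension.
- The exact MCLP solver is enumeration-bounded; large instances fall
  back to greedy (an ILP formulation through an external solver is an
  extension point, not shipped).
- The ambulance model's station→scene simplification means absolute
  coverage numbers understate real response times; conclusions should be
  read comparatively.
- No survival modelling: coverage within the budget is the endpoint, not
  survival probability.
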