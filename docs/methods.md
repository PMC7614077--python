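# Methods

## Scope and coordinate conventions

`ilptrack` covers the post-prediction half of a learned tracking-by-detection
pipeline: extraction of a candidate graph from dense prediction volumes,
globally constrained selection of lineage forests by integer linear
programming (globally or block-wise), evaluation against sparse ground truth,
and a greedy nearest-neighbor baseline. The dense predictions themselves
normally come from a convolutional network trained on sparse point
annotations; training such a network is out of scope, so the package ships
two substitutes that bracket it: the *supervision* module implements the
training-target and loss arithmetic as pure array operations (so the math is
testable without a GPU), and the *simulator* renders network-like prediction
volumes from sampled ground-truth lineages (so the downstream pipeline can be
run and verified end to end).

All positions are `(t, z, y, x)`, 0-based, in voxel units; spatial 3-vectors
are ordered `(z, y, x)`. Anisotropy enters through per-axis Gaussian sigmas,
per-axis mask radii, and per-axis distance weights — the same convention in
every module. Volumes are `(T, Z, Y, X)` or `(T, Z, Y, X, 3)` arrays (zarr on
disk); forests and graphs are CSV.

## The simulator

`simulate_lineages` samples a binary forest frame by frame. Per live cell and
frame, in order: death with probability `p_death` (track ends), exit with
`p_exit` (track ends, node flagged as exited), division with `p_divide`
(scalar or per-frame sequence), otherwise an isotropic Gaussian step of
standard deviation `step_sigma` truncated at `max_step`. Daughters are placed
symmetrically about the mother at `division_separation`, which guarantees
both daughters' rendered movement vectors point exactly at the mother. New
cells enter the field of view at Poisson rate `entry_rate`. A hard minimum
inter-nucleus distance is enforced within every frame; cells are placed
sequentially with rejection sampling, and when a cell is enclosed by
already-placed neighbors the whole frame's draws are retried (up to 20
times) before an explicit packing error names the frame. This frame-level
rejection conditions the process on feasibility, which negligibly biases
event statistics at the configured densities.

`render_predictions` turns a forest into the three prediction volumes. The
indicator is an anisotropic Gaussian of peak 1 at each (continuous) center,
overlaps combined by voxel-wise maximum so the target never exceeds 1; the
movement volume holds, within each nucleus's ellipsoidal support (radius
`support_factor · sigma`, nearest nucleus winning in overlaps), the offset to
the parent's position at the previous frame, zero for track starts; the
foreground mask is the union of true-nucleus supports. Noise knobs: additive
Gaussian indicator noise (jitters peak locations and scores), additive
movement-vector noise, and false blobs at a Poisson rate per frame with
peaks drawn uniformly from a configurable range that straddles the detection
threshold — these stand in for the unconstrained background behavior of a
network trained only inside sparse training masks. False blobs carry zero
movement vectors and are excluded from the foreground mask.

Defaults (chosen once as plausible desk-scale study conditions, not fitted
to any dataset): 20 initial cells in a `30×20×64×64` volume, `p_divide
= 0.02`, `p_death = p_exit = 0.005`, `entry_rate = 0.1` per frame, step
`σ = 1` truncated at 3 voxels, minimum inter-nucleus distance 6 voxels,
indicator `σ = (1.5, 2.5, 2.5)` zyx. The moderate-noise conditions used for
baseline comparisons are indicator noise 0.05, movement noise σ = 1.5
voxels, 0.5 false blobs per frame with peaks in [0.35, 0.7].

The simulator emulates prediction maps, not raw microscopy: there is no
point-spread function, scattering, bleaching, or intensity heterogeneity,
and its motion model is a memoryless truncated Gaussian walk rather than
directed tissue flow. Passing tests therefore demonstrate correctness of
extraction, optimization, and evaluation given predictions of a stated
quality — not detection performance on real images.

## Supervision math

The indicator target is a Gaussian of peak exactly 1 at each annotation,
overlaps resolved by maximum; the training mask is an axis-aligned ellipsoid
of configurable radii around each annotation, and *no voxel outside every
mask ever enters a loss* — with sparse annotations, far-from-annotation
voxels may be unannotated cells, so they are excluded by an explicit mask
rather than a sentinel value. The movement target within each annotation's
mask is the offset to the parent annotation (zero when parentless). The
movement loss is `α L_A + (1 − α) L_B`, where `L_A` is masked MSE over the
full training mask, `L_B` restricts it to NMS-maximal voxels inside the
mask, and `α(i) = 1/(1 + exp(0.01 (20000 − i)))` over training iterations —
exactly 0.5 at iteration 20000. As printed, this schedule weights the
peak-restricted term `L_B` highest at the *start* of training and hands over
to `L_A`; descriptions of this schedule sometimes state the opposite
ordering, so the formula is implemented verbatim and a
`favor_full_mask_early` flag swaps the two weights without changing the
schedule itself. Numerics: the schedule is computed with `expit`, which
saturates to exactly 0/1 in float64 beyond roughly ±37 logits; strict
monotonicity is therefore only numerically observable within about ±17000
iterations of the midpoint.

## Candidate extraction

NMS keeps voxels that are maximal within a per-axis window (matching the
asymmetric footprint scipy uses for even sizes), at or above the score
threshold, and inside the foreground mask when one is supplied. Plateau ties
are broken toward the lexicographically smallest voxel, which makes
extraction deterministic and guarantees no two detections share a window.
The window should be a bit smaller than the minimal inter-nucleus distance;
the default (5 voxels per axis against a minimum distance of 6) follows that
rule. Scores are clipped to [0, 1]; the movement vector is sampled at the
single peak voxel, with no local averaging.

Edges connect each candidate to *all* previous-frame candidates whose
weighted distance to the predicted location is below the search radius —
pruning is deliberately left to the ILP. The edge score is the *squared*
weighted distance; the configuration exposes the threshold as a radius `r`
and compares `d_e < r²`, keeping config units intuitive while storing the
squared score. Per-axis weights let anisotropic voxel sizes enter the
distance. The default radius (10 voxels) exceeds the maximum simulated
per-frame movement plus division separation and detection rounding.

## The ILP

Variables: one binary per node, per edge, and per node for each of the two
auxiliary families (track start `y^T`, division `y^D`). Constraints, for
every edge `e = (v, u)` and node `v` with `N_v` the edges arriving from
frame `t_v + 1` and `P_v` the edges leaving to `t_v − 1`:

```
2 y_e − y_v − y_u                ≤ 0      (edge consistency)
Σ_{n∈N_v} y_n − 2 y_v           ≤ 0      (at most two children)
Σ_{p∈P_v} y_p + y^T_v − y_v     = 0      (continuation)
Σ_{n∈N_v} y_n − y^D_v           ≤ 1      (split, upper)
Σ_{n∈N_v} y_n − 2 y^D_v         ≥ 0      (split, lower)
```

The objective is the linear cost of the README. Node cost `τ^V + w^V s_v`,
edge cost `w^E d_e`, constants `c^T`, `c^D`. The split constraints determine
`y^D` uniquely for any node selection *except* that they would permit a
spurious `y^D = 1` at a single-child node if `c^D` were negative; the
constraints are implemented verbatim and a negative `c^D` triggers a
warning instead of a silent reformulation. Sign conventions (`w^V < 0`,
`w^E > 0`, `c^T, c^D ≥ 0`) are likewise warnings, not errors.

The model is solved with HiGHS through `scipy.optimize.milp` to certified
optimality. Already-decided assignments (block-wise context) are pinned via
variable bounds. An independent verifier (`verify_selection`, a separate
code path that walks the graph rather than the constraint matrix) certifies
every returned selection; `exhaustive_solve` provides a brute-force optimum
for instances up to ~20 edges by vectorised enumeration over edge subsets,
exploiting that `y^T` and `y^D` are determined by `y` and that an isolated
node is worth selecting exactly when `τ^V + w^V s + c^T < 0`.

Degenerate ties: multiple optima may exist; any optimum is accepted and
tests compare objectives, not selections. For cost-sweep monotonicity
(raising `c^D` never increases the division count, and likewise `c^T` for
track starts) the tie-free quantity is the *minimum* auxiliary count over
all optima, computed by a two-stage lexicographic solve
(`min_auxiliary_at_optimum`): first the optimum, then the auxiliary count
minimized subject to the objective staying within a relative 1e-7 of it.

Defaults: `c^T = 2`, `c^D = 1`, `τ^V = 1`, `w^V = −4`, `w^E = 0.1`. The node
weight is −4 rather than −3 so that a perfect standalone detection has
strictly negative total cost (`1 − 4 + 2 = −1`); at −3 the cost ties at
exactly zero and single-frame tracks (cells entering at the last frame)
would be kept or dropped arbitrarily. Nodes at the first frame of a volume
pay `c^T` like any other track start; only block boundaries zero it (below).

## Block-wise solving

`plan_blocks` tiles the `(t, z, y, x)` extent into target regions and colors
block indices modulo `1 + ceil(2·context/block)` per axis, so blocks of one
color have disjoint context-extended regions and may be solved concurrently;
batches run in deterministic color order. The temporal context must be at
least one frame; spatial context should be at least the per-frame movement
(and twice that for reliable global agreement).

`solve_block` reads the subgraph inside the context-extended region, pins
every already-written selection in it (a pinned selected edge forces its
endpoints through the consistency constraint, which matters when an edge was
written before its parent node's owner block ran), zeroes `c^T` for nodes in
the lower-time context margin when that face is a cut rather than the start
of the recording, and writes results only for entities anchored in the
target region — a node belongs to the block containing its position, an edge
to the block owning its later (child) node. How spatially adjacent blocks
should interact with the `c^T = 0` rule for laterally crossing tracks is
genuinely underdetermined; the lower-time-face rule implemented here is one
documented reading, and temporal-only blocking avoids the question entirely.
The store is an in-memory map, optionally persisted one JSON file per block
so interrupted runs resume; a database backend could implement the same
narrow interface. There is no global-optimality guarantee — the assembled
solution is certified *feasible* by the independent verifier, and with a
context of two frames it matched the global objective on all tested
instances (50 seeds in the acceptance script).

## Evaluation

Ground truth is sparse, so false-positive *edges* are not scorable (an
unmatched reconstruction may track an unannotated cell) and are not counted.
Nodes are matched per frame by Hungarian assignment restricted to a hard
radius (default 3 voxels, half the minimum inter-nucleus distance); the
matching procedure is isolated behind the `Matching` type since other
conventions exist. Per ground-truth edge: *FN* if an endpoint is unmatched
or the matched endpoints are not linked — unless the reconstructed child
continues into a *different* matched cell, which is an *identity switch*
(two tracks swapping who they follow). *FP-D* counts matched reconstructed
nodes with two selected children where the ground truth divides into fewer;
*FN-D* counts ground-truth divisions whose matched node does not have two
selected children. The error-free-track fraction at length `L` slides a
window of `L` consecutive nodes along division-free ground-truth tracklets
(divisions end a tracklet) and requires every node matched, every edge
correct, and no division error on the window. This fraction is
non-increasing in `L` when all tracklets are at least `L` long; with shorter
tracklets in the mix the denominator shrinks with `L` and monotonicity can
fail — a property of the sliding-window definition worth knowing when
reading curves.

The greedy baseline links every detection frame by frame to the nearest
previous-frame detection within a radius of its predicted location,
processing detections in descending score order and refusing third
children. It has no notion of cost: it never breaks an implausible link and
happily creates divisions, which is exactly the failure mode the ILP's
`c^D` suppresses.

`grid_search` evaluates the full solve-and-score loop over a parameter grid
with `c^D` fixed at 1 (removing a redundant overall scale), minimizing the
unweighted sum FN + IS + FP-D + FN-D over the validation set — one instance
or several (scores are summed across instances); first-in-grid-order wins
ties, failed grid points are recorded and skipped. The default calibration
grid keeps `c^T ∈ {2, 4}` above `c^D = 1`: if a track start were cheaper
than a division, the optimizer would reconstruct every division as an
appearance (break cost `c^T` < link cost `c^D` + edge cost), systematically
producing FN + FN-D pairs, which contradicts the continuity prior the cost
model encodes.

## Problem sizes

The test suite and acceptance script run on deliberately small instances:
random solver instances with ≤12 nodes/≤16 edges (where exhaustive
enumeration is exact and fast), simulated embryos of 8–20 cells over 12–30
frames in volumes up to `30×20×64×64`. These sizes exercise every code path
— divisions, exits, entries, block boundaries, noise — while keeping the
full suite under a minute; the algorithms themselves scale with graph size,
and block-wise solving exists precisely to decouple peak memory and solve
time from recording length.

## Known limitations

- No network, no training: prediction quality is an *input* here, set by the
  simulator's noise knobs.
- Matching, identity-switch, and division-error bookkeeping follow the
  documented definitions above; other conventions exist and would change
  absolute error counts (not the qualitative comparisons).
- Block-wise solving trades global optimality for parallelism; disagreements
  with the global objective are possible with small contexts and are logged,
  never silent.
- Local parallelism only (threads within one process); multi-machine
  scheduling would reuse the same plan/store contracts but is not shipped.
- The simulator's event rates are testability choices, not biological
  measurements.
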