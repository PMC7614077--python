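# ilptrack

Reconstruction of cell lineage forests from dense detection predictions in
3D+t microscopy, by candidate extraction and globally constrained integer
linear programming — with a synthetic embryo simulator so the whole pipeline
runs, and can be verified, at desk scale.

## The problem

Time-lapse light-sheet recordings of developing embryos contain the complete
history of every nucleus: where it moved, when it divided, when it entered or
left the field of view, when it died. Turning such recordings into lineage
trees by hand is prohibitively slow, and per-frame greedy linking of
detections breaks down exactly where the biology is interesting — near
divisions and crossings. `ilptrack` implements the tracking-by-detection
approach in which dense per-voxel predictions (a *cell indicator* score that
peaks at nucleus centers, and a *movement vector* pointing to the same cell
one frame earlier) are distilled into an over-complete candidate graph, and a
single global optimization selects the subset of candidates that forms the
most plausible set of lineage trees.

## The model

Candidates are extracted by non-maximum suppression on the indicator volume
(window a bit smaller than the minimal inter-nucleus distance, plus a score
threshold and optional foreground filter). Each detection `v` keeps its score
`s_v` and the movement vector `m_v` sampled at its peak voxel. Directed edges
connect `v` at frame `t` to every candidate `u` at `t − 1` whose position lies
within a search radius of the predicted location `l_v + m_v`; the squared
deviation `d_e = ‖l_v + m_v − l_u‖²` is the edge score.

Selection is a binary vector `y = [y^V, y^E]` over nodes and edges,
constrained so the induced subgraph is a *binary forest* (at most one parent
and two children per node — cells move, divide in two, appear, and disappear,
but never merge). Two derived indicator families mark track starts (`y^T`)
and divisions (`y^D`). The ILP minimizes

```
C(y) = Σ_v (τ^V + w^V s_v) y_v  +  Σ_e (w^E d_e) y_e  +  c^T Σ_v y^T_v  +  c^D Σ_v y^D_v
```

with `w^V < 0` (confident detections are rewarded), `w^E > 0` (links that
agree with the predicted movement are cheap), `c^T > 0` (long continuous
lineages are preferred), and `c^D > 0` (movement is far more common than
division). Feasibility and the auxiliaries are enforced by linear
constraints — edge/endpoint consistency, a ≤2-children bound, a track
continuation equality, and two split constraints — solved to certified
optimality with HiGHS (`scipy.optimize.milp`). Volumes too large for one
program are tiled into blocks with context margins and solved in
conflict-free batches, earlier results entering later blocks as pinned
constraints, yielding a globally consistent forest.

Because training a detection network is out of scope here, a simulator
generates ground-truth lineage forests with configurable movement, division,
death, and entry/exit statistics, and renders exactly the prediction volumes
the network would produce — including controllable peak jitter,
movement-vector noise, and false blobs.

## Worked example

```python
from ilptrack import *

config = SimConfig(shape=(16, 16, 48, 48), n_initial=8, seed=7)
gt = simulate_lineages(config)
print("ground truth:", len(gt), "nodes,", gt.n_edges, "edges,",
      len(gt.divisions()), "divisions,", len(gt.roots()), "roots")

indicator, movement, foreground = render_predictions(gt, config)
graph = extract_graph(indicator, movement, CandidateParams())
print("candidate graph:", graph.n_nodes, "nodes,", graph.n_edges, "edges")

selection = solve(graph, SolverParams())
print("selected:", len(selection.nodes), "nodes,", len(selection.edges),
      "edges,", len(selection.track_starts), "track starts,",
      len(selection.divisions), "divisions; objective %.2f" % selection.objective)

rec = selection_to_forest(graph, selection)
report = evaluate(gt, rec, radius=3.0, lengths=[5, 10])
print("errors per GT edge:", report.rates())
print("error-free fraction:", report.error_free)
```

prints

```
ground truth: 136 nodes, 128 edges, 2 divisions, 8 roots
candidate graph: 136 nodes, 200 edges
selected: 136 nodes, 128 edges, 8 track starts, 2 divisions; objective -368.97
errors per GT edge: {'fn': 0.0, 'identity_switches': 0.0, 'fp_divisions': 0.0, 'fn_divisions': 0.0}
error-free fraction: {5: 1.0, 10: 1.0}
```

The candidate graph is over-complete (200 edges for 128 true links); the ILP
selects exactly the true cells and links: zero false-negative edges, identity
switches, and division errors, and every 5- and 10-frame track segment is
reconstructed perfectly. On noisy renderings the same pipeline degrades
gracefully and, after the built-in grid-search calibration, makes fewer
errors than the greedy nearest-neighbor baseline — in particular far fewer
spurious divisions.

The same stages are available from the shell:

```
ilptrack simulate --config sim.yaml --out run/ --seed 7
ilptrack extract  --indicator run/indicator.zarr --movement run/movement.zarr --out run/graph
ilptrack solve    --graph run/graph --out run/sol            # add --blockwise for tiled solving
ilptrack evaluate --gt run/gt.csv --rec run/sol/rec.csv --radius 3 --lengths 5,10,20
ilptrack pipeline --config pipeline.yaml --out run/ --seed 7  # everything at once
```

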