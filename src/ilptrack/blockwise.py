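"""Block-wise lineage solving for volumes too large for one global ILP.

The candidate graph is tiled into blocks whose *target regions* partition
the (t, z, y, x) extent.  Each block is solved on its *context-extended*
region (the target region grown by a margin that must cover at least one
frame in each temporal direction and the maximum spatial movement between
frames), but writes results only for entities anchored in its target
region.  Previously written selections inside the context enter the block's
ILP as pinned equality constraints, so the assembled solution satisfies
every lineage constraint globally.  Blocks whose context regions overlap
are never solved in the same batch; batches are scheduled by a
deterministic checkerboard coloring of block indices.  Within a block, the
track-start cost is zeroed for nodes near the lower-time face of the
context region (when that face is a cut, not the start of the recording),
so tracks crossing block boundaries are not penalized.

There is no guarantee of global optimality, but with a sufficient context
the block-wise objective matches the global one in practice; the 1-block
plan reduces exactly to the global solve.
"""

from __future__ import annotations

import json
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .candidates import CandidateGraph
from .forest import LineageForest
from .tracking import Selection, SolverParams, selection_to_forest, solve
from .verify import verify_selection

__all__ = ["BlockSpec", "SolutionStore", "plan_blocks", "solve_block", "run_blockwise"]


@dataclass(frozen=True)
class BlockSpec:
    """A block's half-open target region and its context margin.

    ``begin``/``end`` are (t, z, y, x) bounds of the target region;
    ``context`` is the per-axis margin (frames for t, voxels otherwise)
    read -- but not written -- around it.
    """

    block_id: int
    begin: tuple[int, int, int, int]
    end: tuple[int, int, int, int]
    context: tuple[int, int, int, int]

    @property
    def context_begin(self) -> tuple[int, ...]:
        return tuple(b - c for b, c in zip(self.begin, self.context))

    @property
    def context_end(self) -> tuple[int, ...]:
        return tuple(e + c for e, c in zip(self.end, self.context))

    def contains(self, t: int, position) -> bool:
        p = (t, *position)
        return all(b <= x < e for x, b, e in zip(p, self.begin, self.end))

    def context_contains(self, t: int, position) -> bool:
        p = (t, *position)
        return all(
            b <= x < e for x, b, e in zip(p, self.context_begin, self.context_end)
        )

    def context_intersects(self, other: "BlockSpec") -> bool:
        return all(
            b1 < e2 and b2 < e1
            for b1, e1, b2, e2 in zip(
                self.context_begin, self.context_end,
                other.context_begin, other.context_end,
            )
        )

    def to_dict(self) -> dict:
        return {
            "block_id": self.block_id,
            "begin": list(self.begin),
            "end": list(self.end),
            "context": list(self.context),
        }


def plan_blocks(
    extent: tuple[int, int, int, int],
    block_shape: tuple[int, int, int, int],
    context: tuple[int, int, int, int],
) -> list[list[BlockSpec]]:
    """Tile ``extent`` into target regions and schedule conflict-free batches.

    Returns an ordered list of batches; within a batch no two blocks'
    context-extended regions intersect, so they may be solved concurrently.
    The schedule is a checkerboard coloring: along each axis, blocks whose
    indices are congruent modulo ``1 + ceil(2 * context / block)`` share a
    color, which guarantees their context regions are disjoint.
    """
    if context[0] < 1 and block_shape[0] < extent[0]:
        raise ValueError("temporal context must be at least one frame")
    if any(b > e for b, e in zip(block_shape, extent)):
        raise ValueError(f"block shape {block_shape} exceeds extent {extent}")
    if any(c > b for c, b in zip(context, block_shape)):
        warnings.warn(
            "context larger than block shape heavily serializes the schedule",
            stacklevel=2,
        )

    counts = [int(np.ceil(e / b)) for e, b in zip(extent, block_shape)]
    strides = [
        1 if n == 1 else 1 + int(np.ceil(2 * c / b))
        for n, c, b in zip(counts, context, block_shape)
    ]
    batches: dict[tuple, list[BlockSpec]] = {}
    block_id = 0
    for it in range(counts[0]):
        for iz in range(counts[1]):
            for iy in range(counts[2]):
                for ix in range(counts[3]):
                    idx = (it, iz, iy, ix)
                    begin = tuple(i * b for i, b in zip(idx, block_shape))
                    end = tuple(
                        min((i + 1) * b, e)
                        for i, b, e in zip(idx, block_shape, extent)
                    )
                    spec = BlockSpec(block_id, begin, end, tuple(context))
                    color = tuple(i % s for i, s in zip(idx, strides))
                    batches.setdefault(color, []).append(spec)
                    block_id += 1
    return [batches[color] for color in sorted(batches)]


class SolutionStore:
    """File-backable store of per-entity selection state.

    Maps node ids and (child, parent) edge pairs to 0/1 selection values
    together with the id of the block that wrote them; each entity is
    written by exactly one block (the one whose target region contains its
    anchor: a node's own position, an edge's later -- child -- node).  With
    a directory path, every block write is persisted as one JSON file so an
    interrupted run can resume.
    """

    def __init__(self, path: str | Path | None = None) -> None:
        self.nodes: dict = {}
        self.edges: dict = {}
        self.completed_blocks: set[int] = set()
        self.path = Path(path) if path is not None else None
        if self.path is not None:
            self.path.mkdir(parents=True, exist_ok=True)
            for f in sorted(self.path.glob("block_*.json")):
                self._absorb(json.loads(f.read_text()))

    def _absorb(self, payload: dict) -> None:
        bid = payload["block_id"]
        for k, v in payload["nodes"].items():
            self.nodes[int(k)] = (int(v), bid)
        for k, v in payload["edges"].items():
            child, parent = (int(s) for s in k.split(","))
            self.edges[(child, parent)] = (int(v), bid)
        self.completed_blocks.add(bid)

    def write_block(self, block_id: int, nodes: dict, edges: dict) -> None:
        for n, v in nodes.items():
            prev = self.nodes.get(n)
            if prev is not None and prev[1] != block_id:
                raise RuntimeError(
                    f"node {n} already written by block {prev[1]}"
                )
        payload = {
            "block_id": block_id,
            "nodes": {str(k): int(v) for k, v in nodes.items()},
            "edges": {f"{c},{p}": int(v) for (c, p), v in edges.items()},
        }
        self._absorb(payload)
        if self.path is not None:
            (self.path / f"block_{block_id:06d}.json").write_text(
                json.dumps(payload)
            )

    def pinned_in(self, graph: CandidateGraph, block: BlockSpec) -> dict:
        """Already-written selection states inside the block's context region."""
        g = graph.graph
        pinned_nodes = {
            n: v
            for n, (v, _b) in self.nodes.items()
            if n in g.nodes
            and block.context_contains(g.nodes[n]["t"], g.nodes[n]["position"])
        }
        # a pinned selected edge forces its endpoints via the consistency
        # constraint, even when one endpoint is not itself written yet
        pinned_edges = {
            (c, p): v
            for (c, p), (v, _b) in self.edges.items()
            if (c, p) in g.edges
        }
        return {"nodes": pinned_nodes, "edges": pinned_edges}

    def to_selection(self, graph: CandidateGraph) -> Selection:
        """Assemble the globally consistent selection with derived auxiliaries."""
        sel = Selection()
        sel.nodes = {n for n, (v, _b) in self.nodes.items() if v}
        sel.edges = {e for e, (v, _b) in self.edges.items() if v}
        with_parent = {c for (c, _p) in sel.edges}
        sel.track_starts = sel.nodes - with_parent
        n_children: dict = {}
        for (_c, p) in sel.edges:
            n_children[p] = n_children.get(p, 0) + 1
        sel.divisions = {p for p, k in n_children.items() if k == 2}
        return sel


def solve_block(
    block: BlockSpec,
    graph: CandidateGraph,
    params: SolverParams,
    store: SolutionStore,
    timeout: float | None = None,
) -> None:
    """Solve one block on its context region and write its target region.

    All earlier batches whose context intersects this block's must already
    be in the store.  Nodes within one temporal context margin of the
    lower-time face of the context region pay no track-start cost, unless
    that face is the start of the recording.
    """
    g = graph.graph
    in_ctx = [
        n
        for n, d in g.nodes(data=True)
        if block.context_contains(d["t"], d["position"])
    ]
    sub = CandidateGraph(g.subgraph(in_ctx).copy())
    pinned = store.pinned_in(sub, block)

    track_costs: dict = {}
    if block.context_begin[0] > 0:  # lower-time face is a cut, not t=0
        # nodes in the lower-time context margin: their past lies outside
        # the context region, so starting a track there is not penalized
        track_costs = {n: 0.0 for n in in_ctx if g.nodes[n]["t"] < block.begin[0]}

    selection = solve(
        sub, params, pinned=pinned, timeout=timeout, node_track_costs=track_costs
    )

    own_nodes = {
        n: int(n in selection.nodes)
        for n in in_ctx
        if block.contains(g.nodes[n]["t"], g.nodes[n]["position"])
    }
    own_edges = {}
    for (c, p) in sub.graph.edges:
        if c in own_nodes:  # edge anchored at its later (child) node
            own_edges[(c, p)] = int((c, p) in selection.edges)
    store.write_block(block.block_id, own_nodes, own_edges)


def run_blockwise(
    graph: CandidateGraph,
    params: SolverParams,
    plan: list[list[BlockSpec]],
    store: SolutionStore | None = None,
    workers: int = 1,
    timeout: float | None = None,
) -> tuple[LineageForest, Selection]:
    """Execute a block plan and assemble the global lineage forest.

    Batches run sequentially; blocks within a batch are independent (their
    context regions are disjoint) and may run concurrently.  Blocks already
    recorded in a resumed store are skipped.  The assembled selection is
    certified by the independent constraint checker before the forest is
    built.
    """
    store = store if store is not None else SolutionStore()
    for batch in plan:
        todo = [b for b in batch if b.block_id not in store.completed_blocks]
        if workers > 1 and len(todo) > 1:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                futures = [
                    pool.submit(solve_block, b, graph, params, store, timeout)
                    for b in todo
                ]
                for f in futures:
                    f.result()
        else:
            for b in todo:
                solve_block(b, graph, params, store, timeout)
    selection = store.to_selection(graph)
    verify_selection(graph, selection)
    forest = selection_to_forest(graph, selection)
    return forest, selection
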