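"""Independent verification of lineage selections.

Checks a :class:`~ilptrack.tracking.Selection` against the candidate graph
by walking nodes and edges directly -- a deliberately separate code path
from the ILP matrix construction -- so solver output (global or block-wise)
can be certified feasible: both consistency families, the continuation
equality, both split constraints, and binary-forest membership.
"""

from __future__ import annotations

from .candidates import CandidateGraph
from .tracking import Selection, SolverParams, edge_cost, node_cost

__all__ = ["ConstraintViolation", "verify_selection", "selection_objective"]


class ConstraintViolation(ValueError):
    """A selection violates one of the lineage constraints."""


def verify_selection(graph: CandidateGraph, selection: Selection) -> None:
    """Raise :class:`ConstraintViolation` if any constraint is violated.

    Checks, for the selected subgraph:

    - every selected edge has both endpoints selected (edge consistency);
    - every node has at most two selected incoming-from-future edges
      (children consistency) -- so the subgraph is a binary forest;
    - every node has at most one selected outgoing-to-past edge, and a
      selected node has either exactly one such edge or its track-start
      indicator set (continuation);
    - the division indicator is 1 exactly on nodes with two selected
      children and 0 on nodes with fewer (split constraints);
    - selected edges span exactly one frame.
    """
    g = graph.graph
    for v in selection.nodes | selection.track_starts | selection.divisions:
        if v not in g.nodes:
            raise ConstraintViolation(f"unknown node {v} in selection")
    for (v, u) in selection.edges:
        if (v, u) not in g.edges:
            raise ConstraintViolation(f"unknown edge ({v}, {u}) in selection")
        if v not in selection.nodes or u not in selection.nodes:
            raise ConstraintViolation(
                f"edge ({v}, {u}) selected but an endpoint is not"
            )
        if g.nodes[v]["t"] != g.nodes[u]["t"] + 1:
            raise ConstraintViolation(f"edge ({v}, {u}) does not span one frame")

    parents: dict = {}
    children: dict = {}
    for (v, u) in selection.edges:
        parents[v] = parents.get(v, 0) + 1
        children[u] = children.get(u, 0) + 1

    for v, k in parents.items():
        if k > 1:
            raise ConstraintViolation(f"node {v} has {k} selected parents")
    for u, k in children.items():
        if k > 2:
            raise ConstraintViolation(f"node {u} has {k} selected children")

    for v in selection.nodes:
        has_parent_edge = parents.get(v, 0) == 1
        is_start = v in selection.track_starts
        if has_parent_edge == is_start:
            raise ConstraintViolation(
                f"continuation violated at node {v}: parent edge "
                f"{'present' if has_parent_edge else 'absent'}, track-start "
                f"indicator {'set' if is_start else 'unset'}"
            )
    for v in selection.track_starts:
        if v not in selection.nodes:
            raise ConstraintViolation(f"track start {v} on unselected node")
    for v in selection.divisions:
        if children.get(v, 0) != 2:
            raise ConstraintViolation(
                f"division indicator at {v} with {children.get(v, 0)} children"
            )
    for u, k in children.items():
        if k == 2 and u not in selection.divisions:
            raise ConstraintViolation(
                f"node {u} has two selected children but no division indicator"
            )


def selection_objective(
    graph: CandidateGraph, selection: Selection, params: SolverParams
) -> float:
    """Recompute the objective of a selection from graph attributes."""
    g = graph.graph
    total = sum(node_cost(g.nodes[v]["score"], params) for v in selection.nodes)
    total += sum(edge_cost(g.edges[e]["distance"], params) for e in selection.edges)
    total += params.c_track * len(selection.track_starts)
    total += params.c_division * len(selection.divisions)
    return float(total)
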