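"""Lineage selection as an integer linear program.

Given an over-complete candidate graph, select the cost-minimal subset of
nodes and edges that forms a binary forest (every node has at most one
parent and at most two children).  Selection is encoded by binary vectors
``y = [y^V, y^E]`` with two auxiliary indicator families: ``y^T`` marks
track starts (a selected node with no selected edge to the previous frame)
and ``y^D`` marks divisions (a selected node with two selected incoming
edges from the next frame).

The objective is

    C(y) = sum_v (tau^V + w^V s_v) y_v + sum_e (w^E d_e) y_e
         + sum_v c^T y_v^T + sum_v c^D y_v^D

with per-node cost individualized by the detection score ``s_v`` (``w^V``
should be negative so confident detections are rewarded) and per-edge cost
by the squared deviation ``d_e`` from the predicted movement (``w^E``
should be positive so well-predicted links are cheap).  ``c^T`` penalizes
starting new tracks, encoding the prior that long continuous lineages are
more plausible; ``c^D`` penalizes divisions, encoding that movement is far
more common than division.

Feasibility is enforced by four linear constraint families per the model:

- consistency (edge):      2 y_e - y_v - y_u <= 0        for every e = (v, u)
- consistency (children):  sum_{n in N_v} y_n - 2 y_v <= 0
- continuation:            sum_{p in P_v} y_p + y_v^T - y_v = 0
- split:                   sum_{n in N_v} y_n - y_v^D <= 1   and
                           sum_{n in N_v} y_n - 2 y_v^D >= 0

where ``P_v`` are edges from ``v`` to the previous frame and ``N_v`` edges
from the next frame into ``v``.  The program is solved exactly with the
HiGHS mixed-integer solver via :func:`scipy.optimize.milp`; a vectorised
exhaustive enumerator over edge subsets is provided as an independent
optimum oracle for small instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .candidates import CandidateGraph
from .forest import LineageForest

__all__ = [
    "SolverParams",
    "Selection",
    "ILPModel",
    "SolverError",
    "node_cost",
    "edge_cost",
    "build_ilp",
    "solve",
    "exhaustive_solve",
    "selection_to_forest",
    "min_auxiliary_at_optimum",
]


class SolverError(RuntimeError):
    pass


@dataclass
class SolverParams:
    """Costs of the lineage-selection objective.

    Sign conventions: ``w_node`` (the score weight) should be negative and
    ``w_edge`` (the distance weight) positive; ``c_division`` should be
    non-negative, otherwise a lone selected child could spuriously claim the
    (then profitable) division indicator, which the split constraints leave
    free at one selected child.
    """

    c_track: float = 2.0  # c^T: cost of starting a new track
    c_division: float = 1.0  # c^D: cost of a division (fixed to 1 in grid search)
    tau_node: float = 1.0  # tau^V: constant node cost offset
    w_node: float = -4.0  # w^V: weight on the cell-indicator score
    w_edge: float = 0.1  # w^E: weight on the squared edge distance

    def __post_init__(self) -> None:
        if self.c_track < 0:
            warnings.warn("c_track < 0 rewards track starts", stacklevel=2)
        if self.c_division < 0:
            warnings.warn(
                "c_division < 0 can be claimed spuriously at single-child nodes",
                stacklevel=2,
            )
        if self.w_node > 0:
            warnings.warn("w_node > 0 penalizes confident detections", stacklevel=2)
        if self.w_edge < 0:
            warnings.warn("w_edge < 0 rewards poorly predicted edges", stacklevel=2)


def node_cost(score: float, params: SolverParams) -> float:
    """Selection cost of a node: tau^V + w^V * s_v."""
    return params.tau_node + params.w_node * score


def edge_cost(distance: float, params: SolverParams) -> float:
    """Selection cost of an edge: w^E * d_e (d_e is the squared deviation)."""
    return params.w_edge * distance


@dataclass
class Selection:
    """A (candidate) solution of the lineage ILP."""

    nodes: set = field(default_factory=set)
    edges: set = field(default_factory=set)  # (child, parent) pairs
    track_starts: set = field(default_factory=set)  # y^T = 1
    divisions: set = field(default_factory=set)  # y^D = 1
    objective: float = 0.0


@dataclass
class ILPModel:
    """Explicit matrix form of the lineage ILP (all variables binary).

    Variable layout: node indicators, then edge indicators, then per-node
    track-start indicators y^T, then per-node division indicators y^D.
    Constraints are rows of ``A`` with bounds ``lb <= A y <= ub``.
    """

    node_ids: list
    edge_list: list  # (child, parent) pairs, sorted
    costs: np.ndarray
    A: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)

    @property
    def n_vars(self) -> int:
        return 2 * self.n_nodes + self.n_edges + self.n_nodes

    def var_index(self, kind: str, key) -> int:
        nV, nE = self.n_nodes, self.n_edges
        if kind == "node":
            return self.node_ids.index(key)
        if kind == "edge":
            return nV + self.edge_list.index(key)
        if kind == "track":
            return nV + nE + self.node_ids.index(key)
        if kind == "division":
            return nV + nE + nV + self.node_ids.index(key)
        raise KeyError(kind)


def build_ilp(
    graph: CandidateGraph,
    params: SolverParams,
    pinned: dict | None = None,
) -> ILPModel:
    """Assemble objective, constraints, and (optionally pinned) bounds.

    ``pinned`` maps already-decided entities to fixed values:
    ``{"nodes": {node_id: 0|1}, "edges": {(child, parent): 0|1}}``.  Pinned
    assignments become equality bounds on the corresponding variables, as
    used for cross-block consistency in block-wise solving.
    """
    g = graph.graph
    node_ids = sorted(g.nodes)
    edge_list = sorted(g.edges)
    nV, nE = len(node_ids), len(edge_list)
    n = 2 * nV + nE + nV
    nidx = {v: i for i, v in enumerate(node_ids)}
    eidx = {e: nV + i for i, e in enumerate(edge_list)}
    t_off, d_off = nV + nE, nV + nE + nV

    costs = np.zeros(n)
    for v, i in nidx.items():
        costs[i] = node_cost(g.nodes[v]["score"], params)
        costs[t_off + i] = params.c_track
        costs[d_off + i] = params.c_division
    for e, j in eidx.items():
        costs[j] = edge_cost(g.edges[e]["distance"], params)

    rows, cols, vals, lbs, ubs = [], [], [], [], []

    def add_row(entries, lo, hi):
        r = len(lbs)
        for c, v in entries:
            rows.append(r)
            cols.append(c)
            vals.append(v)
        lbs.append(lo)
        ubs.append(hi)

    inf = np.inf
    # edge consistency: 2 y_e - y_v - y_u <= 0
    for (v, u) in edge_list:
        add_row([(eidx[(v, u)], 2.0), (nidx[v], -1.0), (nidx[u], -1.0)], -inf, 0.0)
    for v in node_ids:
        i = nidx[v]
        incoming = [eidx[(c, v)] for c in g.predecessors(v)]  # N_v: from t+1
        outgoing = [eidx[(v, p)] for p in g.successors(v)]  # P_v: to t-1
        # children consistency: sum N_v - 2 y_v <= 0
        add_row([(j, 1.0) for j in incoming] + [(i, -2.0)], -inf, 0.0)
        # continuation: sum P_v + y^T_v - y_v = 0
        add_row([(j, 1.0) for j in outgoing] + [(t_off + i, 1.0), (i, -1.0)], 0.0, 0.0)
        # split: sum N_v - y^D_v <= 1  and  sum N_v - 2 y^D_v >= 0
        add_row([(j, 1.0) for j in incoming] + [(d_off + i, -1.0)], -inf, 1.0)
        add_row([(j, 1.0) for j in incoming] + [(d_off + i, -2.0)], 0.0, inf)

    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(lbs), n) if lbs else (0, n)
    )
    var_lb = np.zeros(n)
    var_ub = np.ones(n)
    for kind, idx_map in (("nodes", nidx), ("edges", eidx)):
        for key, val in (pinned or {}).get(kind, {}).items():
            if key not in idx_map:
                raise KeyError(f"pinned {kind[:-1]} {key!r} not in graph")
            var_lb[idx_map[key]] = var_ub[idx_map[key]] = float(val)

    return ILPModel(node_ids, edge_list, costs, A,
                    np.array(lbs), np.array(ubs), var_lb, var_ub)


def _selection_from_x(model: ILPModel, x: np.ndarray, objective: float) -> Selection:
    nV, nE = model.n_nodes, model.n_edges
    xb = x > 0.5
    sel = Selection(objective=float(objective))
    sel.nodes = {model.node_ids[i] for i in range(nV) if xb[i]}
    sel.edges = {model.edge_list[i] for i in range(nE) if xb[nV + i]}
    sel.track_starts = {model.node_ids[i] for i in range(nV) if xb[nV + nE + i]}
    sel.divisions = {model.node_ids[i] for i in range(nV) if xb[nV + nE + nV + i]}
    return sel


def _run_milp(model: ILPModel, costs: np.ndarray, extra: list | None = None,
              timeout: float | None = None):
    constraints = []
    if model.A.shape[0]:
        constraints.append(LinearConstraint(model.A, model.lb, model.ub))
    if extra:
        constraints.extend(extra)
    options = {"presolve": True}
    if timeout is not None:
        options["time_limit"] = float(timeout)
    res = milp(
        c=costs,
        constraints=constraints,
        integrality=np.ones(model.n_vars),
        bounds=Bounds(model.var_lb, model.var_ub),
        options=options,
    )
    if res.status != 0 or res.x is None:
        raise SolverError(
            f"MILP failed (status={res.status}: {res.message}); "
            f"|V|={model.n_nodes}, |E|={model.n_edges}, "
            f"{model.A.shape[0]} constraints"
        )
    return res


def solve(
    graph: CandidateGraph,
    params: SolverParams,
    pinned: dict | None = None,
    timeout: float | None = None,
    node_track_costs: dict | None = None,
) -> Selection:
    """Solve the lineage ILP to proven optimality.

    ``node_track_costs`` optionally overrides the track-start cost c^T per
    node (used by block-wise solving to zero it at block boundaries).
    """
    model = build_ilp(graph, params, pinned)
    costs = model.costs.copy()
    if node_track_costs:
        t_off = model.n_nodes + model.n_edges
        nidx = {v: i for i, v in enumerate(model.node_ids)}
        for v, c in node_track_costs.items():
            costs[t_off + nidx[v]] = float(c)
    if model.n_vars == 0:
        return Selection(objective=0.0)
    res = _run_milp(model, costs, timeout=timeout)
    objective = float(costs @ np.round(res.x))
    return _selection_from_x(model, res.x, objective)


def min_auxiliary_at_optimum(
    graph: CandidateGraph, params: SolverParams, which: str = "division"
) -> int:
    """Minimum count of divisions (or track starts) over all optimal solutions.

    Two-stage lexicographic solve: find the optimal objective, then minimize
    the auxiliary count subject to the objective staying within a small
    tolerance of that optimum.  Makes cost-sweep monotonicity checks immune
    to arbitrary tie-breaking among equally optimal selections.
    """
    model = build_ilp(graph, params)
    if model.n_vars == 0:
        return 0
    res = _run_milp(model, model.costs)
    opt = float(model.costs @ np.round(res.x))
    nV, nE = model.n_nodes, model.n_edges
    off = nV + nE + (nV if which == "division" else 0)
    aux = np.zeros(model.n_vars)
    aux[off:off + nV] = 1.0
    scale = max(1.0, abs(opt))
    cap = LinearConstraint(model.costs[None, :], -np.inf, opt + 1e-7 * scale)
    res2 = _run_milp(model, aux, extra=[cap])
    return int(round(float(aux @ np.round(res2.x))))


def exhaustive_solve(graph: CandidateGraph, params: SolverParams) -> Selection:
    """Brute-force optimum by enumeration over all edge subsets.

    Independent of the MILP path: feasibility (at most one selected parent
    and two selected children per node) is tested with bit arithmetic, the
    auxiliaries are derived analytically (the constraints determine y^T and
    y^D uniquely given y), and isolated nodes are selected exactly when
    their standalone cost ``c^V + c^T`` is negative.  Intended for instances
    with at most ~20 edges.
    """
    g = graph.graph
    node_ids = sorted(g.nodes)
    edge_list = sorted(g.edges)
    nE = len(edge_list)
    if nE > 22:
        raise ValueError(f"{nE} edges is too many for exhaustive enumeration")
    e_of = {e: k for k, e in enumerate(edge_list)}
    ecost = np.array(
        [edge_cost(g.edges[e]["distance"], params) for e in edge_list]
    )
    ncost = {v: node_cost(g.nodes[v]["score"], params) for v in node_ids}

    subs = np.arange(1 << nE, dtype=np.uint32)
    feasible = np.ones(subs.shape, dtype=bool)
    total = np.zeros(subs.shape)

    # per-edge cost contribution
    for k in range(nE):
        total += ((subs >> np.uint32(k)) & np.uint32(1)).astype(float) * ecost[k]

    for v in node_ids:
        in_mask = np.uint32(0)
        for c in g.predecessors(v):
            in_mask |= np.uint32(1 << e_of[(c, v)])
        out_mask = np.uint32(0)
        for p in g.successors(v):
            out_mask |= np.uint32(1 << e_of[(v, p)])
        n_in = np.bitwise_count(subs & in_mask).astype(np.int64)
        n_out = np.bitwise_count(subs & out_mask).astype(np.int64)
        feasible &= (n_out <= 1) & (n_in <= 2)
        incident = (n_in + n_out) > 0
        # incident nodes are forced selected; y^T when no selected parent edge
        total += np.where(incident, ncost[v], 0.0)
        total += np.where(incident & (n_out == 0), params.c_track, 0.0)
        total += np.where(n_in == 2, params.c_division, 0.0)
        # isolated nodes join only if profitable on their own
        standalone = min(0.0, ncost[v] + params.c_track)
        total += np.where(~incident, standalone, 0.0)

    total[~feasible] = np.inf
    best = int(np.argmin(total))
    best_mask = int(subs[best])

    sel = Selection(objective=float(total[best]))
    sel.edges = {edge_list[k] for k in range(nE) if best_mask >> k & 1}
    incident_nodes = {v for e in sel.edges for v in e}
    lone = {
        v for v in node_ids
        if v not in incident_nodes and ncost[v] + params.c_track < 0
    }
    sel.nodes = incident_nodes | lone
    with_parent_edge = {v for (v, _u) in sel.edges}
    sel.track_starts = sel.nodes - with_parent_edge
    child_count: dict = {}
    for (v, u) in sel.edges:
        child_count[u] = child_count.get(u, 0) + 1
    sel.divisions = {v for v, c in child_count.items() if c == 2}
    return sel


def selection_to_forest(graph: CandidateGraph, selection: Selection) -> LineageForest:
    """Materialize a selection as a lineage forest (validated)."""
    from .verify import verify_selection

    verify_selection(graph, selection)
    g = graph.graph
    forest = LineageForest()
    parent_of = {v: u for (v, u) in selection.edges}
    for v in sorted(selection.nodes):
        d = g.nodes[v]
        forest.add_node(v, d["t"], d["position"], parent_id=parent_of.get(v))
    forest.validate()
    return forest
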