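"""Evaluation against sparse ground truth, greedy baseline, and grid search.

Because ground truth is sparse (only some lineages are annotated), false
positive edges cannot be scored -- an unmatched reconstruction may be a real
but unannotated cell.  Errors are therefore counted per ground-truth edge:

- FN (false negative edge): a ground-truth link not reconstructed;
- IS (identity switch): a ground-truth link whose reconstructed child
  continues into a *different* tracked cell, i.e. two reconstructed tracks
  swap which cell they follow;
- FP-D (false positive division): a division reconstructed at a matched
  node where the ground truth shows none;
- FN-D (false negative division): a ground-truth division not reproduced.

Ground-truth and reconstructed nodes are put in correspondence per frame by
optimal bipartite assignment (Hungarian algorithm) restricted to a hard
matching radius.  The fraction of error-free tracks of a given length is
computed over sliding windows along division-free ground-truth tracklets.

A greedy per-frame nearest-neighbor linker (in the spirit of per-frame
tracking platforms that link each detection to its closest predicted
predecessor) serves as the baseline the global ILP is compared against, and
a grid search over the ILP cost parameters -- with the division cost fixed
at 1 to remove the objective's scale redundancy -- selects the parameter
set minimizing the summed error count on a validation region.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .candidates import CandidateGraph
from .forest import LineageForest
from .tracking import SolverParams, selection_to_forest, solve

__all__ = [
    "Matching",
    "EvalReport",
    "match_nodes",
    "count_errors",
    "error_free_fraction",
    "evaluate",
    "greedy_track",
    "grid_search",
]


@dataclass
class Matching:
    """Per-frame injective map from ground-truth to reconstructed nodes."""

    gt_to_rec: dict = field(default_factory=dict)
    radius: float = 0.0

    def rec_to_gt(self) -> dict:
        return {r: g for g, r in self.gt_to_rec.items()}


def match_nodes(gt: LineageForest, rec: LineageForest, radius: float) -> Matching:
    """Optimal one-to-one assignment of nodes per frame within ``radius``.

    For each frame, the Hungarian algorithm minimizes total matched distance
    over the bipartite graph of (ground-truth, reconstructed) pairs closer
    than ``radius``; pairs beyond the radius are never matched.
    """
    matching = Matching(radius=radius)
    frames = sorted(set(n.t for n in gt.nodes.values()))
    big = 1e9
    for t in frames:
        gnodes = gt.nodes_at(t)
        rnodes = rec.nodes_at(t)
        if not gnodes or not rnodes:
            continue
        gpos = np.array([n.position for n in gnodes])
        rpos = np.array([n.position for n in rnodes])
        dist = np.linalg.norm(gpos[:, None, :] - rpos[None, :, :], axis=2)
        cost = np.where(dist <= radius, dist, big)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if dist[i, j] <= radius:
                matching.gt_to_rec[gnodes[i].node_id] = rnodes[j].node_id
    return matching


@dataclass
class EvalReport:
    """Error counts, per-ground-truth-edge rates, and track-level fractions."""

    fn: int = 0
    identity_switches: int = 0
    fp_divisions: int = 0
    fn_divisions: int = 0
    n_gt_edges: int = 0
    n_gt_nodes: int = 0
    n_matched: int = 0
    error_free: dict = field(default_factory=dict)  # length -> fraction
    n_segments: dict = field(default_factory=dict)  # length -> #windows

    @property
    def total_errors(self) -> int:
        return self.fn + self.identity_switches + self.fp_divisions + self.fn_divisions

    def rates(self) -> dict:
        d = max(self.n_gt_edges, 1)
        return {
            "fn": self.fn / d,
            "identity_switches": self.identity_switches / d,
            "fp_divisions": self.fp_divisions / d,
            "fn_divisions": self.fn_divisions / d,
        }

    def to_dict(self) -> dict:
        return {
            "counts": {
                "fn": self.fn,
                "identity_switches": self.identity_switches,
                "fp_divisions": self.fp_divisions,
                "fn_divisions": self.fn_divisions,
                "total": self.total_errors,
            },
            "rates": self.rates(),
            "n_gt_edges": self.n_gt_edges,
            "n_gt_nodes": self.n_gt_nodes,
            "n_matched": self.n_matched,
            "error_free_fraction": {str(k): v for k, v in self.error_free.items()},
            "n_segments": {str(k): v for k, v in self.n_segments.items()},
        }


def _edge_status(
    gt: LineageForest, rec: LineageForest, matching: Matching, child: int, parent: int
) -> str:
    """Classify one ground-truth edge as 'correct', 'fn', or 'is'."""
    m = matching.gt_to_rec
    rc, rp = m.get(child), m.get(parent)
    if rc is None or rp is None:
        return "fn"
    if rec.parent.get(rc) == rp:
        return "correct"
    rec_parent = rec.parent.get(rc)
    if rec_parent is not None and rec_parent in matching.rec_to_gt():
        # the reconstructed track continues, but into a different annotated
        # cell: the two tracks have switched identities
        return "is"
    return "fn"


def count_errors(
    gt: LineageForest, rec: LineageForest, matching: Matching
) -> EvalReport:
    """Count FN, IS, FP-D and FN-D over all ground-truth edges and divisions."""
    report = EvalReport(
        n_gt_edges=gt.n_edges,
        n_gt_nodes=len(gt),
        n_matched=len(matching.gt_to_rec),
    )
    rec_children: dict = {}
    for c, p in rec.parent.items():
        rec_children[p] = rec_children.get(p, 0) + 1

    for child, parent in gt.parent.items():
        status = _edge_status(gt, rec, matching, child, parent)
        if status == "fn":
            report.fn += 1
        elif status == "is":
            report.identity_switches += 1

    gt_children = gt.children_map()
    r2g = matching.rec_to_gt()
    for g, r in matching.gt_to_rec.items():
        if rec_children.get(r, 0) == 2 and len(gt_children[g]) < 2:
            report.fp_divisions += 1
    for g, cs in gt_children.items():
        if len(cs) == 2:
            r = matching.gt_to_rec.get(g)
            if r is None or rec_children.get(r, 0) != 2:
                report.fn_divisions += 1
    return report


def _window_error_free(
    gt: LineageForest,
    rec: LineageForest,
    matching: Matching,
    window: list[int],
    gt_children: dict,
    rec_children: dict,
) -> bool:
    m = matching.gt_to_rec
    for g in window:
        r = m.get(g)
        if r is None:
            return False
        if rec_children.get(r, 0) == 2 and len(gt_children[g]) < 2:
            return False  # spurious division on the segment
        if len(gt_children[g]) == 2 and rec_children.get(r, 0) != 2:
            return False  # missed division at the segment end
    for child, parent in zip(window[1:], window[:-1]):
        if _edge_status(gt, rec, matching, child, parent) != "correct":
            return False
    return True


def error_free_fraction(
    gt: LineageForest,
    rec: LineageForest,
    matching: Matching,
    lengths: list[int],
) -> tuple[dict, dict]:
    """Fraction of error-free ground-truth track segments per length.

    A segment of length ``L`` is a window of ``L`` consecutive nodes on a
    division-free ground-truth tracklet (divisions end tracklets); it is
    error-free when every node is matched, every edge along it is correctly
    reconstructed, and no division error (spurious or missed) occurs on it.
    Returns ``(fractions, n_segments)`` keyed by length.  The fraction is
    non-increasing in L whenever all tracklets are at least as long as the
    largest queried L; shorter tracklets drop out of the denominator.
    """
    gt_children = gt.children_map()
    rec_children: dict = {}
    for c, p in rec.parent.items():
        rec_children[p] = rec_children.get(p, 0) + 1
    tracklets = gt.tracklets()
    fractions: dict = {}
    counts: dict = {}
    for L in lengths:
        if L < 1:
            raise ValueError("segment length must be >= 1")
        good = total = 0
        for tr in tracklets:
            for i in range(0, len(tr) - L + 1):
                total += 1
                if _window_error_free(
                    gt, rec, matching, tr[i : i + L], gt_children, rec_children
                ):
                    good += 1
        fractions[L] = good / total if total else float("nan")
        counts[L] = total
    return fractions, counts


def evaluate(
    gt: LineageForest,
    rec: LineageForest,
    radius: float,
    lengths: list[int] | None = None,
) -> EvalReport:
    """Match, count errors, and compute error-free fractions in one call."""
    matching = match_nodes(gt, rec, radius)
    report = count_errors(gt, rec, matching)
    if lengths:
        report.error_free, report.n_segments = error_free_fraction(
            gt, rec, matching, lengths
        )
    return report


def greedy_track(
    graph: CandidateGraph,
    radius: float,
    axis_weights=(1.0, 1.0, 1.0),
) -> LineageForest:
    """Per-frame nearest-neighbor baseline (no global optimization).

    Every candidate detection becomes a node.  Frame by frame, detections
    (processed in descending score order, ties by node id) link to the
    nearest previous-frame detection within ``radius`` of their predicted
    location ``l_v + m_v``, skipping predecessors that already have two
    children.  The output is a valid binary forest, but nothing discourages
    spurious divisions or rewards continuity -- the contrast with the ILP.
    """
    g = graph.graph
    forest = LineageForest()
    for n in sorted(g.nodes):
        d = g.nodes[n]
        forest.add_node(n, d["t"], d["position"])
    w = np.asarray(axis_weights, dtype=float)
    frames = graph.frames()
    if not frames:
        return forest
    n_children: dict = {}
    for t in frames:
        if t == frames[0]:
            continue
        prev = [(u, g.nodes[u]["position"] * w) for u in graph.nodes_at(t - 1)]
        if not prev:
            continue
        order = sorted(
            graph.nodes_at(t), key=lambda v: (-g.nodes[v]["score"], v)
        )
        for v in order:
            predicted = (g.nodes[v]["position"] + g.nodes[v]["movement"]) * w
            best, best_d = None, radius
            for u, upos in prev:
                if n_children.get(u, 0) >= 2:
                    continue
                d2 = float(np.linalg.norm(predicted - upos))
                if d2 < best_d or (best is not None and d2 == best_d and u < best):
                    best, best_d = u, d2
            if best is not None:
                forest.parent[v] = best
                n_children[best] = n_children.get(best, 0) + 1
    forest.validate()
    return forest


def _restrict_graph(graph: CandidateGraph, region) -> CandidateGraph:
    t0, t1 = region
    keep = [n for n, d in graph.graph.nodes(data=True) if t0 <= d["t"] < t1]
    return CandidateGraph(graph.graph.subgraph(keep).copy())


def _restrict_forest(forest: LineageForest, region) -> LineageForest:
    t0, t1 = region
    out = LineageForest()
    for n in sorted(forest.nodes):
        node = forest.nodes[n]
        if t0 <= node.t < t1:
            par = forest.parent.get(n)
            if par is not None and not (t0 <= forest.nodes[par].t < t1):
                par = None
            out.add_node(n, node.t, node.position, parent_id=par)
    return out


def grid_search(
    graph: CandidateGraph,
    gt: LineageForest,
    param_grid: dict,
    radius: float,
    validation_region: tuple[int, int] | None = None,
    base_params: SolverParams | None = None,
) -> tuple[SolverParams, pd.DataFrame]:
    """Exhaustive search over ILP cost parameters on a validation region.

    ``param_grid`` maps :class:`SolverParams` field names (``c_track``,
    ``tau_node``, ``w_node``, ``w_edge``) to candidate values; the division
    cost is fixed at 1 to eliminate redundant rescalings of the objective.
    Every grid point is solved and scored by the summed error count
    (FN + IS + FP-D + FN-D); the first minimizer in grid order wins.  Grid
    points where the solver fails are recorded with a NaN score and skipped.

    ``graph`` and ``gt`` may be lists of equal length: the validation set
    then comprises several instances, and each grid point is scored by the
    errors summed over all of them.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    graphs = graph if isinstance(graph, (list, tuple)) else [graph]
    gts = gt if isinstance(gt, (list, tuple)) else [gt]
    if len(graphs) != len(gts):
        raise ValueError("graph and gt validation lists differ in length")
    if validation_region is not None:
        graphs = [_restrict_graph(g, validation_region) for g in graphs]
        gts = [_restrict_forest(f, validation_region) for f in gts]
    base = base_params or SolverParams()
    keys = list(param_grid)
    rows = []
    best_params, best_score, best_idx = None, np.inf, None
    for idx, values in enumerate(itertools.product(*(param_grid[k] for k in keys))):
        params = replace(base, c_division=1.0, **dict(zip(keys, values)))
        row = dict(zip(keys, values))
        row["c_division"] = 1.0
        try:
            counts: dict = {}
            score = 0
            for g, f in zip(graphs, gts):
                rec = selection_to_forest(g, solve(g, params))
                report = evaluate(f, rec, radius)
                for k, v in report.to_dict()["counts"].items():
                    counts[k] = counts.get(k, 0) + v
                score += report.total_errors
            row.update(counts)
        except Exception as exc:  # noqa: BLE001 - record failed grid points
            row["error"] = str(exc)
            score = np.nan
        row["total_errors"] = score
        rows.append(row)
        if not np.isnan(score) and score < best_score:
            best_params, best_score, best_idx = params, score, idx
    table = pd.DataFrame(rows)
    if best_params is None:
        raise RuntimeError("every grid point failed")
    return best_params, table
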