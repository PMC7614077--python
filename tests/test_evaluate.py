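"""Evaluation metrics: matching, error taxonomy, track fractions, baselines."""

import numpy as np
import pytest

from ilptrack import (
    CandidateGraph,
    LineageForest,
    SolverParams,
    evaluate,
    greedy_track,
    grid_search,
    match_nodes,
    selection_to_forest,
    solve,
)
from ilptrack.evaluate import count_errors, error_free_fraction


def straight_track(start_id=0, n=5, x0=0.0, parentless_first=True):
    f = LineageForest()
    for i in range(n):
        f.add_node(
            start_id + i,
            i,
            (5.0, 5.0, x0 + i),
            parent_id=None if (i == 0 and parentless_first) else start_id + i - 1,
        )
    return f


def merge_forests(*forests):
    out = LineageForest()
    for f in forests:
        for n in sorted(f.nodes):
            node = f.nodes[n]
            out.add_node(n, node.t, node.position, parent_id=f.parent.get(n))
    return out


def test_identical_forests_match_perfectly():
    gt = straight_track(n=6)
    m = match_nodes(gt, gt, radius=2.0)
    assert m.gt_to_rec == {i: i for i in range(6)}
    report = count_errors(gt, gt, m)
    assert report.total_errors == 0


def test_empty_reconstruction_matches_nothing():
    gt = straight_track(n=4)
    m = match_nodes(gt, LineageForest(), radius=2.0)
    assert m.gt_to_rec == {}
    report = count_errors(gt, LineageForest(), m)
    assert report.fn == gt.n_edges


def test_crossing_assignment_is_globally_optimal():
    # two GT nodes and two rec nodes in a crossing configuration: the
    # Hungarian assignment must pick the pairing with smaller total distance
    gt = LineageForest()
    gt.add_node(0, 0, (0.0, 0.0, 0.0))
    gt.add_node(1, 0, (0.0, 0.0, 4.0))
    rec = LineageForest()
    rec.add_node(10, 0, (0.0, 0.0, 1.0))
    rec.add_node(11, 0, (0.0, 0.0, 3.5))
    m = match_nodes(gt, rec, radius=4.0)
    pairings = {
        frozenset({(0, 10), (1, 11)}): 1.0 + 0.5,
        frozenset({(0, 11), (1, 10)}): 3.5 + 3.0,
    }
    best = min(pairings, key=pairings.get)
    assert frozenset(m.gt_to_rec.items()) == best


def test_missing_middle_edge_is_single_fn():
    gt = straight_track(n=5)
    rec = straight_track(start_id=0, n=5)
    del rec.parent[2]  # drop edge 2->1
    m = match_nodes(gt, rec, radius=1.0)
    report = count_errors(gt, rec, m)
    assert (report.fn, report.identity_switches) == (1, 0)
    assert report.fp_divisions == 0 and report.fn_divisions == 0


def test_identity_switch_counted_on_crossing_tracks():
    # two parallel GT tracks; reconstruction swaps parents at frame 2
    gt = merge_forests(straight_track(0, 4, x0=0.0), straight_track(10, 4, x0=4.0))
    rec = merge_forests(straight_track(0, 4, x0=0.0), straight_track(10, 4, x0=4.0))
    rec.parent[2] = 11  # track A continues from track B's cell
    rec.parent[12] = 1  # and vice versa
    m = match_nodes(gt, rec, radius=1.0)
    report = count_errors(gt, rec, m)
    assert report.identity_switches == 2
    assert report.fn == 0


def test_division_errors_both_ways():
    # GT: mother 0 divides into 1, 2 at t=1
    gt = LineageForest()
    gt.add_node(0, 0, (5.0, 5.0, 5.0))
    gt.add_node(1, 1, (5.0, 5.0, 3.0), parent_id=0)
    gt.add_node(2, 1, (5.0, 5.0, 7.0), parent_id=0)
    # rec misses the division entirely (one daughter only)
    rec = LineageForest()
    rec.add_node(0, 0, (5.0, 5.0, 5.0))
    rec.add_node(1, 1, (5.0, 5.0, 3.0), parent_id=0)
    m = match_nodes(gt, rec, radius=1.0)
    report = count_errors(gt, rec, m)
    assert report.fn_divisions == 1 and report.fp_divisions == 0
    assert report.fn == 1  # the unmatched daughter's edge
    # symmetric case: rec invents a division
    m2 = match_nodes(rec, gt, radius=1.0)
    report2 = count_errors(rec, gt, m2)
    assert report2.fp_divisions == 1 and report2.fn_divisions == 0


def test_error_free_fraction_perfect_and_broken():
    gt = straight_track(n=10)
    m = match_nodes(gt, gt, radius=1.0)
    frac, counts = error_free_fraction(gt, gt, m, [5, 10])
    assert frac == {5: 1.0, 10: 1.0}
    assert counts == {5: 6, 10: 1}
    rec = straight_track(n=10)
    del rec.parent[5]
    m = match_nodes(gt, rec, radius=1.0)
    frac, _ = error_free_fraction(gt, rec, m, [10])
    assert frac[10] == 0.0


def test_error_free_fraction_hand_computed_fixture():
    # ten 12-frame tracks; break one edge in tracks 0..3 at child frame 6
    tracks = [straight_track(100 * i, 12, x0=6.0 * i) for i in range(10)]
    gt = merge_forests(*tracks)
    rec = merge_forests(*tracks)
    for i in range(4):
        del rec.parent[100 * i + 6]
    m = match_nodes(gt, rec, radius=1.0)
    frac, counts = error_free_fraction(gt, rec, m, [4, 12])
    # L=12: 1 window per track, broken in 4 of 10
    assert frac[12] == pytest.approx(0.6)
    # L=4: 9 windows per track; a window [i, i+3] contains the broken edge
    # (5 -> 6) iff i in {3, 4, 5} -> 3 bad windows in each broken track
    assert counts[4] == 90
    assert frac[4] == pytest.approx((90 - 12) / 90)


def test_error_free_fraction_non_increasing_in_length():
    rng = np.random.default_rng(5)
    tracks = [straight_track(100 * i, 15, x0=6.0 * i) for i in range(6)]
    gt = merge_forests(*tracks)
    rec = merge_forests(*tracks)
    for child in list(rec.parent):
        if rng.uniform() < 0.1:
            del rec.parent[child]
    m = match_nodes(gt, rec, radius=1.0)
    lengths = list(range(1, 16))
    frac, _ = error_free_fraction(gt, rec, m, lengths)
    values = [frac[L] for L in lengths]
    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


def test_greedy_recovers_well_separated_tracks():
    g = CandidateGraph()
    nid = 0
    for t in range(5):
        for k in range(3):
            g.add_node(nid, t, (5.0, 5.0 + 10 * k, 5.0 + t), 1.0, (0, 0, -1.0))
            nid += 1
    forest = greedy_track(g, radius=3.0)
    forest.validate()
    assert forest.n_edges == 12
    assert len(forest.tracklets()) == 3


def test_greedy_respects_binary_forest_limits():
    # five frame-1 nodes all pointing at one frame-0 node: at most 2 link
    g = CandidateGraph()
    g.add_node(0, 0, (5.0, 5.0, 5.0), 1.0)
    for i in range(1, 6):
        g.add_node(i, 1, (5.0, 5.0, 4.0 + i), 1.0, (0.0, 0.0, 5.0 - (4.0 + i)))
    forest = greedy_track(g, radius=6.0)
    forest.validate()
    assert sum(1 for p in forest.parent.values() if p == 0) == 2


def test_greedy_errs_on_false_blob_where_ilp_does_not():
    # ground truth: one cell moving (5,5,5) -> (5,5,7); a low-score false
    # blob near the parent links greedily (spurious division) but is not
    # worth its division cost to the ILP
    gt = LineageForest()
    gt.add_node(0, 0, (5.0, 5.0, 5.0))
    gt.add_node(1, 1, (5.0, 5.0, 7.0), parent_id=0)
    g = CandidateGraph()
    g.add_node(0, 0, (5.0, 5.0, 5.0), 1.0)
    g.add_node(1, 1, (5.0, 5.0, 7.0), 1.0, (0.0, 0.0, -2.0))
    g.add_node(2, 1, (5.0, 5.0, 3.0), 0.5, (0.0, 0.0, 0.0))  # false blob
    for v, u in [(1, 0), (2, 0)]:
        pred = g.graph.nodes[v]["position"] + g.graph.nodes[v]["movement"]
        d2 = float(np.sum((pred - g.graph.nodes[u]["position"]) ** 2))
        g.add_edge(v, u, d2)
    ilp = selection_to_forest(g, solve(g, SolverParams()))
    greedy = greedy_track(g, radius=5.0)
    m_ilp = match_nodes(gt, ilp, radius=1.0)
    m_greedy = match_nodes(gt, greedy, radius=1.0)
    assert count_errors(gt, ilp, m_ilp).total_errors == 0
    greedy_report = count_errors(gt, greedy, m_greedy)
    assert greedy_report.fp_divisions == 1
    assert greedy_report.total_errors > 0


def test_grid_search_single_point_and_argmin(small_sim, small_graph):
    _, forest, *_ = small_sim
    single = {"c_track": [2.0]}
    best, table = grid_search(small_graph, forest, single, radius=3.0)
    assert best.c_track == 2.0 and best.c_division == 1.0
    assert len(table) == 1

    grid = {"c_track": [0.5, 2.0], "w_edge": [0.01, 0.1]}
    best, table = grid_search(small_graph, forest, grid, radius=3.0)
    assert len(table) == 4
    # independent recomputation of every cell
    scores = []
    for _, row in table.iterrows():
        params = SolverParams(
            c_track=row.c_track, w_edge=row.w_edge, c_division=1.0
        )
        rec = selection_to_forest(small_graph, solve(small_graph, params))
        scores.append(evaluate(forest, rec, 3.0).total_errors)
    assert list(table.total_errors) == scores
    assert best.c_track == table.c_track[int(np.argmin(scores))]
    assert min(scores) == evaluate(
        forest,
        selection_to_forest(small_graph, solve(small_graph, best)),
        3.0,
    ).total_errors


def test_grid_search_empty_grid_rejected(small_sim, small_graph):
    _, forest, *_ = small_sim
    with pytest.raises(ValueError):
        grid_search(small_graph, forest, {}, radius=3.0)
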