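"""Lineage ILP: cost formulas, constraint matrix, oracle equivalence."""

import numpy as np
import pytest

from ilptrack import (
    CandidateGraph,
    Selection,
    SolverParams,
    exhaustive_solve,
    selection_to_forest,
    solve,
    verify_selection,
)
from ilptrack.testing import random_candidate_graph, random_solver_params
from ilptrack.tracking import (
    build_ilp,
    edge_cost,
    min_auxiliary_at_optimum,
    node_cost,
)
from ilptrack.verify import ConstraintViolation, selection_objective


def chain_graph(n, score=1.0, distance=0.0):
    g = CandidateGraph()
    for t in range(n):
        g.add_node(t, t, (0.0, 0.0, float(t)), score)
    for t in range(1, n):
        g.add_edge(t, t - 1, distance)
    return g


def test_node_cost_formula():
    p = SolverParams(tau_node=1.0, w_node=-2.0)
    assert node_cost(1.0, p) == pytest.approx(-1.0)
    assert node_cost(0.0, p) == pytest.approx(1.0)
    assert node_cost(0.7, SolverParams(tau_node=0.5, w_node=0.0)) == 0.5


def test_edge_cost_formula():
    p = SolverParams(w_edge=0.1)
    assert edge_cost(4.0, p) == pytest.approx(0.4)
    assert edge_cost(0.0, p) == 0.0
    assert edge_cost(8.0, p) == pytest.approx(2 * edge_cost(4.0, p))


def test_build_ilp_tiny_instance_matrix():
    g = chain_graph(2)
    model = build_ilp(g, SolverParams())
    # 2 node + 1 edge + 2 track-start + 2 division variables
    assert model.n_vars == 7
    # 1 edge-consistency row + 4 rows per node
    assert model.A.shape == (9, 7)
    A = model.A.toarray()
    iv, iu = model.var_index("node", 1), model.var_index("node", 0)
    ie = model.var_index("edge", (1, 0))
    # edge consistency 2 y_e - y_v - y_u <= 0
    row = A[0]
    assert row[ie] == 2 and row[iv] == -1 and row[iu] == -1
    assert model.ub[0] == 0 and model.lb[0] == -np.inf
    # continuation for the child node: y_e(out) + y^T - y_v = 0
    it1 = model.var_index("track", 1)
    cont = [
        r for r in range(9)
        if model.lb[r] == 0 and model.ub[r] == 0 and A[r][it1] == 1
    ]
    assert len(cont) == 1
    assert A[cont[0]][ie] == 1 and A[cont[0]][iv] == -1


def test_build_ilp_empty_graph():
    model = build_ilp(CandidateGraph(), SolverParams())
    assert model.n_vars == 0
    assert solve(CandidateGraph(), SolverParams()).objective == 0.0


def test_three_incoming_edges_rejected_by_verifier():
    g = CandidateGraph()
    g.add_node(0, 0, (0, 0, 0), 1.0)
    for i in range(1, 4):
        g.add_node(i, 1, (0, 0, i), 1.0)
        g.add_edge(i, 0, 0.0)
    sel = Selection(
        nodes={0, 1, 2, 3},
        edges={(1, 0), (2, 0), (3, 0)},
        track_starts={0},
        divisions={0},
    )
    with pytest.raises(ConstraintViolation, match="children"):
        verify_selection(g, sel)


def test_unprofitable_graph_selects_nothing():
    g = chain_graph(3, score=0.0, distance=10.0)
    p = SolverParams(c_track=1.0, tau_node=1.0, w_node=-1.0, w_edge=1.0)
    sel = solve(g, p)
    assert sel.nodes == set() and sel.edges == set()
    assert sel.objective == 0.0


def test_profitable_chain_fully_selected():
    g = chain_graph(3)
    p = SolverParams(c_track=0.5, c_division=1.0, tau_node=0.0, w_node=-1.0, w_edge=1.0)
    sel = solve(g, p)
    assert sel.nodes == {0, 1, 2}
    assert sel.edges == {(1, 0), (2, 1)}
    assert sel.track_starts == {0}
    assert sel.divisions == set()
    assert sel.objective == pytest.approx(-2.5)
    assert exhaustive_solve(g, p).objective == pytest.approx(-2.5)


def test_solver_matches_exhaustive_oracle_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(60):
        g = random_candidate_graph(rng)
        p = random_solver_params(rng)
        sel = solve(g, p)
        verify_selection(g, sel)
        oracle = exhaustive_solve(g, p)
        assert sel.objective == pytest.approx(oracle.objective, abs=1e-6)
        assert selection_objective(g, sel, p) == pytest.approx(sel.objective, abs=1e-6)


def test_division_cost_sweep_monotone():
    rng = np.random.default_rng(3)
    g = random_candidate_graph(rng, n_frames=4, max_nodes_per_frame=4, max_edges=20)
    base = SolverParams(c_track=0.2, tau_node=0.0, w_node=-2.0, w_edge=0.05)
    counts = [
        min_auxiliary_at_optimum(
            g,
            SolverParams(**{**base.__dict__, "c_division": c}),
            which="division",
        )
        for c in [0.0, 0.5, 1.0, 2.0, 4.0]
    ]
    assert counts == sorted(counts, reverse=True)


def test_track_cost_sweep_monotone():
    rng = np.random.default_rng(4)
    g = random_candidate_graph(rng, n_frames=4, max_nodes_per_frame=4, max_edges=20)
    base = SolverParams(c_division=1.0, tau_node=0.0, w_node=-2.0, w_edge=0.05)
    counts = [
        min_auxiliary_at_optimum(
            g,
            SolverParams(**{**base.__dict__, "c_track": c}),
            which="track",
        )
        for c in [0.0, 0.5, 1.0, 2.0, 4.0]
    ]
    assert counts == sorted(counts, reverse=True)


def test_pinned_assignments_respected():
    g = chain_graph(3)
    p = SolverParams(c_track=0.5, tau_node=0.0, w_node=-1.0, w_edge=1.0)
    sel = solve(g, p, pinned={"nodes": {2: 0}})
    assert 2 not in sel.nodes
    verify_selection(g, sel)
    sel2 = solve(g, p, pinned={"edges": {(1, 0): 1}})
    assert (1, 0) in sel2.edges and {0, 1} <= sel2.nodes
    with pytest.raises(KeyError):
        solve(g, p, pinned={"nodes": {99: 1}})


def test_negative_division_cost_warns():
    with pytest.warns(UserWarning, match="c_division"):
        SolverParams(c_division=-1.0)


def test_selection_to_forest_valid_and_faithful():
    g = chain_graph(4)
    p = SolverParams(c_track=0.5, tau_node=0.0, w_node=-1.0, w_edge=1.0)
    forest = selection_to_forest(g, solve(g, p))
    forest.validate()
    assert len(forest) == 4 and forest.n_edges == 3
    bad = Selection(nodes={0, 1}, edges={(1, 0)}, track_starts=set())
    with pytest.raises(ConstraintViolation, match="continuation"):
        selection_to_forest(g, bad)


def test_zero_noise_recovery_is_isomorphic(small_sim, small_graph):
    config, forest, *_ = small_sim
    sel = solve(small_graph, SolverParams())
    rec = selection_to_forest(small_graph, sel)
    assert len(rec) == len(forest)
    assert rec.n_edges == forest.n_edges
    # same positions frame by frame (within voxel rounding)
    for t in forest.frames():
        gt_pos = sorted(map(tuple, np.round([n.position for n in forest.nodes_at(t)])))
        rec_pos = sorted(map(tuple, np.round([n.position for n in rec.nodes_at(t)])))
        assert gt_pos == rec_pos
    assert len(rec.divisions()) == len(forest.divisions())
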