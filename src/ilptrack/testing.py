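"""Utilities for exercising the solver: random instances and random params.

Used by the test suite and the acceptance script to generate small random
candidate graphs (layered by frame, with random backward edges) on which
the MILP solution can be checked against exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np

from .candidates import CandidateGraph
from .tracking import SolverParams

__all__ = ["random_candidate_graph", "random_solver_params"]


def random_candidate_graph(
    rng: np.random.Generator,
    n_frames: int = 3,
    max_nodes_per_frame: int = 4,
    max_edges: int = 16,
    edge_prob: float = 0.5,
) -> CandidateGraph:
    """A random layered candidate graph with backward-in-time edges."""
    g = CandidateGraph()
    nid = 0
    frames: dict[int, list[int]] = {}
    for t in range(n_frames):
        frames[t] = []
        for _ in range(int(rng.integers(1, max_nodes_per_frame + 1))):
            g.add_node(
                nid,
                t,
                rng.uniform(0, 20, 3),
                float(rng.uniform()),
                rng.uniform(-2, 2, 3),
            )
            frames[t].append(nid)
            nid += 1
    n_edges = 0
    for t in range(1, n_frames):
        for v in frames[t]:
            for u in frames[t - 1]:
                if n_edges < max_edges and rng.uniform() < edge_prob:
                    g.add_edge(v, u, float(rng.uniform(0, 25)))
                    n_edges += 1
    return g


def random_solver_params(rng: np.random.Generator) -> SolverParams:
    """Random costs respecting the documented sign conventions."""
    return SolverParams(
        c_track=float(rng.uniform(0, 2)),
        c_division=float(rng.uniform(0, 2)),
        tau_node=float(rng.uniform(-1, 1)),
        w_node=float(rng.uniform(-3, 0)),
        w_edge=float(rng.uniform(0, 0.5)),
    )
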