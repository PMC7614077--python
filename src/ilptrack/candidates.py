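"""Candidate-graph extraction from prediction volumes.

Nodes are placed at local maxima of the cell-indicator volume (non-maximum
suppression with a window a bit smaller than the minimal inter-nucleus
distance, a score threshold, and an optional foreground filter).  Each node
carries the indicator score and the movement vector sampled at its voxel.
Edges point one frame backward in time: node ``v`` at frame ``t`` is
connected to every node ``u`` at ``t - 1`` whose position lies within a
search radius of the predicted location ``l_v + m_v``; the squared
(per-axis-weighted) distance between the predicted and actual position is
stored on the edge as its score.  The graph is deliberately over-complete --
pruning to a consistent lineage forest is the ILP's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter
from scipy.spatial import cKDTree

__all__ = [
    "CandidateParams",
    "CandidateGraph",
    "nms_detect",
    "attach_movement",
    "build_edges",
    "extract_graph",
]


@dataclass
class CandidateParams:
    """Extraction hyperparameters.

    ``edge_radius`` is the search radius in (weighted) voxels around the
    predicted previous-frame location; edges require the *squared* weighted
    distance to be below ``edge_radius ** 2``, so the config stays in
    intuitive distance units while the stored edge score is the squared
    distance.  ``axis_weights`` (z, y, x) rescale axes before distances are
    computed, to account for anisotropic voxel sizes.
    """

    nms_window: tuple[int, int, int] = (5, 5, 5)  # (z, y, x) voxels
    threshold: float = 0.3
    edge_radius: float = 10.0
    axis_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class CandidateGraph:
    """Directed candidate graph; edges point one frame backward in time.

    Backed by a :class:`networkx.DiGraph` whose nodes carry ``t``,
    ``position`` (z, y, x), ``score`` and ``movement``, and whose edges
    (child -> parent) carry ``distance`` (the squared weighted deviation
    from the predicted location).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def frames(self) -> list[int]:
        return sorted({d["t"] for _, d in self.graph.nodes(data=True)})

    def nodes_at(self, t: int) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["t"] == t]

    def add_node(self, node_id, t, position, score, movement=(0.0, 0.0, 0.0)):
        self.graph.add_node(
            node_id,
            t=int(t),
            position=np.asarray(position, dtype=float),
            score=float(score),
            movement=np.asarray(movement, dtype=float),
        )

    def add_edge(self, source, target, distance):
        ts, tt = self.graph.nodes[source]["t"], self.graph.nodes[target]["t"]
        if ts != tt + 1:
            raise ValueError(
                f"edge {source}->{target} must point one frame backward "
                f"({ts} -> {tt})"
            )
        self.graph.add_edge(source, target, distance=float(distance))

    def validate(self) -> None:
        for u, v in self.graph.edges:
            if self.graph.nodes[u]["t"] != self.graph.nodes[v]["t"] + 1:
                raise ValueError(f"edge {u}->{v} does not point one frame backward")

    # -- IO ----------------------------------------------------------------

    def to_dataframes(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nrows = [
            {
                "node_id": n,
                "t": d["t"],
                "z": d["position"][0],
                "y": d["position"][1],
                "x": d["position"][2],
                "score": d["score"],
                "mz": d["movement"][0],
                "my": d["movement"][1],
                "mx": d["movement"][2],
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        erows = [
            {"edge_id": i, "source": u, "target": v, "distance": d["distance"]}
            for i, (u, v, d) in enumerate(sorted(self.graph.edges(data=True)))
        ]
        nodes = pd.DataFrame(
            nrows, columns=["node_id", "t", "z", "y", "x", "score", "mz", "my", "mx"]
        )
        edges = pd.DataFrame(erows, columns=["edge_id", "source", "target", "distance"])
        return nodes, edges

    @classmethod
    def from_dataframes(cls, nodes: pd.DataFrame, edges: pd.DataFrame):
        g = cls()
        for r in nodes.itertuples(index=False):
            g.add_node(int(r.node_id), int(r.t), (r.z, r.y, r.x), r.score, (r.mz, r.my, r.mx))
        for r in edges.itertuples(index=False):
            g.add_edge(int(r.source), int(r.target), float(r.distance))
        return g

    def write_csv(self, nodes_path, edges_path) -> None:
        nodes, edges = self.to_dataframes()
        nodes.to_csv(nodes_path, index=False)
        edges.to_csv(edges_path, index=False)

    @classmethod
    def read_csv(cls, nodes_path, edges_path):
        return cls.from_dataframes(
            pd.read_csv(nodes_path, float_precision="round_trip"),
            pd.read_csv(edges_path, float_precision="round_trip"),
        )


def nms_detect(
    indicator: np.ndarray,
    window: tuple[int, int, int],
    threshold: float,
    foreground: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-maximum-suppression detection on one 3D indicator frame.

    Returns ``(positions, scores)``: integer voxel coordinates (n, 3) of
    voxels that are maximal within the centered ``window`` and score at
    least ``threshold``; detections outside ``foreground`` (if given) are
    dropped.  Equal-valued plateau ties are broken toward the
    lexicographically smallest voxel, so no two detections share a window.
    """
    indicator = np.asarray(indicator)
    window = tuple(int(w) for w in window)
    if any(w < 1 for w in window):
        raise ValueError("window must be at least 1 voxel per axis")
    if any(w > s for w, s in zip(window, indicator.shape)):
        raise ValueError(
            f"NMS window {window} larger than volume {indicator.shape}"
        )
    local_max = indicator == maximum_filter(indicator, size=window, mode="nearest")
    cand = np.argwhere(local_max & (indicator >= threshold))
    # window offsets matching scipy's size-w filter: [-(w//2), (w-1)//2]
    back = [w // 2 for w in window]
    fwd = [(w - 1) // 2 for w in window]
    rank_w = np.array(
        [indicator.shape[1] * indicator.shape[2], indicator.shape[2], 1]
    )
    keep = []
    for p in cand:
        lo = [max(c - b, 0) for c, b in zip(p, back)]
        hi = [min(c + f + 1, s) for c, f, s in zip(p, fwd, indicator.shape)]
        patch = indicator[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        v = indicator[tuple(p)]
        if patch.max() > v:
            continue
        # plateau tie: survive only if lexicographically smallest in window
        ties = np.argwhere(patch == v) + np.array(lo)
        if np.all(ties @ rank_w >= int(p @ rank_w)):
            keep.append(p)
    positions = np.array(keep, dtype=int).reshape(-1, 3)
    if foreground is not None and len(positions):
        fg = np.asarray(foreground).astype(bool)
        inside = fg[tuple(positions.T)]
        positions = positions[inside]
    scores = (
        np.clip(indicator[tuple(positions.T)].astype(float), 0.0, 1.0)
        if len(positions)
        else np.zeros(0)
    )
    return positions, scores


def attach_movement(positions: np.ndarray, movement: np.ndarray) -> np.ndarray:
    """Sample the movement volume (Z, Y, X, 3) at detection voxels.

    Each detection keeps exactly the vector stored at its peak voxel; no
    local averaging is performed.
    """
    positions = np.asarray(positions, dtype=int).reshape(-1, 3)
    if len(positions) == 0:
        return np.zeros((0, 3))
    return np.asarray(movement, dtype=float)[tuple(positions.T)]


def build_edges(
    nodes_t: list[tuple[int, np.ndarray, np.ndarray]],
    nodes_prev: list[tuple[int, np.ndarray]],
    radius: float,
    axis_weights=(1.0, 1.0, 1.0),
) -> list[tuple[int, int, float]]:
    """Connect frame-t candidates to previous-frame candidates near their
    predicted location.

    ``nodes_t`` holds ``(node_id, position, movement)`` triples at frame t;
    ``nodes_prev`` holds ``(node_id, position)`` pairs at frame t - 1.  An
    edge (v, u, d) is emitted for every u whose weighted squared distance d
    to ``position_v + movement_v`` is strictly below ``radius ** 2``.  All
    qualifying predecessors are kept; the ILP prunes later.
    """
    if radius <= 0:
        raise ValueError("edge search radius must be positive")
    if not nodes_t or not nodes_prev:
        return []
    w = np.asarray(axis_weights, dtype=float)
    prev_ids = [n[0] for n in nodes_prev]
    prev_pos = np.array([n[1] for n in nodes_prev], dtype=float) * w
    tree = cKDTree(prev_pos)
    edges = []
    for nid, pos, mov in nodes_t:
        predicted = (np.asarray(pos, dtype=float) + np.asarray(mov, dtype=float)) * w
        for j in tree.query_ball_point(predicted, r=radius):
            d2 = float(np.sum((predicted - prev_pos[j]) ** 2))
            if d2 < radius**2:
                edges.append((nid, prev_ids[j], d2))
    return edges


def extract_graph(
    indicator: np.ndarray,
    movement: np.ndarray,
    params: CandidateParams,
    foreground: np.ndarray | None = None,
) -> CandidateGraph:
    """Run detection and edge construction over all frames.

    ``indicator`` is (T, Z, Y, X); ``movement`` is (T, Z, Y, X, 3);
    ``foreground`` optionally (T, Z, Y, X).
    """
    graph = CandidateGraph()
    next_id = 0
    per_frame: dict[int, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    for t in range(indicator.shape[0]):
        fg = foreground[t] if foreground is not None else None
        positions, scores = nms_detect(
            indicator[t], params.nms_window, params.threshold, fg
        )
        movements = attach_movement(positions, movement[t])
        frame_nodes = []
        for pos, s, mov in zip(positions, scores, movements):
            graph.add_node(next_id, t, pos, s, mov)
            frame_nodes.append((next_id, pos.astype(float), mov))
            next_id += 1
        per_frame[t] = frame_nodes
    for t in range(1, indicator.shape[0]):
        prev = [(nid, pos) for nid, pos, _ in per_frame.get(t - 1, [])]
        for v, u, d2 in build_edges(
            per_frame.get(t, []), prev, params.edge_radius, params.axis_weights
        ):
            graph.add_edge(v, u, d2)
    graph.validate()
    return graph
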