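"""Lineage forests: the ground-truth and output structure of the tracker.

A lineage forest is a set of nodes, each living at an integer frame ``t`` with
a 3D position ``(z, y, x)`` in voxel units, connected by parent edges that
always point exactly one frame backward in time.  Every node has at most one
parent and at most two children, so the structure is a binary forest -- the
feasible set of the lineage-selection ILP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ForestNode", "LineageForest", "ForestValidationError"]


class ForestValidationError(ValueError):
    """Raised when a structure violates the binary-forest invariants."""


@dataclass
class ForestNode:
    node_id: int
    t: int
    position: np.ndarray  # (z, y, x) voxel units, float
    radius: float | None = None
    exited: bool = False  # left the field of view after this frame

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector (z, y, x)")


@dataclass
class LineageForest:
    """Binary forest of cell positions over time.

    ``parent`` maps a child node id to its parent node id; the parent is
    always at the child's frame minus one.  Track starts have no entry.
    """

    nodes: dict[int, ForestNode] = field(default_factory=dict)
    parent: dict[int, int] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    def add_node(
        self,
        node_id: int,
        t: int,
        position,
        parent_id: int | None = None,
        radius: float | None = None,
    ) -> ForestNode:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id}")
        node = ForestNode(node_id, int(t), np.asarray(position, dtype=float), radius)
        self.nodes[node_id] = node
        if parent_id is not None and parent_id >= 0:
            self.parent[node_id] = parent_id
        return node

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.parent)

    def children(self, node_id: int) -> list[int]:
        return [c for c, p in self.parent.items() if p == node_id]

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {n: [] for n in self.nodes}
        for c, p in self.parent.items():
            out[p].append(c)
        return out

    def roots(self) -> list[int]:
        return [n for n in self.nodes if n not in self.parent]

    def divisions(self) -> list[int]:
        """Node ids with exactly two children."""
        return [n for n, cs in self.children_map().items() if len(cs) == 2]

    def frames(self) -> list[int]:
        return sorted({n.t for n in self.nodes.values()})

    def nodes_at(self, t: int) -> list[ForestNode]:
        return [n for n in self.nodes.values() if n.t == t]

    def tracklets(self) -> list[list[int]]:
        """Maximal division-free paths, ordered by time.

        A tracklet starts at a root or at a daughter of a division and ends at
        a leaf or at a division (the mother belongs to the ending tracklet).
        """
        cmap = self.children_map()
        starts = list(self.roots())
        starts += [c for p in self.nodes for c in cmap[p] if len(cmap[p]) == 2]
        tracklets = []
        for s in sorted(starts):
            path = [s]
            cur = s
            while len(cmap[cur]) == 1:
                cur = cmap[cur][0]
                path.append(cur)
            tracklets.append(path)
        return tracklets

    # -- validation -------------------------------------------------------

    def validate(self, extent: tuple[int, int, int, int] | None = None) -> None:
        """Check the binary-forest invariants; raise on violation.

        ``extent`` is (T, Z, Y, X); when given, node positions must lie
        inside it unless the node is flagged as exited.
        """
        child_count: dict[int, int] = {}
        for child, par in self.parent.items():
            if child not in self.nodes:
                raise ForestValidationError(f"dangling child id {child}")
            if par not in self.nodes:
                raise ForestValidationError(f"dangling parent id {par} of node {child}")
            if self.nodes[child].t != self.nodes[par].t + 1:
                raise ForestValidationError(
                    f"edge {child}->{par} does not span exactly one frame "
                    f"(t={self.nodes[child].t} -> t={self.nodes[par].t})"
                )
            child_count[par] = child_count.get(par, 0) + 1
        for par, cnt in child_count.items():
            if cnt > 2:
                raise ForestValidationError(f"node {par} has {cnt} > 2 children")
        if extent is not None:
            T, Z, Y, X = extent
            for n in self.nodes.values():
                if n.exited:
                    continue
                z, y, x = n.position
                if not (0 <= n.t < T and 0 <= z < Z and 0 <= y < Y and 0 <= x < X):
                    raise ForestValidationError(
                        f"node {n.node_id} at t={n.t}, pos={n.position} outside extent"
                    )

    # -- IO ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": n.node_id,
                "t": n.t,
                "z": n.position[0],
                "y": n.position[1],
                "x": n.position[2],
                "parent_id": self.parent.get(n.node_id, -1),
            }
            for n in sorted(self.nodes.values(), key=lambda n: (n.t, n.node_id))
        ]
        return pd.DataFrame(
            rows, columns=["node_id", "t", "z", "y", "x", "parent_id"]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validate: bool = True) -> "LineageForest":
        forest = cls()
        for row in df.itertuples(index=False):
            pid = int(row.parent_id)
            forest.add_node(
                int(row.node_id),
                int(row.t),
                (float(row.z), float(row.y), float(row.x)),
                parent_id=pid if pid >= 0 else None,
            )
        if validate:
            forest.validate()
        return forest

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, validate: bool = True) -> "LineageForest":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_dataframe(df, validate=validate)
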