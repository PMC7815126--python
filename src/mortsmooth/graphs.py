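"""Admin-1 adjacency graphs: construction, validation and I/O.

The neighbourhood structure drives both the ICAR spatial prior and the
space-time interaction prior, so the graph is a first-class object shared
by the simulation and smoothing stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AdjacencyGraph",
    "generate_adjacency",
    "read_edge_list",
    "write_edge_list",
    "adjacency_from_geojson",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected neighbourhood graph over area labels.

    Parameters
    ----------
    nodes
        Ordered area labels; the ordering fixes row/column order of every
        matrix built from the graph.
    edges
        Symmetric neighbour pairs, stored once per pair.
    """

    nodes: tuple
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        nodeset = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in nodeset or b not in nodeset:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")

    @classmethod
    def from_edges(cls, nodes: Sequence, edges) -> "AdjacencyGraph":
        canon = frozenset(frozenset((a, b)) for a, b in edges)
        return cls(tuple(nodes), frozenset(tuple(sorted(e, key=str)) for e in canon))

    @property
    def n(self) -> int:
        return len(self.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def components(self) -> list[set]:
        """Connected-component partition of the node set."""
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def is_connected(self) -> bool:
        return self.n_components == 1

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency in node order."""
        idx = {v: i for i, v in enumerate(self.nodes)}
        a = np.zeros((self.n, self.n))
        for u, v in self.edges:
            a[idx[u], idx[v]] = 1.0
            a[idx[v], idx[u]] = 1.0
        return a

    def neighbors(self, node) -> set:
        out = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out


def generate_adjacency(n_areas: int, layout: str = "grid", seed: int = 0) -> AdjacencyGraph:
    """Build a connected synthetic adjacency graph on ``n_areas`` nodes.

    ``layout="grid"`` places nodes row-major on a near-square lattice with
    rook contiguity; ``layout="random_planar"`` triangulates uniform random
    points (Delaunay), which is always planar and connected. Node labels are
    the integers ``1..n_areas``. Deterministic given ``seed``.
    """
    if n_areas < 2:
        raise ValueError("n_areas must be >= 2")
    nodes = tuple(range(1, n_areas + 1))
    if n_areas == 2:
        return AdjacencyGraph.from_edges(nodes, [(1, 2)])

    if layout == "grid":
        ncols = int(np.ceil(np.sqrt(n_areas)))
        edges = []
        for k in range(n_areas):
            r, c = divmod(k, ncols)
            if c + 1 < ncols and k + 1 < n_areas and (k + 1) // ncols == r:
                edges.append((k + 1, k + 2))
            if k + ncols < n_areas:
                edges.append((k + 1, k + ncols + 1))
        return AdjacencyGraph.from_edges(nodes, edges)

    if layout == "random_planar":
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(n_areas, 2))
        tri = Delaunay(pts)
        edges = set()
        for simplex in tri.simplices:
            for i in range(3):
                a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
                edges.add((int(a) + 1, int(b) + 1))
        return AdjacencyGraph.from_edges(nodes, edges)

    raise ValueError(f"unknown layout {layout!r}")


def write_edge_list(graph: AdjacencyGraph, path) -> None:
    """Write a two-column CSV edge list (one row per undirected edge)."""
    rows = sorted((str(a), str(b)) for a, b in graph.edges)
    pd.DataFrame(rows, columns=["area_a", "area_b"]).to_csv(path, index=False)


def read_edge_list(path, nodes: Sequence | None = None) -> AdjacencyGraph:
    """Read a two-column CSV edge list; node set defaults to the labels seen."""
    df = pd.read_csv(Path(path), dtype=str)
    edges = list(df.itertuples(index=False, name=None))
    if nodes is None:
        seen: list = []
        for a, b in edges:
            for x in (a, b):
                if x not in seen:
                    seen.append(x)
        nodes = sorted(seen)
    return AdjacencyGraph.from_edges(nodes, edges)


def adjacency_from_geojson(path) -> AdjacencyGraph:
    """Derive rook contiguity from GeoJSON polygons (shared-boundary test).

    Features must carry an ``id`` or a ``properties.name`` used as the area
    label. Two areas are neighbours when their polygons share more than a
    single point.
    """
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    labels, geoms = [], []
    for i, feat in enumerate(gj["features"]):
        label = feat.get("id") or feat.get("properties", {}).get("name") or str(i + 1)
        labels.append(str(label))
        geoms.append(shape(feat["geometry"]))
    edges = []
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            inter = geoms[i].intersection(geoms[j])
            if not inter.is_empty and inter.geom_type not in ("Point", "MultiPoint"):
                edges.append((labels[i], labels[j]))
    return AdjacencyGraph.from_edges(labels, edges)
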