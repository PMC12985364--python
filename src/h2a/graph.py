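"""Spatial k-NN slide graphs, k-hop subgraph sampling, and grid densification.

A slide becomes an undirected graph whose nodes are spots (with pixel
coordinates) and whose edges connect each spot to its k nearest neighbors
by Euclidean distance (k = 6 matches the hex adjacency of 10x Visium,
k = 8 a square ST grid).  Training and inference operate on k-hop closures
of sampled center sets.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SlideGraph", "Subgraph", "build_knn_graph", "sample_subgraph",
    "sample_training_batches", "make_supergrid", "infer_grid_spacing",
]


@dataclass
class SlideGraph:
    node_ids: list[str]
    coords: np.ndarray                      # (n, 2) pixel (x, y)
    edges: set[tuple[int, int]]             # unordered pairs, stored (lo, hi)
    k_neighbors: int
    _adj: dict[int, list[int]] = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def neighbors(self, i: int) -> list[int]:
        return self.adjacency()[i]

    def adjacency(self) -> dict[int, list[int]]:
        if self._adj is None:
            adj: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
            for a, b in self.edges:
                adj[a].append(b)
                adj[b].append(a)
            for v in adj.values():
                v.sort()
            self._adj = adj
        return self._adj

    def edge_index(self, node_subset: np.ndarray | None = None) -> np.ndarray:
        """Directed (2, 2E) src/dst array, both orientations of every edge.

        With ``node_subset`` (global indices, order defining local indices),
        returns the induced edges re-indexed into the subset.
        """
        if node_subset is None:
            pairs = np.array(sorted(self.edges), dtype=int).reshape(-1, 2)
        else:
            node_subset = np.asarray(node_subset)
            pos = {int(g): l for l, g in enumerate(node_subset)}
            keep = [(pos[a], pos[b]) for a, b in self.edges
                    if a in pos and b in pos]
            pairs = np.array(sorted(keep), dtype=int).reshape(-1, 2)
        if pairs.size == 0:
            return np.zeros((2, 0), dtype=int)
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        return np.stack([src, dst])

    def to_edge_csv(self, path) -> None:
        pairs = sorted(self.edges)
        pd.DataFrame(pairs, columns=["src", "dst"]).to_csv(path, index=False)


@dataclass
class Subgraph:
    centers: np.ndarray                     # global node indices
    nodes: np.ndarray                       # closure, global indices (sorted)
    hop_of: dict[int, int]
    edges: set[tuple[int, int]]             # induced, global index pairs
    hops: int

    def local_edge_index(self) -> np.ndarray:
        pos = {int(g): l for l, g in enumerate(self.nodes)}
        pairs = np.array(sorted((pos[a], pos[b]) for a, b in self.edges),
                         dtype=int).reshape(-1, 2)
        if pairs.size == 0:
            return np.zeros((2, 0), dtype=int)
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        return np.stack([src, dst])

    def local_centers(self) -> np.ndarray:
        pos = {int(g): l for l, g in enumerate(self.nodes)}
        return np.array([pos[int(c)] for c in self.centers], dtype=int)

    def to_json(self, path) -> None:
        payload = {
            "centers": [int(c) for c in self.centers],
            "nodes": [int(v) for v in self.nodes],
            "hop_of": {str(k): int(v) for k, v in self.hop_of.items()},
            "edges": sorted([int(a), int(b)] for a, b in self.edges),
            "hops": self.hops,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def build_knn_graph(coords: np.ndarray, k_neighbors: int,
                    node_ids: list[str] | None = None) -> SlideGraph:
    """Undirected k-NN graph; a pair is connected if either endpoint selects
    the other (union symmetrization).  Ties broken by (distance, node index).
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 spots to build a graph")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= n:
        warnings.warn(f"k_neighbors={k_neighbors} >= n={n}; clamping to n-1")
        k_neighbors = n - 1
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    edges: set[tuple[int, int]] = set()
    block = 512
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = ((coords[start:stop, None, :] - coords[None, :, :]) ** 2).sum(-1)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf
        # stable argsort on distance => ties resolved by node index
        order = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]
        for loc, i in enumerate(rows):
            for j in order[loc]:
                j = int(j)
                edges.add((i, j) if i < j else (j, i))
    return SlideGraph(list(node_ids), coords, edges, k_neighbors)


def sample_subgraph(graph: SlideGraph, centers, hops: int) -> Subgraph:
    """BFS closure of ``centers`` out to ``hops`` with exact hop distances
    and the full induced edge set."""
    centers = np.asarray(centers, dtype=int)
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    if (centers < 0).any() or (centers >= graph.n_nodes).any():
        bad = centers[(centers < 0) | (centers >= graph.n_nodes)]
        raise KeyError(f"unknown center ids: {bad.tolist()}")
    if hops < 0:
        raise ValueError("hops must be >= 0")
    adj = graph.adjacency()
    hop_of: dict[int, int] = {int(c): 0 for c in centers}
    frontier = deque(int(c) for c in centers)
    while frontier:
        u = frontier.popleft()
        if hop_of[u] == hops:
            continue
        for v in adj[u]:
            if v not in hop_of:
                hop_of[v] = hop_of[u] + 1
                frontier.append(v)
    nodes = np.array(sorted(hop_of), dtype=int)
    node_set = set(hop_of)
    induced = {(a, b) for a, b in graph.edges
               if a in node_set and b in node_set}
    return Subgraph(centers=centers, nodes=nodes, hop_of=hop_of,
                    edges=induced, hops=hops)


def sample_training_batches(graph: SlideGraph, batch_size: int, hops: int,
                            rng: np.random.Generator) -> list[Subgraph]:
    """One epoch of minibatch subgraphs: the node set is permuted and split
    into consecutive center chunks, so every node is a center exactly once
    per epoch."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    perm = rng.permutation(graph.n_nodes)
    return [sample_subgraph(graph, perm[i:i + batch_size], hops)
            for i in range(0, graph.n_nodes, batch_size)]


def infer_grid_spacing(coords: np.ndarray) -> tuple[float, float]:
    """(dx, dy) of the rectangular lattice covering ``coords``: dx is the
    modal gap between distinct sorted x values, dy likewise for y."""
    coords = np.asarray(coords, dtype=np.float64)

    def modal_gap(v):
        u = np.unique(np.round(v, 6))
        if len(u) < 2:
            return None
        gaps = np.round(np.diff(u), 6)
        vals, counts = np.unique(gaps, return_counts=True)
        return float(vals[np.argmax(counts)])

    dx, dy = modal_gap(coords[:, 0]), modal_gap(coords[:, 1])
    if dx is None and dy is None:
        raise ValueError("cannot infer grid spacing from coordinates")
    return dx or dy, dy or dx


def make_supergrid(coords: np.ndarray, factor: int,
                   spot_radius_px: float,
                   spacing: tuple[float, float] | None = None
                   ) -> tuple[np.ndarray, float]:
    """Densified sub-spot centers: a rectangular lattice over the bounding
    region of ``coords`` with spacing divided by ``factor``; the original
    lattice points are a subset.  Returns (new_coords, new_radius).
    """
    if factor not in (1, 2, 4, 8, 16):
        raise ValueError("factor must be one of 1, 2, 4, 8, 16")
    coords = np.asarray(coords, dtype=np.float64)
    if factor == 1:
        return coords.copy(), float(spot_radius_px)
    if spacing is None:
        dx, dy = infer_grid_spacing(coords)
        x0, y0 = coords[:, 0].min(), coords[:, 1].min()

        def on_lattice(v, v0, step, sub=2):
            # original points must sit on the factor-densified lattice;
            # hex rows offset by step/2 are covered for even factors
            r = (v - v0) % (step / sub)
            return np.allclose(np.minimum(r, step / sub - r), 0, atol=1e-3)

        if not (on_lattice(coords[:, 0], x0, dx, sub=min(factor, 2)) and
                on_lattice(coords[:, 1], y0, dy, sub=1)):
            raise ValueError(
                "coordinates do not form a rectangular lattice; pass an "
                "explicit spacing=(dx, dy) override")
    else:
        dx, dy = spacing
    sx, sy = dx / factor, dy / factor
    x0, x1 = coords[:, 0].min(), coords[:, 0].max()
    y0, y1 = coords[:, 1].min(), coords[:, 1].max()
    xs = x0 + sx * np.arange(int(round((x1 - x0) / sx)) + 1)
    ys = y0 + sy * np.arange(int(round((y1 - y0) / sy)) + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    new = np.column_stack([gx.ravel(), gy.ravel()])
    return new, float(spot_radius_px) / factor
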