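"""Areal neighborhood structures.

An :class:`AreaGraph` holds the symmetric neighbor relation over areal
units (planning areas, lattice cells, ...) together with per-edge spatial
weights.  It is the adjacency/weights/num structure the intrinsic CAR
prior is defined on; all weights are 1.0 in the default contiguity model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = ["AreaGraph", "make_lattice_graph", "read_gal", "write_gal"]


@dataclass
class AreaGraph:
    """Symmetric weighted neighbor structure over ``n_areas`` areal units.

    Parameters
    ----------
    area_ids
        String identifier per area; internal indices are 0-based and follow
        this ordering in every array the package produces.
    neighbors
        Per-area list of neighbor indices (0-based).
    weights
        Per-area list of edge weights, parallel to ``neighbors``.  If
        omitted, all weights are 1.0 (binary contiguity).
    """

    area_ids: list[str]
    neighbors: list[list[int]]
    weights: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        if n < 1:
            raise ValueError("AreaGraph needs at least one area")
        if len(set(self.area_ids)) != n:
            raise ValueError("area_ids must be unique")
        if len(self.neighbors) != n:
            raise ValueError("neighbors must have one entry per area")
        if not self.weights:
            self.weights = [[1.0] * len(nb) for nb in self.neighbors]
        if len(self.weights) != n or any(
            len(w) != len(nb) for w, nb in zip(self.weights, self.neighbors)
        ):
            raise ValueError("weights must be parallel to neighbors")
        self._validate()

    def _validate(self) -> None:
        wmap: dict[tuple[int, int], float] = {}
        for i, (nbs, ws) in enumerate(zip(self.neighbors, self.weights)):
            if len(set(nbs)) != len(nbs):
                raise ValueError(f"duplicate neighbor entries for area {self.area_ids[i]}")
            for j, w in zip(nbs, ws):
                if j == i:
                    raise ValueError(f"self-loop at area {self.area_ids[i]}")
                if not 0 <= j < self.n_areas:
                    raise ValueError(f"neighbor index {j} out of range")
                if w < 0 or not np.isfinite(w):
                    raise ValueError("weights must be finite and nonnegative")
                wmap[(i, j)] = w
        for (i, j), w in wmap.items():
            if (j, i) not in wmap:
                raise ValueError(
                    f"asymmetric adjacency: {self.area_ids[i]} lists "
                    f"{self.area_ids[j]} but not conversely"
                )
            if wmap[(j, i)] != w:
                raise ValueError(
                    f"asymmetric weight between {self.area_ids[i]} and {self.area_ids[j]}"
                )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors) // 2

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree: sum of edge weights incident to each area."""
        return np.array([float(sum(w)) for w in self.weights])

    def index_of(self, area_id: str) -> int:
        return self.area_ids.index(area_id)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Undirected edges as ``(i, j, w)`` with ``i < j``."""
        out = []
        for i, (nbs, ws) in enumerate(zip(self.neighbors, self.weights)):
            for j, w in zip(nbs, ws):
                if i < j:
                    out.append((i, j, w))
        return out

    def adjacency_matrix(self) -> np.ndarray:
        W = np.zeros((self.n_areas, self.n_areas))
        for i, j, w in self.edge_list():
            W[i, j] = W[j, i] = w
        return W

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian D − W, the (unscaled) ICAR precision structure."""
        W = self.adjacency_matrix()
        return np.diag(W.sum(axis=1)) - W

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_weighted_edges_from(self.edge_list())
        return g

    def coloring(self) -> list[np.ndarray]:
        """Partition areas into independent sets (no two adjacent).

        Used for blocked single-site updates: areas of one color have
        conditionally independent full conditionals.
        """
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        k = max(colors.values(), default=0) + 1
        return [
            np.array(sorted(i for i, c in colors.items() if c == color), dtype=int)
            for color in range(k)
        ]

    @classmethod
    def from_edges(
        cls,
        area_ids: Sequence[str],
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
    ) -> "AreaGraph":
        """Build from undirected edges given by area id (weight defaults to 1)."""
        idx = {a: i for i, a in enumerate(area_ids)}
        neighbors: list[list[int]] = [[] for _ in area_ids]
        weights: list[list[float]] = [[] for _ in area_ids]
        for edge in edges:
            a, b = edge[0], edge[1]
            w = float(edge[2]) if len(edge) == 3 else 1.0
            i, j = idx[a], idx[b]
            neighbors[i].append(j)
            weights[i].append(w)
            neighbors[j].append(i)
            weights[j].append(w)
        return cls(list(area_ids), neighbors, weights)


def make_lattice_graph(rows: int, cols: int) -> AreaGraph:
    """Rook-adjacency rectangular lattice with unit weights.

    A connected test-scale stand-in for real areal contiguity.  Areas are
    labeled ``r{r}c{c}`` row-major; requires ``rows * cols >= 2``.
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice needs rows*cols >= 2")
    ids = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((f"r{r}c{c}", f"r{r}c{c + 1}"))
            if r + 1 < rows:
                edges.append((f"r{r}c{c}", f"r{r + 1}c{c}"))
    return AreaGraph.from_edges(ids, edges)


def read_gal(path) -> AreaGraph:
    """Read a GAL-format spatial weights file (binary contiguity).

    Format: a header line whose last-but-one token is the number of areas,
    then per area a record line ``<id> <n_neighbors>`` followed by a line
    listing the neighbor ids.  Asymmetric records are rejected with the
    offending line numbers.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    k = 0
    while k < len(lines) and not lines[k].strip():
        k += 1
    if k == len(lines):
        raise ValueError(f"{path}: empty GAL file")
    header_no, header = k + 1, lines[k]
    tokens = header.split()
    # GAL headers are either "<n>" or "0 <n> <file> <key>"
    try:
        n = int(tokens[1]) if len(tokens) >= 2 else int(tokens[0])
    except ValueError as exc:
        raise ValueError(f"{path}:{header_no}: malformed GAL header {header!r}") from exc
    records = [
        (k + 1 + i + 1, ln) for i, ln in enumerate(lines[k + 1 :])
    ]
    # zero-neighbor areas may legally have an empty neighbor line, so keep
    # blank lines; but trailing blank lines beyond the records are dropped
    while records and not records[-1][1].strip() and len(records) > 2 * n:
        records.pop()
    if len(records) != 2 * n:
        raise ValueError(
            f"{path}: expected {2 * n} record lines for {n} areas, found {len(records)}"
        )
    area_ids: list[str] = []
    raw: list[tuple[int, list[str]]] = []
    for k in range(n):
        rec_no, rec = records[2 * k]
        nbr_no, nbr = records[2 * k + 1]
        parts = rec.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{rec_no}: malformed record line {rec!r}")
        area_id, count = parts[0], int(parts[1])
        nbr_ids = nbr.split()
        if len(nbr_ids) != count:
            raise ValueError(
                f"{path}:{nbr_no}: area {area_id} declares {count} neighbors "
                f"but lists {len(nbr_ids)}"
            )
        area_ids.append(area_id)
        raw.append((nbr_no, nbr_ids))
    idx = {a: i for i, a in enumerate(area_ids)}
    neighbors: list[list[int]] = []
    for (line_no, nbr_ids), area_id in zip(raw, area_ids):
        row = []
        for b in nbr_ids:
            if b not in idx:
                raise ValueError(f"{path}:{line_no}: unknown neighbor id {b!r}")
            row.append(idx[b])
        neighbors.append(row)
    for i, nbs in enumerate(neighbors):
        for j in nbs:
            if i not in neighbors[j]:
                raise ValueError(
                    f"{path}: asymmetric neighbor records: {area_ids[i]} lists "
                    f"{area_ids[j]} but {area_ids[j]} does not list {area_ids[i]}"
                )
    return AreaGraph(area_ids, neighbors)


def write_gal(graph: AreaGraph, path) -> None:
    """Write binary-contiguity GAL (weights are not representable in GAL)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{graph.n_areas}\n")
        for i, area_id in enumerate(graph.area_ids):
            nbs = graph.neighbors[i]
            fh.write(f"{area_id} {len(nbs)}\n")
            fh.write(" ".join(graph.area_ids[j] for j in nbs) + "\n")
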