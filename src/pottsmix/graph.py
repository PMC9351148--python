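"""Per-section spatial neighborhood graphs from k-nearest-neighbor relations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeighborGraph", "build_knn_graph"]


@dataclass
class NeighborGraph:
    """Undirected spatial graph on the cells of one tissue section.

    ``edges`` is an (E, 2) integer array with i < j per row, no duplicates,
    no self-loops.
    """

    n_nodes: int
    edges: np.ndarray
    section_id: int | str = 1

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            if np.any(self.edges[:, 0] >= self.edges[:, 1]):
                raise ValueError("edges must be stored as (i, j) with i < j")
            if np.any(self.edges < 0) or np.any(self.edges >= self.n_nodes):
                raise ValueError("edge endpoint out of range")
            uniq = np.unique(self.edges, axis=0)
            if uniq.shape[0] != self.edges.shape[0]:
                raise ValueError("duplicate edges")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.edges[:, 0], self.edges[:, 1]


def build_knn_graph(coords: np.ndarray, k: int = 6, section_id: int | str = 1) -> NeighborGraph:
    """Build the union-symmetrized k-nearest-neighbor graph of a section.

    Each cell is linked to its k nearest neighbors under Euclidean distance;
    the directed relation is symmetrized by union into an undirected edge set.
    Distance ties are broken in favor of the smaller cell index, so the result
    is deterministic even with duplicated coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n_cells, 2)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1={k + 1} cells, got {n}")

    pairs = set()
    idx = np.arange(n)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d2 = ((coords[start:stop, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
        for row, i in enumerate(range(start, stop)):
            d = d2[row].copy()
            d[i] = np.inf  # no self-loop
            # lexsort: ties in distance broken by smaller neighbor index
            order = np.lexsort((idx, d))[:k]
            for j in order:
                pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    return NeighborGraph(n_nodes=n, edges=edges, section_id=section_id)
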