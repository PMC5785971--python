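"""Two-layer network construction, validation and edge-list (de)serialisation.

A multiplex here is two undirected simple graphs over one shared node set:
node ``i`` in layer A is the counterpart of node ``i`` in layer B.  The
inter-layer coupling is purely parametric (the ``gamma`` transmission
probabilities act on counterpart pairs), so no inter-layer edges are stored.

Random-regular layers are produced with the pairing (configuration) model
with rejection of self-loops and multi-edges, as implemented by networkx.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "LayerTopology",
    "MultiplexNetwork",
    "make_random_regular",
    "make_random_regular_multiplex",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(eq=False)
class LayerTopology:
    """One network layer: an undirected simple graph on ``n_nodes`` nodes.

    ``adjacency`` is a symmetric 0/1 CSR matrix with a zero diagonal.
    """

    n_nodes: int
    adjacency: sp.csr_array = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be a positive integer")
        adj = sp.csr_array(self.adjacency, dtype=float)
        if adj.shape != (self.n_nodes, self.n_nodes):
            raise ValueError(
                f"adjacency shape {adj.shape} does not match n_nodes={self.n_nodes}"
            )
        if adj.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal (self-loops)")
        if (adj != adj.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        data = adj.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = adj

    @property
    def degree_sequence(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    @property
    def is_regular(self) -> bool:
        deg = self.degree_sequence
        return bool(np.all(deg == deg[0]))

    @property
    def uniform_degree(self) -> int | None:
        """The common degree k when the layer is regular, else None."""
        deg = self.degree_sequence
        return int(deg[0]) if np.all(deg == deg[0]) else None

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def edges(self) -> np.ndarray:
        """Undirected edges as an (m, 2) array with u < v, sorted."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        pairs = np.column_stack([coo.row, coo.col])
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        return pairs[order]

    @classmethod
    def from_edges(cls, n_nodes: int, edges) -> "LayerTopology":
        edges = np.asarray(list(edges), dtype=int).reshape(-1, 2)
        if edges.size:
            u, v = edges[:, 0], edges[:, 1]
            data = np.ones(2 * len(edges))
            adj = sp.coo_array(
                (data, (np.r_[u, v], np.r_[v, u])), shape=(n_nodes, n_nodes)
            ).tocsr()
            adj.data[:] = 1.0  # collapse duplicates
        else:
            adj = sp.csr_array((n_nodes, n_nodes), dtype=float)
        return cls(n_nodes=n_nodes, adjacency=adj)

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "LayerTopology":
        n = graph.number_of_nodes()
        adj = sp.csr_array(
            nx.to_scipy_sparse_array(graph, nodelist=range(n), format="csr", dtype=float)
        )
        return cls(n_nodes=n, adjacency=adj)


@dataclass(eq=False)
class MultiplexNetwork:
    """Two layers over one shared node set; node i pairs with node i."""

    layer_a: LayerTopology
    layer_b: LayerTopology

    def __post_init__(self) -> None:
        if self.layer_a.n_nodes != self.layer_b.n_nodes:
            raise ValueError(
                "layers must share one node set: "
                f"{self.layer_a.n_nodes} != {self.layer_b.n_nodes}"
            )

    @property
    def n_nodes(self) -> int:
        return self.layer_a.n_nodes


def make_random_regular(n_nodes: int, degree: int, seed: int) -> LayerTopology:
    """Seeded random k-regular simple graph on ``n_nodes`` nodes.

    Requires ``n_nodes * degree`` even and ``0 <= degree < n_nodes``.
    Generation uses the pairing model with rejection; a failure after the
    generator's bounded retries is re-raised with context.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be a positive integer")
    if degree < 0:
        raise ValueError(f"degree must be non-negative, got {degree}")
    if degree >= n_nodes:
        raise ValueError(
            f"degree must be smaller than n_nodes (got k={degree}, n={n_nodes})"
        )
    if (n_nodes * degree) % 2 != 0:
        raise ValueError(
            f"n_nodes * degree must be even (got n={n_nodes}, k={degree})"
        )
    try:
        graph = nx.random_regular_graph(degree, n_nodes, seed=seed)
    except nx.NetworkXError as exc:  # pragma: no cover - rare rejection failure
        raise RuntimeError(
            f"random-regular generation failed for n={n_nodes}, k={degree}: {exc}"
        ) from exc
    return LayerTopology.from_networkx(graph)


def make_random_regular_multiplex(
    n_nodes: int, k1: int, k2: int, seed: int
) -> MultiplexNetwork:
    """Two independent random-regular layers with degrees k1 and k2.

    The two layers use seeds ``seed`` and ``seed + 1`` so that a single seed
    reproduces the whole multiplex.
    """
    return MultiplexNetwork(
        layer_a=make_random_regular(n_nodes, k1, seed),
        layer_b=make_random_regular(n_nodes, k2, seed + 1),
    )


def read_edge_list(path, n_nodes: int) -> LayerTopology:
    """Read an undirected edge list: one ``u v`` pair per line, 0-based ids.

    Blank lines and lines starting with ``#`` are ignored.  Duplicate and
    reversed pairs collapse to a single edge.  Self-loops and out-of-range
    ids are rejected with the offending line number.
    """
    edges = set()
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two integers, got {line!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: expected two integers, got {line!r}"
                ) from exc
            if u == v:
                raise ValueError(f"{path}: line {lineno}: self-loop on node {u}")
            for node in (u, v):
                if not 0 <= node < n_nodes:
                    raise ValueError(
                        f"{path}: line {lineno}: node id {node} outside [0, {n_nodes})"
                    )
            edges.add((min(u, v), max(u, v)))
    return LayerTopology.from_edges(n_nodes, sorted(edges))


def write_edge_list(topology: LayerTopology, path) -> None:
    """Write each undirected edge once as ``u v`` with u < v, sorted."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        for u, v in topology.edges():
            handle.write(f"{u} {v}\n")
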