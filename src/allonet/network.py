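"""Binary amino-acid interaction networks from Cα coordinates.

Two residues are connected when their Cα–Cα Euclidean distance is strictly
below a threshold (8 Å by convention for coarse residue-contact networks).
The resulting graph is stored as a dense 0/1 adjacency matrix ordered
monomer 1 (positions 1..N) then monomer 2 (positions 1..N), together with
the monomer partition that the block-based reach analysis relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import StructureModel

__all__ = [
    "DEFAULT_THRESHOLD",
    "ContactNetwork",
    "NetworkSummary",
    "build_contact_network",
    "network_summary",
    "write_edgelist_tsv",
    "write_graphml",
    "read_graphml",
]

#: Default Cα–Cα contact threshold in Å.
DEFAULT_THRESHOLD = 8.0

# node label: (monomer_id, sequence_position, residue_name, author_number)
NodeLabel = tuple[int, int, str, str]


@dataclass(frozen=True)
class ContactNetwork:
    """Undirected binary residue-contact graph with a monomer partition.

    ``monomer_sizes`` is ``(N, N)`` for a dimer network (nodes 0..N-1 are
    monomer 1, N..2N-1 monomer 2) or ``(n, 0)`` for a single-partition
    graph such as the toy fixtures used by the centrality oracles.
    """

    node_labels: tuple[NodeLabel, ...]
    adjacency: np.ndarray
    threshold: float
    monomer_sizes: tuple[int, int]

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        n = len(self.node_labels)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} does not match {n} nodes")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be exactly 0 or 1")
        n1, n2 = self.monomer_sizes
        if n2 == 0:
            if n1 != n:
                raise ValueError("single-partition size must cover all nodes")
        elif n1 != n2 or n1 + n2 != n:
            raise ValueError(
                f"partition {self.monomer_sizes} must split {n} nodes into two equal halves"
            )
        object.__setattr__(self, "adjacency", np.ascontiguousarray(A, dtype=np.int8))

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def is_dimer(self) -> bool:
        return self.monomer_sizes[1] > 0

    @property
    def partition(self) -> tuple[slice, slice]:
        """Index ranges of monomer 1 and monomer 2."""
        n1 = self.monomer_sizes[0]
        return slice(0, n1), slice(n1, n1 + self.monomer_sizes[1])

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edge list as (i, j) index pairs with i < j."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    def to_graph(self) -> nx.Graph:
        """A networkx view with residue metadata on the nodes."""
        g = nx.Graph(threshold=self.threshold)
        for idx, (mono, pos, name, author) in enumerate(self.node_labels):
            g.add_node(
                idx,
                monomer=mono,
                position=pos,
                residue_name=name,
                author_number=author,
            )
        g.add_edges_from(self.edges())
        return g


def build_contact_network(
    model: StructureModel, threshold: float = DEFAULT_THRESHOLD
) -> ContactNetwork:
    """Build the residue contact network of a dimer model.

    An edge joins residues *i* ≠ *j* iff their Cα distance is strictly
    below ``threshold`` (a distance exactly equal to the threshold yields
    no edge). Consecutive residues receive no special treatment: at real
    backbone geometry (≈3.8 Å virtual bonds) they always fall below an
    8 Å cutoff anyway.
    """
    if not threshold > 0:
        raise ValueError(f"invalid threshold: {threshold!r} (must be > 0)")
    coords = model.coordinates()
    dist = squareform(pdist(coords))
    adjacency = (dist < threshold).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    off_diag_zero = (dist == 0) & adjacency.astype(bool)
    if off_diag_zero.any():
        pairs = np.argwhere(np.triu(off_diag_zero))
        warnings.warn(
            f"{len(pairs)} residue pair(s) have coincident Cα coordinates "
            "(distance 0); they are connected but the input looks malformed",
            stacklevel=2,
        )
    labels = tuple(
        (r.monomer_id, r.sequence_position, r.residue_name, r.author_number)
        for r in model.residues()
    )
    n = model.n_residues
    return ContactNetwork(
        node_labels=labels,
        adjacency=adjacency,
        threshold=float(threshold),
        monomer_sizes=(n, n),
    )


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    intra_monomer_edges: tuple[int, int]
    inter_monomer_edges: int
    degree_min: int
    degree_mean: float
    degree_max: int


def network_summary(net: ContactNetwork) -> NetworkSummary:
    """Edge and degree bookkeeping, split by the monomer partition."""
    deg = net.degrees()
    if net.is_dimer:
        p1, p2 = net.partition
        A = net.adjacency
        intra1 = int(A[p1, p1].sum()) // 2
        intra2 = int(A[p2, p2].sum()) // 2
        inter = int(A[p1, p2].sum())
    else:
        intra1, intra2, inter = net.n_edges, 0, 0
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        intra_monomer_edges=(intra1, intra2),
        inter_monomer_edges=inter,
        degree_min=int(deg.min()) if len(deg) else 0,
        degree_mean=float(deg.mean()) if len(deg) else 0.0,
        degree_max=int(deg.max()) if len(deg) else 0,
    )


def write_edgelist_tsv(net: ContactNetwork, path: str | Path) -> None:
    """Write the undirected edge list as a two-column TSV of node indices."""
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\n")
        for i, j in net.edges():
            fh.write(f"{i}\t{j}\n")


def write_graphml(net: ContactNetwork, path: str | Path) -> None:
    """Export the network (with residue metadata) as GraphML."""
    nx.write_graphml(net.to_graph(), str(path))


def read_graphml(path: str | Path) -> ContactNetwork:
    """Reconstruct a :class:`ContactNetwork` from a GraphML export
    produced by :func:`write_graphml`."""
    g = nx.read_graphml(str(path))
    order = sorted(g.nodes, key=int)
    index = {node: i for i, node in enumerate(order)}
    labels = []
    for node in order:
        data = g.nodes[node]
        labels.append(
            (
                int(data["monomer"]),
                int(data["position"]),
                str(data["residue_name"]),
                str(data["author_number"]),
            )
        )
    n = len(order)
    A = np.zeros((n, n), dtype=np.int8)
    for u, v in g.edges:
        A[index[u], index[v]] = A[index[v], index[u]] = 1
    n1 = sum(1 for lbl in labels if lbl[0] == 1)
    sizes = (n1, n - n1)
    return ContactNetwork(
        node_labels=tuple(labels),
        adjacency=A,
        threshold=float(g.graph.get("threshold", DEFAULT_THRESHOLD)),
        monomer_sizes=sizes,
    )
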