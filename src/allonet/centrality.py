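"""Connectivity measures on residue interaction networks.

Two complementary per-residue measures are computed on the dimer graph:

* **Betweenness** β(i): the sum over all unordered node pairs (u, v) of
  the fraction of shortest u–v paths that pass through i (endpoints
  excluded, unnormalised). Residues with high betweenness sit at the
  strategic intersections that shortest inter-domain routes must cross.

* **Reach** ρ(i) (communicability): column sums of the matrix exponential
  G = e^A of the adjacency matrix. Since (A^k)_ij counts walks of exactly
  k steps from i to j, G accumulates walks of every length with a 1/k!
  weight that devalues longer excursions; a residue with large ρ reaches
  many others in few steps.

For a homodimer both measures are reported per monomer, β_k(i) and
ρ_k(i), and averaged across the two equivalent positions. The reach
averaging works on the matrix: G is subdivided into four N×N blocks, the
two intra-monomer diagonal blocks G¹¹ and G²² are combined element-wise
(the cross blocks G¹² and G²¹ are kept only as diagnostics), and ρ(i) is
the column sum of the combined matrix Ḡ.

The module also carries the independent oracles the implementation is
validated against: exhaustive shortest-path enumeration for betweenness,
recursive walk enumeration for the A^k interpretation, and the explicit
truncated exponential series for G.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .network import ContactNetwork

__all__ = [
    "CommunicabilityMatrix",
    "CentralityProfile",
    "betweenness_scores",
    "betweenness_bruteforce",
    "betweenness_profile",
    "communicability",
    "reach_profile",
    "monomer_average",
    "centrality_profile",
    "walk_count_oracle",
    "truncated_exp_series",
]

AverageMode = Literal["mean", "sum"]
BetweennessScope = Literal["dimer", "monomer"]


# ---------------------------------------------------------------------------
# Betweenness
# ---------------------------------------------------------------------------

def _adjacency_lists(adjacency: np.ndarray) -> list[list[int]]:
    return [np.flatnonzero(row).tolist() for row in np.asarray(adjacency)]


def betweenness_scores(adjacency: np.ndarray, exact: bool = False) -> list:
    """Unnormalised shortest-path betweenness of every node.

    Brandes' algorithm: one BFS per source accumulates, for each node, the
    pair dependencies δ_s(v) = Σ_w σ_sv/σ_sw (1 + δ_s(w)) over the
    shortest-path DAG. Summing over sources and halving (each unordered
    pair is visited from both ends) gives
    β(i) = Σ_{u<v, u≠i≠v} σ_uv(i)/σ_uv. Disconnected pairs contribute 0.

    With ``exact=True`` the path-count ratios are accumulated as
    :class:`fractions.Fraction`, giving exact rational betweenness values;
    otherwise IEEE floats are used.
    """
    nbrs = _adjacency_lists(adjacency)
    n = len(nbrs)
    zero = Fraction(0) if exact else 0.0
    bc = [zero] * n
    for s in range(n):
        dist = [-1] * n
        sigma = [0] * n
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0
        sigma[s] = 1
        order: list[int] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = [zero] * n
        for w in reversed(order):
            for v in preds[w]:
                ratio = (
                    Fraction(sigma[v], sigma[w]) if exact else sigma[v] / sigma[w]
                )
                delta[v] = delta[v] + ratio * (1 + delta[w])
            if w != s:
                bc[w] = bc[w] + delta[w]
    return [b / 2 for b in bc]


def betweenness_bruteforce(adjacency: np.ndarray) -> list[Fraction]:
    """Betweenness by exhaustive shortest-path enumeration (oracle).

    For every unordered pair (u, v): BFS distances from v, then a DFS that
    walks from u strictly down the distance gradient enumerates every
    shortest path explicitly. Exact Fraction arithmetic throughout. Only
    intended for small graphs.
    """
    nbrs = _adjacency_lists(adjacency)
    n = len(nbrs)
    bc = [Fraction(0)] * n

    def bfs_dist(src: int) -> list[int]:
        dist = [-1] * n
        dist[src] = 0
        queue = deque([src])
        while queue:
            v = queue.popleft()
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        return dist

    for v in range(n):
        dist_v = bfs_dist(v)
        for u in range(v + 1, n):
            if dist_v[u] < 0:
                continue  # disconnected pair contributes nothing
            paths: list[tuple[int, ...]] = []

            def extend(node: int, acc: tuple[int, ...]) -> None:
                if node == v:
                    paths.append(acc)
                    return
                for w in nbrs[node]:
                    if dist_v[w] == dist_v[node] - 1:
                        extend(w, acc + (w,))

            extend(u, (u,))
            sigma = len(paths)
            through = [0] * n
            for p in paths:
                for node in p[1:-1]:
                    through[node] += 1
            for i in range(n):
                if through[i]:
                    bc[i] += Fraction(through[i], sigma)
    return bc


def betweenness_profile(
    net: ContactNetwork, scope: BetweennessScope = "dimer"
) -> np.ndarray:
    """Per-node betweenness β over the contact network.

    With ``scope="dimer"`` (default) shortest paths run over the full
    two-monomer graph, so routes may cross the interface; β_k(i) is then
    simply the value at monomer k's copy of position i. With
    ``scope="monomer"`` each monomer's induced subgraph is analysed
    independently. Returns one value per node in network order.
    """
    if scope == "dimer" or not net.is_dimer:
        return np.array(betweenness_scores(net.adjacency), dtype=float)
    if scope != "monomer":
        raise ValueError(f"unknown betweenness scope: {scope!r}")
    p1, p2 = net.partition
    parts = [
        betweenness_scores(net.adjacency[p, p]) for p in (p1, p2)
    ]
    return np.array(parts[0] + parts[1], dtype=float)


# ---------------------------------------------------------------------------
# Communicability / reach
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunicabilityMatrix:
    """The matrix exponential G = e^A with its monomer block decomposition.

    ``blocks`` maps "11", "22", "12", "21" to the four N×N sub-matrices
    (for a single-partition graph only "11" is present and equals G).
    ``averaged`` is the combined intra-monomer matrix Ḡ — the element-wise
    mean of G¹¹ and G²² by default, or their sum with ``average="sum"``;
    the choice rescales every reach value by the same factor and cannot
    change any ranking. The cross blocks are diagnostics only.
    """

    G: np.ndarray
    blocks: dict[str, np.ndarray]
    averaged: np.ndarray
    average_mode: AverageMode = "mean"


def communicability(
    net: ContactNetwork, average: AverageMode = "mean"
) -> CommunicabilityMatrix:
    """Compute G = e^A and its monomer blocks for a contact network.

    The exponential includes the k = 0 identity term, so every diagonal
    entry is ≥ 1 and an edgeless graph yields G = I. Disconnected graphs
    are fine: e^A is then block-diagonal.
    """
    A = np.asarray(net.adjacency, dtype=float)
    G = expm(A)
    if net.is_dimer:
        p1, p2 = net.partition
        blocks = {
            "11": G[p1, p1],
            "22": G[p2, p2],
            "12": G[p1, p2],
            "21": G[p2, p1],
        }
        combined = blocks["11"] + blocks["22"]
        if average == "mean":
            combined = combined / 2.0
        elif average != "sum":
            raise ValueError(f"unknown average mode: {average!r}")
        return CommunicabilityMatrix(G=G, blocks=blocks, averaged=combined, average_mode=average)
    return CommunicabilityMatrix(G=G, blocks={"11": G}, averaged=G, average_mode=average)


def reach_profile(cm: CommunicabilityMatrix) -> dict[str, np.ndarray]:
    """Column sums of the averaged and per-monomer communicability blocks.

    Returns ``{"avg": ρ(i), "m1": ρ_1(i), "m2": ρ_2(i)}`` where
    ρ(i) = Σ_j Ḡ_ji and ρ_k(i) = Σ_j (G^kk)_ji, diagonal included. All
    matrices are symmetric, so column sums equal row sums.
    """
    out = {"avg": cm.averaged.sum(axis=0)}
    out["m1"] = cm.blocks["11"].sum(axis=0)
    out["m2"] = cm.blocks["22"].sum(axis=0) if "22" in cm.blocks else out["m1"].copy()
    return out


def monomer_average(
    values_m1: Sequence[float],
    values_m2: Sequence[float],
    mode: AverageMode = "mean",
) -> np.ndarray:
    """Combine the two equivalent positions of a homodimer per position."""
    v1 = np.asarray(values_m1, dtype=float)
    v2 = np.asarray(values_m2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"monomer length mismatch: {v1.shape} vs {v2.shape}")
    total = v1 + v2
    if mode == "mean":
        return total / 2.0
    if mode == "sum":
        return total
    raise ValueError(f"unknown average mode: {mode!r}")


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CentralityProfile:
    """Per-position betweenness and reach of one structure variant.

    All arrays have length N (the monomer length); ``residue_names`` and
    ``author_numbers`` hold the metadata of monomer 1 and monomer 2
    position by position.
    """

    variant_label: str
    positions: np.ndarray
    residue_names: tuple[tuple[str, ...], tuple[str, ...]]
    author_numbers: tuple[tuple[str, ...], tuple[str, ...]]
    beta_m1: np.ndarray
    beta_m2: np.ndarray
    beta_avg: np.ndarray
    rho_m1: np.ndarray
    rho_m2: np.ndarray
    rho_avg: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        """One row per (monomer, position); the value columns depend only
        on the position."""
        rows = []
        for k in (1, 2):
            names = self.residue_names[k - 1]
            authors = self.author_numbers[k - 1]
            for idx, pos in enumerate(self.positions):
                rows.append(
                    {
                        "monomer": k,
                        "position": int(pos),
                        "residue_name": names[idx],
                        "author_number": authors[idx],
                        "beta_m1": self.beta_m1[idx],
                        "beta_m2": self.beta_m2[idx],
                        "beta_avg": self.beta_avg[idx],
                        "rho_m1": self.rho_m1[idx],
                        "rho_m2": self.rho_m2[idx],
                        "rho_avg": self.rho_avg[idx],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path, variant_label: str | None = None) -> "CentralityProfile":
        df = pd.read_csv(path, sep="\t", dtype={"author_number": str})
        m1 = df[df["monomer"] == 1].sort_values("position")
        m2 = df[df["monomer"] == 2].sort_values("position")
        return cls(
            variant_label=variant_label if variant_label is not None else str(path),
            positions=m1["position"].to_numpy(dtype=int),
            residue_names=(
                tuple(m1["residue_name"]),
                tuple(m2["residue_name"]),
            ),
            author_numbers=(
                tuple(m1["author_number"]),
                tuple(m2["author_number"]),
            ),
            beta_m1=m1["beta_m1"].to_numpy(dtype=float),
            beta_m2=m1["beta_m2"].to_numpy(dtype=float),
            beta_avg=m1["beta_avg"].to_numpy(dtype=float),
            rho_m1=m1["rho_m1"].to_numpy(dtype=float),
            rho_m2=m1["rho_m2"].to_numpy(dtype=float),
            rho_avg=m1["rho_avg"].to_numpy(dtype=float),
        )


def centrality_profile(
    net: ContactNetwork,
    variant_label: str = "",
    scope: BetweennessScope = "dimer",
    average: AverageMode = "mean",
) -> CentralityProfile:
    """Full per-position centrality profile of a dimer contact network."""
    if not net.is_dimer:
        raise ValueError("centrality_profile requires a two-monomer network")
    n = net.monomer_sizes[0]
    beta = betweenness_profile(net, scope=scope)
    beta_m1, beta_m2 = beta[:n], beta[n:]
    cm = communicability(net, average=average)
    rho = reach_profile(cm)
    labels = net.node_labels
    return CentralityProfile(
        variant_label=variant_label,
        positions=np.arange(1, n + 1),
        residue_names=(
            tuple(lbl[2] for lbl in labels[:n]),
            tuple(lbl[2] for lbl in labels[n:]),
        ),
        author_numbers=(
            tuple(lbl[3] for lbl in labels[:n]),
            tuple(lbl[3] for lbl in labels[n:]),
        ),
        beta_m1=beta_m1,
        beta_m2=beta_m2,
        beta_avg=monomer_average(beta_m1, beta_m2, mode=average),
        rho_m1=rho["m1"],
        rho_m2=rho["m2"],
        rho_avg=rho["avg"],
    )


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def walk_count_oracle(adjacency: np.ndarray, k: int) -> np.ndarray:
    """Count walks of exactly ``k`` steps between every node pair by
    exhaustive recursive enumeration (never via matrix powers).

    Serves as the independent ground truth for the interpretation of A^k
    as walk counts, hence for the series form of e^A. Exponential in k:
    keep the graph small (≲ 10 nodes) and k ≤ 5.
    """
    if k < 0:
        raise ValueError("walk length must be non-negative")
    nbrs = _adjacency_lists(adjacency)
    n = len(nbrs)
    counts = np.zeros((n, n), dtype=np.int64)

    def rec(start: int, node: int, steps: int) -> None:
        if steps == k:
            counts[start, node] += 1
            return
        for w in nbrs[node]:
            rec(start, w, steps + 1)

    for i in range(n):
        rec(i, i, 0)
    return counts


def truncated_exp_series(adjacency: np.ndarray, k_max: int = 60) -> np.ndarray:
    """Σ_{k=0..k_max} A^k / k! by explicit term-wise accumulation — the
    series oracle that defines correctness of the e^A computation."""
    A = np.asarray(adjacency, dtype=float)
    term = np.eye(A.shape[0])
    total = term.copy()
    for k in range(1, k_max + 1):
        term = term @ A / k
        total += term
    return total
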