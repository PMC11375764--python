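from collections import deque

import numpy as np
import pytest

from allonet import ContactNetwork, ResidueRecord, StructureModel
from allonet.centrality import CentralityProfile


def make_model(coords1, coords2, names=None, source_label="test model"):
    """Hand-build a StructureModel from two coordinate arrays."""
    coords1 = np.asarray(coords1, dtype=float)
    coords2 = np.asarray(coords2, dtype=float)
    n = len(coords1)
    if names is None:
        names = ["GLY"] * n
    monomers = tuple(
        tuple(
            ResidueRecord(
                monomer_id=k,
                sequence_position=i + 1,
                residue_name=names[i],
                author_number=str(i + 1),
                ca_position=tuple(c[i]),
            )
            for i in range(n)
        )
        for k, c in ((1, coords1), (2, coords2))
    )
    return StructureModel(monomers=monomers, source_label=source_label)


def make_network(adjacency, monomer_sizes=None):
    """Wrap a raw 0/1 adjacency matrix as a ContactNetwork."""
    A = np.asarray(adjacency, dtype=np.int8)
    n = A.shape[0]
    if monomer_sizes is None:
        monomer_sizes = (n, 0)
    n1 = monomer_sizes[0]
    labels = tuple(
        (1 if i < n1 else 2, i % n1 + 1 if monomer_sizes[1] else i + 1, "GLY", str(i + 1))
        for i in range(n)
    )
    return ContactNetwork(
        node_labels=labels, adjacency=A, threshold=8.0, monomer_sizes=monomer_sizes
    )


def random_adjacency(rng, n, p=0.35, connected=False, max_tries=200):
    """Random symmetric 0/1 adjacency with zero diagonal (G(n, p))."""
    for _ in range(max_tries):
        upper = np.triu(rng.random((n, n)) < p, k=1)
        A = (upper | upper.T).astype(np.int8)
        if not connected or _is_connected(A):
            return A
    raise AssertionError("could not sample a connected graph")


def _is_connected(A):
    n = A.shape[0]
    seen = {0}
    queue = deque([0])
    while queue:
        v = queue.popleft()
        for w in np.flatnonzero(A[v]):
            if w not in seen:
                seen.add(int(w))
                queue.append(int(w))
    return len(seen) == n


def make_profile(beta_m1, beta_m2, rho_m1, rho_m2, label="variant", names=None):
    """Build a CentralityProfile directly from per-monomer value arrays."""
    beta_m1 = np.asarray(beta_m1, dtype=float)
    beta_m2 = np.asarray(beta_m2, dtype=float)
    rho_m1 = np.asarray(rho_m1, dtype=float)
    rho_m2 = np.asarray(rho_m2, dtype=float)
    n = len(beta_m1)
    if names is None:
        names = tuple(["ALA"] * n)
    return CentralityProfile(
        variant_label=label,
        positions=np.arange(1, n + 1),
        residue_names=(tuple(names), tuple(names)),
        author_numbers=(tuple(str(i + 1) for i in range(n)),) * 2,
        beta_m1=beta_m1,
        beta_m2=beta_m2,
        beta_avg=(beta_m1 + beta_m2) / 2,
        rho_m1=rho_m1,
        rho_m2=rho_m2,
        rho_avg=(rho_m1 + rho_m2) / 2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
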