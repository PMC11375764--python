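"""Synthetic dimer structures and analytic toy networks.

Real dimer snapshots from molecular-dynamics runs are bulky and often not
redistributable, so this module generates stand-ins with the properties
the connectivity analysis actually depends on: a pair of equal-length
chains whose Cα contact graph at 8 Å has folded-protein-like density
(consecutive residues always in contact, a handful of spatial neighbours
per residue), a tunable number of inter-monomer interface contacts, and
an optional localized perturbation that emulates the structural footprint
of a point-mutant snapshot.

The chain model is a self-avoiding random walk with fixed 3.8 Å steps,
biased to stay inside a confinement radius that scales like the radius of
gyration of globular proteins (≈ 3·N^0.38 Å). No claim of physical
realism is made beyond the contact graph: the analysis never looks at
anything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .network import DEFAULT_THRESHOLD, ContactNetwork
from .structure_io import STANDARD_AMINO_ACIDS, ResidueRecord, StructureModel

__all__ = [
    "GenerationError",
    "Perturbation",
    "DimerSpec",
    "generate_dimer",
    "toy_network",
    "write_fixture",
]

_AA_CODES = tuple(sorted(STANDARD_AMINO_ACIDS))


class GenerationError(RuntimeError):
    """Raised when a structure satisfying the spec cannot be generated
    within the bounded search budget."""


@dataclass(frozen=True)
class Perturbation:
    """A localized coordinate perturbation emulating a mutant snapshot.

    Residues within ``radius`` sequence positions of ``position`` (in both
    monomers) are displaced along a seeded random direction, with a cosine
    taper so the displacement is ``magnitude`` Å at the site and fades to
    zero at the window edge. Only contacts involving the displaced
    residues can change.
    """

    position: int
    magnitude: float = 2.5
    radius: int = 5

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("perturbation position is 1-based")
        if self.magnitude < 0 or self.radius < 0:
            raise ValueError("perturbation magnitude and radius must be >= 0")


@dataclass(frozen=True)
class DimerSpec:
    """Parameters of a synthetic homodimer snapshot.

    Defaults give a 524-residue monomer (the size of the intracellular
    domain analysed in the motivating system), realistic Cα spacing and a
    modest interface. Identical specs (seed included) always generate
    byte-identical coordinates.
    """

    n_res: int = 524
    seed: int = 0
    step_length: float = 3.8
    compactness: float = 2.0
    interface_contacts: int = 30
    threshold: float = DEFAULT_THRESHOLD
    monomer2: Literal["rigid_copy", "independent"] = "rigid_copy"
    perturbation: Perturbation | None = None
    min_separation: float = 3.0

    def __post_init__(self) -> None:
        if self.n_res < 2:
            raise ValueError("n_res must be >= 2")
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        if self.interface_contacts < 0:
            raise ValueError("interface_contacts must be >= 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.perturbation is not None and self.perturbation.position > self.n_res:
            raise ValueError("perturbation position exceeds monomer length")


def _random_units(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _confinement_radius(n_res: int) -> float:
    # constant-density globule: radius grows like N^(1/3), in Å
    return 4.0 * n_res ** (1 / 3)


#: Weight of the local-crowding penalty in the chain growth; together with
#: the confinement radius it sets the realized contact density (mean degree
#: ≈ 6–10 at an 8 Å threshold across chain lengths).
_CROWDING = 0.35


def _self_avoiding_chain(
    rng: np.random.Generator,
    n_res: int,
    step_length: float,
    compactness: float,
    min_separation: float,
    n_candidates: int = 24,
) -> np.ndarray:
    """Grow a biased self-avoiding walk of ``n_res`` beads.

    Each step proposes ``n_candidates`` random directions, discards those
    that clash (< ``min_separation`` Å to any earlier bead) and picks among
    the survivors with weights exp(−compactness·overshoot/step −
    0.35·crowding), where overshoot is the distance beyond the confinement
    radius and crowding the count of existing beads within 8 Å. The
    confinement keeps the chain globular; the crowding penalty keeps the
    local contact density protein-like instead of random-walk dense. Dead
    ends trigger backtracking; the total backtrack budget is 50·n_res.
    """
    r_target = _confinement_radius(n_res)
    pts: list[np.ndarray] = [np.zeros(3)]
    backtracks = 0
    max_backtracks = 50 * n_res
    while len(pts) < n_res:
        current = pts[-1]
        cands = current + step_length * _random_units(rng, n_candidates)
        prev = np.asarray(pts)
        if len(pts) > 1:
            d = cdist(cands, prev)
            keep = d[:, :-1].min(axis=1) >= min_separation
            cands, d = cands[keep], d[keep]
            crowding = (d < 8.0).sum(axis=1)
        else:
            crowding = np.ones(len(cands))
        if len(cands) == 0:
            backtracks += 1
            if backtracks > max_backtracks or len(pts) == 1:
                raise GenerationError(
                    "generation failed: self-avoiding chain dead-ended after "
                    f"{backtracks} backtracks at length {len(pts)}/{n_res}"
                )
            pts.pop()
            continue
        overshoot = np.maximum(0.0, np.linalg.norm(cands, axis=1) - r_target)
        w = np.exp(-compactness * overshoot / step_length - _CROWDING * crowding)
        pts.append(cands[rng.choice(len(cands), p=w / w.sum())])
    return np.asarray(pts)


def _place_second_monomer(
    rng: np.random.Generator,
    coords1: np.ndarray,
    coords2_raw: np.ndarray,
    spec: DimerSpec,
    max_attempts: int = 40,
) -> np.ndarray:
    """Rigidly place monomer 2 so the realized inter-monomer contact count
    at the spec threshold lands within ±20% of the target, with no
    inter-monomer clash below ``min_separation``."""
    target = spec.interface_contacts
    thr2 = spec.threshold ** 2
    lo = int(np.floor(0.8 * target))
    hi = int(np.ceil(1.2 * target))
    centroid1 = coords1.mean(axis=0)
    best: tuple[int, float] | None = None
    for _ in range(max_attempts):
        R = _random_rotation(rng)
        local = (coords2_raw - coords2_raw.mean(axis=0)) @ R.T
        u = _random_units(rng, 1)[0]
        base = local + centroid1  # monomer 2 at offset d along u from here
        diff = coords1[:, None, :] - base[None, :, :]
        w2 = np.einsum("ijk,ijk->ij", diff, diff)
        p = diff @ u
        if target == 0:
            d = float(p.max() + spec.threshold + 10.0)
            return base + d * u
        d_hi = float(p.max() + spec.threshold)
        d_lo = max(0.0, float(p.min() - spec.threshold))
        for d in np.arange(d_hi, d_lo, -0.1):
            d2 = w2 - 2.0 * d * p + d * d
            min_d2 = float(d2.min())
            if min_d2 < spec.min_separation ** 2:
                break  # moving closer only worsens the clash
            count = int((d2 < thr2).sum())
            if lo <= count <= hi:
                return base + d * u
            if best is None or abs(count - target) < abs(best[0] - target):
                best = (count, d)
            if count > hi:
                break
    achieved = best[0] if best is not None else 0
    raise GenerationError(
        "generation failed: could not realize an interface with "
        f"{target} (+/-20%) contacts after {max_attempts} placements "
        f"(closest achieved: {achieved})"
    )


def _apply_perturbation(
    rng: np.random.Generator, coords: np.ndarray, pert: Perturbation
) -> np.ndarray:
    """Displace the residue window of both monomers along seeded random
    directions with a cosine taper."""
    n = coords.shape[0] // 2
    out = coords.copy()
    if pert.magnitude == 0.0:
        return out
    idx = np.arange(1, n + 1)
    dist = np.abs(idx - pert.position)
    in_window = dist <= pert.radius
    taper = 0.5 * (1.0 + np.cos(np.pi * dist / (pert.radius + 1)))
    for k, direction in enumerate(_random_units(rng, 2)):
        block = slice(k * n, (k + 1) * n)
        out[block][in_window] += (
            pert.magnitude * taper[in_window, None] * direction[None, :]
        )
    return out


def generate_dimer(spec: DimerSpec) -> StructureModel:
    """Generate a synthetic two-monomer snapshot from a :class:`DimerSpec`.

    Monomer 2 is either a rigidly rotated/translated copy of monomer 1
    (``rigid_copy``, the homodimer default) or an independently grown
    chain with the same sequence. The same spec always yields the same
    model; the perturbation draws from its own random stream, so the
    unperturbed residues of a perturbed spec match the unperturbed spec
    coordinate for coordinate.
    """
    ss = np.random.SeedSequence(spec.seed)
    chain_rng, chain2_rng, place_rng, pert_rng, seq_rng = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    coords1 = _self_avoiding_chain(
        chain_rng, spec.n_res, spec.step_length, spec.compactness, spec.min_separation
    )
    if spec.monomer2 == "rigid_copy":
        coords2_raw = coords1
    elif spec.monomer2 == "independent":
        coords2_raw = _self_avoiding_chain(
            chain2_rng, spec.n_res, spec.step_length, spec.compactness, spec.min_separation
        )
    else:
        raise ValueError(f"unknown monomer2 mode: {spec.monomer2!r}")
    coords2 = _place_second_monomer(place_rng, coords1, coords2_raw, spec)
    coords = np.vstack([coords1, coords2])
    if spec.perturbation is not None:
        coords = _apply_perturbation(pert_rng, coords, spec.perturbation)

    sequence = seq_rng.choice(_AA_CODES, size=spec.n_res)
    label = f"synthetic dimer (seed={spec.seed}, n_res={spec.n_res}"
    if spec.perturbation is not None:
        p = spec.perturbation
        label += f", perturbed @{p.position} by {p.magnitude} A over +/-{p.radius}"
    label += ")"
    monomers = tuple(
        tuple(
            ResidueRecord(
                monomer_id=k,
                sequence_position=i + 1,
                residue_name=str(sequence[i]),
                author_number=str(i + 1),
                ca_position=tuple(coords[(k - 1) * spec.n_res + i]),
            )
            for i in range(spec.n_res)
        )
        for k in (1, 2)
    )
    return StructureModel(monomers=monomers, source_label=label)


# ---------------------------------------------------------------------------
# Toy networks
# ---------------------------------------------------------------------------

def _toy_edges(kind: str, size: int) -> tuple[int, list[tuple[int, int]]]:
    if kind == "path":
        if size < 2:
            raise ValueError("invalid toy spec: path needs size >= 2")
        return size, [(i, i + 1) for i in range(size - 1)]
    if kind == "cycle":
        if size < 3:
            raise ValueError("invalid toy spec: cycle needs size >= 3")
        return size, [(i, (i + 1) % size) for i in range(size)]
    if kind == "star":
        if size < 2:
            raise ValueError("invalid toy spec: star needs size >= 2")
        return size, [(0, i) for i in range(1, size)]
    if kind == "complete":
        if size < 2:
            raise ValueError("invalid toy spec: complete needs size >= 2")
        return size, [(i, j) for i in range(size) for j in range(i + 1, size)]
    if kind == "two_cliques_bridge":
        # two K_size cliques joined through a single bridge node
        if size < 2:
            raise ValueError("invalid toy spec: cliques need size >= 2")
        n = 2 * size + 1
        bridge = size
        edges = [(i, j) for i in range(size) for j in range(i + 1, size)]
        edges += [
            (i, j)
            for i in range(size + 1, n)
            for j in range(i + 1, n)
        ]
        edges += [(0, bridge), (bridge, size + 1)]
        return n, edges
    raise ValueError(f"invalid toy spec: unknown kind {kind!r}")


def toy_network(kind: str, size: int, dimer: bool = False) -> ContactNetwork:
    """Build a named toy graph as a :class:`ContactNetwork`.

    Kinds: ``path``, ``cycle``, ``star``, ``complete`` (``size`` = node
    count) and ``two_cliques_bridge`` (``size`` = clique size; 2·size+1
    nodes with the bridge in the middle). With ``dimer=True`` (even node
    count only) the nodes are split into two equal "monomers"; otherwise a
    single partition is declared.
    """
    n, edges = _toy_edges(kind, size)
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    if dimer:
        if n % 2:
            raise ValueError(f"invalid toy spec: cannot split {n} nodes into two monomers")
        half = n // 2
        sizes = (half, half)
        labels = tuple(
            (1 + (i >= half), i % half + 1, "GLY", str(i % half + 1)) for i in range(n)
        )
    else:
        sizes = (n, 0)
        labels = tuple((1, i + 1, "GLY", str(i + 1)) for i in range(n))
    return ContactNetwork(
        node_labels=labels, adjacency=A, threshold=0.0, monomer_sizes=sizes
    )


# ---------------------------------------------------------------------------
# PDB fixture writing
# ---------------------------------------------------------------------------

_CHAIN_IDS = ("A", "B")


def write_fixture(model: StructureModel, path: str | Path) -> Path:
    """Write a model as a minimal CA-only PDB file (chains A and B,
    coordinates at 3 decimals), reloadable by :func:`allonet.structure_io.
    load_structure`."""
    path = Path(path)
    lines = []
    serial = 0
    for k, monomer in enumerate(model.monomers):
        chain = _CHAIN_IDS[k]
        for rec in monomer:
            serial += 1
            num = rec.author_number
            icode = " "
            if num and not num[-1].isdigit():
                num, icode = num[:-1], num[-1]
            x, y, z = rec.ca_position
            lines.append(
                f"ATOM  {serial:>5d}  CA  {rec.residue_name:<3s} {chain}"
                f"{int(num):>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}           C"
            )
        serial += 1
        lines.append(f"TER   {serial:>5d}      {model.monomers[k][-1].residue_name:<3s} {chain}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
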