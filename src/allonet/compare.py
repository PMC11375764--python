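"""Differential centrality between two structure variants.

Given the per-position profiles of a reference (typically the wildtype)
and an alternative (a point-mutant snapshot), the per-residue differences

    Δβ(i) = β_ref(i) − β_alt(i),    Δρ(i) = ρ_ref(i) − ρ_alt(i)

are formed on the monomer-averaged values. A positive Δ means greater
connectivity in the reference; a negative Δ, greater connectivity in the
alternative. The residues at the two ends of the sorted Δ list are the
candidates for functionally important positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .centrality import CentralityProfile

__all__ = [
    "Mutation",
    "VariantComparison",
    "Extreme",
    "parse_mutation",
    "delta_profiles",
    "rank_extremes",
    "comparison_frame",
]

Measure = Literal["beta", "rho"]


@dataclass(frozen=True)
class Mutation:
    """A declared substitution, e.g. ``902:V>L`` (position in the reported
    author numbering, one-letter or three-letter codes accepted)."""

    position: str
    ref_aa: str
    alt_aa: str


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _as_three(code: str) -> str:
    code = code.strip().upper()
    if len(code) == 1:
        return _ONE_TO_THREE.get(code, code)
    return code


def parse_mutation(text: str) -> Mutation:
    """Parse a ``POS:REF>ALT`` mutation string such as ``"902:V>L"``."""
    try:
        pos, change = text.split(":")
        ref, alt = change.split(">")
    except ValueError as exc:
        raise ValueError(f"cannot parse mutation {text!r}; expected POS:REF>ALT") from exc
    return Mutation(position=pos.strip(), ref_aa=_as_three(ref), alt_aa=_as_three(alt))


@dataclass(frozen=True)
class VariantComparison:
    """Per-position Δβ and Δρ between a reference and an alternative."""

    ref_label: str
    alt_label: str
    positions: np.ndarray
    residue_names_ref: tuple[str, ...]
    residue_names_alt: tuple[str, ...]
    author_numbers: tuple[str, ...]
    delta_beta: np.ndarray
    delta_rho: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def delta(self, measure: Measure) -> np.ndarray:
        if measure == "beta":
            return self.delta_beta
        if measure == "rho":
            return self.delta_rho
        raise ValueError(f"unknown measure: {measure!r}")


def delta_profiles(
    ref: CentralityProfile,
    alt: CentralityProfile,
    mutations: Iterable[Mutation | str] = (),
) -> VariantComparison:
    """Form Δβ(i) and Δρ(i) = reference − alternative on averaged values.

    Residue-name disagreements at positions other than the declared
    mutation sites are reported as a warning (the profiles may come from
    differently-prepared snapshots); a declared mutation is expected to
    disagree and is not flagged.
    """
    if ref.n_positions != alt.n_positions:
        raise ValueError(
            f"profile mismatch: {ref.variant_label!r} has {ref.n_positions} "
            f"positions, {alt.variant_label!r} has {alt.n_positions}"
        )
    muts = [parse_mutation(m) if isinstance(m, str) else m for m in mutations]
    declared = {m.position for m in muts}
    names_ref = ref.residue_names[0]
    names_alt = alt.residue_names[0]
    authors = ref.author_numbers[0]
    unexpected = [
        f"{authors[i]} ({names_ref[i]} vs {names_alt[i]})"
        for i in range(ref.n_positions)
        if names_ref[i] != names_alt[i] and authors[i] not in declared
    ]
    if unexpected:
        warnings.warn(
            "residue identity differs at undeclared position(s): "
            + ", ".join(unexpected),
            stacklevel=2,
        )
    return VariantComparison(
        ref_label=ref.variant_label,
        alt_label=alt.variant_label,
        positions=np.asarray(ref.positions, dtype=int),
        residue_names_ref=names_ref,
        residue_names_alt=names_alt,
        author_numbers=authors,
        delta_beta=np.asarray(ref.beta_avg, dtype=float) - np.asarray(alt.beta_avg, dtype=float),
        delta_rho=np.asarray(ref.rho_avg, dtype=float) - np.asarray(alt.rho_avg, dtype=float),
    )


@dataclass(frozen=True)
class Extreme:
    position: int
    residue_name: str
    author_number: str
    delta: float


def _sorted_indices(delta: np.ndarray, positions: np.ndarray) -> np.ndarray:
    # descending by delta, ties broken by ascending sequence position
    return np.lexsort((positions, -delta))


def rank_extremes(
    cmp: VariantComparison, measure: Measure, n: int = 6
) -> tuple[list[Extreme], list[Extreme]]:
    """The ``n`` most reference-shifted and ``n`` most alternative-shifted
    residues of the sorted Δ list.

    Returns ``(top, bottom)``: ``top`` holds the n largest Δ values in
    descending order (greatest connectivity surplus in the reference),
    ``bottom`` the n smallest in ascending order (surplus in the
    alternative). Ties break deterministically by ascending position.
    """
    if n > cmp.n_positions:
        raise ValueError(
            f"rank size exceeds profile: n={n} > {cmp.n_positions} positions"
        )
    delta = cmp.delta(measure)
    order = _sorted_indices(delta, cmp.positions)

    def make(idx: int) -> Extreme:
        return Extreme(
            position=int(cmp.positions[idx]),
            residue_name=cmp.residue_names_ref[idx],
            author_number=cmp.author_numbers[idx],
            delta=float(delta[idx]),
        )

    top = [make(i) for i in order[:n]]
    # bottom: ascending delta, ties still by ascending position
    bottom_order = np.lexsort((cmp.positions, delta))
    bottom = [make(i) for i in bottom_order[:n]]
    return top, bottom


def comparison_frame(cmp: VariantComparison, n: int = 6) -> pd.DataFrame:
    """Tabular view of a comparison with per-measure ranks and extreme
    flags (rank 1 = largest Δ; flags mark membership of the top/bottom-n)."""
    order_beta = _sorted_indices(cmp.delta_beta, cmp.positions)
    order_rho = _sorted_indices(cmp.delta_rho, cmp.positions)
    rank_beta = np.empty(cmp.n_positions, dtype=int)
    rank_rho = np.empty(cmp.n_positions, dtype=int)
    rank_beta[order_beta] = np.arange(1, cmp.n_positions + 1)
    rank_rho[order_rho] = np.arange(1, cmp.n_positions + 1)

    def flags(rank: np.ndarray) -> list[str]:
        out = []
        for r in rank:
            if r <= n:
                out.append("top")
            elif r > cmp.n_positions - n:
                out.append("bottom")
            else:
                out.append("")
        return out

    return pd.DataFrame(
        {
            "position": cmp.positions,
            "author_number": cmp.author_numbers,
            "residue_name_ref": cmp.residue_names_ref,
            "residue_name_alt": cmp.residue_names_alt,
            "delta_beta": cmp.delta_beta,
            "delta_rho": cmp.delta_rho,
            "rank_beta": rank_beta,
            "rank_rho": rank_rho,
            "flag_beta": flags(rank_beta),
            "flag_rho": flags(rank_rho),
        }
    )
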