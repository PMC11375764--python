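"""Reading protein structures into per-residue Cα records.

The downstream connectivity analysis represents every residue by the
position of its backbone Cα atom, so this module reduces a PDB file to an
ordered list of (chain, position, residue name, Cα coordinate) records —
one per residue per chain — and groups them into a two-monomer
:class:`StructureModel` suitable for homodimer analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "StructureError",
    "ResidueRecord",
    "StructureModel",
    "load_structure",
    "renumber",
]

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)


class StructureError(ValueError):
    """Raised when a structure file violates the two-monomer contract."""


@dataclass(frozen=True)
class ResidueRecord:
    """A single residue reduced to its Cα atom.

    Parameters
    ----------
    monomer_id:
        Which monomer of the dimer the residue belongs to (1 or 2).
    sequence_position:
        1-based index within the monomer, assigned by order of appearance.
    residue_name:
        Three-letter amino-acid code.
    author_number:
        The residue number as written in the source file, insertion code
        appended verbatim (e.g. ``"100A"``). Kept as a label: only reporting
        depends on it.
    ca_position:
        Cα coordinates in Å.
    """

    monomer_id: int
    sequence_position: int
    residue_name: str
    author_number: str
    ca_position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.monomer_id not in (1, 2):
            raise StructureError(f"monomer_id must be 1 or 2, got {self.monomer_id}")
        if self.sequence_position < 1:
            raise StructureError("sequence_position is 1-based")
        pos = np.asarray(self.ca_position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(
                f"ca_position must be 3 finite coordinates, got {self.ca_position!r}"
            )


@dataclass(frozen=True)
class StructureModel:
    """An ordered two-monomer structure with one Cα position per residue.

    Both monomers must contain the same number of residues (N ≥ 2) with
    sequence positions running 1..N without gaps: the dimer-averaging steps
    of the analysis pair position *i* of monomer 1 with position *i* of
    monomer 2.
    """

    monomers: tuple[tuple[ResidueRecord, ...], tuple[ResidueRecord, ...]]
    source_label: str = ""
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.monomers) != 2:
            raise StructureError("a StructureModel holds exactly 2 monomers")
        n1, n2 = (len(m) for m in self.monomers)
        if n1 != n2:
            raise StructureError(f"monomer length mismatch: {n1} vs {n2} residues")
        if n1 < 2:
            raise StructureError("each monomer needs at least 2 residues")
        for k, monomer in enumerate(self.monomers, start=1):
            for i, rec in enumerate(monomer, start=1):
                if rec.monomer_id != k:
                    raise StructureError(
                        f"residue at monomer {k} position {i} carries monomer_id {rec.monomer_id}"
                    )
                if rec.sequence_position != i:
                    raise StructureError(
                        f"monomer {k}: sequence_position must run 1..N without gaps "
                        f"(found {rec.sequence_position} at slot {i})"
                    )

    @property
    def n_residues(self) -> int:
        """Residue count N of each monomer."""
        return len(self.monomers[0])

    def residues(self) -> Iterable[ResidueRecord]:
        """All residues, monomer 1 first, each in sequence order."""
        yield from self.monomers[0]
        yield from self.monomers[1]

    def coordinates(self, monomer: int | None = None) -> np.ndarray:
        """Cα coordinates as an array — (2N, 3) or (N, 3) for one monomer."""
        if monomer is None:
            recs: Sequence[ResidueRecord] = list(self.residues())
        else:
            recs = self.monomers[monomer - 1]
        return np.array([r.ca_position for r in recs], dtype=float)


def _shift_author_number(label: str, offset: int) -> str:
    """Shift the numeric part of an author-number label, keeping any
    insertion code suffix verbatim."""
    digits = ""
    i = 0
    if label[:1] == "-":
        digits, i = "-", 1
    while i < len(label) and label[i].isdigit():
        digits += label[i]
        i += 1
    if not digits.lstrip("-"):
        raise StructureError(f"author number {label!r} has no numeric part to shift")
    return f"{int(digits) + offset}{label[i:]}"


def renumber(model: StructureModel, offset: int) -> StructureModel:
    """Shift every residue's author number by ``offset``.

    Used to translate between numbering conventions of orthologous
    sequences (e.g. a bovine-numbered model reported against human
    positions). Purely cosmetic: sequence positions, coordinates and hence
    every centrality value are unchanged.
    """
    if offset == 0:
        return model
    new_monomers = tuple(
        tuple(
            replace(rec, author_number=_shift_author_number(rec.author_number, offset))
            for rec in monomer
        )
        for monomer in model.monomers
    )
    return StructureModel(
        monomers=new_monomers,  # type: ignore[arg-type]
        source_label=model.source_label,
        numbering_offset=model.numbering_offset + offset,
    )


def _first_altloc_ca(residue):
    """The Cα atom of a residue, taking the first-listed alternate
    conformer when the atom is disordered. Returns None if absent."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        atom = atom.disordered_get_list()[0]
    return atom


def load_structure(
    path: str | Path,
    chain_ids: tuple[str, str] = ("A", "B"),
    model_index: int = 1,
    extra_residues: Iterable[str] = (),
    source_label: str | None = None,
) -> StructureModel:
    """Read a PDB file into a two-monomer :class:`StructureModel`.

    Parameters
    ----------
    path:
        PDB file with at least the two requested chains.
    chain_ids:
        Chain identifiers of monomer 1 and monomer 2, in that order.
    model_index:
        1-based index of the model to read; files with a single (implicit)
        model use the default ``1``.
    extra_residues:
        Additional residue names (beyond the 20 standard amino acids) to
        admit into the network, provided they carry a Cα atom. HETATM
        records, waters and ligands are always skipped.

    Raises
    ------
    StructureError
        ``"chain not found"`` for a missing chain; ``"incomplete residue"``
        naming the residue when a selected residue has no Cα atom;
        ``"monomer length mismatch"`` when the chains differ in length.
    """
    path = Path(path)
    allowed = STANDARD_AMINO_ACIDS | {str(r).upper() for r in extra_residues}
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not 1 <= model_index <= len(models):
        raise StructureError(
            f"model {model_index} not found (file has {len(models)} model(s))"
        )
    model = models[model_index - 1]

    monomers: list[tuple[ResidueRecord, ...]] = []
    for monomer_id, chain_id in enumerate(chain_ids, start=1):
        if chain_id not in model:
            raise StructureError(f"chain not found: {chain_id!r} in {path.name}")
        chain = model[chain_id]
        records = []
        position = 0
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag.strip():
                continue  # HETATM / water
            resname = residue.get_resname().strip().upper()
            if resname not in allowed:
                continue
            atom = _first_altloc_ca(residue)
            if atom is None:
                raise StructureError(
                    f"incomplete residue: {chain_id}/{resseq}{icode.strip()} "
                    f"({resname}) has no CA atom"
                )
            position += 1
            x, y, z = (float(c) for c in atom.coord)
            records.append(
                ResidueRecord(
                    monomer_id=monomer_id,
                    sequence_position=position,
                    residue_name=resname,
                    author_number=f"{resseq}{icode.strip()}",
                    ca_position=(x, y, z),
                )
            )
        monomers.append(tuple(records))

    if len(monomers[0]) != len(monomers[1]):
        raise StructureError(
            "monomer length mismatch: chain "
            f"{chain_ids[0]} has {len(monomers[0])} residues, "
            f"chain {chain_ids[1]} has {len(monomers[1])}"
        )
    names1 = [r.residue_name for r in monomers[0]]
    names2 = [r.residue_name for r in monomers[1]]
    if names1 != names2:
        n_diff = sum(a != b for a, b in zip(names1, names2))
        warnings.warn(
            f"{path.name}: the two chains differ in residue identity at "
            f"{n_diff} position(s); treating them as a homodimer anyway",
            stacklevel=2,
        )
    return StructureModel(
        monomers=(monomers[0], monomers[1]),
        source_label=source_label if source_label is not None else str(path),
    )
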