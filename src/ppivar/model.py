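"""Core in-memory containers for assemblies, chains and hetero-dimers.

An :class:`Assembly` is one biological assembly: the author-designated,
biologically relevant multi-chain form of a crystal structure.  Residues are
indexed 1-based on the full deposited sequence (SEQRES), so that positions
are comparable across entries that use different author numbering.  Residues
without resolved coordinates are kept in the chain but carry no atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: 3-letter -> 1-letter code for the 20 standard amino acids.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass
class Atom:
    """A heavy atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element")


@dataclass
class Residue:
    """One residue; ``seqres_index`` is its 1-based SEQRES position.

    ``atoms`` may be empty only for residues without resolved coordinates;
    such residues are excluded from all geometric computations.
    """

    seqres_index: int
    author_id: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def resolved(self) -> bool:
        return len(self.atoms) > 0

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclass
class Chain:
    """A protein chain: SEQRES string plus (possibly partial) coordinates."""

    chain_id: str
    seqres: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.seqres) < 1:
            raise ValueError(f"chain {self.chain_id} has empty SEQRES")
        seen = set()
        for r in self.residues:
            if r.resolved:
                if not 1 <= r.seqres_index <= len(self.seqres):
                    raise ValueError(
                        f"residue {r.seqres_index} outside SEQRES of chain "
                        f"{self.chain_id}"
                    )
                if r.seqres_index in seen:
                    raise ValueError(
                        f"duplicate SEQRES position {r.seqres_index} in chain "
                        f"{self.chain_id}"
                    )
                seen.add(r.seqres_index)

    def resolved_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.resolved]

    def resolved_positions(self) -> set[int]:
        return {r.seqres_index for r in self.residues if r.resolved}

    def residue_at(self, seqres_index: int) -> Residue | None:
        for r in self.residues:
            if r.seqres_index == seqres_index:
                return r
        return None

    def atom_coords(self) -> np.ndarray:
        """All resolved atom coordinates, one row per atom."""
        rows = [a.coord for r in self.resolved_residues() for a in r.atoms]
        return np.array(rows, dtype=float).reshape(-1, 3)

    def atom_residue_index(self) -> np.ndarray:
        """SEQRES position of each atom row of :meth:`atom_coords`."""
        rows = [r.seqres_index for r in self.resolved_residues() for _ in r.atoms]
        return np.array(rows, dtype=int)


@dataclass
class Assembly:
    """One biological assembly with resolution/method metadata."""

    assembly_id: str
    chains: list[Chain]
    resolution: float | None = None
    method: str = "X-RAY DIFFRACTION"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in assembly {self.assembly_id}")
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution must be positive when present")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id} in assembly {self.assembly_id}")

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)


@dataclass(frozen=True)
class MappingEntry:
    accession: str
    family: str


class ProteinMapping:
    """Chain -> protein accession / family lookup table.

    Stands in for a precomputed structure-to-protein-database mapping; keys
    are ``(assembly_id, chain_id)``.
    """

    def __init__(self, entries: dict[tuple[str, str], MappingEntry] | None = None):
        self.entries: dict[tuple[str, str], MappingEntry] = dict(entries or {})

    def add(self, assembly_id: str, chain_id: str, accession: str, family: str) -> None:
        self.entries[(assembly_id, chain_id)] = MappingEntry(accession, family)

    def get(self, assembly_id: str, chain_id: str) -> MappingEntry | None:
        return self.entries.get((assembly_id, chain_id))

    def __len__(self) -> int:
        return len(self.entries)


def unordered(a, b) -> tuple:
    """Canonical unordered-pair key."""
    return (a, b) if a <= b else (b, a)


@dataclass
class HeteroDimer:
    """An ordered pair of interacting chains mapped to two different proteins.

    The chain order is canonical (sorted by family, then accession, then
    sequence, then chain id) so that corresponding sides of two dimers of the
    same interaction can be matched positionally.
    """

    assembly_id: str
    chainX: Chain
    chainY: Chain
    accX: str
    accY: str
    famX: str
    famY: str
    interface: "object | None" = None  # InterfaceAnnotation, filled later
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.accX == self.accY:
            raise ValueError("hetero-dimer requires two different accessions")

    @property
    def uid(self) -> str:
        return f"{self.assembly_id}:{self.chainX.chain_id}-{self.chainY.chain_id}"

    @property
    def seq_pair(self) -> tuple[str, str]:
        return unordered(self.chainX.seqres, self.chainY.seqres)

    @property
    def prot_pair(self) -> tuple[str, str]:
        return unordered(self.accX, self.accY)

    @property
    def fam_pair(self) -> tuple[str, str]:
        return unordered(self.famX, self.famY)

    def sort_key(self) -> tuple:
        return (self.assembly_id, self.chainX.chain_id, self.chainY.chain_id)

    def side(self, which: str) -> tuple[Chain, str, str]:
        """Return (chain, accession, family) for side 'X' or 'Y'."""
        if which == "X":
            return self.chainX, self.accX, self.famX
        if which == "Y":
            return self.chainY, self.accY, self.famY
        raise ValueError(which)


def canonical_chain_order(
    chain_a: Chain, meta_a: MappingEntry, chain_b: Chain, meta_b: MappingEntry
) -> bool:
    """True if (a, b) is already in canonical order for a dimer."""
    key_a = (meta_a.family, meta_a.accession, chain_a.seqres, chain_a.chain_id)
    key_b = (meta_b.family, meta_b.accession, chain_b.seqres, chain_b.chain_id)
    return key_a <= key_b
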