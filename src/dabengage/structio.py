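"""Minimal macromolecular structure model with PDB/mmCIF I/O.

Downstream geometry needs only a small, deterministic slice of a deposited
structure: resolved residues in file order, their Cα and heavy-atom
coordinates, and the crystal cell. This module builds that slice on top of
gemmi (first model only, altloc A kept, waters dropped) and exposes chain
termini as defined by the first/last *resolved* residue carrying a Cα —
crystal structures routinely have disordered termini, so the measurable
terminus is the resolved one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "CrystalCell",
    "Structure",
    "StructureError",
    "EmptyStructureError",
    "MissingAtomError",
    "read_structure",
    "write_structure",
    "chain_terminal_ca",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Base error for structure parsing/validation problems."""


class EmptyStructureError(StructureError):
    """Raised when a file yields no usable polymer chains."""


class MissingAtomError(StructureError):
    """Raised when a required atom (e.g. a terminal Cα) cannot be found."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    is_ca: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name!r}: coordinate must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if sum(a.is_ca for a in self.atoms) > 1:
            raise StructureError(f"residue {self.name} {self.seq_id}: more than one Cα")

    @property
    def ca(self) -> Optional[Atom]:
        for a in self.atoms:
            if a.is_ca:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    entity_role: Literal["antigen", "binder_domain", "other"] = "other"

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates of resolved residues, file order; shape (n, 3)."""
        pts = [r.ca.coord for r in self.residues if r.ca is not None]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def ca_by_seq_id(self) -> dict[int, np.ndarray]:
        return {r.seq_id: r.ca.coord for r in self.residues if r.ca is not None}


@dataclass
class CrystalCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = ""
    z_asu_per_cell: int = 1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise StructureError("cell angles must lie in (0, 180) degrees")
        if self.z_asu_per_cell < 1:
            raise StructureError("Z (asymmetric units per cell) must be >= 1")

    def volume(self) -> float:
        """Cell volume in ų via the general triclinic formula."""
        ca_, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca_**2 - cb**2 - cg**2 + 2.0 * ca_ * cb * cg
        if arg <= 0:
            raise StructureError("degenerate cell: non-positive metric determinant")
        return self.a * self.b * self.c * math.sqrt(arg)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    cell: Optional[CrystalCell] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate chain ids in {self.source_id!r}: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.source_id!r}")

    def copy(self) -> "Structure":
        chains = [
            Chain(
                c.chain_id,
                [
                    Residue(
                        r.seq_id,
                        r.name,
                        [Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.is_ca) for a in r.atoms],
                        r.insertion_code,
                    )
                    for r in c.residues
                ],
                c.entity_role,
            )
            for c in self.chains
        ]
        return Structure(chains, self.cell, self.source_id)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every atom mapped x -> R x + t."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for c in out.chains:
            for r in c.residues:
                for a in r.atoms:
                    a.coord = R @ a.coord + t
        return out


def _convert_gemmi(st: gemmi.Structure, keep_waters: bool) -> Structure:
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{st.name!r}: no models")
    model = st[0]  # first model only: deterministic geometry
    chains: list[Chain] = []
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            if gres.is_water() and not keep_waters:
                continue
            atoms: list[Atom] = []
            for gat in gres:
                if gat.altloc not in ("", "\x00", " ", "A"):
                    continue
                atoms.append(
                    Atom(
                        name=gat.name,
                        element=gat.element.name,
                        coord=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                        occupancy=min(max(gat.occ, 0.0), 1.0),
                        is_ca=(gat.name == "CA" and gat.element.name != "Ca"),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        seq_id=gres.seqid.num,
                        name=gres.name,
                        atoms=atoms,
                        insertion_code=(gres.seqid.icode or "").strip(),
                    )
                )
        if residues:
            chains.append(Chain(chain_id=gch.name, residues=residues))
    if not chains:
        raise EmptyStructureError(f"{st.name!r}: no polymer chains with atoms")
    cell = None
    if st.cell and st.cell.a > 0:
        cell = CrystalCell(
            a=st.cell.a,
            b=st.cell.b,
            c=st.cell.c,
            alpha=st.cell.alpha,
            beta=st.cell.beta,
            gamma=st.cell.gamma,
            space_group=st.spacegroup_hm or "",
            z_asu_per_cell=_z_from_spacegroup(st.spacegroup_hm),
        )
    return Structure(chains=chains, cell=cell, source_id=st.name or "")


def _z_from_spacegroup(hm: Optional[str]) -> int:
    if not hm:
        return 1
    sg = gemmi.find_spacegroup_by_name(hm)
    if sg is None:
        return 1
    return len(sg.operations())


def read_structure(path: str, dialect: Literal["pdb", "mmcif"] = "pdb", *, keep_waters: bool = False) -> Structure:
    """Read the first model of a PDB or mmCIF file.

    Waters are excluded by default; altloc A is kept; chain and residue order
    follow the file. Raises :class:`EmptyStructureError` if no polymer chain
    with atoms survives, and a parse error naming the offending input
    otherwise.
    """
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        elif dialect == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except (RuntimeError, OSError) as exc:
        raise StructureError(f"cannot parse {path!r} as {dialect}: {exc}") from exc
    return _convert_gemmi(st, keep_waters)


def write_structure(structure: Structure, path: str, dialect: Literal["pdb"] = "pdb") -> None:
    """Write a structure as PDB. Round-trips counts and coordinates to 3 decimals."""
    if not structure.chains or all(not c.residues for c in structure.chains):
        raise EmptyStructureError("refusing to write an empty structure")
    if dialect != "pdb":
        raise ValueError(f"unsupported write dialect {dialect!r}")
    st = gemmi.Structure()
    st.name = structure.source_id or "dabengage"
    if structure.cell is not None:
        st.cell = gemmi.UnitCell(
            structure.cell.a,
            structure.cell.b,
            structure.cell.c,
            structure.cell.alpha,
            structure.cell.beta,
            structure.cell.gamma,
        )
        if structure.cell.space_group:
            st.spacegroup_hm = structure.cell.space_group
    model = gemmi.Model("1")
    for chain in structure.chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            for atom in res.atoms:
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.element = gemmi.Element(atom.element)
                gat.pos = gemmi.Position(*atom.coord)
                gat.occ = atom.occupancy
                gres.add_atom(gat)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def chain_terminal_ca(chain: Chain, end: Literal["n_term", "c_term"]) -> np.ndarray:
    """Cα coordinate of the first (n_term) / last (c_term) resolved residue with a Cα.

    Residues lacking a Cα are skipped, falling back to the nearest resolved
    residue (in file order) that has one.
    """
    if end not in ("n_term", "c_term"):
        raise ValueError(f"end must be 'n_term' or 'c_term', got {end!r}")
    residues: Iterable[Residue] = chain.residues if end == "n_term" else reversed(chain.residues)
    for res in residues:
        ca = res.ca
        if ca is not None:
            return ca.coord.copy()
    raise MissingAtomError(f"chain {chain.chain_id!r}: no residue has a Cα atom")
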