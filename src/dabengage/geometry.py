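"""Rigid superposition, inter-terminal distances, interfaces, solvent content.

The mechanistic argument for the side-on engagement mode rests on three Cα-Cα
distances measured between domain-antibody termini bound at the two equivalent
epitopes of the VEGF homodimer:

* ``d_vh_vh`` — V_H C-terminal Cα to V_H C-terminal Cα (the attachment points
  of the N-terminal linkers of the full molecule),
* ``d_vk_vk`` — V_κ N-terminal Cα to V_κ N-terminal Cα (the C-terminal linker
  attachment points),
* ``d_cross`` — V_H C-terminal Cα to the V_κ N-terminal Cα bound at the
  *opposite* epitope, measured after the two co-crystal structures are
  superposed on their shared antigen.

This module provides the Kabsch superposition used to bring two complexes into
a common antigen frame, the distance report itself, heavy-atom interface
detection, and the Matthews solvent-content check for a crystal cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import CrystalCell, Structure, chain_terminal_ca

__all__ = [
    "SuperpositionResult",
    "TerminalDistanceReport",
    "InterfaceSet",
    "GeometryError",
    "kabsch_superpose",
    "superpose_on_antigen",
    "terminal_distances",
    "interface_residues",
    "solvent_content",
    "MATTHEWS_CONSTANT",
]

#: Matthews convention: reciprocal protein density in ų·Da⁻¹ units such that
#: solvent fraction = 1 − MATTHEWS_CONSTANT / V_M.
MATTHEWS_CONSTANT = 1.23


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper rotation, det = +1
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å, after transformation
    n_atoms: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation


@dataclass
class TerminalDistanceReport:
    d_vh_vh: Optional[float] = None  # Å, V_H C-term ↔ V_H C-term
    d_vk_vk: Optional[float] = None  # Å, V_κ N-term ↔ V_κ N-term
    d_cross: Optional[float] = None  # Å, V_H C-term ↔ opposite-epitope V_κ N-term
    provenance: str = ""

    def as_dict(self) -> dict:
        return {
            "d_vh_vh": self.d_vh_vh,
            "d_vk_vk": self.d_vk_vk,
            "d_cross": self.d_cross,
            "provenance": self.provenance,
        }


@dataclass
class InterfaceSet:
    epitope_residues: list[tuple[str, int]] = field(default_factory=list)
    paratope_residues: list[tuple[str, int]] = field(default_factory=list)
    cutoff: float = 4.5


def kabsch_superpose(moving: Sequence, fixed: Sequence) -> SuperpositionResult:
    """Optimal least-squares rigid superposition of paired point sets.

    Returns the proper rotation R (reflections excluded by determinant
    correction of the SVD solution) and translation t minimising
    ``|| (R·moving + t) − fixed ||``; ``rmsd`` is evaluated after applying the
    transform. Requires ≥3 non-collinear point pairs.
    """
    P = np.asarray(moving, float).reshape(-1, 3)
    Q = np.asarray(fixed, float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise GeometryError(f"point sets differ in length: {P.shape[0]} vs {Q.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 point pairs, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set: superposition ill-conditioned")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def superpose_on_antigen(
    complex_a: Structure,
    complex_b: Structure,
    antigen_map: Sequence[tuple[str, str]],
    *,
    rmsd_cap: float = 5.0,
) -> tuple[Structure, SuperpositionResult, bool]:
    """Transform ``complex_b`` into ``complex_a``'s frame via shared antigen chains.

    ``antigen_map`` pairs antigen chain ids ``(chain_in_a, chain_in_b)``;
    Cα atoms are matched by identical residue ``seq_id`` within each mapped
    pair (the deposited antigen chains share numbering, so no alignment is
    attempted). Returns the moved copy of ``complex_b``, the superposition
    result on the antigen Cαs, and a warning flag set when the antigen rmsd
    exceeds ``rmsd_cap`` (a sanity cap, not a failure).
    """
    fixed_pts: list[np.ndarray] = []
    moving_pts: list[np.ndarray] = []
    for ch_a, ch_b in antigen_map:
        ca_a = complex_a.chain(ch_a).ca_by_seq_id()
        ca_b = complex_b.chain(ch_b).ca_by_seq_id()
        for seq_id in sorted(set(ca_a) & set(ca_b)):
            fixed_pts.append(ca_a[seq_id])
            moving_pts.append(ca_b[seq_id])
    if len(fixed_pts) < 3:
        raise GeometryError(
            f"antigen mapping {list(antigen_map)} yields {len(fixed_pts)} matched Cα (<3)"
        )
    sup = kabsch_superpose(moving_pts, fixed_pts)
    moved = complex_b.transform(sup.rotation, sup.translation)
    return moved, sup, sup.rmsd > rmsd_cap


RoleValue = tuple  # (domain_type, terminus[, epitope_tag])


def _collect_termini(
    merged: Structure, roles: Mapping[str, RoleValue]
) -> dict[str, list[tuple[np.ndarray, Optional[object]]]]:
    """Group terminal Cα coordinates by domain type, keeping optional epitope tags."""
    out: dict[str, list[tuple[np.ndarray, Optional[object]]]] = {"vh": [], "vk": []}
    for chain_id, role in roles.items():
        domain = role[0]
        terminus = role[1]
        epitope = role[2] if len(role) > 2 else None
        if domain not in out:
            raise GeometryError(f"unknown domain type {domain!r} for chain {chain_id!r}")
        chain = merged.chain(chain_id)  # KeyError if the role names a missing chain
        coord = chain_terminal_ca(chain, terminus)
        out[domain].append((coord, epitope))
    return out


def terminal_distances(merged: Structure, roles: Mapping[str, RoleValue]) -> TerminalDistanceReport:
    """Measure the three inter-terminal Cα distances from a merged model.

    ``roles`` maps chain id → ``(domain_type, terminus)`` with ``domain_type``
    in {"vh", "vk"} and ``terminus`` in {"n_term", "c_term"}; an optional third
    element tags the epitope the chain occupies. Each report field is filled
    only when the needed chains are present:

    * ``d_vh_vh`` / ``d_vk_vk`` need two chains of that type;
    * ``d_cross`` pairs each V_H with the V_κ at the *other* epitope. With
      explicit epitope tags that is the differently-tagged partner; without
      tags the larger of the two V_H/V_κ distances is used, because dAbs bound
      at the same epitope occupy overlapping space and are necessarily the
      closer pair.
    """
    groups = _collect_termini(merged, roles)
    report = TerminalDistanceReport(provenance=f"structure {merged.source_id!r}")

    def pair_distance(entries: list) -> Optional[float]:
        if len(entries) != 2:
            return None
        return float(np.linalg.norm(entries[0][0] - entries[1][0]))

    report.d_vh_vh = pair_distance(groups["vh"])
    report.d_vk_vk = pair_distance(groups["vk"])

    if groups["vh"] and groups["vk"]:
        tagged = all(e[1] is not None for e in groups["vh"] + groups["vk"])
        cross: list[float] = []
        for (vh_xyz, vh_tag), (vk_xyz, vk_tag) in itertools.product(groups["vh"], groups["vk"]):
            d = float(np.linalg.norm(vh_xyz - vk_xyz))
            if tagged:
                if vh_tag != vk_tag:
                    cross.append(d)
            else:
                cross.append(d)
        if cross:
            report.d_cross = min(cross) if tagged else max(cross)
    return report


def interface_residues(
    structure: Structure,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cutoff: float = 4.5,
) -> InterfaceSet:
    """Residues of two chain groups with any heavy-atom pair within ``cutoff`` Å.

    ``group_a`` is reported as the epitope side, ``group_b`` as the paratope
    side; both lists come back deduplicated and sorted.
    """
    if not group_a or not group_b:
        raise GeometryError("both chain groups must be non-empty")
    if set(group_a) & set(group_b):
        raise GeometryError("chain groups must be disjoint")

    def heavy_atoms(chain_ids: Sequence[str]):
        coords: list[np.ndarray] = []
        labels: list[tuple[str, int]] = []
        for cid in chain_ids:
            for res in structure.chain(cid).residues:
                for atom in res.atoms:
                    if atom.element.upper() == "H":
                        continue
                    coords.append(atom.coord)
                    labels.append((cid, res.seq_id))
        return np.array(coords, float).reshape(-1, 3), labels

    xyz_a, lab_a = heavy_atoms(group_a)
    xyz_b, lab_b = heavy_atoms(group_b)
    epi: set[tuple[str, int]] = set()
    para: set[tuple[str, int]] = set()
    if cutoff > 0 and len(xyz_a) and len(xyz_b):
        tree = cKDTree(xyz_b)
        for ia, neighbours in enumerate(tree.query_ball_point(xyz_a, cutoff)):
            if neighbours:
                epi.add(lab_a[ia])
                for ib in neighbours:
                    para.add(lab_b[ib])
    return InterfaceSet(
        epitope_residues=sorted(epi),
        paratope_residues=sorted(para),
        cutoff=cutoff,
    )


def solvent_content(cell: CrystalCell, asu_protein_mass: float) -> float:
    """Matthews solvent fraction of a crystal from cell + asymmetric-unit mass.

    ``V_M = V_cell / (Z · M)`` with M in Da; the solvent fraction is
    ``1 − 1.23 / V_M``, clamped to [0, 1). Strictly decreasing in the mass.
    """
    if asu_protein_mass <= 0:
        raise GeometryError("asymmetric-unit protein mass must be positive")
    v_m = cell.volume() / (cell.z_asu_per_cell * asu_protein_mass)
    return float(min(max(1.0 - MATTHEWS_CONSTANT / v_m, 0.0), 1.0 - 1e-12))
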