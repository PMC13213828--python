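"""Structure I/O and rigid-body geometry for binding-site analysis.

Coordinates live in a :class:`biotite.structure.AtomArray`; the thin
:class:`StructureModel` wrapper adds a model identifier and whether the
B-factor column carries per-residue predicted confidence (pLDDT), as it
does for AlphaFold-class models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as _pdb
from biotite.structure.io import pdbx as _pdbx
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as _Rotation

__all__ = [
    "StructureModel",
    "BindingSite",
    "Transform",
    "read_structure",
    "write_structure",
    "binding_site",
    "superpose",
    "transfer_ligand",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class StructureModel:
    """One set of atomic coordinates with per-residue identity and B-factors."""

    atoms: struc.AtomArray
    model_id: str = ""
    plddt_available: bool = False

    def __post_init__(self) -> None:
        if self.atoms.array_length() == 0:
            raise ValueError(f"structure {self.model_id!r} has zero atoms")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError(f"structure {self.model_id!r} has non-finite coordinates")

    @property
    def coord(self) -> np.ndarray:
        return self.atoms.coord

    def protein(self) -> struc.AtomArray:
        """Polymer (non-hetero, non-water) atoms."""
        mask = ~self.atoms.hetero & (self.atoms.res_name != "HOH")
        return self.atoms[mask]

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue number) keys of protein residues."""
        prot = self.protein()
        seen: dict[tuple[str, int], None] = {}
        for ch, num in zip(prot.chain_id, prot.res_id):
            seen.setdefault((str(ch), int(num)))
        return list(seen)

    def atom_map(
        self, residues: Iterable[tuple[str, int]] | None = None
    ) -> dict[tuple[str, int, str], int]:
        """(chain, residue number, atom name) -> atom index, optionally restricted."""
        keys = set(residues) if residues is not None else None
        out: dict[tuple[str, int, str], int] = {}
        a = self.atoms
        for i in range(a.array_length()):
            key = (str(a.chain_id[i]), int(a.res_id[i]))
            if keys is not None and key not in keys:
                continue
            out[(key[0], key[1], str(a.atom_name[i]))] = i
        return out

    def ligand_atoms(self, resname: str) -> np.ndarray:
        """Coordinates of hetero atoms with the given residue name."""
        mask = self.atoms.hetero & (self.atoms.res_name == resname)
        if not mask.any():
            raise ValueError(f"no hetero atoms named {resname!r} in {self.model_id!r}")
        return self.atoms.coord[mask]


def read_structure(
    path: str | Path, fmt: str | None = None, model_id: str | None = None
) -> StructureModel:
    """Read a PDB or mmCIF coordinate file (format inferred from the suffix).

    Alternate locations are resolved to the highest occupancy; the B-factor
    column is retained, so predicted models keep their per-residue pLDDT.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    extra = ["b_factor", "occupancy"]
    if fmt == "pdb":
        pdb_file = _pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1, altloc="occupancy", extra_fields=extra)
    elif fmt == "mmcif":
        cif_file = _pdbx.CIFFile.read(str(path))
        atoms = _pdbx.get_structure(cif_file, model=1, altloc="occupancy",
                                    extra_fields=extra)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no atoms parsed")
    return StructureModel(atoms=atoms, model_id=model_id or path.stem)


def write_structure(model: StructureModel, path: str | Path) -> Path:
    """Write a model to PDB format (B-factors preserved)."""
    path = Path(path)
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(model.atoms)
    pdb_file.write(str(path))
    return path


@dataclass(frozen=True)
class BindingSite:
    """Residues within a distance cutoff of the bound ligand(s)."""

    residues: frozenset[tuple[str, int]]
    cutoff: float = 5.0

    def __len__(self) -> int:
        return len(self.residues)

    def sorted(self) -> list[tuple[str, int]]:
        return sorted(self.residues)


def binding_site(
    ref: StructureModel,
    ligand_atoms: np.ndarray | Sequence[Sequence[float]],
    cutoff: float = 5.0,
) -> BindingSite:
    """Residues with any atom within ``cutoff`` (Å, default 5) of any ligand atom.

    Multiple ligands can simply be concatenated: the site is the union over
    all supplied ligand atoms.
    """
    lig = np.asarray(ligand_atoms, dtype=float).reshape(-1, 3)
    if lig.size == 0:
        raise ValueError("ligand_atoms is empty")
    prot = ref.protein()
    dist, _ = cKDTree(lig).query(prot.coord, k=1)
    near = dist <= cutoff
    residues = frozenset(
        (str(ch), int(num))
        for ch, num in zip(prot.chain_id[near], prot.res_id[near])
    )
    if not residues:
        warnings.warn(
            f"no residues within {cutoff} Å of the ligand in {ref.model_id!r}",
            stacklevel=2,
        )
    return BindingSite(residues=residues, cutoff=cutoff)


@dataclass(frozen=True)
class Transform:
    """Rigid-body transform x -> (x - center) @ R.T + center + shift."""

    rotation: np.ndarray
    center: np.ndarray
    shift: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(coords, dtype=float)
        return (c - self.center) @ self.rotation.T + self.center + self.shift


def _paired_coords(
    mobile: StructureModel,
    ref: StructureModel,
    selection: Iterable[tuple[str, int, str]],
) -> tuple[np.ndarray, np.ndarray]:
    m_map = mobile.atom_map()
    r_map = ref.atom_map()
    mob, fix = [], []
    for key in selection:
        if key in m_map and key in r_map:
            mob.append(mobile.atoms.coord[m_map[key]])
            fix.append(ref.atoms.coord[r_map[key]])
    return np.asarray(mob, dtype=float), np.asarray(fix, dtype=float)


def superpose(
    mobile: StructureModel,
    ref: StructureModel,
    selection: Iterable[tuple[str, int, str]],
) -> tuple[Transform, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``ref``.

    Atoms are paired by (chain, residue number, atom name) over the
    selection.  Returns the optimal proper rotation + translation and the
    post-fit RMSD over the paired atoms.  Requires at least three
    non-collinear pairs.
    """
    mob, fix = _paired_coords(mobile, ref, selection)
    if len(mob) < 3:
        raise ValueError(f"superposition needs >= 3 paired atoms, got {len(mob)}")
    mob_center = mob.mean(axis=0)
    fix_center = fix.mean(axis=0)
    centered = mob - mob_center
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("superposition selection is collinear")
    # Kabsch in float64 (proper rotation, det = +1)
    rotation, rssd = _Rotation.align_vectors(fix - fix_center, centered)
    rot = rotation.as_matrix()
    tr = Transform(rotation=rot, center=mob_center,
                   shift=fix_center - mob_center)
    rmsd = float(np.sqrt(rssd**2 / len(mob)))
    return tr, rmsd


def backbone_selection(
    site: BindingSite | Iterable[tuple[str, int]]
) -> list[tuple[str, int, str]]:
    """Backbone (N, CA, C, O) atom keys of the given residues."""
    residues = site.residues if isinstance(site, BindingSite) else site
    return [(ch, num, name) for ch, num in sorted(residues) for name in BACKBONE_ATOMS]


def transfer_ligand(
    apo: StructureModel,
    holo: StructureModel,
    ligand_atoms: np.ndarray,
    clash_cutoff: float = 2.5,
    site_cutoff: float = 5.0,
) -> np.ndarray:
    """Carry holo ligand coordinates into an apo frame, pruning clashes.

    The holo structure is superposed onto the apo structure on the
    binding-site backbone (site = residues within ``site_cutoff`` of the
    ligand in the holo frame); the ligand coordinates follow the same
    transform; ligand atoms with any receptor atom within ``clash_cutoff``
    (Å, default 2.5) are then removed.
    """
    lig = np.asarray(ligand_atoms, dtype=float).reshape(-1, 3)
    site = binding_site(holo, lig, cutoff=site_cutoff)
    tr, _ = superpose(holo, apo, backbone_selection(site))
    moved = tr.apply(lig)
    rec = apo.protein().coord
    dist, _ = cKDTree(rec).query(moved, k=1)
    kept = moved[dist >= clash_cutoff]
    if kept.size == 0:
        warnings.warn("all transferred ligand atoms clash with the receptor",
                      stacklevel=2)
    return kept
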