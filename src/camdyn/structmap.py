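"""Structure-level computations on PDB coordinate files.

Thin layer over biotite's AtomArray: fixed-width PDB parsing with a
keep-first altloc policy, Kabsch least-squares superposition and RMSD over
matched atom selections, distance-based ligand contact listing, and
painting per-residue analysis values (CSP, HDX uptake differences, nOe
changes) into the B-factor column for visualisation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "StructureModel",
    "ContactSet",
    "read_structure",
    "kabsch_rmsd",
    "ligand_contacts",
    "paint_residue_values",
    "write_structure",
]

_WATER = {"HOH", "WAT", "DOD"}


@dataclasses.dataclass
class StructureModel:
    """A parsed structure: biotite AtomArray plus provenance."""

    atoms: struc.AtomArray
    path: str | None = None

    def __post_init__(self):
        if self.atoms.array_length() == 0:
            raise ValueError("empty structure")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("non-finite coordinates")

    def __len__(self):
        return self.atoms.array_length()

    def protein(self) -> struc.AtomArray:
        a = self.atoms
        return a[struc.filter_amino_acids(a)]

    def hetero(self, resname: str) -> struc.AtomArray:
        a = self.atoms
        return a[(a.res_name == resname)]

    def without_water(self) -> "StructureModel":
        a = self.atoms
        return StructureModel(a[~np.isin(a.res_name, list(_WATER))], self.path)


def read_structure(path) -> StructureModel:
    """Read ATOM/HETATM records from a PDB file.

    Alternate locations: the first altloc of each atom is kept (deterministic
    policy); hydrogens are retained if present but all distance analyses use
    heavy atoms only.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(
        model=1, altloc="first", extra_fields=["b_factor", "occupancy", "atom_id"]
    )
    return StructureModel(atoms, path=str(path))


def write_structure(model: StructureModel, path) -> Path:
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    path = Path(path)
    pdb.write(str(path))
    return path


def _matched_ca(a: struc.AtomArray, b: struc.AtomArray, atom_name: str,
                res_range: tuple[int, int] | None):
    def table(arr):
        m = arr.atom_name == atom_name
        if res_range is not None:
            m &= (arr.res_id >= res_range[0]) & (arr.res_id <= res_range[1])
        sub = arr[m & struc.filter_amino_acids(arr)]
        return {(c, r): i for i, (c, r) in enumerate(zip(sub.chain_id, sub.res_id))}, sub

    ta, sa = table(a)
    tb, sb = table(b)
    keys = sorted(set(ta) & set(tb))
    if len(keys) < 3:
        raise ValueError("fewer than 3 matched atoms")
    ia = [ta[k] for k in keys]
    ib = [tb[k] for k in keys]
    return sa[ia], sb[ib]


def kabsch_rmsd(
    a: StructureModel,
    b: StructureModel,
    atom_name: str = "CA",
    res_range: tuple[int, int] | None = None,
) -> float:
    """RMSD (A) after optimal proper-rotation superposition.

    Atoms are matched by (chain, residue index, atom name) intersection;
    superposition is the closed-form least-squares (Kabsch) solution with
    reflections excluded.
    """
    sa, sb = _matched_ca(a.atoms, b.atoms, atom_name, res_range)
    fitted, _ = struc.superimpose(sa, sb)
    return float(struc.rmsd(sa, fitted))


@dataclasses.dataclass
class ContactSet:
    """Protein residues within *cutoff* of any ligand heavy atom."""

    residues: pd.DataFrame  # chain, res_id, res_name, min_distance
    ligand_resname: str
    cutoff: float

    def residue_ids(self) -> list[int]:
        return sorted(self.residues.res_id.unique().tolist())


def ligand_contacts(
    model: StructureModel, ligand_resname: str, cutoff: float = 3.9
) -> ContactSet:
    """Heavy-atom contact listing between protein and a named ligand."""
    prot = model.protein()
    prot = prot[prot.element != "H"]
    lig = model.hetero(ligand_resname)
    lig = lig[lig.element != "H"]
    if lig.array_length() == 0:
        raise ValueError(f"ligand {ligand_resname!r} absent")
    d = np.linalg.norm(
        prot.coord[:, None, :] - lig.coord[None, :, :], axis=-1
    ).min(axis=1)
    rows = {}
    for chain, rid, rname, dist in zip(prot.chain_id, prot.res_id, prot.res_name, d):
        key = (chain, int(rid))
        if dist <= cutoff and (key not in rows or dist < rows[key][3]):
            rows[key] = (chain, int(rid), rname, float(dist))
    df = pd.DataFrame(
        sorted(rows.values(), key=lambda r: (r[0], r[1])),
        columns=["chain", "res_id", "res_name", "min_distance"],
    )
    return ContactSet(df, ligand_resname, cutoff)


def paint_residue_values(
    model: StructureModel,
    values: pd.DataFrame,
    missing_value: float = -1.0,
) -> StructureModel:
    """Write per-residue scalars into the B-factor column of every atom.

    *values* carries columns (residue, value).  Residues without a value get
    the sentinel.  Values are clamped to the PDB field range
    [-99.99, 999.99] so the result stays writable as valid fixed-width PDB.
    """
    if len(values) == 0:
        raise ValueError("empty value table")
    lut = dict(zip(values.residue.astype(int), values.value.astype(float)))
    atoms = model.atoms.copy()
    b = np.array([lut.get(int(r), missing_value) for r in atoms.res_id])
    atoms.b_factor = np.clip(b, -99.99, 999.99)
    return StructureModel(atoms, model.path)
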