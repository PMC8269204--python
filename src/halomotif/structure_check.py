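"""Minimal atomic-coordinate support for enzyme-substrate contact checks.

Parses PDB-format coordinate files (via Biopython's parser) into a flat atom
table and measures minimum contact distances between residue and ligand atom
selections — enough to verify, e.g., that the glutamine side chains of a
5-Trp halogenase's Trp3 motif hydrogen-bond the bound tryptophan's
carboxylate.  Alternate locations are resolved to the highest-occupancy
conformer (ties broken toward altloc 'A'); mmCIF is not supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser

#: "Side chain" atom names used for Gln when a selector says ``sidechain``.
GLN_SIDECHAIN = ("CG", "CD", "OE1", "NE2")
#: Carboxylate oxygens of an amino-acid ligand.
CARBOXYLATE = ("O", "OXT")


class StructureParseError(ValueError):
    pass


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    chain: str
    res_name: str
    res_number: str  # residue number, insertion code appended when present
    atom_name: str
    x: float
    y: float
    z: float
    element: str
    is_ligand: bool

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    atoms: list[Atom]

    @property
    def ligands(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_ligand]

    def select(
        self,
        chain: str | None = None,
        res_number: str | None = None,
        res_name: str | None = None,
        atom_names: tuple[str, ...] | None = None,
        ligand: bool | None = None,
    ) -> list[Atom]:
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if res_number is not None and a.res_number != str(res_number):
                continue
            if res_name is not None and a.res_name != res_name:
                continue
            if atom_names is not None and a.atom_name not in atom_names:
                continue
            if ligand is not None and a.is_ligand != ligand:
                continue
            out.append(a)
        return out


def parse_structure(path) -> StructureModel:
    """Parse ATOM/HETATM records of a PDB file into a :class:`StructureModel`.

    Waters are kept (they are HETATM ligand records); alternate locations are
    collapsed to one conformer per atom by highest occupancy, then altloc 'A'.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("model", str(path))
    atoms: list[Atom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                hetflag, resseq, icode = residue.id
                is_ligand = hetflag.strip() != ""
                res_number = f"{resseq}{icode.strip()}"
                for atom in residue:
                    if atom.is_disordered():
                        variants = sorted(
                            atom.disordered_get_list(),
                            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                        )
                        atom = variants[0]
                    x, y, z = (float(v) for v in atom.coord)
                    atoms.append(Atom(
                        chain=chain.id, res_name=residue.resname.strip(),
                        res_number=res_number, atom_name=atom.get_name(),
                        x=x, y=y, z=z,
                        element=(atom.element or "").strip(),
                        is_ligand=is_ligand,
                    ))
        break  # first model only
    if not any(not a.is_ligand for a in atoms) and not atoms:
        raise StructureParseError(f"{path}: no ATOM records found")
    if not atoms:
        raise StructureParseError(f"{path}: no atoms parsed")
    return StructureModel(atoms)


def min_contact_distance(
    model: StructureModel,
    residue_atoms: list[Atom],
    ligand_atoms: list[Atom],
    report: list | None = None,
) -> float:
    """Minimum Euclidean distance over the selection cross-product, in Å.

    Reported to 0.01 Å.  When ``report`` is a list, every atom pair and its
    distance is appended to it for audit.
    """
    if not residue_atoms:
        raise SelectionError("residue selection is empty")
    if not ligand_atoms:
        raise SelectionError("ligand selection is empty")
    a = np.array([at.coords for at in residue_atoms])
    b = np.array([at.coords for at in ligand_atoms])
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    if report is not None:
        for i, ra in enumerate(residue_atoms):
            for j, la in enumerate(ligand_atoms):
                report.append((ra, la, round(float(d[i, j]), 2)))
    return round(float(d.min()), 2)


def gln_carboxylate_distance(
    model: StructureModel, chain: str, res_number: str | int,
    ligand_name: str = "TRP",
) -> float:
    """Distance from a Gln side-chain amide to the nearest ligand carboxylate O.

    When several ligand copies exist, the closest one is used.
    """
    res = model.select(chain=chain, res_number=str(res_number),
                       atom_names=GLN_SIDECHAIN, ligand=False)
    lig = model.select(res_name=ligand_name, atom_names=CARBOXYLATE, ligand=True)
    return min_contact_distance(model, res, lig)
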