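"""Minimal structure ingestion for interaction featurization.

Proteins are read from PDB files and reduced to the per-atom records the
dictionary-based typer needs: residue name, PDB atom name and coordinates.
Ligands are read from SDF (MOL V2000) files with RDKit so that valence, ring
membership and aromaticity are perceived from the bond block; the
protonation/tautomer state is taken exactly as written in the file.

Only heavy atoms are returned. Hydrogens contribute solely through the
attached-hydrogen count carried by each heavy atom.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import BiopythonWarning
from Bio.PDB import PDBParser
from rdkit import Chem

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid residue names covered by the typing dictionary.
STANDARD_RESIDUES = frozenset([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
])


class StructureError(ValueError):
    """Raised when a structure file cannot be parsed or violates preconditions."""


class EmptyStructureError(StructureError):
    """Raised when a file yields no usable heavy atoms."""


@dataclass(frozen=True)
class ProteinAtom:
    """A protein heavy atom as seen by the dictionary-based typer."""

    residue_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]


@dataclass(frozen=True)
class LigandAtom:
    """A ligand heavy atom with the perceived attributes ECIF typing uses."""

    element: str
    explicit_valence: int
    n_heavy_neighbors: int
    n_attached_hydrogens: int
    is_aromatic: bool
    in_ring: bool
    coords: tuple[float, float, float]


def load_protein(path: str | Path) -> list[ProteinAtom]:
    """Read the heavy atoms of standard amino-acid residues from a PDB file.

    Hydrogens, waters, HETATM records (ligands, ions, cofactors) and alternate
    locations other than '' / 'A' are excluded. Non-standard residues are
    skipped with a warning: atoms without a dictionary entry simply produce no
    features downstream.

    Raises
    ------
    StructureError
        If the file cannot be parsed.
    EmptyStructureError
        If no usable heavy atom remains after filtering.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BiopythonWarning)
            structure = parser.get_structure("protein", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    atoms: list[ProteinAtom] = []
    skipped_residues: set[str] = set()
    for model in structure:
        for chain in model:
            for residue in chain:
                hetflag = residue.id[0]
                resname = residue.get_resname().strip()
                if hetflag != " ":
                    if hetflag != "W":  # waters are silently dropped
                        skipped_residues.add(resname)
                    continue
                if resname not in STANDARD_RESIDUES:
                    skipped_residues.add(resname)
                    continue
                for atom in residue:
                    if atom.element in ("H", "D"):
                        continue
                    if atom.get_altloc() not in (" ", "", "A"):
                        continue
                    x, y, z = (float(v) for v in atom.coord)
                    if not all(math.isfinite(v) for v in (x, y, z)):
                        raise StructureError(
                            f"non-finite coordinates for {resname} {atom.get_name()}")
                    atoms.append(ProteinAtom(
                        residue_name=resname,
                        atom_name=atom.get_name().strip(),
                        element=atom.element,
                        coords=(x, y, z),
                    ))
        break  # first model only
    if skipped_residues:
        logger.warning("skipped non-standard residues in %s: %s",
                       path.name, ", ".join(sorted(skipped_residues)))
    if not atoms:
        raise EmptyStructureError(f"no standard-residue heavy atoms in {path}")
    return atoms


def _ligand_atom(atom: Chem.Atom, conformer: Chem.Conformer) -> LigandAtom:
    pos = conformer.GetAtomPosition(atom.GetIdx())
    heavy = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)
    return LigandAtom(
        element=atom.GetSymbol(),
        explicit_valence=atom.GetTotalValence(),
        n_heavy_neighbors=heavy,
        n_attached_hydrogens=atom.GetTotalNumHs(includeNeighbors=True),
        is_aromatic=atom.GetIsAromatic(),
        in_ring=atom.IsInRing(),
        coords=(pos.x, pos.y, pos.z),
    )


def ligand_atoms_from_mol(mol: Chem.Mol) -> list[LigandAtom]:
    """Extract heavy-atom records from an RDKit molecule with a 3D conformer."""
    if mol.GetNumConformers() == 0:
        raise StructureError("molecule has no conformer")
    conformer = mol.GetConformer()
    if not conformer.Is3D():
        raise StructureError("molecule has 2D coordinates only; a 3D conformer "
                             "is required for distance-based featurization")
    atoms = [_ligand_atom(a, conformer)
             for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if not atoms:
        raise EmptyStructureError("molecule contains no heavy atoms")
    return atoms


def load_ligand(path: str | Path) -> list[LigandAtom]:
    """Read the first molecule of an SDF file as a list of heavy-atom records.

    The bond block is required so RDKit can perceive valence, ring membership
    and aromaticity; hydrogens may be explicit or implicit and are folded into
    each heavy atom's attached-hydrogen count.

    Raises
    ------
    StructureError
        On parse/sanitization failure (naming the molecule when possible) or
        when only 2D coordinates are present.
    """
    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    if len(supplier) == 0:
        raise StructureError(f"no molecule records in {path}")
    mol = supplier[0]
    if mol is None:
        raise StructureError(f"sanitization failed for first molecule in {path}")
    try:
        return ligand_atoms_from_mol(mol)
    except StructureError as exc:
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else path.name
        raise StructureError(f"{name}: {exc}") from exc


def load_ligand_mol(path: str | Path) -> Chem.Mol:
    """Read the first molecule of an SDF file as a sanitized RDKit molecule."""
    supplier = Chem.SDMolSupplier(str(Path(path)), removeHs=False, sanitize=True)
    if len(supplier) == 0 or supplier[0] is None:
        raise StructureError(f"cannot read molecule from {path}")
    return supplier[0]
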