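"""Regenerate the packaged atom-typing and descriptor assets.

Run from the repository root:

    python scripts/build_assets.py

Writes into src/msecif/assets/:

* ``protein_types.tsv``   -- per-(residue, atom-name) ECIF types for the heavy atoms
  of the 20 standard amino acids, derived with RDKit from capped (ACE-X-NME) residue
  models under fixed protonation conventions (Asp/Glu deprotonated, Lys/Arg
  protonated, His neutral epsilon-tautomer with H on NE2).
* ``ligand_types.tsv``    -- the curated ligand atom-environment list; every entry is
  validated against its witness molecule before writing.
* ``ligand_descriptors_default.txt`` -- the default retained ligand-descriptor list,
  produced by applying the zero-variance / null / extreme-value filter to the
  packaged reference corpus with the installed RDKit.

The shipped assets are the output of this script; it exists so the derivation is
reproducible and auditable, not because the package regenerates anything at run time.
"""
from __future__ import annotations

import sys
from pathlib import Path

from rdkit import Chem

ASSETS = Path(__file__).resolve().parents[1] / "src" / "msecif" / "assets"

# --------------------------------------------------------------------------- protein
# ACE-X-NME capped residues; the atom-name list maps SMILES atom order to PDB
# atom names (None marks cap atoms that are not part of the dictionary).
RESIDUES: dict[str, tuple[str, list[str | None]]] = {
    "ALA": ("CC(=O)N[C@@H](C)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "C", "O", None, None]),
    "GLY": ("CC(=O)NCC(=O)NC",
            [None, None, None, "N", "CA", "C", "O", None, None]),
    "VAL": ("CC(=O)N[C@@H](C(C)C)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG1", "CG2", "C", "O", None, None]),
    "LEU": ("CC(=O)N[C@@H](CC(C)C)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "CD1", "CD2", "C", "O", None, None]),
    "ILE": ("CC(=O)N[C@@H]([C@@H](CC)C)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG1", "CD1", "CG2", "C", "O", None, None]),
    "PRO": ("CC(=O)N1CCC[C@H]1C(=O)NC",
            [None, None, None, "N", "CD", "CG", "CB", "CA", "C", "O", None, None]),
    "PHE": ("CC(=O)N[C@@H](Cc1ccccc1)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "CD1", "CE1", "CZ", "CE2", "CD2",
             "C", "O", None, None]),
    "TYR": ("CC(=O)N[C@@H](Cc1ccc(O)cc1)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "CD1", "CE1", "CZ", "OH", "CE2",
             "CD2", "C", "O", None, None]),
    "TRP": ("CC(=O)N[C@@H](Cc1c[nH]c2ccccc12)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "CD1", "NE1", "CE2", "CZ2", "CH2",
             "CZ3", "CE3", "CD2", "C", "O", None, None]),
    "SER": ("CC(=O)N[C@@H](CO)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "OG", "C", "O", None, None]),
    "THR": ("CC(=O)N[C@@H]([C@@H](O)C)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "OG1", "CG2", "C", "O", None, None]),
    "CYS": ("CC(=O)N[C@@H](CS)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "SG", "C", "O", None, None]),
    "MET": ("CC(=O)N[C@@H](CCSC)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "SD", "CE", "C", "O", None, None]),
    "ASN": ("CC(=O)N[C@@H](CC(=O)N)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "OD1", "ND2", "C", "O", None, None]),
    "GLN": ("CC(=O)N[C@@H](CCC(=O)N)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "CD", "OE1", "NE2", "C", "O",
             None, None]),
    "ASP": ("CC(=O)N[C@@H](CC(=O)[O-])C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "OD1", "OD2", "C", "O", None, None]),
    "GLU": ("CC(=O)N[C@@H](CCC(=O)[O-])C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "CD", "OE1", "OE2", "C", "O",
             None, None]),
    "LYS": ("CC(=O)N[C@@H](CCCC[NH3+])C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "CD", "CE", "NZ", "C", "O",
             None, None]),
    "ARG": ("CC(=O)N[C@@H](CCCNC(=[NH2+])N)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2",
             "C", "O", None, None]),
    "HIS": ("CC(=O)N[C@@H](Cc1nc[nH]c1)C(=O)NC",
            [None, None, None, "N", "CA", "CB", "CG", "ND1", "CE1", "NE2", "CD2",
             "C", "O", None, None]),
}

# --------------------------------------------------------------------------- ligand
# Curated ligand atom environments: (six-element type, witness SMILES, witness atom
# index, comment). 77 entries; together with the 20 protein types this spans the
# 1540-dimensional six-element pair space.
LIGAND_WITNESSES: list[tuple[str, str, int, str]] = [
    ("C;4;1;1;0;0", "C#CC", 0, "terminal alkyne CH"),
    ("C;4;1;2;0;0", "C=CC", 0, "terminal alkene CH2"),
    ("C;4;1;3;0;0", "CC", 0, "methyl"),
    ("C;4;2;0;0;0", "CC#CC", 1, "internal alkyne C"),
    ("C;4;2;0;0;1", "C1CC#CCCCC1", 2, "ring alkyne C (cyclooctyne)"),
    ("C;4;2;1;0;0", "CC=CC", 1, "acyclic sp2 CH"),
    ("C;4;2;1;0;1", "C1=CCCCC1", 0, "non-aromatic ring sp2 CH"),
    ("C;4;2;1;1;1", "c1ccccc1", 0, "aromatic CH"),
    ("C;4;2;2;0;0", "CCC", 1, "acyclic CH2"),
    ("C;4;2;2;0;1", "C1CCCCC1", 0, "ring CH2"),
    ("C;4;3;0;0;0", "CC(C)=C", 1, "acyclic sp2 C, trisubstituted"),
    ("C;4;3;0;0;1", "O=C1CCCCC1", 1, "ring carbonyl carbon"),
    ("C;4;3;0;1;1", "Cc1ccccc1", 1, "substituted aromatic C"),
    ("C;4;3;1;0;0", "CC(C)C", 1, "acyclic CH"),
    ("C;4;3;1;0;1", "CC1CCCCC1", 1, "ring CH"),
    ("C;4;4;0;0;0", "CC(C)(C)C", 1, "quaternary C"),
    ("C;4;4;0;0;1", "CC1(C)CCCCC1", 1, "ring quaternary C"),
    ("N;2;1;0;0;0", "CN=[N+]=[N-]", 3, "azide terminal N"),
    ("N;2;1;1;0;0", "CS(=O)(=O)[NH-]", 4, "deprotonated primary sulfonamide"),
    ("N;2;2;0;0;0", "CS(=O)(=O)[N-]C", 4, "deprotonated secondary sulfonamide"),
    ("N;3;1;0;0;0", "CC#N", 2, "nitrile N"),
    ("N;3;1;1;0;0", "CC(=N)N", 2, "terminal imine NH"),
    ("N;3;1;2;0;0", "CN", 1, "primary amine"),
    ("N;3;2;0;0;0", "CC=NC", 2, "acyclic imine N"),
    ("N;3;2;0;0;1", "C1CCC=N1", 4, "cyclic imine N"),
    ("N;3;2;0;1;1", "c1ccncc1", 3, "pyridine-type aromatic N"),
    ("N;3;2;1;0;0", "CNC", 1, "secondary amine / amide NH"),
    ("N;3;2;1;0;1", "C1CCNCC1", 3, "saturated ring NH"),
    ("N;3;2;1;1;1", "c1cc[nH]c1", 3, "pyrrole-type aromatic NH"),
    ("N;3;3;0;0;0", "CN(C)C", 1, "tertiary amine"),
    ("N;3;3;0;0;1", "CN1CCCCC1", 1, "N-substituted saturated ring N"),
    ("N;3;3;0;1;1", "Cn1cccc1", 1, "N-substituted aromatic N"),
    ("N;4;1;2;0;0", "CC(N)=[NH2+]", 3, "amidinium =NH2+"),
    ("N;4;1;3;0;0", "C[NH3+]", 1, "primary ammonium"),
    ("N;4;2;0;0;0", "CN=[N+]=[N-]", 2, "azide central N"),
    ("N;4;2;1;0;0", "CC=[NH+]C", 2, "protonated acyclic imine"),
    ("N;4;2;1;0;1", "C1CCC=[NH+]1", 4, "protonated cyclic imine"),
    ("N;4;2;1;1;1", "c1cc[nH+]cc1", 3, "pyridinium NH+"),
    ("N;4;2;2;0;0", "C[NH2+]C", 1, "secondary ammonium"),
    ("N;4;2;2;0;1", "C1CC[NH2+]CC1", 3, "ring secondary ammonium"),
    ("N;4;3;0;0;0", "C[N+](=O)[O-]", 1, "nitro N (charge-separated)"),
    ("N;4;3;0;0;1", "C[N+]1=CCCC1", 1, "ring iminium N"),
    ("N;4;3;0;1;1", "C[n+]1ccccc1", 1, "N-substituted pyridinium"),
    ("N;4;3;1;0;0", "C[NH+](C)C", 1, "tertiary ammonium"),
    ("N;4;3;1;0;1", "C[NH+]1CCCCC1", 1, "ring tertiary ammonium"),
    ("N;4;4;0;0;0", "C[N+](C)(C)C", 1, "quaternary ammonium"),
    ("N;4;4;0;0;1", "C[N+]1(C)CCCCC1", 1, "ring quaternary ammonium"),
    ("O;1;1;0;0;0", "CC(=O)[O-]", 3, "oxide / carboxylate O-"),
    ("O;2;1;0;0;0", "CC(=O)C", 2, "carbonyl O"),
    ("O;2;1;1;0;0", "CO", 1, "hydroxyl"),
    ("O;2;2;0;0;0", "COC", 1, "acyclic ether/ester O"),
    ("O;2;2;0;0;1", "C1CCOC1", 3, "saturated ring O"),
    ("O;2;2;0;1;1", "c1ccoc1", 3, "furan-type aromatic O"),
    ("S;1;1;0;0;0", "C[S-]", 1, "thiolate"),
    ("S;2;1;0;0;0", "NC(=S)N", 2, "thiocarbonyl S"),
    ("S;2;1;1;0;0", "CS", 1, "thiol"),
    ("S;2;2;0;0;0", "CSC", 1, "acyclic thioether"),
    ("S;2;2;0;0;1", "C1CCSC1", 3, "saturated ring S"),
    ("S;2;2;0;1;1", "c1ccsc1", 3, "thiophene-type aromatic S"),
    ("S;3;3;0;0;0", "C[S+](C)C", 1, "sulfonium"),
    ("S;3;3;0;0;1", "C[S+]1CCCC1", 1, "ring sulfonium"),
    ("S;4;3;0;0;0", "CS(=O)C", 1, "sulfoxide"),
    ("S;4;3;0;0;1", "O=S1CCCC1", 1, "cyclic sulfoxide"),
    ("S;6;4;0;0;0", "CS(C)(=O)=O", 1, "sulfone / sulfonamide S"),
    ("S;6;4;0;0;1", "O=S1(=O)CCCC1", 1, "cyclic sulfone"),
    ("P;3;3;0;0;0", "CP(C)C", 1, "phosphine"),
    ("P;3;3;0;0;1", "CP1CCCC1", 1, "ring phosphine"),
    ("P;4;4;0;0;0", "C[P+](C)(C)C", 1, "phosphonium"),
    ("P;5;3;1;0;0", "COP(=O)OC", 2, "H-phosphonate P"),
    ("P;5;4;0;0;0", "COP(=O)(OC)OC", 2, "phosphate/phosphonate P"),
    ("P;5;4;0;0;1", "O=P1(O)OCCO1", 1, "cyclic phosphate P"),
    ("B;3;3;0;0;0", "CB(O)O", 1, "boronic acid B"),
    ("B;3;3;0;0;1", "CB1OC(C)(C)C(C)(C)O1", 1, "cyclic boronate B"),
    ("F;1;1;0;0;0", "CF", 1, "organofluorine"),
    ("Cl;1;1;0;0;0", "CCl", 1, "organochlorine"),
    ("Br;1;1;0;0;0", "CBr", 1, "organobromine"),
    ("I;1;1;0;0;0", "CI", 1, "organoiodine"),
]


def atom_type6(atom: Chem.Atom) -> str:
    heavy = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)
    return ";".join([
        atom.GetSymbol(),
        str(atom.GetTotalValence()),
        str(heavy),
        str(atom.GetTotalNumHs(includeNeighbors=True)),
        str(int(atom.GetIsAromatic())),
        str(int(atom.IsInRing())),
    ])


def to_five(t6: str) -> str:
    f = t6.split(";")
    return ";".join(f[:4] + f[5:])


def build_protein_table() -> list[tuple[str, str, str, str]]:
    rows = []
    for res, (smi, names) in RESIDUES.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() != len(names):
            raise RuntimeError(f"bad residue template for {res}")
        for atom, name in zip(mol.GetAtoms(), names):
            if name is None:
                continue
            t6 = atom_type6(atom)
            rows.append((res, name, to_five(t6), t6))
    rows.sort()
    return rows


def validate_ligand_witnesses() -> None:
    seen = set()
    for t6, smi, idx, _ in LIGAND_WITNESSES:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise RuntimeError(f"witness SMILES unparseable for {t6}: {smi}")
        got = atom_type6(mol.GetAtomWithIdx(idx))
        if got != t6:
            raise RuntimeError(f"witness mismatch for {t6}: {smi}[{idx}] -> {got}")
        if t6 in seen:
            raise RuntimeError(f"duplicate ligand type {t6}")
        seen.add(t6)


def build_descriptor_list() -> list[str]:
    # imported lazily so this script works before/after the package is installed
    sys.path.insert(0, str(ASSETS.parents[1]))
    from msecif.fixtures import reference_ligand_corpus
    from msecif.ligand_descriptors import compute_descriptors, filter_descriptors
    import pandas as pd

    table = pd.DataFrame([compute_descriptors(Chem.MolFromSmiles(s))
                          for s in reference_ligand_corpus()])
    return filter_descriptors(table)


def main() -> None:
    ASSETS.mkdir(parents=True, exist_ok=True)

    rows = build_protein_table()
    types6 = sorted({r[3] for r in rows})
    with open(ASSETS / "protein_types.tsv", "w") as fh:
        fh.write("residue\tatom_name\tfive_element_type\tsix_element_type\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    print(f"protein_types.tsv: {len(rows)} entries, {len(types6)} distinct types")

    validate_ligand_witnesses()
    with open(ASSETS / "ligand_types.tsv", "w") as fh:
        fh.write("six_element_type\tfive_element_type\twitness_smiles\t"
                 "witness_atom_index\tcomment\n")
        for t6, smi, idx, comment in sorted(LIGAND_WITNESSES):
            fh.write(f"{t6}\t{to_five(t6)}\t{smi}\t{idx}\t{comment}\n")
    n_lig5 = len({to_five(t) for t, _, _, _ in LIGAND_WITNESSES})
    print(f"ligand_types.tsv: {len(LIGAND_WITNESSES)} six-element types, "
          f"{n_lig5} five-element types")
    print(f"pair space: 6-element {len(types6) * len(LIGAND_WITNESSES)}, "
          f"5-element {len({to_five(t) for t in types6}) * n_lig5}")

    retained = build_descriptor_list()
    with open(ASSETS / "ligand_descriptors_default.txt", "w") as fh:
        fh.write("\n".join(retained) + "\n")
    print(f"ligand_descriptors_default.txt: {len(retained)} descriptors")


if __name__ == "__main__":
    main()
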