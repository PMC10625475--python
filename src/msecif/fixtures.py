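"""Synthetic inputs: toy protein-ligand complexes with exactly specified typed
contacts, and seeded regression datasets that mimic interaction-count tables.

Toy complexes are the package's ground-truth generator. Each requested pair
spec is realized as one spatial cluster: a single protein atom (emitted as an
isolated residue whose residue/atom names select the requested dictionary
type, so typing is exact by construction) and one ligand "witness" fragment
whose designated atom carries the requested perceived type. The witness
atom sits at exactly the requested distance from its protein partner; all
other fragment atoms are placed in a junk zone hundreds of Angstroms away
(bond lengths in the file are deliberately unphysical — chemical perception
reads the bond block, not geometry), and clusters are spaced far apart, so
pair enumeration at any supported threshold recovers exactly the requested
typed pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, StructureBuilder
from rdkit import Chem
from rdkit.Geometry import Point3D

from .atom_typing import (FIVE_ELEMENT, SIX_ELEMENT, ECIFAtomType,
                          ligand_type_table, protein_typing_table)

#: Clusters are spaced this far apart along x (Angstrom).
_CLUSTER_SPACING = 40.0
#: Non-witness fragment atoms are parked at this y offset.
_JUNK_OFFSET = 300.0
#: Largest requested pair distance the no-cross-talk layout supports.
MAX_SPEC_DISTANCE = 20.0


class FixtureError(ValueError):
    """Raised when a requested pair spec cannot be realized."""


@dataclass(frozen=True)
class PairSpec:
    """One requested protein-ligand contact: two ECIF types and a distance."""

    protein_type: str | ECIFAtomType
    ligand_type: str | ECIFAtomType
    distance: float

    def parsed(self) -> tuple[ECIFAtomType, ECIFAtomType, float]:
        p = (self.protein_type if isinstance(self.protein_type, ECIFAtomType)
             else ECIFAtomType.parse(self.protein_type))
        l = (self.ligand_type if isinstance(self.ligand_type, ECIFAtomType)
             else ECIFAtomType.parse(self.ligand_type))
        if p.variant != l.variant:
            raise FixtureError(f"variant mismatch in spec {p.render()} / {l.render()}")
        if not 0 < self.distance <= MAX_SPEC_DISTANCE:
            raise FixtureError(f"distance must be in (0, {MAX_SPEC_DISTANCE}] A, "
                               f"got {self.distance}")
        return p, l, float(self.distance)


def _protein_site(requested: ECIFAtomType) -> tuple[str, str]:
    """A (residue, atom name) whose dictionary entry renders the requested type."""
    idx = 0 if requested.variant == FIVE_ELEMENT else 1
    wanted = requested.render()
    for (res, name), types in sorted(protein_typing_table().items()):
        if types[idx] == wanted:
            return res, name
    raise FixtureError(f"no dictionary site realizes protein type {wanted}")


def _ligand_witness(requested: ECIFAtomType) -> tuple[str, int]:
    """A (witness SMILES, atom index) realizing the requested ligand type."""
    key = ("five_element_type" if requested.variant == FIVE_ELEMENT
           else "six_element_type")
    wanted = requested.render()
    for row in ligand_type_table():
        if row[key] == wanted:
            return row["witness_smiles"], int(row["witness_atom_index"])
    raise FixtureError(f"no witness fragment realizes ligand type {wanted}")


def make_toy_complex(specs: list[PairSpec], out_dir: str | Path,
                     basename: str = "toy") -> tuple[Path, Path]:
    """Write a minimal PDB/SDF pair realizing exactly the requested contacts.

    Returns ``(pdb_path, sdf_path)``. With an empty spec list, valid files
    with one protein atom and one distant ligand fragment are written, so the
    loaders succeed and pair enumeration yields zero pairs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{basename}.pdb"
    sdf_path = out_dir / f"{basename}.sdf"

    placements = []   # (residue, atom_name, protein_xyz, smiles, witness_idx, d)
    for spec in specs:
        ptype, ltype, d = spec.parsed()
        res, name = _protein_site(ptype)
        smiles, widx = _ligand_witness(ltype)
        placements.append((res, name, smiles, widx, d))
    if not placements:
        placements.append(("ALA", "N", "CO", 1, _JUNK_OFFSET))

    # ---- protein: one isolated residue per cluster
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("toy")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for k, (res, name, _, _, _) in enumerate(placements):
        builder.init_residue(res, " ", k + 1, " ")
        x = k * _CLUSTER_SPACING
        builder.init_atom(name, np.array([x, 0.0, 0.0]), 0.0, 1.0, " ",
                          f" {name:<3}", element=name[0])
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(pdb_path))

    # ---- ligand: witness fragments combined into one SDF record
    combined = Chem.Mol()
    witness_global: list[int] = []
    for _, _, smiles, widx, _ in placements:
        frag = Chem.MolFromSmiles(smiles)
        if frag is None:
            raise FixtureError(f"witness SMILES unparseable: {smiles}")
        witness_global.append(combined.GetNumAtoms() + widx)
        combined = Chem.CombineMols(combined, frag)

    conf = Chem.Conformer(combined.GetNumAtoms())
    junk_count = 0
    atom_cursor = 0
    for k, (_, _, smiles, widx, d) in enumerate(placements):
        frag_n = Chem.MolFromSmiles(smiles).GetNumAtoms()
        x0 = k * _CLUSTER_SPACING
        for local in range(frag_n):
            gidx = atom_cursor + local
            if gidx == witness_global[k] and d <= MAX_SPEC_DISTANCE:
                conf.SetAtomPosition(gidx, Point3D(x0 + d, 0.0, 0.0))
            else:
                # off-plane z keeps RDKit from re-tagging the record as 2D
                conf.SetAtomPosition(
                    gidx, Point3D(x0, _JUNK_OFFSET + 3.0 * junk_count, 50.0))
                junk_count += 1
        atom_cursor += frag_n
    conf.Set3D(True)
    mol = Chem.RWMol(combined)
    mol.AddConformer(conf)
    mol.SetProp("_Name", basename)
    writer = Chem.SDWriter(str(sdf_path))
    writer.write(mol)
    writer.close()
    return pdb_path, sdf_path


def supported_ligand_types(variant: str = FIVE_ELEMENT) -> list[str]:
    """Rendered ligand types the fixture generator can realize."""
    key = "five_element_type" if variant == FIVE_ELEMENT else "six_element_type"
    return sorted({row[key] for row in ligand_type_table()})


def supported_protein_types(variant: str = FIVE_ELEMENT) -> list[str]:
    """Rendered protein types the fixture generator can realize."""
    idx = 0 if variant == FIVE_ELEMENT else 1
    return sorted({v[idx] for v in protein_typing_table().values()})


def random_specs(n: int, seed: int, low: float = 2.1, high: float = 9.9,
                 variant: str = FIVE_ELEMENT) -> list[PairSpec]:
    """Seeded random pair specs over the realizable type lists."""
    rng = np.random.default_rng(seed)
    ptypes = supported_protein_types(variant)
    ltypes = supported_ligand_types(variant)
    return [PairSpec(ptypes[rng.integers(len(ptypes))],
                     ltypes[rng.integers(len(ltypes))],
                     float(rng.uniform(low, high)))
            for _ in range(n)]


# ------------------------------------------------------------- regression datasets

def make_regression_dataset(n: int, n_informative: int, noise_sd: float,
                            seed: int, n_sparse: int = 40,
                            n_dense: int = 12
                            ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """A seeded synthetic affinity-regression dataset.

    Features mimic an interaction-count table: ``count_*`` columns are
    non-negative integers that are mostly zero, plus dense descriptor-like
    ``desc_*`` columns. The target is a linear function of the informative
    columns with a mild pairwise interaction, plus Gaussian noise:
    pk = 5 + sum_i w_i x_i + 0.15 x_0 x_1 + N(0, noise_sd).

    Returns ``(features, pk, informative_names)``.
    """
    if n < 1 or n_sparse < 1 or n_dense < 0:
        raise ValueError("invalid dataset sizes")
    if not 0 <= n_informative <= n_sparse:
        raise ValueError("n_informative must be within the sparse column count")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(0.25, size=(n, n_sparse))
    # informative count columns get enough occupancy to carry signal
    for j in range(n_informative):
        counts[:, j] = rng.poisson(2.0, size=n)
    dense = rng.normal(0.0, 1.0, size=(n, n_dense))
    names = ([f"count_{i:03d}" for i in range(n_sparse)]
             + [f"desc_{i:03d}" for i in range(n_dense)])
    features = pd.DataFrame(np.hstack([counts, dense]), columns=names)
    features[names[:n_sparse]] = features[names[:n_sparse]].astype(int)

    weights = [1.2, 0.9, 0.7, 0.6, 0.5] + [0.4] * max(0, n_informative - 5)
    signal = np.zeros(n)
    for j in range(n_informative):
        signal += weights[j] * counts[:, j]
    if n_informative >= 2:
        signal += 0.15 * counts[:, 0] * counts[:, 1]
    pk = 5.0 + signal + rng.normal(0.0, noise_sd, size=n)
    informative = names[:n_informative]
    return features, pd.Series(pk, name="pk"), informative


# --------------------------------------------------------------- reference corpus

def reference_ligand_corpus() -> list[str]:
    """A fixed corpus of drug-like molecules (SMILES).

    Used to regenerate the default retained-descriptor asset and as a varied
    test bed for descriptor computation. Chosen to span common drug-like
    chemotypes (acids, bases, aromatics, heterocycles, halogens, sulfonamides,
    phosphates); membership is frozen so the derived asset is reproducible.
    """
    return [
        "CC(=O)Oc1ccccc1C(=O)O",                      # aspirin
        "CC(C)Cc1ccc(C(C)C(=O)O)cc1",                 # ibuprofen
        "CC(=O)Nc1ccc(O)cc1",                         # paracetamol
        "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                 # caffeine
        "CN1CCC[C@H]1c1cccnc1",                       # nicotine
        "NC(=O)c1ccc[nH]1",                           # pyrrole amide
        "Nc1ccc(S(=O)(=O)Nc2ccccn2)cc1",              # sulfapyridine-like
        "CC(N)Cc1ccccc1",                             # amphetamine-like
        "NCCc1ccc(O)c(O)c1",                          # dopamine
        "NC(Cc1c[nH]c2ccccc12)C(=O)O",                # tryptophan
        "OC(=O)c1cc(O)c(O)c(O)c1",                    # gallic acid
        "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1",             # resveratrol
        "CN(C)CCCN1c2ccccc2CCc2ccccc21",              # tricyclic amine
        "Clc1ccccc1-c1nc2ccccc2[nH]1",                # chloro-benzimidazole
        "COc1ccc2cc(C(C)C(=O)O)ccc2c1",               # naproxen
        "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",             # atenolol
        "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",              # salbutamol
        "Clc1ccc(C(c2ccccc2)N2CCN(CCOCCO)CC2)cc1",    # hydroxyzine-like
        "O=C(O)CCc1ccccc1",                           # hydrocinnamic acid
        "O=C(Nc1ccccc1)c1cccnc1",                     # nicotinanilide
        "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O", # penicillin G core
        "CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2",         # atropine
        "COc1cc2c(cc1OC)CCN(C)CC2",                   # tetrahydroisoquinoline
        "O=c1[nH]cnc2[nH]cnc12",                      # hypoxanthine
        "Nc1ncnc2[nH]cnc12",                          # adenine
        "O=c1cc[nH]c(=O)[nH]1",                      # uracil
        "NC1CCCCC1",                                  # cyclohexylamine
        "OC1CCCCC1",                                  # cyclohexanol
        "O=S(=O)(N)c1ccc(Cl)cc1",                     # chlorobenzenesulfonamide
        "FC(F)(F)c1ccccc1",                           # benzotrifluoride
        "Brc1ccc2[nH]ccc2c1",                         # bromoindole
        "Ic1ccccc1",                                  # iodobenzene
        "CSCCC(N)C(=O)O",                             # methionine
        "OCC1OC(O)C(O)C(O)C1O",                       # glucose
        "OP(=O)(O)OCC1OC(n2cnc3c(N)ncnc32)C(O)C1O",   # AMP-like
        "CC(=O)NC1C(O)OC(CO)C(O)C1O",                 # GlcNAc
        "c1ccc2c(c1)oc1ccccc12",                      # dibenzofuran
        "c1ccc2c(c1)sc1ccccc12",                      # dibenzothiophene
        "c1ccc(-c2ccc3ncccc3c2)cc1",                  # arylquinoline
        "CC(C)=CCCC(C)=CCO",                          # geraniol
        "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",             # estradiol
        "CC(CS)C(=O)N1CCCC1C(=O)O",                   # captopril
        "NC(N)=Nc1nc(CSCCC(N)=N)cs1",                 # guanidine-thiazole
        "CN(C)C(=N)N=C(N)N",                          # metformin
        "O=C1CCCCCN1",                                # caprolactam
        "O=C1OC(=O)c2ccccc21",                        # phthalic anhydride
        "C[N+](C)(C)CCO",                             # choline
        "CC(=O)OCC[N+](C)(C)C",                       # acetylcholine
        "O=[N+]([O-])c1ccc(O)cc1",                    # nitrophenol
        "N#Cc1ccccc1",                                # benzonitrile
        "C#Cc1ccccc1",                                # phenylacetylene
        "CN=[N+]=[N-]",                               # methyl azide
        "CB(O)O",                                     # methylboronic acid
        "COP(=O)(OC)OC",                              # trimethyl phosphate
        "CS(=O)c1ccccc1",                             # phenyl sulfoxide
        "O=S1(=O)CCCC1",                              # sulfolane
        "C1CCNC1",                                    # pyrrolidine
        "C1COCCN1",                                   # morpholine
        "C1CN1",                                      # aziridine
        "c1cnc2[nH]ccc2c1",                           # azaindole
        "O=C(O)C1CCCN1",                              # proline
        "OC(=O)CC(O)(CC(=O)O)C(=O)O",                 # citric acid
    ]
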