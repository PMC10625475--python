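"""ECIF-style qualitative atom typing and the protein-ligand pair vocabulary.

An atom is represented by a short string of perceived attributes joined by
semicolons: element symbol, explicit valence, number of attached heavy atoms,
number of attached hydrogens, (optionally aromaticity,) and ring membership.
The six-element variant keeps the aromaticity flag; the five-element variant —
used by both distance-aware feature families — drops it.

Protein atoms are typed by dictionary: every heavy atom of the 20 standard
amino acids has a fixed entry keyed on (residue name, PDB atom name), so a
protein structure needs no chemical perception (and no hydrogens). Ligand
atoms are typed from the attributes RDKit perceives from the SDF bond block.

The pair vocabulary is the full cross product of the packaged protein and
ligand type lists in lexicographic order; it fixes feature naming, order and
dimensionality (1540 pairs in the six-element variant).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib.resources import files

from .io_structures import LigandAtom, ProteinAtom

logger = logging.getLogger(__name__)

FIVE_ELEMENT = "five_element"
SIX_ELEMENT = "six_element"
VARIANTS = (FIVE_ELEMENT, SIX_ELEMENT)


class VocabularyError(RuntimeError):
    """Raised when the packaged type assets are missing or corrupt."""


@dataclass(frozen=True, order=True)
class ECIFAtomType:
    """A rendered-orderable qualitative atom representation.

    ``is_aromatic`` is ``None`` in the five-element variant and a boolean in
    the six-element variant.
    """

    symbol: str
    explicit_valence: int
    n_heavy_neighbors: int
    n_attached_hydrogens: int
    in_ring: bool
    is_aromatic: bool | None = None

    @property
    def variant(self) -> str:
        return FIVE_ELEMENT if self.is_aromatic is None else SIX_ELEMENT

    def render(self) -> str:
        fields = [self.symbol, str(self.explicit_valence),
                  str(self.n_heavy_neighbors), str(self.n_attached_hydrogens)]
        if self.is_aromatic is not None:
            fields.append(str(int(self.is_aromatic)))
        fields.append(str(int(self.in_ring)))
        return ";".join(fields)

    @classmethod
    def parse(cls, text: str) -> "ECIFAtomType":
        fields = text.split(";")
        if len(fields) not in (5, 6):
            raise ValueError(f"not an ECIF atom type: {text!r}")
        aromatic = bool(int(fields[4])) if len(fields) == 6 else None
        return cls(symbol=fields[0],
                   explicit_valence=int(fields[1]),
                   n_heavy_neighbors=int(fields[2]),
                   n_attached_hydrogens=int(fields[3]),
                   in_ring=bool(int(fields[-1])),
                   is_aromatic=aromatic)

    def drop_aromaticity(self) -> "ECIFAtomType":
        """Project a six-element type onto the five-element variant."""
        if self.is_aromatic is None:
            return self
        return ECIFAtomType(self.symbol, self.explicit_valence,
                            self.n_heavy_neighbors, self.n_attached_hydrogens,
                            self.in_ring, None)


def pair_name(protein_type: ECIFAtomType | str,
              ligand_type: ECIFAtomType | str) -> str:
    """Join a protein and a ligand type into a feature name with a hyphen."""
    if isinstance(protein_type, str):
        protein_type = ECIFAtomType.parse(protein_type)
    if isinstance(ligand_type, str):
        ligand_type = ECIFAtomType.parse(ligand_type)
    if protein_type.variant != ligand_type.variant:
        raise ValueError(
            f"variant mismatch: {protein_type.render()} is "
            f"{protein_type.variant}, {ligand_type.render()} is "
            f"{ligand_type.variant}")
    return f"{protein_type.render()}-{ligand_type.render()}"


# ------------------------------------------------------------------ packaged assets

def _asset_text(name: str) -> str:
    try:
        return (files("msecif") / "assets" / name).read_text()
    except (FileNotFoundError, OSError) as exc:
        raise VocabularyError(f"packaged asset {name} is missing") from exc


@lru_cache(maxsize=1)
def protein_typing_table() -> dict[tuple[str, str], tuple[str, str]]:
    """(residue, atom name) -> (five-element, six-element) rendered types."""
    table: dict[tuple[str, str], tuple[str, str]] = {}
    lines = _asset_text("protein_types.tsv").splitlines()
    if not lines or lines[0].split("\t")[:2] != ["residue", "atom_name"]:
        raise VocabularyError("protein_types.tsv has an unexpected header")
    for line in lines[1:]:
        res, name, t5, t6 = line.rstrip("\n").split("\t")
        table[(res, name)] = (t5, t6)
    if not table:
        raise VocabularyError("protein_types.tsv is empty")
    return table


@lru_cache(maxsize=1)
def ligand_type_table() -> list[dict[str, str]]:
    """Rows of the packaged ligand type list (with witness fragments)."""
    lines = _asset_text("ligand_types.tsv").splitlines()
    header = lines[0].split("\t") if lines else []
    if "six_element_type" not in header:
        raise VocabularyError("ligand_types.tsv has an unexpected header")
    rows = [dict(zip(header, line.rstrip("\n").split("\t"))) for line in lines[1:]]
    if not rows:
        raise VocabularyError("ligand_types.tsv is empty")
    return rows


def _distinct_protein_types(variant: str) -> list[ECIFAtomType]:
    idx = 0 if variant == FIVE_ELEMENT else 1
    rendered = sorted({v[idx] for v in protein_typing_table().values()})
    return [ECIFAtomType.parse(t) for t in rendered]


def _distinct_ligand_types(variant: str) -> list[ECIFAtomType]:
    key = "five_element_type" if variant == FIVE_ELEMENT else "six_element_type"
    rendered = sorted({row[key] for row in ligand_type_table()})
    return [ECIFAtomType.parse(t) for t in rendered]


# ------------------------------------------------------------------------ operations

def type_protein_atom(atom: ProteinAtom,
                      variant: str = FIVE_ELEMENT) -> ECIFAtomType | None:
    """Look up the dictionary type for a protein atom, or ``None`` if absent.

    Absence is a valid outcome (non-standard residues, metals, terminal OXT
    atoms): untyped atoms simply contribute no features.
    """
    _check_variant(variant)
    entry = protein_typing_table().get((atom.residue_name, atom.atom_name))
    if entry is None:
        return None
    return ECIFAtomType.parse(entry[0 if variant == FIVE_ELEMENT else 1])


def type_ligand_atom(atom: LigandAtom, variant: str = FIVE_ELEMENT) -> ECIFAtomType:
    """Render a ligand atom's perceived attributes as an ECIF type."""
    _check_variant(variant)
    return ECIFAtomType(
        symbol=atom.element,
        explicit_valence=atom.explicit_valence,
        n_heavy_neighbors=atom.n_heavy_neighbors,
        n_attached_hydrogens=atom.n_attached_hydrogens,
        in_ring=atom.in_ring,
        is_aromatic=atom.is_aromatic if variant == SIX_ELEMENT else None,
    )


@dataclass(frozen=True)
class PairVocabulary:
    """The ordered protein-ligand pair feature space for one variant."""

    variant: str
    protein_types: tuple[ECIFAtomType, ...]
    ligand_types: tuple[ECIFAtomType, ...]
    pair_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.pair_names)

    @property
    def index(self) -> dict[str, int]:
        return _vocab_index(self)

    @classmethod
    def from_types(cls, variant: str,
                   protein_types: list[ECIFAtomType],
                   ligand_types: list[ECIFAtomType]) -> "PairVocabulary":
        ptypes = tuple(sorted(protein_types, key=lambda t: t.render()))
        ltypes = tuple(sorted(ligand_types, key=lambda t: t.render()))
        names = tuple(pair_name(p, l) for p in ptypes for l in ltypes)
        if len(set(names)) != len(names):
            raise VocabularyError("duplicate pair names in vocabulary")
        return cls(variant, ptypes, ltypes, names)


@lru_cache(maxsize=4)
def _vocab_index(vocab: PairVocabulary) -> dict[str, int]:
    return {name: i for i, name in enumerate(vocab.pair_names)}


@lru_cache(maxsize=2)
def build_vocabulary(variant: str = FIVE_ELEMENT) -> PairVocabulary:
    """Build the packaged pair vocabulary for a variant.

    The six-element vocabulary spans 20 x 77 = 1540 pairs. Dropping the
    aromaticity flag merges environment pairs that differ only in that flag,
    so the five-element vocabulary deduplicates to 20 x 68 = 1360 pairs (see
    the methods note for the enumeration).
    """
    _check_variant(variant)
    return PairVocabulary.from_types(
        variant, _distinct_protein_types(variant), _distinct_ligand_types(variant))


@lru_cache(maxsize=2)
def _ligand_vocab_rendered(variant: str) -> frozenset[str]:
    key = "five_element_type" if variant == FIVE_ELEMENT else "six_element_type"
    return frozenset(row[key] for row in ligand_type_table())


def ligand_type_in_vocabulary(atom_type: ECIFAtomType) -> bool:
    """Whether a ligand type is part of the packaged type list."""
    return atom_type.render() in _ligand_vocab_rendered(atom_type.variant)


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
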