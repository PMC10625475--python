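"""Distance-aware protein-ligand interaction features.

Three feature families over typed heavy-atom pairs within a distance
threshold:

* ``ecif_counts``           -- the classic single-threshold contact count per
  pair type (one value per vocabulary pair);
* ``multi_shelled_features`` -- the same counts subdivided into concentric
  distance shells, each shell named by its upper bound (``<pair>-<bound>``);
* ``weighted_features``     -- per pair type, the sum of 1/d or 1/d^2 over all
  contacts, so close contacts weigh more than distant ones.

Shell intervals are half-open ``(lower, upper]``: the first shell is
``(0, min_shell]`` and the outer threshold is inclusive. Feature order is
vocabulary order, then shell bound ascending — a deterministic column order is
part of the output contract.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import atom_typing
from .atom_typing import (FIVE_ELEMENT, SIX_ELEMENT, ECIFAtomType,
                          PairVocabulary, build_vocabulary, pair_name)
from .io_structures import LigandAtom, ProteinAtom, load_ligand, load_protein

logger = logging.getLogger(__name__)

#: Default distance thresholds (Angstrom) per feature family.
DEFAULT_THRESHOLDS = {"ecif": 6.0, "multishell": 10.0, "weighted": 10.0}
DEFAULT_STEP = 2.0
DEFAULT_MIN_SHELL = 2.5


@dataclass(frozen=True)
class TypedPair:
    """One protein-atom/ligand-atom contact: types plus distance in Angstrom."""

    protein_type: ECIFAtomType
    ligand_type: ECIFAtomType
    distance: float

    @property
    def name(self) -> str:
        return pair_name(self.protein_type, self.ligand_type)


@dataclass(frozen=True)
class ShellScheme:
    """Ordered shell upper bounds derived from (threshold, step, minimum shell).

    ``bounds`` increase from ``min_shell`` in constant steps; the terminal
    shell is capped at the threshold and may be narrower than ``step``.
    """

    min_shell: float
    step: float
    threshold: float
    bounds: tuple[float, ...]

    def shell_of(self, distance: float) -> int:
        """Index of the shell containing ``distance`` (intervals ``(lo, hi]``)."""
        if distance > self.threshold:
            raise ValueError(f"distance {distance} exceeds threshold {self.threshold}")
        return int(np.searchsorted(self.bounds, distance, side="left"))


@dataclass
class FeatureVector:
    """A named, ordered feature map for one complex."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if len(self.names) != len(self.values):
            raise ValueError("names and values lengths differ")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=name)


def enumerate_pairs(protein_atoms: list[ProteinAtom],
                    ligand_atoms: list[LigandAtom],
                    threshold: float,
                    variant: str = FIVE_ELEMENT) -> list[TypedPair]:
    """All typed heavy-atom pairs with Euclidean distance <= threshold.

    Protein atoms without a dictionary entry are skipped silently; ligand
    atoms whose type lies outside the packaged type list are skipped with a
    warning (rare environments produce no features rather than an error).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ptypes, pcoords = [], []
    for atom in protein_atoms:
        t = atom_typing.type_protein_atom(atom, variant)
        if t is not None:
            ptypes.append(t)
            pcoords.append(atom.coords)
    ltypes, lcoords = [], []
    unknown: set[str] = set()
    for atom in ligand_atoms:
        t = atom_typing.type_ligand_atom(atom, variant)
        if not atom_typing.ligand_type_in_vocabulary(t):
            unknown.add(t.render())
            continue
        ltypes.append(t)
        lcoords.append(atom.coords)
    if unknown:
        logger.warning("ignoring ligand atoms with out-of-vocabulary types: %s",
                       ", ".join(sorted(unknown)))
    if not ptypes or not ltypes:
        return []
    dist = cdist(np.asarray(pcoords, dtype=float), np.asarray(lcoords, dtype=float))
    pairs = [TypedPair(ptypes[i], ltypes[j], float(dist[i, j]))
             for i, j in zip(*np.nonzero(dist <= threshold))]
    return pairs


def shell_scheme(threshold: float, step: float,
                 min_shell: float = DEFAULT_MIN_SHELL) -> ShellScheme:
    """Build the shell scheme for a threshold, step width and minimum shell."""
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0 < min_shell < threshold:
        raise ValueError(f"min_shell must satisfy 0 < min_shell < threshold "
                         f"(got {min_shell} vs {threshold})")
    bounds = [float(min_shell)]
    # tolerance so e.g. threshold 10.0 with step 2.0 ends exactly at 10.0
    while bounds[-1] + step < threshold - 1e-9:
        bounds.append(round(bounds[-1] + step, 9))
    bounds.append(float(threshold))
    return ShellScheme(min_shell=float(min_shell), step=float(step),
                       threshold=float(threshold), bounds=tuple(bounds))


def format_bound(bound: float) -> str:
    """Render a shell bound for feature names (always with a decimal point)."""
    text = f"{bound:g}"
    return text if "." in text or "e" in text else text + ".0"


def shell_feature_names(vocab: PairVocabulary, scheme: ShellScheme) -> list[str]:
    return [f"{name}-{format_bound(b)}"
            for name in vocab.pair_names for b in scheme.bounds]


def multi_shelled_features(pairs: list[TypedPair], scheme: ShellScheme,
                           vocab: PairVocabulary | None = None) -> FeatureVector:
    """Per-shell contact counts: ``<pair>-<bound>`` holds the number of
    contacts of that pair type with distance in ``(previous bound, bound]``."""
    vocab = vocab or build_vocabulary(_pairs_variant(pairs) or FIVE_ELEMENT)
    n_shells = len(scheme.bounds)
    values = np.zeros(len(vocab) * n_shells, dtype=int)
    index = vocab.index
    for pair in pairs:
        values[index[pair.name] * n_shells + scheme.shell_of(pair.distance)] += 1
    return FeatureVector(shell_feature_names(vocab, scheme), values)


def weighted_features(pairs: list[TypedPair], squared: bool = True,
                      vocab: PairVocabulary | None = None) -> FeatureVector:
    """Per pair type, the sum of inverse (squared) distances over contacts."""
    vocab = vocab or build_vocabulary(_pairs_variant(pairs) or FIVE_ELEMENT)
    values = np.zeros(len(vocab), dtype=float)
    index = vocab.index
    power = 2 if squared else 1
    for pair in pairs:
        if pair.distance <= 0:
            raise ValueError("zero or negative interatomic distance; overlapping "
                             "atoms cannot be weighted")
        values[index[pair.name]] += 1.0 / pair.distance ** power
    return FeatureVector(list(vocab.pair_names), values)


def ecif_counts(pairs: list[TypedPair],
                vocab: PairVocabulary | None = None) -> FeatureVector:
    """Single-threshold contact counts (the classic ECIF feature value)."""
    vocab = vocab or build_vocabulary(_pairs_variant(pairs) or FIVE_ELEMENT)
    values = np.zeros(len(vocab), dtype=int)
    index = vocab.index
    for pair in pairs:
        values[index[pair.name]] += 1
    return FeatureVector(list(vocab.pair_names), values)


def _pairs_variant(pairs: list[TypedPair]) -> str | None:
    return pairs[0].protein_type.variant if pairs else None


# ------------------------------------------------------------------- whole complexes

def featurize_complex(protein_path: str | Path,
                      ligand_path: str | Path,
                      method: str = "multishell",
                      threshold: float | None = None,
                      step: float = DEFAULT_STEP,
                      squared: bool = True,
                      variant: str | None = None) -> FeatureVector:
    """Featurize one protein (PDB) / ligand (SDF) complex.

    ``method`` is one of ``ecif`` (single-threshold counts, defaults to the
    six-element variant at 6 A), ``multishell`` (shelled counts, five-element,
    10 A / 2 A step) or ``weighted`` (inverse-distance sums, five-element,
    10 A, squared weights).
    """
    if method not in DEFAULT_THRESHOLDS:
        raise ValueError(f"unknown method {method!r}")
    threshold = DEFAULT_THRESHOLDS[method] if threshold is None else threshold
    variant = variant or (SIX_ELEMENT if method == "ecif" else FIVE_ELEMENT)
    pairs = enumerate_pairs(load_protein(protein_path), load_ligand(ligand_path),
                            threshold, variant)
    vocab = build_vocabulary(variant)
    if method == "multishell":
        return multi_shelled_features(pairs, shell_scheme(threshold, step), vocab)
    if method == "weighted":
        return weighted_features(pairs, squared, vocab)
    return ecif_counts(pairs, vocab)


def featurize_table(complexes: list[tuple[str, str | Path, str | Path]],
                    **kwargs) -> pd.DataFrame:
    """Featurize many (complex_id, protein_path, ligand_path) triples.

    Returns a DataFrame indexed by complex id with one column per feature, in
    the deterministic feature order.
    """
    if not complexes:
        raise ValueError("no complexes to featurize")
    rows, ids = [], []
    for complex_id, protein_path, ligand_path in complexes:
        fv = featurize_complex(protein_path, ligand_path, **kwargs)
        rows.append(fv.values)
        ids.append(complex_id)
        names = fv.names
    return pd.DataFrame(rows, index=pd.Index(ids, name="complex_id"), columns=names)


def drop_unobserved(features: pd.DataFrame) -> pd.DataFrame:
    """Drop feature columns that are zero for every complex in a table.

    Trained models are often reported on this observed-only matrix; the full
    matrix keeps the complete vocabulary-defined column set.
    """
    return features.loc[:, (features != 0).any(axis=0)]
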