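"""Whole-ligand physicochemical descriptors and the retention filter.

The descriptor catalog is RDKit's ``Descriptors`` module (molecular weight,
logP, counts of rings/donors/acceptors, topological indices, ...). Because
catalog membership and numeric output drift across provider versions, the
default retained-descriptor list is a shipped, versioned asset regenerated by
applying the filtering procedure — drop zero-variance, null-bearing and
extreme-valued columns over a reference corpus — rather than recomputed live.

The retained list is a function of a *training* table only; applying it to
new ligands never re-runs the filter (train/test leakage guard).
"""
from __future__ import annotations

from functools import lru_cache
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .featurization import FeatureVector
from .io_structures import StructureError, load_ligand_mol

#: Default bound beyond which a descriptor value counts as "extreme".
DEFAULT_EXTREME_BOUND = 1e8


def descriptor_catalog() -> list[str]:
    """Names of all descriptors in the provider's catalog, in catalog order."""
    return [name for name, _ in Descriptors._descList]


def compute_descriptors(mol: Chem.Mol | str | Path) -> pd.Series:
    """One value per catalog descriptor for a single ligand.

    Accepts an RDKit molecule or an SDF path. Descriptors that fail or return
    non-finite values are recorded as null (NaN), not dropped, so downstream
    filtering can see them.
    """
    if not isinstance(mol, Chem.Mol):
        mol = load_ligand_mol(mol)
    if mol is None:
        raise StructureError("ligand could not be perceived")
    values = {}
    for name, fn in Descriptors._descList:
        try:
            v = float(fn(mol))
        except Exception:
            v = float("nan")
        values[name] = v if np.isfinite(v) else float("nan")
    return pd.Series(values)


def filter_descriptors(table: pd.DataFrame,
                       extreme_bound: float = DEFAULT_EXTREME_BOUND) -> list[str]:
    """Names of descriptors that survive the retention filter, in input order.

    A descriptor is dropped when, over the whole table, it (a) has zero
    variance, (b) contains at least one null, or (c) takes any value with
    magnitude above ``extreme_bound``.
    """
    if table.empty:
        raise ValueError("descriptor table is empty")
    retained = []
    for name in table.columns:
        col = table[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            continue
        if np.nanmax(np.abs(col)) > extreme_bound:
            continue
        if np.nanstd(col) == 0.0:
            continue
        retained.append(name)
    if not retained:
        raise ValueError("all descriptors were dropped by the filter")
    return retained


@lru_cache(maxsize=1)
def default_retained_descriptors() -> list[str]:
    """The shipped default retained-descriptor list."""
    text = (files("msecif") / "assets" / "ligand_descriptors_default.txt").read_text()
    return [line for line in text.splitlines() if line.strip()]


def assemble_features(interaction: FeatureVector,
                      descriptors: pd.Series,
                      retained: list[str] | None = None) -> FeatureVector:
    """Concatenate interaction features with retained ligand descriptors.

    Interaction features come first; descriptor order follows the retained
    list. Missing retained descriptors are an error (the retained list must
    have been derived from the same catalog).
    """
    retained = default_retained_descriptors() if retained is None else retained
    missing = [name for name in retained if name not in descriptors.index]
    if missing:
        raise KeyError(f"retained descriptors missing from input: {missing[:5]}")
    values = np.concatenate([np.asarray(interaction.values, dtype=float),
                             descriptors[retained].to_numpy(dtype=float)])
    return FeatureVector(list(interaction.names) + list(retained), values)
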