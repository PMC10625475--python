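"""Featurization: pair enumeration, shell schemes, counts and weighted sums."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from msecif.atom_typing import FIVE_ELEMENT, ECIFAtomType, PairVocabulary
from msecif.featurization import (TypedPair, ecif_counts, enumerate_pairs,
                                  format_bound, multi_shelled_features,
                                  shell_scheme, weighted_features)
from msecif.io_structures import LigandAtom, ProteinAtom

P_N = ECIFAtomType.parse("N;3;2;1;0")
L_O = ECIFAtomType.parse("O;2;1;1;0")
PAIR = "N;3;2;1;0-O;2;1;1;0"


def _toy_vocab():
    return PairVocabulary.from_types(
        FIVE_ELEMENT, [P_N, ECIFAtomType.parse("C;4;3;1;0")],
        [L_O, ECIFAtomType.parse("C;4;1;3;0")])


def _worked_pairs(distances=(2.0, 3.0, 4.0)):
    return [TypedPair(P_N, L_O, d) for d in distances]


def _protein_n(xyz):
    return ProteinAtom("ALA", "N", "N", xyz)


def _ligand_o(xyz):
    return LigandAtom("O", 2, 1, 1, False, False, xyz)


class TestEnumeratePairs:
    def test_threshold_boundary_is_inclusive(self):
        pairs = enumerate_pairs([_protein_n((0, 0, 0))],
                                [_ligand_o((6.0, 0, 0))], threshold=6.0)
        assert len(pairs) == 1 and pairs[0].distance == pytest.approx(6.0)

    def test_pair_beyond_threshold_excluded(self):
        assert enumerate_pairs([_protein_n((0, 0, 0))],
                               [_ligand_o((6.0, 0, 0))], threshold=5.9) == []

    def test_worked_example_geometry(self):
        protein = [_protein_n((d, 0, 0)) for d in (2.0, 3.0, 4.0)]
        pairs = enumerate_pairs(protein, [_ligand_o((0, 0, 0))], threshold=6.0)
        assert sorted(round(p.distance, 6) for p in pairs) == [2.0, 3.0, 4.0]
        assert all(p.name == PAIR for p in pairs)

    def test_untyped_protein_atoms_skipped(self):
        unknown = ProteinAtom("XYZ", "FE1", "FE", (1.0, 0, 0))
        pairs = enumerate_pairs([unknown, _protein_n((2.0, 0, 0))],
                                [_ligand_o((0, 0, 0))], threshold=6.0)
        assert len(pairs) == 1

    def test_out_of_vocabulary_ligand_atom_skipped(self):
        exotic = LigandAtom("Se", 2, 2, 0, False, False, (1.0, 0, 0))
        pairs = enumerate_pairs([_protein_n((0, 0, 0))],
                                [exotic, _ligand_o((2.0, 0, 0))], threshold=6.0)
        assert len(pairs) == 1

    def test_threshold_monotonicity(self):
        protein = [_protein_n((float(d), 0, 0)) for d in range(2, 10)]
        ligand = [_ligand_o((0, 0, 0))]
        previous = 0
        for threshold in (3.0, 5.0, 7.0, 9.0, 11.0):
            count = len(enumerate_pairs(protein, ligand, threshold))
            assert count >= previous
            previous = count


class TestShellScheme:
    def test_printed_three_shell_scheme(self):
        assert shell_scheme(6.0, 2.0).bounds == (2.5, 4.5, 6.0)

    def test_default_scheme_has_narrow_terminal_shell(self):
        assert shell_scheme(10.0, 2.0).bounds == (2.5, 4.5, 6.5, 8.5, 10.0)

    def test_degenerate_terminal_shell(self):
        assert shell_scheme(2.5001, 2.0).bounds == (2.5, 2.5001)

    def test_min_shell_must_be_below_threshold(self):
        with pytest.raises(ValueError):
            shell_scheme(2.0, 2.0, min_shell=2.5)

    def test_first_shell_covers_zero_to_min_shell(self):
        scheme = shell_scheme(10.0, 2.0)
        assert scheme.shell_of(0.5) == 0
        assert scheme.shell_of(2.5) == 0      # upper bound inclusive
        assert scheme.shell_of(2.5000001) == 1

    @given(st.floats(min_value=0.01, max_value=10.0))
    def test_every_distance_falls_in_exactly_one_shell(self, d):
        scheme = shell_scheme(10.0, 2.0)
        k = scheme.shell_of(d)
        lower = 0.0 if k == 0 else scheme.bounds[k - 1]
        assert lower < d <= scheme.bounds[k]

    def test_bound_formatting(self):
        assert format_bound(6.0) == "6.0"
        assert format_bound(2.5) == "2.5"
        assert format_bound(10.0) == "10.0"
        assert format_bound(2.5001) == "2.5001"


class TestMultiShelled:
    def test_printed_worked_example(self, vocab5):
        ms = multi_shelled_features(_worked_pairs(), shell_scheme(6.0, 2.0),
                                    vocab5)
        assert ms[f"{PAIR}-2.5"] == 1
        assert ms[f"{PAIR}-4.5"] == 2
        assert ms[f"{PAIR}-6.0"] == 0
        assert len(ms) == len(vocab5) * 3

    def test_empty_pair_list_gives_zero_vector(self):
        vocab = _toy_vocab()
        ms = multi_shelled_features([], shell_scheme(6.0, 2.0), vocab)
        assert len(ms) == len(vocab) * 3 and not ms.values.any()

    def test_distance_beyond_scheme_threshold_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            multi_shelled_features([TypedPair(P_N, L_O, 7.0)],
                                   shell_scheme(6.0, 2.0), _toy_vocab())

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1),
                              st.floats(min_value=0.01, max_value=10.0)),
                    max_size=40))
    def test_shell_sum_conservation(self, raw):
        """Summing a pair type's shell counts recovers its single-threshold
        count, for any input."""
        vocab = _toy_vocab()
        ptypes = list(vocab.protein_types)
        ltypes = list(vocab.ligand_types)
        pairs = [TypedPair(ptypes[i], ltypes[j], d) for i, j, d in raw]
        scheme = shell_scheme(10.0, 2.0)
        ms = multi_shelled_features(pairs, scheme, vocab)
        counts = ecif_counts(pairs, vocab)
        shelled = ms.values.reshape(len(vocab), len(scheme.bounds))
        assert (shelled.sum(axis=1) == counts.values).all()

    def test_permutation_invariance(self, vocab5):
        pairs = _worked_pairs((2.0, 3.0, 4.0, 5.5, 5.9))
        forward = multi_shelled_features(pairs, shell_scheme(6.0, 2.0), vocab5)
        backward = multi_shelled_features(pairs[::-1], shell_scheme(6.0, 2.0),
                                          vocab5)
        assert (forward.values == backward.values).all()
        assert forward.names == backward.names


class TestWeighted:
    def test_printed_inverse_square_value(self, vocab5):
        w = weighted_features(_worked_pairs(), squared=True, vocab=vocab5)
        assert w[PAIR] == pytest.approx(1 / 4 + 1 / 9 + 1 / 16, abs=1e-12)
        assert round(w[PAIR], 4) == 0.4236

    def test_inverse_distance_value(self, vocab5):
        w = weighted_features(_worked_pairs(), squared=False, vocab=vocab5)
        assert w[PAIR] == pytest.approx(1 / 2 + 1 / 3 + 1 / 4, abs=1e-12)

    def test_empty_pair_list_gives_zero_vector(self):
        vocab = _toy_vocab()
        w = weighted_features([], vocab=vocab)
        assert len(w) == len(vocab) and not w.values.any()

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            weighted_features([TypedPair(P_N, L_O, 0.0)], vocab=_toy_vocab())

    @given(st.floats(min_value=0.5, max_value=9.0),
           st.floats(min_value=0.05, max_value=0.4),
           st.booleans())
    def test_decreasing_distance_increases_weight(self, d, shrink, squared):
        vocab = _toy_vocab()
        near = weighted_features([TypedPair(P_N, L_O, d - shrink)],
                                 squared=squared, vocab=vocab)
        far = weighted_features([TypedPair(P_N, L_O, d)],
                                squared=squared, vocab=vocab)
        assert near[PAIR] > far[PAIR]


class TestEcifCounts:
    def test_worked_example_count(self, vocab5):
        assert ecif_counts(_worked_pairs(), vocab5)[PAIR] == 3

    def test_counts_match_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        protein = [_protein_n(tuple(xyz)) for xyz in rng.uniform(0, 12, (25, 3))]
        ligand = [_ligand_o(tuple(xyz)) for xyz in rng.uniform(0, 12, (25, 3))]
        threshold = 6.0
        pairs = enumerate_pairs(protein, ligand, threshold)
        brute = 0
        for p in protein:
            for l in ligand:
                d = np.sqrt(sum((a - b) ** 2 for a, b in zip(p.coords, l.coords)))
                if d <= threshold:
                    brute += 1
        assert len(pairs) == brute
        assert ecif_counts(pairs).values.sum() == brute
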