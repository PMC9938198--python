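"""Exterior labeling, partitioning, assembly, and corpus statistics."""

import numpy as np
import pytest

from rnapart.exterior import (
    assemble,
    context_composition,
    exterior_runs_to_bed,
    extract_substructure,
    fragment_stats,
    label_exterior,
    labels_to_tsv,
    partition_ifragments,
)
from rnapart.struct_io import SecondaryStructure, StructureError
from rnapart.synthetic import SynthParams, generate_corpus

from conftest import brute_force_exterior, random_pair_structure


class TestLabelExterior:
    def test_unpaired_rna_all_exterior(self):
        s = SecondaryStructure("ACGUAC")
        assert label_exterior(s).tolist() == [1] * 6

    def test_nested_helix_labels(self):
        s = SecondaryStructure("ACGUACGUACGU", {(2, 7), (3, 6)})
        assert label_exterior(s).tolist() == [1, 1, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1]

    def test_pseudoknot_intervals_cover(self):
        # crossing pairs (0,5),(3,9): everything in [0,9] is covered
        s = SecondaryStructure("ACGUACGUACGU", {(0, 5), (3, 9)})
        expected = [0] * 10 + [1, 1]
        assert label_exterior(s).tolist() == expected

    def test_matches_brute_force_oracle(self, rng):
        """Interval-union labeling == all-pairs enclosure check."""
        for _ in range(250):
            s = random_pair_structure(rng, max_n=120)
            assert np.array_equal(label_exterior(s), brute_force_exterior(s))

    def test_adding_pair_never_adds_exterior(self, rng):
        """Monotonicity: extra pairs can only shrink the exterior set."""
        for _ in range(40):
            s = random_pair_structure(rng, max_n=60)
            before = label_exterior(s)
            i, j = sorted(int(v) for v in rng.choice(len(s.sequence), 2, replace=False))
            if i == j:
                continue
            bigger = SecondaryStructure(s.sequence, s.pairs | {(i, j)})
            after = label_exterior(bigger)
            assert np.all(after <= before)


class TestPartition:
    def test_all_exterior_yields_no_fragments(self):
        assert partition_ifragments("ACGUAC", [1] * 6) == []

    def test_single_fragment(self):
        frags = partition_ifragments(
            "ACGUACGUACGU", [1, 1, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1]
        )
        assert [(f.start, f.end) for f in frags] == [(2, 8)]
        assert frags[0].sequence == "GUACGU"

    def test_multiple_runs(self):
        labels = [0, 0, 1, 1, 0, 0, 0, 1, 0, 0]
        frags = partition_ifragments("ACGUACGUAC", labels)
        assert [(f.start, f.end) for f in frags] == [(0, 2), (4, 7), (8, 10)]

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            partition_ifragments("ACGU", [1, 0])


class TestExtractAssemble:
    def test_extract_shifts_coordinates(self):
        s = SecondaryStructure("ACGUACGUACGU", {(2, 7), (3, 6)})
        frags = partition_ifragments(s.sequence, label_exterior(s))
        sub = extract_substructure(s, frags[0])
        assert sub.pairs == {(0, 5), (1, 4)}
        assert sub.sequence == "GUACGU"

    def test_straddling_pair_rejected(self):
        s = SecondaryStructure("ACGUACGU", {(1, 6)})
        frag = partition_ifragments(s.sequence, [1, 0, 0, 0, 1, 1, 1, 1])[0]
        with pytest.raises(StructureError, match="straddles"):
            extract_substructure(s, frag)

    def test_overlapping_fragments_rejected(self):
        frags = partition_ifragments("ACGUACGU", [0, 0, 0, 0, 0, 1, 1, 1])
        frags.append(frags[0])
        with pytest.raises(ValueError, match="overlap"):
            assemble(8, frags)

    def test_roundtrip_identity_on_random_structures(self, rng):
        """assemble . extract . partition . label is the identity on pairs,
        and every pair lands in exactly one fragment."""
        for _ in range(200):
            s = random_pair_structure(rng, max_n=150)
            labels = label_exterior(s)
            frags = partition_ifragments(s.sequence, labels)
            for f in frags:
                f.substructure = extract_substructure(s, f)
            n_assigned = sum(len(f.substructure.pairs) for f in frags)
            assert n_assigned == len(s.pairs)
            back = assemble(len(s.sequence), frags, sequence=s.sequence)
            assert back.pairs == s.pairs


class TestFragmentStats:
    def test_identical_single_fragment_corpus(self):
        s = SecondaryStructure("AGGGAAACCCA", {(1, 9), (2, 8), (3, 7)})
        stats = fragment_stats([s, s])
        assert stats.per_rna["n_fragments"].tolist() == [1, 1]
        # degenerate variance: correlation undefined, not NaN
        assert stats.correlations["rna_length_vs_fragment_count"] is None

    def test_two_rna_hand_computed(self):
        # RNA a: one 6-nt fragment; RNA b: fragments of 6 and 8 nt
        a = SecondaryStructure("AGGAUCCA", {(1, 6), (2, 5)})
        b = SecondaryStructure(
            "GGAUCCAAGGGAUUCCCA", {(0, 5), (1, 4), (8, 15), (9, 14), (10, 13)}
        )
        stats = fragment_stats([a, b])
        assert stats.per_rna["n_fragments"].tolist() == [1, 2]
        assert sorted(stats.fragment_lengths.tolist()) == [6, 6, 8]
        assert stats.mean_fragment_length == pytest.approx(20 / 3)
        r, _ = stats.correlations["rna_length_vs_fragment_count"]
        assert r == pytest.approx(1.0)

    def test_recovers_generated_fragment_count(self):
        params = SynthParams(n_fragments=3, fragment_length_mean=40, linker_length_mean=8)
        corpus = [s for s, _ in generate_corpus(30, params, seed=7)]
        stats = fragment_stats(corpus)
        assert stats.per_rna["n_fragments"].mean() == pytest.approx(3, abs=0.2)


class TestContextComposition:
    def test_gc_depleted_exterior_detected(self):
        params = SynthParams(
            n_fragments=(1, 3), fragment_length_mean=40, linker_length_mean=15,
            exterior_gc=0.2, fragment_gc=0.6,
        )
        corpus = [s for s, _ in generate_corpus(60, params, seed=3)]
        table = context_composition(corpus, window=31, per_class=300, seed=0)
        freq = table.set_index("base")
        gc_ext = freq.loc["G", "freq_exterior"] + freq.loc["C", "freq_exterior"]
        gc_non = freq.loc["G", "freq_non_exterior"] + freq.loc["C", "freq_non_exterior"]
        assert gc_ext < gc_non
        assert np.isclose(freq["freq_exterior"].sum(), 1.0, atol=1e-9)
        assert np.isclose(freq["freq_non_exterior"].sum(), 1.0, atol=1e-9)

    def test_all_exterior_corpus_errors(self):
        s = SecondaryStructure("ACGU" * 20)
        with pytest.raises(ValueError, match="too small"):
            context_composition([s], window=31, per_class=10)


class TestSerialization:
    def test_tsv_and_bed(self):
        labels = [1, 1, 0, 0, 1]
        tsv = labels_to_tsv("x", "ACGUA", labels)
        assert tsv.splitlines()[1] == "x\t1\tA\t1"
        bed = exterior_runs_to_bed("x", labels)
        assert bed.splitlines() == ["x\t0\t2", "x\t4\t5"]
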