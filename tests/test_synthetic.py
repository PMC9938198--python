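"""Self-consistency and statistical properties of the generator."""

import numpy as np
import pytest

from rnapart.exterior import label_exterior, partition_ifragments
from rnapart.struct_io import write_structure
from rnapart.synthetic import (
    MIN_FRAGMENT,
    SynthParams,
    generate_dataset,
    generate_structure,
)


class TestGenerateStructure:
    def test_zero_fragments_all_exterior(self):
        s, labels = generate_structure(SynthParams(n_fragments=0), seed=0)
        assert s.pairs == set()
        assert labels.tolist() == [1] * len(s.sequence)

    def test_single_fragment_no_linkers_all_interior(self):
        params = SynthParams(n_fragments=1, linker_length_mean=0)
        s, labels = generate_structure(params, seed=1)
        assert labels.sum() == 0

    def test_labels_always_match_label_exterior(self, rng):
        params = SynthParams(n_fragments=(1, 6), fragment_length_mean=50,
                             linker_length_mean=8, pseudoknot_prob=0.3)
        for k in range(150):
            s, labels = generate_structure(params, seed=int(rng.integers(2**31)))
            assert np.array_equal(labels, label_exterior(s))

    def test_fragment_count_matches_request(self, rng):
        params = SynthParams(n_fragments=4, fragment_length_mean=40, linker_length_mean=8)
        counts = []
        for k in range(40):
            s, labels = generate_structure(params, seed=k)
            counts.append(len(partition_ifragments(s.sequence, labels)))
        assert np.mean(counts) == pytest.approx(4, abs=0.3)

    def test_paired_positions_complementary(self):
        params = SynthParams(n_fragments=(1, 3), pseudoknot_prob=0.5)
        valid = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
        for k in range(25):
            s, _ = generate_structure(params, seed=k)
            for i, j in s.pairs:
                assert (s.sequence[i], s.sequence[j]) in valid

    def test_no_triples_ct_representable(self):
        params = SynthParams(n_fragments=(1, 4), pseudoknot_prob=0.5)
        for k in range(25):
            s, _ = generate_structure(params, seed=k)
            write_structure(s, "ct")  # raises on triples

    def test_pseudoknots_emitted_when_enabled(self):
        params = SynthParams(n_fragments=2, fragment_length_mean=60, pseudoknot_prob=1.0)
        found = False
        for k in range(20):
            s, _ = generate_structure(params, seed=k)
            pairs = sorted(s.pairs)
            for a in pairs:
                for b in pairs:
                    if a[0] < b[0] < a[1] < b[1]:
                        found = True
        assert found

    def test_infeasible_fragment_rejected(self):
        from rnapart.synthetic import _build_fragment_pairs

        with pytest.raises(ValueError, match="infeasible"):
            _build_fragment_pairs(MIN_FRAGMENT - 1, SynthParams(), np.random.default_rng(0))

    def test_exterior_gc_depleted(self):
        params = SynthParams(n_fragments=(1, 3), fragment_length_mean=40,
                             linker_length_mean=15, exterior_gc=0.2, fragment_gc=0.6)
        ext_gc = non_gc = ext_n = non_n = 0
        for k in range(60):
            s, labels = generate_structure(params, seed=k)
            seq = np.array(list(s.sequence))
            is_gc = np.isin(seq, ["G", "C"])
            ext = labels.astype(bool)
            ext_gc += is_gc[ext].sum()
            ext_n += ext.sum()
            non_gc += is_gc[~ext].sum()
            non_n += (~ext).sum()
        assert ext_gc / ext_n < non_gc / non_n

    def test_seed_reproducibility(self):
        params = SynthParams()
        s1, l1 = generate_structure(params, seed=77)
        s2, l2 = generate_structure(params, seed=77)
        assert s1.sequence == s2.sequence
        assert s1.pairs == s2.pairs
        assert np.array_equal(l1, l2)


class TestGenerateDataset:
    PARAMS = SynthParams(n_fragments=(1, 3), fragment_length_mean=40,
                         linker_length_mean=8, label_noise=0.2)

    def test_zero_noise_coarse_equals_accurate(self):
        params = SynthParams(n_fragments=(1, 3), fragment_length_mean=40,
                             linker_length_mean=8, label_noise=0.0)
        ds = generate_dataset(20, params, seed=0, window_length=60)
        for part in ("train", "val", "test"):
            assert np.array_equal(ds["coarse"][part].y, ds["accurate"][part].y)

    def test_noise_rate_binomial(self):
        ds = generate_dataset(60, self.PARAMS, seed=1, window_length=60)
        acc, coarse = ds["accurate"]["train"], ds["coarse"]["train"]
        real = acc.mask > 0
        flipped = (acc.y != coarse.y)[real].mean()
        n = int(real.sum())
        tol = 4 * np.sqrt(0.2 * 0.8 / n)
        assert flipped == pytest.approx(0.2, abs=tol)

    def test_same_seed_identical_datasets(self):
        d1 = generate_dataset(15, self.PARAMS, seed=3, window_length=60)
        d2 = generate_dataset(15, self.PARAMS, seed=3, window_length=60)
        for variant in ("accurate", "coarse"):
            for part in ("train", "val", "test"):
                assert np.array_equal(d1[variant][part].x, d2[variant][part].x)
                assert np.array_equal(d1[variant][part].y, d2[variant][part].y)

    def test_split_sizes(self):
        ds = generate_dataset(20, self.PARAMS, seed=0, window_length=60,
                              split=(0.5, 0.25, 0.25))
        assert len(ds["accurate"]["train"]) > 0
        assert len(ds["accurate"]["val"]) > 0
        assert len(ds["accurate"]["test"]) > 0

    def test_too_small_corpus_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(2, self.PARAMS, seed=0, split=(0.9, 0.05, 0.05))

    def test_padding_labeled_zero_masked_out(self):
        ds = generate_dataset(10, self.PARAMS, seed=5, window_length=200)
        train = ds["accurate"]["train"]
        pad = train.mask == 0
        assert np.all(train.y[pad] == 0)
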