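"""Unit and property tests for the six augmentation transforms."""

import numpy as np
import pytest
from scipy import stats

import seqaug as sa
from seqaug import AugmentationConfig, OneHotBatch, decode, encode
from seqaug.augment import (
    apply_inversion,
    apply_translocation,
    augment_batch,
    pad_to_length,
)
from seqaug.seqdata import complement_permutation

from conftest import random_batch

ALPHA = 0.001


def rng(seed=0):
    return np.random.default_rng(seed)


class TestTransversion:
    def test_zero_probability_is_identity(self, small_batch):
        out = sa.transversion(small_batch, 0.0, rng())
        assert np.array_equal(out.data, small_batch.data)

    def test_complement_definition(self):
        out = sa.transversion(encode(["AAAA"]), 1.0, rng())
        assert decode(out) == ["TTTT"]

    def test_involution(self, small_batch):
        once = sa.transversion(small_batch, 1.0, rng())
        twice = sa.transversion(once, 1.0, rng())
        assert np.array_equal(twice.data, small_batch.data)

    def test_reverse_complement_semantics(self):
        out = sa.transversion(encode(["ACGTTT"]), 1.0, rng())
        assert decode(out) == ["AAACGT"]


class TestTranslocation:
    def test_zero_shift_is_identity(self, small_batch):
        out = sa.translocation(small_batch, 0, rng())
        assert np.array_equal(out.data, small_batch.data)

    def test_index_arithmetic_oracle(self):
        # independent oracle: out[i] = in[(i - s) mod L], checked by string rotation
        b = encode(["ACGTAA"])
        shifted = apply_translocation(b.data, np.array([2]))
        assert decode(OneHotBatch(shifted)) == ["AAACGT"]
        s = "ACGTAA"
        expect = "".join(s[(i - 2) % 6] for i in range(6))
        assert decode(OneHotBatch(shifted)) == [expect]

    def test_shift_then_inverse_is_identity(self, small_batch):
        fwd = apply_translocation(small_batch.data, np.array([7] * 8))
        back = apply_translocation(fwd, np.array([-7] * 8))
        assert np.array_equal(back, small_batch.data)

    def test_shift_max_too_large_rejected(self, tiny_batch):
        with pytest.raises(ValueError, match="shift_max"):
            sa.translocation(tiny_batch, 6, rng())

    def test_shift_distribution_uniform(self):
        # chi-square goodness of fit against U{-3..3}, n=10,000; the realised
        # shifts are read off a cloned rng and verified against the output
        b = random_batch(10_000, 12, seed=5)
        out = sa.translocation(b, 3, rng(11))
        shifts = rng(11).integers(-3, 4, size=10_000)
        for i in (0, 1, 2, 5_000, 9_999):  # spot-check the clone is faithful
            assert np.array_equal(out.data[i], np.roll(b.data[i], shifts[i], axis=0))
        counts = np.bincount(shifts + 3, minlength=7)
        assert stats.chisquare(counts).pvalue > ALPHA


class TestDeletion:
    def test_zero_deletion_is_identity(self, small_batch):
        out = sa.deletion(small_batch, 0, 0, rng())
        assert np.array_equal(out.data, small_batch.data)

    def test_ordered_subsequence_preserved(self):
        # structural oracle: the retained letters appear in order in the output
        b = encode(["ACGTAC"])
        out = sa.deletion(b, 2, 2, rng(3))
        assert out.length == 6
        s_out = decode(out)[0]
        # some contiguous 4-mer of the input (with a 2-cut removed) must embed
        found = False
        for p in range(5):
            kept = "ACGTAC"[:p] + "ACGTAC"[p + 2:]
            it = iter(s_out)
            if all(c in it for c in kept):
                found = True
        assert found

    def test_output_strict_one_hot(self, small_batch):
        out = sa.deletion(small_batch, 5, 10, rng(1))
        assert out.is_strict_onehot()

    def test_delete_max_too_large_rejected(self, tiny_batch):
        with pytest.raises(ValueError, match="delete_max"):
            sa.deletion(tiny_batch, 0, 6, rng())

    def test_length_distribution_uniform(self):
        # realised (l, p) come from a cloned rng; each is verified structurally
        # against the output, then lengths are chi-squared against U{2..6}
        n, L = 10_000, 30
        b = random_batch(n, L, seed=6)
        out = sa.deletion(b, 2, 6, rng(12))
        clone = rng(12)
        lengths = clone.integers(2, 7, size=n)
        starts = clone.integers(0, L - lengths + 1)
        for i in (0, 1, 4_999, 9_999):
            l, p = int(lengths[i]), int(starts[i])
            kept = np.concatenate([b.data[i, :p], b.data[i, p + l :]])
            assert np.array_equal(out.data[i, l // 2 : l // 2 + L - l], kept)
        counts = np.bincount(lengths - 2, minlength=5)
        assert stats.chisquare(counts).pvalue > ALPHA


class TestInsertion:
    def test_zero_insertion_is_identity(self, small_batch):
        out = sa.insertion(small_batch, 0, 0, rng())
        assert np.array_equal(out.data, small_batch.data)

    def test_output_length_always_L_plus_max(self, small_batch):
        out = sa.insertion(small_batch, 0, 12, rng(2))
        assert out.length == small_batch.length + 12

    def test_input_recoverable_as_ordered_subsequence(self):
        # subsequence-containment oracle on decoded strings
        b = encode(["ACGTACGTAC"])
        out = sa.insertion(b, 3, 8, rng(4))
        s_in, s_out = "ACGTACGTAC", decode(out)[0]
        it = iter(s_out)
        assert all(c in it for c in s_in)

    def test_insertion_length_distribution_uniform(self):
        # realised (l, p) from a cloned rng, verified structurally, then
        # chi-squared against U{2..6}
        n, L, imax = 10_000, 20, 6
        b = random_batch(n, L, seed=14)
        out = sa.insertion(b, 2, imax, rng(13))
        clone = rng(13)
        lengths = clone.integers(2, imax + 1, size=n)
        positions = clone.integers(0, L + 1, size=n)
        for i in (0, 1, 4_999, 9_999):
            l, p = int(lengths[i]), int(positions[i])
            left = (imax - l) // 2
            assert np.array_equal(out.data[i, left : left + p], b.data[i, :p])
            assert np.array_equal(
                out.data[i, left + p + l : left + p + l + (L - p)], b.data[i, p:]
            )
        counts = np.bincount(lengths - 2, minlength=imax - 1)
        assert stats.chisquare(counts).pvalue > ALPHA


class TestInversion:
    def test_zero_inversion_is_identity(self, small_batch):
        out = sa.inversion(small_batch, 0, 0, rng())
        assert np.array_equal(out.data, small_batch.data)

    def test_full_palindrome_unchanged(self):
        out_data = apply_inversion(
            encode(["ACGT"]).data, np.array([4]), np.array([0]),
            complement_permutation(),
        )
        assert decode(OneHotBatch(out_data)) == ["ACGT"]

    def test_same_segment_twice_is_identity(self, small_batch):
        perm = complement_permutation()
        lengths, starts = np.full(8, 13), np.full(8, 20)
        once = apply_inversion(small_batch.data, lengths, starts, perm)
        twice = apply_inversion(once, lengths, starts, perm)
        assert np.array_equal(twice, small_batch.data)

    def test_invert_max_above_length_rejected(self, tiny_batch):
        with pytest.raises(ValueError, match="invert_max"):
            sa.inversion(tiny_batch, 0, 7, rng())


class TestMutation:
    def test_zero_fraction_is_identity(self, small_batch):
        out = sa.mutation(small_batch, 0.0, rng())
        assert np.array_equal(out.data, small_batch.data)

    def test_exact_hamming_distance(self):
        # mismatch-count oracle on decoded strings
        b = random_batch(20, 100, seed=7)
        out = sa.mutation(b, 0.05, rng(8))
        for s_in, s_out in zip(decode(b), decode(out)):
            ham = sum(a != c for a, c in zip(s_in, s_out))
            assert ham == 5

    def test_alternative_bases_uniform(self):
        # chi-square: at a fixed position each of the 3 alternatives ~ 1/3
        b = OneHotBatch(np.tile(np.eye(4)[[0]], (10_000, 1, 1)))  # all "A", L=1
        out = sa.mutation(b, 1.0, rng(9))
        new = np.argmax(out.data[:, 0], axis=1)
        assert not np.any(new == 0)  # guaranteed change
        counts = np.bincount(new)[1:]
        assert stats.chisquare(counts).pvalue > ALPHA


class TestNoise:
    def test_zero_std_is_identity(self, small_batch):
        out = sa.noise(small_batch, 0.0, rng())
        assert np.array_equal(out.data, small_batch.data)

    def test_moments_match(self):
        b = random_batch(1000, 200, seed=10)
        out = sa.noise(b, 0.3, rng(10))
        delta = out.data - b.data
        n = delta.size
        assert abs(delta.mean()) < 4 * 0.3 / np.sqrt(n)  # CLT bound
        assert abs(delta.std() - 0.3) < 0.02 * 0.3  # chi-square variance bound

    def test_not_strict_onehot_after_noise(self, small_batch):
        out = sa.noise(small_batch, 0.1, rng())
        assert not out.is_strict_onehot()


class TestAugmentBatch:
    def test_null_config_is_identity(self, small_batch):
        out = augment_batch(small_batch, AugmentationConfig.null(), rng())
        assert np.array_equal(out.data, small_batch.data)

    def test_translocation_only_preserves_column_multiset(self, small_batch):
        cfg = AugmentationConfig(enabled=("translocation",), max_augs=1, shift_max=10)
        out = augment_batch(small_batch, cfg, rng(1))
        for a, b in zip(decode(small_batch), decode(out)):
            assert sorted(a) == sorted(b)  # multiset-equality oracle
            assert b in a + a  # a rotation of the input

    def test_batch_mode_shares_one_shift(self):
        b = random_batch(16, 40, seed=11)
        cfg = AugmentationConfig(
            enabled=("translocation",), max_augs=1, shift_max=10, batch_mode=True
        )
        out = augment_batch(b, cfg, rng(2))
        # find the one shift of sequence 0; all others must share it
        shift = None
        for s in range(-10, 11):
            if np.array_equal(out.data[0], np.roll(b.data[0], s, axis=0)):
                shift = s
                break
        assert shift is not None
        for i in range(len(b)):
            assert np.array_equal(out.data[i], np.roll(b.data[i], shift, axis=0))

    def test_insertion_enabled_forces_constant_length(self):
        b = random_batch(6, 30, seed=12)
        cfg = AugmentationConfig(
            enabled=("insertion", "mutation"), max_augs=1, insert_max=8, mutate_frac=0.1
        )
        for seed in range(6):  # whichever type is drawn, length is L + insert_max
            out = augment_batch(b, cfg, rng(seed))
            assert out.length == 38

    def test_no_insertion_enabled_keeps_length(self):
        b = random_batch(4, 30, seed=13)
        cfg = AugmentationConfig(enabled=("mutation", "inversion"), max_augs=2)
        out = augment_batch(b, cfg, rng(3))
        assert out.length == 30

    def test_determinism_same_seed_same_output(self, small_batch):
        cfg = AugmentationConfig()
        a = augment_batch(small_batch, cfg, rng(42))
        b = augment_batch(small_batch, cfg, rng(42))
        assert np.array_equal(a.data, b.data)

    def test_strict_onehot_preserved_without_noise(self, small_batch):
        cfg = AugmentationConfig(
            enabled=("transversion", "insertion", "translocation", "deletion",
                     "inversion", "mutation"),
            max_augs=3, delete_max=10, insert_max=10,
        )
        out = augment_batch(small_batch, cfg, rng(5))
        assert out.is_strict_onehot()

    def test_max_augs_exceeding_enabled_rejected(self):
        with pytest.raises(ValueError, match="max_augs"):
            AugmentationConfig(enabled=("mutation",), max_augs=2)

    def test_pad_to_length_contract(self, small_batch):
        out = pad_to_length(small_batch, 57, rng(6))
        left = (57 - 50) // 2
        assert out.length == 57
        assert np.array_equal(out.data[:, left : left + 50], small_batch.data)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"insert_min": 5, "insert_max": 2},
            {"rc_prob": 1.5},
            {"mutate_frac": -0.1},
            {"noise_std": -1.0},
            {"enabled": ("warp",)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AugmentationConfig(**kwargs)

    def test_yaml_round_trip(self):
        import yaml

        cfg = AugmentationConfig(shift_max=7, enabled=("mutation", "noise"), max_augs=1)
        back = AugmentationConfig.from_dict(yaml.safe_load(yaml.safe_dump(cfg.to_dict())))
        assert back == cfg
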