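"""Window/sequence encoders: worked examples, oracles, and invariants."""

import itertools

import numpy as np
import pytest

from puppred.encoders import (
    AAIndexTable,
    CksaapConfig,
    FeatureMatrix,
    PseAACConfig,
    PseAACPropertyTable,
    cksaap_feature_names,
    encode_aai,
    encode_cksaap,
    encode_onehot,
    encode_pseaac,
    encode_tpc,
    encode_windows,
    fuse_features,
    tpc_feature_names,
)
from puppred.windows import ALPHABET21, CANONICAL_AA

from conftest import random_peptides


# --- independent counting oracles -----------------------------------------

def naive_tpc(peptide):
    """Brute-force tripeptide counting, independent of the encoder."""
    tri = ["".join(t) for t in itertools.product(ALPHABET21, repeat=3)]
    counts = {t: 0 for t in tri}
    for i in range(len(peptide) - 2):
        counts[peptide[i : i + 3]] += 1
    total = sum(counts.values())
    return np.array([counts[t] / total for t in tri])

def naive_cksaap(peptide, k_max):
    """Brute-force k-spaced pair counting with F_N = L - k - 1."""
    pairs = ["".join(p) for p in itertools.product(ALPHABET21, repeat=2)]
    out = []
    L = len(peptide)
    for k in range(k_max + 1):
        counts = {p: 0 for p in pairs}
        for i in range(L - k - 1):
            counts[peptide[i] + peptide[i + k + 1]] += 1
        out.extend(counts[p] / (L - k - 1) for p in pairs)
    return np.array(out)


class TestTpc:
    def test_single_tripeptide(self):
        v = encode_tpc("AAA")
        assert v[tpc_feature_names().index("AAA")] == 1.0
        assert v.sum() == pytest.approx(1.0)
        assert np.count_nonzero(v) == 1

    def test_two_tripeptides(self):
        v = encode_tpc("AAAC")
        names = tpc_feature_names()
        assert v[names.index("AAA")] == pytest.approx(0.5)
        assert v[names.index("AAC")] == pytest.approx(0.5)

    def test_dimension_is_21_cubed(self):
        assert encode_tpc("X" * 28 + "K" + "X" * 28).shape == (9261,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            encode_tpc("AK")

    def test_matches_naive_counting_oracle(self, rng):
        for pep in random_peptides(rng, 100):
            np.testing.assert_array_equal(encode_tpc(pep), naive_tpc(pep))


class TestCksaap:
    def test_zero_spaced_pairs_akak(self):
        v = encode_cksaap("AKAK", CksaapConfig(k_max=0))
        names = cksaap_feature_names(CksaapConfig(k_max=0))
        assert v[names.index("k0_AK")] == pytest.approx(2 / 3)
        assert v[names.index("k0_KA")] == pytest.approx(1 / 3)
        assert np.count_nonzero(v) == 2

    def test_pair_space_is_441_per_k(self):
        cfg = CksaapConfig(k_max=3)
        assert encode_cksaap("A" * 20, cfg).shape == (441 * 4,)

    def test_default_window_dimension(self):
        assert encode_cksaap("X" * 28 + "K" + "X" * 28).shape == (2646,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            encode_cksaap("AKAKAK", CksaapConfig(k_max=5))

    def test_matches_naive_counting_oracle(self, rng):
        cfg = CksaapConfig(k_max=5)
        for pep in random_peptides(rng, 100):
            np.testing.assert_array_equal(encode_cksaap(pep, cfg), naive_cksaap(pep, 5))

    def test_each_k_block_sums_to_one(self, rng):
        for pep in random_peptides(rng, 20):
            v = encode_cksaap(pep).reshape(6, 441)
            np.testing.assert_allclose(v.sum(axis=1), 1.0, atol=1e-9)


class TestOneHot:
    def test_alanine_is_first_bit(self):
        v = encode_onehot("A" + "K" + "A", delta=1).reshape(3, 20)
        assert v[0, 0] == 1 and v[0, 1:].sum() == 0

    def test_x_is_all_zero_block(self):
        v = encode_onehot("XKX", delta=1).reshape(3, 20)
        assert v[0].sum() == 0 and v[2].sum() == 0

    def test_default_window_dimension(self):
        assert encode_onehot("X" * 28 + "K" + "X" * 28, 28).shape == (1140,)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            encode_onehot("AKA", delta=2)

    def test_row_sum_counts_non_x_residues(self, rng):
        for pep in random_peptides(rng, 30, lengths=(11, 11)):
            v = encode_onehot(pep, delta=5)
            assert v.sum() == sum(1 for c in pep if c != "X")

    def test_residue_order_a_first_y_last(self):
        v = encode_onehot("YKA", delta=1).reshape(3, 20)
        assert v[0, 19] == 1 and v[2, 0] == 1


class TestAai:
    def test_default_window_dimension(self):
        assert encode_aai("X" * 28 + "K" + "X" * 28).shape == (855,)

    def test_all_x_window_is_zero_with_zeros_policy(self):
        assert not encode_aai("XXX").any()

    def test_single_residue_is_table_column(self):
        table = AAIndexTable.default()
        np.testing.assert_array_equal(encode_aai("A", table), table.values[:, 0])

    def test_table_shape_enforced(self):
        with pytest.raises(ValueError):
            AAIndexTable(index_ids=["a"], values=np.zeros((2, 20)))


class TestPseaac:
    def test_default_dimension_and_normalization(self):
        v = encode_pseaac("MKVLAKDEFGHIKLMNPQRSTVWYACDE")
        assert v.shape == (25,)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_homopolymer_nulls_correlation_factors(self):
        v = encode_pseaac("A" * 30)
        assert v[0] == pytest.approx(1.0)
        assert np.count_nonzero(v) == 1

    def test_omega_zero_reduces_to_plain_composition(self):
        seq = "MKVLAKDEFGHIKLMNPQRSTVWYACDE"
        v = encode_pseaac(seq, cfg=PseAACConfig(omega=0.0))
        comp = np.array([seq.count(a) / len(seq) for a in CANONICAL_AA])
        np.testing.assert_allclose(v[:20], comp, atol=1e-12)
        assert not v[20:].any()

    def test_sequence_not_longer_than_lambda_rejected(self):
        with pytest.raises(ValueError):
            encode_pseaac("MKVLA", cfg=PseAACConfig(lam=5))

    def test_x_is_stripped_before_encoding(self):
        assert np.array_equal(
            encode_pseaac("MXKVXLAKDEFGHIKLM"), encode_pseaac("MKVLAKDEFGHIKLM")
        )

    def test_property_table_standardization(self):
        t = PseAACPropertyTable.default()
        np.testing.assert_allclose(t.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(t.values.std(axis=1), 1.0, atol=1e-9)


def test_encoders_are_deterministic(rng):
    pep = random_peptides(rng, 1, lengths=(57, 57))[0]
    pep = pep[:28] + "K" + pep[29:]
    for fn in (
        lambda: encode_tpc(pep),
        lambda: encode_onehot(pep, 28),
        lambda: encode_aai(pep),
        lambda: encode_cksaap(pep),
        lambda: encode_pseaac(pep.replace("X", "") + "AAAAA"),
    ):
        np.testing.assert_array_equal(fn(), fn())


class TestFeatureMatrix:
    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            FeatureMatrix(["a"], np.array([[np.nan]]), ["s1"])

    def test_rejects_duplicate_names(self):
        with pytest.raises(ValueError):
            FeatureMatrix(["a", "a"], np.zeros((1, 2)), ["s1"])

    def test_tsv_round_trip(self, tmp_path):
        fm = FeatureMatrix(["f1", "f2"], np.array([[0.5, 1.25], [2.0, -3.5]]), ["s1", "s2"])
        fm.to_tsv(tmp_path / "m.tsv")
        back = FeatureMatrix.from_tsv(tmp_path / "m.tsv")
        assert back.feature_names == fm.feature_names
        assert back.sample_ids == fm.sample_ids
        np.testing.assert_array_equal(back.values, fm.values)

    def test_npz_round_trip(self, tmp_path):
        fm = FeatureMatrix(["f1"], np.array([[0.125], [7.0]]), ["a", "b"])
        fm.to_npz(tmp_path / "m.npz")
        back = FeatureMatrix.from_npz(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.values, fm.values)


class TestFuse:
    def test_goknn_plus_embedding_is_906(self):
        a = FeatureMatrix([f"g{i}" for i in range(10)], np.zeros((3, 10)), ["a", "b", "c"])
        b = FeatureMatrix([f"e{i}" for i in range(896)], np.zeros((3, 896)), ["a", "b", "c"])
        fused = fuse_features([a, b], prefixes=["goknn", "emb"])
        assert fused.n_features == 906

    def test_single_part_unchanged(self):
        a = FeatureMatrix(["x"], np.ones((2, 1)), ["a", "b"])
        assert fuse_features([a]) is a

    def test_permuted_sample_ids_rejected(self):
        a = FeatureMatrix(["x"], np.ones((2, 1)), ["a", "b"])
        b = FeatureMatrix(["y"], np.ones((2, 1)), ["b", "a"])
        with pytest.raises(ValueError):
            fuse_features([a, b], prefixes=["p", "q"])


def test_encode_windows_registry_fuses_named_subset():
    peps = ["A" * 5 + "K" + "A" * 5, "X" * 5 + "K" + "C" * 5]
    fm = encode_windows(peps, ["w1", "w2"], delta=5, encoder_names=["onehot", "pseaac"])
    assert fm.n_features == 20 * 11 + 25
    assert fm.feature_names[0].startswith("onehot:")
    with pytest.raises(KeyError):
        encode_windows(peps, ["w1", "w2"], 5, ["nope"])
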