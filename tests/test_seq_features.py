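"""Sequence descriptors vs a pure-counting oracle; k-mer and Bi-GRU encoders."""

import warnings
from collections import Counter

import numpy as np
import pytest

from dgcgrn.seq_features import (BiGRUEncoder, KmerEncoding, atgc_ratio,
                                 cksnap0, gc_content, kmerize, nac,
                                 physchem_vector, z_curve)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


# -- independent counting oracle (Counter-based, no shared code paths) ------

def oracle_vector(seq: str) -> np.ndarray:
    c = Counter(b for b in seq if b in "ACGT")
    n = sum(c.values())
    x = (c["A"] + c["G"]) - (c["C"] + c["T"])
    y = (c["A"] + c["C"]) - (c["T"] + c["G"])
    z = (c["A"] + c["T"]) - (c["C"] + c["G"])
    gc = (c["G"] + c["C"]) / n
    denom = (c["G"] + c["C"]) or 1
    atgc = (c["A"] + c["T"]) / denom
    nac_v = [c[b] / n for b in "ACGT"]
    pairs = Counter(seq[i:i + 2] for i in range(len(seq) - 1)
                    if set(seq[i:i + 2]) <= set("ACGT"))
    total = sum(pairs.values())
    ck = [pairs[a + b] / total for a in "ACGT" for b in "ACGT"]
    return np.concatenate([[x / n, y / n, z / n], [gc], [atgc], nac_v, ck])


class TestKmerize:
    def test_single_window(self):
        assert kmerize("ACGTA", 5) == ["ACGTA"]

    def test_stride_one_overlap(self):
        assert kmerize("ACGTAC", 5) == ["ACGTA", "CGTAC"]

    def test_too_short_gives_empty(self):
        assert kmerize("ACG", 5) == []

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kmerize("ACGT", 0)


class TestDescriptors:
    @pytest.mark.parametrize("seq,expected", [
        ("A", (1.0, 1.0, 1.0)),
        ("G", (1.0, -1.0, -1.0)),
        ("ACGT", (0.0, 0.0, 0.0)),
    ])
    def test_z_curve_hand_values(self, seq, expected):
        np.testing.assert_allclose(z_curve(seq), expected)

    def test_z_curve_is_cumulative_in_increments_of_one(self):
        # recompute per-position: each non-N base moves each raw coordinate
        # by exactly +/-1
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 60)
        prev = np.zeros(3)
        for i in range(1, len(seq) + 1):
            raw = z_curve(seq[:i]) * i
            step = raw - prev
            np.testing.assert_allclose(np.abs(step), np.ones(3), atol=1e-9)
            prev = raw

    def test_z_curve_coordinate_identity(self):
        # A+C+G+T = n implies X+Y+Z = 4A - n (scaled by 1/n here)
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(5, 100)))
            n = len(seq)
            lhs = z_curve(seq).sum()
            rhs = (4 * seq.count("A") - n) / n
            assert lhs == pytest.approx(rhs, abs=1e-12)

    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5), ("GGCC", 1.0), ("ATATAGC", 2 / 7)])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_gc_reverse_complement_invariant(self):
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(2)
        for _ in range(30):
            s = random_seq(rng, int(rng.integers(2, 80)))
            rc = s.translate(comp)[::-1]
            assert gc_content(s) == pytest.approx(gc_content(rc))

    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 1.0), ("GC", 0.0), ("AATTG", 4.0), ("AATT", 4.0)])
    def test_atgc_ratio_with_pseudocount(self, seq, expected):
        assert atgc_ratio(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("seq,expected", [
        ("AAAA", (1, 0, 0, 0)),
        ("ACGT", (0.25, 0.25, 0.25, 0.25)),
        ("AACG", (0.5, 0.25, 0.25, 0)),
    ])
    def test_nac(self, seq, expected):
        np.testing.assert_allclose(nac(seq), expected)

    def test_cksnap_examples(self):
        v = cksnap0("AA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0
        assert cksnap0("AAAA")[0] == 1.0
        v = cksnap0("ACGT")
        # pairs AC, CG, GT each 1/3
        assert v[1] == v[6] == v[11] == pytest.approx(1 / 3)

    def test_all_n_sequences_rejected(self):
        for fn in (z_curve, gc_content, nac):
            with pytest.raises(ValueError):
                fn("NNN")
        with pytest.raises(ValueError):
            cksnap0("A")  # no adjacent pair

    def test_vector_layout(self):
        v = physchem_vector("ACGT")
        assert v.shape == (25,)
        np.testing.assert_allclose(v[:3], 0.0)   # balanced z-curve
        assert v[3] == 0.5                        # gc
        np.testing.assert_allclose(v[5:9], 0.25)  # uniform nac

    def test_matches_counting_oracle_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            seq = random_seq(rng, int(rng.integers(2, 120)))
            np.testing.assert_array_equal(physchem_vector(seq),
                                          oracle_vector(seq))

    def test_composition_sums_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            seq = random_seq(rng, int(rng.integers(2, 60)))
            assert abs(nac(seq).sum() - 1.0) < 1e-12
            assert abs(cksnap0(seq).sum() - 1.0) < 1e-12

    def test_n_bases_excluded_from_counts(self):
        assert gc_content("GCNN") == 1.0
        np.testing.assert_allclose(nac("ANCNG"), (1 / 3, 1 / 3, 1 / 3, 0.0))


class TestKmerEncoding:
    def test_token_ids_within_vocabulary(self):
        enc = KmerEncoding.build(["g1"], {"g1": "ACGTACGT"}, k=3)
        valid = enc.tokens[0, :enc.lengths[0]]
        assert np.all(valid < 4 ** 3)

    def test_n_containing_kmer_maps_to_unknown(self):
        enc = KmerEncoding.build(["g1"], {"g1": "ACNGT"}, k=3)
        assert enc.unknown_id in enc.tokens[0, :enc.lengths[0]]

    def test_short_sequence_yields_empty_tokens(self):
        enc = KmerEncoding.build(["g1", "g2"], {"g1": "AC", "g2": "ACGTACGT"},
                                 k=5)
        assert enc.lengths[0] == 0 and enc.lengths[1] == 4

    def test_padding_and_truncation(self):
        enc = KmerEncoding.build(["a", "b"], {"a": "ACGTACGTAC", "b": "ACGTA"},
                                 k=5, max_len=3)
        assert enc.tokens.shape == (2, 3)
        assert enc.lengths.tolist() == [3, 1]
        assert enc.tokens[1, 1] == enc.pad_id


class TestBiGRU:
    def _enc(self, k=2, seed=0, out_dim=6):
        return BiGRUEncoder(4 ** k + 2, emb_dim=4, hidden=5, out_dim=out_dim,
                            seed=seed)

    def test_output_width_default_60(self):
        enc = KmerEncoding.build(["g1"], {"g1": "ACGTACGTA"}, k=5)
        model = BiGRUEncoder(enc.vocab_size, seed=0)
        assert model.encode(enc).data.shape == (1, 60)

    def test_deterministic_given_seed(self):
        enc = KmerEncoding.build(["a", "b"], {"a": "ACGTAC", "b": "GGTTAA"}, k=2)
        out1 = self._enc(seed=3).encode(enc).data
        out2 = self._enc(seed=3).encode(enc).data
        np.testing.assert_array_equal(out1, out2)

    def test_batch_permutation_equivariance(self):
        seqs = {"a": "ACGTACAA", "b": "GGTTAACC", "c": "TTTTACGT"}
        enc1 = KmerEncoding.build(["a", "b", "c"], seqs, k=2, max_len=7)
        enc2 = KmerEncoding.build(["c", "a", "b"], seqs, k=2, max_len=7)
        model = self._enc(seed=1)
        out1 = model.encode(enc1).data
        out2 = model.encode(enc2).data
        np.testing.assert_allclose(out2, out1[[2, 0, 1]], atol=1e-12)

    def test_empty_sequence_gets_zero_vector_with_warning(self):
        enc = KmerEncoding.build(["a", "b"], {"a": "AC", "b": "ACGTACGT"}, k=5)
        model = BiGRUEncoder(enc.vocab_size, seed=0, out_dim=6)
        with pytest.warns(UserWarning, match="a"):
            out = model.encode(enc).data
        assert not out[0].any() and out[1].any()

    def test_gradients_flow_to_all_parameters(self):
        enc = KmerEncoding.build(["a", "b"], {"a": "ACGTA", "b": "GTACG"}, k=2)
        model = self._enc(seed=2)
        (model.encode(enc) ** 2).sum().backward()
        for p in model.params():
            assert p.grad is not None
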