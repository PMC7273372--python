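"""AAC/CKSAAP encoders against independent brute-force oracles."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enzid.encoding import (
    ALPHABET,
    HUMAN_ENZYME_K3_PAIRS,
    EncodingSpec,
    FeatureDescriptor,
    FeatureMatrix,
    aac_descriptors,
    cksaap_descriptors,
    encode_aac,
    encode_cksaap,
    encode_dataset,
)
from enzid.sequence_io import LabeledDataset, ProteinSequence


def brute_aac(residues: str) -> np.ndarray:
    """Independent per-character tally oracle."""
    c = Counter(residues)
    return np.array([c[a] / len(residues) for a in ALPHABET])


def brute_cksaap(residues: str, k: int, denom: int) -> np.ndarray:
    """Independent sliding-window pair enumeration oracle."""
    counts: Counter = Counter()
    for p in range(len(residues) - k - 1):
        counts[(residues[p], residues[p + k + 1])] += 1
    return np.array([counts[(a, b)] / denom for a in ALPHABET for b in ALPHABET])


residues = st.text(alphabet=ALPHABET, min_size=7, max_size=500)


class TestDescriptors:
    def test_canonical_names(self):
        assert FeatureDescriptor("AAC", "A").name == "A"
        assert FeatureDescriptor("CKSAAP", "A", "L", 3).name == "A***L"
        assert FeatureDescriptor("CKSAAP", "A", "L", 0).name == "AL"

    @pytest.mark.parametrize("name", ["A", "AL", "A***L", "G*P", "Y*****Y"])
    def test_name_parse_round_trip(self, name):
        assert FeatureDescriptor.from_name(name).name == name

    @pytest.mark.parametrize("bad", ["", "A**?L", "ZZ", "a", "A***"])
    def test_bad_names_rejected(self, bad):
        with pytest.raises(ValueError):
            FeatureDescriptor.from_name(bad)

    def test_aac_descriptors_carry_no_pair_fields(self):
        with pytest.raises(ValueError):
            FeatureDescriptor("AAC", "A", "L", 3)

    def test_block_orders(self):
        assert [d.name for d in aac_descriptors()] == list(ALPHABET)
        names = [d.name for d in cksaap_descriptors(0)]
        assert names[:3] == ["AA", "AC", "AD"]
        assert names[20] == "CA" and names[-1] == "YY"


class TestEncodeAAC:
    def test_single_residue_sequence(self):
        v = encode_aac(ProteinSequence("s", "AAAA"))
        assert v[0] == 1.0 and v[1:].sum() == 0

    def test_uniform_case(self):
        v = encode_aac(ProteinSequence("s", "ACDE"))
        assert np.allclose(v[:4], 0.25) and v[4:].sum() == 0

    @given(r=residues)
    def test_matches_tally_oracle_and_sums_to_one(self, r):
        v = encode_aac(ProteinSequence("s", r))
        assert np.allclose(v, brute_aac(r))
        assert np.isclose(v.sum(), 1.0)


class TestEncodeCKSAAP:
    def test_k0_forced_counts(self):
        v = encode_cksaap(ProteinSequence("s", "AAAA"), 0)
        assert v[0] == pytest.approx(3 / 4)
        assert v.sum() == pytest.approx(3 / 4)

    def test_k1_forced_counts(self):
        v = encode_cksaap(ProteinSequence("s", "AAAA"), 1)
        assert v[0] == pytest.approx(2 / 3)

    def test_k1_two_pairs(self):
        v = encode_cksaap(ProteinSequence("s", "ACACA"), 1)
        assert v[0] == pytest.approx(0.5)  # A*A at (1,3) and (3,5)
        assert v[21] == pytest.approx(0.25)  # C*C
        assert v.sum() == pytest.approx(0.75)

    @given(r=residues, k=st.integers(0, 5))
    def test_matches_window_oracle_both_conventions(self, r, k):
        L = len(r)
        seq = ProteinSequence("s", r)
        paper = encode_cksaap(seq, k, "paper")
        pairs = encode_cksaap(seq, k, "pair-count")
        assert np.allclose(paper, brute_cksaap(r, k, L - k))
        assert np.allclose(pairs, brute_cksaap(r, k, L - k - 1))
        assert np.isclose(pairs.sum(), 1.0)

    @given(r=residues, k=st.integers(0, 5))
    def test_count_conservation(self, r, k):
        """Raw pair counts always total L - k - 1."""
        seq = ProteinSequence("s", r)
        counts = encode_cksaap(seq, k, "paper") * (len(r) - k)
        assert np.isclose(counts.sum(), len(r) - k - 1)

    def test_dpc_is_k0(self):
        """Dipeptide composition = adjacent-pair CKSAAP."""
        r = "ACDEFGHIKLMNPQRSTVWYAAC"
        v = encode_cksaap(ProteinSequence("s", r), 0)
        dpc = Counter(r[i : i + 2] for i in range(len(r) - 1))
        expect = np.array(
            [dpc[a + b] / len(r) for a in ALPHABET for b in ALPHABET]
        )
        assert np.allclose(v, expect)

    def test_too_short_error_names_sequence_and_k(self):
        with pytest.raises(ValueError, match=r"shorty.*5.*k\+2"):
            encode_cksaap(ProteinSequence("shorty", "ACDEF"), 4)

    def test_invalid_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            encode_cksaap(ProteinSequence("s", "ACDEF"), 0, "other")


def _dataset(n=5, L=30, seed=0):
    rng = np.random.default_rng(seed)
    seqs = [
        ProteinSequence(f"s{i}", "".join(rng.choice(list(ALPHABET), L)))
        for i in range(n)
    ]
    return LabeledDataset(seqs, np.array([1, 1, 1, 0, 0][:n]))


class TestEncodeDataset:
    def test_aac_only_shape(self):
        fm = encode_dataset(_dataset(), EncodingSpec(include_aac=True))
        assert fm.values.shape == (5, 20)
        assert fm.column_names == list(ALPHABET)

    def test_full_shape_aac_plus_six_gaps(self):
        spec = EncodingSpec(include_aac=True, k_list=(0, 1, 2, 3, 4, 5))
        fm = encode_dataset(_dataset(), spec)
        assert fm.values.shape == (5, 20 + 6 * 400)

    def test_subset_columns_in_aac_then_list_order(self):
        spec = EncodingSpec(include_aac=True, subset=HUMAN_ENZYME_K3_PAIRS)
        fm = encode_dataset(_dataset(), spec)
        assert fm.values.shape == (5, 40)
        assert fm.column_names == list(ALPHABET) + list(HUMAN_ENZYME_K3_PAIRS)

    def test_subset_values_match_full_encoding(self):
        ds = _dataset()
        sub = encode_dataset(ds, EncodingSpec(subset=HUMAN_ENZYME_K3_PAIRS))
        full = encode_dataset(ds, EncodingSpec(k_list=(3,)))
        picked = full.select_columns(list(HUMAN_ENZYME_K3_PAIRS))
        assert np.allclose(sub.values[:, 20:], picked.values)

    def test_no_features_is_an_error(self):
        with pytest.raises(ValueError, match="no features"):
            EncodingSpec(include_aac=False, k_list=())

    def test_row_permutation_equivariance(self):
        """Permuting sequence order permutes rows identically."""
        ds = _dataset()
        spec = EncodingSpec(include_aac=True, k_list=(2,))
        fm = encode_dataset(ds, spec)
        perm = [3, 1, 4, 0, 2]
        ds2 = LabeledDataset(
            [ds.sequences[i] for i in perm], ds.labels[perm]
        )
        fm2 = encode_dataset(ds2, spec)
        assert np.allclose(fm2.values, fm.values[perm])

    def test_labels_carried_through(self):
        fm = encode_dataset(_dataset(), EncodingSpec(include_aac=True))
        assert list(fm.labels) == [1, 1, 1, 0, 0]

    def test_values_in_unit_interval(self):
        fm = encode_dataset(_dataset(), EncodingSpec(include_aac=True, k_list=(0, 3)))
        assert (fm.values >= 0).all() and (fm.values <= 1).all()

    def test_tsv_round_trip(self, tmp_path):
        spec = EncodingSpec(include_aac=True, k_list=(1,))
        fm = encode_dataset(_dataset(), spec)
        path = tmp_path / "feat.tsv"
        fm.to_tsv(path, decimals=10)
        back = FeatureMatrix.from_tsv(path)
        assert back.column_names == fm.column_names
        assert back.ids == fm.ids
        assert list(back.labels) == list(fm.labels)
        assert np.allclose(back.values, fm.values, atol=1e-9)
        assert back.spec == spec
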