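"""Mutation encoding, record filtering and design-matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_coefficient_count
from promland import codec
from promland.codec import (
    FeatureIndex,
    InvalidAlphabetError,
    RegionMap,
    build_design_matrix,
    count_model_coefficients,
    decode_sequence,
    encode_mutation,
    encode_sequence,
    filter_records,
    hamming_to_wildtype,
    make_records,
)

# the full cyclic dummy-variable table (wild type -> mutant -> code)
ENCODING_TABLE = {
    ("A", "T"): "100", ("A", "C"): "010", ("A", "G"): "001",
    ("T", "A"): "001", ("T", "C"): "100", ("T", "G"): "010",
    ("C", "A"): "010", ("C", "T"): "001", ("C", "G"): "100",
    ("G", "A"): "100", ("G", "T"): "010", ("G", "C"): "001",
}

seq_strategy = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestEncodeMutation:
    @pytest.mark.parametrize("pair,code", sorted(ENCODING_TABLE.items()))
    def test_table(self, pair, code):
        assert encode_mutation(*pair) == code

    @pytest.mark.parametrize("base", "ACGT")
    def test_wildtype_identity(self, base):
        assert encode_mutation(base, base) == "000"

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            encode_mutation("A", "N")


class TestSequenceCodec:
    def test_wildtype_encodes_to_zero(self):
        wt = "ACGTACGT"
        assert not encode_sequence(wt, wt).any()

    def test_known_encodings(self):
        assert encode_sequence("TG", "AG").tolist() == [1, 0, 0, 0, 0, 0]
        assert encode_sequence("TC", "AG").tolist() == [1, 0, 0, 0, 0, 1]

    def test_decode_single_indicator(self):
        # "100" on a C-site means mutation to G (cyclic order A,T,C,G)
        enc = np.array([1, 0, 0])
        assert decode_sequence(enc, "C") == "G"

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            encode_sequence("ACG", "AC")

    def test_multiple_indicators_rejected(self):
        with pytest.raises(ValueError):
            decode_sequence(np.array([1, 1, 0]), "A")

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_bijection(self, data):
        wt = data.draw(seq_strategy)
        seq = data.draw(
            st.text(alphabet="ACGT", min_size=len(wt), max_size=len(wt))
        )
        enc = encode_sequence(seq, wt)
        assert decode_sequence(enc, wt) == seq
        per_site = enc.reshape(-1, 3).sum(axis=1)
        assert set(per_site.tolist()) <= {0, 1}


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d",
        [("ACGT", "ACGT", 0), ("ACGT", "TCGT", 1), ("ACG", "TGC", 3)],
    )
    def test_values(self, a, b, d):
        assert hamming_to_wildtype(a, b) == d

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming_to_wildtype("ACG", "AC")


class TestFilterRecords:
    WT = "AAAA"

    def test_same_bin_duplicates_collapsed(self):
        rec = make_records(["ACAA", "ACAA", "ACAA"], [3, 3, 5])
        out, report = filter_records(rec, self.WT, max_mutations=4)
        # the two same-bin rows merge (count 2); the different-bin row survives
        assert len(out) == 2
        assert report["n_removed_duplicates"] == 1
        assert out.loc[out["bin"] == 3, "count"].item() == 2

    def test_mutation_threshold(self):
        rec = make_records(["TTTT", "ATAA"], [1, 2])
        out, report = filter_records(rec, self.WT, max_mutations=3)
        assert out["sequence"].tolist() == ["ATAA"]
        assert report["n_removed_mutations"] == 1

    def test_empty_input(self):
        out, report = filter_records(make_records([], []), self.WT)
        assert len(out) == 0 and report["n_output"] == 0

    def test_duplicates_across_bins_kept(self):
        rec = make_records(["ACAA"] * 3, [1, 2, 3])
        out, _ = filter_records(rec, self.WT)
        assert len(out) == 3


class TestCoefficientCounts:
    def test_quadratic_model_75(self):
        assert count_model_coefficients(75, 2) == 25_201

    def test_minimal(self):
        assert count_model_coefficients(1, 1) == 4

    @pytest.mark.parametrize("L,order", [(L, o) for o in (1, 2, 3) for L in range(o, 11)])
    def test_matches_brute_force(self, L, order):
        assert count_model_coefficients(L, order) == brute_force_coefficient_count(L, order)

    def test_too_short(self):
        with pytest.raises(ValueError):
            count_model_coefficients(2, 3)


class TestDesignMatrix:
    def test_column_counts(self):
        for L, order in [(5, 1), (5, 2), (4, 3), (3, 2)]:
            wt = "ACGT" * 2
            X, idx = build_design_matrix(["A" * L], wt[:L], order=order)
            assert X.shape[1] == len(idx) == count_model_coefficients(L, order) - 1

    def test_order2_l3_is_36_columns(self):
        X, _ = build_design_matrix(["AAA"], "AAA", order=2)
        assert X.shape[1] == 9 + 27

    def test_interactions_are_products(self):
        rng = np.random.default_rng(0)
        wt = "ACGTACG"
        seqs = ["".join(rng.choice(list("ACGT"), len(wt))) for _ in range(40)]
        X, idx = build_design_matrix(seqs, wt, order=3)
        D = X.toarray()
        add_pos = {(lab[1], lab[2]): i for i, lab in enumerate(idx.labels) if lab[0] == "b"}
        for col, lab in enumerate(idx.labels):
            if lab[0] == "J":
                _, i, mi, j, mj = lab
                expect = D[:, add_pos[(i, mi)]] * D[:, add_pos[(j, mj)]]
            elif lab[0] == "T":
                _, i, mi, j, mj, k, mk = lab
                expect = (
                    D[:, add_pos[(i, mi)]]
                    * D[:, add_pos[(j, mj)]]
                    * D[:, add_pos[(k, mk)]]
                )
            else:
                continue
            np.testing.assert_array_equal(D[:, col], expect)

    def test_feature_index_position_roundtrip(self):
        idx = FeatureIndex.build(6, 2)
        for col, lab in enumerate(idx.labels):
            assert idx.position(lab) == col

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix(["ACG", "AC"], "ACG")

    def test_unknown_order(self):
        with pytest.raises(ValueError):
            build_design_matrix(["ACG"], "ACG", order=4)


class TestRegionMap:
    def test_report_coordinate_roundtrip(self):
        rm = RegionMap.default()
        rep = rm.to_report_coords()
        assert rep["CRP1"] == (-75, -65)
        assert rm.blocks["CRP1"] == (0, 10)
        assert rm.blocks["RNAP2"] == (60, 74)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            RegionMap({"X": (70, 80)}, length=75)


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        rec = make_records(["ACGT", "AGGT"], [1, 5], condition="c1")
        p = tmp_path / "r.tsv"
        codec.write_records_tsv(rec, p)
        back = codec.read_records_tsv(p)
        pd.testing.assert_frame_equal(rec, back)

    def test_fasta_bin_parsing(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">s1 bin=3\nACGT\n>s2 bin=7\nAGGT\n")
        rec = codec.read_records_fasta(p)
        assert rec["bin"].tolist() == [3, 7]
        assert rec["sequence"].tolist() == ["ACGT", "AGGT"]
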