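import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirnapred.core_data import SiRNARecord, ValidationError
from sirnapred.features import (
    BASE_DIGIT,
    N_FEATURES,
    ConfigurationError,
    NearestNeighborTable,
    build_feature_vector,
    decode_dinucleotide,
    decode_trinucleotide,
    delta_delta_g,
    delta_g_duplex,
    encode_dinucleotide,
    encode_trinucleotide,
    extract_2_3NT,
    extract_compositions,
    extract_representation,
    feature_matrix,
    feature_names,
    kmer_motifs,
)

guides = st.text(alphabet="ACGU", min_size=21, max_size=21)


class TestWindowCodes:
    @pytest.mark.parametrize(
        "pair, code", [(("A", "A"), 1), (("C", "C"), 16), (("U", "G"), 7)]
    )
    def test_dinucleotide_examples(self, pair, code):
        assert encode_dinucleotide(*pair) == code

    @pytest.mark.parametrize(
        "triple, code",
        [(("A", "A", "A"), 1), (("C", "C", "C"), 64), (("C", "U", "G"), 55)],
    )
    def test_trinucleotide_examples(self, triple, code):
        assert encode_trinucleotide(*triple) == code

    def test_dinucleotide_bijection(self):
        """All 16 ordered pairs map 1:1 onto {1..16} and decode back."""
        codes = {}
        for a, b in itertools.product("AUGC", repeat=2):
            code = encode_dinucleotide(a, b)
            assert (BASE_DIGIT[a] - 1) * 4 + BASE_DIGIT[b] == code
            codes[code] = (a, b)
            assert decode_dinucleotide(code) == (a, b)
        assert sorted(codes) == list(range(1, 17))

    def test_trinucleotide_bijection(self):
        codes = {}
        for a, b, c in itertools.product("AUGC", repeat=3):
            code = encode_trinucleotide(a, b, c)
            codes[code] = (a, b, c)
            assert decode_trinucleotide(code) == (a, b, c)
        assert sorted(codes) == list(range(1, 65))

    def test_invalid_base(self):
        with pytest.raises(ValidationError):
            encode_dinucleotide("A", "N")

    def test_extract_all_A(self):
        feats = extract_2_3NT("A" * 21)
        assert len(feats) == 39
        assert [feats[f"NT2_pos{p}"] for p in range(1, 21)] == [1] * 20
        assert [feats[f"NT3_pos{p}"] for p in range(1, 20)] == [1] * 19

    def test_extract_matches_per_window_brute_force(self):
        guide = ("ACG" * 7)[:21]
        feats = extract_2_3NT(guide)
        for p in range(20):
            assert feats[f"NT2_pos{p + 1}"] == encode_dinucleotide(
                guide[p], guide[p + 1]
            )
        for p in range(19):
            assert feats[f"NT3_pos{p + 1}"] == encode_trinucleotide(
                guide[p], guide[p + 1], guide[p + 2]
            )


class TestThermodynamics:
    def test_table_complete_and_stacking_negative(self, nn_table):
        assert len(nn_table.increments) == 16
        assert all(v < 0 for v in nn_table.increments.values())

    def test_uniform_table_linearity(self, uniform_table):
        assert delta_g_duplex("A" * 21, uniform_table) == pytest.approx(20 * -1.5)

    def test_missing_step_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            NearestNeighborTable(increments={"AA": -0.9}, version="partial")

    def test_hand_walked_sum(self, nn_table):
        guide = "UUACGUACGUACGUACGUACG"
        expected = sum(nn_table[guide[i : i + 2]] for i in range(20))
        assert delta_g_duplex(guide, nn_table) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=30)
    @given(guides)
    def test_window_additivity(self, guide):
        """dG_duplex = 5'-window (4 steps) + middle 12 steps + 3'-window."""
        table = NearestNeighborTable.default()
        total = delta_g_duplex(guide, table)
        five = sum(table[guide[i : i + 2]] for i in range(4))
        middle = sum(table[guide[i : i + 2]] for i in range(4, 16))
        three = sum(table[guide[i : i + 2]] for i in range(16, 20))
        assert total == pytest.approx(five + middle + three)

    def test_ddg_zero_for_identical_ends(self, nn_table):
        assert delta_delta_g("A" * 21, nn_table) == 0.0
        # same 5 terminal nts in the same walk order at both ends
        guide = "ACGUA" + "U" * 11 + "ACGUA"
        assert delta_delta_g(guide, nn_table) == 0.0

    def test_ddg_matches_two_window_walk(self, nn_table):
        guide = "GGCCAUUUUUUUUUUUAUAUA"
        dg5 = sum(nn_table[guide[i : i + 2]] for i in range(4))
        dg3 = sum(nn_table[guide[i : i + 2]] for i in range(16, 20))
        assert delta_delta_g(guide, nn_table) == pytest.approx(dg5 - dg3)
        # GC-rich 5' end is more stable: ddG negative under the 5'-minus-3' sign
        assert delta_delta_g(guide, nn_table) < 0


class TestRepresentation:
    def test_digit_map(self):
        feats = extract_representation("U" + "A" * 19 + "C")
        assert feats["POS1"] == 0.2
        assert feats["POS2"] == 0.1
        assert feats["POS21"] == 0.4
        assert len(feats) == 21

    def test_all_A(self):
        assert list(extract_representation("A" * 21).values()) == [0.1] * 21


class TestCompositions:
    def test_homopolymer(self):
        feats = extract_compositions("A" * 10)
        assert feats["A"] == 1.0
        assert feats["C"] == feats["G"] == feats["U"] == 0.0
        assert feats["AA"] == 1.0 and feats["AAA"] == 1.0

    def test_brute_force_window_counts(self):
        seq = "ACGUACGU"
        feats = extract_compositions(seq)
        for k in (1, 2, 3):
            n_windows = len(seq) - k + 1
            for motif in kmer_motifs(k):
                count = sum(
                    seq[i : i + k] == motif for i in range(n_windows)
                )
                assert feats[motif] == pytest.approx(count / n_windows)

    @settings(derandomize=True, max_examples=30)
    @given(st.text(alphabet="ACGU", min_size=3, max_size=60))
    def test_each_k_block_sums_to_one(self, seq):
        feats = extract_compositions(seq)
        for k in (1, 2, 3):
            block = sum(feats[m] for m in kmer_motifs(k))
            assert block == pytest.approx(1.0, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            extract_compositions("AC")


class TestFeatureVector:
    def test_layout_is_230(self):
        names = feature_names()
        assert len(names) == N_FEATURES == 230
        nt = [n for n in names if n.startswith("NT")]
        thermo = [n for n in names if n in ("dG_duplex", "ddG")]
        pos = [n for n in names if n.startswith("POS")]
        comp = [n for n in names if n.startswith(("sirna_", "mrna_"))]
        assert (len(nt), len(thermo), len(pos), len(comp)) == (39, 2, 21, 168)
        # fixed block order
        assert names[:39] == nt and names[39:41] == thermo and names[41:62] == pos

    def test_vector_values_and_ranges(self, nn_table):
        rec = SiRNARecord(
            "r", "UUACGUACGUACGUACGUACG", 0.5, "ACGUACGUACGUACGUACGUACGUACGU"
        )
        fv = build_feature_vector(rec, nn_table)
        s = fv.as_series()
        assert len(fv) == 230
        assert s[[f"NT2_pos{p}" for p in range(1, 21)]].between(1, 16).all()
        assert s[[f"NT3_pos{p}" for p in range(1, 20)]].between(1, 64).all()
        assert set(s[[f"POS{i}" for i in range(1, 22)]]) <= {0.1, 0.2, 0.3, 0.4}
        comp = s[[n for n in fv.names if n.startswith(("sirna_", "mrna_"))]]
        assert comp.between(0, 1).all()

    def test_deterministic(self, nn_table):
        rec = SiRNARecord("r", "ACGUACGUACGUACGUACGUA", None, "U" * 30)
        a = build_feature_vector(rec, nn_table)
        b = build_feature_vector(rec, nn_table)
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)

    def test_missing_context_errors_unless_guide_only(self, nn_table):
        rec = SiRNARecord("r", "ACGUACGUACGUACGUACGUA")
        with pytest.raises(ValidationError, match="context"):
            build_feature_vector(rec, nn_table)
        fv = build_feature_vector(rec, nn_table, include_mrna=False)
        assert len(fv) == 146

    def test_context_window_clips_around_target_site(self, nn_table):
        from sirnapred.core_data import reverse_complement

        guide = "ACGUACGUACGUACGUACGUA"
        context = "GGGGGGGGGG" + reverse_complement(guide) + "CCCCCCCCCC"
        rec = SiRNARecord("r", guide, None, context)
        fv_full = build_feature_vector(rec, nn_table)
        fv_win = build_feature_vector(rec, nn_table, context_window=0)
        # windowed context is exactly the target site -> G/C flanks vanish
        s = fv_win.as_series()
        assert s["mrna_G"] + s["mrna_C"] < fv_full.as_series()["mrna_G"] + fv_full.as_series()["mrna_C"]

    def test_feature_matrix_shape_and_index(self, toy_dataset, nn_table):
        X = feature_matrix(toy_dataset, nn_table)
        assert X.shape == (4, 230)
        assert list(X.index) == toy_dataset.ids()
        assert list(X.columns) == feature_names()
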