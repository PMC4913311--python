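import numpy as np
import pytest
from Bio.Align import substitution_matrices

from hybridfold.fixtures import random_profile
from hybridfold.profiles import (
    AA_ALPHABET,
    AA_BACKGROUND,
    HybridProfile,
    build_aa_profile,
    build_pb_profile_from_structures,
    build_sa_profile_from_structures,
    concat_hybrid,
    format_profile,
    henikoff_weights,
    parse_profile,
    read_profile,
    sa_classes_to_string,
    sa_string_to_classes,
    write_profile,
)


class TestHenikoffWeights:
    def test_single_sequence(self):
        assert henikoff_weights(["ACDE"]) == pytest.approx([1.0])

    def test_identical_pair_split_evenly(self):
        assert henikoff_weights(["ACDE", "ACDE"]) == pytest.approx([0.5, 0.5])

    def test_hand_evaluated_three_rows(self):
        w = henikoff_weights(["AA", "AA", "AC"])
        assert w == pytest.approx([0.29167, 0.29167, 0.41667], abs=1e-4)

    def test_ragged_raises(self):
        with pytest.raises(ValueError, match="ragged"):
            henikoff_weights(["AC", "ACD"])

    def test_divergent_sequence_gains_weight(self):
        w = henikoff_weights(["ACDEFG", "ACDEFG", "ACDEFG", "PWYKRH"])
        assert w[3] > w[0]


class TestAAProfile:
    def test_single_sequence_one_hot_without_pseudocounts(self):
        prof = build_aa_profile(["ACD"], pseudocount_beta=0.0)
        assert prof.sequence == "ACD"
        for i, c in enumerate("ACD"):
            assert prof.probs[i, AA_ALPHABET.index(c)] == pytest.approx(1.0)
        assert np.allclose(prof.gap, 0.0)

    def test_gap_frequency_counts_weighted_gaps(self):
        rows = ["A", "A", "-", "-"]
        prof = build_aa_profile(
            rows, master_index=0, pseudocount_beta=0.0, weights=np.full(4, 0.25)
        )
        assert prof.gap[0] == pytest.approx(0.5)

    def test_pseudocount_mixing_matches_independent_evaluation(self):
        # Independent evaluation of p'(A) for a column of two A's, beta=10:
        # reconstruct BLOSUM62 conditional probabilities from the published
        # half-bit scores and the background frequencies.
        mat = substitution_matrices.load("BLOSUM62")
        joint = np.zeros((20, 20))
        for i, a in enumerate(AA_ALPHABET):
            for j, b in enumerate(AA_ALPHABET):
                joint[i, j] = AA_BACKGROUND[i] * AA_BACKGROUND[j] * 2.0 ** (mat[a][b] / 2.0)
        joint /= joint.sum()
        cond_given_A = joint[:, 0] / joint[:, 0].sum()
        n_eff = 2.0  # two equal-weight identical sequences
        f_obs = np.zeros(20)
        f_obs[0] = 1.0
        expected = (n_eff * f_obs + 10.0 * cond_given_A) / (n_eff + 10.0)
        expected /= expected.sum()

        prof = build_aa_profile(["A", "A"], pseudocount_beta=10.0)
        assert prof.probs[0] == pytest.approx(expected, abs=1e-12)

    def test_master_gap_columns_dropped(self):
        prof = build_aa_profile(["A-C", "AGC"], master_index=0, pseudocount_beta=0.0)
        assert prof.sequence == "AC"
        assert len(prof) == 2

    def test_row_order_permutation_invariance(self):
        rows = ["ACDEF", "AGDEF", "ACDKF", "PCDEF"]
        a = build_aa_profile(rows, master_index=0)
        b = build_aa_profile([rows[0], rows[3], rows[1], rows[2]], master_index=0)
        assert np.allclose(a.probs, b.probs)
        assert np.allclose(a.gap, b.gap)

    def test_beta_moves_towards_pseudocount_distribution(self):
        small = build_aa_profile(["A", "A"], pseudocount_beta=1.0).probs[0]
        large = build_aa_profile(["A", "A"], pseudocount_beta=100.0).probs[0]
        assert large[0] < small[0]  # observed A probability shrinks toward prior

    def test_rows_sum_to_one(self):
        prof = build_aa_profile(["ACDEFGHIKL", "ACDXFG-IKL", "MCDEFGHIKP"])
        assert np.allclose(prof.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            build_aa_profile([])
        with pytest.raises(ValueError, match="master index"):
            build_aa_profile(["AC"], master_index=5)


class TestCategoricalProfiles:
    def test_single_structure_one_hot(self):
        prof = build_pb_profile_from_structures(["m"], epsilon=0.0)
        assert prof.probs[0, "abcdefghijklmnop".index("m")] == pytest.approx(1.0)

    def test_two_structures_split(self):
        prof = build_pb_profile_from_structures(["m", "d"], epsilon=0.0)
        assert prof.probs[0, "abcdefghijklmnop".index("m")] == pytest.approx(0.5)
        assert prof.probs[0, "abcdefghijklmnop".index("d")] == pytest.approx(0.5)

    def test_all_undefined_column_is_uniform(self):
        prof = build_pb_profile_from_structures(["Z", "Z"], epsilon=0.0)
        assert np.allclose(prof.probs[0], 1.0 / 16)

    def test_alignment_mapping_and_master_columns(self):
        # member 2 has a deletion in the 2-column alignment
        prof = build_pb_profile_from_structures(["md", "m"], rows=["MD", "M-"], epsilon=0.0)
        assert prof.probs.shape == (2, 16)
        assert prof.probs[0, "abcdefghijklmnop".index("m")] == pytest.approx(1.0)
        assert prof.probs[1, "abcdefghijklmnop".index("d")] == pytest.approx(1.0)

    def test_sa_profile_cases(self):
        p1 = build_sa_profile_from_structures([[3]], epsilon=0.0)
        assert p1.probs[0, 2] == pytest.approx(1.0)
        p2 = build_sa_profile_from_structures([[1], [10]], epsilon=0.0)
        assert p2.probs[0, 0] == pytest.approx(0.5)
        assert p2.probs[0, 9] == pytest.approx(0.5)

    def test_smoothing_keeps_rows_normalised(self):
        prof = build_pb_profile_from_structures(["mmdd"], epsilon=0.05)
        assert np.allclose(prof.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            build_pb_profile_from_structures(["md"], rows=["M"])

    def test_sa_string_round_trip(self):
        classes = [1, 5, 10, 9]
        assert sa_string_to_classes(sa_classes_to_string(classes)) == classes


class TestConcatAndSerialisation:
    def test_concat_length_mismatch_names_component(self):
        aa = build_aa_profile(["ACD"])
        pb = build_pb_profile_from_structures(["md"])
        sa = build_sa_profile_from_structures([[1, 2, 3]])
        with pytest.raises(ValueError, match="PB"):
            concat_hybrid(aa, pb, sa)

    def test_round_trip_is_bitwise(self, tmp_path):
        hp = random_profile(17, seed=5)
        path = tmp_path / "p.orp"
        write_profile(hp, path)
        back = read_profile(path)
        assert back.sequence == hp.sequence
        for name in ("aa", "gap", "pb", "sa"):
            assert np.array_equal(getattr(back, name), getattr(hp, name))
        assert format_profile(back) == format_profile(hp)

    def test_wrong_column_count_reports_line(self):
        hp = random_profile(3, seed=1)
        text = format_profile(hp)
        lines = text.splitlines()
        lines[-1] = lines[-1].rsplit("\t", 1)[0]  # drop one column of last row
        with pytest.raises(ValueError, match=r":\d+: expected"):
            parse_profile("\n".join(lines))

    def test_unsupported_version_raises(self):
        text = format_profile(random_profile(3, seed=2)).replace("#ORP 1", "#ORP 99")
        with pytest.raises(ValueError, match="unsupported version"):
            parse_profile(text)

    def test_validate_rejects_bad_rows(self):
        hp = random_profile(4, seed=3)
        hp.aa[0, 0] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            hp.validate()
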