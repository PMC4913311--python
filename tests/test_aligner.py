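import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_force_best_score, brute_force_correlation
from hybridfold.aligner import (
    ScoringParams,
    align,
    alignment_stats,
    column_score_matrix,
    correlation_score,
    gap_penalties,
)
from hybridfold.fixtures import random_profile
from hybridfold.profiles import HybridProfile


def one_hot_profile(seq, gap=0.0, identifier="p"):
    """One-hot AA columns; uniform PB/SA so only the AA component scores."""
    L = len(seq)
    aa = np.zeros((L, 20))
    from hybridfold.profiles import AA_ALPHABET

    for i, c in enumerate(seq):
        aa[i, AA_ALPHABET.index(c)] = 1.0
    return HybridProfile(
        identifier=identifier,
        sequence=seq,
        aa=aa,
        gap=np.full(L, gap),
        pb=np.full((L, 16), 1 / 16),
        sa=np.full((L, 10), 0.1),
    )


def aa_only_params(**kw):
    return ScoringParams(
        w_pb=0.0, w_sa=0.0, aa_background=np.full(20, 1 / 20.0), **kw
    )


class TestColumnScore:
    def test_uniform_columns_score_zero_against_uniform_background(self):
        q = random_profile(1, 1)
        q.aa[:] = 1 / 20.0
        s = column_score_matrix(q, q, aa_only_params())
        assert s[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_one_hot_columns_score_log2_20(self):
        p = one_hot_profile("W")
        s = column_score_matrix(p, p, aa_only_params())
        assert s[0, 0] == pytest.approx(np.log2(20), abs=1e-9)

    def test_orthogonal_one_hot_columns_hit_floor(self):
        s = column_score_matrix(one_hot_profile("W"), one_hot_profile("A"), aa_only_params())
        assert s[0, 0] == pytest.approx(-10.0)

    def test_zero_background_rejected_at_construction(self):
        with pytest.raises(ValueError, match="positive"):
            ScoringParams(aa_background=np.zeros(20))


class TestGapPenalties:
    @pytest.mark.parametrize("g,expected", [(0.0, (3.0, 0.3)), (1.0, (0.0, 0.0)), (0.5, (1.5, 0.15))])
    def test_linear_in_gap_probability(self, g, expected):
        p = one_hot_profile("AC", gap=g)
        op, ext = gap_penalties(p, ScoringParams())
        assert op[0] == pytest.approx(expected[0])
        assert ext[0] == pytest.approx(expected[1])


class TestCorrelationScore:
    @pytest.mark.parametrize("scores,d,expected", [
        ([5.0], 3, 0.0),
        ([1, 2, 3], 0, 0.0),
        ([1, 1, 1, 1, 1], 2, 7.0),
    ])
    def test_examples(self, scores, d, expected):
        assert correlation_score(scores, d) == pytest.approx(expected)

    @pytest.mark.parametrize("s", [-1.5, 0.5, 2.0])
    @pytest.mark.parametrize("L,d", [(4, 1), (8, 4), (20, 4), (12, 7)])
    def test_constant_scores_closed_form(self, s, L, d):
        expected = s**2 * (d * (L - d) + d * (d - 1) / 2)
        assert correlation_score([s] * L, d) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        scores=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=12),
        d=st.integers(0, 6),
    )
    def test_matches_pair_enumeration(self, scores, d):
        assert correlation_score(scores, d) == pytest.approx(brute_force_correlation(scores, d))

    def test_nonnegative_when_scores_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.uniform(0, 3, size=rng.integers(1, 15))
            assert correlation_score(s, 4) >= 0.0


class TestAlign:
    def test_self_alignment_global_is_identity(self):
        q = random_profile(12, seed=7)
        params = ScoringParams(mode="global", w_corr=0.0)
        res = align(q, q, params)
        assert res.columns == [(i, i) for i in range(12)]
        S = column_score_matrix(q, q, params)
        assert res.score_raw == pytest.approx(float(np.trace(S)))
        assert res.identity == 100.0 and res.coverage == 100.0
        assert res.score_total == res.score_raw

    def test_gloloc_finds_embedded_template(self):
        q = one_hot_profile("MKTAYWQRLD", identifier="q")
        t = one_hot_profile("AYWQ", identifier="t")  # copy of query positions 4..7
        res = align(q, t, ScoringParams(mode="gloloc"))
        assert [c[1] for c in res.columns] == [0, 1, 2, 3]
        assert (res.query_start, res.query_end) == (4, 7)
        assert (res.template_start, res.template_end) == (1, 4)
        assert res.identity == 100.0

    @pytest.mark.parametrize("mode", ["gloloc", "local", "global"])
    def test_matches_brute_force_enumeration(self, mode):
        params = ScoringParams(mode=mode)
        for seed in range(60):
            rng = np.random.default_rng(seed)
            nq, nt = rng.integers(1, 6, size=2)
            q = random_profile(int(nq), 3 * seed + 1)
            t = random_profile(int(nt), 3 * seed + 2)
            S = column_score_matrix(q, t, params)
            qo, qe = gap_penalties(q, params)
            to, te = gap_penalties(t, params)
            expected = brute_force_best_score(S, qo, qe, to, te, mode)
            assert align(q, t, params).score_raw == pytest.approx(expected, abs=1e-9)

    def test_mode_dominance(self):
        for seed in range(25):
            q = random_profile(8, seed + 100)
            t = random_profile(6, seed + 200)
            scores = {
                m: align(q, t, ScoringParams(mode=m)).score_raw
                for m in ("local", "gloloc", "global")
            }
            assert scores["local"] >= scores["gloloc"] - 1e-9
            assert scores["gloloc"] >= scores["global"] - 1e-9

    @pytest.mark.parametrize("mode", ["local", "global"])
    def test_raw_score_symmetry(self, mode):
        for seed in range(15):
            q = random_profile(7, seed + 300)
            t = random_profile(5, seed + 400)
            a = align(q, t, ScoringParams(mode=mode)).score_raw
            b = align(t, q, ScoringParams(mode=mode)).score_raw
            assert a == pytest.approx(b, abs=1e-9)

    def test_unrelated_flank_never_hurts_gloloc(self):
        params = ScoringParams(mode="gloloc")
        for seed in range(10):
            q = random_profile(8, seed + 500)
            t = random_profile(6, seed + 600)
            flank = random_profile(3, seed + 700)
            extended = HybridProfile(
                identifier="ext",
                sequence=flank.sequence + q.sequence,
                aa=np.vstack([flank.aa, q.aa]),
                gap=np.concatenate([flank.gap, q.gap]),
                pb=np.vstack([flank.pb, q.pb]),
                sa=np.vstack([flank.sa, q.sa]),
            )
            assert (
                align(extended, t, params).score_raw
                >= align(q, t, params).score_raw - 1e-9
            )

    def test_traceback_path_reproduces_raw_score(self):
        for seed, mode in [(1, "gloloc"), (2, "local"), (3, "global")]:
            q = random_profile(9, seed)
            t = random_profile(7, seed + 50)
            params = ScoringParams(mode=mode)
            res = align(q, t, params)
            S = column_score_matrix(q, t, params)
            qo, qe = gap_penalties(q, params)
            to, te = gap_penalties(t, params)
            total, prev = 0.0, None
            for qi, tj in res.columns:
                if qi is not None and tj is not None:
                    total += S[qi, tj]
                    prev = "M"
                elif qi is not None:
                    total -= qe[qi] if prev == "X" else qo[qi]
                    prev = "X"
                else:
                    total -= te[tj] if prev == "Y" else to[tj]
                    prev = "Y"
            assert total == pytest.approx(res.score_raw, abs=1e-9)

    def test_gloloc_consumes_whole_template(self):
        for seed in range(10):
            q = random_profile(10, seed + 800)
            t = random_profile(5, seed + 900)
            res = align(q, t, ScoringParams(mode="gloloc"))
            consumed = [tj for _, tj in res.columns if tj is not None]
            assert consumed == list(range(5))

    def test_empty_profile_raises(self):
        q = random_profile(3, 1)
        empty = HybridProfile(
            identifier="e", sequence="", aa=np.zeros((0, 20)), gap=np.zeros(0),
            pb=np.zeros((0, 16)), sa=np.zeros((0, 10)),
        )
        with pytest.raises(ValueError, match="empty"):
            align(q, empty, ScoringParams())


class TestAlignmentStats:
    def test_partial_alignment_arithmetic(self):
        # 10-residue query, 5 aligned columns, 2 identities
        qseq = "AAAAACCCCC"
        tseq = "AAGGG"
        columns = [(i, i) for i in range(5)]
        identity, coverage, bounds = alignment_stats(columns, qseq, tseq)
        assert identity == pytest.approx(40.0)
        assert coverage == pytest.approx(50.0)
        assert bounds == (1, 5, 1, 5)

    def test_empty_alignment_reports_zeros(self):
        identity, coverage, bounds = alignment_stats([], "ACDE", "ACDE")
        assert identity == 0.0 and coverage == 0.0 and bounds == (0, 0, 0, 0)

    def test_gap_columns_excluded_from_identity(self):
        columns = [(0, 0), (1, None), (2, 1)]
        identity, coverage, _ = alignment_stats(columns, "AAA", "AA")
        assert identity == pytest.approx(100.0)
        assert coverage == pytest.approx(200.0 / 3)
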