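import pytest

from rnaepm.dp import fill_dp
from rnaepm.ensemble import compute_ensemble
from rnaepm.epm import Epm, epm_score, is_significant, validate_epm
from rnaepm.params import Params, TracebackControls
from rnaepm.sequence import RnaSequence
from rnaepm.synthetic import maximal_relaxed, maximal_strict
from rnaepm.traceback import (
    filter_relaxed_maximal,
    is_maximal_strict,
    trace_heuristic,
    trace_suboptimal,
)

from test_dp import refilter

WIDE = TracebackControls(max_score_diff=0.0, max_epms=10_000, min_epm_score=-1e9)


def params_for(mode, theta, **kw):
    if mode == "strict":
        return Params(theta1=theta, theta2=theta, theta3=theta, **kw)
    return Params.relaxed(theta1=theta, theta2=theta, theta3=theta, **kw)


class TestSuboptimalStrict:
    def test_identical_hairpins_trace_the_full_identity_epm(self, model):
        """Self-comparison of a perfect hairpin at the optimal score.

        Expected set frozen from exhaustive EPM enumeration plus the
        pairwise inclusion-order maximality filter (24020 valid EPMs,
        1540 maximal, a single one at the optimal score): the full
        identity matching with the complete 4-pair stem.
        """
        seq = RnaSequence("x", "GGGGAAAACCCC")
        probs = compute_ensemble(seq, model)
        params = Params(theta1=0.0, theta2=0.0, theta3=0.0, traceback=WIDE)
        dp = fill_dp(probs, probs, params)
        got = trace_suboptimal(dp)
        want = Epm(
            M=frozenset((i, i) for i in range(1, 13)),
            S=frozenset(
                {(1, 12, 1, 12), (2, 11, 2, 11), (3, 10, 3, 10), (4, 9, 4, 9)}
            ),
        )
        assert [e.key() for e in got] == [want.key()]
        assert got[0].score == pytest.approx(dp.max_f)

    def test_no_common_characters_traces_nothing(self, model):
        A = RnaSequence("A", "GGGG")
        B = RnaSequence("B", "CCCC")
        dp = fill_dp(
            compute_ensemble(A, model),
            compute_ensemble(B, model),
            Params(traceback=WIDE),
        )
        assert trace_suboptimal(dp) == []

    def test_end_condition_no_extension_beyond_right_end(self, small_corpus):
        """No traced strict EPM can be grown by the exact next diagonal match."""
        for (A, B, pA, pB, _) in small_corpus[:6]:
            params = params_for("strict", 0.01, traceback=WIDE)
            dp = fill_dp(pA, pB, params)
            for e in trace_suboptimal(dp):
                j, l = e.end()
                if j < len(A) and l < len(B):
                    assert A[j + 1] != B[l + 1]

    @pytest.mark.parametrize("diff", [0.0, 5.0])
    def test_band_matches_oracle(self, small_corpus, diff):
        controls = TracebackControls(
            max_score_diff=diff, max_epms=10_000, min_epm_score=-1e9
        )
        for (A, B, pA, pB, oracle) in small_corpus:
            params = params_for("strict", 0.01, traceback=controls)
            dp = fill_dp(pA, pB, params)
            sig = refilter(oracle, pA, pB, params, strict=True)
            sig_max = maximal_strict(sig, A, B)
            thr = dp.max_f - diff
            want = {e.key() for e in sig_max if e.score >= thr - 1e-9}
            got = trace_suboptimal(dp)
            assert {e.key() for e in got} == want

    def test_every_traced_epm_is_independently_valid(self, small_corpus):
        for (A, B, pA, pB, _) in small_corpus[:6]:
            params = params_for("relaxed", 0.01, traceback=WIDE)
            dp = fill_dp(pA, pB, params)
            for e in trace_suboptimal(dp):
                assert validate_epm(e.M, e.S, A, B, e.mode)
                assert is_significant(e, pA, pB, params)
                assert epm_score(e, pA, pB, params) == pytest.approx(e.score)

    def test_determinism(self, small_corpus):
        A, B, pA, pB, _ = small_corpus[1]
        params = params_for(
            "relaxed",
            0.0,
            traceback=TracebackControls(max_score_diff=4.0, max_epms=100, min_epm_score=-1e9),
        )
        runs = [trace_suboptimal(fill_dp(pA, pB, params)) for _ in range(2)]
        assert runs[0] == runs[1]


class TestSuboptimalRelaxed:
    def test_all_oracle_maximal_epms_are_traced(self, small_corpus):
        controls = TracebackControls(
            max_score_diff=5.0, max_epms=10_000, min_epm_score=-1e9
        )
        for (A, B, pA, pB, oracle) in small_corpus:
            params = params_for("relaxed", 0.01, traceback=controls)
            dp = fill_dp(pA, pB, params)
            sig = refilter(oracle, pA, pB, params, strict=False)
            thr = dp.max_f - 5.0
            want = {
                e.key()
                for e in maximal_relaxed(sig, len(A), len(B))
                if e.score >= thr - 1e-9
            }
            got = {e.key() for e in trace_suboptimal(dp)}
            assert want <= got


class TestHeuristic:
    def test_dominant_epm_is_found_with_optimal_score(self, model):
        seq = RnaSequence("x", "GGGGAAAACCCC")
        probs = compute_ensemble(seq, model)
        params = Params(
            theta1=0.01, theta2=0.01, theta3=0.01,
            traceback=TracebackControls(strategy="heuristic", max_epms=100, min_epm_score=1.0),
        )
        dp = fill_dp(probs, probs, params)
        got = trace_heuristic(dp)
        assert got and got[0].score == pytest.approx(dp.max_f)

    def test_no_matches_yields_empty(self, model):
        A = RnaSequence("A", "GGGG")
        B = RnaSequence("B", "CCCC")
        dp = fill_dp(compute_ensemble(A, model), compute_ensemble(B, model), Params())
        assert trace_heuristic(dp) == []

    def test_one_epm_per_end_with_locally_optimal_score(self, small_corpus):
        from rnaepm.traceback import _real_best_at

        for (A, B, pA, pB, _) in small_corpus[:6]:
            params = params_for(
                "strict",
                0.01,
                traceback=TracebackControls(
                    strategy="heuristic", max_epms=10_000, min_epm_score=0.5
                ),
            )
            dp = fill_dp(pA, pB, params)
            got = trace_heuristic(dp)
            ends = [e.end() for e in got]
            assert len(ends) == len(set(ends))
            for e in got:
                x, y = e.end()
                assert e.score == pytest.approx(_real_best_at(dp, x, y))


class TestMaximality:
    def test_extensible_epm_is_not_maximal(self, two_hairpin_pair, model):
        seqA, seqB, light, _, _ = two_hairpin_pair
        # make the outer pair's ends exact so the extension exists
        seqB2 = RnaSequence("exB2", "G" + seqB.residues[1:15] + "C")
        pA = compute_ensemble(seqA, model)
        pB = compute_ensemble(seqB2, model)
        params = Params(theta1=0.0, theta2=0.0, theta3=0.0)
        dp = fill_dp(pA, pB, params)
        assert not is_maximal_strict(light, dp)

    def test_full_cover_epm_is_maximal(self, model):
        seq = RnaSequence("x", "GAGA")
        probs = compute_ensemble(seq, model)
        params = Params(theta1=0.0, theta2=0.0, theta3=0.0)
        dp = fill_dp(probs, probs, params)
        full = Epm(frozenset((i, i) for i in range(1, 5)), frozenset())
        assert is_maximal_strict(full, dp)

    def test_mode_error_for_relaxed_epm(self, model):
        seq = RnaSequence("x", "GAGA")
        probs = compute_ensemble(seq, model)
        dp = fill_dp(probs, probs, Params(theta1=0.0, theta2=0.0, theta3=0.0))
        with pytest.raises(ValueError):
            is_maximal_strict(Epm(frozenset(), frozenset(), mode="relaxed"), dp)

    def test_agreement_with_pairwise_inclusion_oracle(self, small_corpus):
        from dataclasses import replace

        for (A, B, pA, pB, oracle) in small_corpus[:6]:
            params = params_for("strict", 0.01)
            dp = fill_dp(pA, pB, params)
            sig = refilter(oracle, pA, pB, params, strict=True)
            want = {e.key() for e in maximal_strict(sig, A, B)}
            for e in sig:
                strict_e = replace(e, mode="strict")
                assert is_maximal_strict(strict_e, dp) == (e.key() in want)

    def test_score_inclusion_chain_keeps_only_top(self):
        """A dips-then-rises extension chain retains only the final EPM."""
        base = frozenset({(3, 3)})
        bp = (4, 8, 4, 8)
        a = Epm(base, frozenset(), mode="relaxed", score=5.0)
        d = Epm(base | {(4, 4), (8, 8)}, frozenset({bp}), "relaxed", 3.0)
        e = Epm(d.M | {(9, 9)}, d.S, "relaxed", 4.0)
        f = Epm(e.M | {(10, 10)}, e.S, "relaxed", 6.0)
        kept = filter_relaxed_maximal([a, d, e, f], 12, 12)
        assert kept == [f]

    def test_incomparable_group_unchanged(self):
        e1 = Epm(frozenset({(1, 1)}), frozenset(), "relaxed", 1.0)
        e2 = Epm(frozenset({(5, 2)}), frozenset(), "relaxed", 2.0)
        assert filter_relaxed_maximal([e1, e2], 8, 8) == [e1, e2]
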