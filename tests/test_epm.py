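import numpy as np
import pytest

from rnaepm.ensemble import EnsembleProbs, compute_ensemble
from rnaepm.epm import (
    Epm,
    epm_score,
    includes,
    is_significant,
    parent_map,
    sigma,
    tau,
    validate_epm,
)
from rnaepm.params import EnergyModel, Params, is_neg_inf
from rnaepm.sequence import RnaSequence


def probs_with(residues, bpp=(), stacked=()):
    """Hand-built ensemble container for scoring tests."""
    n = len(residues)
    p = EnsembleProbs(
        n=n,
        residues=residues,
        model=EnergyModel(),
        bpp=np.zeros((n + 1, n + 1)),
        stacked=np.zeros((n + 1, n + 1)),
        unpaired=np.ones(n + 1),
    )
    for (i, j), v in dict(bpp).items():
        p.bpp[i, j] = v
    for (i, j), v in dict(stacked).items():
        p.stacked[i, j] = v
    return p


class TestSigmaTau:
    def test_sigma_is_one_for_identical_bases(self):
        A = RnaSequence("A", "GACU")
        B = RnaSequence("B", "GCAU")
        assert sigma(A, B, 1, 1) == 1.0
        assert is_neg_inf(sigma(A, B, 2, 2))
        with pytest.raises(IndexError):
            sigma(A, B, 0, 1)

    def test_tau_direct_evaluation(self):
        pA = probs_with("GAAAC", bpp={(1, 5): 1.0})
        pB = probs_with("GAAAC", bpp={(1, 5): 1.0})
        params = Params()  # alpha = (1, 5, 5)
        assert tau(1, 5, 1, 5, pA, pB, params) == pytest.approx(12.0)

    def test_tau_relaxed_left_end_mismatch(self):
        pA = probs_with("GAAAC", bpp={(1, 5): 1.0})
        pB = probs_with("CAAAC", bpp={(1, 5): 1.0})
        params = Params.relaxed(str_mm=-10.0)
        # 1*(-10 + 1) + 5*2 = 1
        assert tau(1, 5, 1, 5, pA, pB, params) == pytest.approx(1.0)

    def test_tau_strict_mismatch_forbidden(self):
        pA = probs_with("GAAAC", bpp={(1, 5): 1.0})
        pB = probs_with("AAAAU", bpp={(1, 5): 1.0})
        assert is_neg_inf(tau(1, 5, 1, 5, pA, pB, Params()))

    def test_tau_stacking_term_only_when_requested(self):
        pA = probs_with("GGAACC", bpp={(1, 6): 1.0}, stacked={(1, 6): 0.5})
        pB = probs_with("GGAACC", bpp={(1, 6): 1.0}, stacked={(1, 6): 0.5})
        params = Params()
        plain = tau(1, 6, 1, 6, pA, pB, params)
        stacked = tau(1, 6, 1, 6, pA, pB, params, with_stacking=True)
        assert stacked - plain == pytest.approx(params.alpha3 * 1.0)


class TestEpmScore:
    def test_empty_epm_scores_zero(self):
        pA = probs_with("GAAAC")
        assert epm_score(Epm(frozenset(), frozenset()), pA, pA, Params()) == 0.0

    def test_single_sequence_match(self):
        pA = probs_with("GAAAC")
        e = Epm(frozenset({(1, 1)}), frozenset())
        assert epm_score(e, pA, pA, Params()) == 1.0

    def test_worked_two_hairpin_example(self, two_hairpin_pair):
        seqA, seqB, light, _, _ = two_hairpin_pair
        pA = compute_ensemble(seqA)
        pB = compute_ensemble(seqB)
        params = Params()
        assert light.sequence_matches == frozenset({(9, 13)})
        assert light.structure_matches == frozenset(
            {(2, 2), (3, 3), (10, 14), (11, 15)}
        )
        # the outer pair match carries the stacking term: its directly
        # nested pair match is part of the EPM
        expected = (
            sigma(seqA, seqB, 9, 13)
            + tau(2, 11, 2, 15, pA, pB, params, with_stacking=True)
            + tau(3, 10, 3, 14, pA, pB, params)
        )
        assert epm_score(light, pA, pB, params) == pytest.approx(expected)


class TestValidation:
    def test_worked_example_is_valid_strict(self, two_hairpin_pair):
        seqA, seqB, light, _, _ = two_hairpin_pair
        assert validate_epm(light.M, light.S, seqA, seqB, "strict")

    def test_extension_with_mismatched_pair_is_relaxed_only(self, two_hairpin_pair):
        seqA, seqB, _, extended, _ = two_hairpin_pair
        assert validate_epm(extended.M, extended.S, seqA, seqB, "relaxed")
        report = validate_epm(extended.M, extended.S, seqA, seqB, "strict")
        assert not report and "mismatch" in report.violated

    def test_disconnected_parts_are_invalid(self, two_hairpin_pair):
        seqA, seqB, _, _, disconnected = two_hairpin_pair
        report = validate_epm(
            disconnected.M, disconnected.S, seqA, seqB, "strict"
        )
        assert not report and report.violated == "not connected"

    def test_crossing_matches_rejected(self):
        s = RnaSequence("s", "GGAAACCC")
        report = validate_epm({(1, 2), (2, 1)}, set(), s, s, "strict")
        assert not report

    def test_pair_ends_must_be_matched(self):
        s = RnaSequence("s", "GGAAACCC")
        report = validate_epm({(1, 1)}, {(1, 8, 1, 8)}, s, s, "strict")
        assert not report and "ends" in report.violated

    def test_crossing_structure_rejected(self):
        s = RnaSequence("s", "GGUAAACACC")
        M = {(1, 1), (2, 2), (8, 8), (10, 10)}
        S = {(1, 8, 1, 8), (2, 10, 2, 10)}
        report = validate_epm(M, S, s, s, "strict")
        assert not report and "crossing structure" in report.violated


class TestParentsAndInclusion:
    def test_parent_of_endpoint_is_own_pair(self, two_hairpin_pair):
        seqA, seqB, light, _, _ = two_hairpin_pair
        parents = parent_map(light, len(seqA), len(seqB))
        assert parents[(2, 2)] == (2, 11, 2, 15)
        assert parents[(3, 3)] == (3, 10, 3, 14)
        assert parents[(9, 13)] == (3, 10, 3, 14)
        assert parents[(3, 10, 3, 14)] == (2, 11, 2, 15)
        assert parents[(2, 11, 2, 15)] == (0, 13, 0, 17)

    def test_inclusion_requires_parent_preservation(self, two_hairpin_pair):
        seqA, seqB, light, extended, _ = two_hairpin_pair
        n, m = len(seqA), len(seqB)
        assert includes(light, extended, n, m)
        assert not includes(extended, light, n, m)
        # wrapping a lone match in a new pair re-parents it: incomparable
        lone = Epm(frozenset({(9, 13)}), frozenset())
        assert includes(lone, light, n, m) is False

    def test_significance_rechecks_in_loop_probabilities(self, two_hairpin_pair):
        seqA, seqB, light, _, _ = two_hairpin_pair
        pA = compute_ensemble(seqA)
        pB = compute_ensemble(seqB)
        assert is_significant(light, pA, pB, Params(theta1=0.0, theta2=0.0, theta3=0.0))
        assert not is_significant(
            light, pA, pB, Params(theta1=1.0, theta2=1.0, theta3=1.0)
        )
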