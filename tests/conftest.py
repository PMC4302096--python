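import pytest

from rnaepm.ensemble import compute_ensemble
from rnaepm.epm import Epm
from rnaepm.params import EnergyModel, Params
from rnaepm.sequence import RnaSequence
from rnaepm.synthetic import enumerate_epms, random_sequence


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def uniform_model():
    return EnergyModel(mode="uniform")


def make_two_hairpin_pair():
    """Sequences realizing the worked two-hairpin matching example.

    A (length 12) and B (length 16) admit the strict EPM
    M = {2~2, 3~3, 9~13, 10~14, 11~15}, S = {(2,11~2,15), (3,10~3,14)}
    and its relaxed-only extension by the base-pair match (1,12~1,16)
    whose both ends mismatch.
    """
    seqA = RnaSequence("exA", "GGCAAAAAAGCC")
    seqB = RnaSequence("exB", "AGCAAAAAAAAAAGCU")
    light = Epm(
        M=frozenset({(2, 2), (3, 3), (9, 13), (10, 14), (11, 15)}),
        S=frozenset({(2, 11, 2, 15), (3, 10, 3, 14)}),
        mode="strict",
    )
    extended = Epm(
        M=light.M | {(1, 1), (12, 16)},
        S=light.S | {(1, 12, 1, 16)},
        mode="relaxed",
    )
    disconnected = Epm(
        M=frozenset({(2, 2), (9, 13)}), S=frozenset(), mode="strict"
    )
    return seqA, seqB, light, extended, disconnected


@pytest.fixture(scope="session")
def two_hairpin_pair():
    return make_two_hairpin_pair()


def make_pair_corpus(n_pairs, seed_base, lengths=(7, 12), model=None):
    """Seeded random sequence pairs with ensembles and the full oracle
    EPM set (enumerated once at fully permissive thresholds; callers
    re-filter significance per threshold)."""
    model = model or EnergyModel()
    permissive = Params.relaxed(theta1=0.0, theta2=0.0, theta3=0.0)
    corpus = []
    lo, hi = lengths
    for t in range(n_pairs):
        nA = lo + (t * 7) % (hi - lo + 1)
        nB = lo + (t * 5 + 3) % (hi - lo + 1)
        A = random_sequence(nA, 0.5, seed=seed_base + 2 * t, id=f"A{t}")
        B = random_sequence(nB, 0.5, seed=seed_base + 2 * t + 1, id=f"B{t}")
        pA = compute_ensemble(A, model)
        pB = compute_ensemble(B, model)
        oracle = enumerate_epms(A, B, pA, pB, permissive)
        corpus.append((A, B, pA, pB, oracle))
    return corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A modest corpus for unit-level cross-checks."""
    return make_pair_corpus(12, seed_base=40_000)
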