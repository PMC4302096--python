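import numpy as np
import pytest

from rnaepm.ensemble import (
    CacheError,
    cache_read,
    cache_write,
    compute_ensemble,
    count_structures,
    enumerate_structures,
    probs_by_enumeration,
    psi,
    structure_energy,
)
from rnaepm.params import EnergyModel
from rnaepm.sequence import InputError, RnaSequence
from rnaepm.synthetic import random_sequence


def assert_probs_close(a, b, tol=1e-9):
    assert np.abs(a.bpp - b.bpp).max() < tol
    assert np.abs(a.stacked - b.stacked).max() < tol
    assert np.abs(a.unpaired - b.unpaired).max() < tol
    for da, db in (
        (a.in_loop_unpaired, b.in_loop_unpaired),
        (a.in_loop_pair, b.in_loop_pair),
    ):
        for key in set(da) | set(db):
            ea, eb = da.get(key, {}), db.get(key, {})
            for e in set(ea) | set(eb):
                assert abs(ea.get(e, 0.0) - eb.get(e, 0.0)) < tol, (key, e)


class TestSmallExamples:
    def test_too_short_to_fold_is_all_unpaired(self, model):
        probs = compute_ensemble(RnaSequence("x", "ACGU"), model)
        assert probs.bpp.max() == 0.0
        assert np.allclose(probs.unpaired[1:], 1.0)

    def test_unpairable_sequence_has_single_structure(self, model):
        structs = enumerate_structures(RnaSequence("x", "AAAA"), model)
        assert len(structs) == 1
        assert structs[0] == (frozenset(), 1.0)

    def test_single_hairpin_candidate(self, model):
        structs = enumerate_structures(RnaSequence("x", "GAAAC"), model)
        assert sorted(s for s, _ in structs) == [
            frozenset(),
            frozenset({(1, 5)}),
        ]

    def test_open_chain_weight_is_one(self, model):
        structs = dict(enumerate_structures(RnaSequence("x", "GGGAAAACCC"), model))
        assert structs[frozenset()] == 1.0

    def test_uniform_bpp_equals_structure_count_ratio(self, uniform_model):
        seq = RnaSequence("x", "GGGAAAACCC")
        structs = enumerate_structures(seq, uniform_model)
        total = len(structs)
        with_15 = sum(1 for s, _ in structs if (1, 10) in s)
        probs = compute_ensemble(seq, uniform_model)
        assert probs.bpp_at(1, 10) == pytest.approx(with_15 / total, abs=1e-12)

    def test_structure_count_cross_check(self, uniform_model):
        seq = RnaSequence("x", "GGGAAAACCC")
        assert count_structures(seq, uniform_model) == len(
            enumerate_structures(seq, uniform_model)
        )

    def test_enumeration_cap(self, model):
        with pytest.raises(InputError):
            enumerate_structures(random_sequence(25, seed=1), model, cap=18)

    def test_stacked_structure_energy(self, model):
        seq = RnaSequence("x", "GGAAAACC")
        pairs = frozenset({(1, 8), (2, 7)})
        # two CG-ish pairs: G-C each -3, one stack -1, interior + hairpin consts 0
        assert structure_energy(seq, model, pairs) == pytest.approx(-7.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["weighted", "uniform"])
    def test_matches_enumeration_on_seeded_sequences(self, mode):
        model = EnergyModel(
            mode=mode,
            hairpin_const=0.2 if mode == "weighted" else 0.0,
            interior_const=0.1 if mode == "weighted" else 0.0,
            multiloop_const=0.4 if mode == "weighted" else 0.0,
        )
        for t in range(8):
            seq = random_sequence(8 + t % 7, 0.5, seed=7000 + t)
            assert_probs_close(
                compute_ensemble(seq, model), probs_by_enumeration(seq, model)
            )

    def test_parent_partition_of_unpaired_probability(self, model):
        for t in range(8):
            seq = random_sequence(9 + t % 5, 0.5, seed=8000 + t)
            probs = compute_ensemble(seq, model)
            for k in range(1, len(seq) + 1):
                total = sum(
                    entries.get(k, 0.0)
                    for entries in probs.in_loop_unpaired.values()
                )
                assert total == pytest.approx(float(probs.unpaired[k]), abs=1e-9)

    def test_parent_partition_of_pair_probability(self, model):
        seq = random_sequence(12, 0.5, seed=8100)
        probs = compute_ensemble(seq, model)
        for i in range(1, 13):
            for j in range(i + 1, 13):
                total = sum(
                    entries.get((i, j), 0.0)
                    for entries in probs.in_loop_pair.values()
                )
                assert total == pytest.approx(probs.bpp_at(i, j), abs=1e-9)

    def test_probability_bounds(self, model):
        seq = random_sequence(12, 0.6, seed=8200)
        probs = compute_ensemble(seq, model)
        assert probs.bpp.min() >= 0 and probs.bpp.max() <= 1 + 1e-12
        for i in range(1, 12):
            for j in range(i + 1, 13):
                assert probs.stacked_at(i, j) <= probs.bpp_at(i, j) + 1e-12
        for (pi, pj), entries in probs.in_loop_unpaired.items():
            if (pi, pj) == psi(probs.n):
                continue
            for k, v in entries.items():
                assert v <= min(probs.bpp_at(pi, pj), probs.unpaired[k]) + 1e-12

    def test_reverse_complement_symmetry_uniform(self, uniform_model):
        # GGGGCCCC is its own reverse complement; G/C only, so no wobble
        # pairs break the mirror symmetry
        seq = RnaSequence("x", "GGGGCCCC")
        probs = compute_ensemble(seq, uniform_model)
        n = len(seq)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                assert probs.bpp_at(i, j) == pytest.approx(
                    probs.bpp_at(n + 1 - j, n + 1 - i), abs=1e-12
                )


from hypothesis import given, settings
from hypothesis import strategies as st

rna = st.text(alphabet="ACGU", min_size=1, max_size=10)


class TestPropertyBased:
    @given(rna)
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_unpaired_probability_partition(self, residues):
        probs = compute_ensemble(RnaSequence("h", residues))
        for k in range(1, probs.n + 1):
            total = sum(
                d.get(k, 0.0) for d in probs.in_loop_unpaired.values()
            )
            assert abs(total - float(probs.unpaired[k])) < 1e-9

    @given(rna)
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_partition_function_at_least_open_chain(self, residues):
        from rnaepm.ensemble import _Inside

        ins = _Inside(RnaSequence("h", residues), EnergyModel())
        assert ins.Z >= 1.0
        assert ins.Qb.min() >= 0.0


class TestCache:
    def test_round_trip(self, model, tmp_path):
        seq = random_sequence(12, 0.5, seed=9000)
        probs = compute_ensemble(seq, model)
        path = tmp_path / "ens.tsv"
        cache_write(probs, path)
        again = cache_read(path, seq, model)
        assert_probs_close(probs, again, tol=1e-12)

    def test_gzip_round_trip(self, model, tmp_path):
        seq = random_sequence(10, 0.5, seed=9001)
        probs = compute_ensemble(seq, model)
        path = tmp_path / "ens.tsv.gz"
        cache_write(probs, path)
        assert_probs_close(probs, cache_read(path, seq, model), tol=1e-12)

    def test_parameter_stamp_mismatch(self, model, tmp_path):
        seq = random_sequence(10, 0.5, seed=9002)
        path = tmp_path / "ens.tsv"
        cache_write(compute_ensemble(seq, model), path)
        other = EnergyModel(min_hairpin=4)
        with pytest.raises(CacheError):
            cache_read(path, seq, other)

    def test_wrong_sequence_rejected(self, model, tmp_path):
        path = tmp_path / "ens.tsv"
        cache_write(compute_ensemble(random_sequence(10, seed=1), model), path)
        with pytest.raises(CacheError):
            cache_read(path, random_sequence(10, seed=2), model)

    def test_truncated_file_rejected(self, model, tmp_path):
        seq = random_sequence(10, 0.5, seed=9003)
        path = tmp_path / "ens.tsv"
        cache_write(compute_ensemble(seq, model), path)
        content = path.read_text().splitlines()
        path.write_text("\n".join(content[:-2]))
        with pytest.raises(CacheError):
            cache_read(path, seq, model)
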