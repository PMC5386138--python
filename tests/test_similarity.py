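"""Term/set/group similarity, cache equivalence and the permutation test."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import ontokit as ok
from ontokit.similarity import SimSpec
from ontokit.synthetic import CorpusSpec, DagSpec, PlantedGroup, random_annotations, random_dag

from .conftest import IC_T2, IC_T4, T0, T1, T2, T3, T4

LIN_T3_T4 = 2 * IC_T2 / (IC_T2 + IC_T4)  # ≈ 0.5392


def _random_corpus(seed: int, n_terms=40, n_objects=12, terms_per_object=3):
    index = ok.build_index(random_dag(DagSpec(n_terms=n_terms, mean_parents=1.7, seed=seed)))
    table = random_annotations(
        index, CorpusSpec(n_objects=n_objects, terms_per_object=terms_per_object, seed=seed)
    )
    prop = ok.propagate(index, table)
    ict = ok.information_content(index, prop)
    return index, prop, ict


class TestTermSimilarity:
    def test_resnik_diamond_mica(self, diamond, diamond_ic):
        # common ancestors of T3 and T4 are {T3,T1,T2,T0}; max IC is at T3
        assert ok.term_similarity(diamond, diamond_ic, T3, T4, "resnik") == \
            pytest.approx(IC_T2)

    def test_resnik_zero_information_ancestry(self, diamond, diamond_ic):
        assert ok.term_similarity(diamond, diamond_ic, T1, T2, "resnik") == 0.0
        # 0/0 rule: both branches reach only IC-0 shared ancestry
        assert ok.term_similarity(diamond, diamond_ic, T1, T1, "lin") == 0.0

    def test_lin_diamond_value(self, diamond, diamond_ic):
        assert ok.term_similarity(diamond, diamond_ic, T3, T4, "lin") == \
            pytest.approx(LIN_T3_T4)

    def test_lin_self_similarity_one_for_positive_ic(self, diamond, diamond_ic):
        for t in (T2, T3, T4):
            assert ok.term_similarity(diamond, diamond_ic, t, t, "lin") == 1.0

    def test_no_frequency_error_names_term(self, diamond):
        table = ok.read_annotations(f"X\t{T0}\n", diamond)
        ict = ok.information_content(diamond, table)
        with pytest.raises(ok.NoFrequencyError, match=T4):
            ok.term_similarity(diamond, ict, T0, T4, "resnik")

    def test_symmetry_range_and_self_dominance(self):
        index, prop, ict = _random_corpus(seed=5)
        terms = sorted(ict.ic)
        rng = np.random.default_rng(5)
        for _ in range(200):
            t, u = (terms[int(i)] for i in rng.integers(len(terms), size=2))
            for method in ok.METHODS:
                s_tu = ok.term_similarity(index, ict, t, u, method)
                s_ut = ok.term_similarity(index, ict, u, t, method)
                assert s_tu == pytest.approx(s_ut, abs=1e-12)
                assert s_tu >= 0.0
                if method == "lin":
                    assert s_tu <= 1.0 + 1e-12
            # self-comparison maximizes Resnik over any partner
            assert ok.term_similarity(index, ict, t, t, "resnik") >= \
                ok.term_similarity(index, ict, t, u, "resnik") - 1e-12


class TestSetSimilarity:
    def test_singletons_collapse_to_term_similarity(self, diamond, diamond_ic):
        assert ok.set_similarity(diamond, diamond_ic, {T3}, {T4}, "lin") == \
            pytest.approx(LIN_T3_T4)

    def test_self_similarity_is_one_with_positive_ic(self, diamond, diamond_ic):
        assert ok.set_similarity(diamond, diamond_ic, {T2, T3, T4}, {T2, T3, T4}, "lin") \
            == pytest.approx(1.0)

    def test_empty_set_raises(self, diamond, diamond_ic):
        with pytest.raises(ok.EmptySetError):
            ok.set_similarity(diamond, diamond_ic, set(), {T3}, "lin")

    def test_symmetry_on_random_corpora(self):
        index, prop, ict = _random_corpus(seed=7)
        sets = [prop.terms_of[o] for o in prop.objects]
        for a, b in itertools.combinations(sets[:6], 2):
            for method in ok.METHODS:
                assert ok.set_similarity(index, ict, a, b, method) == \
                    pytest.approx(ok.set_similarity(index, ict, b, a, method), abs=1e-12)

    def test_matches_brute_force_best_match_average(self):
        """Independent oracle: literal double loop over term pairs."""
        index, prop, ict = _random_corpus(seed=9)
        a = prop.terms_of[prop.objects[0]]
        b = prop.terms_of[prop.objects[1]]
        for method in ok.METHODS:
            s = np.array([
                [ok.term_similarity(index, ict, x, y, method) for y in sorted(b)]
                for x in sorted(a)
            ])
            expected = 0.5 * (s.max(axis=1).mean() + s.max(axis=0).mean())
            assert ok.set_similarity(index, ict, a, b, method) == \
                pytest.approx(expected, abs=1e-12)


class TestPairwiseMatrix:
    @pytest.mark.parametrize("method", ok.METHODS)
    def test_cache_modes_agree_exactly(self, method):
        index, prop, ict = _random_corpus(seed=13, n_objects=10)
        sets = [prop.terms_of[o] for o in prop.objects]
        reference = ok.pairwise_set_matrix(
            index, ict, sets, SimSpec(method=method, cache_mode="none")
        )
        assert np.allclose(reference, reference.T, atol=0)
        for mode in ("term_matrix", "set_matrix", "lookup_index"):
            other = ok.pairwise_set_matrix(
                index, ict, sets, SimSpec(method=method, cache_mode=mode)
            )
            assert np.abs(other - reference).max() <= 1e-12

    def test_single_set_gives_1x1(self, diamond, diamond_ic):
        m = ok.pairwise_set_matrix(diamond, diamond_ic, [{T3, T4}])
        assert m.shape == (1, 1)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SimSpec(method="wang")
        with pytest.raises(ValueError):
            SimSpec(cache_mode="mystery")


class TestGroupSimilarity:
    def test_pair_group_is_single_entry(self):
        m = np.array([[0.0, 0.3], [0.3, 0.0]])
        assert ok.group_similarity(m, [0, 1]) == pytest.approx(0.3)

    def test_constant_off_diagonal(self):
        m = np.full((5, 5), 0.7)
        np.fill_diagonal(m, 1.0)
        assert ok.group_similarity(m, [0, 2, 4]) == pytest.approx(0.7)

    def test_diamond_corpus_three_object_mean(self, diamond, diamond_table, diamond_ic):
        prop = ok.propagate(diamond, diamond_table)
        sets = [prop.terms_of[o] for o in prop.objects]
        m = ok.pairwise_set_matrix(diamond, diamond_ic, sets, SimSpec(method="lin"))
        expected = (m[0, 1] + m[0, 2] + m[1, 2]) / 3
        assert ok.group_similarity(m, [0, 1, 2]) == pytest.approx(expected)

    def test_degenerate_group_raises(self):
        with pytest.raises(ok.DegenerateGroupError):
            ok.group_similarity(np.zeros((3, 3)), [1])

    def test_bad_indices_raise(self):
        with pytest.raises(ValueError):
            ok.group_similarity(np.zeros((3, 3)), [0, 0])
        with pytest.raises(ValueError):
            ok.group_similarity(np.zeros((3, 3)), [0, 7])


class TestSimP:
    def test_constant_matrix_gives_p_one(self):
        m = np.full((6, 6), 0.5)
        result = ok.sim_p(m, [0, 1, 2], n_permutations=200, seed=1)
        assert result.p_value == 1.0

    def test_p_at_least_add_one_bound_and_seeded(self):
        rng = np.random.default_rng(2)
        m = rng.random((8, 8))
        m = (m + m.T) / 2
        r1 = ok.sim_p(m, [0, 1, 2], n_permutations=99, seed=42)
        r2 = ok.sim_p(m, [0, 1, 2], n_permutations=99, seed=42)
        assert r1 == r2
        assert 1 / 100 <= r1.p_value <= 1.0
        assert r1.seed == 42

    def test_whole_population_group_raises(self):
        with pytest.raises(ok.DegenerateNullError):
            ok.sim_p(np.zeros((3, 3)), [0, 1, 2], n_permutations=10, seed=0)

    def test_planted_cluster_detected(self):
        index = ok.build_index(random_dag(DagSpec(n_terms=60, mean_parents=1.6, seed=21)))
        table = random_annotations(
            index,
            CorpusSpec(n_objects=20, terms_per_object=2,
                       planted_group=PlantedGroup(size=5), seed=21),
        )
        prop = ok.propagate(index, table)
        ict = ok.information_content(index, prop)
        sets = [prop.terms_of[o] for o in prop.objects]
        m = ok.pairwise_set_matrix(index, ict, sets, SimSpec(method="lin"))
        result = ok.sim_p(m, [0, 1, 2, 3, 4], n_permutations=1000, seed=21)
        assert result.p_value < 0.05

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """MC p-value vs the exact p over all C(8,3) subsets."""
        index, prop, ict = _random_corpus(seed=17, n_objects=8)
        sets = [prop.terms_of[o] for o in prop.objects]
        m = ok.pairwise_set_matrix(index, ict, sets, SimSpec(method="lin"))
        group = [0, 1, 2]
        observed = ok.group_similarity(m, group)
        null = [ok.group_similarity(m, list(g))
                for g in itertools.combinations(range(8), 3)]
        exact = sum(1 for v in null if v >= observed) / len(null)
        n_perm = 20_000
        result = ok.sim_p(m, group, n_permutations=n_perm, seed=17)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(result.p_value - exact) <= 3 * se + 1 / (n_perm + 1)


def test_write_formats(diamond, diamond_table, diamond_ic):
    prop = ok.propagate(diamond, diamond_table)
    sets = [prop.terms_of[o] for o in prop.objects]
    m = ok.pairwise_set_matrix(diamond, diamond_ic, sets)
    text = ok.write_matrix(m, prop.objects)
    rows = text.splitlines()
    assert rows[0] == "\tX\tY\tZ"
    assert rows[1].startswith("X\t")
    r = ok.sim_p(m, [0, 1], n_permutations=9, seed=3)
    assert ok.write_sim_p(r).rstrip("\n").split("\t")[2:] == ["9", "3"]
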