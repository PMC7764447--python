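"""ORA, BH adjustment and affinity-propagation term reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    ap_brute_force_optimum,
    ap_net_similarity,
    bh_stepup_by_hand,
    hypergeom_tail_enumeration,
)
from crossomics.enrichment import (
    affinity_propagation,
    bh_adjust,
    ora,
    reduce_terms,
    term_similarity,
)
from crossomics.io_model import GeneSet, GeneSetCollection


def collection(sets: dict[str, set[str]], universe) -> GeneSetCollection:
    return GeneSetCollection(
        sets={n: GeneSet(n, "", frozenset(m)) for n, m in sets.items()},
        universe=frozenset(universe),
    )


class TestBH:
    def test_hand_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.05, 0.5]) == pytest.approx([0.10, 0.5])
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_empty_and_bounds(self):
        assert bh_adjust([]) == []
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_equal_inputs_unchanged(self):
        assert bh_adjust([0.3] * 5) == pytest.approx([0.3] * 5)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=300)
    def test_matches_stepup_oracle(self, pvals):
        adjusted = bh_adjust(pvals)
        assert adjusted == pytest.approx(bh_stepup_by_hand(pvals), abs=1e-12)
        # monotone when input sorted ascending
        srt = bh_adjust(sorted(pvals))
        assert all(a <= b + 1e-15 for a, b in zip(srt, srt[1:]))


class TestORA:
    def test_saturated_term_small_universe(self):
        universe = [f"G{i}" for i in range(20)]
        coll = collection({"T": set(universe[:5])}, universe)
        (res,) = ora(universe[:5], coll)
        # all 5 draws hit the 5-member term: p = 1/C(20,5)
        assert res.k == res.K == res.n == 5 and res.N == 20
        assert res.p_value == pytest.approx(1 / 15504, rel=1e-9)
        assert res.enrichment_ratio == pytest.approx(4.0)

    def test_disjoint_term(self):
        universe = [f"G{i}" for i in range(20)]
        coll = collection({"T": set(universe[10:15])}, universe)
        (res,) = ora(universe[:5], coll)
        assert res.k == 0 and res.p_value == 1.0 and res.enrichment_ratio == 0.0

    def test_query_equal_universe_saturates_every_term(self):
        universe = [f"G{i}" for i in range(10)]
        coll = collection({"A": set(universe[:4]), "B": set(universe[2:9])}, universe)
        for res in ora(universe, coll):
            assert res.k == res.K
            assert res.enrichment_ratio == pytest.approx(1.0)
            assert res.p_value == 1.0

    def test_query_outside_universe_is_error(self):
        coll = collection({"T": {"G1"}}, ["G1", "G2"])
        with pytest.raises(ValueError, match="universe"):
            ora({"NOPE"}, coll)

    def test_sorted_by_p_then_term(self):
        universe = [f"G{i}" for i in range(30)]
        coll = collection(
            {"Z": set(universe[:5]), "A": set(universe[:5]), "W": set(universe[20:25])},
            universe,
        )
        res = ora(universe[:5], coll)
        assert [r.term for r in res[:2]] == ["A", "Z"]

    def test_background_overrides_universe(self):
        universe = [f"G{i}" for i in range(100)]
        coll = collection({"T": set(universe[:10])}, universe)
        (res,) = ora(universe[:5], coll, background=universe[:50])
        assert res.N == 50

    @given(st.data())
    @settings(deadline=None, max_examples=30)
    def test_pvalues_match_enumeration_on_tiny_universes(self, data):
        N = data.draw(st.integers(4, 10))
        universe = [f"G{i}" for i in range(N)]
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        members = set(data.draw(st.permutations(universe))[:K])
        query = set(data.draw(st.permutations(universe))[:n])
        coll = collection({"T": members}, universe)
        (res,) = ora(query, coll)
        exact = hypergeom_tail_enumeration(res.k, K, n, N)
        assert res.p_value == pytest.approx(float(exact), abs=1e-12)


class TestAffinityPropagation:
    def test_single_point_is_its_own_exemplar(self):
        res = affinity_propagation(np.array([[0.5]]))
        assert res.exemplars == [0] and res.assignment == [0] and res.converged

    def test_two_identical_groups_of_three(self):
        S = np.zeros((6, 6))
        for group in ([0, 1, 2], [3, 4, 5]):
            for i in group:
                for j in group:
                    S[i, j] = 1.0
        off = S[~np.eye(6, dtype=bool)]
        np.fill_diagonal(S, np.median(off))
        res = affinity_propagation(S)
        assert len(res.exemplars) == 2
        # group assignment exact: all of each triple to one exemplar
        assert len({res.assignment[i] for i in (0, 1, 2)}) == 1
        assert len({res.assignment[i] for i in (3, 4, 5)}) == 1
        # matches the exhaustive optimum
        opt_net, _ = ap_brute_force_optimum(S)
        assert ap_net_similarity(S, res.exemplars) == pytest.approx(opt_net)

    def test_near_optimal_on_random_points(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = int(rng.integers(2, 9))
            S = rng.random((m, m))
            S = (S + S.T) / 2
            np.fill_diagonal(S, np.median(S[~np.eye(m, dtype=bool)]))
            res = affinity_propagation(S)
            net = ap_net_similarity(S, res.exemplars)
            opt, _ = ap_brute_force_optimum(S)
            assert net >= opt - 0.05 * abs(opt)

    def test_asymmetric_matrix_rejected(self):
        S = np.array([[0.1, 0.9], [0.2, 0.1]])
        with pytest.raises(ValueError, match="symmetric"):
            affinity_propagation(S)

    def test_bad_damping_rejected(self):
        with pytest.raises(ValueError, match="damping"):
            affinity_propagation(np.eye(2), damping=0.3)


class TestTermSimilarity:
    def test_jaccard_and_preference(self):
        coll = collection(
            {"A": {"G1", "G2"}, "B": {"G2", "G3"}, "C": {"G9", "G8"}},
            [f"G{i}" for i in range(1, 10)],
        )
        sim = term_similarity(["A", "B", "C"], coll)
        assert sim.matrix[0, 1] == pytest.approx(1 / 3)
        assert sim.matrix[0, 2] == 0.0
        assert sim.preference == pytest.approx(np.median([1 / 3, 0, 0]))
        assert np.allclose(np.diag(sim.matrix), sim.preference)

    def test_overlap_coefficient_option(self):
        coll = collection(
            {"A": {"G1", "G2", "G3"}, "B": {"G1"}}, ["G1", "G2", "G3"]
        )
        sim = term_similarity(["A", "B"], coll, metric="overlap-coef")
        assert sim.matrix[0, 1] == pytest.approx(1.0)


class TestReduceTerms:
    def _results(self, query, sets, universe):
        coll = collection(sets, universe)
        return ora(query, coll, fdr_threshold=0.05), coll

    def test_single_significant_term_is_its_own_exemplar(self):
        universe = [f"G{i}" for i in range(50)]
        results, coll = self._results(universe[:5], {"T": set(universe[:5])}, universe)
        out = reduce_terms(results, coll)
        assert out[0].is_exemplar and out[0].exemplar == "T"

    def test_duplicate_terms_yield_one_exemplar(self):
        universe = [f"G{i}" for i in range(60)]
        members = set(universe[:6])
        results, coll = self._results(
            universe[:6], {"T1": members, "T2": members}, universe
        )
        out = reduce_terms(results, coll)
        sig = [r for r in out if r.significant]
        exemplars = {r.term for r in sig if r.is_exemplar}
        assert len(exemplars) == 1
        assert {r.exemplar for r in sig} == exemplars

    def test_disjoint_terms_are_both_exemplars(self):
        universe = [f"G{i}" for i in range(80)]
        results, coll = self._results(
            universe[:12],
            {"T1": set(universe[:6]), "T2": set(universe[6:12])},
            universe,
        )
        out = reduce_terms(results, coll)
        assert all(r.is_exemplar for r in out if r.significant)

    def test_permutation_invariant_in_term_order(self):
        universe = [f"G{i}" for i in range(100)]
        sets = {
            "T1": set(universe[:8]),
            "T2": set(universe[2:10]),
            "T3": set(universe[40:48]),
        }
        query = set(universe[:10]) | set(universe[40:44])
        results, coll = self._results(query, sets, universe)
        out1 = reduce_terms(results, coll)
        out2 = reduce_terms(list(reversed(results)), coll)
        flags1 = {r.term: (r.is_exemplar, r.exemplar) for r in out1}
        flags2 = {r.term: (r.is_exemplar, r.exemplar) for r in out2}
        assert flags1 == flags2

    def test_no_significant_terms_passthrough(self):
        universe = [f"G{i}" for i in range(100)]
        results, coll = self._results(
            universe[:5], {"T": set(universe[50:90])}, universe
        )
        out = reduce_terms(results, coll)
        assert all(not r.is_exemplar for r in out)
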