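import numpy as np
import pytest

from cpredictor3 import (
    GoDag,
    protein_similarity,
    semantic_contributions,
    semantic_value,
    similarity_matrix,
    term_similarity,
)

from conftest import brute_force_contributions, random_dag


class TestSemanticContributions:
    def test_root_has_trivial_map(self, worked):
        assert semantic_contributions(worked.dag, "A") == {"A": 1.0}
        assert semantic_value(worked.dag, "A") == 1.0

    def test_chain_values(self, worked):
        smap = semantic_contributions(worked.dag, "C")
        assert smap == pytest.approx({"C": 1.0, "B": 0.8, "A": 0.64})
        assert semantic_value(worked.dag, "C") == pytest.approx(2.44)

    def test_diamond_takes_best_path(self):
        # C -part_of-> X -is_a-> A and C -is_a-> Y -is_a-> A
        dag = GoDag.from_edges([
            ("C", "X", 0.6), ("X", "A", 0.8),
            ("C", "Y", 0.8), ("Y", "A", 0.8),
        ])
        smap = semantic_contributions(dag, "C")
        assert smap["A"] == pytest.approx(max(0.6 * 0.8, 0.8 * 0.8))

    def test_unknown_term_raises(self, worked):
        with pytest.raises(KeyError):
            semantic_contributions(worked.dag, "nope")

    def test_matches_path_product_oracle_on_random_dags(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            dag = random_dag(rng, int(rng.integers(2, 13)))
            for term in dag.terms:
                got = semantic_contributions(dag, term)
                want = brute_force_contributions(dag, term)
                assert got.keys() == want.keys()
                for t in want:
                    assert got[t] == pytest.approx(want[t], abs=1e-12)


class TestTermSimilarity:
    def test_self_similarity_is_one(self, worked):
        for term in "ABC":
            assert term_similarity(worked.dag, term, term) == pytest.approx(1.0)

    def test_disjoint_roots_score_zero(self):
        dag = GoDag.from_edges([("b1", "a1", 0.8), ("b2", "a2", 0.8)])
        assert term_similarity(dag, "b1", "b2") == 0.0

    def test_chain_pair_value(self, worked):
        # shared ancestry {B, A}: ((1+0.8)+(0.8+0.64)) / (1.8+2.44)
        value = term_similarity(worked.dag, "B", "C")
        assert value == pytest.approx(3.24 / 4.24)
        assert value == pytest.approx(0.7642, abs=1e-4)

    def test_symmetry_and_bounds_on_random_dags(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            dag = random_dag(rng, 10)
            terms = sorted(dag.terms)
            for a in terms[:5]:
                for b in terms[5:]:
                    s_ab = term_similarity(dag, a, b)
                    s_ba = term_similarity(dag, b, a)
                    assert s_ab == pytest.approx(s_ba)
                    assert 0.0 <= s_ab <= 1.0

    def test_literal_numerator_differs_from_wang(self, worked):
        wang = term_similarity(worked.dag, "C", "C", numerator="wang")
        literal = term_similarity(worked.dag, "C", "C", numerator="literal")
        assert wang == pytest.approx(1.0)
        assert literal != pytest.approx(1.0)  # sum of SV(t) over ancestry / 2*SV


class TestProteinSimilarity:
    ANN = {"p1": {"C"}, "p2": {"B"}, "p3": {"C"}, "p4": {"A", "B"}}

    def test_identical_annotation_sets_score_one(self, worked):
        assert protein_similarity(worked.dag, self.ANN, "p1", "p3") == pytest.approx(1.0)

    def test_singleton_sets_reduce_to_term_similarity(self, worked):
        expected = term_similarity(worked.dag, "B", "C")
        assert protein_similarity(worked.dag, self.ANN, "p1", "p2") == pytest.approx(expected)

    def test_disjoint_ancestries_score_zero(self):
        dag = GoDag.from_edges([("b1", "a1", 0.8), ("b2", "a2", 0.8)])
        ann = {"p": {"b1"}, "q": {"b2"}}
        assert protein_similarity(dag, ann, "p", "q") == 0.0

    def test_unannotated_protein_raises(self, worked):
        with pytest.raises(KeyError):
            protein_similarity(worked.dag, self.ANN, "p1", "ghost")

    def test_best_match_average_formula_directly(self, worked):
        # m=2, n=1: Sim = (max(S(A,C), S(B,C)) summed per side) / 3
        s_ac = term_similarity(worked.dag, "A", "C")
        s_bc = term_similarity(worked.dag, "B", "C")
        expected = (s_ac + s_bc + max(s_ac, s_bc)) / 3
        assert protein_similarity(worked.dag, self.ANN, "p4", "p1") == pytest.approx(expected)

    def test_shared_extra_term_checked_against_brute_force(self, worked):
        ann = {"p": {"B"}, "q": {"A"}, "p_t": {"B", "C"}, "q_t": {"A", "C"}}
        got = protein_similarity(worked.dag, ann, "p_t", "q_t")
        terms_p, terms_q = sorted(ann["p_t"]), sorted(ann["q_t"])
        pair = [[term_similarity(worked.dag, x, y) for y in terms_q] for x in terms_p]
        brute = (sum(max(row) for row in pair)
                 + sum(max(col) for col in zip(*pair))) / (len(terms_p) + len(terms_q))
        assert got == pytest.approx(brute)


class TestSimilarityMatrix:
    def test_single_protein(self, worked):
        sim = similarity_matrix(worked.dag, {"p": {"C"}})
        assert sim.shape == (1, 1) and sim.iloc[0, 0] == 1.0

    def test_identical_annotations_give_all_ones(self, worked):
        sim = similarity_matrix(worked.dag, {"p": {"B", "C"}, "q": {"B", "C"}})
        assert np.allclose(sim.to_numpy(), 1.0)

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(9)
        dag = random_dag(rng, 9)
        terms = sorted(dag.terms)
        ann = {f"p{i}": {terms[int(t)] for t in rng.integers(0, 9, size=2)}
               for i in range(6)}
        sim = similarity_matrix(dag, ann)
        for i, p in enumerate(sim.index):
            for j, q in enumerate(sim.columns):
                expected = 1.0 if p == q else protein_similarity(dag, ann, p, q)
                assert sim.iloc[i, j] == pytest.approx(expected)
        assert np.allclose(sim.to_numpy(), sim.to_numpy().T)
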