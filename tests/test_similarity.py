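import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eoesgc.similarity import (
    ContributionTable,
    DiseaseOntology,
    KernelParams,
    SimilarityMatrix,
    UnknownDiseaseError,
    build_dag,
    dag_membership_counts,
    disease_semantic_matrices,
    disease_set_similarity,
    gip_similarity,
    integrate_similarity,
    mirna_functional_similarity,
    semantic_contribution_m1,
    semantic_contribution_m2,
    semantic_similarity,
    semantic_value,
    threshold_filter,
)

from conftest import random_dag_edges


class TestBuildDag:
    def test_singleton(self):
        ont = DiseaseOntology(terms={"T"}, edges=set(), disease_terms={"D": {"T"}})
        nodes, edges = build_dag(ont, "D")
        assert nodes == {"T"}
        assert edges == set()

    def test_chain(self, chain_ontology):
        nodes, edges = build_dag(chain_ontology, "D")
        assert nodes == {"c", "p", "g"}
        assert edges == {("c", "p"), ("p", "g")}

    def test_diamond(self, diamond_ontology):
        nodes, edges = build_dag(diamond_ontology, "D")
        assert nodes == {"c", "p1", "p2", "g"}
        assert len(edges) == 4

    def test_unknown_disease(self, chain_ontology):
        with pytest.raises(UnknownDiseaseError):
            build_dag(chain_ontology, "nope")

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseOntology(
                terms={"a", "b"},
                edges={("a", "b"), ("b", "a")},
                disease_terms={},
            )


class TestModel1Contributions:
    def test_own_term_is_one(self, chain_ontology):
        dag = build_dag(chain_ontology, "D")
        table = semantic_contribution_m1(dag, "D", {"c"}, 0.5)
        assert table.contributions["c"] == 1.0

    def test_chain_values(self, chain_ontology):
        dag = build_dag(chain_ontology, "D")
        table = semantic_contribution_m1(dag, "D", {"c"}, 0.5)
        assert table.contributions == {"c": 1.0, "p": 0.5, "g": 0.25}

    def test_diamond_distance_two(self, diamond_ontology):
        dag = build_dag(diamond_ontology, "D")
        table = semantic_contribution_m1(dag, "D", {"c"}, 0.5)
        assert table.contributions["g"] == 0.25

    def test_shortcut_edge_takes_max(self):
        ont = DiseaseOntology(
            terms={"c", "p", "g"},
            edges={("c", "p"), ("p", "g"), ("c", "g")},
            disease_terms={"D": {"c"}},
        )
        table = semantic_contribution_m1(build_dag(ont, "D"), "D", {"c"}, 0.5)
        assert table.contributions["g"] == 0.5

    def test_brute_force_path_oracle(self):
        """Contribution equals max over all upward paths of delta^len."""
        rng = np.random.default_rng(42)
        delta = 0.5
        for _ in range(25):
            n = int(rng.integers(2, 13))
            names, edges = random_dag_edges(rng, n)
            ont = DiseaseOntology(
                terms=set(names), edges=edges, disease_terms={"D": {names[-1]}}
            )
            dag = build_dag(ont, "D")
            table = semantic_contribution_m1(dag, "D", {names[-1]}, delta)

            parent_map = {}
            for c, p in dag[1]:
                parent_map.setdefault(c, []).append(p)

            def best(term, start):
                # max over all paths start -> term of delta**len
                out = {start: 1.0}
                frontier = [(start, 1.0)]
                while frontier:
                    node, val = frontier.pop()
                    for par in parent_map.get(node, []):
                        cand = val * delta
                        if cand > out.get(par, 0.0):
                            out[par] = cand
                            frontier.append((par, cand))
                return out.get(term, 0.0)

            for term in dag[0]:
                assert table.contributions[term] == pytest.approx(
                    best(term, names[-1]), abs=1e-12
                )


class TestSemanticValueAndSimilarity:
    def test_singleton_value(self):
        t = ContributionTable("D", {"D": 1.0}, "model1")
        assert semantic_value(t) == 1.0

    def test_chain_value(self, chain_ontology):
        dag = build_dag(chain_ontology, "D")
        t = semantic_contribution_m1(dag, "D", {"c"}, 0.5)
        assert semantic_value(t) == pytest.approx(1.75)

    def test_diamond_value(self, diamond_ontology):
        dag = build_dag(diamond_ontology, "D")
        t = semantic_contribution_m1(dag, "D", {"c"}, 0.5)
        assert semantic_value(t) == pytest.approx(2.25)

    def test_self_similarity_is_one(self, chain_ontology):
        dag = build_dag(chain_ontology, "D")
        t = semantic_contribution_m1(dag, "D", {"c"}, 0.5)
        assert semantic_similarity(t, t) == pytest.approx(1.0)

    def test_shared_parent_one_third(self, shared_parent_ontology):
        ta = semantic_contribution_m1(
            build_dag(shared_parent_ontology, "A"), "A", {"a"}, 0.5
        )
        tb = semantic_contribution_m1(
            build_dag(shared_parent_ontology, "B"), "B", {"b"}, 0.5
        )
        assert semantic_similarity(ta, tb) == pytest.approx(1 / 3, abs=1e-6)

    def test_disjoint_dags(self):
        t1 = ContributionTable("A", {"x": 1.0}, "model1")
        t2 = ContributionTable("B", {"y": 1.0}, "model1")
        assert semantic_similarity(t1, t2) == 0.0

    def test_model_mismatch_raises(self):
        t1 = ContributionTable("A", {"x": 1.0}, "model1")
        t2 = ContributionTable("B", {"x": 1.0}, "model2")
        with pytest.raises(ValueError):
            semantic_similarity(t1, t2)


class TestModel2Contributions:
    def test_universal_term_scores_zero(self, shared_parent_ontology):
        counts = dag_membership_counts(shared_parent_ontology, ["A", "B"])
        t = semantic_contribution_m2(shared_parent_ontology, "A", counts, 2)
        assert t.contributions["P"] == pytest.approx(0.0)

    def test_rare_term_natural_log(self):
        ont = DiseaseOntology(
            terms={"t", "r"},
            edges={("t", "r")},
            disease_terms={"A": {"t"}, "B": {"r"}, "C": {"r"}, "E": {"r"}},
        )
        counts = dag_membership_counts(ont, ["A", "B", "C", "E"])
        t = semantic_contribution_m2(ont, "A", counts, 4)
        assert t.contributions["t"] == pytest.approx(-math.log(0.25), abs=1e-5)
        assert t.contributions["t"] == pytest.approx(1.38629, abs=1e-5)

    def test_shared_parent_similarity_zero(self, shared_parent_ontology):
        counts = dag_membership_counts(shared_parent_ontology, ["A", "B"])
        ta = semantic_contribution_m2(shared_parent_ontology, "A", counts, 2)
        tb = semantic_contribution_m2(shared_parent_ontology, "B", counts, 2)
        # own terms a, b: -ln(1/2); shared parent contributes 0
        assert semantic_value(ta) == pytest.approx(0.6931, abs=1e-4)
        assert semantic_similarity(ta, tb) == pytest.approx(0.0)

    def test_count_exceeding_n_raises(self, shared_parent_ontology):
        with pytest.raises(ValueError):
            semantic_contribution_m2(
                shared_parent_ontology, "A", {"a": 5, "P": 5}, 2
            )


class TestGip:
    def test_identical_profiles(self):
        profiles = np.array([[1.0, 0.0], [1.0, 0.0]])
        s = gip_similarity(profiles, ["a", "b"])
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_profiles_hand_value(self):
        profiles = np.array([[1.0, 0.0], [0.0, 1.0]])
        s = gip_similarity(profiles, ["a", "b"], gamma_prime=0.5)
        assert s.values[0, 1] == pytest.approx(math.exp(-1), abs=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        profiles = rng.random((6, 10))
        labels = [str(i) for i in range(6)]
        s1 = gip_similarity(profiles, labels)
        s2 = gip_similarity(3.7 * profiles, labels)
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-12)

    def test_all_zero_profiles_raise(self):
        with pytest.raises(ValueError):
            gip_similarity(np.zeros((3, 4)), ["a", "b", "c"])

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        s = gip_similarity(rng.random((8, 5)), [str(i) for i in range(8)])
        s.validate()
        np.testing.assert_allclose(np.diag(s.values), 1.0)


class TestSetAndFunctionalSimilarity:
    def test_self_set(self, toy_similarity):
        assert disease_set_similarity(0, [0], toy_similarity.values) == 1.0

    def test_max_rule(self, toy_similarity):
        # S(d1, {d2, d3}) = max(0.4, 0.8)
        assert disease_set_similarity(0, [1, 2], toy_similarity.values) == 0.8

    def test_empty_set_raises(self, toy_similarity):
        with pytest.raises(ValueError):
            disease_set_similarity(0, [], toy_similarity.values)

    def test_zero_similarities(self):
        s = np.zeros((2, 2))
        assert disease_set_similarity(0, [1], s) == 0.0

    def test_functional_toy_value(self, toy_similarity):
        # m1 -> {d1, d2}; m2 -> {d3}; S(d1,d3)=0.8? no: labels d1,d2,d3
        # spec toy: S(d1,d3)=0.4, S(d2,d3)=0.8
        values = np.array(
            [[1.0, 0.0, 0.4], [0.0, 1.0, 0.8], [0.4, 0.8, 1.0]]
        )
        sim = SimilarityMatrix(["d1", "d2", "d3"], values)
        a = np.array([[1, 1, 0], [0, 0, 1]])
        fs = mirna_functional_similarity(a, ["m1", "m2"], sim)
        assert fs.values[0, 1] == pytest.approx((0.4 + 0.8 + 0.8) / 3, abs=1e-6)

    def test_identical_single_disease(self):
        sim = SimilarityMatrix(["d"], np.array([[1.0]]))
        a = np.array([[1], [1]])
        fs = mirna_functional_similarity(a, ["m1", "m2"], sim)
        assert fs.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_zero_similarity(self):
        sim = SimilarityMatrix(["d1", "d2"], np.eye(2))
        a = np.array([[1, 0], [0, 1]])
        fs = mirna_functional_similarity(a, ["m1", "m2"], sim)
        assert fs.values[0, 1] == 0.0

    def test_empty_disease_set_row_zero(self):
        sim = SimilarityMatrix(["d1", "d2"], np.eye(2))
        a = np.array([[1, 1], [0, 0]])
        fs = mirna_functional_similarity(a, ["m1", "m2"], sim)
        assert fs.values[0, 1] == 0.0
        assert fs.values[1, 1] == 1.0


class TestIntegrationAndThreshold:
    def test_alpha_one_mean_of_semantics(self):
        labels = ["a", "b"]
        s1 = SimilarityMatrix(labels, np.array([[1, 0.4], [0.4, 1]]))
        s2 = SimilarityMatrix(labels, np.array([[1, 0.6], [0.6, 1]]))
        gip = SimilarityMatrix(labels, np.array([[1, 0.8], [0.8, 1]]))
        out = integrate_similarity([s1, s2], gip, 1.0)
        assert out.values[0, 1] == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        labels = ["a", "b"]
        s1 = SimilarityMatrix(labels, np.array([[1, 0.4], [0.4, 1]]))
        s2 = SimilarityMatrix(labels, np.array([[1, 0.6], [0.6, 1]]))
        gip = SimilarityMatrix(labels, np.array([[1, 0.8], [0.8, 1]]))
        out = integrate_similarity([s1, s2], gip, 0.5)
        assert out.values[0, 1] == pytest.approx(0.65)

    def test_alpha_zero_returns_gip(self):
        labels = ["a", "b"]
        s1 = SimilarityMatrix(labels, np.eye(2))
        gip = SimilarityMatrix(labels, np.array([[1, 0.8], [0.8, 1]]))
        out = integrate_similarity([s1], gip, 0.0)
        np.testing.assert_allclose(out.values, gip.values)

    def test_label_mismatch_raises(self):
        s1 = SimilarityMatrix(["a", "b"], np.eye(2))
        gip = SimilarityMatrix(["x", "y"], np.eye(2))
        with pytest.raises(ValueError):
            integrate_similarity([s1], gip, 0.5)

    def test_threshold_zeroes_below(self):
        s = SimilarityMatrix(["a", "b"], np.array([[1, 0.2], [0.2, 1]]))
        out = threshold_filter(s, 0.3)
        assert out.values[0, 1] == 0.0

    def test_boundary_kept(self):
        s = SimilarityMatrix(["a", "b"], np.array([[1, 0.3], [0.3, 1]]))
        out = threshold_filter(s, 0.3)
        assert out.values[0, 1] == 0.3

    def test_h_zero_identity(self):
        rng = np.random.default_rng(2)
        v = rng.random((4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        s = SimilarityMatrix(list("abcd"), v)
        np.testing.assert_allclose(threshold_filter(s, 0.0).values, v)

    @given(h=st.floats(0, 1), seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_threshold_idempotent_and_nonincreasing(self, h, seed):
        rng = np.random.default_rng(seed)
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        s = SimilarityMatrix(list("abcde"), v)
        once = threshold_filter(s, h)
        twice = threshold_filter(once, h)
        np.testing.assert_array_equal(once.values, twice.values)
        assert np.all(once.values <= v + 1e-15)

    def test_diagonal_exempt(self):
        s = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.1], [0.1, 1.0]]))
        out = threshold_filter(s, 0.9)
        np.testing.assert_allclose(np.diag(out.values), 1.0)


class TestKernelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gamma_prime": 0.0},
            {"alpha": 1.5},
            {"h": -0.1},
            {"delta": 1.0},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            KernelParams(**kwargs)


class TestSemanticMatrices:
    def test_full_matrix_invariants(self):
        rng = np.random.default_rng(7)
        names, edges = random_dag_edges(rng, 10)
        ont = DiseaseOntology(
            terms=set(names),
            edges=edges,
            disease_terms={f"D{i}": {names[-(i + 1)]} for i in range(4)},
        )
        s1, s2 = disease_semantic_matrices(ont, [f"D{i}" for i in range(4)])
        for s in (s1, s2):
            s.validate()
            np.testing.assert_allclose(np.diag(s.values), 1.0)

    def test_missing_disease_zero_row(self, chain_ontology):
        s1, _ = disease_semantic_matrices(chain_ontology, ["D", "ghost"])
        assert s1.values[0, 1] == 0.0
        assert s1.values[1, 1] == 1.0
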