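import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from codeharmony.embed import EmbeddingSet
from codeharmony.mapping import (MappingSpec, SimilarityMatrix,
                                 apply_harmonizer, build_harmonizer,
                                 directional_similarity, frequency_refine,
                                 regression_similarity, select_threshold,
                                 select_topk)
from codeharmony.store import CodeMatrix, FrequencyTable, GroupCatalog


def _emb(vocab, V):
    return EmbeddingSet(vocabulary=list(vocab), V=np.asarray(V, float),
                        dimension=np.asarray(V).shape[1], provenance={})


def _freq(site, mapping, pt=1.0):
    frame = pd.DataFrame({"frequency": pd.Series(mapping, dtype=int)})
    frame["rate"] = frame["frequency"] / pt
    return FrequencyTable(site_id=site, frame=frame, person_time=pt)


ONE_GROUP = GroupCatalog({c: "g" for c in ("a", "b", "x", "y")})


class TestDirectionalSimilarity:
    def test_identical_vectors_score_one(self):
        E = _emb(["a"], [[1.0, 2.0]])
        sim = directional_similarity(E, E, GroupCatalog({"a": "g"}))
        assert sim.values[0, 0] == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        src = _emb(["a"], [[1.0, 0.0]])
        ref = _emb(["b"], [[0.0, 1.0]])
        sim = directional_similarity(src, ref, GroupCatalog({"a": "g", "b": "g"}))
        assert sim.values[0, 0] == pytest.approx(0.0)

    def test_hand_computed_angle(self):
        src = _emb(["a"], [[1.0, 0.0]])
        ref = _emb(["b"], [np.array([1.0, 1.0]) / np.sqrt(2)])
        sim = directional_similarity(src, ref, GroupCatalog({"a": "g", "b": "g"}))
        assert sim.values[0, 0] == pytest.approx(np.sqrt(2) / 2)

    def test_cross_group_pairs_masked(self):
        src = _emb(["a"], [[1.0, 0.0]])
        ref = _emb(["b", "c"], [[1.0, 0.0], [1.0, 0.0]])
        sim = directional_similarity(src, ref, GroupCatalog({"a": "g", "b": "g", "c": "h"}))
        assert np.isnan(sim.values[0, 1])

    def test_zero_norm_row_flagged(self):
        src = _emb(["a"], [[0.0, 0.0]])
        ref = _emb(["b"], [[1.0, 0.0]])
        with pytest.warns(UserWarning, match="zero-norm"):
            sim = directional_similarity(src, ref, GroupCatalog({"a": "g", "b": "g"}))
        assert np.isnan(sim.values[0, 0])


class TestRegressionSimilarity:
    def test_single_candidate_equals_inner_product(self):
        src = _emb(["a"], [[0.6, 0.8]])
        ref = _emb(["b"], [[0.0, 1.0]])
        sim = regression_similarity(src, ref, GroupCatalog({"a": "g", "b": "g"}))
        assert sim.values[0, 0] == pytest.approx(0.8)

    def test_orthonormal_candidates_give_projections(self):
        src = _emb(["a"], [[0.3, 0.7]])
        ref = _emb(["x", "y"], np.eye(2))
        sim = regression_similarity(src, ref, GroupCatalog({"a": "g", "x": "g", "y": "g"}))
        assert sim.values[0, 0] == pytest.approx(0.3)
        assert sim.values[0, 1] == pytest.approx(0.7)

    def test_correlated_candidates_match_ridge_oracle(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(3, 4))
        x = rng.normal(size=4)
        lam = 0.3
        src = _emb(["a"], x[None, :])
        ref = _emb(["p", "q", "r"], Y)
        groups = GroupCatalog({c: "g" for c in ("a", "p", "q", "r")})
        sim = regression_similarity(src, ref, groups, ridge=lam)
        oracle = np.linalg.solve(Y @ Y.T + lam * np.eye(3), Y @ x)
        assert np.allclose(sim.values[0], oracle, atol=1e-10)

    def test_collinear_candidates_without_ridge_rejected(self):
        src = _emb(["a"], [[1.0, 0.0]])
        ref = _emb(["p", "q"], [[1.0, 0.0], [1.0, 0.0]])
        groups = GroupCatalog({c: "g" for c in ("a", "p", "q")})
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            regression_similarity(src, ref, groups, ridge=0.0)


class TestFrequencyRefine:
    def _sim(self, value=0.8):
        return SimilarityMatrix(["a"], ["b"], np.array([[value]]), "DS")

    def test_equal_rates_leave_similarity_unchanged(self):
        sim = frequency_refine(self._sim(), _freq("A", {"a": 50}), _freq("B", {"b": 50}),
                               gamma=0.5)
        assert sim.values[0, 0] == pytest.approx(0.8)

    def test_gamma_zero_is_identity(self):
        sim = frequency_refine(self._sim(), _freq("A", {"a": 10}), _freq("B", {"b": 9000}),
                               gamma=0.0)
        assert sim.values[0, 0] == pytest.approx(0.8)

    def test_e_squared_rate_gap_with_half_gamma(self):
        # smoothed rates differ by exactly e^2 => multiplier e^{-1}
        f_a = 40
        f_b = int(round((f_a + 10) * np.e**2 - 10))
        sim = frequency_refine(self._sim(1.0), _freq("A", {"a": f_a}),
                               _freq("B", {"b": f_b}), gamma=0.5)
        assert sim.values[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-3)

    @given(st.floats(-1, 1), st.integers(0, 500), st.integers(0, 500))
    def test_sign_preserved_and_damping_monotone(self, s, f_a, f_b):
        sim = frequency_refine(self._sim(s), _freq("A", {"a": f_a}),
                               _freq("B", {"b": f_b}), gamma=0.7)
        out = sim.values[0, 0]
        assert abs(out) <= abs(s) + 1e-12
        assert np.sign(out) == np.sign(s) or out == 0


class TestSelection:
    def _sim3(self):
        return SimilarityMatrix(["a"], ["x", "y", "z"],
                                np.array([[0.9, 0.5, 0.1]]), "DS")

    def test_topk_orders_by_similarity(self):
        spec = select_topk(self._sim3(), 2)
        assert spec.selections["a"] == [("x", 0.9), ("y", 0.5)]

    def test_tie_broken_by_reference_frequency(self):
        sim = SimilarityMatrix(["a"], ["x", "y"], np.array([[0.5, 0.5]]), "DS")
        freq = _freq("B", {"x": 5, "y": 500})
        spec = select_topk(sim, 1, ref_freq=freq)
        assert spec.top1("a") == "y"

    def test_k_larger_than_candidates_returns_all(self):
        spec = select_topk(self._sim3(), 5)
        assert len(spec.selections["a"]) == 3

    def test_threshold_keeps_strictly_above_tau(self):
        spec = select_threshold(self._sim3(), 0.5)
        assert [c for c, _ in spec.selections["a"]] == ["x"]


class TestHarmonizer:
    def test_top1_operator_is_binary(self):
        sim = self_sim = SimilarityMatrix(["a"], ["x", "y"],
                                          np.array([[0.9, 0.2]]), "DS")
        op = build_harmonizer(select_topk(sim, 1), sim)
        assert np.array_equal(op.M, [[1.0, 0.0]])

    def test_two_candidates_normalized_weights(self):
        sim = SimilarityMatrix(["a"], ["x", "y"], np.array([[0.6, 0.2]]), "DS")
        op = build_harmonizer(select_topk(sim, 2), sim)
        assert np.allclose(op.M, [[0.75, 0.25]])

    def test_unmapped_code_drop_policy_gives_zero_row(self):
        sim = SimilarityMatrix(["a"], ["x"], np.array([[np.nan]]), "DS")
        spec = MappingSpec(selections={}, rule="topK", K=1)
        op = build_harmonizer(spec, sim, unmapped_policy="drop")
        assert np.array_equal(op.M, [[0.0]])
        assert op.unmapped["a"] == "drop"

    def test_unmapped_shared_code_carries_identity(self):
        sim = SimilarityMatrix(["x"], ["x", "y"], np.array([[np.nan, np.nan]]), "DS")
        op = build_harmonizer(MappingSpec({}, "topK", K=1), sim)
        assert np.array_equal(op.M, [[1.0, 0.0]])

    def test_nonpositive_selected_similarities_fall_back(self):
        sim = SimilarityMatrix(["a"], ["x"], np.array([[-0.4]]), "DS")
        spec = MappingSpec({"a": [("x", -0.4)]}, "topK", K=1)
        with pytest.warns(UserWarning, match="nonpositive"):
            op = build_harmonizer(spec, sim, unmapped_policy="drop")
        assert op.M.sum() == 0.0

    def test_apply_identity_operator_is_noop(self):
        X = CodeMatrix(np.arange(6, dtype=float).reshape(2, 3), ["p", "q"],
                       ["a", "b", "c"], "count")
        sim = SimilarityMatrix(["a", "b", "c"], ["a", "b", "c"],
                               np.eye(3), "DS")
        spec = select_topk(sim, 1)
        out = apply_harmonizer(X, build_harmonizer(spec, sim))
        assert np.array_equal(out.values, X.values)

    def test_row_stochastic_mapping_conserves_counts(self):
        rng = np.random.default_rng(1)
        X = CodeMatrix(rng.poisson(3, (5, 3)).astype(float), list("pqrst"),
                       ["a", "b", "c"], "count")
        sim = SimilarityMatrix(["a", "b", "c"], ["x", "y"],
                               rng.uniform(0.1, 1, (3, 2)), "DS")
        op = build_harmonizer(select_topk(sim, 2), sim)
        out = apply_harmonizer(X, op)
        assert np.allclose(out.values.sum(axis=1), X.values.sum(axis=1))

    def test_vocabulary_mismatch_rejected(self):
        X = CodeMatrix(np.zeros((1, 2)), ["p"], ["a", "b"], "count")
        sim = SimilarityMatrix(["a"], ["x"], np.array([[0.5]]), "DS")
        op = build_harmonizer(select_topk(sim, 1), sim)
        with pytest.raises(ValueError, match="vocabulary"):
            apply_harmonizer(X, op)

    def test_granularity_collapse_sums_lateral_columns(self):
        """Three laterality codes mapped onto one unspecified code produce a
        harmonized column equal to the sum of the three source columns."""
        from codeharmony.store import patient_code_matrix
        from codeharmony.synth import generate_cohort, scenario_granularity

        config = scenario_granularity(n_patients=120, seed=8)
        ev_a, cov_a, _, _, truth = generate_cohort(config)
        lats = ["LAT_R", "LAT_L", "LAT_B"]
        assert all(truth.mapping[c] == [("UNSP", 1.0)] for c in lats)
        X = patient_code_matrix(ev_a, cov_a, lats, "count")
        sim = SimilarityMatrix(lats, ["UNSP"], np.ones((3, 1)), "DS")
        out = apply_harmonizer(X, build_harmonizer(select_topk(sim, 1), sim))
        assert np.allclose(out.values[:, 0], X.values.sum(axis=1))
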