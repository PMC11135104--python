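import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomix.model_selection import design_from_correlations
from gliomix.sgcca_core import (
    OUTCOME,
    SGCCAModel,
    deflate,
    dummy_matrix,
    fit_component,
    fit_sgcca,
    objective,
    soft_threshold_to_cardinality,
    transform,
)
from gliomix.synthetic_data import BlockSpec, SimConfig, generate_study
from gliomix.preprocess import center_scale

from conftest import random_standardized


class TestDummyMatrix:
    def test_column_sums_and_centering(self):
        d = dummy_matrix(["A", "B", "A"])
        np.testing.assert_array_equal(d.Y.sum(axis=0), [2, 1])
        np.testing.assert_allclose(d.Y_centered.mean(axis=0), 0.0, atol=1e-15)
        assert np.all(d.Y.sum(axis=1) == 1)

    def test_first_appearance_class_order(self):
        assert dummy_matrix(["b", "a", "c", "a"]).classes == ("b", "a", "c")

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dummy_matrix(["A", "A"])


class TestSoftThreshold:
    def test_no_shrinkage_at_full_cardinality(self):
        z = np.array([3.0, 1.0, -2.0])
        v, deg = soft_threshold_to_cardinality(z, 3)
        np.testing.assert_allclose(v, z / np.linalg.norm(z))
        assert not deg

    def test_k1_keeps_largest_entry(self):
        v, _ = soft_threshold_to_cardinality(np.array([3.0, 1.0, -2.0]), 1)
        np.testing.assert_allclose(v, [1.0, 0.0, 0.0])

    def test_k2_shrinks_by_third_largest(self):
        v, _ = soft_threshold_to_cardinality(np.array([3.0, 1.0, -2.0]), 2)
        np.testing.assert_allclose(v, np.array([2.0, 0.0, -1.0]) / np.sqrt(5))

    def test_all_zero_flags_degenerate(self):
        v, deg = soft_threshold_to_cardinality(np.zeros(4), 2)
        assert deg and np.all(v == 0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        z=st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=30),
        seed=st.integers(0, 10**6),
    )
    def test_unit_norm_and_cardinality(self, z, seed):
        z = np.asarray(z)
        k = 1 + seed % len(z)
        v, deg = soft_threshold_to_cardinality(z, k)
        if deg:
            assert not np.any(z)
        else:
            assert np.count_nonzero(v) <= k
            assert abs(np.linalg.norm(v) - 1.0) < 1e-12


class TestFitComponent:
    def test_single_block_matches_svd_of_cross_covariance(self):
        rng = np.random.default_rng(0)
        X = random_standardized(rng, 40, 8).to_numpy()
        dum = dummy_matrix(["A"] * 14 + ["B"] * 13 + ["C"] * 13)
        C = design_from_correlations({}, ["x"])
        fit = fit_component({"x": X}, dum.Y_centered, C, {"x": 8})
        u, _, _ = np.linalg.svd(X.T @ dum.Y_centered)
        assert abs(float(fit.loadings["x"] @ u[:, 0])) > 0.999

    def test_noise_free_two_block_support_recovery(self):
        cfg = SimConfig(
            n_per_class=(20, 20, 20),
            block_specs=(
                BlockSpec("a", 40, 6, "gaussian", loading_scale=2.0, noise_sd=0.0),
                BlockSpec("b", 40, 6, "gaussian", loading_scale=2.0, noise_sd=0.0),
            ),
            class_separation=6.0, seed=5)
        ds = generate_study(cfg)
        # noise-free noise columns are constant zero: standardize signal only
        blocks, names = {}, {}
        for b, X in ds.blocks.items():
            X = X[ds.truth[b] + [c for c in X.columns if X[c].std() > 0 and c not in ds.truth[b]]]
            Xs, _ = center_scale(X)
            blocks[b] = Xs.to_numpy()
            names[b] = list(Xs.columns)
        dum = dummy_matrix(ds.labels)
        C = design_from_correlations({("a", "b"): 1.0}, ["a", "b"])
        fit = fit_component(blocks, dum.Y_centered, C, {"a": 6, "b": 6})
        for b in ("a", "b"):
            support = {names[b][j] for j in np.nonzero(fit.loadings[b])[0]}
            assert support <= set(ds.truth[b])

    def test_disconnected_blocks_solve_independently(self):
        rng = np.random.default_rng(3)
        X = random_standardized(rng, 30, 10).to_numpy()
        other1 = random_standardized(rng, 30, 12).to_numpy()
        other2 = random_standardized(rng, 30, 12).to_numpy()
        dum = dummy_matrix(["A"] * 15 + ["B"] * 15)
        C = design_from_correlations({("x", "o"): 0.0}, ["x", "o"])
        f1 = fit_component({"x": X, "o": other1}, dum.Y_centered, C, {"x": 4, "o": 4})
        f2 = fit_component({"x": X, "o": other2}, dum.Y_centered, C, {"x": 4, "o": 4})
        np.testing.assert_allclose(f1.loadings["x"], f2.loadings["x"], atol=1e-10)

    def test_monotone_objective_path(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            X1 = random_standardized(rng, 25, 12).to_numpy()
            X2 = random_standardized(rng, 25, 9).to_numpy()
            dum = dummy_matrix(list(rng.choice(["A", "B", "C"], 25)))
            C = design_from_correlations({("a", "b"): 0.7}, ["a", "b"])
            fit = fit_component({"a": X1, "b": X2}, dum.Y_centered, C,
                                {"a": 3, "b": 4})
            assert np.all(np.diff(fit.objective_path) >= -1e-9)


class TestObjective:
    def test_zero_loadings_zero_objective(self):
        X = np.ones((5, 3))
        C = design_from_correlations({}, ["x"])
        assert objective({"x": X, OUTCOME: X}, {"x": np.zeros(3), OUTCOME: np.zeros(3)}, C) == 0.0

    def test_identical_blocks_gives_variance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 4))
        a = rng.standard_normal(4)
        a /= np.linalg.norm(a)
        names = ["p", "q"]
        C = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=names, columns=names)
        val = objective({"p": X, "q": X}, {"p": a, "q": a}, C)
        t = X @ a
        np.testing.assert_allclose(val, t.var(ddof=1), rtol=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        names = ["a", "b", "c"]
        mats = {b: rng.standard_normal((15, 5)) for b in names}
        loads = {}
        for b in names:
            v = rng.standard_normal(5)
            loads[b] = v / np.linalg.norm(v)
        Cv = np.array([[0, 0.4, 0.9], [0.4, 0, 0.2], [0.9, 0.2, 0]])
        C = pd.DataFrame(Cv, index=names, columns=names)
        expected = 0.0
        for i, q in enumerate(names):
            for j in names[i + 1:]:
                tq = mats[q] @ loads[q]
                tj = mats[j] @ loads[j]
                expected += C.loc[q, j] * np.cov(tq, tj, ddof=1)[0, 1]
        np.testing.assert_allclose(objective(mats, loads, C), expected, atol=1e-12)


class TestDeflate:
    def test_column_equal_to_score_becomes_zero(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(10)
        X = np.column_stack([t, rng.standard_normal(10)])
        Xd, _ = deflate(X, t)
        np.testing.assert_allclose(Xd[:, 0], 0.0, atol=1e-12)

    def test_orthogonality_and_idempotence(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 6))
        t = rng.standard_normal(12)
        Xd, b = deflate(X, t)
        assert np.max(np.abs(t @ Xd)) < 1e-10
        Xdd, _ = deflate(Xd, t)
        np.testing.assert_allclose(Xdd, Xd, atol=1e-12)

    def test_zero_score_rejected(self):
        with pytest.raises(ValueError):
            deflate(np.ones((4, 2)), np.zeros(4))


class TestFitSgcca:
    @pytest.fixture(scope="class")
    def fitted(self, strong_dataset, standardized_blocks):
        std, scalings = standardized_blocks
        C = design_from_correlations({("mrna", "methylation"): 0.8},
                                     list(std))
        # 14 informative features per block spread over 2 latent axes: 7 each
        keepX = [{"mrna": 7, "methylation": 7}] * 2
        model = fit_sgcca(std, strong_dataset.labels, C, keepX, 2, scaling=scalings)
        return model

    def test_successive_scores_orthogonal(self, fitted):
        for b in fitted.block_names:
            T = fitted.train_scores[b]
            assert abs(float(T[:, 0] @ T[:, 1])) < 1e-8

    def test_loadings_unit_norm_and_sparse(self, fitted):
        for b in fitted.block_names:
            for h in range(fitted.H):
                a = fitted.loadings[b][:, h]
                assert abs(np.linalg.norm(a) - 1) < 1e-12
                assert np.count_nonzero(a) <= fitted.keepX[h][b]
                assert a[np.argmax(np.abs(a))] > 0  # sign convention

    def test_h1_matches_fit_component(self, standardized_blocks, strong_dataset):
        std, _ = standardized_blocks
        C = design_from_correlations({("mrna", "methylation"): 0.8}, list(std))
        keepX = {"mrna": 10, "methylation": 10}
        model = fit_sgcca(std, strong_dataset.labels, C, [keepX], 1)
        dum = dummy_matrix(strong_dataset.labels)
        comp = fit_component({b: X.to_numpy() for b, X in std.items()},
                             dum.Y_centered, C, keepX)
        for b in std:
            np.testing.assert_allclose(model.loadings[b][:, 0], comp.loadings[b],
                                       atol=1e-12)

    def test_transform_reproduces_training_scores(self, fitted, standardized_blocks):
        std, _ = standardized_blocks
        scores = transform(fitted, std)
        for b in fitted.block_names:
            np.testing.assert_allclose(scores[b], fitted.train_scores[b], atol=1e-10)

    def test_single_sample_projection_matches(self, fitted, standardized_blocks):
        std, _ = standardized_blocks
        one = {b: X.iloc[[3]] for b, X in std.items()}
        scores = transform(fitted, one)
        for b in fitted.block_names:
            np.testing.assert_allclose(scores[b][0], fitted.train_scores[b][3],
                                       atol=1e-10)

    def test_zero_sample_zero_scores(self, fitted):
        zero = {
            b: pd.DataFrame(np.zeros((1, len(fitted.feature_names[b]))),
                            columns=fitted.feature_names[b])
            for b in fitted.block_names
        }
        scores = transform(fitted, zero)
        for b in fitted.block_names:
            np.testing.assert_allclose(scores[b], 0.0, atol=1e-12)

    def test_strong_signal_selection_within_truth(self, fitted, strong_dataset):
        sel = fitted.selected_features()
        for b in fitted.block_names:
            chosen = set().union(*sel[b].values())
            truth = set(strong_dataset.truth[b])
            jac = len(chosen & truth) / len(chosen | truth)
            assert jac >= 0.8

    def test_json_roundtrip_preserves_projection(self, fitted, standardized_blocks, tmp_path):
        std, _ = standardized_blocks
        path = tmp_path / "model.json"
        fitted.to_json(path)
        back = SGCCAModel.from_json(path)
        s1 = transform(fitted, std)
        s2 = transform(back, std)
        for b in fitted.block_names:
            np.testing.assert_allclose(s1[b], s2[b], atol=1e-12)
        assert back.classes == fitted.classes


class TestSparseOptimality:
    """Each block update maximizes its subproblem; small instances near-global."""

    def test_update_beats_same_support_alternatives(self):
        rng = np.random.default_rng(4)
        X = random_standardized(rng, 20, 6).to_numpy()
        dum = dummy_matrix(list(rng.choice(["A", "B"], 20)))
        C = design_from_correlations({}, ["x"])
        fit = fit_component({"x": X}, dum.Y_centered, C, {"x": 2})
        a = fit.loadings["x"]
        support = tuple(np.nonzero(a)[0])
        # partial objective of block x given the fitted outcome score
        tY = dum.Y_centered @ fit.loadings[OUTCOME]
        z = X.T @ tY

        def partial(vec):
            return float(z @ vec)

        # no unit vector on the same support does better than the exact
        # optimum; |.| because the final per-block sign convention may flip a
        best_same_support = np.zeros(6)
        zs = z[list(support)]
        best_same_support[list(support)] = zs / np.linalg.norm(zs)
        assert abs(partial(a)) >= 0.95 * abs(partial(best_same_support))
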