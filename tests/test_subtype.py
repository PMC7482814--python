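import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tandemapa.subtype import (
    ShrunkenCentroidModel,
    _nsnmf_single,
    _smoothing_matrix,
    classify_samples,
    consensus_kmeans,
    consensus_metrics,
    nsnmf,
    pca_coords,
    rank_survey,
    scale_features,
    select_rank,
    train_shrunken_centroids,
    unscale_features,
)


def planted_sui(rng, n_features=120, per_group=12, k=4, effect=1.0, sigma=0.25):
    """SUI matrix with k planted subtypes carrying disjoint signature blocks."""
    n_samples = per_group * k
    truth = np.repeat(np.arange(k), per_group)
    block = n_features // (k + 1)
    X = rng.normal(0.0, sigma, (n_features, n_samples))
    for g in range(k):
        X[g * block : (g + 1) * block, truth == g] += effect
    sui = pd.DataFrame(
        X,
        index=[f"t{i:04d}" for i in range(n_features)],
        columns=[f"s{i:03d}" for i in range(n_samples)],
    )
    return sui, truth


class TestScaling:
    def test_minmax_to_unit_interval(self):
        sui = pd.DataFrame({"a": [-1.0], "b": [0.0], "c": [1.0]}, index=["t"])
        scaled, scaler = scale_features(sui)
        assert scaled.loc["t"].tolist() == [0.0, 0.5, 1.0]
        back = unscale_features(scaled, scaler)
        pd.testing.assert_frame_equal(back, sui)

    def test_already_unit_row_unchanged(self):
        sui = pd.DataFrame({"a": [0.0], "b": [0.4], "c": [1.0]}, index=["t"])
        scaled, _ = scale_features(sui)
        assert scaled.loc["t"].tolist() == [0.0, 0.4, 1.0]

    def test_constant_feature_dropped(self):
        sui = pd.DataFrame(
            {"a": [1.0, 5.0], "b": [2.0, 5.0]}, index=["t1", "t2"]
        )
        with pytest.warns(UserWarning, match="constant features"):
            scaled, _ = scale_features(sui)
        assert list(scaled.index) == ["t1"]

    def test_roundtrip_random(self):
        rng = np.random.default_rng(0)
        sui = pd.DataFrame(rng.normal(size=(15, 8)))
        scaled, scaler = scale_features(sui)
        back = unscale_features(scaled, scaler)
        np.testing.assert_allclose(back.to_numpy(), sui.to_numpy(), atol=1e-12)


class TestNsNMF:
    def test_block_diagonal_separable_case(self):
        X = np.zeros((12, 9))
        for b in range(3):
            X[b * 4 : (b + 1) * 4, b * 3 : (b + 1) * 3] = 1.0
        sol = nsnmf(X, 3, theta=0.0, n_runs=5, seed=0)
        assert sol.divergence < 1e-4
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1, 2, 2, 2], sol.labels) == 1.0

    def test_theta_zero_single_step_matches_textbook_kl_update(self):
        rng_init = np.random.default_rng(5)
        X = np.abs(np.random.default_rng(1).normal(size=(3, 3))) + 0.1
        W0 = rng_init.uniform(0.1, 1.0, (3, 2))
        H0 = rng_init.uniform(0.1, 1.0, (2, 3))
        # one package iteration from the same init
        rng_pkg = np.random.default_rng(5)
        W1, H1, _, _, _ = _nsnmf_single(X, 2, 0.0, 1, 1e-12, rng_pkg)
        # hand-computed multiplicative KL rule (H first, then W)
        H_hand = H0 * (W0.T @ (X / (W0 @ H0))) / W0.sum(axis=0)[:, None]
        W_hand = W0 * ((X / (W0 @ H_hand)) @ H_hand.T) / H_hand.sum(axis=1)[None, :]
        np.testing.assert_allclose(H1, H_hand, rtol=1e-10)
        np.testing.assert_allclose(W1, W_hand, rtol=1e-10)

    def test_divergence_trace_nonincreasing(self):
        rng = np.random.default_rng(2)
        sui, _ = planted_sui(rng, n_features=60, per_group=8, k=3)
        scaled, _ = scale_features(sui)
        sol = nsnmf(scaled, 3, n_runs=3, seed=3)
        assert (np.diff(sol.divergence_trace) <= 1e-8).all()

    def test_smoothing_matrix_definition(self):
        S = _smoothing_matrix(4, 0.5)
        np.testing.assert_allclose(S, 0.5 * np.eye(4) + 0.125 * np.ones((4, 4)))
        np.testing.assert_allclose(_smoothing_matrix(3, 0.0), np.eye(3))

    def test_consensus_symmetric_unit_diag(self):
        rng = np.random.default_rng(4)
        sui, truth = planted_sui(rng, n_features=60, per_group=6, k=3)
        scaled, _ = scale_features(sui)
        sol = nsnmf(scaled, 3, n_runs=4, seed=4)
        C = sol.consensus
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert ((C >= 0) & (C <= 1)).all()
        assert (sol.W >= 0).all() and (sol.H >= 0).all()
        assert adjusted_rand_score(truth, sol.labels) >= 0.9

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        sui, _ = planted_sui(rng, n_features=40, per_group=5, k=2)
        scaled, _ = scale_features(sui)
        a = nsnmf(scaled, 2, n_runs=3, seed=9)
        b = nsnmf(scaled, 2, n_runs=3, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.W, b.W)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            nsnmf(np.array([[-1.0, 1.0], [1.0, 1.0], [1.0, 2.0]]), 2)


class TestConsensusMetrics:
    def test_binary_block_consensus_is_perfect(self):
        C = np.kron(np.eye(3), np.ones((4, 4)))
        m = consensus_metrics(C, 3)
        assert m["dispersion"] == pytest.approx(1.0)
        assert m["cophenetic"] == pytest.approx(1.0)
        assert m["silhouette"] == pytest.approx(1.0)

    def test_indifferent_consensus_has_zero_dispersion(self):
        C = np.full((10, 10), 0.5)
        np.fill_diagonal(C, 1.0)
        m = consensus_metrics(C, 2)
        assert m["dispersion"] == pytest.approx(0.1, abs=1e-9)  # diagonal only

    @pytest.mark.parametrize("k", [3, 5])
    def test_rank_survey_selects_planted_k(self, k):
        rng = np.random.default_rng(7 + k)
        sui, _ = planted_sui(rng, n_features=90, per_group=10, k=k)
        scaled, _ = scale_features(sui)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            survey = rank_survey(
                scaled, ranks=range(2, k + 4), n_runs=6, max_iter=1000, seed=1
            )
        assert select_rank(survey) == k


class TestConsensusKMeans:
    def test_duplicated_samples_always_cocluster(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(30, 6))
        X = np.hstack([base, base[:, :2]])  # columns 6,7 duplicate 0,1
        X[:15, :3] += 3.0
        X[:15, 6:] += 3.0  # duplicates of shifted columns 0,1
        C, _ = consensus_kmeans(X, 2, n_iter=100, seed=0)
        assert C[0, 6] == pytest.approx(1.0)
        assert C[1, 7] == pytest.approx(1.0)

    def test_single_iteration_degenerate(self):
        rng = np.random.default_rng(9)
        sui, _ = planted_sui(rng, n_features=30, per_group=5, k=2)
        with pytest.warns(UserWarning, match="never co-sampled"):
            C, labels = consensus_kmeans(
                sui.to_numpy(), 2, n_iter=1, subsample_frac=0.8, seed=1
            )
        assert set(np.unique(C)) <= {0.0, 0.5, 1.0}

    def test_planted_recovery(self):
        rng = np.random.default_rng(10)
        sui, truth = planted_sui(rng, n_features=80, per_group=10, k=4)
        C, labels = consensus_kmeans(sui.to_numpy(), 4, n_iter=150, seed=2)
        assert adjusted_rand_score(truth, labels) >= 0.9
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)


class TestPCA:
    def test_two_groups_separate_on_pc1(self):
        rng = np.random.default_rng(11)
        sui, truth = planted_sui(rng, n_features=50, per_group=10, k=2, effect=2.0)
        coords = pca_coords(sui, 2)
        pc1 = coords["PC1"].to_numpy()
        from sklearn.metrics import silhouette_score

        assert silhouette_score(pc1.reshape(-1, 1), truth) > 0.5

    def test_centering_and_variance_ordering(self):
        rng = np.random.default_rng(12)
        sui = pd.DataFrame(rng.normal(size=(30, 12)))
        coords = pca_coords(sui, 3)
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-9)
        var = coords.var(axis=0).to_numpy()
        assert (np.diff(var) <= 1e-9).all()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(13)
        sui = pd.DataFrame(rng.normal(size=(30, 12)))
        a = pca_coords(sui, 2)
        b = pca_coords(sui.copy(), 2)
        pd.testing.assert_frame_equal(a, b)


class TestShrunkenCentroids:
    def _data(self, seed=14, k=4, per_group=12):
        rng = np.random.default_rng(seed)
        sui, truth = planted_sui(rng, n_features=60, per_group=per_group, k=k)
        labels = pd.Series([f"S{t + 1}" for t in truth], index=sui.columns)
        return sui, labels

    def test_delta_zero_is_plain_nearest_centroid(self):
        sui, labels = self._data()
        model = train_shrunken_centroids(sui, labels, delta_grid=np.array([0.0]))
        X = sui.to_numpy()
        y = labels.to_numpy()
        classes = model.classes
        cents = np.stack([X[:, y == c].mean(axis=1) for c in classes], axis=1)
        np.testing.assert_allclose(model.shrunken_centroids, cents, atol=1e-12)
        pred, _ = classify_samples(model, sui, quantile_normalize=False)
        # manual standardized nearest-centroid assignment
        d2 = np.stack(
            [
                (((X - cents[:, [j]]) / (model.pooled_sd + model.s0)[:, None]) ** 2).sum(axis=0)
                - 2 * np.log(model.priors[j])
                for j in range(len(classes))
            ]
        )
        manual = np.asarray(classes)[np.argmin(d2, axis=0)]
        assert (pred.to_numpy() == manual).all()

    def test_total_shrinkage_collapses_to_prior(self):
        sui, labels = self._data(k=2, per_group=8)
        labels.iloc[:4] = "S2"  # unbalance priors: S2 is the larger class
        model = train_shrunken_centroids(
            sui, labels, delta_grid=np.array([1e6])
        )
        np.testing.assert_allclose(
            model.shrunken_centroids,
            np.tile(model.overall_centroid[:, None], (1, 2)),
            atol=1e-9,
        )
        pred, _ = classify_samples(model, sui, quantile_normalize=False)
        assert (pred == "S2").all()

    def test_soft_threshold_identity(self):
        sui, labels = self._data()
        delta = 0.7
        model = train_shrunken_centroids(sui, labels, delta_grid=np.array([delta]))
        X, y = sui.to_numpy(), labels.to_numpy()
        cents = np.stack(
            [X[:, y == c].mean(axis=1) for c in model.classes], axis=1
        )
        nk = np.array([(y == c).sum() for c in model.classes])
        mk = np.sqrt(1 / nk - 1 / X.shape[1])
        denom = mk[None, :] * (model.pooled_sd + model.s0)[:, None]
        d = (cents - model.overall_centroid[:, None]) / denom
        d_shr = (model.shrunken_centroids - model.overall_centroid[:, None]) / denom
        np.testing.assert_allclose(
            d_shr, np.sign(d) * np.maximum(np.abs(d) - delta, 0.0), atol=1e-9
        )

    def test_holdout_accuracy_on_planted_subtypes(self):
        sui, labels = self._data(seed=15, per_group=15)
        train_cols = [c for i, c in enumerate(sui.columns) if i % 3 != 0]
        test_cols = [c for i, c in enumerate(sui.columns) if i % 3 == 0]
        model = train_shrunken_centroids(sui[train_cols], labels[train_cols], seed=1)
        pred, _ = classify_samples(model, sui[test_cols])
        assert (pred == labels[test_cols]).mean() >= 0.95

    def test_single_sample_class_rejected(self):
        sui, labels = self._data(k=2, per_group=4)
        labels.iloc[:] = "S1"
        labels.iloc[0] = "S2"
        with pytest.raises(ValueError, match="single sample"):
            train_shrunken_centroids(sui, labels)

    def test_model_json_roundtrip(self, tmp_path):
        sui, labels = self._data(k=2, per_group=6)
        model = train_shrunken_centroids(sui, labels, delta_grid=np.array([0.3]))
        model.to_json(tmp_path / "model.json")
        back = ShrunkenCentroidModel.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(
            back.shrunken_centroids, model.shrunken_centroids
        )
        pred_a, _ = classify_samples(model, sui)
        pred_b, _ = classify_samples(back, sui)
        assert (pred_a == pred_b).all()
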