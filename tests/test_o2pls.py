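"""Preprocessing and the O2PLS decomposition against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from hcmomics import synthio
from hcmomics.o2pls import (
    O2PLS,
    filter_low_counts,
    fit_o2pls,
    log_quantile_normalize,
    match_samples,
)


def frame(arr, prefix_r="S", prefix_c="F"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr,
                        index=[f"{prefix_r}{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix_c}{j}" for j in range(arr.shape[1])])


class TestFilterLowCounts:
    def test_well_expressed_feature_retained(self):
        m = frame(np.full((23, 3), 10))
        assert filter_low_counts(m).shape[1] == 3

    def test_all_zero_feature_removed_at_defaults(self):
        m = frame(np.full((23, 2), 50))
        m["F1"] = 0
        out = filter_low_counts(m)
        assert list(out.columns) == ["F0"]

    def test_planted_low_count_features_removed_exactly(self, rng):
        """23x100 with 40 planted low-count features vs a per-feature check."""
        counts = rng.integers(20, 200, size=(23, 100))
        low = rng.choice(100, size=40, replace=False)
        for j in low:
            n_fail = rng.integers(22, 24)       # fails in 22 or 23 samples
            rows = rng.choice(23, size=n_fail, replace=False)
            counts[:, j] = 15
            counts[rows, j] = rng.integers(0, 10)
        m = frame(counts)
        out = filter_low_counts(m)
        # brute-force per-feature oracle
        expected = [c for j, c in enumerate(m.columns)
                    if (counts[:, j] < 10).sum() < 22]
        assert list(out.columns) == expected
        assert set(m.columns[sorted(low)]).isdisjoint(out.columns)

    def test_min_failing_samples_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            filter_low_counts(frame(np.ones((5, 3))), min_failing_samples=6)


class TestMatchSamples:
    def test_intersection_in_x_order(self):
        X = frame(np.arange(9).reshape(3, 3))
        X.index = ["a", "b", "c"]
        Y = frame(np.arange(12).reshape(4, 3))
        Y.index = ["d", "c", "b", "e"]
        Xm, Ym = match_samples(X, Y)
        assert list(Xm.index) == ["b", "c"] and list(Ym.index) == ["b", "c"]

    def test_identical_sets_unchanged(self):
        X = frame(np.ones((3, 2)))
        Y = frame(np.ones((3, 4)))
        Xm, Ym = match_samples(X, Y)
        assert list(Xm.index) == list(X.index) == list(Ym.index)

    def test_shuffled_rows_realigned_by_label(self, rng):
        X = frame(rng.normal(size=(6, 3)))
        Y = frame(rng.normal(size=(6, 4)))
        Ys = Y.sample(frac=1, random_state=0)
        Xm, Ym = match_samples(X, Ys)
        assert list(Xm.index) == list(Ym.index)
        pd.testing.assert_frame_equal(Ym, Y.loc[Ym.index])

    def test_empty_intersection_rejected(self):
        X = frame(np.ones((2, 2)))
        Y = frame(np.ones((2, 2)))
        Y.index = ["q1", "q2"]
        with pytest.raises(ValueError):
            match_samples(X, Y)


class TestLogQuantileNormalize:
    def test_identical_samples_unchanged_by_quantile_step(self):
        row = np.array([3.0, 0.0, 7.0, 1.0])
        m = frame(np.tile(row, (4, 1)))
        out = log_quantile_normalize(m)
        assert np.allclose(out.to_numpy(), np.log1p(np.tile(row, (4, 1))))

    def test_sorted_rows_identical_after_normalization(self, rng):
        m = frame(rng.integers(0, 500, size=(9, 40)))
        out = log_quantile_normalize(m).to_numpy()
        sorted_rows = np.sort(out, axis=1)
        assert np.allclose(sorted_rows, sorted_rows[0])

    def test_within_sample_rank_order_preserved(self, rng):
        m = frame(rng.integers(0, 500, size=(6, 30)))
        out = log_quantile_normalize(m)
        for i in range(6):
            a = m.iloc[i].to_numpy()
            b = out.iloc[i].to_numpy()
            assert (np.diff(b[np.argsort(a, kind="stable")]) >= 0).all()

    def test_matches_sort_average_reassign_oracle(self, rng):
        m = frame(rng.integers(0, 1000, size=(23, 500)))
        out = log_quantile_normalize(m).to_numpy()
        logged = np.log1p(m.to_numpy().astype(float))
        mean_sorted = np.sort(logged, axis=1).mean(axis=0)
        oracle = np.empty_like(logged)
        for i in range(logged.shape[0]):
            order = np.argsort(logged[i], kind="stable")
            oracle[i, order] = mean_sorted
        assert np.allclose(out, oracle)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log_quantile_normalize(frame(np.array([[1.0, -2.0]])))


class TestFit:
    def test_loadings_match_direct_svd_oracle(self):
        from hcmomics.studies import o2pls_svd_oracle

        res = o2pls_svd_oracle(n=24, p=200, q=300, r=3, seed=0)
        assert res["max_loading_dev"] < 1e-8
        assert res["orthonormality_defect"] < 1e-10
        assert res["reconstruction_defect"] < 1e-10

    def test_x_equals_y_symmetry(self, rng):
        X = frame(rng.normal(size=(10, 20)))
        res = fit_o2pls(X, X.copy(), r=1)
        assert np.allclose(res.T.to_numpy(), res.U.to_numpy())
        r, _ = pearsonr(res.T.iloc[:, 0], res.U.iloc[:, 0])
        assert r == pytest.approx(1.0)

    def test_scores_are_projections_without_specific_parts(self, rng):
        X = frame(rng.normal(size=(12, 15)))
        Y = frame(rng.normal(size=(12, 18)))
        res = fit_o2pls(X, Y, r=2)
        Xc = X.to_numpy() - X.to_numpy().mean(0)
        Yc = Y.to_numpy() - Y.to_numpy().mean(0)
        assert np.allclose(res.T.to_numpy(), Xc @ res.W.to_numpy())
        assert np.allclose(res.U.to_numpy(), Yc @ res.C.to_numpy())

    def test_residual_norm_non_increasing_in_r(self, rng):
        X = frame(rng.normal(size=(15, 30)))
        Y = frame(rng.normal(size=(15, 25)))
        norms = []
        for r in (1, 2, 3, 4):
            res = fit_o2pls(X, Y, r=r)
            norms.append(np.linalg.norm(res.residual_x.to_numpy()))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_specific_components_orthogonal_to_joint_scores(self, rng):
        X = frame(rng.normal(size=(16, 40)))
        Y = frame(rng.normal(size=(16, 30)))
        res = fit_o2pls(X, Y, r=1, nx=2, ny=1)
        cross = res.T.to_numpy().T @ res.T_x_specific.to_numpy()
        assert np.max(np.abs(cross)) < 1e-8
        # reconstruction identity still exact with specific parts
        Xc = X.to_numpy() - X.to_numpy().mean(0)
        recon = (res.T.to_numpy() @ res.W.to_numpy().T
                 + res.T_x_specific.to_numpy() @ res.P_x_specific.to_numpy().T
                 + res.residual_x.to_numpy())
        assert np.allclose(Xc, recon)

    def test_two_runs_bit_identical(self, rng):
        X = frame(rng.normal(size=(12, 20)))
        Y = frame(rng.normal(size=(12, 22)))
        a = fit_o2pls(X, Y, r=2)
        b = fit_o2pls(X, Y, r=2)
        assert (a.W.to_numpy() == b.W.to_numpy()).all()
        assert (a.T.to_numpy() == b.T.to_numpy()).all()
        # copies may differ only at floating-point noise level
        c = fit_o2pls(X.copy(), Y.copy(), r=2)
        assert np.allclose(a.W.to_numpy(), c.W.to_numpy(), atol=1e-12)

    def test_sign_convention_largest_entry_positive(self, rng):
        X = frame(rng.normal(size=(10, 12)))
        Y = frame(rng.normal(size=(10, 14)))
        res = fit_o2pls(X, Y, r=2)
        for mat in (res.W, res.C):
            arr = mat.to_numpy()
            for k in range(arr.shape[1]):
                assert arr[np.argmax(np.abs(arr[:, k])), k] > 0

    def test_invalid_requests_rejected(self, rng):
        X = frame(rng.normal(size=(8, 5)))
        Y = frame(rng.normal(size=(8, 10)))
        with pytest.raises(ValueError, match="rank"):
            fit_o2pls(X, Y, r=6)
        X = frame(rng.normal(size=(8, 10)))
        Y = frame(rng.normal(size=(8, 10)))
        Ybad = Y.copy()
        Ybad.index = [f"Q{i}" for i in range(8)]
        with pytest.raises(ValueError, match="same samples"):
            O2PLS(X, Ybad)
        with pytest.raises(ValueError, match="smaller than the sample count"):
            O2PLS(X, Y, n_joint=4, n_x_specific=4)

    def test_recovers_planted_joint_factor(self, small_omics):
        """|correlation| between fitted joint score 1 and the planted factor
        exceeds 0.95 at group effect 2."""
        X, Y, truth = small_omics
        Xn = log_quantile_normalize(X)
        Yn = log_quantile_normalize(Y)
        res = fit_o2pls(Xn, Yn, r=1)
        r, _ = pearsonr(res.T.iloc[:, 0], truth.factor_scores.iloc[:, 0])
        assert abs(r) > 0.95


class TestRankFeatures:
    @pytest.fixture(scope="class")
    def toy_results(self):
        X = frame(np.eye(4, 6))
        Y = frame(np.eye(4, 5))
        res = fit_o2pls(X, Y, r=1)
        return res

    def test_magnitude_ordering_with_signs(self, rng):
        X = frame(rng.normal(size=(8, 10)))
        Y = frame(rng.normal(size=(8, 3)))
        res = fit_o2pls(X, Y, r=1)
        res.C.iloc[:, 0] = [0.9, -0.95, 0.1]
        ranked = res.rank_features(side="Y", k=2)
        assert list(ranked["feature"]) == ["F1", "F0"]
        assert list(ranked["rank"]) == [1, 2]

    def test_ties_break_lexicographically(self, rng):
        X = frame(rng.normal(size=(8, 10)))
        Y = frame(rng.normal(size=(8, 4)))
        res = fit_o2pls(X, Y, r=1)
        res.C.iloc[:, 0] = [0.5, -0.5, 0.5, -0.5]
        ranked = res.rank_features(side="Y", k=4)
        assert list(ranked["feature"]) == ["F0", "F1", "F2", "F3"]

    def test_k_exceeding_feature_count_warns_returns_all(self, rng):
        X = frame(rng.normal(size=(8, 10)))
        Y = frame(rng.normal(size=(8, 4)))
        res = fit_o2pls(X, Y, r=1)
        with pytest.warns(UserWarning, match="returning all"):
            ranked = res.rank_features(side="Y", k=100)
        assert len(ranked) == 4

    def test_planted_high_loading_features_rank_top(self, small_omics):
        """The 20 largest planted loadings all appear within the top 40."""
        X, Y, truth = small_omics
        res = fit_o2pls(log_quantile_normalize(X), log_quantile_normalize(Y), r=1)
        planted = truth.loadings_y.iloc[:, 0].abs().sort_values(ascending=False)
        top_true = set(planted.index[:20])
        ranked = res.rank_features(side="Y", k=40)
        assert top_true <= set(ranked["feature"])


class TestSeparation:
    def test_strong_effect_gives_perfect_separation(self):
        X, Y, truth = synthio.simulate_multiomics(
            n_samples=24, p_regions=150, q_genes=100, group_effect=4.0,
            n_de=0, seed=21)
        res = fit_o2pls(log_quantile_normalize(X), log_quantile_normalize(Y), r=1)
        rep = res.separation(truth.group_labels)
        row = rep[(rep["side"] == "T") & (rep["component"] == "joint1")].iloc[0]
        assert row["separable"]
        assert row["auc_oriented"] == pytest.approx(1.0)

    def test_constant_scores_auc_half(self, rng):
        X = frame(rng.normal(size=(10, 12)))
        Y = frame(rng.normal(size=(10, 11)))
        res = fit_o2pls(X, Y, r=1)
        res.T.iloc[:, 0] = 1.0
        res.U.iloc[:, 0] = 1.0
        rep = res.separation(["case"] * 5 + ["control"] * 5)
        assert (rep["auc"] == 0.5).all()
        assert not rep["separable"].any()

    def test_single_class_rejected(self, rng):
        X = frame(rng.normal(size=(6, 8)))
        res = fit_o2pls(X, X.copy(), r=1)
        with pytest.raises(ValueError, match="two group"):
            res.separation(["case"] * 6)

    def test_summary_mentions_components(self, rng):
        X = frame(rng.normal(size=(8, 9)))
        Y = frame(rng.normal(size=(8, 7)))
        res = fit_o2pls(X, Y, r=2)
        text = res.summary()
        assert "joint1" in text and "joint2" in text and "residual" in text
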