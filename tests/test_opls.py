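"""OPLS-DA fitting, cross-validated Q², VIP, S-plot and subset validation."""

import numpy as np
import pandas as pd
import pytest

from cyclomet.opls import (
    classify_model,
    cross_validate_q2,
    fit_oplsda,
    permutation_q2,
    s_plot,
    validate_subset,
    vip_scores,
)


def planted_data(n=30, p=100, n_markers=10, effect=3.0, seed=0):
    """Two balanced classes; the first n_markers features carry a shift of
    `effect` standard deviations, the rest are pure noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[y == "A", :n_markers] += effect
    return X, y


class TestFit:
    def test_single_signal_recovery(self):
        # y perfectly separable along feature 0; the rest is faint noise
        rng = np.random.default_rng(1)
        y = np.array(["A", "B"] * 10)
        X = 0.05 * rng.normal(size=(20, 30))
        X[:, 0] = np.where(y == "A", -2.0, 2.0)
        m = fit_oplsda(X, y, n_orth=0)
        assert m.r2y >= 0.99
        assert np.argmax(np.abs(m.w)) == 0

    def test_scores_orthogonality(self):
        X, y = planted_data(seed=2)
        m = fit_oplsda(X, y, n_orth=2)
        for k in range(m.n_orth):
            corr = np.corrcoef(m.t_pred, m.t_orth[k])[0, 1]
            assert abs(corr) < 1e-8

    def test_unit_weight_norms(self):
        X, y = planted_data(seed=3)
        m = fit_oplsda(X, y, n_orth=2)
        assert np.linalg.norm(m.w) == pytest.approx(1.0, abs=1e-10)
        for k in range(m.n_orth):
            assert np.linalg.norm(m.w_orth[k]) == pytest.approx(1.0, abs=1e-10)

    def test_replication_invariance(self):
        X, y = planted_data(n=12, p=20, seed=4)
        m1 = fit_oplsda(X, y, n_orth=1)
        m2 = fit_oplsda(np.vstack([X, X]), np.concatenate([y, y]), n_orth=1)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-10)

    def test_errors(self):
        X, y = planted_data(n=10, p=5, seed=5)
        with pytest.raises(ValueError):
            fit_oplsda(X, np.repeat("A", 10))  # single class
        with pytest.raises(ValueError):
            fit_oplsda(X, y, n_orth=-1)
        with pytest.raises(ValueError):
            fit_oplsda(X, y, n_orth=8)  # >= n-2
        with pytest.raises(ValueError):
            fit_oplsda(X[:3], y[:3])  # n < 4

    def test_matches_reference_pls_first_component(self):
        """With no orthogonal components the predictive scores equal the
        first component of a reference NIPALS PLS (up to sign/scale)."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(7)
        for seed in range(3):
            X, y = planted_data(n=24, p=40, n_markers=5, effect=2.0, seed=seed)
            m = fit_oplsda(X, y, n_orth=0)
            yc = np.where(y == "A", -1.0, 1.0)
            pls = sklearn.PLSRegression(n_components=1, scale=False).fit(X, yc - yc.mean())
            t_ref = pls.x_scores_.ravel()
            cosine = abs(m.t_pred @ t_ref) / (np.linalg.norm(m.t_pred) * np.linalg.norm(t_ref))
            assert cosine > 0.9999


class TestQ2:
    def test_strong_structure_highly_significant(self):
        q2s = [
            cross_validate_q2(*planted_data(n=30, p=50, n_markers=10, effect=3.0, seed=s), seed=s)
            for s in range(15)
        ]
        assert np.median(q2s) > 0.7

    def test_noise_is_invalid_even_when_training_fit_is_high(self):
        r2ys, q2s = [], []
        for s in range(25):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(30, 100))
            y = np.array(["A", "B"] * 15)
            r2ys.append(fit_oplsda(X, y, n_orth=1).r2y)
            q2s.append(cross_validate_q2(X, y, n_orth=1, seed=s))
        assert np.median(r2ys) > 0.8  # overfit in training...
        assert np.median(q2s) <= 0.4  # ...but invalid under cross-validation

    def test_permuted_labels_fail(self):
        X, y = planted_data(n=30, p=50, n_markers=10, effect=3.0, seed=9)
        rng = np.random.default_rng(9)
        q2s = [cross_validate_q2(X, y[rng.permutation(30)], seed=s) for s in range(9)]
        assert np.median(q2s) < 0.4

    def test_q2_bounded_by_one_and_r2y(self):
        for seed in range(3):
            X, y = planted_data(n=28, p=30, n_markers=8, effect=2.5, seed=seed)
            q2 = cross_validate_q2(X, y, seed=seed)
            r2y = fit_oplsda(X, y, n_orth=1).r2y
            assert q2 <= 1.0
            assert q2 <= r2y + 1e-6

    def test_fold_stratification_limit(self):
        X, y = planted_data(n=10, p=5, seed=1)  # 5 per class
        with pytest.raises(ValueError, match="stratify"):
            cross_validate_q2(X, y, folds=7)

    def test_deterministic_in_seed(self):
        X, y = planted_data(seed=12)
        assert cross_validate_q2(X, y, seed=5) == cross_validate_q2(X, y, seed=5)


class TestVip:
    def test_normalization_sum_of_squares_equals_p(self):
        for seed in range(4):
            X, y = planted_data(n=20, p=37, seed=seed)
            m = fit_oplsda(X, y, n_orth=1)
            vip = vip_scores(m)
            assert float((vip["vip"] ** 2).sum()) == pytest.approx(37, abs=1e-6)

    def test_informative_feature_tops_ranking(self):
        X, y = planted_data(n=30, p=100, n_markers=1, effect=3.0, seed=21)
        m = fit_oplsda(X, y, n_orth=1)
        vip = vip_scores(m, feature_ids=[f"F{i}" for i in range(100)])
        assert vip.index[0] == "F0"
        assert vip["vip"].iloc[0] > 0.7

    def test_identical_features_all_unit_vip(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=30)
        X = np.tile(col[:, None], (1, 8))
        y = np.array(["A", "B"] * 15)
        m = fit_oplsda(X, y, n_orth=0)
        vip = vip_scores(m)
        np.testing.assert_allclose(vip["vip"].to_numpy(), 1.0, atol=1e-8)

    def test_tie_break_by_mz(self):
        X, y = planted_data(n=20, p=4, n_markers=0, seed=2)
        X[:, 2] = X[:, 1]  # identical weights -> tie
        m = fit_oplsda(X, y, n_orth=0)
        vip = vip_scores(m, mz=[400.0, 300.0, 200.0, 100.0])
        tied = vip.loc[vip.index.isin([1, 2])]
        assert list(tied["mz"]) == sorted(tied["mz"])  # lower m/z ranked first


class TestSPlot:
    def test_bounds_and_signs(self):
        X, y = planted_data(n=30, p=60, n_markers=5, effect=2.0, seed=8)
        m = fit_oplsda(X, y, n_orth=1)
        sp = s_plot(m, X)
        assert sp["pcorr1"].between(-1, 1).all()
        nz = sp[(sp["p1"] != 0) & (sp["pcorr1"] != 0)]
        assert (np.sign(nz["p1"]) == np.sign(nz["pcorr1"])).all()

    def test_informative_features_at_extremes(self):
        X, y = planted_data(n=30, p=60, n_markers=5, effect=3.0, seed=8)
        m = fit_oplsda(X, y, n_orth=1)
        sp = s_plot(m, X, feature_ids=[f"F{i}" for i in range(60)])
        extreme = set(sp["pcorr1"].abs().nlargest(5).index)
        assert extreme == {"F0", "F1", "F2", "F3", "F4"}

    def test_zero_variance_flagged(self):
        X, y = planted_data(n=20, p=5, seed=4)
        X[:, 3] = 2.5
        m = fit_oplsda(X, y, n_orth=0)
        sp = s_plot(m, X).sort_index()
        assert bool(sp.loc[3, "zero_variance"])
        assert sp.loc[3, "pcorr1"] == 0.0


class TestClassifyModel:
    @pytest.mark.parametrize(
        "q2,verdict",
        [
            (0.615, "valid"),
            (0.778, "highly significant"),
            (0.40, "invalid"),  # boundary is strict
            (0.70, "valid"),
            (-0.2, "invalid"),
        ],
    )
    def test_thresholds(self, q2, verdict):
        assert classify_model(q2) == verdict


class TestValidateSubset:
    def test_planted_markers_give_useful_subset(self):
        X, y = planted_data(n=30, p=200, n_markers=30, effect=3.0, seed=17)
        m = fit_oplsda(X, y, n_orth=1)
        ledger = validate_subset(X, y, vip_scores(m), top_n=30, seed=17)
        rows = ledger.rows.set_index("model")
        assert rows.loc["include_top_vip", "q2"] > 0.7
        assert rows.loc["exclude_top_vip", "q2"] < 0.4
        assert ledger.useful_subset

    def test_pure_noise_subset_not_useful(self):
        flags = []
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(30, 80))
            y = np.array(["A", "B"] * 15)
            m = fit_oplsda(X, y, n_orth=1)
            flags.append(validate_subset(X, y, vip_scores(m), top_n=10, seed=s).useful_subset)
        assert sum(flags) <= 2  # majority of seeds: no useful subset in noise

    def test_degenerate_top_n(self):
        X, y = planted_data(n=20, p=10, seed=3)
        m = fit_oplsda(X, y, n_orth=1)
        with pytest.raises(ValueError):
            validate_subset(X, y, vip_scores(m), top_n=0)
        with pytest.raises(ValueError):
            validate_subset(X, y, vip_scores(m), top_n=10)

    def test_ledger_deterministic(self):
        X, y = planted_data(n=24, p=50, n_markers=10, seed=6)
        m = fit_oplsda(X, y, n_orth=1)
        vip = vip_scores(m)
        l1 = validate_subset(X, y, vip, top_n=10, seed=6)
        l2 = validate_subset(X, y, vip, top_n=10, seed=6)
        pd.testing.assert_frame_equal(l1.rows, l2.rows)
        assert l1.useful_subset == l2.useful_subset


class TestPermutation:
    def test_structured_data_beats_null(self):
        X, y = planted_data(n=30, p=50, n_markers=10, effect=3.0, seed=13)
        observed = cross_validate_q2(X, y, seed=13)
        null = permutation_q2(X, y, n_perm=20, seed=13)
        assert observed > null["p95"]
        assert null["median"] < 0.4

    def test_min_permutations(self):
        X, y = planted_data(seed=1)
        with pytest.raises(ValueError):
            permutation_q2(X, y, n_perm=5)
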