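import numpy as np
import pytest

from ftirchemo import chemometrics as ch
from ftirchemo.preprocess import PretreatmentChain
from ftirchemo.sampling import split as ks_split


class TestPCA:
    def test_rank_one_first_fraction_is_one(self, rng):
        X = np.outer(rng.random(10), rng.random(4))
        _, frac = ch.pca(X, 3)
        assert frac[0] == pytest.approx(1.0, abs=1e-12)

    def test_fractions_match_eigen_oracle(self, rng):
        X = rng.standard_normal((10, 5))
        _, frac = ch.pca(X, 5)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        assert np.allclose(frac, eig / eig.sum(), atol=1e-10)

    def test_scores_have_zero_column_means(self, rng):
        X = rng.standard_normal((12, 6))
        scores, _ = ch.pca(X, 3)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ch.pca(np.ones((1, 3)), 1)


def _two_blob_data(rng, n=30, p=8, gap=10.0):
    X = rng.standard_normal((n, p))
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X[y == "b", 0] += gap
    return X, y


class TestPLSDA:
    def test_separable_classes_train_accuracy_one(self, rng):
        X, y = _two_blob_data(rng)
        _, rep = ch.fit_plsda(X, y, max_components=3)
        assert rep.train_accuracy == 1.0

    def test_r2y_at_least_q2(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((24, 10))
            y = np.array(["a", "b", "c"] * 8)
            _, rep = ch.fit_plsda(X, y, max_components=5)
            assert rep.r2y >= rep.q2 - 1e-10

    def test_one_component_on_rank_one_data_matches_least_squares(self, rng):
        # rank-1 X: PLS with 1 component reproduces the OLS predictions
        u = rng.standard_normal(8)
        v = rng.standard_normal(2)
        X = np.outer(u, v)
        y = np.array(["a", "b"] * 4)
        model, _ = ch.fit_plsda(X, y, n_components=1)
        Y = np.column_stack([(y == "a").astype(float), (y == "b").astype(float)])
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        pred_ols = Xc @ coef + Y.mean(axis=0)
        assert np.allclose(model.predict(X), pred_ols, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        with pytest.raises(ValueError, match="2 classes"):
            ch.fit_plsda(X, np.array(["a"] * 6))

    def test_empty_test_partition_rejected(self, rng):
        X, y = _two_blob_data(rng)
        with pytest.raises(ValueError, match="empty"):
            ch.fit_plsda(X, y, X_test=np.empty((0, 8)), labels_test=np.array([]))

    def test_test_metrics_reported(self, rng):
        X, y = _two_blob_data(rng, n=40)
        sp = ks_split(X, {"cal": 0.7, "test": 0.3})
        _, rep = ch.fit_plsda(
            X[sp["cal"]], y[sp["cal"]],
            X_test=X[sp["test"]], labels_test=y[sp["test"]],
        )
        assert rep.rmsep is not None
        assert rep.test_accuracy == 1.0


class TestVIP:
    def test_sum_of_squares_equals_p(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((20, 12))
            y = np.array(["a", "b"] * 10)
            model, _ = ch.fit_plsda(X, y, max_components=4)
            vip = ch.vip_scores(model)
            assert vip @ vip == pytest.approx(12.0, abs=1e-8)

    def test_informative_variable_has_max_vip(self, rng):
        X = rng.standard_normal((40, 10))
        y = np.array(["a", "b"] * 20)
        X[y == "b", 3] += 5.0
        model, _ = ch.fit_plsda(X, y, max_components=3)
        vip = ch.vip_scores(model)
        assert np.argmax(vip) == 3
        assert vip[3] > 1.0

    def test_one_component_collapse(self, rng):
        X = rng.standard_normal((16, 6))
        y = np.array(["a", "b"] * 8)
        model, _ = ch.fit_plsda(X, y, n_components=1)
        vip = ch.vip_scores(model)
        w = model.x_weights[:, 0]
        expected = np.abs(w) * np.sqrt(6) / np.linalg.norm(w)
        assert np.allclose(vip, expected, atol=1e-10)


class TestPermutationTest:
    def test_separable_beats_all_permutations(self, rng):
        X, y = _two_blob_data(rng, n=24, gap=12.0)
        res = ch.permutation_test(X, y, n_perm=20, max_components=3, seed=5)
        assert np.all(res.permuted_q2 < res.true_q2)
        assert not res.overfit

    def test_noise_flagged_as_overfit(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((30, 20))
        y = np.array(["a", "b", "c"] * 10)
        res = ch.permutation_test(X, y, n_perm=30, max_components=3, seed=6)
        assert res.overfit

    def test_single_permutation(self, rng):
        X, y = _two_blob_data(rng, n=16)
        res = ch.permutation_test(X, y, n_perm=1, max_components=2, seed=0)
        assert res.permuted_q2.shape == (1,)

    def test_zero_perm_rejected(self, rng):
        X, y = _two_blob_data(rng, n=16)
        with pytest.raises(ValueError):
            ch.permutation_test(X, y, n_perm=0)


class TestPLSR:
    def test_noiseless_linear_r2_one_and_rpd_capped(self, rng):
        X = rng.standard_normal((30, 6))
        w = rng.standard_normal(6)
        y = X @ w + 2.0
        _, rep = ch.fit_plsr(
            X[:20], y[:20], max_components=6, X_test=X[20:], y_test=y[20:]
        )
        assert rep.r2c == pytest.approx(1.0, abs=1e-8)
        assert rep.r2p == pytest.approx(1.0, abs=1e-8)
        assert rep.rmsep < 1e-8
        assert rep.rpd_capped
        assert rep.rpd == ch.RPD_CAP

    def test_permuted_null_r2p_near_zero_rpd_near_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 10))
        y = rng.standard_normal(60)
        _, rep = ch.fit_plsr(
            X[:40], y[:40], max_components=3, X_test=X[40:], y_test=y[40:]
        )
        assert rep.r2p < 0.3
        assert 0.5 < rep.rpd < 2.0

    def test_rpd_identity(self, rng):
        X = rng.standard_normal((40, 8))
        w = rng.standard_normal(8)
        y = X @ w + 0.5 * rng.standard_normal(40)
        _, rep = ch.fit_plsr(
            X[:28], y[:28], max_components=5, X_test=X[28:], y_test=y[28:]
        )
        sd_ref = np.std(y[28:], ddof=1)
        assert rep.rpd * rep.rmsep == pytest.approx(sd_ref, abs=1e-9)

    def test_full_rank_equals_ols(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        m = ch._fit_pls(X, y.reshape(-1, 1), 5)
        model = ch._model_from(m, "Raw")
        Xc = X - X.mean(axis=0)
        coef, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        pred_ols = Xc @ coef + y.mean()
        assert np.allclose(model.predict(X).ravel(), pred_ols, atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ch.fit_plsr(np.ones((1, 3)), np.ones(1))

    def test_parameter_recovery_cosine_similarity(self, quant_spectra, quant_table):
        # SNR >= 10 regime: the fitted coefficient vector points along the
        # identifiable part of the true coupling.  With n < p the data only
        # determine w inside the subspace where X varies well above the
        # noise floor, so both vectors are compared after projection onto
        # the strong singular directions of the calibration matrix.
        table, log = quant_table
        band = quant_spectra.restrict(1800, 1200)
        X = band.absorbance
        sp = ks_split(X, {"cal": 0.7, "test": 0.3})
        Xc = X[sp["cal"]] - X[sp["cal"]].mean(axis=0)
        _, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        Vk = Vt[sv >= 0.1 * sv[0]]
        hits = 0
        for j in range(table.n_compounds):
            y = table.values[:, j]
            model, rep = ch.fit_plsr(
                X[sp["cal"]], y[sp["cal"]],
                X_test=X[sp["test"]], y_test=y[sp["test"]],
            )
            a = Vk @ model.coef.ravel()
            b = Vk @ log.coupling[j]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            if rep.r2p >= 0.9 and cos >= 0.95:
                hits += 1
        assert hits >= 10


class TestChainSearch:
    def test_duplicated_chains_pick_first(self, small_spectra):
        chains = [PretreatmentChain.from_string("FD")] * 2
        reports, best = ch.chain_search_classification(small_spectra, chains)
        assert best == 0

    def test_one_row_per_chain(self, small_spectra):
        names = ("Raw", "FD", "SNV")
        chains = [PretreatmentChain.from_string(c) for c in names]
        reports, _ = ch.chain_search_classification(small_spectra, chains)
        assert [r.chain for r in reports] == list(names)
        for r in reports:
            assert r.rmsep is not None and r.test_accuracy is not None

    def test_empty_chain_list_rejected(self, small_spectra):
        with pytest.raises(ValueError, match="non-empty"):
            ch.chain_search_classification(small_spectra, [])

    def test_regression_best_by_r2p(self, quant_spectra, quant_table):
        table, _ = quant_table
        band = quant_spectra.restrict(1800, 1200)
        chains = [PretreatmentChain.from_string(c) for c in ("Raw", "SNV")]
        reports, best = ch.chain_search_regression(
            band, table, chains, table.compound_names[0]
        )
        assert reports[best].r2p == max(r.r2p for r in reports)
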