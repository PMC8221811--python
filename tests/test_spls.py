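"""SPLS core, deconfounding, bagging, nested CV, permutation, lesion, transfer."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from dacuity.network import ConsensusPartition, exclude_high_motion
from dacuity.spls import (
    SPLSConfig,
    _fit_fold,
    _prefilter_mask,
    bagged_fit,
    confound_design,
    deconfound,
    fit_spls,
    module_feature_mask,
    nested_cv_predict,
    partial_corr,
    permutation_pvalue,
    specificity_partial,
    transfer_to_followup,
    virtual_lesion_scan,
)


def fast_config(**kw):
    base = dict(eta_grid=(0.5,), k_grid=(1,), outer_folds=5, inner_folds=3,
                n_repeats=1, n_boot=5, n_perm=20, seed=0)
    base.update(kw)
    return SPLSConfig(**base)


class TestFitSPLS:
    def test_dense_limit_matches_pls_oracle(self):
        rng = np.random.default_rng(0)
        for t in range(10):
            n, p, k = 30, 10, int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            b = fit_spls(X - X.mean(0), y - y.mean(), 0.0, k)
            oracle = PLSRegression(n_components=k, scale=False).fit(X, y).coef_.ravel()
            assert np.abs(b - oracle).max() < 1e-8

    def test_exact_support_recovery_noiseless(self):
        rng = np.random.default_rng(1)
        A = np.linalg.qr(rng.standard_normal((400, 300)), mode="reduced")[0]
        beta = np.zeros(300)
        beta[[5, 100, 250]] = 1.0
        y = A @ beta
        b = fit_spls(A, y - y.mean(), 0.8, 1)
        assert set(np.flatnonzero(b)) == {5, 100, 250}

    def test_eta_near_one_keeps_argmax_only(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 20))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 7] + 0.1 * rng.standard_normal(100)
        b = fit_spls(X, y - y.mean(), 0.999, 1)
        assert np.flatnonzero(b).tolist() == [7]

    def test_zero_variance_target_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_spls(np.eye(5), np.ones(5), 0.5, 1)

    def test_excess_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            fit_spls(np.random.default_rng(0).standard_normal((5, 3)), np.arange(5.0), 0.0, 4)


class TestDeconfound:
    def _cov(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "age": rng.uniform(14, 24, n),
            "sex": rng.integers(0, 2, n),
            "site": rng.integers(0, 3, n),
            "fd": rng.uniform(0.05, 0.25, n),
            "dof": rng.normal(60, 5, n),
            "volume": rng.normal(1200, 100, n),
        })

    def test_exact_linear_target_residuals_vanish(self):
        cov = self._cov(200)
        design = confound_design(cov)
        y = 2.0 + design.to_numpy(float) @ np.arange(1, design.shape[1] + 1, dtype=float)
        resid, beta, cols = deconfound(y, design, np.arange(100))
        assert np.abs(resid[:100]).max() < 1e-8

    def test_orthogonal_covariates_leave_target(self):
        rng = np.random.default_rng(3)
        n = 5000
        cov = self._cov(n)
        y = rng.standard_normal(n)
        design = confound_design(cov)
        resid, *_ = deconfound(y, design, np.arange(n))
        assert np.corrcoef(resid, y)[0, 1] > 0.99

    def test_test_rows_do_not_influence_training_residuals(self):
        cov = self._cov(100)
        rng = np.random.default_rng(4)
        y = rng.standard_normal(100)
        design = confound_design(cov)
        r1, *_ = deconfound(y, design, np.arange(60))
        cov2 = cov.copy()
        cov2.loc[60:, "age"] = 99.0
        r2, *_ = deconfound(y, confound_design(cov2), np.arange(60))
        assert np.array_equal(r1[:60], r2[:60])

    def test_collinear_columns_named(self):
        cov = self._cov(50)
        cov["age_copy"] = cov["age"]
        with pytest.raises(ValueError, match="age"):
            deconfound(np.arange(50.0), confound_design(cov), np.arange(50))

    def test_site_encoded_with_reference_dropped(self):
        cov = self._cov(50)
        design = confound_design(cov)
        site_cols = [c for c in design.columns if c.startswith("site_")]
        assert len(site_cols) == cov["site"].nunique() - 1
        assert "age_x_sex" in design.columns


class TestPrefilterBagging:
    def test_null_prefilter_rate(self):
        rng = np.random.default_rng(5)
        hits = []
        for rep in range(20):
            X = rng.standard_normal((100, 500))
            y = rng.standard_normal(100)
            hits.append(_prefilter_mask(X, y, 0.05).mean())
        # binomial 95% envelope around 5% for 20 x 500 trials
        assert abs(np.mean(hits) - 0.05) < 0.01

    def test_single_bootstrap_equals_single_fit(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 40))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 0] + rng.standard_normal(60)
        cfg = fast_config(n_boot=1, prefilter_alpha=0.5)
        coef, intercept, freq, keep = bagged_fit(X, y, 0.5, 1, cfg, rng=np.random.default_rng(9))
        idx = np.random.default_rng(9).integers(0, 60, size=60)
        yb = (y - y.mean())[idx]
        manual = fit_spls(X[idx][:, keep], yb - yb.mean(), 0.5, 1)
        assert np.allclose(coef[keep], manual)

    def test_planted_features_selected_more_often(self):
        rng = np.random.default_rng(7)
        n, p = 150, 200
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        beta = np.zeros(p)
        beta[:10] = 0.4
        y = X @ beta + rng.standard_normal(n)
        cfg = fast_config(n_boot=50)
        coef, _, freq, keep = bagged_fit(X, y - y.mean(), 0.5, 1, cfg, rng=rng)
        assert freq[:10].mean() > freq[10:].mean()

    def test_empty_prefilter_warns_and_predicts_mean(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 20))
        y = rng.standard_normal(50)
        cfg = fast_config(prefilter_alpha=1e-12)
        with pytest.warns(UserWarning, match="prefilter"):
            coef, intercept, freq, keep = bagged_fit(X, y, 0.5, 1, cfg)
        assert not keep.any() and np.all(coef == 0) and intercept == pytest.approx(y.mean())


@pytest.fixture(scope="module")
def small_prediction(scanned_cohort_module):
    conn, ds, truth, d = scanned_cohort_module
    cfg = fast_config(outer_folds=10, n_boot=10, eta_grid=(0.7, 0.9), k_grid=(1, 2),
                      inner_folds=4, n_repeats=2, seed=3)
    res = nested_cv_predict(ds.features(), d, ds.covariates, cfg)
    return ds, d, cfg, res


@pytest.fixture(scope="module")
def scanned_cohort_module():
    from dacuity.synthetic import CohortSpec, ConnectivitySpec, generate_connectivity, generate_measure_table

    spec = CohortSpec(n_subjects=220, seed=7)
    _, truth = generate_measure_table(spec)
    conn = ConnectivitySpec(n_nodes=42, n_modules=14, n_signal_edges_d=10,
                            n_signal_edges_iq=10, seed=8)
    ds = generate_connectivity(conn, truth, wave=1)
    ds, _ = exclude_high_motion(ds)
    d = truth.latent.query("wave == 1").set_index("subject").loc[ds.subjects, "d"].to_numpy()
    return conn, ds, truth, d


class TestNestedCV:
    def test_each_subject_predicted_once_per_repeat(self, small_prediction):
        ds, d, cfg, res = small_prediction
        assert res.predictions.shape == (cfg.n_repeats, ds.n_subjects)
        for rep in range(cfg.n_repeats):
            assert np.bincount(res.folds[rep], minlength=cfg.outer_folds).sum() == ds.n_subjects
        assert res.r_mean == pytest.approx(res.r_per_repeat.mean())

    def test_planted_signal_predicts(self, small_prediction):
        _, _, _, res = small_prediction
        assert res.r_mean > 0.15

    def test_tiny_folds_rejected(self, scanned_cohort_module):
        _, ds, _, d = scanned_cohort_module
        cfg = fast_config(outer_folds=len(d) // 2)
        with pytest.raises(ValueError, match="fold"):
            nested_cv_predict(ds.features(), d, ds.covariates, cfg)

    def test_no_leak_from_own_test_targets(self, small_prediction):
        """Changing a fold's test-subject targets must not change that fold's fit."""
        ds, d, cfg, res = small_prediction
        X = ds.features()
        base = res.observed_resid[0].copy()
        fold0 = res.fold_models[0][0]
        modified = base.copy()
        modified[fold0.test_idx] = np.random.default_rng(0).standard_normal(fold0.test_idx.size)

        def fold0_coef(target):
            rng = np.random.default_rng(123)
            te = np.zeros(len(target), bool)
            te[fold0.test_idx] = True
            Xs = (X - fold0.x_mean) / fold0.x_sd
            coef, *_ = _fit_fold(Xs[~te], target[~te], cfg, rng)
            return coef

        assert np.array_equal(fold0_coef(base), fold0_coef(modified))


class TestPermutation:
    def test_low_perm_count_rejected(self, small_prediction):
        ds, d, cfg, res = small_prediction
        bad = fast_config(n_perm=10)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_pvalue(res, ds.features(), bad)

    def test_signal_detected(self, small_prediction):
        ds, d, cfg, res = small_prediction
        null = permutation_pvalue(res, ds.features(), cfg)
        assert null.p_value < 0.05
        assert null.null_r.shape == (cfg.n_perm,)

    def test_observed_below_null_mean_gives_large_p(self, scanned_cohort_module):
        _, ds, _, d = scanned_cohort_module
        cfg = fast_config(n_perm=20, seed=5)
        res = nested_cv_predict(ds.features(), d, ds.covariates, cfg)
        res.r_per_repeat = np.array([-0.3])
        res.r_mean = -0.3
        null = permutation_pvalue(res, ds.features(), cfg)
        assert null.p_value > 0.5


class TestPartialCorr:
    def test_matches_residual_identity(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(200)
        x = 0.5 * z + rng.standard_normal(200)
        y = -0.3 * z + rng.standard_normal(200)
        got = partial_corr(x, y, z)
        # closed form from pairwise correlations
        rxy, rxz, ryz = (np.corrcoef(a, b)[0, 1] for a, b in ((x, y), (x, z), (y, z)))
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_independent_control_preserves_r(self, small_prediction):
        ds, d, cfg, res = small_prediction
        rng = np.random.default_rng(10)
        control = rng.standard_normal(ds.n_subjects)
        null = permutation_pvalue(res, ds.features(), cfg, keep_null_predictions=True)
        pr, pp = specificity_partial(res, control, null)
        assert abs(pr - res.r_mean) < 0.05

    def test_constant_control_rejected(self, small_prediction):
        ds, d, cfg, res = small_prediction
        null = permutation_pvalue(res, ds.features(), cfg, keep_null_predictions=True)
        with pytest.raises(ValueError, match="constant"):
            specificity_partial(res, np.ones(ds.n_subjects), null)


class TestVirtualLesion:
    def test_feature_counts_and_test_family(self, scanned_cohort_module):
        conn, ds, truth, d = scanned_cohort_module
        labels = truth.planted_partition
        part = ConsensusPartition(labels=labels, gamma=1.0,
                                  consensus_matrix=np.eye(labels.size), n_runs=1)
        n = labels.size
        for m in (1, 5, 14):
            size = (labels == m).sum()
            expected = size * (size - 1) // 2 + size * (n - size)
            assert module_feature_mask(labels, m).sum() == expected
        cfg = fast_config(outer_folds=5, n_boot=3, n_perm=20, seed=4)
        out = virtual_lesion_scan(ds, d, part, cfg)
        assert len(out) == 15  # 14 modules + the all-connections model
        assert {"test", "r_mean", "p", "p_fdr", "significant_fdr"} <= set(out.columns)
        assert out["p_fdr"].min() >= out["p"].min()


class TestTransfer:
    def test_identical_followup_reproduces_baseline_predictions(self, small_prediction):
        ds, d, cfg, res = small_prediction
        r, p, r_rep, excluded, preds = transfer_to_followup(res, ds, d, ds.subjects)
        assert excluded == []
        order = pd.Index(ds.subjects).get_indexer(preds["subject"])
        for rep in range(cfg.n_repeats):
            assert np.array_equal(
                preds[f"pred_rep{rep + 1}"].to_numpy(), res.predictions[rep][order]
            )
        assert r == pytest.approx(res.r_mean)

    def test_new_subjects_excluded(self, small_prediction):
        ds, d, cfg, res = small_prediction
        fu = ds.subset(np.arange(ds.n_subjects))
        fu.subjects = fu.subjects.copy()
        fu.subjects[0] = 10_000  # not in the baseline sample
        r, p, r_rep, excluded, preds = transfer_to_followup(res, fu, d, ds.subjects)
        assert excluded == [10_000]
        assert 10_000 not in set(preds["subject"])

    def test_no_overlap_rejected(self, small_prediction):
        ds, d, cfg, res = small_prediction
        fu = ds.subset(np.arange(4))
        fu.subjects = np.array([90001, 90002, 90003, 90004])
        with pytest.raises(ValueError, match="overlap"):
            transfer_to_followup(res, fu, d[:4], ds.subjects)
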