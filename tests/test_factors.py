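"""Parallel analysis, minres EFA, CFA selection, scoring, stability."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dacuity._utils import congruence
from dacuity.factors import (
    FactorConvergenceError,
    FactorModel,
    confirm_and_select,
    fit_cfa,
    fit_ecfa,
    match_factors,
    parallel_analysis,
    score_subjects,
    stability_cross_scoring,
)
from dacuity.synthetic import MEASURES


def battery_table(x: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(x, columns=list(MEASURES)[: x.shape[1]])
    df.insert(0, "subject", np.arange(len(df)))
    df.insert(1, "wave", 1)
    return df


def one_factor_data(n=500, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    lam = np.linspace(0.4, 0.9, 32)
    f = rng.standard_normal(n)
    x = np.outer(f, lam) + noise * rng.standard_normal((n, 32))
    return battery_table(x), lam, f


class TestParallelAnalysis:
    def test_pure_noise_retains_at_most_one(self):
        counts = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            t = battery_table(rng.standard_normal((400, 32)))
            counts.append(parallel_analysis(t, n_reps=30, seed=rep))
        assert np.mean(counts) <= 1
        assert np.median(counts) == 0

    def test_planted_four_factor_battery(self, standardized_baseline):
        std, _, _ = standardized_baseline
        assert parallel_analysis(std, n_reps=50, seed=0) >= 4

    def test_deterministic(self, standardized_baseline):
        std, _, _ = standardized_baseline
        a = parallel_analysis(std, n_reps=30, seed=5)
        b = parallel_analysis(std, n_reps=30, seed=5)
        assert a == b

    def test_low_reps_rejected(self, standardized_baseline):
        std, _, _ = standardized_baseline
        with pytest.raises(ValueError):
            parallel_analysis(std, n_reps=5)


class TestECFA:
    def test_noiseless_single_factor(self):
        # with no unique variance, standardized loadings approach 1 and the
        # factor score reproduces the latent variable essentially exactly
        t, lam, f = one_factor_data(noise=0.02)
        m = fit_ecfa(t, 1)
        assert m.loadings[:, 0].min() > 0.99
        assert m.uniquenesses.max() < 0.05
        scores = score_subjects(m, battery_table(
            (t.loc[:, list(MEASURES)].to_numpy() - t.loc[:, list(MEASURES)].mean().to_numpy())
            / t.loc[:, list(MEASURES)].std(ddof=0).to_numpy()))
        assert abs(np.corrcoef(scores["d"], f)[0, 1]) >= 0.999

    def test_two_orthogonal_factors_recovered(self):
        rng = np.random.default_rng(3)
        lam = np.zeros((32, 2))
        lam[:16, 0] = 0.7
        lam[16:, 1] = 0.6
        f = rng.standard_normal((600, 2))
        x = f @ lam.T + rng.standard_normal((600, 32)) * np.sqrt(1 - (lam ** 2).sum(1))
        m = fit_ecfa(battery_table(x), 2)
        matched, _, _ = match_factors(lam, m.loadings)
        for j in range(2):
            assert congruence(lam[:, j], matched[:, j]) >= 0.95

    def test_k_zero_rejected(self, standardized_baseline):
        std, _, _ = standardized_baseline
        with pytest.raises(ValueError):
            fit_ecfa(std, 0)

    def test_exceeding_bound_warns_but_fits(self, standardized_baseline):
        std, _, _ = standardized_baseline
        with pytest.warns(UserWarning, match="parallel-analysis bound"):
            m = fit_ecfa(std, 5, max_factors=4)
        assert m.k == 5

    def test_json_roundtrip(self, standardized_baseline):
        std, _, _ = standardized_baseline
        m = fit_ecfa(std, 2)
        back = FactorModel.from_json(m.to_json())
        assert np.allclose(back.loadings, m.loadings)
        assert np.allclose(back.scoring_weights, m.scoring_weights)
        assert back.measure_names == m.measure_names


class TestCFA:
    def test_true_sparse_model_fits_well(self):
        # data generated from an exactly sparse two-factor model: the CFA that
        # frees precisely the salient loadings is the true model
        rng = np.random.default_rng(11)
        lam = np.zeros((32, 2))
        lam[:10, 0] = 0.65
        lam[10:18, 1] = 0.55
        f = rng.standard_normal((500, 2))
        x = f @ lam.T + rng.standard_normal((500, 32)) * np.sqrt(1 - (lam ** 2).sum(1))
        t = battery_table(x)
        m = fit_ecfa(t.iloc[:250], 2)
        _, fit = fit_cfa(t.iloc[250:], m)
        assert fit.converged
        assert fit.cfi >= 0.95
        assert fit.rmsea_lo <= fit.rmsea <= fit.rmsea_hi + 1e-12

    def test_thresholded_model_converges_on_fixture(self, standardized_baseline):
        std, _, _ = standardized_baseline
        m = fit_ecfa(std.iloc[: len(std) // 2], 4)
        _, fit = fit_cfa(std.iloc[len(std) // 2:], m)
        assert fit.converged
        assert 0 <= fit.cfi <= 1 and fit.rmsea < 0.08

    def test_empty_factor_under_identified(self, standardized_baseline):
        std, _, _ = standardized_baseline
        m = fit_ecfa(std, 3)
        weak = FactorModel(
            k=3, loadings=np.column_stack([m.loadings[:, :2], np.full(32, 0.1)]),
            uniquenesses=m.uniquenesses, phi=np.eye(3),
            scoring_weights=m.scoring_weights, measure_names=m.measure_names,
        )
        with pytest.raises(FactorConvergenceError, match="under-identified"):
            fit_cfa(std, weak)

    def test_selection_excludes_under_identified(self, standardized_baseline):
        std, _, _ = standardized_baseline
        disc = std.iloc[: len(std) // 2]
        test = std.iloc[len(std) // 2:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = [fit_ecfa(disc, k) for k in (1, 2, 3, 4)]
        chosen, indices, _ = confirm_and_select(models, test)
        assert chosen in indices
        assert indices[chosen].converged


class TestScoring:
    def test_column_order_invariance(self, standardized_baseline):
        std, _, _ = standardized_baseline
        m = fit_ecfa(std, 4)
        shuffled = std[["subject", "wave"] + list(np.random.default_rng(0).permutation(MEASURES))]
        s1 = score_subjects(m, std)
        s2 = score_subjects(m, shuffled)
        assert np.allclose(s1["d"], s2["d"])

    def test_scoring_linear_in_data(self, standardized_baseline):
        std, _, _ = standardized_baseline
        m = fit_ecfa(std, 2)
        doubled = std.copy()
        doubled.loc[:, list(MEASURES)] = 2 * std.loc[:, list(MEASURES)].to_numpy()
        assert np.allclose(2 * score_subjects(m, std)["d"], score_subjects(m, doubled)["d"])

    def test_identical_followup_scores_match(self, standardized_baseline):
        std, _, _ = standardized_baseline
        m = fit_ecfa(std, 4)
        assert np.array_equal(
            score_subjects(m, std)["d"].to_numpy(), score_subjects(m, std)["d"].to_numpy()
        )

    def test_six_task_subset_close_to_full(self, standardized_baseline):
        from dacuity.synthetic import LONGITUDINAL_TASKS

        std, _, _ = standardized_baseline
        m = fit_ecfa(std, 4)
        full = score_subjects(m, std)["d"]
        sub = score_subjects(m, std, task_subset=LONGITUDINAL_TASKS)["d"]
        assert np.corrcoef(full, sub)[0, 1] >= 0.9

    def test_missing_measure_rejected(self, standardized_baseline):
        std, _, _ = standardized_baseline
        m = fit_ecfa(std, 2)
        with pytest.raises(ValueError, match="missing"):
            score_subjects(m, std.drop(columns=["trust_initial"]))

    def test_unknown_task_subset_rejected(self, standardized_baseline):
        std, _, _ = standardized_baseline
        m = fit_ecfa(std, 2)
        with pytest.raises(ValueError):
            score_subjects(m, std, task_subset=["not_a_task"])


class TestStability:
    def test_identical_tables_give_unit_correlation(self, standardized_baseline):
        std, _, _ = standardized_baseline
        res = stability_cross_scoring(std, std)
        assert res.r_cross == pytest.approx(1.0, abs=1e-10)
        assert not res.flagged

    def test_permuted_measures_flagged(self, standardized_baseline):
        std, _, _ = standardized_baseline
        rng = np.random.default_rng(6)
        shuffled = std.copy()
        cols = list(MEASURES)
        perm = rng.permutation(cols)
        shuffled.loc[:, cols] = shuffled.loc[:, list(perm)].to_numpy()
        res = stability_cross_scoring(std, shuffled)
        assert abs(res.r_cross) < 0.5
        assert res.flagged
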