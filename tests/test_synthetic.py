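"""Generator contracts: determinism, planted structure, null behavior."""

import numpy as np
import pandas as pd
import pytest

from dacuity.synthetic import (
    CohortSpec,
    ConnectivitySpec,
    MEASURES,
    generate_connectivity,
    generate_measure_table,
    generate_trust_exchanges,
    implied_d_iq_correlation,
)
from dacuity.trust import exchange_scores


class TestMeasureTable:
    def test_same_seed_identical(self):
        t1, _ = generate_measure_table(CohortSpec(n_subjects=50, seed=3))
        t2, _ = generate_measure_table(CohortSpec(n_subjects=50, seed=3))
        pd.testing.assert_frame_equal(t1, t2)

    def test_noiseless_rank_at_most_four(self):
        spec = CohortSpec(n_subjects=400, seed=1, uniqueness=np.zeros(32), missing_rate=0.0)
        table, _ = generate_measure_table(spec)
        base = table[table["wave"] == 1].loc[:, list(MEASURES)].to_numpy()
        # undo the marginal skew injection before the rank check
        from dacuity.synthetic import SKEWED_MEASURES

        for j, name in enumerate(MEASURES):
            if name in SKEWED_MEASURES:
                base[:, j] = np.log(base[:, j])
        svals = np.linalg.svd(base - base.mean(0), compute_uv=False)
        assert (svals > 1e-8 * svals[0]).sum() <= 4

    def test_retention_and_missingness(self, cohort):
        spec, table, _ = cohort
        n_base = (table["wave"] == 1).sum()
        n_fu = (table["wave"] == 2).sum()
        assert n_base == spec.n_subjects
        assert abs(n_fu / n_base - spec.retention) < 0.07
        frac_missing = table.loc[:, list(MEASURES)].isna().to_numpy().mean()
        assert abs(frac_missing - spec.missing_rate) < 0.01

    def test_latent_d_standardized_with_age_slope(self, cohort):
        spec, _, truth = cohort
        lat = truth.latent
        base = lat[lat["wave"] == 1]
        assert abs(base["d"].std() - 1.0) < 0.1
        z_age = (base["age"] - base["age"].mean()) / base["age"].std()
        slope = np.polyfit(z_age, base["d"], 1)[0]
        assert abs(slope - spec.beta_age) < 0.12

    def test_d_iq_correlation_matches_spec(self):
        spec = CohortSpec(n_subjects=800, seed=11)
        _, truth = generate_measure_table(spec)
        base = truth.latent.query("wave == 1")
        expected = implied_d_iq_correlation(spec)
        assert abs(base["d"].corr(base["iq_comp"]) - expected) < 0.08

    def test_latent_retest_correlation(self):
        spec = CohortSpec(n_subjects=2000, seed=5)
        _, truth = generate_measure_table(spec)
        lat = truth.latent.pivot_table(index="subject", columns="wave", values="d")
        lat = lat.dropna()
        assert abs(lat[1].corr(lat[2]) - spec.retest_r) < 0.05

    @pytest.mark.parametrize("field,value", [
        ("retention", 0.0), ("missing_rate", 0.5), ("sex_ratio", 1.5),
    ])
    def test_invalid_spec_rejected(self, field, value):
        with pytest.raises(ValueError):
            generate_measure_table(CohortSpec(n_subjects=20, **{field: value}))

    def test_zero_loadings_give_unstructured_battery(self):
        """Global null sanity: no recoverable common factor when nothing is planted."""
        spec = CohortSpec(
            n_subjects=400, seed=9,
            common_loadings=np.zeros(32),
            specific_structure={},
            uniqueness=np.ones(32),
            missing_rate=0.0,
        )
        table, _ = generate_measure_table(spec)
        base = table[table["wave"] == 1].loc[:, list(MEASURES)].to_numpy()
        from dacuity.synthetic import SKEWED_MEASURES

        for j, name in enumerate(MEASURES):
            if name in SKEWED_MEASURES:
                base[:, j] = np.log(base[:, j])
        eig = np.sort(np.linalg.eigvalsh(np.corrcoef(base, rowvar=False)))[::-1]
        assert eig[0] < 1.8  # leading eigenvalue consistent with pure noise at n=400


class TestConnectivity:
    def test_symmetric_zero_diag(self, scanned_cohort):
        _, ds, _ = scanned_cohort
        assert np.allclose(ds.matrices, ds.matrices.transpose(0, 2, 1))
        assert np.allclose(ds.matrices.diagonal(axis1=1, axis2=2), 0.0)

    def test_template_exact_when_no_noise(self):
        _, truth = generate_measure_table(CohortSpec(n_subjects=30, seed=2))
        spec = ConnectivitySpec(n_nodes=20, n_modules=4, subject_noise_sd=0.0,
                                effect_d=0.0, effect_iq=0.0,
                                site_offsets=(0.0,), fd_slope=0.0, volume_slope=0.0, seed=3)
        ds = generate_connectivity(spec, truth)
        assert np.allclose(ds.matrices, ds.matrices[0])

    def test_null_effects_within_null_envelope(self):
        """With effect_d = 0 no edge should correlate with d beyond the
        Bonferroni-corrected envelope of the sample-correlation null."""
        _, truth = generate_measure_table(CohortSpec(n_subjects=300, seed=4))
        spec = ConnectivitySpec(n_nodes=25, n_modules=5, effect_d=0.0, effect_iq=0.0, seed=5)
        ds = generate_connectivity(spec, truth)
        d = truth.latent.query("wave == 1").set_index("subject").loc[ds.subjects, "d"].to_numpy()
        X = ds.features()
        xc = (X - X.mean(0)) / X.std(0)
        r = xc.T @ ((d - d.mean()) / d.std()) / len(d)
        n_edges = X.shape[1]
        from scipy import stats

        bound = np.tanh(stats.norm.isf(0.005 / n_edges) / np.sqrt(len(d) - 3))
        assert np.abs(r).max() < bound

    def test_strong_effect_edges_dominate_ranking(self):
        _, truth = generate_measure_table(CohortSpec(n_subjects=300, seed=6))
        spec = ConnectivitySpec(n_nodes=40, n_modules=4, n_signal_edges_d=50,
                                effect_d=0.5, effect_iq=0.0, seed=7)
        ds = generate_connectivity(spec, truth)
        d = truth.latent.query("wave == 1").set_index("subject").loc[ds.subjects, "d"].to_numpy()
        X = ds.features()
        r = np.abs(np.corrcoef(X.T, d)[:-1, -1])
        top100 = np.argsort(r)[::-1][:100]
        recall = np.isin(truth.planted_edges_d, top100).mean()
        assert recall >= 0.8

    def test_edge_sets_within_range_and_recorded(self, scanned_cohort):
        conn, ds, truth = scanned_cohort
        n_edges = conn.n_nodes * (conn.n_nodes - 1) // 2
        assert truth.planted_edges_d.max() < n_edges
        assert truth.planted_partition is not None
        assert len(np.unique(truth.planted_partition)) == conn.n_modules

    def test_wave_mismatch_raises(self):
        _, truth = generate_measure_table(CohortSpec(n_subjects=30, seed=8))
        with pytest.raises(ValueError, match="wave"):
            generate_connectivity(ConnectivitySpec(n_nodes=10, n_modules=2), truth, wave=9)

    def test_roundtrip_manifest(self, tmp_path, scanned_cohort):
        _, ds, _ = scanned_cohort
        small = ds.subset(np.arange(4))
        small.write(tmp_path)
        back = type(ds).read(tmp_path)
        assert np.allclose(back.matrices, small.matrices)
        assert list(back.subjects) == list(small.subjects)


class TestTrustGenerator:
    def test_same_seed_identical(self):
        a = generate_trust_exchanges({"policy": "random"}, seed=5, n_subjects=3)
        b = generate_trust_exchanges({"policy": "random"}, seed=5, n_subjects=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.investor, y.investor)
            assert np.array_equal(x.trustee, y.trustee)

    def test_coaxing_orientation_near_zero(self):
        exchanges = generate_trust_exchanges({"policy": "coaxing"}, seed=1, n_subjects=30)
        oris = [exchange_scores(ex)["orientation_deg"] for ex in exchanges]
        assert np.mean(np.abs(oris)) < 15
        assert max(np.abs(oris)) < 30

    def test_mutual_reduction_orientation_near_minus135(self):
        exchanges = generate_trust_exchanges({"policy": "mutual_reduction"}, seed=2, n_subjects=30)
        oris = np.array([exchange_scores(ex)["orientation_deg"] for ex in exchanges])
        assert np.all(np.abs(oris + 135) < 20)

    def test_bounds_respected(self):
        for ex in generate_trust_exchanges({"policy": "random"}, seed=3, n_subjects=10):
            assert np.all(ex.investor >= 0) and np.all(ex.investor <= ex.endowment)
            assert np.all(ex.trustee >= 0) and np.all(ex.trustee <= 3 * ex.investor + 1e-9)

    def test_too_few_rounds_rejected(self):
        with pytest.raises(ValueError):
            generate_trust_exchanges({"policy": "random"}, n_rounds=1)
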