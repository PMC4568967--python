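"""QC chain: transforms, filters, imputation, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metanetdiff import qc, synth
from metanetdiff.data import bio_design
from metanetdiff.exceptions import ConfigError, DataError, InsufficientDataError

from conftest import make_matrix, simple_design


class TestLogTransform:
    def test_pseudocount_examples(self):
        m = make_matrix([[0.0, 7.0]], scale="raw")
        out = qc.log_transform(m)
        assert out.scale == "log"
        np.testing.assert_allclose(out.values.to_numpy(), [[0.0, 3.0]])

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(0, 1e5, (20, 8)), scale="raw")
        back = qc.unlog(qc.log_transform(m))
        np.testing.assert_allclose(back.values.to_numpy(),
                                   m.values.to_numpy(), rtol=1e-9)

    def test_negative_intensity_rejected(self):
        with pytest.raises(DataError):
            qc.log_transform(make_matrix([[-1.0, 2.0]], scale="raw"))

    def test_missing_preserved(self):
        m = make_matrix([[1.0, np.nan]], scale="raw")
        assert qc.log_transform(m).values.isna().to_numpy().tolist() == [[False, True]]


class TestOutlierDetection:
    def test_sign_flipped_sample_flagged(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(60, 1))
        X = base + 0.05 * rng.normal(size=(60, 12))
        X[:, 11] = -X[:, 11]                      # anti-correlated sample
        rep = qc.detect_outlier_samples(make_matrix(X), z_cut=-3.0)
        assert rep.flagged == ["s11"]

    def test_identical_samples_no_flags(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 5))
        rep = qc.detect_outlier_samples(make_matrix(X))
        assert rep.flagged == [] and np.allclose(rep.z_k, 0.0)

    def test_minus_infinity_cut_flags_nothing(self):
        rng = np.random.default_rng(2)
        rep = qc.detect_outlier_samples(make_matrix(rng.normal(size=(30, 8))),
                                        z_cut=-np.inf)
        assert rep.flagged == []

    def test_z_scores_standardized(self):
        rng = np.random.default_rng(3)
        rep = qc.detect_outlier_samples(make_matrix(rng.normal(size=(40, 10))))
        assert abs(rep.z_k.mean()) < 1e-9
        assert abs(rep.z_k.std(ddof=1) - 1.0) < 1e-9

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            qc.detect_outlier_samples(make_matrix(np.ones((5, 2))))

    def test_planted_outlier_recovered_from_generator(self):
        cfg = synth.SynthConfig(n_features=400, seed=3, n_outlier_samples=1,
                                outlier_sd=5.0, frac_missing=0.0)
        design = synth.make_design(cfg)
        m, truth = synth.simulate_features(design, cfg)
        rep = qc.detect_outlier_samples(qc.log_transform(m), z_cut=-3.0)
        planted_bio = set(truth.samples.index[truth.samples.planted_outlier])
        flagged_bio = set(design.set_index("sample_id")
                          .loc[rep.flagged, "bio_id"])
        assert planted_bio <= flagged_bio


class TestSnrFilter:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            X = rng.uniform(5, 20, size=(12, 12))
            X[rng.random(X.shape) < 0.1] = np.nan
            design = simple_design(4, tech=3)
            m = make_matrix(X, sample_ids=design.sample_id.tolist())
            kept, stats = qc.snr_filter(m, design, threshold=20.0)
            # independent recomputation
            expected_keep = []
            for i in range(12):
                sds = []
                for g in range(4):
                    grp = X[i, 3 * g:3 * g + 3]
                    grp = grp[~np.isnan(grp)]
                    sds.append(np.std(grp, ddof=1) if len(grp) >= 2 else np.nan)
                sigma = np.nanmean(sds) if not np.all(np.isnan(sds)) else np.nan
                mean = np.nanmean(X[i])
                snr = np.inf if (np.isnan(sigma) or sigma == 0) else mean / sigma
                if not snr < 20.0:
                    expected_keep.append(f"F{i:04d}")
            assert list(kept.feature_ids) == expected_keep

    def test_arithmetic_example_removed(self):
        # mean 100, sigma_tech 10 -> SNR 10 < 20
        X = np.array([[90.0, 100.0, 110.0, 90.0, 100.0, 110.0]])
        design = simple_design(2, tech=3)
        m = make_matrix(X, sample_ids=design.sample_id.tolist())
        kept, stats = qc.snr_filter(m, design)
        assert kept.n_features == 0
        assert stats.table.snr.iloc[0] == pytest.approx(10.0)

    def test_noiseless_feature_kept(self):
        X = np.array([[5.0, 5.0, 5.0, 7.0, 7.0, 7.0]])
        design = simple_design(2, tech=3)
        kept, stats = qc.snr_filter(
            make_matrix(X, sample_ids=design.sample_id.tolist()), design)
        assert kept.n_features == 1
        assert np.isinf(stats.table.snr.iloc[0])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        design = simple_design(4, tech=3)
        m = make_matrix(rng.uniform(1, 30, (30, 12)),
                        sample_ids=design.sample_id.tolist())
        once, _ = qc.snr_filter(m, design)
        twice, _ = qc.snr_filter(once, design)
        assert list(once.feature_ids) == list(twice.feature_ids)

    def test_requires_technical_replicates(self):
        design = simple_design(4, tech=1)
        with pytest.raises(ConfigError):
            qc.snr_filter(make_matrix(np.ones((3, 4)),
                                      sample_ids=design.sample_id.tolist()),
                          design)


class TestCollapseAndMissingness:
    def test_collapse_examples(self):
        design = simple_design(2, tech=2)
        X = np.array([[2.0, 4.0, 5.0, np.nan]])
        out = qc.collapse_tech_reps(
            make_matrix(X, sample_ids=design.sample_id.tolist()), design)
        np.testing.assert_allclose(out.values.to_numpy(), [[3.0, 5.0]])

    def test_collapse_single_rep_identity(self):
        design = simple_design(3, tech=1)
        X = np.arange(6.0).reshape(2, 3)
        out = qc.collapse_tech_reps(
            make_matrix(X, sample_ids=design.sample_id.tolist()), design)
        np.testing.assert_allclose(out.values.to_numpy(), X)

    def test_collapse_all_missing_stays_missing(self):
        design = simple_design(2, tech=2)
        X = np.array([[np.nan, np.nan, 1.0, 3.0]])
        out = qc.collapse_tech_reps(
            make_matrix(X, sample_ids=design.sample_id.tolist()), design)
        assert np.isnan(out.values.iloc[0, 0]) and out.values.iloc[0, 1] == 2.0

    @pytest.mark.parametrize("n_missing,max_frac,kept", [
        (1, 0.10, True),    # 1/12 = 8.3%
        (2, 0.10, False),   # 2/12 = 16.7%
        (1, 0.0, False),
    ])
    def test_missingness_threshold(self, n_missing, max_frac, kept):
        X = np.ones((1, 12))
        X[0, :n_missing] = np.nan
        out = qc.missingness_filter(make_matrix(X), max_frac=max_frac)
        assert (out.n_features == 1) is kept

    def test_missingness_matches_oracle_and_idempotent(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 10))
        X[rng.random(X.shape) < 0.15] = np.nan
        m = make_matrix(X)
        out = qc.missingness_filter(m, max_frac=0.10)
        expected = [f"F{i:04d}" for i in range(200)
                    if np.isnan(X[i]).mean() <= 0.10]
        assert list(out.feature_ids) == expected
        assert list(qc.missingness_filter(out, 0.10).feature_ids) == expected


class TestImpute:
    def test_identity_when_complete(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(10, 6)))
        out = qc.impute(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_perfectly_correlated_pair_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 2.0 * x + 1.0
        X = np.vstack([x, y])
        X[1, 3] = np.nan
        out = qc.impute(make_matrix(X), method="knn", k=2)
        assert out.values.iloc[1, 3] == pytest.approx(2.0 * 4.0 + 1.0, abs=1e-6)

    @pytest.mark.parametrize("method", ["knn", "em_regression"])
    def test_beats_mean_imputation_on_correlated_data(self, method):
        rng = np.random.default_rng(8)
        z = rng.normal(size=36)
        X = np.sqrt(0.8) * z[None, :] + np.sqrt(0.2) * rng.normal(size=(40, 36))
        mask = rng.random(X.shape) < 0.10
        Xm = X.copy()
        Xm[mask] = np.nan
        out = qc.impute(make_matrix(Xm), method=method, seed=0)
        rmse = np.sqrt(np.mean((out.values.to_numpy()[mask] - X[mask]) ** 2))
        means = np.nanmean(Xm, axis=1)
        rmse_mean = np.sqrt(np.mean(
            (np.tile(means[:, None], (1, 36))[mask] - X[mask]) ** 2))
        assert rmse < rmse_mean

    def test_unimputable_feature(self):
        X = np.array([[np.nan, np.nan], [1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(Exception):
            qc.impute(make_matrix(X))


class TestCenterAndQuantile:
    def test_center_example_and_postcondition(self):
        m = make_matrix([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        out = qc.center_features(m)
        np.testing.assert_allclose(out.values.iloc[0], [-1.0, 0.0, 1.0])
        assert out.scale == "centered"
        assert out.values.mean(axis=1).abs().max() < 1e-12

    def test_center_preserves_variance(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(15, 9)))
        out = qc.center_features(m)
        np.testing.assert_allclose(out.values.var(axis=1), m.values.var(axis=1))

    def test_quantile_example(self):
        m = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = qc.quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 7.0, 5.0])
        m = make_matrix(np.tile(col[:, None], (1, 4)))
        out = qc.quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 8), st.integers(3, 12), st.integers(0, 10**6))
    def test_columns_share_sorted_vector(self, n_cols, n_rows, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(size=(n_rows, n_cols)))
        out = qc.quantile_normalize(m).values.to_numpy()
        s = np.sort(out, axis=0)
        np.testing.assert_allclose(s, np.tile(s[:, [0]], (1, n_cols)), atol=1e-12)
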