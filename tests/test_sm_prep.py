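"""Subject-measure filtering, Gaussianization, confounds, covariance
completion and PCA staging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conncca.sm_prep import (
    apply_deconfound,
    build_confounds,
    deconfound,
    inverse_normal_transform,
    nearest_spd,
    pairwise_covariance,
    pca_scores_from_spd,
    prepare_sm,
    quantitative_filter,
    sm_bookkeeping,
)


class TestQuantitativeFilter:
    def test_constant_column_dropped_for_no_variation(self):
        ledger = quantitative_filter(pd.DataFrame({"c": np.ones(20)}))
        assert ledger.loc["c", "status"] == "dropped_c2"

    def test_sparse_column_dropped_for_missingness(self):
        x = np.arange(20, dtype=float)
        x[:11] = np.nan  # 45% present
        ledger = quantitative_filter(pd.DataFrame({"c": x}))
        assert ledger.loc["c", "status"] == "dropped_c1"

    def test_outlier_column_matches_direct_formula(self, rng):
        # max(Y)/mean(Y) <= n, so the 100x rule needs n > 100 subjects
        x = rng.standard_normal(200)
        x[0] = 1e4
        y = (x - np.median(x)) ** 2
        assert y.max() > 100 * y.mean()  # direct formula evaluation
        ledger = quantitative_filter(pd.DataFrame({"c": x}))
        assert ledger.loc["c", "status"] == "dropped_c3"
        assert ledger.loc["c", "outlier_ratio"] == pytest.approx(y.max() / y.mean())

    def test_first_failing_criterion_wins(self):
        # both mostly-missing AND constant: attributed to criterion 1
        x = np.full(20, np.nan)
        x[:5] = 1.0
        ledger = quantitative_filter(pd.DataFrame({"c": x}))
        assert ledger.loc["c", "status"] == "dropped_c1"

    def test_kept_columns_survive_rerun(self, rng):
        df = pd.DataFrame(rng.standard_normal((100, 8)))
        df.columns = [f"c{i}" for i in range(8)]
        first = quantitative_filter(df)
        kept = [c for c in df.columns if first.loc[c, "status"] == "kept"]
        second = quantitative_filter(df[kept])
        assert (second["status"] == "kept").all()


class TestInverseNormalTransform:
    def test_blom_formula_five_values(self):
        out = inverse_normal_transform(np.array([10.0, 20.0, 30.0, 40.0, 50.0]))
        expected = stats.norm.ppf((np.arange(1, 6) - 0.375) / 5.25)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(expected[2], 0.0, atol=1e-15)
        assert expected[3] == pytest.approx(0.4972, abs=2e-4)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_allclose(
            inverse_normal_transform(x), inverse_normal_transform(np.exp(x))
        )

    def test_missing_preserved_and_ties_averaged(self):
        x = np.array([1.0, np.nan, 2.0, 2.0, 3.0])
        out = inverse_normal_transform(x)
        assert np.isnan(out[1])
        assert out[2] == out[3]  # tied values share the average rank

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.full(10, 3.0))

    def test_gaussianized_moments(self, rng):
        x = rng.exponential(size=500)  # heavily skewed input
        out = inverse_normal_transform(x)
        assert abs(out.mean()) < 0.02
        assert abs(stats.skew(out)) < 0.1


class TestBuildConfounds:
    def test_seven_quantitative_in_twelve_out(self, rng):
        base = pd.DataFrame(
            rng.standard_normal((30, 7)), columns=list("abcdefg")
        )
        out = build_confounds(base)
        assert out.shape == (30, 12)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)

    def test_hand_arithmetic(self):
        base = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in "abcdefg"})
        out = build_confounds(base)
        np.testing.assert_allclose(out["c"], [-1, 0, 1])
        np.testing.assert_allclose(out["c^2"], [1 / 3, -2 / 3, 1 / 3])

    def test_missing_imputed_as_zero_after_demeaning(self):
        base = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in "abcdefg"})
        base.loc[1, "d"] = np.nan
        out = build_confounds(base)
        np.testing.assert_allclose(out["d"], [-1, 0, 1])  # imputed to the mean

    def test_categorical_expansion_not_squared(self):
        base = pd.DataFrame({c: [1.0, 2.0, 3.0, 4.0] for c in "abcdefg"})
        base["a"] = ["x", "x", "y", "z"]
        out = build_confounds(base, categorical=("a",))
        # one-of-K minus last level: 2 indicator cols; squares only for c..g
        assert out.shape[1] == 2 + 6 + 5
        assert not any(name.startswith("a") and name.endswith("^2") for name in out)

    def test_wrong_base_count_rejected(self):
        with pytest.raises(ValueError, match="7 base"):
            build_confounds(pd.DataFrame(np.zeros((5, 6))))


class TestDeconfound:
    def test_confound_column_removed_completely(self, rng):
        conf = rng.standard_normal((40, 3))
        out = deconfound(conf[:, [1]].copy(), conf)
        assert np.max(np.abs(out)) < 1e-10

    def test_orthogonal_confounds_leave_demeaned_data(self, rng):
        x = rng.standard_normal(60)
        x -= x.mean()
        conf = rng.standard_normal((60, 2))
        conf -= conf.mean(axis=0)
        conf -= np.outer(conf.T @ x, x).T / (x @ x)  # orthogonalize to x
        out = deconfound(x[:, None].copy(), conf)
        np.testing.assert_allclose(out[:, 0], x, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal((5, 2))
        conf = rng.standard_normal((5, 1))
        design = np.column_stack([np.ones(5), conf])
        beta = np.linalg.solve(design.T @ design, design.T @ x)
        np.testing.assert_allclose(
            deconfound(x, conf), x - design @ beta, atol=1e-12
        )

    def test_missing_rows_fitted_separately(self, rng):
        x = rng.standard_normal((50, 2))
        x[3, 0] = np.nan
        conf = rng.standard_normal((50, 2))
        out = deconfound(x, conf)
        assert np.isnan(out[3, 0]) and not np.isnan(out[3, 1])
        obs = ~np.isnan(x[:, 0])
        # residual orthogonal to each confound over the observed rows
        for j in range(2):
            assert abs(out[obs, 0] @ conf[obs, j]) < 1e-8

    def test_betas_round_trip(self, rng):
        x = rng.standard_normal((30, 3))
        conf = rng.standard_normal((30, 2))
        res, betas = deconfound(x, conf, return_betas=True)
        np.testing.assert_allclose(apply_deconfound(x, conf, betas), res, atol=1e-12)


class TestPairwiseCovariance:
    def test_no_missing_equals_exact_covariance(self, rng):
        x = rng.standard_normal((12, 6))
        xc = x - x.mean(axis=0)
        np.testing.assert_allclose(pairwise_covariance(x), xc @ xc.T / 6, atol=1e-12)

    def test_hand_computed_with_one_missing_cell(self):
        x = np.array(
            [[1.0, 2.0, 0.0, 1.0], [0.0, np.nan, 1.0, 3.0], [2.0, 1.0, 2.0, 2.0]]
        )
        out = pairwise_covariance(x)
        xc = x - np.nanmean(x, axis=0)
        # subjects 0 and 1 share SMs 0, 2, 3 only
        prods = [xc[0, j] * xc[1, j] for j in (0, 2, 3)]
        assert out[0, 1] == pytest.approx(np.mean(prods))
        # subjects 0 and 2 share everything
        assert out[0, 2] == pytest.approx(np.nanmean(xc[0] * xc[2]))

    def test_isolated_subject_pair_rejected(self):
        x = np.array([[1.0, np.nan], [np.nan, 1.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="shares no observed"):
            pairwise_covariance(x)


class TestNearestSPD:
    def test_spd_input_unchanged(self, rng):
        a = rng.standard_normal((6, 6))
        spd = a @ a.T + 6 * np.eye(6)
        np.testing.assert_allclose(nearest_spd(spd), spd, atol=1e-10)

    def test_eigen_clipping_oracle_2x2(self):
        out = nearest_spd(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]], atol=1e-9)

    def test_matches_clipping_oracle_and_cholesky(self, rng):
        for _ in range(10):
            a = rng.standard_normal((8, 8))
            a = (a + a.T) / 2
            out = nearest_spd(a)
            w, v = np.linalg.eigh(a)
            oracle = (v * np.maximum(w, 0)) @ v.T
            assert np.max(np.abs(out - oracle)) < 1e-6
            np.linalg.cholesky(out)  # must always factor

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            nearest_spd(np.array([[1.0, np.nan], [np.nan, 1.0]]))


class TestPCAFromSPD:
    def test_rank_one_matrix(self, rng):
        v = rng.standard_normal(7)
        s4 = np.outer(v, v)
        scores = pca_scores_from_spd(s4, d=2)
        np.testing.assert_allclose(np.abs(scores[:, 0]), np.abs(v), atol=1e-8)
        np.testing.assert_allclose(scores[:, 1], 0.0, atol=1e-6)

    def test_matches_dense_eigendecomposition(self, rng):
        a = rng.standard_normal((6, 6))
        s4 = a @ a.T
        scores = pca_scores_from_spd(s4, d=4)
        w, v = np.linalg.eigh(s4)
        w, v = w[::-1][:4], v[:, ::-1][:, :4]
        oracle = v * np.sqrt(w)
        for k in range(4):  # match up to column sign
            assert min(
                np.max(np.abs(scores[:, k] - oracle[:, k])),
                np.max(np.abs(scores[:, k] + oracle[:, k])),
            ) < 1e-10

    def test_d_too_large_rejected(self):
        with pytest.raises(ValueError):
            pca_scores_from_spd(np.eye(3), d=4)


class TestBookkeeping:
    def test_selection_arithmetic(self):
        report = sm_bookkeeping(n_matched=89, n_confounds=7, n_undesirable=8)
        assert report.n_final == 74

    def test_no_exclusions_is_identity(self):
        assert sm_bookkeeping(50, 0, 0).n_final == 50

    def test_subject_missing_most_sms_flagged(self, rng):
        x = rng.standard_normal((5, 74))
        x[2, :38] = np.nan  # 38 of 74 missing (> 50%)
        report = sm_bookkeeping(89, 7, 8, sm_values=x)
        assert report.flagged_subjects == [2]

    def test_negative_remainder_rejected(self):
        with pytest.raises(ValueError):
            sm_bookkeeping(10, 7, 8)


class TestPreparedStages:
    def test_stage_invariants(self, small_cohort):
        sm = small_cohort.sm[[c for c, f in small_cohort.sm_flags.items() if f == "signal"]]
        conf = build_confounds(
            small_cohort.confound_base, categorical=("site", "scanner")
        ).to_numpy()
        prep = prepare_sm(sm, conf, d=8)
        # S4 symmetric positive definite
        np.testing.assert_allclose(prep.s4, prep.s4.T, atol=1e-10)
        assert np.linalg.eigvalsh(prep.s4).min() > -1e-8
        # deconfounded columns orthogonal to every confound on observed rows
        for j in range(prep.s3.shape[1]):
            obs = ~np.isnan(prep.s3[:, j])
            assert np.max(np.abs(prep.s3[obs, j] @ conf[obs])) < 1e-6
        # S5 columns ordered by decreasing variance contribution
        norms = np.linalg.norm(prep.s5, axis=0)
        assert (np.diff(norms) <= 1e-10).all()
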