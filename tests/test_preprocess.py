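"""Spline and PCA preprocessing: imputation, denoising, CV, QC."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from temposig import (
    SyntheticSpec,
    TemporalMatrix,
    fit_spline_variable,
    generate_clustered_timecourses,
    nipals_pca,
    preprocess_pca,
    preprocess_spline,
    qc_compare,
    select_dof_cv,
    svd_impute,
)
from temposig.errors import (
    InsufficientPointsError,
    NoEligibleVariablesError,
    ParameterError,
    ShapeError,
)

T = np.array([1.0, 3.0, 5.0, 7.0, 10.0, 14.0])


def _tm(values, ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"V{i}" for i in range(values.shape[0])]
    return TemporalMatrix(values, T, ids)


class TestSplineFit:
    @pytest.mark.parametrize("missing", [(), (1,), (2, 4)])
    def test_line_reproduced_at_dof2(self, missing):
        series = 0.7 * T - 2.0
        series[list(missing)] = np.nan
        fitted = fit_spline_variable(series, T, dof=2)
        np.testing.assert_allclose(fitted, 0.7 * T - 2.0, atol=1e-8)

    def test_cubic_polynomial_reproduced_at_dof4(self):
        poly = 0.05 * T ** 3 - 0.4 * T ** 2 + T - 1
        series = poly.copy()
        series[2] = np.nan  # interior hole; full axis still spanned
        fitted = fit_spline_variable(series, T, dof=4)
        np.testing.assert_allclose(fitted, poly, atol=1e-6)

    def test_constant_series_stays_constant(self):
        fitted = fit_spline_variable(np.full(6, 3.3), T, dof=2)
        np.testing.assert_allclose(fitted, 3.3, atol=1e-8)

    def test_interpolating_dof_is_identity(self, rng):
        series = rng.normal(size=6)
        fitted = fit_spline_variable(series, T, dof=6)
        np.testing.assert_allclose(fitted, series, atol=1e-8)

    def test_too_few_points_raises(self):
        series = np.array([1.0, 2.0, 3.0, np.nan, np.nan, np.nan])
        with pytest.raises(InsufficientPointsError):
            fit_spline_variable(series, T, dof=2)

    def test_dof_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            fit_spline_variable(np.arange(6.0), T, dof=7)


def _loo_oracle_poly(series, dof):
    """Independent CV oracle: dof<=4 regression splines without interior
    knots coincide with degree dof-1 polynomial least squares."""
    obs = ~np.isnan(series)
    x, y = T[obs], series[obs]
    err = 0.0
    for j in range(1, len(x) - 1):
        mask = np.ones(len(x), dtype=bool)
        mask[j] = False
        coef = np.polyfit(x[mask], y[mask], deg=dof - 1)
        err += (np.polyval(coef, x[j]) - y[j]) ** 2
    return err


class TestDofSelection:
    def test_noiseless_lines_pick_smallest_dof(self):
        values = np.outer(np.arange(1, 6), T) + 3.0
        sel = select_dof_cv(_tm(values), dof_grid=(2, 3, 4, 5))
        assert sel.global_dof == 2

    def test_noiseless_cubics_pick_dof4_and_match_oracle(self):
        coefs = [(0.02, -0.3, 1.0), (0.05, 0.1, -0.5), (-0.03, 0.2, 0.3)]
        values = np.array([a * T ** 3 + b * T ** 2 + c * T
                           for a, b, c in coefs])
        m = _tm(values)
        sel = select_dof_cv(m, dof_grid=(2, 3, 4))
        assert sel.global_dof == 4
        for dof in (2, 3, 4):
            oracle = sum(_loo_oracle_poly(values[i], dof) for i in range(3))
            assert sel.cv_errors[dof] == pytest.approx(oracle, rel=1e-6,
                                                       abs=1e-9)

    def test_single_variable_modes_coincide(self, rng):
        values = rng.normal(size=(1, 6))
        g = select_dof_cv(_tm(values), mode="global")
        p = select_dof_cv(_tm(values), mode="per_variable")
        assert p.per_variable[0] == g.global_dof

    def test_no_eligible_variable_raises(self):
        values = np.array([[1.0, 2.0, np.nan, np.nan, 3.0, 4.0]])
        with pytest.raises(NoEligibleVariablesError):
            select_dof_cv(_tm(values))


class TestPreprocessSpline:
    def test_interpolating_dof_on_complete_data_is_identity(self, rng):
        values = rng.normal(size=(8, 6))
        m = _tm(values)
        pre, qc = preprocess_spline(m, dof=6)
        np.testing.assert_allclose(pre.values, values, atol=1e-8)
        assert qc.median_pearson == pytest.approx(1.0)
        assert qc.median_msd == pytest.approx(0.0, abs=1e-16)

    def test_sparse_rows_route_to_svd_fallback(self, rng):
        values = rng.normal(size=(10, 6))
        values[0, 3:] = np.nan  # 3 observations only
        pre, _ = preprocess_spline(_tm(values), dof=4)
        assert pre.row_method[0] == "svd"
        assert all(tag == "spline" for tag in pre.row_method[1:])
        assert not np.isnan(pre.values).any()
        # the fallback row keeps its observed cells untouched
        np.testing.assert_array_equal(pre.values[0, :3], values[0, :3])

    def test_denoises_toward_ground_truth(self):
        # at 20% missing the per-row error budget is dominated by the
        # leverage of imputed cells (boundary cells are extrapolated), so
        # the honest characterisation is the median error and the interior
        # imputation accuracy, not a per-row worst-case bound
        spec = SyntheticSpec(m=200, snr=4.0, missing_rate=0.2,
                             spike_noise_fraction=0.0, seed=7)
        matrix, truth = generate_clustered_timecourses(spec)
        pre, qc = preprocess_spline(matrix)
        sigma = spec.noise_sd
        msd = np.mean((pre.values - truth.noiseless_matrix) ** 2, axis=1)
        assert np.median(msd) < sigma ** 2
        assert qc.median_pearson >= 0.9
        interior = matrix.missing_mask.copy()
        interior[:, [0, -1]] = False
        err = pre.values - truth.noiseless_matrix
        assert np.sqrt(np.mean(err[interior] ** 2)) < 2 * sigma

    def test_output_always_complete(self, small_matrix):
        pre, _ = preprocess_spline(small_matrix, dof=3)
        assert not np.isnan(pre.values).any()


class TestSvdImpute:
    def test_complete_matrix_unchanged(self, rng):
        X = rng.normal(size=(6, 5))
        np.testing.assert_array_equal(svd_impute(X, rank=2), X)

    def test_rank1_cell_recovered(self):
        u = np.array([1.0, 2.0, -1.0, 0.5])
        v = np.array([0.3, -1.2, 2.0, 0.7])
        X = np.outer(u, v)
        Xm = X.copy()
        Xm[1, 2] = np.nan
        out = svd_impute(Xm, rank=1, tol=1e-12, max_iter=1000)
        assert out[1, 2] == pytest.approx(X[1, 2], abs=1e-8)

    def test_observed_cells_never_altered(self, rng):
        X = rng.normal(size=(15, 6))
        mask = rng.random(X.shape) < 0.2
        mask[:, 0] = False
        Xm = np.where(mask, np.nan, X)
        out = svd_impute(Xm, rank=3)
        np.testing.assert_array_equal(out[~mask], X[~mask])

    def test_matches_als_oracle_on_shared_structure(self, rng):
        # half the rows miss one column; rank structure is shared
        U = rng.normal(size=(12, 2))
        V = rng.normal(size=(5, 2))
        X = U @ V.T
        Xm = X.copy()
        Xm[:6, 4] = np.nan
        out = svd_impute(Xm, rank=2, tol=1e-12, max_iter=2000)

        # independent oracle: plain alternating least squares from scratch
        obs = ~np.isnan(Xm)
        rng2 = np.random.default_rng(1)
        S, L = rng2.normal(size=(12, 2)), rng2.normal(size=(5, 2))
        for _ in range(500):
            for i in range(12):
                S[i], *_ = np.linalg.lstsq(L[obs[i]], Xm[i, obs[i]],
                                           rcond=None)
            for j in range(5):
                L[j], *_ = np.linalg.lstsq(S[obs[:, j]], Xm[obs[:, j], j],
                                           rcond=None)
        oracle = S @ L.T
        np.testing.assert_allclose(out[~obs], oracle[~obs], atol=1e-4)

    def test_invalid_rank(self, rng):
        with pytest.raises(ParameterError):
            svd_impute(rng.normal(size=(4, 4)), rank=4)


class TestNipals:
    def test_matches_truncated_svd_on_complete(self, rng):
        X = rng.normal(size=(25, 6))
        res = nipals_pca(X, 3)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        assert np.max(subspace_angles(res.loadings, Vt[:3].T)) < 1e-6
        assert np.max(subspace_angles(res.scores, U[:, :3])) < 1e-6
        np.testing.assert_allclose(res.explained_variance, s[:3] ** 2,
                                   rtol=1e-8)

    def test_rank1_explains_everything(self):
        X = np.outer([1.0, 2.0, 3.0, 4.0], [0.5, -1.0, 2.0])
        res = nipals_pca(X, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_rank2_with_missing_recovered(self, rng):
        U = rng.normal(size=(30, 2))
        V = rng.normal(size=(8, 2))
        X = U @ V.T
        mask = rng.random(X.shape) < 0.10
        Xm = np.where(mask, np.nan, X)
        res = nipals_pca(Xm, 2)
        recon = res.scores @ res.loadings.T
        assert np.abs(recon - X)[~mask].max() < 1e-3

    def test_unit_norm_loadings(self, rng):
        res = nipals_pca(rng.normal(size=(10, 5)), 2)
        np.testing.assert_allclose(np.linalg.norm(res.loadings, axis=0), 1.0,
                                   rtol=1e-10)


class TestPreprocessPca:
    def test_exact_rank_matrix_reconstructed(self, rng):
        U = rng.normal(size=(12, 2))
        V = rng.normal(size=(6, 2))
        X = U @ V.T
        pre, qc = preprocess_pca(_tm(X), r=3)  # centered matrix needs rank 3
        np.testing.assert_allclose(pre.values, X, atol=1e-8)
        assert qc.median_pearson == pytest.approx(1.0)

    def test_full_rank_limit_is_identity(self, rng):
        X = rng.normal(size=(10, 6))
        pre, _ = preprocess_pca(_tm(X), r=5)  # row-centered rank <= n-1
        np.testing.assert_allclose(pre.values, X, atol=1e-8)

    def test_denoising_beats_raw_input(self, rng):
        U = rng.normal(size=(60, 2))
        V = rng.normal(size=(6, 2))
        truth = U @ V.T
        noisy = truth + rng.normal(scale=0.3, size=truth.shape)
        pre, _ = preprocess_pca(_tm(noisy), r=2)
        msd_pre = np.mean((pre.values - truth) ** 2, axis=1)
        msd_raw = np.mean((noisy - truth) ** 2, axis=1)
        assert (msd_pre < msd_raw).mean() >= 0.9

    def test_reconstruction_error_nonincreasing_in_rank(self, rng):
        X = rng.normal(size=(15, 6))
        errors = []
        for r in range(1, 6):
            pre, _ = preprocess_pca(_tm(X), r=r)
            errors.append(float(np.sum((pre.values - X) ** 2)))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_imputes_missing_with_both_methods(self, small_matrix):
        for impute in ("svdimpute", "nipals"):
            pre, _ = preprocess_pca(small_matrix, r=2, impute=impute)
            assert not np.isnan(pre.values).any()


class TestQcCompare:
    def test_identity_comparison(self, rng):
        X = rng.normal(size=(10, 6))
        m = _tm(X)
        qc = qc_compare(m, X)
        np.testing.assert_allclose(qc.per_variable_pearson, 1.0)
        np.testing.assert_allclose(qc.per_variable_msd, 0.0, atol=1e-16)

    def test_shift_changes_msd_not_pearson(self, rng):
        X = rng.normal(size=(10, 6))
        m = _tm(X)
        qc = qc_compare(m, X + 0.5)
        np.testing.assert_allclose(qc.per_variable_pearson, 1.0)
        np.testing.assert_allclose(qc.per_variable_msd, 0.25, rtol=1e-12)

    def test_matches_formula_level_recomputation(self, rng):
        X = rng.normal(size=(20, 6))
        mask = rng.random(X.shape) < 0.2
        mask[:, 0] = False
        Xm = np.where(mask, np.nan, X)
        Y = rng.normal(size=(20, 6))
        qc = qc_compare(_tm(Xm), Y)
        for i in range(20):
            obs = ~mask[i]
            x, y = Xm[i, obs], Y[i, obs]
            msd = np.mean((x - y) ** 2)
            assert qc.per_variable_msd[i] == pytest.approx(msd, rel=1e-12)
            if obs.sum() >= 3:
                r_num = np.sum((x - x.mean()) * (y - y.mean()))
                r_den = np.sqrt(np.sum((x - x.mean()) ** 2)
                                * np.sum((y - y.mean()) ** 2))
                assert qc.per_variable_pearson[i] == pytest.approx(
                    r_num / r_den, rel=1e-10)

    def test_shape_mismatch_raises(self, small_matrix, rng):
        with pytest.raises(ShapeError):
            qc_compare(small_matrix, rng.normal(size=(3, 3)))
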