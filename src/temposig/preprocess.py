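"""Joint imputation and denoising of temporal matrices.

Two alternative routes complete and smooth the matrix:

* **Cubic splines** — each variable with at least 4 observed points is fit by
  a cubic regression spline whose flexibility is set by its degrees of
  freedom (dof = number of basis functions: 2 = linear, 3 = quadratic,
  4 = cubic, k >= 5 = cubic with k-4 interior knots). Evaluating the fitted
  curve at every time point imputes missing cells and smooths observed ones
  in a single step. The dof can be chosen automatically by cross-validation,
  globally or per variable. Variables with fewer than 4 observations fall
  back to low-rank SVD imputation.
* **Reduced-rank PCA** — missing cells are completed by iterative SVD
  imputation (or NIPALS), then the row-centered matrix is reconstructed from
  its top r principal components, discarding the residual variation as noise.

Either route returns a complete matrix plus a QC report comparing it with the
input (per-variable Pearson correlation and mean squared difference over the
originally observed cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .data import TemporalMatrix
from .errors import (
    InsufficientPointsError,
    NoEligibleVariablesError,
    ParameterError,
    ShapeError,
)

DEFAULT_DOF_GRID = (2, 3, 4, 5)
DEFAULT_SEED = 20200603


# ---------------------------------------------------------------------------
# Cubic regression splines


def _spline_knots(x_obs: np.ndarray, dof: int, degree: int) -> np.ndarray:
    """Clamped knot vector giving exactly `dof` B-spline basis functions."""
    n_interior = dof - (degree + 1)
    lo, hi = x_obs[0], x_obs[-1]
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x_obs, qs)
    else:
        interior = np.array([])
    return np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )


def _spline_fit_predict(x_obs, y_obs, x_eval, dof: int) -> np.ndarray:
    """Least-squares B-spline fit on (x_obs, y_obs), evaluated at x_eval.

    Outside the observed range the fitted curve is continued *linearly* with
    its boundary slope (the natural-spline convention): cubic extrapolation
    at a missing boundary time point is wildly unstable and would seed the
    completed matrix with outliers.
    """
    x_obs = np.asarray(x_obs, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    degree = min(3, dof - 1)
    t = _spline_knots(np.sort(x_obs), dof, degree)
    design = BSpline.design_matrix(x_obs, t, degree, extrapolate=True).toarray()
    coef, *_ = np.linalg.lstsq(design, y_obs, rcond=None)
    spline = BSpline(t, coef, degree, extrapolate=True)
    out = spline(x_eval)
    lo, hi = x_obs.min(), x_obs.max()
    left, right = x_eval < lo, x_eval > hi
    if left.any():
        out[left] = spline(lo) + spline(lo, nu=1) * (x_eval[left] - lo)
    if right.any():
        out[right] = spline(hi) + spline(hi, nu=1) * (x_eval[right] - hi)
    return out


def fit_spline_variable(series, time_points, dof) -> np.ndarray:
    """Fit one variable's time course with a cubic regression spline.

    Parameters
    ----------
    series : length-n array, NaN = missing
    time_points : length-n strictly increasing array
    dof : degrees of freedom, 2 <= dof <= number of observed points

    Returns
    -------
    length-n array: the spline evaluated at every time point (missing cells
    imputed, observed cells smoothed).
    """
    series = np.asarray(series, dtype=float)
    time_points = np.asarray(time_points, dtype=float)
    obs = ~np.isnan(series)
    n_obs = int(obs.sum())
    if n_obs < 4:
        raise InsufficientPointsError(
            f"cubic splines need >= 4 observed points, got {n_obs}"
        )
    dof = int(round(float(dof)))
    if dof < 2 or dof > n_obs:
        raise ParameterError(f"dof must lie in [2, {n_obs}], got {dof}")
    return _spline_fit_predict(time_points[obs], series[obs], time_points, dof)


@dataclass
class DofSelection:
    """Result of cross-validated dof selection."""

    mode: str                       # "global" | "per_variable"
    dof_grid: tuple
    global_dof: int | None = None
    per_variable: dict = field(default_factory=dict)  # variable index -> dof
    cv_errors: dict = field(default_factory=dict)     # dof -> summed CV error

    def dof_for(self, index: int, n_obs: int) -> int:
        dof = self.per_variable.get(index, self.global_dof)
        return int(min(dof, n_obs))


def _loo_cv_error(x_obs, y_obs, dof: int) -> float:
    """Leave-one-interior-observation-out squared prediction error.

    The two boundary observations are never held out: predicting them would
    score cubic *extrapolation*, whose error explodes for flexible fits and
    swamps the interpolation error the selection is meant to compare.
    """
    err = 0.0
    n = len(x_obs)
    for j in range(1, n - 1):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        pred = _spline_fit_predict(x_obs[mask], y_obs[mask], x_obs[j:j + 1], dof)
        err += (pred[0] - y_obs[j]) ** 2
    return err


def _kfold_cv_error(x_obs, y_obs, dof: int, folds: int, rng) -> float:
    """K-fold variant; boundary observations stay in every training set."""
    n = len(x_obs)
    interior = np.arange(1, n - 1)
    folds = min(folds, len(interior))
    order = rng.permutation(interior)
    err = 0.0
    for f in range(folds):
        test = order[f::folds]
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        if mask.sum() < 2:
            continue
        pred = _spline_fit_predict(x_obs[mask], y_obs[mask], x_obs[test], dof)
        err += float(np.sum((pred - y_obs[test]) ** 2))
    return err


def select_dof_cv(matrix: TemporalMatrix, dof_grid=DEFAULT_DOF_GRID,
                  mode: str = "global", folds="loo",
                  seed: int = DEFAULT_SEED) -> DofSelection:
    """Choose spline degrees of freedom by cross-validation.

    ``mode="global"`` returns the single dof minimising the held-out squared
    prediction error summed over all eligible variables (>= 5 observed points
    for leave-one-out); ``mode="per_variable"`` minimises per variable. Ties
    break toward the smallest dof.
    """
    dof_grid = tuple(sorted(int(d) for d in dof_grid))
    if any(d < 2 for d in dof_grid):
        raise ParameterError("dof grid values must be >= 2")
    if mode not in ("global", "per_variable"):
        raise ParameterError(f"unknown CV mode: {mode}")
    rng = np.random.default_rng(seed)
    min_obs = 5 if folds == "loo" else 4
    eligible = [
        i for i in range(matrix.n_variables)
        if (~np.isnan(matrix.values[i])).sum() >= min_obs
    ]
    if not eligible:
        raise NoEligibleVariablesError(
            f"no variable has >= {min_obs} observed points"
        )

    per_row_err = {}  # index -> {dof: err}
    for i in eligible:
        row = matrix.values[i]
        obs = ~np.isnan(row)
        x_obs, y_obs = matrix.time_points[obs], row[obs]
        errs = {}
        for dof in dof_grid:
            if folds == "loo":
                errs[dof] = _loo_cv_error(x_obs, y_obs, dof)
            else:
                errs[dof] = _kfold_cv_error(x_obs, y_obs, dof, int(folds), rng)
        per_row_err[i] = errs

    def _smallest_within_tol(errs: dict) -> int:
        # numerically-equal CV errors (e.g. all zero for noiseless data)
        # tie-break toward the smallest dof
        best = min(errs.values())
        tol = best * 1e-9 + 1e-12
        return min(d for d, e in errs.items() if e <= best + tol)

    sel = DofSelection(mode=mode, dof_grid=dof_grid)
    total = {d: sum(per_row_err[i][d] for i in eligible) for d in dof_grid}
    sel.cv_errors = total
    sel.global_dof = _smallest_within_tol(total)
    if mode == "per_variable":
        sel.per_variable = {
            i: _smallest_within_tol(per_row_err[i]) for i in eligible
        }
    return sel


# ---------------------------------------------------------------------------
# SVD imputation and NIPALS


def svd_impute(values: np.ndarray, rank: int, tol: float = 1e-6,
               max_iter: int = 100) -> np.ndarray:
    """Iterative low-rank completion of a matrix with missing cells.

    Missing cells are initialised at their row mean (column mean fallback) and
    repeatedly overwritten by the rank-`rank` truncated-SVD reconstruction of
    the completed matrix until the relative change of the imputed cells drops
    below `tol`. Observed cells are never altered.
    """
    X = np.array(values, dtype=float)
    m, n = X.shape
    if not 1 <= rank < min(m, n):
        raise ParameterError(f"rank must lie in [1, {min(m, n) - 1}], got {rank}")
    missing = np.isnan(X)
    if not missing.any():
        return X
    row_mean = np.where(
        np.all(np.isnan(values), axis=1), np.nan, np.nanmean(values, axis=1)
    )
    col_mean = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=0)
    fill = np.broadcast_to(row_mean[:, None], X.shape).copy()
    col_fill = np.broadcast_to(col_mean[None, :], X.shape)
    fill[np.isnan(fill)] = col_fill[np.isnan(fill)]
    fill[np.isnan(fill)] = np.nanmean(values)
    X[missing] = fill[missing]

    prev = X[missing].copy()
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        X[missing] = recon[missing]
        cur = X[missing]
        # change of the imputed cells relative to the overall matrix scale
        # (the imputed cells alone may legitimately be near zero)
        denom = max(float(np.linalg.norm(X)), 1e-12)
        if np.linalg.norm(cur - prev) / denom < tol:
            break
        prev = cur.copy()
    else:
        warnings.warn(
            f"svd_impute did not converge in {max_iter} iterations; "
            "returning best iterate", RuntimeWarning,
        )
    return X


@dataclass
class NipalsResult:
    scores: np.ndarray            # (m, r)
    loadings: np.ndarray          # (n, r), unit norm columns
    explained_variance: np.ndarray  # (r,) sum-of-squares captured per component
    converged: np.ndarray         # (r,) bool flags

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.explained_variance.sum() + getattr(self, "_residual_ss", 0.0)
        return self.explained_variance / total


def nipals_pca(values: np.ndarray, r: int, tol: float = 1e-10,
               max_iter: int = 2000, refine: bool = True) -> NipalsResult:
    """Sequential PCA by NIPALS, tolerating missing cells.

    Components are extracted one at a time by alternating regressions that
    skip missing cells, deflating after each; loadings have unit norm and
    components come out in decreasing explained-variance order (enforced by
    a final sort). No centering is applied here — center beforehand if the
    analysis calls for it.

    With missing cells the purely sequential pass is only approximate
    (deflation propagates the bias of each component's masked regressions),
    so by default the factors are polished by alternating least squares over
    the observed cells (`refine=True`), which drives the reconstruction of
    an exactly low-rank matrix to numerical accuracy. The refined factors
    are re-orthogonalised through an SVD of the reconstruction.
    """
    X = np.array(values, dtype=float)
    m, n = X.shape
    if not 1 <= r < min(m, n):
        raise ParameterError(f"r must lie in [1, {min(m, n) - 1}], got {r}")
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all() or not obs.any(axis=0).all():
        raise ParameterError("every row and column needs >= 1 observed value")
    total_ss = float(np.nansum(X ** 2))

    Xd = np.where(obs, X, 0.0)  # deflated working copy; missing held at 0
    scores = np.zeros((m, r))
    loadings = np.zeros((n, r))
    ev = np.zeros(r)
    converged = np.zeros(r, dtype=bool)

    for k in range(r):
        col = np.argmax(np.sum(Xd ** 2 * obs, axis=0))
        t = Xd[:, col].copy()
        if np.allclose(t, 0):
            t = np.ones(m)
        for _ in range(max_iter):
            denom_p = obs.T @ (t ** 2)
            p = (Xd.T @ t) / np.where(denom_p > 0, denom_p, 1.0)
            norm = np.linalg.norm(p)
            if norm == 0:
                break
            p /= norm
            denom_t = obs @ (p ** 2)
            t_new = (Xd @ p) / np.where(denom_t > 0, denom_t, 1.0)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-30):
                t = t_new
                converged[k] = True
                break
            t = t_new
        if not converged[k]:
            warnings.warn(
                f"NIPALS component {k + 1} did not converge", RuntimeWarning
            )
        scores[:, k] = t
        loadings[:, k] = p
        Xd = Xd - np.where(obs, np.outer(t, p), 0.0)
        ev[k] = float(t @ t)

    if refine and not obs.all():
        scores, loadings = _als_refine(X, obs, scores, loadings, tol=1e-12,
                                       max_sweeps=500)
        recon = scores @ loadings.T
        Ur, sr, Vtr = np.linalg.svd(recon, full_matrices=False)
        scores = Ur[:, :r] * sr[:r]
        loadings = Vtr[:r].T
        ev = sr[:r] ** 2

    order = np.argsort(-ev)
    result = NipalsResult(scores[:, order], loadings[:, order], ev[order],
                          converged[order])
    result._residual_ss = max(total_ss - float(ev.sum()), 0.0)
    return result


def _als_refine(X, obs, scores, loadings, tol: float, max_sweeps: int):
    """Alternating least squares on observed cells, warm-started."""
    S = scores.copy()
    L = loadings.copy()
    prev = S @ L.T
    for _ in range(max_sweeps):
        for i in range(X.shape[0]):
            oi = obs[i]
            S[i], *_ = np.linalg.lstsq(L[oi], X[i, oi], rcond=None)
        for j in range(X.shape[1]):
            oj = obs[:, j]
            L[j], *_ = np.linalg.lstsq(S[oj], X[oj, j], rcond=None)
        recon = S @ L.T
        if np.linalg.norm(recon - prev) <= tol * max(np.linalg.norm(recon),
                                                     1e-30):
            break
        prev = recon
    return S, L


# ---------------------------------------------------------------------------
# Full preprocessing routes


@dataclass
class PreprocessedMatrix:
    """A complete, denoised matrix with method provenance.

    `values` is the smoothed/reconstructed matrix used for clustering.
    `imputed_values` keeps the observed cells untouched and fills only the
    missing ones — the membership evaluation operates on it, since heavily
    smoothed profiles confined to a low-dimensional curve family carry too
    little residual information to discriminate genuine from accidental
    cluster membership. `null_smoother` maps any complete row into the
    smoothed space, so jackstraw null rows can traverse the same
    preprocessing as the observed data.
    """

    values: np.ndarray
    time_points: np.ndarray
    variable_ids: list
    method: str                   # "spline" | "pca"
    params: dict
    row_method: list              # per-row tag: "spline" | "svd" | "pca"
    provenance: dict = field(default_factory=dict)
    imputed_values: np.ndarray | None = None
    null_smoother: object = None  # callable row -> smoothed row

    def __post_init__(self):
        if np.isnan(self.values).any():
            raise ShapeError("preprocessed matrix must be complete")
        if self.imputed_values is None:
            self.imputed_values = self.values

    def as_temporal_matrix(self) -> TemporalMatrix:
        meta = {k: str(v) for k, v in self.provenance.items()}
        return TemporalMatrix(self.values, self.time_points,
                              self.variable_ids, meta)


@dataclass
class QCReport:
    """Per-variable agreement between input and preprocessed matrices."""

    per_variable_pearson: np.ndarray
    per_variable_msd: np.ndarray
    median_pearson: float
    median_msd: float
    n_excluded_pearson: int

    def to_dict(self) -> dict:
        return {
            "median_pearson": self.median_pearson,
            "median_msd": self.median_msd,
            "n_excluded_pearson": self.n_excluded_pearson,
        }


def qc_compare(original: TemporalMatrix, processed) -> QCReport:
    """Compare a preprocessed matrix with its input over observed cells.

    Per variable: Pearson correlation (rows with < 3 observed cells or zero
    variance on either side are excluded from the Pearson median and counted)
    and mean squared difference. Medians summarise the vectors, matching the
    platform's QC convention.
    """
    proc_values = processed.values if hasattr(processed, "values") else processed
    proc_values = np.asarray(proc_values, dtype=float)
    if proc_values.shape != original.values.shape:
        raise ShapeError(
            f"shape mismatch: {proc_values.shape} vs {original.values.shape}"
        )
    m = original.n_variables
    pearson = np.full(m, np.nan)
    msd = np.full(m, np.nan)
    for i in range(m):
        x = original.values[i]
        obs = ~np.isnan(x)
        y = proc_values[i, obs]
        x = x[obs]
        msd[i] = float(np.mean((x - y) ** 2))
        if len(x) >= 3 and np.std(x) > 0 and np.std(y) > 0:
            pearson[i] = float(np.corrcoef(x, y)[0, 1])
    n_excluded = int(np.isnan(pearson).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median_pearson = float(np.nanmedian(pearson)) if n_excluded < m else np.nan
    return QCReport(pearson, msd, median_pearson, float(np.median(msd)),
                    n_excluded)


def preprocess_spline(matrix: TemporalMatrix, dof="cv.global",
                      dof_grid=DEFAULT_DOF_GRID, fallback_rank: int = 2,
                      seed: int = DEFAULT_SEED):
    """Spline route: smooth/impute each variable, SVD fallback for sparse rows.

    Variables with >= 4 observed points get a cubic regression spline (dof
    fixed, or chosen by CV when `dof` is ``"cv.global"`` /
    ``"cv.per_variable"``); variables with fewer observations have their
    missing cells filled by rank-`fallback_rank` SVD imputation of the whole
    matrix and are left unsmoothed.

    Returns
    -------
    (PreprocessedMatrix, QCReport)
    """
    m, n = matrix.values.shape
    n_obs = (~np.isnan(matrix.values)).sum(axis=1)

    if isinstance(dof, str):
        if dof not in ("cv.global", "cv.per_variable"):
            raise ParameterError(f"unknown dof option: {dof!r}")
        mode = "global" if dof == "cv.global" else "per_variable"
        selection = select_dof_cv(matrix, dof_grid, mode=mode, seed=seed)
    else:
        selection = DofSelection(mode="fixed", dof_grid=tuple(dof_grid),
                                 global_dof=int(round(float(dof))))

    out = np.array(matrix.values, dtype=float)
    row_method = []
    spline_rows = np.flatnonzero(n_obs >= 4)
    sparse_rows = np.flatnonzero(n_obs < 4)
    if len(sparse_rows) and matrix.missing_mask.any():
        rank = min(fallback_rank, min(m, n) - 1)
        completed = svd_impute(matrix.values, rank=rank)
    else:
        completed = np.where(np.isnan(out), 0.0, out)

    for i in range(m):
        if i in set(sparse_rows):
            out[i] = np.where(np.isnan(out[i]), completed[i], out[i])
            row_method.append("svd")
        else:
            dof_i = selection.dof_for(i, int(n_obs[i]))
            out[i] = fit_spline_variable(matrix.values[i], matrix.time_points,
                                         dof_i)
            row_method.append("spline")

    params = {"dof": dof if isinstance(dof, str) else selection.global_dof,
              "dof_grid": list(selection.dof_grid),
              "selected_global_dof": selection.global_dof,
              "fallback_rank": fallback_rank,
              "n_spline_rows": int(len(spline_rows)),
              "n_fallback_rows": int(len(sparse_rows)),
              "seed": seed}
    imputed = np.where(np.isnan(matrix.values), out, matrix.values)
    global_dof = int(min(selection.global_dof, n))
    time_points = matrix.time_points

    def null_smoother(row, _tp=time_points, _dof=global_dof):
        n_obs = int((~np.isnan(row)).sum())
        return fit_spline_variable(row, _tp, min(_dof, n_obs))

    pre = PreprocessedMatrix(out, matrix.time_points, matrix.variable_ids,
                             method="spline", params=params,
                             row_method=row_method,
                             provenance={"method": "spline", **{
                                 k: str(v) for k, v in params.items()}},
                             imputed_values=imputed,
                             null_smoother=null_smoother)
    return pre, qc_compare(matrix, pre)


def _auto_rank(centered: np.ndarray, var_fraction: float) -> int:
    s = np.linalg.svd(centered, compute_uv=False)
    frac = np.cumsum(s ** 2) / max(float(np.sum(s ** 2)), 1e-300)
    r = int(np.searchsorted(frac, var_fraction) + 1)
    return max(1, min(r, min(centered.shape) - 1))


def preprocess_pca(matrix: TemporalMatrix, r="auto", impute: str = "svdimpute",
                   var_fraction: float = 0.9):
    """PCA route: complete the matrix, then reconstruct from top components.

    Missing cells are imputed by iterative SVD completion (``"svdimpute"``) or
    NIPALS; the completed matrix is row-centered, reconstructed from its top
    `r` principal components and the centers restored. ``r="auto"`` picks the
    smallest rank capturing at least `var_fraction` of the variance.

    Returns
    -------
    (PreprocessedMatrix, QCReport)
    """
    if impute not in ("svdimpute", "nipals"):
        raise ParameterError(f"unknown imputation method: {impute!r}")
    X = np.array(matrix.values, dtype=float)
    m, n = X.shape
    missing = np.isnan(X)

    if r == "auto":
        row_mean = np.nanmean(X, axis=1, keepdims=True)
        rough = np.where(missing, np.broadcast_to(row_mean, X.shape), X)
        rank = _auto_rank(rough - rough.mean(axis=1, keepdims=True),
                          var_fraction)
    else:
        rank = int(r)
        if not 1 <= rank < min(m, n):
            raise ParameterError(f"r must lie in [1, {min(m, n) - 1}], got {rank}")

    if missing.any():
        if impute == "svdimpute":
            completed = svd_impute(X, rank=rank)
        else:
            centers = np.nanmean(X, axis=1, keepdims=True)
            res = nipals_pca(X - centers, rank)
            recon = res.scores @ res.loadings.T + centers
            completed = np.where(missing, recon, X)
    else:
        completed = X

    centers = completed.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(completed - centers, full_matrices=False)
    recon = (U[:, :rank] * s[:rank]) @ Vt[:rank] + centers

    V = Vt[:rank].T  # (n, rank) basis of the retained temporal subspace

    def null_smoother(row, _V=V):
        c = row.mean()
        return c + (row - c) @ _V @ _V.T

    params = {"r": rank, "impute": impute, "var_fraction": var_fraction,
              "auto": r == "auto"}
    pre = PreprocessedMatrix(recon, matrix.time_points, matrix.variable_ids,
                             method="pca", params=params,
                             row_method=["pca"] * m,
                             provenance={"method": "pca", **{
                                 k: str(v) for k, v in params.items()}},
                             imputed_values=completed,
                             null_smoother=null_smoother)
    return pre, qc_compare(matrix, pre)
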