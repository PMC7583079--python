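"""Jackstraw evaluation of cluster membership.

Testing whether a variable belongs to the cluster it was assigned to is
circular when the clusters were learned from the same matrix: every variable
looks associated with its own cluster mean. The jackstraw breaks the
circularity by resampling. In each of B iterations a small number s of rows
are replaced by permuted copies of themselves (destroying their temporal
structure while preserving the marginal distribution), the matrix is
re-clustered starting from the observed centers, and the membership
F-statistics of those synthetic null rows — which by construction do not
belong anywhere — are pooled into an empirical null. Observed F-statistics
are compared against this pool to give per-variable p-values that account
for the over-fitting of the clustering itself.

The p-values feed a two-group mixture: pi0 (the null proportion, Storey
estimator) and a monotone density estimate of the p-values give a local
false discovery rate, and the posterior inclusion probability PIP = 1 - lfdr
is the probability that a variable genuinely follows its cluster's pattern.
Selection retains variables with PIP above a threshold (0.8 in the platform's
cardiac O-PTM use case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .cluster import ClusteringResult, hierarchical_cluster, kmeans_cluster
from .errors import DegenerateCenterError, ParameterError

_F_CAP = np.finfo(float).max / 4  # sentinel for a perfect (RSS = 0) fit


def membership_f_stat(variable, center) -> float:
    """Regression F-statistic of a variable on its cluster's mean profile.

    Simple linear regression y = a + b*c: F = (TSS - RSS) / (RSS / (n - 2))
    with TSS about the variable's mean. A constant variable gives F = 0; a
    perfect fit (RSS = 0) is reported as a large finite cap so ordering
    against the null pool stays well defined.
    """
    y = np.asarray(variable, dtype=float)
    c = np.asarray(center, dtype=float)
    n = len(y)
    if n < 3 or len(c) != n:
        raise ParameterError("need equal-length series with n >= 3")
    c_var = np.var(c)
    if c_var == 0:
        raise DegenerateCenterError("cluster center is constant")
    yc = y - y.mean()
    cc = c - c.mean()
    tss = float(yc @ yc)
    if tss == 0:
        return 0.0
    beta = float(yc @ cc) / float(cc @ cc)
    rss = tss - beta ** 2 * float(cc @ cc)
    rss = max(rss, 0.0)
    if rss <= tss * 1e-14:
        return float(_F_CAP)
    return float((tss - rss) / (rss / (n - 2)))


def _f_stats_for(X: np.ndarray, labels: np.ndarray,
                 centers: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        center = centers[labels[i] - 1]
        if np.var(center) == 0:
            out[i] = 0.0
        else:
            out[i] = membership_f_stat(X[i], center)
    return out


@dataclass
class JackstrawResult:
    """Observed and null F-statistics with derived p-values, lfdr and PIPs."""

    observed_f: np.ndarray
    null_f: np.ndarray            # pooled, length s*B
    p_values: np.ndarray
    pi0: float
    lfdr: np.ndarray
    pip: np.ndarray               # 1 - lfdr, elementwise
    q_values: np.ndarray          # BH on the jackstraw p-values (reported only)
    s: int
    B: int
    seed: int
    variable_ids: list | None = None
    labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"s": self.s, "B": self.B, "seed": self.seed, "pi0": self.pi0}


@dataclass
class SelectionReport:
    """Variables retained by the PIP threshold."""

    pip_threshold: float
    retained_ids: list
    n_input: int
    n_retained: int

    def to_dict(self) -> dict:
        return {
            "pip_threshold": self.pip_threshold,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "retained_ids": list(self.retained_ids),
        }


def jackstraw_cluster_test(matrix, clustering: ClusteringResult,
                           s: int | None = None, B: int | None = None,
                           seed: int = 20200603, variable_ids=None,
                           smoother=None, cluster_matrix=None,
                           null_maker=None) -> JackstrawResult:
    """Jackstraw test of cluster membership for every variable.

    Parameters
    ----------
    matrix : complete (m, n) array or TemporalMatrix-like
        The matrix the clustering was computed from.
    clustering : ClusteringResult
        Output of `kmeans_cluster` or `hierarchical_cluster` on `matrix`.
    s : rows permuted per iteration (default ceil(0.1 * m))
    B : iterations (default smallest B with s * B >= 10000)
    seed : RNG seed; the whole procedure is deterministic given it.
    smoother : optional callable row -> row applied to each permuted null row
        to map it into the space the clustering lives in. When the clustered
        matrix went through a per-row smoother (e.g. the spline
        preprocessing), the synthetic nulls must pass through the same
        smoother to stay exchangeable with the observed rows — a raw
        permuted row is jagged, fits any smooth center poorly, and would
        make the null stochastically too weak.
    cluster_matrix : optional complete (m, n) array: the matrix `clustering`
        was computed from, when it differs from the evaluation matrix. The
        canonical split is evaluation on the imputed-but-unsmoothed matrix
        (full residual information for the F-statistic) with clustering and
        re-clustering on its smoothed counterpart; requires `smoother`.
    null_maker : optional callable (i, rng) -> (eval_row, cluster_row)
        producing the synthetic null version of row i in both spaces. Use it
        to mirror row-level preprocessing exactly (e.g. permute only the
        observed values of the row and re-impute its missing pattern), so
        that nulls and observed rows traverse the identical pipeline.
        Overrides `smoother` for null construction.

    Notes
    -----
    p-values use the add-one empirical estimator
    ``p_i = (1 + #{null F >= observed F_i}) / (1 + s*B)`` and therefore lie
    in [1/(s*B + 1), 1].
    """
    X = matrix.values if hasattr(matrix, "values") else np.asarray(matrix,
                                                                   dtype=float)
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if variable_ids is None and hasattr(matrix, "variable_ids"):
        variable_ids = list(matrix.variable_ids)
    if s is None:
        s = ceil(0.1 * m)
    s = int(s)
    if not 1 <= s < m:
        raise ParameterError(f"s must lie in [1, m-1] = [1, {m - 1}], got {s}")
    if B is None:
        B = ceil(10000 / s)
    B = int(B)
    if B < 1:
        raise ParameterError("B must be >= 1")

    if cluster_matrix is not None:
        C = np.asarray(cluster_matrix, dtype=float)
        if C.shape != X.shape:
            raise ParameterError("cluster_matrix shape must match matrix")
        if smoother is None:
            raise ParameterError("cluster_matrix requires a smoother mapping "
                                 "evaluation rows into the clustered space")
    else:
        C = X

    observed_f = _f_stats_for(X, clustering.labels, clustering.centers)

    rng = np.random.default_rng(seed)
    null_f = np.empty(s * B)
    for b in range(B):
        idx = rng.choice(m, size=s, replace=False)
        Xb = X.copy()
        Cb = C.copy() if C is not X else Xb
        for i in idx:
            if null_maker is not None:
                Xb[i], Cb[i] = null_maker(i, rng)
            else:
                Xb[i] = rng.permutation(X[i])
                if smoother is not None:
                    Cb[i] = smoother(Xb[i])
        re = _recluster(Cb, clustering, int(rng.integers(2 ** 31)))
        null_f[b * s:(b + 1) * s] = _f_stats_for(
            Xb[idx], re.labels[idx], re.centers
        )

    sorted_null = np.sort(null_f)
    n_ge = len(sorted_null) - np.searchsorted(sorted_null, observed_f,
                                              side="left")
    p_values = (1.0 + n_ge) / (1.0 + s * B)

    pi0 = estimate_pi0(p_values)
    lfdr, pip = compute_pips(p_values, pi0)
    q_values = multipletests(p_values, method="fdr_bh")[1]
    return JackstrawResult(observed_f, null_f, p_values, pi0, lfdr, pip,
                           q_values, s, B, int(seed), variable_ids,
                           clustering.labels.copy())


def jackstraw_membership(original, preprocessed, clustering,
                         s: int | None = None, B: int | None = None,
                         seed: int = 20200603) -> JackstrawResult:
    """Jackstraw evaluation wired to a preprocessing result.

    Clustering (and the re-clustering inside each jackstraw iteration)
    happens in the smoothed space of `preprocessed.values`; the membership
    F-statistics are computed on `preprocessed.imputed_values`, where the
    observed cells are untouched.

    Each synthetic null row mirrors the observed pipeline exactly: the
    *observed* values of the row are permuted among the observed positions
    (its missing pattern is preserved), the row is re-imputed/re-smoothed by
    the same per-row smoother, and only then does it enter the
    re-clustering. Without this, observed rows would carry self-consistent
    imputed cells and a smoothness advantage the nulls lack, biasing the
    membership p-values.
    """
    smoothed = preprocessed.values
    imputed = preprocessed.imputed_values
    ids = getattr(original, "variable_ids", None)
    smoother = preprocessed.null_smoother
    raw = getattr(original, "values", None)
    missing = (np.isnan(raw) if raw is not None
               else np.zeros_like(imputed, dtype=bool))

    # the spline smoother is a per-row operation that tolerates missing
    # cells, so the null can keep each row's own missing pattern; the PCA
    # projection operates on complete rows only
    pattern_preserving = preprocessed.method == "spline" and raw is not None

    def null_maker(i, rng):
        obs = ~missing[i]
        if pattern_preserving and 4 <= obs.sum() < len(obs):
            row = raw[i].copy()
            row[obs] = rng.permutation(row[obs])
            fitted = smoother(row)
            return np.where(obs, row, fitted), fitted
        permuted = rng.permutation(imputed[i])
        return permuted, smoother(permuted)

    if smoother is None:
        return jackstraw_cluster_test(imputed, clustering, s=s, B=B,
                                      seed=seed, variable_ids=ids)
    return jackstraw_cluster_test(
        imputed, clustering, s=s, B=B, seed=seed, variable_ids=ids,
        smoother=smoother, cluster_matrix=smoothed, null_maker=null_maker,
    )


def _recluster(Xb: np.ndarray, clustering: ClusteringResult,
               seed: int) -> ClusteringResult:
    """Re-fit the same clustering model on a jackstraw-perturbed matrix.

    K-means takes the better (by WCSS) of a Lloyd run warm-started at the
    observed centers and a fresh best-of-restarts fit with as many restarts
    as the observed clustering used. Warm-starting alone leaves the
    synthetic nulls without the restart-selection advantage the observed
    rows enjoyed, which makes observed F-statistics stochastically larger
    than null ones and the p-values measurably anti-conservative.
    The hierarchical model (deterministic, no initialization) is re-fit with
    the same distance/linkage and K.
    """
    if clustering.method == "kmeans":
        warm = kmeans_cluster(Xb, clustering.K, init=clustering.centers)
        restarts = clustering.restarts or 0
        if restarts < 1:
            return warm
        cold = kmeans_cluster(Xb, clustering.K, restarts=restarts, seed=seed)
        return warm if warm.wcss <= cold.wcss else cold
    return hierarchical_cluster(Xb, clustering.K,
                                distance=clustering.distance,
                                linkage=clustering.linkage or "average")


# ---------------------------------------------------------------------------
# pi0, local FDR and PIPs


def estimate_pi0(p_values, lambdas=None) -> float:
    """Storey-type estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on a lambda grid, then a
    cubic-polynomial smooth evaluated at the largest lambda, clamped to
    (0, 1]. With fewer than 20 p-values the estimate is unstable and the
    conservative pi0 = 1 is returned with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    m = len(p)
    if m < 20:
        warnings.warn("fewer than 20 p-values; falling back to pi0 = 1",
                      RuntimeWarning)
        return 1.0
    lambdas = np.arange(0.05, 0.96, 0.05) if lambdas is None else \
        np.asarray(lambdas, dtype=float)
    pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    # var(pi0(lambda)) grows like 1/(1-lambda): weight the fit accordingly,
    # and average the smoothed curve over the top grid points rather than
    # reading a single extrapolated edge value (which is noise-dominated).
    coef = np.polyfit(lambdas, pi0_l, deg=3, w=np.sqrt(1.0 - lambdas))
    smoothed = np.polyval(coef, lambdas)
    k = min(5, len(lambdas))
    pi0 = float(np.mean(smoothed[-k:]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def compute_pips(p_values, pi0: float, n_bins: int | None = None):
    """Local FDR and posterior inclusion probabilities from p-values.

    The p-value density f(p) is estimated by an equal-width histogram made
    monotone non-increasing toward p = 1 (pool-adjacent-violators); under the
    two-group model with a Uniform(0,1) null,
    ``lfdr(p) = pi0 * 1 / f(p)`` (clamped to [0, 1]) and ``PIP = 1 - lfdr``.

    Returns
    -------
    (lfdr, pip) arrays; ``pip + lfdr == 1`` elementwise by construction.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    if not 0 < pi0 <= 1:
        raise ParameterError("pi0 must lie in (0, 1]")
    m = len(p)
    if n_bins is None:
        n_bins = int(min(50, max(10, m // 50)))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    width = 1.0 / n_bins
    density = counts / (m * width)
    if np.all(counts == (counts > 0) * m):  # all p in one bin
        warnings.warn("degenerate p-value distribution (single bin)",
                      RuntimeWarning)
    centers = (edges[:-1] + edges[1:]) / 2
    iso = IsotonicRegression(increasing=False)
    f_hat_bins = iso.fit_transform(centers, density)
    bin_idx = np.minimum((p / width).astype(int), n_bins - 1)
    f_hat = f_hat_bins[bin_idx]
    with np.errstate(divide="ignore"):
        lfdr = np.where(f_hat > 0, pi0 / np.maximum(f_hat, 1e-300), np.inf)
    lfdr = np.clip(lfdr, 0.0, 1.0)
    pip = 1.0 - lfdr
    return lfdr, pip


def pip_filter(result: JackstrawResult, threshold: float = 0.8) -> SelectionReport:
    """Retain variables whose PIP strictly exceeds `threshold`."""
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must lie in [0, 1]")
    keep = result.pip > threshold
    if result.variable_ids is not None:
        retained = [result.variable_ids[i] for i in np.flatnonzero(keep)]
    else:
        retained = [int(i) for i in np.flatnonzero(keep)]
    return SelectionReport(float(threshold), retained, len(result.pip),
                           int(keep.sum()))
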