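"""PCA for complete and missing-value matrices, plus a distance-based outlier screen.

The missing-value variant replaces unobserved cells with rank-r model
reconstructions, iterating (re-center, truncated SVD, re-impute) until the
imputed estimates stabilize.  Observed cells are never modified.  This is the
classical model-based imputation scheme for score-level fusion, where each
row missing one platform's scores is missing a contiguous column block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats

__all__ = ["PCAModel", "fit_pca", "fit_pca_missing", "project_pca", "detect_outliers"]


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.abs(U).argmax(axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return signs


@dataclass
class PCAModel:
    """Column-mean-centered PCA of rank r.

    ``loadings`` is q x r with orthonormal columns; ``scores`` is n x r;
    ``explained_variance`` holds each component's share of total variance.
    For a missing-value fit, ``imputed_values`` records the positions
    (row, col) and final estimates of the originally missing cells and
    ``observed_error_history`` the RMS reconstruction error over observed
    cells at each iteration.
    """

    loadings: np.ndarray
    scores: np.ndarray
    column_means: np.ndarray
    explained_variance: np.ndarray
    singular_values: np.ndarray
    imputed_values: list[tuple[int, int, float]] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = True
    observed_error_history: list[float] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.loadings.shape[1]


def _svd_pca(Xc: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    P = Vt[:r].T
    signs = _fix_signs(P)
    P = P * signs
    T = Xc @ P
    total = (s ** 2).sum()
    ev = (s[:r] ** 2) / total if total > 0 else np.zeros(r)
    return P, T, ev, s[:r]


def fit_pca(X: np.ndarray, r: int) -> PCAModel:
    """Rank-r PCA of a complete matrix via column-mean-centered SVD."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix has missing cells; use fit_pca_missing")
    n, q = X.shape
    if not (1 <= r <= min(n - 1, q)):
        raise ValueError(f"r={r} out of range [1, {min(n - 1, q)}]")
    mu = X.mean(axis=0)
    P, T, ev, s = _svd_pca(X - mu, r)
    return PCAModel(P, T, mu, ev, s)


def fit_pca_missing(
    X: np.ndarray,
    r: int,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> PCAModel:
    """Rank-r PCA of a matrix with NaN-marked missing cells.

    Missing cells start at observed column means and are iterated to the
    rank-r model reconstruction; convergence is declared when the relative
    Frobenius change of the imputed cells drops to ``tol``.  Column means are
    re-estimated each iteration.  Every row and column must have at least one
    observed cell.
    """
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    mask = np.isnan(X)  # True = missing
    if not (1 <= r <= min(n - 1, q)):
        raise ValueError(f"r={r} out of range [1, {min(n - 1, q)}]")
    if mask.all(axis=1).any():
        i = int(mask.all(axis=1).argmax())
        raise ValueError(f"row {i} is fully missing")
    if mask.all(axis=0).any():
        j = int(mask.all(axis=0).argmax())
        raise ValueError(f"column {j} is fully missing")

    if not mask.any():
        model = fit_pca(X, r)
        model.n_iterations = 0
        return model

    Xf = X.copy()
    col_means_obs = np.nanmean(X, axis=0)
    Xf[mask] = np.broadcast_to(col_means_obs, X.shape)[mask]

    prev = Xf[mask].copy()
    # change is measured against the observed data's RMS (not the imputed
    # cells' own norm, which can legitimately be ~0, e.g. for standardized
    # columns)
    scale = float(np.sqrt(np.mean(X[~mask] ** 2)))
    scale = scale if scale > 0 else 1.0
    n_mis = int(mask.sum())
    err_hist: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = Xf.mean(axis=0)
        Xc = Xf - mu
        P, T, ev, s = _svd_pca(Xc, r)
        recon = T @ P.T + mu
        err_hist.append(float(np.sqrt(np.mean((recon[~mask] - X[~mask]) ** 2))))
        Xf[mask] = recon[mask]
        cur = Xf[mask]
        change = np.linalg.norm(cur - prev) / (np.sqrt(n_mis) * scale)
        prev = cur.copy()
        if change <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"missing-value PCA did not converge in {max_iter} iterations "
            f"(last relative change {change:.3g})", stacklevel=2,
        )
    mu = Xf.mean(axis=0)
    P, T, ev, s = _svd_pca(Xf - mu, r)
    imputed = [(int(i), int(j), float(Xf[i, j])) for i, j in np.argwhere(mask)]
    return PCAModel(P, T, mu, ev, s, imputed, it, converged, err_hist)


def project_pca(model: PCAModel, x_new: np.ndarray,
                allow_underdetermined: bool = False) -> np.ndarray:
    """Score a new sample; missing (NaN) coordinates are handled by least squares.

    Complete case: ``(x - mu) @ P``.  Incomplete case: the score t minimizing
    ``||x_obs - mu_obs - P_obs t||^2`` over the observed coordinates; at least
    r coordinates must be observed unless ``allow_underdetermined``, in which
    case the minimum-norm solution is returned (score components the observed
    coordinates say nothing about are set to zero, the score mean).
    """
    x = np.asarray(x_new, dtype=float)
    if x.ndim == 2:
        return np.vstack([project_pca(model, row, allow_underdetermined)
                          for row in x])
    obs = ~np.isnan(x)
    r = model.rank
    if obs.sum() < r and not allow_underdetermined:
        raise ValueError(f"only {int(obs.sum())} observed entries; need >= {r}")
    if obs.all():
        return (x - model.column_means) @ model.loadings
    Pobs = model.loadings[obs]
    resid = x[obs] - model.column_means[obs]
    t, *_ = np.linalg.lstsq(Pobs, resid, rcond=None)
    return t


def detect_outliers(
    X: np.ndarray,
    r: int,
    quantile: float = 0.975,
    sample_ids: list[str] | None = None,
):
    """Classical-PCA outlier screen: score (Mahalanobis) and orthogonal distances.

    A sample is flagged if its squared score distance exceeds the chi-square(r)
    quantile or its orthogonal (residual-norm) distance exceeds a cutoff from
    the Wilson-Hilferty normal approximation of the residual distribution.
    Exploratory only — never applied automatically inside the fusion pipeline.
    """
    import pandas as pd

    if not (0.0 < quantile < 1.0):
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    model = fit_pca(X, r)
    T = model.scores
    # per-component score variance; Mahalanobis in score space is diagonal
    lam = (model.singular_values ** 2) / (n - 1)
    lam = np.where(lam > 0, lam, np.finfo(float).tiny)
    sd2 = (T ** 2 / lam).sum(axis=1)
    score_dist = np.sqrt(sd2)
    score_cut = np.sqrt(scipy.stats.chi2.ppf(quantile, df=r))

    resid = (X - model.column_means) - T @ model.loadings.T
    od = np.linalg.norm(resid, axis=1)
    # Wilson-Hilferty: od^(2/3) approximately normal
    od23 = od ** (2.0 / 3.0)
    m, s = od23.mean(), od23.std(ddof=1)
    if s == 0:
        od_cut = np.inf
    else:
        od_cut = (m + s * scipy.stats.norm.ppf(quantile)) ** 1.5
    flagged = (score_dist > score_cut) | (od > od_cut)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    table = pd.DataFrame({
        "sample_id": ids,
        "score_distance": score_dist,
        "orthogonal_distance": od,
        "flagged": flagged,
    })
    return [ids[i] for i in np.flatnonzero(flagged)], table
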