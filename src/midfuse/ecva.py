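"""Extended Canonical Variates Analysis (eCVA).

Fisher-style canonical variates maximize the ratio of between-group to
within-group variance, w' S_b w / w' S_w w, which for non-singular S_w is the
eigenproblem S_w^-1 S_b w = lambda w with at most min(p, g-1) non-trivial
directions.  When variables outnumber samples S_w is singular and the
eigenproblem cannot be solved directly; eCVA recasts it as the regression

    S_w B  ~  Y,       Y columns = pairwise group-mean differences,

and solves it with a rank-deficient-tolerant PLS2 fit of ``n_pls`` latent
variables.  The canonical directions W are the leading g-1 left singular
vectors of the coefficient matrix B; scores are the centered data projected
on W.  With well-conditioned S_w and a full complement of latent variables
the PLS solution collapses to B = S_w^-1 Y, recovering the classical
solution exactly.

The PLS2 solver here is a deliberately uncentered NIPALS with deflation:
the rows of the predictor matrix S_w are variables, not samples, so the
customary column centering of regression PLS would distort the eigenproblem
being solved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ScalingModel

__all__ = [
    "ECVAModel",
    "within_covariance",
    "between_covariance",
    "pls2_regression",
    "fit_ecva",
    "project_ecva",
    "select_pls_components",
    "select_top_k_and_refit",
]


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, list[int]]:
    labels = np.asarray(labels, dtype=int)
    classes = sorted(set(labels.tolist()))
    return labels, classes


def within_covariance(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled within-group covariance: sum of group scatters over (n - g).

    Every group needs >= 2 samples; requires n > g.
    """
    X = np.asarray(X, dtype=float)
    labels, classes = _check_labels(labels)
    n, p = X.shape
    g = len(classes)
    if n <= g:
        raise ValueError(f"need n > g (got n={n}, g={g})")
    S = np.zeros((p, p))
    for c in classes:
        Xi = X[labels == c]
        if Xi.shape[0] < 2:
            raise ValueError(f"class {c} has a single sample; cannot pool within-group scatter")
        Xc = Xi - Xi.mean(axis=0)
        S += Xc.T @ Xc
    S /= (n - g)
    return (S + S.T) / 2.0


def between_covariance(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Between-group covariance: sum_i n_i (xbar_i - xbar)(xbar_i - xbar)' / (g - 1)."""
    X = np.asarray(X, dtype=float)
    labels, classes = _check_labels(labels)
    g = len(classes)
    if g < 2:
        raise ValueError(f"need >= 2 groups, got {g}")
    xbar = X.mean(axis=0)
    p = X.shape[1]
    S = np.zeros((p, p))
    for c in classes:
        Xi = X[labels == c]
        d = Xi.mean(axis=0) - xbar
        S += Xi.shape[0] * np.outer(d, d)
    S /= (g - 1)
    return (S + S.T) / 2.0


def pls2_regression(X: np.ndarray, Y: np.ndarray, n_components: int,
                    max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Uncentered NIPALS PLS2: return B with X @ B approximating Y.

    Deflation-based latent-variable regression; with n_components equal to
    rank(X) the coefficients coincide with the minimum-norm least-squares
    solution.  No centering or scaling is applied — the caller's problem
    defines the origin.
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    n, p = X.shape
    m = Y.shape[1]
    A = int(n_components)
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((m, A))
    for a in range(A):
        if np.linalg.norm(X) * np.linalg.norm(Y) == 0:
            A = a
            break
        u = Y[:, int(np.argmax((Y ** 2).sum(axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = X.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0:
                break
            w_new /= nw
            t = X @ w_new
            tt = t @ t
            if tt == 0:
                break
            q = Y.T @ t / tt
            nq = q @ q
            u_new = Y @ q / nq if nq > 0 else u
            if np.linalg.norm(w_new - w) <= tol:
                w = w_new
                break
            w, u = w_new, u_new
        else:
            w = w_new
        t = X @ w
        tt = t @ t
        if tt <= np.finfo(float).tiny:
            A = a
            break
        p_load = X.T @ t / tt
        q = Y.T @ t / tt
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a] = w, p_load, q
    W, P, Q = W[:, :A], P[:, :A], Q[:, :A]
    if A == 0:
        return np.zeros((p, m))
    # B = W (P'W)^-1 Q'
    M = P.T @ W
    return W @ np.linalg.solve(M, Q.T)


def _fix_signs_columns(W: np.ndarray) -> np.ndarray:
    idx = np.abs(W).argmax(axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


@dataclass
class ECVAModel:
    """Fitted eCVA model for one block (on already-scaled data)."""

    W: np.ndarray                      # p x (g-1) canonical directions, unit columns
    T: np.ndarray                      # n_train x (g-1) scores
    S_within: np.ndarray | None        # pooled within covariance (kept for p <= 512)
    Y_targets: np.ndarray              # p x m pairwise mean-difference targets
    B: np.ndarray                      # PLS coefficient matrix, p x m
    n_pls: int
    group_means: np.ndarray            # g x p (scaled space)
    overall_mean: np.ndarray
    classes: list[int]
    eigen_ratios: np.ndarray           # per-direction between/within variance ratio
    scaling: ScalingModel | None = None
    selected_variables: list[str] | None = None
    variable_ids: list[str] | None = None

    @property
    def n_directions(self) -> int:
        return self.W.shape[1]


def fit_ecva(X: np.ndarray, labels: np.ndarray, n_pls: int) -> ECVAModel:
    """Fit eCVA on a scaled training matrix.

    Builds Y from all g(g-1)/2 pairwise group-mean differences (for g=2 this
    is the single canonical difference), solves S_w B ~ Y by PLS2 with
    ``n_pls`` components, extracts W as the leading min(p, g-1) left singular
    vectors of B (unit norm, largest-magnitude entry positive) and scores
    T = (X - overall_mean) W.
    """
    X = np.asarray(X, dtype=float)
    labels, classes = _check_labels(labels)
    n, p = X.shape
    g = len(classes)
    if g < 2:
        raise ValueError("need >= 2 classes")
    if not (1 <= n_pls <= min(n - 1, p)):
        raise ValueError(f"n_pls={n_pls} out of range [1, {min(n - 1, p)}]")

    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    overall = X.mean(axis=0)

    pairs = [(i, j) for i in range(g) for j in range(i + 1, g)]
    Y = np.column_stack([means[i] - means[j] for i, j in pairs])
    if np.linalg.norm(Y) == 0:
        raise ValueError("no between-group signal: all group means are equal")

    # S_w = Xc' Xc / (n - g) has rank <= n - g; the PLS2 solution of
    # S_w B ~ Y depends on the problem only through its projection onto
    # range(S_w) (every NIPALS weight lies there), so for p >> n we solve the
    # equivalent reduced problem in the within-scatter eigenbasis.  This is a
    # change of basis, not an approximation: the full-rank limit is
    # B = S_w^+ Y either way.
    Xc = np.empty_like(X)
    for c in classes:
        rows = labels == c
        Xc[rows] = X[rows] - X[rows].mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("within-group scatter is zero; cannot fit eCVA")
    Q = Vt[:rank].T                                  # p x r
    A = np.diag(s[:rank] ** 2 / (n - g))             # Q' S_w Q
    B = Q @ pls2_regression(A, Q.T @ Y, min(n_pls, rank))
    Sw = within_covariance(X, labels) if p <= 512 else None
    n_dir = min(p, g - 1)
    U, sv, _ = np.linalg.svd(B, full_matrices=False)
    W = U[:, :n_dir]
    W = _fix_signs_columns(W)
    T = (X - overall) @ W

    # between/within variance ratio per direction, via projections (avoids
    # materializing p x p matrices for wide blocks)
    counts = np.array([(labels == c).sum() for c in classes])
    Mw = (means - overall) @ W
    num = (counts[:, None] * Mw ** 2).sum(axis=0) / (g - 1)
    den = ((Xc @ W) ** 2).sum(axis=0) / (n - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    return ECVAModel(W, T, Sw, Y, B, n_pls, means, overall, classes, ratios)


def project_ecva(model: ECVAModel, X_new: np.ndarray) -> np.ndarray:
    """Project new (already-scaled) samples on the canonical directions."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"expected {model.W.shape[0]} variables, got {X_new.shape[1]}"
            + (f"; model retains {model.selected_variables}" if model.selected_variables else "")
        )
    return (X_new - model.overall_mean) @ model.W


def _score_centroids(T: np.ndarray, labels: np.ndarray, classes: list[int]) -> np.ndarray:
    return np.vstack([T[labels == c].mean(axis=0) for c in classes])


def select_pls_components(
    X: np.ndarray,
    labels: np.ndarray,
    grid: list[int],
    n_splits: int = 7,
) -> int:
    """Choose the inner PLS component count by venetian-blinds cross-validation.

    Folds are assigned by cycling fold indices within each class (stratified,
    deterministic in the input order).  Each held-out sample is classified by
    the nearest class centroid in canonical-score space (Euclidean); the
    candidate with the fewest misclassifications wins, ties going to the
    smallest count.
    """
    grid = sorted(set(int(c) for c in grid))
    if not grid:
        raise ValueError("empty candidate grid")
    X = np.asarray(X, dtype=float)
    labels, classes = _check_labels(labels)
    n = X.shape[0]
    if len(grid) == 1:
        c = grid[0]
        if not (1 <= c <= min(n - 1, X.shape[1])):
            raise ValueError(f"n_pls={c} out of range")
        return c

    min_class = min(int((labels == c).sum()) for c in classes)
    k = n_splits
    # each training fold-complement must keep >=2 samples of each class
    while k > 2 and min_class - int(np.ceil(min_class / k)) < 2:
        k -= 1
        warnings.warn(f"reducing CV fold count to {k} to keep all classes in training folds",
                      stacklevel=2)
    if min_class - int(np.ceil(min_class / k)) < 2:
        raise ValueError("too few samples per class for cross-validation")

    fold = np.empty(n, dtype=int)
    for c in classes:
        idx = np.flatnonzero(labels == c)
        fold[idx] = np.arange(idx.size) % k

    errors = {}
    for cand in grid:
        wrong = 0
        for f in range(k):
            tr, te = fold != f, fold == f
            if not te.any():
                continue
            model = fit_ecva(X[tr], labels[tr], min(cand, np.count_nonzero(tr) - 1))
            cent = _score_centroids(model.T, labels[tr], model.classes)
            Tte = project_ecva(model, X[te])
            d = ((Tte[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
            pred = np.array(model.classes)[d.argmin(axis=1)]
            wrong += int((pred != labels[te]).sum())
        errors[cand] = wrong
    best = min(errors, key=lambda c: (errors[c], c))
    return best


def select_top_k_and_refit(
    X: np.ndarray,
    labels: np.ndarray,
    k: int,
    n_pls: int,
    variable_ids: list[str] | None = None,
) -> ECVAModel:
    """Rank variables by the norm of their W rows, keep the top k, refit.

    The screen fits eCVA on all p variables, scores each variable by the
    Euclidean length of its row of W over the g-1 directions, retains the k
    largest and refits on the reduced matrix.  Scaling (if any) is the
    caller's concern and is re-fit by block-level callers on the retained
    columns.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > p:
        raise ValueError(f"k={k} exceeds p={p}")
    full = fit_ecva(X, labels, n_pls)
    importance = np.linalg.norm(full.W, axis=1)
    order = np.argsort(-importance, kind="stable")
    keep = np.sort(order[:k])
    reduced = fit_ecva(X[:, keep], labels, min(n_pls, k))
    ids = variable_ids if variable_ids is not None else [str(j) for j in range(p)]
    reduced.selected_variables = [ids[j] for j in keep]
    reduced.variable_ids = reduced.selected_variables
    return reduced
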