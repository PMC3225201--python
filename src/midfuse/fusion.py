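"""The mid-level fusion pipeline.

Architecture: a representative test set is split off with the Kennard-Stone
algorithm; each block is preprocessed and compressed by eCVA into g-1
canonical scores on its own present training samples; the per-block scores
are concatenated (missing where a sample was not measured on a platform) and
analyzed by missing-value PCA; classification is nearest class centroid in
the retained PC space (Mahalanobis with the pooled within-class covariance,
in the spirit of principal component discriminant analysis).

All fitted statistics — scaling, canonical directions, PCA loadings,
centroids — derive from training samples only.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import AlignedStudy, OmicsBlock, align_blocks
from .preprocess import ScalingModel, fit_scaling, apply_scaling, integral_normalize
from .ecva import ECVAModel, fit_ecva, project_ecva, select_pls_components
from .mvpca import PCAModel, fit_pca_missing, project_pca

__all__ = [
    "FusionConfig",
    "BlockFit",
    "FusionModel",
    "kennard_stone_order",
    "kennard_stone_split",
    "fit_fusion",
    "classify",
    "evaluate",
    "low_level_fusion",
    "single_block_study",
    "model_fingerprint",
]


@dataclass
class FusionConfig:
    """Pipeline configuration.

    Per-block entries (``scaling``, ``normalize``, ``n_pls``, ``top_k``) are
    dicts keyed by block_id; a missing key falls back to the stated default.
    ``n_pls`` values may be an int or a candidate grid (list) resolved by
    inner cross-validation.
    """

    test_fraction: float = 0.20
    scaling: dict = field(default_factory=dict)        # block_id -> method, default vast
    normalize: dict = field(default_factory=dict)      # block_id -> none|integral
    n_pls: dict = field(default_factory=dict)          # block_id -> int | list[int]
    top_k: dict = field(default_factory=dict)          # block_id -> int | None
    r_global: int | None = None                        # default: all score columns
    seed: int = 0
    classifier: str = "nearest_centroid_mahalanobis"
    ks_stratified: bool = True
    default_scaling: str = "vast"
    default_n_pls: int | list = 3
    # standardize the concatenated canonical-score columns before the global
    # PCA.  Score scales are incommensurate across platforms, and with
    # block-contiguous missing patterns an unstandardized missing-value PCA
    # has a degenerate direction along which imputed cells grow without
    # bound; per-column autoscaling removes it.
    score_scaling: str = "autoscale"

    def __post_init__(self) -> None:
        if not (0.0 <= self.test_fraction < 1.0):
            raise ValueError(f"test_fraction must be in [0, 1), got {self.test_fraction}")
        if self.r_global is not None and self.r_global < 1:
            raise ValueError("r_global must be >= 1")
        if self.classifier not in ("nearest_centroid_mahalanobis", "nearest_centroid_euclidean"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.score_scaling not in ("none", "autoscale"):
            raise ValueError(f"unknown score_scaling {self.score_scaling!r}")

    def block_scaling(self, block_id: str) -> str:
        return self.scaling.get(block_id, self.default_scaling)

    def block_normalize(self, block_id: str) -> str:
        return self.normalize.get(block_id, "none")

    def block_n_pls(self, block_id: str):
        return self.n_pls.get(block_id, self.default_n_pls)

    def block_top_k(self, block_id: str) -> int | None:
        return self.top_k.get(block_id)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BlockFit:
    """Everything fitted for one block: preprocessing state + eCVA model."""

    block_id: str
    normalize: str
    scaling: ScalingModel
    kept_variable_ids: list[str]       # raw variable ids retained (after zero-var drop / top-k)
    ecva: ECVAModel
    n_pls: int


@dataclass
class FusionModel:
    """Fitted mid-level fusion model."""

    block_fits: list[BlockFit]
    concat_scores: np.ndarray          # n_train x sum_b(g-1), NaN where absent
    score_means: np.ndarray            # per-score-column standardization (train)
    score_sds: np.ndarray
    pca: PCAModel
    centroids: np.ndarray              # g x r_global, training-sample PC centroids
    pooled_cov: np.ndarray             # r_global x r_global pooled within-class covariance
    classes: list[int]
    config: FusionConfig
    train_ids: list[str]
    test_ids: list[str]
    score_column_blocks: list[str]     # block_id per concatenated score column

    @property
    def r_global(self) -> int:
        return self.pca.rank


def kennard_stone_order(X: np.ndarray, k: int) -> list[int]:
    """Row indices of the first ``k`` Kennard-Stone selections, in pick order.

    Seeds with the two mutually farthest points (Euclidean), then repeatedly
    adds the point whose minimal distance to the selected set is largest;
    ties break to the lowest index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[0]
    if k <= 0:
        return []
    if k >= m:
        return list(range(m))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    Doff = D.copy()
    np.fill_diagonal(Doff, -1.0)  # degenerate (all-identical) sets fall back to (0, 1)
    i, j = np.unravel_index(int(Doff.argmax()), D.shape)  # lowest flat index on ties
    first, second = (i, j) if i < j else (j, i)
    if k == 1:
        return [int(first)]
    selected = [int(first), int(second)]
    mind = np.minimum(D[first], D[second])
    while len(selected) < k:
        mind[selected] = -1.0
        nxt = int(mind.argmax())
        selected.append(nxt)
        mind = np.minimum(mind, D[nxt])
    return selected


def kennard_stone_split(
    X: np.ndarray,
    labels: Sequence[int] | None,
    fraction: float,
    stratified: bool = True,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list, list]:
    """Kennard-Stone selection of a representative subset as the TEST set.

    The classic max-min procedure on Euclidean distances: seed with the two
    mutually farthest points, then repeatedly add the point whose minimal
    distance to the already-selected set is largest.  Run per class when
    ``stratified`` (requires ``labels``); the test set has round(fraction*n)
    members (per class when stratified).  Deterministic: ties break to the
    lowest index.  Returns (train, test) as sample ids when given, else as
    row indices.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    ids = list(sample_ids) if sample_ids is not None else list(range(n))
    if len(ids) != n:
        raise ValueError("sample_ids length must match X rows")

    def _ks_indices(idx: np.ndarray, k: int) -> list[int]:
        return [int(idx[s]) for s in kennard_stone_order(X[idx], k)]

    if stratified:
        if labels is None:
            raise ValueError("stratified split requires labels")
        lab = np.asarray(labels)
        test_rows: list[int] = []
        for c in sorted(set(lab.tolist())):
            idx = np.flatnonzero(lab == c)
            k = int(round(fraction * idx.size))
            if fraction > 0 and k < 1:
                warnings.warn(f"class {c}: fraction*n < 1, contributing 0 test samples",
                              stacklevel=2)
            test_rows.extend(_ks_indices(idx, k))
    else:
        k = int(round(fraction * n))
        test_rows = _ks_indices(np.arange(n), k)

    test_set = set(test_rows)
    train = [ids[i] for i in range(n) if i not in test_set]
    test = [ids[i] for i in sorted(test_rows)]
    return train, test


def _block_raw_matrix(block: OmicsBlock, normalize: str) -> OmicsBlock:
    if normalize == "integral":
        return integral_normalize(block)
    if normalize in ("none", None):
        return block
    raise ValueError(f"unknown normalize mode {normalize!r}")


def _fit_block(block: OmicsBlock, labels: dict[str, int], train_ids: list[str],
               config: FusionConfig) -> BlockFit:
    """Preprocess + eCVA for one block on its present training samples."""
    present_train = [s for s in train_ids if s in set(block.sample_ids)]
    classes = sorted(set(labels[s] for s in block.sample_ids))
    counts = {c: sum(1 for s in present_train if labels[s] == c) for c in classes}
    short = [c for c, k in counts.items() if k < 2]
    if short:
        raise ValueError(
            f"block {block.block_id!r}: class(es) {short} have <2 training samples"
        )
    norm_mode = config.block_normalize(block.block_id)
    normed = _block_raw_matrix(block, norm_mode)
    sub = normed.subset_samples(present_train)
    y = np.array([labels[s] for s in present_train], dtype=int)

    def _scaled_fit(variable_ids: list[str]):
        reduced = sub.subset_variables(variable_ids)
        scal = fit_scaling(reduced.values, config.block_scaling(block.block_id))
        kept_ids = [variable_ids[j] for j in scal.kept_columns]
        scal.dropped_variables = [variable_ids[j] for j in range(len(variable_ids))
                                  if j not in set(scal.kept_columns.tolist())]
        Xs = apply_scaling(scal, reduced.values)
        return scal, kept_ids, Xs

    scal, kept_ids, Xs = _scaled_fit(list(block.variable_ids))
    spec = config.block_n_pls(block.block_id)
    if isinstance(spec, (list, tuple)):
        n_pls = select_pls_components(Xs, y, list(spec))
    else:
        n_pls = int(spec)
    n_pls = min(n_pls, len(present_train) - 1, len(kept_ids))

    k = config.block_top_k(block.block_id)
    if k is not None and k < len(kept_ids):
        full = fit_ecva(Xs, y, n_pls)
        importance = np.linalg.norm(full.W, axis=1)
        order = np.argsort(-importance, kind="stable")[:k]
        top_ids = [kept_ids[j] for j in np.sort(order)]
        scal, kept_ids, Xs = _scaled_fit(top_ids)   # scaling re-fit on retained columns
        n_pls = min(n_pls, len(kept_ids))
    model = fit_ecva(Xs, y, n_pls)
    model.variable_ids = kept_ids
    model.selected_variables = kept_ids
    model.scaling = scal
    return BlockFit(block.block_id, norm_mode, scal, kept_ids, model, n_pls)


def _project_block(fit: BlockFit, block: OmicsBlock, sample_id: str) -> np.ndarray:
    """One sample's canonical scores through a fitted block (raw -> scaled -> eCVA)."""
    normed = _block_raw_matrix(block.subset_samples([sample_id]), fit.normalize)
    row = normed.subset_variables(fit.kept_variable_ids).values
    Xs = apply_scaling(fit.scaling, row)
    return project_ecva(fit.ecva, Xs)[0]


def _concat_scores(study: AlignedStudy, fits: list[BlockFit],
                   sample_ids: list[str]) -> np.ndarray:
    out = np.full((len(sample_ids), sum(f.ecva.n_directions for f in fits)), np.nan)
    col = 0
    for b, fit in enumerate(fits):
        block = study.blocks[b]
        width = fit.ecva.n_directions
        present = set(block.sample_ids)
        # project all present samples at once for speed
        here = [s for s in sample_ids if s in present]
        if here:
            normed = _block_raw_matrix(block.subset_samples(here), fit.normalize)
            Xs = apply_scaling(fit.scaling,
                               normed.subset_variables(fit.kept_variable_ids).values)
            T = project_ecva(fit.ecva, Xs)
            pos = {s: i for i, s in enumerate(sample_ids)}
            for i, s in enumerate(here):
                out[pos[s], col:col + width] = T[i]
        col += width
    return out


def _ks_representation(study: AlignedStudy) -> tuple[np.ndarray, list[str]]:
    """Autoscaled concatenation of all blocks over samples present in every block."""
    everywhere = [s for i, s in enumerate(study.sample_ids) if study.presence[i].all()]
    mats = []
    for block in study.blocks:
        sub = block.subset_samples(everywhere)
        scal = fit_scaling(sub.values, "autoscale")
        mats.append(apply_scaling(scal, sub.values))
    return np.hstack(mats), everywhere


def fit_fusion(
    study: AlignedStudy,
    config: FusionConfig | None = None,
    split: tuple[list[str], list[str]] | None = None,
) -> FusionModel:
    """Fit the full mid-level fusion pipeline.

    When ``split`` is None and ``test_fraction > 0``, the test set is chosen
    by stratified Kennard-Stone in the autoscaled concatenation of samples
    present in every block; samples missing from some block always train.
    Pass an explicit ``(train_ids, test_ids)`` to reuse a previous split.
    """
    config = config or FusionConfig()
    classes = study.class_indices()
    g = len(classes)
    # default: keep the full concatenated-score space (sum_b (g-1) PCs, capped
    # below by the training size); classification then loses nothing to the
    # change of basis, while interpretation and score plots use the leading
    # g-1 PCs
    r_global = config.r_global if config.r_global is not None else len(study.blocks) * (g - 1)

    if split is not None:
        train_ids, test_ids = list(split[0]), list(split[1])
    elif config.test_fraction > 0:
        Xrep, everywhere = _ks_representation(study)
        lab = [study.labels[s] for s in everywhere]
        _, test_ids = kennard_stone_split(
            Xrep, lab, config.test_fraction, config.ks_stratified, everywhere)
        test_set = set(test_ids)
        train_ids = [s for s in study.sample_ids if s not in test_set]
    else:
        train_ids, test_ids = list(study.sample_ids), []

    fits = [_fit_block(block, study.labels, train_ids, config)
            for block in study.blocks]
    concat = _concat_scores(study, fits, train_ids)
    if np.isnan(concat).all(axis=1).any():
        i = int(np.isnan(concat).all(axis=1).argmax())
        raise ValueError(f"training sample {train_ids[i]!r} is missing from every block")
    r_global = min(r_global, concat.shape[1], len(train_ids) - 1)
    if config.score_scaling == "autoscale":
        score_means = np.nanmean(concat, axis=0)
        score_sds = np.nanstd(concat, axis=0, ddof=1)
        score_sds = np.where(score_sds > 0, score_sds, 1.0)
    else:
        score_means = np.zeros(concat.shape[1])
        score_sds = np.ones(concat.shape[1])
    # generous iteration budget: the score matrix is tiny, and the default
    # 1000 iterations can fall short of the 1e-9 tolerance
    pca = fit_pca_missing((concat - score_means) / score_sds, r_global,
                          max_iter=20000)

    y = np.array([study.labels[s] for s in train_ids], dtype=int)
    Tg = pca.scores
    centroids = np.vstack([Tg[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((r_global, r_global))
    for c in classes:
        Tc = Tg[y == c] - Tg[y == c].mean(axis=0)
        pooled += Tc.T @ Tc
    pooled /= max(len(train_ids) - g, 1)

    cols = [f.block_id for f in fits for _ in range(f.ecva.n_directions)]
    return FusionModel(fits, concat, score_means, score_sds, pca, centroids,
                       pooled, classes, config, train_ids, test_ids, cols)


def classify(model: FusionModel, study: AlignedStudy,
             sample_ids: list[str]) -> np.ndarray:
    """Predict class labels for the given samples.

    Each sample is pushed through every block it was measured in (stored
    scaling, stored canonical directions), the possibly-incomplete score
    vector is projected into PC space (least squares over observed
    coordinates), and the nearest class centroid wins; ties go to the lowest
    class index.
    """
    blocks_by_id = {b.block_id: (i, b) for i, b in enumerate(study.blocks)}
    if model.classifier_is_mahalanobis:
        VI = np.linalg.pinv(model.pooled_cov)
    preds = np.empty(len(sample_ids), dtype=int)
    for i, s in enumerate(sample_ids):
        vec = []
        any_present = False
        for fit in model.block_fits:
            _, block = blocks_by_id[fit.block_id]
            if s in set(block.sample_ids):
                vec.append(_project_block(fit, block, s))
                any_present = True
            else:
                vec.append(np.full(fit.ecva.n_directions, np.nan))
        if not any_present:
            raise ValueError(f"sample {s!r} is present in no block")
        scores = (np.concatenate(vec) - model.score_means) / model.score_sds
        t = project_pca(model.pca, scores, allow_underdetermined=True)
        diff = model.centroids - t
        if model.classifier_is_mahalanobis:
            d2 = np.einsum("ci,ij,cj->c", diff, VI, diff)
        else:
            d2 = (diff ** 2).sum(axis=1)
        preds[i] = model.classes[int(d2.argmin())]
    return preds


# attached as a property-style helper so classify stays readable
def _classifier_is_mahalanobis(self: FusionModel) -> bool:
    return self.config.classifier == "nearest_centroid_mahalanobis"


FusionModel.classifier_is_mahalanobis = property(_classifier_is_mahalanobis)


def evaluate(model: FusionModel, study: AlignedStudy,
             test_ids: list[str]) -> tuple[float, pd.DataFrame]:
    """Accuracy and g x g confusion matrix (rows true, columns predicted)."""
    if not test_ids:
        raise ValueError("empty test set")
    pred = classify(model, study, test_ids)
    true = study.label_vector(test_ids)
    classes = model.classes
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true, pred):
        cm[pos[int(t)], pos[int(p)]] += 1
    acc = float(np.trace(cm)) / len(test_ids)
    cmdf = pd.DataFrame(cm, index=[f"true_{c}" for c in classes],
                        columns=[f"pred_{c}" for c in classes])
    return acc, cmdf


def low_level_fusion(study: AlignedStudy, r: int = 2) -> PCAModel:
    """Baseline: concatenate autoscaled raw blocks and run missing-value PCA."""
    n = study.n_samples
    mats = []
    for b, block in enumerate(study.blocks):
        scal = fit_scaling(block.values, "autoscale")
        Xs = apply_scaling(scal, block.values)
        full = np.full((n, Xs.shape[1]), np.nan)
        pos = {s: i for i, s in enumerate(study.sample_ids)}
        for i, s in enumerate(block.sample_ids):
            full[pos[s]] = Xs[i]
        mats.append(full)
    return fit_pca_missing(np.hstack(mats), r)


def single_block_study(study: AlignedStudy, block_id: str) -> AlignedStudy:
    """The one-block study obtained by dropping all other blocks."""
    matching = [b for b in study.blocks if b.block_id == block_id]
    if not matching:
        raise KeyError(f"no block {block_id!r} in study")
    block = matching[0]
    labels = {s: study.labels[s] for s in block.sample_ids}
    return align_blocks([block], labels)


def model_fingerprint(model: FusionModel) -> str:
    """SHA-256 over every fitted array — two identical fits hash identically."""
    h = hashlib.sha256()

    def add(a) -> None:
        arr = np.ascontiguousarray(np.asarray(a, dtype=float))
        h.update(arr.tobytes())

    for fit in model.block_fits:
        add(fit.ecva.W); add(fit.ecva.T); add(fit.ecva.B)
        add(fit.ecva.group_means); add(fit.ecva.overall_mean)
        add(fit.scaling.column_means); add(fit.scaling.column_sds)
        h.update(",".join(fit.kept_variable_ids).encode())
    add(model.pca.loadings); add(model.pca.scores); add(model.pca.column_means)
    add(model.score_means); add(model.score_sds)
    add(model.centroids); add(model.pooled_cov)
    h.update(",".join(model.train_ids).encode())
    return h.hexdigest()
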