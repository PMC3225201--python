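"""Model interpretation: variable importance and correlation networks.

The fused model is a composition of two linear layers, so global weights of
the original variables are obtained by back-projection: the block's canonical
directions W (p_b x (g-1)) times the global-PCA loading rows that belong to
that block's score columns.  A variable's importance for a target group is
the projection of its global-weight row on the unit vector pointing at that
group's centroid in PC space; importances are normalized jointly over all
blocks so the largest magnitude is 1, and the sign encodes up/down regulation
in the target group.

Variables are then put into context by class-conditional correlation
networks: all pairwise Pearson correlations within each class, thresholded at
|r| > 0.8 (strict), seeded subnetwork extraction, and Graphviz DOT export
(squares for model-important variables, ellipses otherwise; solid edges for
the reference class, dotted for the others).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AlignedStudy, PeptideProteinMap
from .fusion import FusionModel

__all__ = [
    "ImportanceTable",
    "CorrelationNetwork",
    "global_weights",
    "group_importance",
    "aggregate_peptides",
    "correlation_matrix",
    "build_network",
    "extract_subnetwork",
    "export_dot",
]


@dataclass
class ImportanceTable:
    """Per-variable importance for one target class.

    ``frame`` columns: variable_id, block_id, raw_importance, importance
    (max-1 normalized, in [-1, 1]), sign (+1 up / -1 down in the target
    group), mean_shift_sign (sign of the variable's scaled training-mean
    shift in the target group, as a consistency check).
    """

    target_class: int
    frame: pd.DataFrame

    def top(self, k: int) -> pd.DataFrame:
        return self.frame.reindex(
            self.frame["importance"].abs().sort_values(ascending=False, kind="stable").index
        ).head(k)

    def important_set(self, k: int) -> set[str]:
        return set(self.top(k)["variable_id"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")


@dataclass
class CorrelationNetwork:
    """Variables as nodes; per-class edge sets thresholded on |Pearson r|.

    ``nodes`` maps variable_id -> {"block": block_id, "important": bool};
    ``edges`` is a list of (var_a, var_b, class_index, r) with var_a < var_b.
    """

    nodes: dict[str, dict]
    edges: list[tuple[str, str, int, float]]
    threshold: float = 0.8

    def edge_count(self, class_index: int | None = None) -> int:
        if class_index is None:
            return len(self.edges)
        return sum(1 for e in self.edges if e[2] == class_index)

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for a, b, _, _ in self.edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def to_edge_csv(self, path) -> None:
        df = pd.DataFrame(self.edges, columns=["var_a", "var_b", "class", "r"])
        df = df.sort_values(["class", "var_a", "var_b"], kind="stable")
        df.to_csv(path, index=False, float_format="%.10g")


def global_weights(fusion: FusionModel, block_id: str) -> pd.DataFrame:
    """Back-projected global weights: W_block @ P_block, rows = retained variables."""
    ids = [f.block_id for f in fusion.block_fits]
    if block_id not in ids:
        raise KeyError(f"no block {block_id!r} in fusion model (have {ids})")
    fit = fusion.block_fits[ids.index(block_id)]
    cols = np.array([b == block_id for b in fusion.score_column_blocks])
    # loading rows map standardized score columns to PCs; fold the score
    # standardization in so rows refer to the block's raw canonical scores
    P_block = fusion.pca.loadings[cols, :] / fusion.score_sds[cols, None]
    GW = fit.ecva.W @ P_block                     # p_b x r_global
    return pd.DataFrame(GW, index=fit.kept_variable_ids,
                        columns=[f"PC{i + 1}" for i in range(GW.shape[1])])


def group_importance(fusion: FusionModel, target_class: int,
                     n_components: int | None = None) -> ImportanceTable:
    """Importance of every retained variable for defining ``target_class``.

    raw importance = (global-weight row) . d, with d the unit vector to the
    target class centroid in the leading ``n_components`` PCs (default g-1,
    the interpretation plane); all blocks are normalized jointly so
    max |importance| = 1.
    """
    if target_class not in fusion.classes:
        raise ValueError(f"class {target_class} not in model classes {fusion.classes}")
    r = n_components if n_components is not None \
        else min(len(fusion.classes) - 1, fusion.r_global)
    c = fusion.classes.index(target_class)
    centroid = fusion.centroids[c][:r]
    norm = np.linalg.norm(centroid)
    if norm == 0:
        raise ValueError("group indistinguishable from grand mean: centroid at origin")
    d = centroid / norm

    rows = []
    col = 0
    for fit in fusion.block_fits:
        sl = slice(col, col + fit.ecva.n_directions)
        GW = fit.ecva.W @ (fusion.pca.loadings[sl, :r] / fusion.score_sds[sl, None])
        raw = GW @ d
        # sign-consistency check: scaled training-mean shift of the variable
        # in the target group relative to the overall mean
        cls_idx = fit.ecva.classes.index(target_class) if target_class in fit.ecva.classes else None
        if cls_idx is not None:
            shift = fit.ecva.group_means[cls_idx] - fit.ecva.overall_mean
            shift_sign = np.sign(shift)
        else:
            shift_sign = np.zeros(len(fit.kept_variable_ids))
        for j, vid in enumerate(fit.kept_variable_ids):
            rows.append({
                "variable_id": vid,
                "block_id": fit.block_id,
                "raw_importance": float(raw[j]),
                "mean_shift_sign": int(shift_sign[j]),
            })
        col += fit.ecva.n_directions
    frame = pd.DataFrame(rows)
    peak = frame["raw_importance"].abs().max()
    if peak == 0:
        raise ValueError("all global weights orthogonal to the group direction")
    frame["importance"] = frame["raw_importance"] / peak
    frame["sign"] = np.sign(frame["importance"]).astype(int)
    frame = frame[["variable_id", "block_id", "raw_importance", "importance",
                   "sign", "mean_shift_sign"]]
    return ImportanceTable(target_class, frame)


def aggregate_peptides(
    table: ImportanceTable,
    pep_map: PeptideProteinMap,
    min_peptides: int = 3,
) -> pd.DataFrame:
    """Roll peptide importances up to proteins.

    A protein is reported only when at least ``min_peptides`` of its peptides
    behave similarly (share the majority importance sign); its importance is
    the mean over those same-sign peptides, dissenters excluded.  Zero
    importances count with the positive group.  A sign tie breaks to the
    group with the larger total |importance|.
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    df = table.frame[table.frame["variable_id"].isin(pep_map.mapping)]
    out = []
    for acc, grp in df.groupby(df["variable_id"].map(pep_map.mapping), sort=True):
        imp = grp["importance"].to_numpy()
        pos, neg = imp[imp >= 0], imp[imp < 0]
        if len(pos) > len(neg):
            majority = pos
        elif len(neg) > len(pos):
            majority = neg
        else:
            majority = pos if np.abs(pos).sum() >= np.abs(neg).sum() else neg
        if len(majority) < min_peptides:
            continue
        out.append({
            "protein_accession": acc,
            "n_peptides": int(len(imp)),
            "n_agreeing": int(len(majority)),
            "importance": float(majority.mean()),
        })
    return pd.DataFrame(out, columns=["protein_accession", "n_peptides",
                                      "n_agreeing", "importance"])


def _selected_variables(study: AlignedStudy,
                        variables: list[tuple[str, str]] | None) -> list[tuple[str, str]]:
    if variables is not None:
        seen: set[str] = set()
        for _, vid in variables:
            if vid in seen:
                raise ValueError(f"variable id {vid!r} selected from more than one block")
            seen.add(vid)
        return list(variables)
    out: list[tuple[str, str]] = []
    seen = set()
    for block in study.blocks:
        for vid in block.variable_ids:
            if vid in seen:
                raise ValueError(
                    f"variable id {vid!r} appears in two blocks; pass an explicit selection"
                )
            seen.add(vid)
            out.append((block.block_id, vid))
    return out


def correlation_matrix(
    study: AlignedStudy,
    class_index: int,
    variables: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """All pairwise Pearson correlations within one class.

    ``variables`` is a list of (block_id, variable_id); default all variables
    of all blocks.  Each pair is computed over the class's samples present in
    every block the pair involves (complete-pair deletion).  A variable
    constant within the class gives r = 0 (degenerate, no real association);
    pairs with < 3 usable samples give r = NaN (edge impossible).
    """
    sel = _selected_variables(study, variables)
    block_ids = [b.block_id for b in study.blocks]
    per_block_vars: dict[str, list[str]] = {bid: [] for bid in block_ids}
    for bid, vid in sel:
        if bid not in per_block_vars:
            raise KeyError(f"unknown block {bid!r}")
        per_block_vars[bid].append(vid)

    cls_samples = [s for s in study.sample_ids if study.labels[s] == class_index]
    # per-block class submatrices, indexed by sample id
    sub: dict[str, pd.DataFrame] = {}
    for block in study.blocks:
        vids = per_block_vars[block.block_id]
        if not vids:
            continue
        here = [s for s in cls_samples if s in set(block.sample_ids)]
        sub[block.block_id] = block.subset_samples(here).subset_variables(vids).to_frame()

    all_ids = [vid for _, vid in sel]
    R = pd.DataFrame(np.nan, index=all_ids, columns=all_ids)
    done: set[tuple[str, str]] = set()
    for bi, vi in [(b, per_block_vars[b]) for b in block_ids if per_block_vars[b]]:
        for bj, vj in [(b, per_block_vars[b]) for b in block_ids if per_block_vars[b]]:
            if (bi, bj) in done or (bj, bi) in done:
                continue
            done.add((bi, bj))
            common = [s for s in sub[bi].index if s in set(sub[bj].index)]
            if len(common) < 3:
                continue
            A = sub[bi].loc[common].to_numpy()
            Bm = sub[bj].loc[common].to_numpy()
            r = _pearson_block(A, Bm)
            R.loc[vi, vj] = r
            if bi != bj:
                R.loc[vj, vi] = r.T
    return R


def _pearson_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between columns of A and columns of B (constant column -> 0)."""
    n = A.shape[0]
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = Ac.std(axis=0, ddof=1)
    sb = Bc.std(axis=0, ddof=1)
    cov = Ac.T @ Bc / (n - 1)
    denom = np.outer(sa, sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def build_network(
    matrices: dict[int, pd.DataFrame],
    threshold: float = 0.8,
    node_blocks: dict[str, str] | None = None,
    important: set[str] | None = None,
) -> CorrelationNetwork:
    """Threshold per-class correlation matrices into a network.

    An edge (a, b, class) exists iff |r| > threshold STRICTLY — a correlation
    of exactly 0.8 at the default threshold yields no edge.  ``important``
    flags nodes found relevant by the fusion model (rendered as squares).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    important = important or set()
    nodes: dict[str, dict] = {}
    edges: list[tuple[str, str, int, float]] = []
    for cls in sorted(matrices):
        R = matrices[cls]
        ids = list(R.index)
        for vid in ids:
            nodes.setdefault(vid, {
                "block": (node_blocks or {}).get(vid, ""),
                "important": vid in important,
            })
        vals = R.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r = vals[i, j]
                if np.isnan(r):
                    continue
                if abs(r) > threshold:
                    a, b = sorted((ids[i], ids[j]))
                    edges.append((a, b, cls, float(r)))
    return CorrelationNetwork(nodes, edges, threshold)


def extract_subnetwork(
    net: CorrelationNetwork, seeds: list[str], layers: int = 2
) -> CorrelationNetwork:
    """Nodes within ``layers`` correlation hops of any seed, with induced edges.

    Adjacency counts edges of any class; class annotations are kept on the
    induced edges.
    """
    if layers < 1:
        raise ValueError("layers must be >= 1")
    unknown = [s for s in seeds if s not in net.nodes]
    if unknown:
        raise KeyError(f"unknown seed(s): {unknown}")
    adj: dict[str, set[str]] = {}
    for a, b, _, _ in net.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    frontier = set(seeds)
    keep = set(seeds)
    for _ in range(layers):
        frontier = set().union(*(adj.get(v, set()) for v in frontier)) - keep if frontier else set()
        keep |= frontier
        if not frontier:
            break
    nodes = {v: dict(net.nodes[v]) for v in keep}
    edges = [e for e in net.edges if e[0] in keep and e[1] in keep]
    return CorrelationNetwork(nodes, edges, net.threshold)


def export_dot(
    net: CorrelationNetwork,
    class_styles: dict[int, str] | None = None,
    reference_class: int | None = None,
) -> str:
    """Render the network as deterministic Graphviz DOT text.

    Important variables are squares (shape=box), the rest ellipses.  Edges of
    the reference class (default: the lowest class index, i.e. the healthy
    control group) are solid; other classes default to dotted unless
    ``class_styles`` overrides.  Nodes and edges are emitted in lexicographic
    order so identical networks yield byte-identical text.
    """
    classes = sorted({e[2] for e in net.edges})
    if reference_class is None:
        reference_class = classes[0] if classes else None
    styles = dict(class_styles or {})
    for c in classes:
        styles.setdefault(c, "solid" if c == reference_class else "dotted")
    lines = ["graph correlation_network {"]
    for vid in sorted(net.nodes):
        shape = "box" if net.nodes[vid].get("important") else "ellipse"
        lines.append(f'  "{vid}" [shape={shape}];')
    for a, b, cls, r in sorted(net.edges, key=lambda e: (e[0], e[1], e[2])):
        lines.append(f'  "{a}" -- "{b}" [style={styles[cls]}, class={cls}, r="{r:.4f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
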