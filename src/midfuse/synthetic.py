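"""Seeded generator of two-block studies with known ground truth.

The generator emulates the statistical structure the fusion method is built
for: three balanced groups of 15 animals, one high-dimensional block
(default 2000 variables, standing in for peptide abundances) with a two-batch
nuisance offset, one low-dimensional block (153 variables, binned metabolite
intensities), latent-factor multicollinearity, a few samples missing per
block, and class-discriminant variables of known identity and sign.

Class structure enters through a small number of study-level biological
*processes* — think "neuro-inflammation" (disease group only) and
"peripheral inflammation" (both challenged groups).  Each process has a
zero-sum class contrast and a shared within-class variability score, and
each block sees every process with its own strength: by default the
high-dimensional block reports the disease-specific process strongly and the
general-inflammation process weakly, the low-dimensional block the other way
round.  Each platform alone therefore discriminates all groups imperfectly
while their fusion can combine the two strong readouts — the situation
mid-level fusion exists for.

Discriminant variables are not shifted independently: each process moves a
whole module of co-regulated variables (random signs, loadings around
``factor_loading``), shared across blocks, so planted variables correlate
strongly within and between platforms.  This matters statistically: the
discriminant directions then lie in the leading within-class covariance
structure, where a PLS-based eCVA with a handful of latent variables can
find them, just as in real data — isolated independent mean shifts at
p >> n sit in the covariance tail and are invisible to any low-rank method.

Intensities follow a multiplicative model: a positive baseline per variable
modulated by the standardized signal with a per-variable coefficient of
variation.  Planted variables are well-measured (low CV); noise features
span the instrument's stability range.  Down-weighting unstable variables is
precisely what vast scaling exploits, which is why it is the default
preprocessing of the fusion pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import OmicsBlock, AlignedStudy, PeptideProteinMap, align_blocks

__all__ = ["BlockSpec", "SimulationConfig", "GroundTruth", "simulate_study", "write_study"]


@dataclass
class BlockSpec:
    """Design of one simulated block.

    ``effect_sizes[k]`` scales the study's k-th process in this block (class
    shift on the process score, in units of its unit within-class SD);
    ``n_discriminant[k]`` planted variables form the block's module for that
    process.  ``peptides_per_protein`` > 0 organizes the block's variables
    into parent features and makes planted modules whole same-signed protein
    groups.  Intensities are ``baseline * (1 + cv * z)`` (or
    ``baseline * exp(cv * z)`` with ``lognormal``) with z the standardized
    signal; planted variables use ``planted_cv``, the rest draw from
    ``noise_cv``.
    """

    block_id: str
    p: int
    n_discriminant: tuple[int, ...]
    effect_sizes: tuple[float, ...]
    factor_loading: float = 2.2
    n_latent: int = 4
    latent_scale: float = 0.5
    noise_sd: float = 1.0
    baseline: tuple[float, float] = (8.0, 12.0)
    planted_cv: float = 0.10
    noise_cv: tuple[float, float] = (0.10, 0.40)
    batch: bool = False
    batch_offset: float = 1.0
    batch_variable_fraction: float = 0.10
    n_missing: int = 0
    peptides_per_protein: int = 0
    lognormal: bool = False
    id_prefix: str = "v"


@dataclass
class SimulationConfig:
    """Full study design; defaults mirror the target study's shape.

    ``processes`` are zero-sum class contrasts shared by all blocks: the
    first separates the disease group from both controls, the second the
    healthy controls from the two challenged groups.
    """

    g: int = 3
    samples_per_class: int = 15
    seed: int = 0
    processes: tuple[tuple[float, ...], ...] = ((-0.5, -0.5, 1.0), (-1.0, 0.5, 0.5))
    blocks: list[BlockSpec] = field(default_factory=lambda: [
        BlockSpec("proteomics", p=2000, n_discriminant=(24, 12),
                  effect_sizes=(2.0, 1.0), batch=True, n_missing=3,
                  peptides_per_protein=4, id_prefix="pep"),
        BlockSpec("metabolomics", p=153, n_discriminant=(6, 12),
                  effect_sizes=(1.0, 2.0), n_missing=5, id_prefix="met"),
    ])

    def __post_init__(self) -> None:
        if self.g < 2 or self.samples_per_class < 2:
            raise ValueError("need g >= 2 and >= 2 samples per class")
        for c in self.processes:
            if len(c) != self.g:
                raise ValueError(f"process contrast {c} has length != g={self.g}")
        for b in self.blocks:
            if len(b.effect_sizes) != len(self.processes):
                raise ValueError(f"block {b.block_id!r}: one effect size per process required")
            if len(b.n_discriminant) != len(self.processes):
                raise ValueError(f"block {b.block_id!r}: one planted count per process required")
            if not (0 < sum(b.n_discriminant) <= b.p):
                raise ValueError(f"block {b.block_id!r}: planted counts out of range")
            if b.n_missing >= self.samples_per_class:
                raise ValueError(f"block {b.block_id!r}: too many missing samples")


@dataclass
class GroundTruth:
    """What was planted.

    ``discriminant`` maps block_id -> variable_id -> record with the
    variable's sign, process index, effect size and per-class mean shift (in
    within-class SD units of the variable's standardized signal).
    """

    labels: dict[str, int]
    batch: dict[str, int]
    discriminant: dict[str, dict[str, dict]]
    process_scores: np.ndarray          # n x n_processes shared latent scores
    missing: dict[str, list[str]]

    def disease_sign(self, block_id: str, variable_id: str, target_class: int) -> float:
        """Expected sign of the variable's shift in ``target_class`` (1-based)."""
        rec = self.discriminant[block_id][variable_id]
        return float(np.sign(rec["class_shift"][target_class - 1]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "batch": self.batch,
            "discriminant": self.discriminant,
            "missing": self.missing,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _pick_module_columns(spec: BlockSpec, rng: np.random.Generator,
                         available: np.ndarray, count: int):
    """Planted columns for one process: whole protein groups when mapped."""
    if spec.peptides_per_protein > 0:
        ppp = spec.peptides_per_protein
        prot_pool = sorted(set(int(j) // ppp for j in available))
        n_prot = max(1, count // ppp)
        chosen = rng.choice(len(prot_pool), size=n_prot, replace=False)
        cols, signs = [], []
        for idx in chosen:
            k = prot_pool[idx]
            s = float(rng.choice([-1.0, 1.0]))
            for j in range(k * ppp, min((k + 1) * ppp, spec.p)):
                cols.append(j)
                signs.append(s)
        return np.array(cols), np.array(signs)
    cols = rng.choice(available, size=count, replace=False)
    return np.sort(cols), rng.choice([-1.0, 1.0], size=count)


def _simulate_block(spec: BlockSpec, labels: np.ndarray, g: int,
                    rng: np.random.Generator, sample_ids: list[str],
                    processes: np.ndarray, z: np.ndarray):
    n = labels.size
    K = processes.shape[0]

    modules: list[tuple[np.ndarray, np.ndarray]] = []
    taken: set[int] = set()
    for k in range(K):
        avail = np.array([j for j in range(spec.p) if j not in taken])
        cols, signs = _pick_module_columns(spec, rng, avail, spec.n_discriminant[k])
        taken.update(int(j) for j in cols)
        modules.append((cols, signs))

    baseline = rng.uniform(*spec.baseline, size=spec.p)
    if spec.n_latent > 0:
        L = rng.standard_normal((n, spec.n_latent))
        Lam = rng.standard_normal((spec.n_latent, spec.p)) * spec.latent_scale
        Z = L @ Lam
    else:
        Z = np.zeros((n, spec.p))
    Z += rng.standard_normal((n, spec.p)) * spec.noise_sd

    truth: dict[str, dict] = {}
    sd_per_col = np.full(spec.p, np.nan)
    for k, (cols, signs) in enumerate(modules):
        contrast = np.asarray(processes[k], dtype=float)
        contrast = contrast - contrast.mean()
        factor = spec.effect_sizes[k] * contrast[labels - 1] + z[:, k]
        loadings = signs * spec.factor_loading * rng.uniform(0.9, 1.1, size=cols.size)
        Z[:, cols] += np.outer(factor, loadings) * spec.noise_sd

    batch = np.zeros(n, dtype=int)
    if spec.batch:
        batch = (rng.random(n) < 0.5).astype(int)
        nbv = int(round(spec.batch_variable_fraction * spec.p))
        bvars = rng.choice(spec.p, size=nbv, replace=False)
        Z[np.ix_(batch == 1, bvars)] += spec.batch_offset * spec.noise_sd

    # multiplicative intensity model (see module docstring)
    col_sd = Z.std(axis=0, ddof=1)
    Zs = (Z - Z.mean(axis=0)) / col_sd
    cv = rng.uniform(*spec.noise_cv, size=spec.p)
    for cols, _ in modules:
        cv[cols] = spec.planted_cv
    if spec.lognormal:
        X = baseline * np.exp(cv * Zs)
    else:
        X = baseline * (1.0 + cv * Zs)

    width = len(str(spec.p))
    var_ids = [f"{spec.id_prefix}_{j:0{width}d}" for j in range(spec.p)]
    meta = None
    if spec.peptides_per_protein > 0:
        meta = {var_ids[j]: f"{spec.id_prefix.upper()}PROT_{j // spec.peptides_per_protein:04d}"
                for j in range(spec.p)}

    for k, (cols, signs) in enumerate(modules):
        contrast = np.asarray(processes[k], dtype=float)
        contrast = contrast - contrast.mean()
        for j, s in zip(cols, signs):
            truth[var_ids[j]] = {
                "sign": float(s),
                "process": k,
                "effect": float(spec.effect_sizes[k]),
                "class_shift": [float(s * spec.factor_loading * spec.effect_sizes[k]
                                      * c / col_sd[j]) for c in contrast],
            }

    missing_rows = sorted(rng.choice(n, size=spec.n_missing, replace=False).tolist()) \
        if spec.n_missing else []
    keep = [i for i in range(n) if i not in set(missing_rows)]
    block = OmicsBlock(spec.block_id, [sample_ids[i] for i in keep], var_ids,
                       X[keep], meta)
    return block, truth, batch, [sample_ids[i] for i in missing_rows]


def simulate_study(config: SimulationConfig) -> tuple[AlignedStudy, GroundTruth]:
    """Generate a seeded study and its ground truth (bit-reproducible per seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.g * config.samples_per_class
    width = len(str(n))
    sample_ids = [f"s{i + 1:0{width}d}" for i in range(n)]
    labels_vec = np.repeat(np.arange(1, config.g + 1), config.samples_per_class)
    labels = {s: int(c) for s, c in zip(sample_ids, labels_vec)}

    processes = np.asarray(config.processes, dtype=float)
    z = rng.standard_normal((n, processes.shape[0]))
    blocks, disc, missing, batch_all = [], {}, {}, {}
    for spec in config.blocks:
        block, truth, batch, gone = _simulate_block(
            spec, labels_vec, config.g, rng, sample_ids, processes, z)
        blocks.append(block)
        disc[spec.block_id] = truth
        missing[spec.block_id] = gone
        if spec.batch:
            batch_all = {s: int(b) for s, b in zip(sample_ids, batch)}
    study = align_blocks(blocks, labels)
    return study, GroundTruth(labels, batch_all, disc, z, missing)


def write_study(study: AlignedStudy, truth: GroundTruth, outdir: str | Path) -> None:
    """Write block CSVs, labels CSV, peptide-protein map TSV and truth JSON."""
    from .datamodel import write_block
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for block in study.blocks:
        write_block(block, outdir / f"{block.block_id}.csv")
        if block.variable_meta:
            pairs.extend(sorted(block.variable_meta.items()))
    pd.DataFrame(
        [(s, study.labels[s]) for s in study.sample_ids],
        columns=["sample_id", "class"],
    ).to_csv(outdir / "labels.csv", index=False)
    if pairs:
        PeptideProteinMap.from_pairs(pairs).write(outdir / "peptide_protein_map.tsv")
    truth.to_json(outdir / "ground_truth.json")
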