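"""Domain types, readers and multi-block sample alignment.

An :class:`OmicsBlock` is one platform's samples x variables feature table
(e.g. peptide abundances from LC-MS, or binned NMR intensities).  Several
blocks measured on (mostly) the same animals are aligned on the union of
their sample ids into an :class:`AlignedStudy`; a boolean presence mask
records which sample was measured on which platform.  The union (rather than
the intersection) is kept deliberately: the second fusion layer tolerates
missing score rows, so samples measured on a single platform still
contribute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsBlock",
    "AlignedStudy",
    "PeptideProteinMap",
    "read_block",
    "write_block",
    "align_blocks",
    "read_labels",
]


@dataclass
class OmicsBlock:
    """One platform's feature table: ``values[i, j]`` is sample i, variable j.

    Parameters
    ----------
    block_id
        Short platform name (e.g. ``"proteomics"``).
    sample_ids
        Ordered, unique sample identifiers (length ``n``).
    variable_ids
        Ordered, unique variable identifiers (length ``p``).
    values
        ``n x p`` real matrix of abundances / intensities, arbitrary units.
    variable_meta
        Optional map variable_id -> parent feature id (peptide -> protein).
    """

    block_id: str
    sample_ids: list[str]
    variable_ids: list[str]
    values: np.ndarray
    variable_meta: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        n, p = len(self.sample_ids), len(self.variable_ids)
        if n < 1 or p < 1:
            raise ValueError(f"block {self.block_id!r}: needs >=1 sample and >=1 variable")
        if self.values.shape != (n, p):
            raise ValueError(
                f"block {self.block_id!r}: values shape {self.values.shape} != ({n}, {p})"
            )
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"block {self.block_id!r}: duplicate sample id {dup!r}")
        dup = _first_duplicate(self.variable_ids)
        if dup is not None:
            raise ValueError(f"block {self.block_id!r}: duplicate variable id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"block {self.block_id!r}: non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, variable {self.variable_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_ids)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsBlock":
        """Return a new block restricted to the given samples (kept order)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"block {self.block_id!r}: samples not present: {missing}")
        idx = [pos[s] for s in sample_ids]
        return OmicsBlock(
            self.block_id, list(sample_ids), list(self.variable_ids),
            self.values[idx], self.variable_meta,
        )

    def subset_variables(self, variable_ids: list[str]) -> "OmicsBlock":
        pos = {v: j for j, v in enumerate(self.variable_ids)}
        missing = [v for v in variable_ids if v not in pos]
        if missing:
            raise KeyError(f"block {self.block_id!r}: variables not present: {missing}")
        idx = [pos[v] for v in variable_ids]
        meta = None
        if self.variable_meta is not None:
            meta = {v: self.variable_meta[v] for v in variable_ids if v in self.variable_meta}
        return OmicsBlock(self.block_id, list(self.sample_ids), list(variable_ids),
                          self.values[:, idx], meta)


@dataclass
class AlignedStudy:
    """Blocks aligned on the union of sample ids, with labels and presence mask.

    ``presence[i, b]`` is True iff sample ``sample_ids[i]`` was measured in
    block ``b``.  ``labels`` maps sample id -> class index in ``1..g``.
    """

    sample_ids: list[str]
    labels: dict[str, int]
    blocks: list[OmicsBlock]
    presence: np.ndarray
    summary: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        n, nb = len(self.sample_ids), len(self.blocks)
        if self.presence.shape != (n, nb):
            raise ValueError(f"presence shape {self.presence.shape} != ({n}, {nb})")
        if any(not self.presence[i].any() for i in range(n)):
            i = next(i for i in range(n) if not self.presence[i].any())
            raise ValueError(f"sample {self.sample_ids[i]!r} appears in no block")
        classes = self.class_indices()
        if len(classes) < 2:
            raise ValueError(f"need >=2 classes, got {len(classes)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def class_indices(self) -> list[int]:
        return sorted(set(self.labels[s] for s in self.sample_ids))

    @property
    def n_classes(self) -> int:
        return len(self.class_indices())

    def label_vector(self, sample_ids: list[str] | None = None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else sample_ids
        return np.array([self.labels[s] for s in ids], dtype=int)

    def block_samples(self, b: int, restrict_to: list[str] | None = None) -> list[str]:
        """Sample ids present in block ``b`` (optionally intersected, keeping order)."""
        present = {self.sample_ids[i] for i in np.flatnonzero(self.presence[:, b])}
        pool = self.sample_ids if restrict_to is None else restrict_to
        return [s for s in pool if s in present]


@dataclass
class PeptideProteinMap:
    """Rows of (variable_id, protein_accession); each variable maps to one protein."""

    mapping: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "PeptideProteinMap":
        mapping: dict[str, str] = {}
        for var, acc in pairs:
            var, acc = str(var), str(acc)
            if var in mapping and mapping[var] != acc:
                raise ValueError(
                    f"variable {var!r} maps to two proteins: {mapping[var]!r} and {acc!r}"
                )
            mapping[var] = acc
        return cls(mapping)

    @classmethod
    def read(cls, path: str | Path) -> "PeptideProteinMap":
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (variable_id, protein_accession)")
        return cls.from_pairs(list(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.mapping.items()), columns=["variable_id", "protein_accession"]
        )
        df.to_csv(path, sep="\t", index=False)


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_block(path: str | Path, block_id: str) -> OmicsBlock:
    """Read a CSV/TSV feature table (first column sample id, header = variables).

    Raises on duplicate sample ids, non-numeric cells (naming row and column)
    and empty files.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing feature table")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValueError(f"{path}: no data rows / variable columns")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    variable_ids = [str(c) for c in df.columns[1:]]
    body = df.iloc[:, 1:]
    values = np.empty((len(sample_ids), len(variable_ids)), dtype=float)
    for j, col in enumerate(body.columns):
        try:
            # astype(float) parses exactly (bit-level round trip); to_numeric
            # does not
            values[:, j] = body[col].astype(float).to_numpy()
        except (ValueError, TypeError):
            bad = pd.to_numeric(body[col], errors="coerce")
            i = int(bad.isna().to_numpy().argmax())
            raise ValueError(
                f"{path}: non-numeric cell at sample {sample_ids[i]!r}, "
                f"variable {variable_ids[j]!r}: {body[col].iloc[i]!r}"
            ) from None
    return OmicsBlock(block_id, sample_ids, variable_ids, values)


def write_block(block: OmicsBlock, path: str | Path) -> None:
    """Write a block back to CSV (round-trips with :func:`read_block`)."""
    df = block.to_frame()
    df.index.name = "sample_id"
    # default str() formatting is shortest-round-trip: read_block recovers
    # every value bit-exactly
    df.to_csv(path)


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column `sample_id,class` CSV into a label dict."""
    df = pd.read_csv(path, header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id,class")
    return {str(s): int(c) for s, c in zip(df.iloc[:, 0], df.iloc[:, 1])}


def align_blocks(
    blocks: list[OmicsBlock], labels: dict[str, int]
) -> AlignedStudy:
    """Align blocks on the sorted union of their sample ids.

    Alignment is by exact, case-sensitive string match of sample ids.  Every
    sample in every block must be labeled.  A class entirely absent from some
    block is allowed here but recorded as a warning (a per-block eCVA fit on
    that block will fail its own precondition later).
    """
    if not blocks:
        raise ValueError("need at least one block")
    for b in blocks:
        unlabeled = [s for s in b.sample_ids if s not in labels]
        if unlabeled:
            raise ValueError(
                f"block {b.block_id!r}: samples without a label: {unlabeled}"
            )
    union = sorted(set().union(*(set(b.sample_ids) for b in blocks)))
    presence = np.zeros((len(union), len(blocks)), dtype=bool)
    for j, b in enumerate(blocks):
        have = set(b.sample_ids)
        presence[:, j] = [s in have for s in union]

    classes = sorted(set(labels[s] for s in union))
    rows = []
    for j, b in enumerate(blocks):
        counts = {g: 0 for g in classes}
        for s in b.sample_ids:
            counts[labels[s]] += 1
        for g in classes:
            if counts[g] == 0:
                warnings.warn(
                    f"class {g} has no samples in block {b.block_id!r}; "
                    "eCVA on that block will be impossible",
                    stacklevel=2,
                )
        rows.append({"block_id": b.block_id, "n_samples": b.n_samples,
                     **{f"class_{g}": counts[g] for g in classes}})
    summary = pd.DataFrame(rows)
    logger.info("aligned %d blocks on %d samples:\n%s", len(blocks), len(union), summary)
    return AlignedStudy(union, dict(labels), list(blocks), presence, summary)
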