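"""Loading, writing and preprocessing of expression matrices.

The pipeline consumes a genes x samples matrix of normalized RNA-seq
expression values (e.g. RSEM normalized counts).  Values below 1 are mostly
read-depth noise, so preprocessing floors them at 1 and log2-transforms;
every downstream module assumes this transform has been applied exactly
once, which the :class:`ExpressionDataset` tracks with ``is_log2``.

Train/test partitions are stratified: each class contributes its
proportional share of training samples, drawn uniformly without
replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "Partition",
    "floor_log2",
    "stratified_split",
    "load_dataset",
    "write_dataset",
    "write_partition",
    "read_partition",
]

GENDERS = ("male", "female", "unknown")


@dataclass
class ExpressionDataset:
    """A labeled genes x samples expression matrix.

    Parameters
    ----------
    values
        Expression matrix, shape ``(n_genes, n_samples)``.  Raw normalized
        values at load time; log2 scale once :meth:`apply_floor_log2` has
        run (``is_log2`` records which).
    gene_ids, sample_ids
        Unique row / column identifiers.
    class_labels
        One class name per sample.
    gender
        Optional per-sample gender, each in ``{"male", "female", "unknown"}``.
    gene_flags
        Optional set of flagged gene ids (e.g. pseudogenes).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    class_labels: list[str]
    gender: list[str] | None = None
    gene_flags: set[str] | None = None
    is_log2: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene_ids for {n_genes} matrix rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {n_samples} matrix columns"
            )
        if len(self.class_labels) != n_samples:
            raise ValueError("class_labels must have one entry per sample")
        for name, ids in (("gene_ids", self.gene_ids), ("sample_ids", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValueError(f"duplicate {name}: {dupes[:5]}")
        if self.gender is not None:
            if len(self.gender) != n_samples:
                raise ValueError("gender must have one entry per sample")
            bad = sorted(set(self.gender) - set(GENDERS))
            if bad:
                raise ValueError(f"invalid gender values: {bad}")
        if self.gene_flags is not None:
            unknown = sorted(self.gene_flags - set(self.gene_ids))
            if unknown:
                raise ValueError(f"gene_flags reference unknown genes: {unknown[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        """Distinct class names, sorted."""
        return sorted(set(self.class_labels))

    def apply_floor_log2(self) -> "ExpressionDataset":
        """Return a copy with values floored at 1 and log2-transformed.

        Raises
        ------
        ValueError
            If the transform was already applied.
        """
        if self.is_log2:
            raise ValueError("dataset is already on the log2 scale")
        return replace(self, values=floor_log2(self.values), is_log2=True)

    def class_indices(self, class_name: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.class_labels) == class_name)
        if idx.size == 0:
            raise ValueError(f"no samples with class {class_name!r}")
        return idx


def floor_log2(raw: np.ndarray) -> np.ndarray:
    """Floor values at 1, then log2: ``v -> log2(max(v, 1))``.

    Normalized read counts below 1 are dominated by sampling noise; the
    floor maps them all to 0 on the log scale.  Output is elementwise
    non-negative.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("input contains non-finite values")
    if np.any(raw < 0):
        raise ValueError("input contains negative values")
    return np.log2(np.maximum(raw, 1.0))


@dataclass(frozen=True)
class Partition:
    """A stratified train/test split of sample indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    train_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "train_indices", np.asarray(self.train_indices, dtype=int)
        )
        object.__setattr__(
            self, "test_indices", np.asarray(self.test_indices, dtype=int)
        )
        train = set(self.train_indices.tolist())
        test = set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")

    @property
    def n_samples(self) -> int:
        return self.train_indices.size + self.test_indices.size


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    class_labels: list[str], train_fraction: float, seed: int
) -> Partition:
    """Split samples into train/test, proportionally per class.

    Per class with ``n_c`` samples, ``round(train_fraction * n_c)``
    samples (round half up, clamped to ``[1, n_c - 1]`` so neither side is
    empty) go to training, drawn uniformly without replacement.
    Deterministic given ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = np.asarray(class_labels)
    rng = np.random.default_rng(seed)
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    for cls in sorted(set(class_labels)):
        idx = np.flatnonzero(labels == cls)
        n_c = idx.size
        if n_c < 2:
            raise ValueError(
                f"class {cls!r} has {n_c} sample(s); at least 2 are required"
            )
        n_train = min(max(_round_half_up(train_fraction * n_c), 1), n_c - 1)
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_parts.append(np.sort(chosen))
        test_parts.append(np.setdiff1d(idx, chosen))
    return Partition(
        train_indices=np.sort(np.concatenate(train_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
        seed=seed,
        train_fraction=train_fraction,
    )


# ---------------------------------------------------------------------------
# TSV interchange formats
# ---------------------------------------------------------------------------
# Expression matrix: genes in rows, samples in columns, first column gene ids.
# Sample annotation: columns sample_id, class[, gender].
# Gene annotation:   columns gene_id, flag (flag in {0, 1}).


def load_dataset(
    matrix_path: str | Path,
    sample_annotation_path: str | Path,
    gene_annotation_path: str | Path | None = None,
) -> ExpressionDataset:
    """Assemble an :class:`ExpressionDataset` from TSV files.

    The matrix columns keep their file order.  Values are left on the raw
    scale; call :meth:`ExpressionDataset.apply_floor_log2` before analysis.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in matrix.index]
    sample_ids = [str(s) for s in matrix.columns]
    try:
        values = matrix.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(matrix.columns):
            for i, cell in enumerate(matrix[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell {cell!r} at gene {gene_ids[i]!r}, "
                        f"sample {col!r} (row {i}, column {j})"
                    ) from None
        raise

    ann = pd.read_csv(sample_annotation_path, sep="\t", dtype=str)
    if "sample_id" not in ann.columns or "class" not in ann.columns:
        raise ValueError("sample annotation needs columns sample_id and class")
    ann = ann.set_index("sample_id")
    missing = [s for s in sample_ids if s not in ann.index]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing}")
    class_labels = [str(ann.loc[s, "class"]) for s in sample_ids]
    gender = None
    if "gender" in ann.columns:
        gender = [str(ann.loc[s, "gender"]) for s in sample_ids]

    gene_flags = None
    if gene_annotation_path is not None:
        gann = pd.read_csv(gene_annotation_path, sep="\t", dtype=str)
        if "gene_id" not in gann.columns or "flag" not in gann.columns:
            raise ValueError("gene annotation needs columns gene_id and flag")
        gene_flags = set(gann.loc[gann["flag"].astype(int) == 1, "gene_id"])

    return ExpressionDataset(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        class_labels=class_labels,
        gender=gender,
        gene_flags=gene_flags,
        is_log2=False,
    )


def write_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    sample_annotation_path: str | Path,
    gene_annotation_path: str | Path | None = None,
) -> None:
    """Write a dataset in the TSV formats :func:`load_dataset` reads."""
    frame = pd.DataFrame(
        dataset.values, index=dataset.gene_ids, columns=dataset.sample_ids
    )
    frame.index.name = "gene_id"
    frame.to_csv(matrix_path, sep="\t")

    ann = pd.DataFrame(
        {"sample_id": dataset.sample_ids, "class": dataset.class_labels}
    )
    if dataset.gender is not None:
        ann["gender"] = dataset.gender
    ann.to_csv(sample_annotation_path, sep="\t", index=False)

    if gene_annotation_path is not None:
        flags = dataset.gene_flags or set()
        gann = pd.DataFrame(
            {
                "gene_id": dataset.gene_ids,
                "flag": [int(g in flags) for g in dataset.gene_ids],
            }
        )
        gann.to_csv(gene_annotation_path, sep="\t", index=False)


def write_partition(
    partition: Partition, sample_ids: list[str], path: str | Path
) -> None:
    rows = [(sample_ids[i], "train") for i in partition.train_indices]
    rows += [(sample_ids[i], "test") for i in partition.test_indices]
    pd.DataFrame(rows, columns=["sample_id", "split"]).to_csv(
        path, sep="\t", index=False
    )


def read_partition(
    path: str | Path, sample_ids: list[str], seed: int = -1, train_fraction: float = 0.75
) -> Partition:
    table = pd.read_csv(path, sep="\t", dtype=str)
    pos = {s: i for i, s in enumerate(sample_ids)}
    train = [pos[s] for s, sp in zip(table["sample_id"], table["split"]) if sp == "train"]
    test = [pos[s] for s, sp in zip(table["sample_id"], table["split"]) if sp == "test"]
    return Partition(
        train_indices=np.sort(train),
        test_indices=np.sort(test),
        seed=seed,
        train_fraction=train_fraction,
    )
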