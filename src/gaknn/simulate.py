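"""Synthetic expression data with planted class structure.

The generator emulates the statistical shape of a pan-cancer RNA-seq
design: thousands of genes, many classes with unbalanced sample counts,
a small set of genes per class whose mean log2 expression is shifted
upward in that class only, per-sample gender labels with class-specific
proportions, and a flagged gene subset standing in for an annotation
category such as pseudogenes.  Ground truth (which genes were planted
where, which are flagged) is recorded so recovery can be scored.

Values are produced on the raw scale as ``2 ** (log2-space draw)`` so the
standard floor-at-1 log2 transform recovers the simulated structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_dataset",
           "generate_survival_free_clusters"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for :func:`generate_dataset`.

    ``effect_size`` is the mean shift, in log2 units, applied to a class's
    informative genes within that class.  ``flagged_informative_bias`` is
    the fraction of informative genes drawn from the flagged gene set
    (values above ``flagged_fraction`` plant an enrichment signal).
    ``gender_shift``/``n_gender_shift_genes`` optionally elevate a set of
    non-informative genes in male samples across all classes, for
    exercising gender rank-difference analyses; both default to no effect.
    """

    n_classes: int
    samples_per_class: tuple[int, ...]
    n_genes: int
    informative_per_class: int
    effect_size: float
    baseline_log_mean: float = 8.0
    noise_sd: float = 1.0
    flagged_fraction: float = 0.0
    flagged_informative_bias: float = 0.0
    gender_proportion_per_class: tuple[float, ...] | None = None
    gender_shift: float = 0.0
    n_gender_shift_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples_per_class", tuple(int(n) for n in self.samples_per_class)
        )
        if self.gender_proportion_per_class is not None:
            object.__setattr__(
                self,
                "gender_proportion_per_class",
                tuple(float(p) for p in self.gender_proportion_per_class),
            )
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class must have n_classes entries")
        if any(n < 1 for n in self.samples_per_class):
            raise ValueError("samples_per_class entries must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.informative_per_class < 0:
            raise ValueError("informative_per_class must be non-negative")
        if self.informative_per_class * self.n_classes > self.n_genes:
            raise ValueError(
                "informative_per_class x n_classes exceeds n_genes"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("flagged_fraction", "flagged_informative_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gender_proportion_per_class is not None:
            if len(self.gender_proportion_per_class) != self.n_classes:
                raise ValueError(
                    "gender_proportion_per_class must have n_classes entries"
                )
            if any(not 0.0 <= p <= 1.0 for p in self.gender_proportion_per_class):
                raise ValueError("gender_proportion_per_class must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_class)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded by :func:`generate_dataset`.

    ``informative_genes`` maps class name to the set of gene indices whose
    mean was shifted in that class; the sets are disjoint across classes.
    """

    informative_genes: dict[str, set[int]]
    flagged_genes: set[int]

    def all_informative(self) -> set[int]:
        out: set[int] = set()
        for genes in self.informative_genes.values():
            out |= genes
        return out


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate a raw-scale expression dataset with planted structure.

    Log2-space values are ``baseline_log_mean + shift + N(0, noise_sd)``
    where the shift is ``effect_size`` for a class's informative genes in
    that class's samples.  Bit-identical output for identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_samples
    class_names = [f"C{c}" for c in range(spec.n_classes)]

    # Flagged set first so informative genes can be biased toward it.
    n_flagged = _round_half_up(spec.flagged_fraction * spec.n_genes)
    flagged = rng.choice(spec.n_genes, size=n_flagged, replace=False)
    flagged_set = set(int(g) for g in flagged)
    unflagged = np.setdiff1d(np.arange(spec.n_genes), flagged)

    total_inf = spec.informative_per_class * spec.n_classes
    n_inf_flagged = min(_round_half_up(spec.flagged_informative_bias * total_inf),
                        n_flagged, total_inf)
    if total_inf - n_inf_flagged > unflagged.size:
        raise ValueError(
            "not enough unflagged genes for the requested informative set; "
            "raise n_genes or flagged_informative_bias"
        )
    pool = np.concatenate([
        rng.choice(flagged, size=n_inf_flagged, replace=False)
        if n_inf_flagged else np.empty(0, dtype=int),
        rng.choice(unflagged, size=total_inf - n_inf_flagged, replace=False)
        if total_inf - n_inf_flagged else np.empty(0, dtype=int),
    ]).astype(int)
    rng.shuffle(pool)
    informative = {
        class_names[c]: set(
            int(g)
            for g in pool[c * spec.informative_per_class:(c + 1) * spec.informative_per_class]
        )
        for c in range(spec.n_classes)
    }

    log_values = spec.baseline_log_mean + spec.noise_sd * rng.standard_normal(
        (spec.n_genes, n_samples)
    )
    class_labels: list[str] = []
    col = 0
    for c, n_c in enumerate(spec.samples_per_class):
        cols = slice(col, col + n_c)
        genes = sorted(informative[class_names[c]])
        if genes:
            log_values[np.ix_(genes, range(col, col + n_c))] += spec.effect_size
        class_labels.extend([class_names[c]] * n_c)
        col += n_c

    gender: list[str] | None = None
    if spec.gender_proportion_per_class is not None:
        gender = []
        for c, n_c in enumerate(spec.samples_per_class):
            p_male = spec.gender_proportion_per_class[c]
            draws = rng.random(n_c) < p_male
            gender.extend("male" if d else "female" for d in draws)
        if spec.gender_shift != 0.0 and spec.n_gender_shift_genes > 0:
            candidates = np.setdiff1d(
                np.arange(spec.n_genes), np.fromiter(pool, dtype=int, count=len(pool))
            )
            shift_genes = rng.choice(
                candidates, size=spec.n_gender_shift_genes, replace=False
            )
            male_cols = np.flatnonzero(np.asarray(gender) == "male")
            if male_cols.size:
                log_values[np.ix_(np.sort(shift_genes), male_cols)] += spec.gender_shift

    width = len(str(spec.n_genes - 1))
    gene_ids = [f"G{g:0{width}d}" for g in range(spec.n_genes)]
    swidth = len(str(n_samples - 1))
    sample_ids = [f"S{s:0{swidth}d}" for s in range(n_samples)]

    dataset = ExpressionDataset(
        values=np.exp2(log_values),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        class_labels=class_labels,
        gender=gender,
        gene_flags={gene_ids[g] for g in flagged_set} or None,
        is_log2=False,
    )
    truth = SyntheticTruth(informative_genes=informative, flagged_genes=flagged_set)
    return dataset, truth


def generate_survival_free_clusters(
    n_clusters: int,
    samples_per_cluster: int,
    n_genes: int,
    separation: float,
    seed: int,
    noise_sd: float = 1.0,
    baseline_log_mean: float = 8.0,
) -> tuple[ExpressionDataset, np.ndarray]:
    """Single-class dataset whose samples form Gaussian clusters.

    Cluster centroids are placed so that every pair is exactly
    ``separation`` apart in log2 gene space (simplex construction over the
    first ``n_clusters`` genes); per-gene noise sd is ``noise_sd``.  Used
    to exercise silhouette-based choice of k.  Returns the dataset (raw
    scale) and the planted cluster label per sample.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    if n_genes < n_clusters:
        raise ValueError("n_genes must be at least n_clusters")
    rng = np.random.default_rng(seed)
    n_samples = n_clusters * samples_per_cluster

    # Orthogonal-corner simplex: centroid c offsets gene c by separation/sqrt(2),
    # giving pairwise centroid distance exactly `separation`.
    centroids = np.zeros((n_clusters, n_genes))
    centroids[np.arange(n_clusters), np.arange(n_clusters)] = separation / np.sqrt(2.0)

    labels = np.repeat(np.arange(n_clusters), samples_per_cluster)
    log_values = baseline_log_mean + noise_sd * rng.standard_normal(
        (n_genes, n_samples)
    )
    log_values += centroids[labels].T

    width = len(str(n_genes - 1))
    swidth = len(str(n_samples - 1))
    dataset = ExpressionDataset(
        values=np.exp2(log_values),
        gene_ids=[f"G{g:0{width}d}" for g in range(n_genes)],
        sample_ids=[f"S{s:0{swidth}d}" for s in range(n_samples)],
        class_labels=["C0"] * n_samples,
        is_log2=False,
    )
    return dataset, labels
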