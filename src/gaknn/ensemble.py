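"""Repeated GA/KNN runs, prediction profiles, modal accuracy, gene ranks.

Because the number of genes vastly exceeds the number of samples, many
different small gene sets classify about equally well.  Running the GA
many times over a fixed train/test partition maps this space: each run
contributes one near-optimal subset and one prediction per test sample.
Aggregating across runs gives, per test sample, the proportion of runs
assigning it to each category (the true-class entry is the
proportion-times-correctly-classified, pi_cc) and, per gene, how often it
was selected — the gene's importance for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .ga import GAConfig, GARunResult, evolve
from .io import ExpressionDataset, Partition
from .knn import UNCLASSIFIED, knn_predict_batch, standardize_train_test

__all__ = [
    "EnsembleResult",
    "PredictionProfile",
    "GeneFrequencyTable",
    "run_ensemble",
    "compute_profiles",
    "modal_accuracy",
    "gene_frequencies",
    "merge_profiles_across_partitions",
    "summarize_by_class",
    "write_profiles",
    "write_frequencies",
]


@dataclass
class EnsembleResult:
    """Per-run GA results and test-set predictions for one partition.

    ``predictions[r][s]`` is run r's predicted category (a class name or
    ``UNCLASSIFIED``) for the s-th test sample, in ``test_indices`` order.
    """

    dataset: ExpressionDataset
    partition: Partition
    config: GAConfig
    runs: list[GARunResult]
    predictions: list[list[str]]

    @property
    def classes(self) -> list[str]:
        return self.dataset.classes

    @property
    def test_sample_ids(self) -> list[str]:
        return [self.dataset.sample_ids[i] for i in self.partition.test_indices]

    @property
    def test_true_classes(self) -> list[str]:
        return [self.dataset.class_labels[i] for i in self.partition.test_indices]


@dataclass(frozen=True)
class PredictionProfile:
    """One test sample's category proportions across ensemble runs.

    ``proportions`` covers every class plus ``UNCLASSIFIED`` and sums to 1;
    ``pi_cc`` is the true-class entry.
    """

    sample_id: str
    true_class: str
    proportions: dict[str, float]
    pi_cc: float


@dataclass(frozen=True)
class GeneFrequencyTable:
    """Selection counts and ranks over one or more ensembles.

    ``counts[g]`` is the number of runs whose best subset contained gene
    g (0 for never-selected genes, which still receive ranks so that
    full-table rank comparisons are possible).  Rank 1 is the most
    frequent; ties break lexicographically on gene id.
    """

    counts: dict[str, int]
    ranks: dict[str, int]
    total_runs: int
    chromosome_length: int

    def top(self, n: int) -> list[str]:
        """The n best-ranked gene ids, in rank order."""
        return sorted(self.ranks, key=self.ranks.__getitem__)[:n]


def _single_run(
    train_std: np.ndarray,
    train_labels: np.ndarray,
    train_codes: np.ndarray,
    test_std: np.ndarray,
    categories: np.ndarray,
    config: GAConfig,
    seed: int,
) -> tuple[GARunResult, list[str]]:
    run = evolve(train_std, train_labels, replace(config, seed=seed))
    codes = knn_predict_batch(
        train_std,
        train_codes,
        test_std,
        n_classes=categories.size,
        subset=run.best_subset,
        k=config.k_neighbors,
    )
    labels = [UNCLASSIFIED if c < 0 else str(categories[c]) for c in codes]
    return run, labels


def run_ensemble(
    dataset: ExpressionDataset,
    partition: Partition,
    config: GAConfig,
    n_runs: int,
    base_seed: int,
    n_jobs: int = 1,
) -> EnsembleResult:
    """Repeat the GA/KNN procedure ``n_runs`` times on one fixed partition.

    Run r is seeded ``base_seed + r`` and is self-contained, so runs can
    execute in parallel (``n_jobs``) without changing any result.  Gene
    standardization parameters are computed once from the training samples
    and frozen for the whole ensemble.
    """
    if not dataset.is_log2:
        raise ValueError("dataset must be log2-transformed before classification")
    if partition.n_samples != dataset.n_samples:
        raise ValueError("partition does not match the dataset's sample count")
    train_idx = partition.train_indices
    test_idx = partition.test_indices
    train_std, test_std = standardize_train_test(
        dataset.values[:, train_idx], dataset.values[:, test_idx]
    )
    labels = np.asarray(dataset.class_labels)
    train_labels = labels[train_idx]
    categories, _ = np.unique(labels, return_inverse=True)
    cat_pos = {c: i for i, c in enumerate(categories)}
    train_codes = np.array([cat_pos[c] for c in train_labels])

    jobs = (
        delayed(_single_run)(
            train_std, train_labels, train_codes, test_std, categories, config,
            base_seed + r,
        )
        for r in range(n_runs)
    )
    results = Parallel(n_jobs=n_jobs)(jobs)
    runs = [r for r, _ in results]
    predictions = [p for _, p in results]
    return EnsembleResult(
        dataset=dataset,
        partition=partition,
        config=config,
        runs=runs,
        predictions=predictions,
    )


def _categories(result: EnsembleResult) -> list[str]:
    return result.classes + [UNCLASSIFIED]


def compute_profiles(result: EnsembleResult) -> list[PredictionProfile]:
    """Per test sample, the proportion of runs assigning each category."""
    if not result.runs:
        raise ValueError("ensemble has no runs")
    cats = _categories(result)
    n_runs = len(result.predictions)
    profiles = []
    for s, (sid, true_class) in enumerate(
        zip(result.test_sample_ids, result.test_true_classes)
    ):
        counts = {c: 0 for c in cats}
        for r in range(n_runs):
            counts[result.predictions[r][s]] += 1
        proportions = {c: counts[c] / n_runs for c in cats}
        profiles.append(
            PredictionProfile(
                sample_id=sid,
                true_class=true_class,
                proportions=proportions,
                pi_cc=proportions[true_class],
            )
        )
    return profiles


def _modal_category(counts: dict[str, int]) -> str:
    """Most frequent category; ties favor lexicographically smaller class
    names, with UNCLASSIFIED losing every tie."""

    def key(cat: str) -> tuple[int, int, str]:
        return (-counts[cat], cat == UNCLASSIFIED, cat)

    return min(counts, key=key)


def modal_accuracy(result: EnsembleResult) -> tuple[dict[str, float], float]:
    """Fraction of test samples whose most-frequent prediction is correct.

    Returns per-class accuracies and the overall accuracy weighted by the
    number of test samples per class (i.e. the plain fraction of correct
    samples).  A sample whose modal category is ``UNCLASSIFIED`` counts as
    incorrect.
    """
    cats = _categories(result)
    n_runs = len(result.predictions)
    correct: dict[str, int] = {}
    totals: dict[str, int] = {}
    for s, true_class in enumerate(result.test_true_classes):
        counts = {c: 0 for c in cats}
        for r in range(n_runs):
            counts[result.predictions[r][s]] += 1
        modal = _modal_category(counts)
        totals[true_class] = totals.get(true_class, 0) + 1
        correct[true_class] = correct.get(true_class, 0) + int(modal == true_class)
    per_class = {c: correct[c] / totals[c] for c in totals}
    overall = sum(correct.values()) / sum(totals.values())
    return per_class, overall


def gene_frequencies(results: list[EnsembleResult]) -> GeneFrequencyTable:
    """Pool selection counts across all runs of all given ensembles.

    Each run contributes its best subset once.  Counts sum to
    ``chromosome_length x total runs`` exactly.
    """
    if not results:
        raise ValueError("no ensembles given")
    gene_ids = results[0].dataset.gene_ids
    for res in results[1:]:
        if res.dataset.gene_ids != gene_ids:
            raise ValueError("ensembles have mismatched gene universes")
    counts = np.zeros(len(gene_ids), dtype=int)
    total_runs = 0
    for res in results:
        for run in res.runs:
            counts[run.best_subset] += 1
            total_runs += 1
    order = sorted(range(len(gene_ids)), key=lambda g: (-counts[g], gene_ids[g]))
    ranks = {gene_ids[g]: i + 1 for i, g in enumerate(order)}
    return GeneFrequencyTable(
        counts={gene_ids[g]: int(counts[g]) for g in range(len(gene_ids))},
        ranks=ranks,
        total_runs=total_runs,
        chromosome_length=results[0].config.chromosome_length,
    )


def merge_profiles_across_partitions(
    profile_sets: list[list[PredictionProfile]],
) -> list[PredictionProfile]:
    """Average profiles of samples appearing in multiple test sets.

    A sample seen in several partitions' test sets gets the arithmetic
    mean of its proportion vectors (still summing to 1); samples seen once
    pass through.  Output is sorted by sample id.
    """
    all_cats: list[str] = []
    for profiles in profile_sets:
        for p in profiles:
            for c in p.proportions:
                if c not in all_cats:
                    all_cats.append(c)
    grouped: dict[str, list[PredictionProfile]] = {}
    for profiles in profile_sets:
        for p in profiles:
            grouped.setdefault(p.sample_id, []).append(p)
    merged = []
    for sid in sorted(grouped):
        group = grouped[sid]
        true_class = group[0].true_class
        if any(p.true_class != true_class for p in group):
            raise ValueError(f"sample {sid!r} has conflicting true classes")
        proportions = {
            c: sum(p.proportions.get(c, 0.0) for p in group) / len(group)
            for c in all_cats
        }
        merged.append(
            PredictionProfile(
                sample_id=sid,
                true_class=true_class,
                proportions=proportions,
                pi_cc=proportions[true_class],
            )
        )
    return merged


def summarize_by_class(
    profiles: list[PredictionProfile],
    per_class_modal: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-class summary of pi_cc: min, quartiles, mean, max.

    Mirrors the usual report layout (one row per class); if per-class
    modal accuracies are given they are appended as a column.
    """
    rows = []
    by_class: dict[str, list[float]] = {}
    for p in profiles:
        by_class.setdefault(p.true_class, []).append(p.pi_cc)
    for cls in sorted(by_class):
        vals = np.asarray(by_class[cls])
        row = {
            "class": cls,
            "n": vals.size,
            "min": vals.min(),
            "q1": np.percentile(vals, 25),
            "median": np.percentile(vals, 50),
            "mean": vals.mean(),
            "q3": np.percentile(vals, 75),
            "max": vals.max(),
        }
        if per_class_modal is not None:
            row["modal_accuracy"] = per_class_modal.get(cls, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(profiles: list[PredictionProfile], path: str | Path) -> None:
    cats: list[str] = []
    for p in profiles:
        for c in p.proportions:
            if c not in cats:
                cats.append(c)
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "true_class": p.true_class}
        row.update({c: p.proportions.get(c, 0.0) for c in cats})
        row["pi_cc"] = p.pi_cc
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_frequencies(table: GeneFrequencyTable, path: str | Path) -> None:
    genes = sorted(table.ranks, key=table.ranks.__getitem__)
    pd.DataFrame(
        {
            "gene_id": genes,
            "count": [table.counts[g] for g in genes],
            "rank": [table.ranks[g] for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)
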