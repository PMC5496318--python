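"""Secondary analyses on top of the ensemble output.

Covers: subtype discovery within one tumor type (k-means on the
top-ranked discriminative genes, cluster count chosen by mean silhouette),
enrichment of a flagged gene category (e.g. pseudogenes) among the top
ranks (hypergeometric upper tail), comparison of two gene rankings
(top-N union/intersection and full-table rank differences), two-sided
Wilcoxon rank-sum tests of a gene's expression between genders within a
tumor type, and proportion-matched subsampling of one cohort to mirror
another's class composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .ensemble import GeneFrequencyTable
from .io import ExpressionDataset

__all__ = [
    "SubtypeResult",
    "RankComparison",
    "subtype_discovery",
    "hypergeom_enrichment",
    "compare_rankings",
    "ranksum_by_gender",
    "matched_subsample",
]


@dataclass(frozen=True)
class SubtypeResult:
    """k-means subtypes for one tumor type.

    ``genes_used`` are the top-ranked genes surviving the non-zero-IQR
    filter within this type; ``chosen_k`` maximizes the mean silhouette
    over the candidate k values (smaller k wins ties).
    """

    class_name: str
    genes_used: list[str]
    chosen_k: int
    assignments: np.ndarray
    silhouette_by_k: dict[int, float]


@dataclass(frozen=True)
class RankComparison:
    """Top-N agreement between two gene rankings.

    ``rank_differences`` maps each gene in the union of the two top-N
    lists to its full-table signed rank difference (A minus B);
    ``large_difference_genes`` are those whose absolute difference exceeds
    the screening threshold.
    """

    top_n: int
    union_size: int
    intersection_size: int
    rank_differences: dict[str, int]
    large_difference_genes: list[str]


def subtype_discovery(
    dataset: ExpressionDataset,
    class_name: str,
    ranked_genes: GeneFrequencyTable,
    n_top: int = 50,
    candidate_k: tuple[int, ...] = (2, 3),
    seed: int = 0,
) -> SubtypeResult:
    """Cluster one class's samples on its usable top-ranked genes.

    The ``n_top`` best-ranked genes are filtered to those with a non-zero
    interquartile range within this class (constant genes carry no
    clustering information); k-means with 10 restarts is run for each
    candidate k and the k with the highest mean silhouette score
    (Euclidean) is returned.
    """
    if not dataset.is_log2:
        raise ValueError("dataset must be log2-transformed before clustering")
    cols = dataset.class_indices(class_name)
    if cols.size < max(candidate_k) + 1:
        raise ValueError(
            f"class {class_name!r} has {cols.size} samples; "
            f"need more than max(candidate_k)"
        )
    gene_pos = {g: i for i, g in enumerate(dataset.gene_ids)}
    top = ranked_genes.top(n_top)
    usable: list[str] = []
    for g in top:
        vals = dataset.values[gene_pos[g], cols]
        if np.percentile(vals, 75) - np.percentile(vals, 25) > 0:
            usable.append(g)
    if len(usable) < 2:
        raise ValueError(
            f"only {len(usable)} gene(s) with non-zero IQR in class {class_name!r}"
        )
    x = dataset.values[np.ix_([gene_pos[g] for g in usable], cols)].T

    silhouette_by_k: dict[int, float] = {}
    assignments_by_k: dict[int, np.ndarray] = {}
    for k in sorted(candidate_k):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(x)
        if len(set(labels.tolist())) < 2:
            silhouette_by_k[k] = -1.0
        else:
            silhouette_by_k[k] = float(silhouette_score(x, labels))
        assignments_by_k[k] = labels
    chosen_k = max(sorted(silhouette_by_k), key=lambda k: (silhouette_by_k[k], -k))
    return SubtypeResult(
        class_name=class_name,
        genes_used=usable,
        chosen_k=chosen_k,
        assignments=assignments_by_k[chosen_k],
        silhouette_by_k=silhouette_by_k,
    )


def hypergeom_enrichment(
    flagged_in_top: int, top_n: int, flagged_total: int, universe: int
) -> float:
    """Upper-tail hypergeometric p-value for flagged-gene enrichment.

    P(X >= flagged_in_top) where X counts flagged genes in a uniform draw
    of ``top_n`` genes from a universe containing ``flagged_total``
    flagged ones.
    """
    if not 0 <= flagged_in_top <= min(top_n, flagged_total):
        raise ValueError("flagged_in_top exceeds top_n or flagged_total")
    if top_n > universe or flagged_total > universe:
        raise ValueError("top_n and flagged_total must not exceed the universe")
    return float(stats.hypergeom.sf(flagged_in_top - 1, universe, flagged_total, top_n))


def compare_rankings(
    table_a: GeneFrequencyTable,
    table_b: GeneFrequencyTable,
    top_n: int,
    rank_diff_threshold: int = 100,
) -> RankComparison:
    """Compare two gene rankings on their top-N membership and ranks.

    Rank differences use the full tables (a gene outside one top-N list
    still has a well-defined rank there), so a gene ranked 45 in one
    cohort and 932 in the other is reported as such.
    """
    if set(table_a.ranks) != set(table_b.ranks):
        raise ValueError("tables have mismatched gene universes")
    top_a = set(table_a.top(top_n))
    top_b = set(table_b.top(top_n))
    union = top_a | top_b
    inter = top_a & top_b
    diffs = {g: table_a.ranks[g] - table_b.ranks[g] for g in sorted(union)}
    large = sorted(g for g, d in diffs.items() if abs(d) > rank_diff_threshold)
    return RankComparison(
        top_n=top_n,
        union_size=len(union),
        intersection_size=len(inter),
        rank_differences=diffs,
        large_difference_genes=large,
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Uses midranks, so ties are handled exactly.  p = min(1, 2 * min(
    P(W <= w), P(W >= w))) over all C(n+m, n) assignments.
    """
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n = x.size
    w_obs = ranks[:n].sum()
    idx = np.array(list(combinations(range(pooled.size), n)), dtype=np.intp)
    sums = ranks[idx].sum(axis=1)
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n, m = x.size, y.size
    big_n = n + m
    w = ranks[:n].sum()
    mu = n * (big_n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1))
    var = n * m / 12.0 * (big_n + 1 - tie_term)
    if var == 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def ranksum_by_gender(
    dataset: ExpressionDataset, gene_id: str, class_name: str
) -> tuple[float, float]:
    """Two-sided rank-sum test of a gene between genders within a class.

    Returns (rank sum of the male group, two-sided p).  The null is
    enumerated exactly when both groups have at most 10 samples; larger
    groups use the normal approximation with tie correction.
    """
    if dataset.gender is None:
        raise ValueError("dataset has no gender annotation")
    try:
        row = dataset.gene_ids.index(gene_id)
    except ValueError:
        raise ValueError(f"unknown gene {gene_id!r}") from None
    cols = dataset.class_indices(class_name)
    gender = np.asarray(dataset.gender)[cols]
    vals = dataset.values[row, cols]
    x = vals[gender == "male"]
    y = vals[gender == "female"]
    for name, grp in (("male", x), ("female", y)):
        if grp.size == 0:
            raise ValueError(f"no {name} samples in class {class_name!r}")
    w = float(_midranks(np.concatenate([x, y]))[: x.size].sum())
    if x.size <= 10 and y.size <= 10:
        p = _exact_ranksum_p(x, y)
    else:
        p = _approx_ranksum_p(x, y)
    return w, p


def matched_subsample(
    dataset: ExpressionDataset,
    source_gender: str,
    target_counts: dict[str, int],
    n_replicates: int,
    seed: int,
) -> list[np.ndarray]:
    """Random cohorts from one gender matching target per-class counts.

    Each replicate draws, per class, exactly ``target_counts[class]``
    source-gender samples uniformly without replacement (within the
    replicate); replicates are independent.  Used to test whether
    cohort differences persist once sample sizes and class proportions
    are matched.
    """
    if dataset.gender is None:
        raise ValueError("dataset has no gender annotation")
    gender = np.asarray(dataset.gender)
    labels = np.asarray(dataset.class_labels)
    rng = np.random.default_rng(seed)
    pools: dict[str, np.ndarray] = {}
    for cls, want in target_counts.items():
        pool = np.flatnonzero((labels == cls) & (gender == source_gender))
        if pool.size < want:
            raise ValueError(
                f"class {cls!r} has {pool.size} {source_gender} sample(s); "
                f"{want} requested (short by {want - pool.size})"
            )
        pools[cls] = pool
    replicates = []
    for _ in range(n_replicates):
        parts = [
            np.sort(rng.choice(pools[cls], size=want, replace=False))
            for cls, want in sorted(target_counts.items())
        ]
        replicates.append(np.sort(np.concatenate(parts)))
    return replicates
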