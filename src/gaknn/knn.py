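"""k-nearest-neighbor classification on gene subsets, with a reject option.

Distances are Euclidean over the genes in the active subset.  The vote is
a strict majority: with k = 5 a class needs at least 3 of the 5 nearest
training neighbors, otherwise the query is rejected as ``UNCLASSIFIED``
(a 2-2-1 vote is a reject).  Ties at the k-th neighbor are broken by
training-sample index, so results do not depend on sample order.

The GA's fitness for a candidate subset is the leave-one-out training
accuracy under this rule; each training sample is excluded from its own
neighbor search (with itself included, it would be its own nearest
neighbor at distance 0 and the score would be meaningless).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "UNCLASSIFIED",
    "standardize_train_test",
    "knn_predict",
    "knn_predict_batch",
    "training_fitness",
]

UNCLASSIFIED = "UNCLASSIFIED"


def standardize_train_test(
    train_values: np.ndarray, test_values: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-gene z-scoring with training-set statistics.

    Means and standard deviations are computed on the training samples
    only and applied unchanged to the test samples, so no test information
    leaks into the geometry.  Genes constant across the training set get
    sd treated as 1, standardizing them to all-zeros: they contribute
    nothing to any distance.
    """
    train_values = np.asarray(train_values, dtype=float)
    mean = train_values.mean(axis=1, keepdims=True)
    sd = train_values.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    train_std = (train_values - mean) / sd
    test_std = None
    if test_values is not None:
        test_std = (np.asarray(test_values, dtype=float) - mean) / sd
    return train_std, test_std


def _validate_subset(subset: np.ndarray, n_genes: int) -> np.ndarray:
    subset = np.asarray(subset, dtype=int)
    if subset.ndim != 1 or subset.size == 0:
        raise ValueError("gene subset must be a non-empty 1-D index array")
    if len(set(subset.tolist())) != subset.size:
        raise ValueError("gene subset contains duplicate indices")
    if subset.min() < 0 or subset.max() >= n_genes:
        raise ValueError("gene subset index out of range")
    return subset


def _majority_vote(neighbor_labels: np.ndarray, k: int) -> str:
    """Strict-majority vote: the winning class needs > k/2 of the votes."""
    labels, counts = np.unique(neighbor_labels, return_counts=True)
    top = counts.argmax()
    if counts[top] * 2 > k:
        return str(labels[top])
    return UNCLASSIFIED


def knn_predict(
    train_values: np.ndarray,
    train_labels: list[str],
    query: np.ndarray,
    subset: np.ndarray,
    k: int,
) -> str:
    """Classify one query sample by its k nearest training samples.

    Distances use only the genes in ``subset``.  Returns the class held by
    a strict majority of the k nearest neighbors, else ``UNCLASSIFIED``.
    """
    train_values = np.asarray(train_values, dtype=float)
    n_train = train_values.shape[1]
    if k > n_train:
        raise ValueError(f"k={k} exceeds the {n_train} training samples")
    subset = _validate_subset(subset, train_values.shape[0])
    diffs = train_values[subset, :] - np.asarray(query, dtype=float)[subset, None]
    sq_dist = (diffs**2).sum(axis=0)
    order = np.argsort(sq_dist, kind="stable")  # ties fall back to train index
    neighbor_labels = np.asarray(train_labels)[order[:k]]
    return _majority_vote(neighbor_labels, k)


def _votes_from_sq_dist(
    sq_dist: np.ndarray, train_codes: np.ndarray, n_classes: int, k: int
) -> np.ndarray:
    """Vectorized strict-majority vote for a (queries x train) distance matrix.

    Returns the winning class code per query, or -1 for a reject.

    Fast path: partial selection of the k nearest.  When the k-th and
    (k+1)-th distances of a row are exactly equal, the set of k nearest is
    ambiguous and that row falls back to a stable full sort whose ties
    break by training index — the same policy as :func:`knn_predict`.
    """
    n_q, n_train = sq_dist.shape
    if n_train > k:
        part = np.argpartition(sq_dist, k, axis=1)
        kth = np.take_along_axis(sq_dist, part[:, :k], axis=1).max(axis=1)
        nxt = np.take_along_axis(sq_dist, part[:, k : k + 1], axis=1)[:, 0]
        neigh_idx = np.sort(part[:, :k], axis=1)
        ambiguous = np.flatnonzero(kth >= nxt)
        for row in ambiguous:
            order = np.argsort(sq_dist[row], kind="stable")
            neigh_idx[row] = order[:k]
    else:
        neigh_idx = np.broadcast_to(np.arange(k), (n_q, k))
    neigh = train_codes[neigh_idx]  # (n_queries, k)
    counts = np.bincount(
        (np.arange(n_q)[:, None] * n_classes + neigh).ravel(),
        minlength=n_q * n_classes,
    ).reshape(n_q, n_classes)
    best = counts.argmax(axis=1)
    best_count = counts[np.arange(n_q), best]
    return np.where(best_count * 2 > k, best, -1)


def knn_predict_batch(
    train_values: np.ndarray,
    train_codes: np.ndarray,
    query_values: np.ndarray,
    n_classes: int,
    subset: np.ndarray,
    k: int,
) -> np.ndarray:
    """Classify many queries at once; labels are integer class codes.

    Returns one code per query column, -1 meaning ``UNCLASSIFIED``.
    Equivalent to calling :func:`knn_predict` per query.
    """
    train_values = np.asarray(train_values, dtype=float)
    if k > train_values.shape[1]:
        raise ValueError("k exceeds the number of training samples")
    subset = _validate_subset(subset, train_values.shape[0])
    x = train_values[subset, :]  # (L, n_train)
    q = np.asarray(query_values, dtype=float)[subset, :]  # (L, n_queries)
    sq = ((x[:, None, :] - q[:, :, None]) ** 2).sum(axis=0)  # (n_queries, n_train)
    return _votes_from_sq_dist(sq, np.asarray(train_codes), n_classes, k)


def training_fitness(
    train_values: np.ndarray,
    train_labels: list[str] | np.ndarray,
    subset: np.ndarray,
    k: int,
) -> float:
    """Leave-one-out KNN accuracy of a gene subset on the training set.

    Each sample is predicted from the remaining training samples;
    ``UNCLASSIFIED`` counts as incorrect.
    """
    train_values = np.asarray(train_values, dtype=float)
    n_train = train_values.shape[1]
    if n_train < k + 1:
        raise ValueError("training set must have at least k + 1 samples")
    subset = _validate_subset(subset, train_values.shape[0])
    labels = np.asarray(train_labels)
    classes, codes = np.unique(labels, return_inverse=True)
    x = train_values[subset, :]
    # ||xi - xj||^2 via the Gram matrix; cheaper than forming all pairwise diffs
    sq_norm = (x * x).sum(axis=0)
    sq = sq_norm[:, None] + sq_norm[None, :] - 2.0 * (x.T @ x)
    np.fill_diagonal(sq, np.inf)  # exclude self from its own neighbor search
    pred = _votes_from_sq_dist(sq, codes, classes.size, k)
    return float(np.mean(pred == codes))
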