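"""Tests of subtype discovery, enrichment, rank comparison, rank-sum tests,
and matched subsampling."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from gaknn import (
    ExpressionDataset,
    GeneFrequencyTable,
    compare_rankings,
    floor_log2,
    generate_survival_free_clusters,
    hypergeom_enrichment,
    matched_subsample,
    ranksum_by_gender,
    subtype_discovery,
)
from gaknn.downstream import _approx_ranksum_p, _exact_ranksum_p


def enumeration_hypergeom(flagged_in_top, top_n, flagged_total, universe):
    """Oracle: count top-N draws with >= flagged_in_top flagged genes over
    all C(universe, top_n) subsets, as an exact rational."""
    flagged = set(range(flagged_total))
    hits = total = 0
    for draw in combinations(range(universe), top_n):
        total += 1
        hits += len(flagged.intersection(draw)) >= flagged_in_top
    return Fraction(hits, total)


class TestHypergeomEnrichment:
    def test_zero_hits_is_certain(self):
        assert hypergeom_enrichment(0, 5, 3, 20) == 1.0

    def test_worked_example_one_third(self):
        p = hypergeom_enrichment(2, 3, 4, 10)
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_everything_flagged_is_certain(self):
        assert hypergeom_enrichment(4, 4, 10, 10) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(5, 3, 10, 20)
        with pytest.raises(ValueError):
            hypergeom_enrichment(1, 25, 10, 20)

    def test_matches_exhaustive_enumeration(self):
        """Exact rational agreement with subset enumeration, universe <= 12."""
        for universe in (5, 8, 12):
            for flagged_total in range(universe + 1):
                for top_n in range(1, universe + 1):
                    for k in range(0, min(top_n, flagged_total) + 1):
                        expected = enumeration_hypergeom(
                            k, top_n, flagged_total, universe
                        )
                        got = hypergeom_enrichment(k, top_n, flagged_total, universe)
                        assert got == pytest.approx(float(expected), abs=1e-10)


def _table(order):
    """GeneFrequencyTable with the given gene order (rank 1 first)."""
    counts = {g: len(order) - i for i, g in enumerate(order)}
    ranks = {g: i + 1 for i, g in enumerate(order)}
    return GeneFrequencyTable(
        counts=counts, ranks=ranks, total_runs=len(order), chromosome_length=1
    )


class TestCompareRankings:
    def test_self_comparison_is_identity(self):
        table = _table([f"g{i}" for i in range(20)])
        cmp = compare_rankings(table, table, top_n=10)
        assert cmp.union_size == 10
        assert cmp.intersection_size == 10
        assert all(d == 0 for d in cmp.rank_differences.values())
        assert cmp.large_difference_genes == []

    def test_inclusion_exclusion(self):
        genes = [f"g{i}" for i in range(30)]
        a = _table(genes)
        b = _table(genes[::-1])
        for top_n in (5, 10, 15):
            cmp = compare_rankings(a, b, top_n=top_n)
            assert cmp.union_size + cmp.intersection_size == 2 * top_n

    def test_swap_negates_differences(self):
        genes = [f"g{i}" for i in range(15)]
        a = _table(genes)
        b = _table(genes[5:] + genes[:5])
        ab = compare_rankings(a, b, top_n=7, rank_diff_threshold=3)
        ba = compare_rankings(b, a, top_n=7, rank_diff_threshold=3)
        assert ab.union_size == ba.union_size
        assert ab.intersection_size == ba.intersection_size
        for g, d in ab.rank_differences.items():
            assert ba.rank_differences[g] == -d
        assert ab.large_difference_genes == ba.large_difference_genes

    def test_full_table_ranks_used_for_outsiders(self):
        genes = [f"g{i:03d}" for i in range(200)]
        # gene g150 jumps to rank 1 in B; in A it stays at rank 151
        b_order = [genes[150]] + [g for g in genes if g != genes[150]]
        cmp = compare_rankings(_table(genes), _table(b_order), top_n=10,
                               rank_diff_threshold=100)
        assert cmp.rank_differences[genes[150]] == 151 - 1
        assert cmp.large_difference_genes == [genes[150]]

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            compare_rankings(_table(["a", "b"]), _table(["a", "c"]), top_n=1)


def _gender_dataset(male_values, female_values, class_name="T"):
    vals = np.array(male_values + female_values, dtype=float)[None, :]
    n = vals.shape[1]
    return ExpressionDataset(
        values=vals,
        gene_ids=["g0"],
        sample_ids=[f"s{i}" for i in range(n)],
        class_labels=[class_name] * n,
        gender=["male"] * len(male_values) + ["female"] * len(female_values),
        is_log2=True,
    )


def enumeration_ranksum_p(x, y):
    """Oracle: exact two-sided rank-sum p with hand-computed midranks and
    rational arithmetic over all group assignments."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    midrank = [Fraction(0)] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mean_rank = Fraction(sum(range(i + 1, j + 1)), j - i)
        for t in range(i, j):
            midrank[order[t]] = mean_rank
        i = j
    n = len(x)
    w_obs = sum(midrank[:n])
    sums = [
        sum(midrank[i] for i in idx)
        for idx in combinations(range(len(pooled)), n)
    ]
    p_le = Fraction(sum(s <= w_obs for s in sums), len(sums))
    p_ge = Fraction(sum(s >= w_obs for s in sums), len(sums))
    return min(Fraction(1), 2 * min(p_le, p_ge))


class TestRanksumByGender:
    def test_worked_example_one_third(self):
        ds = _gender_dataset([1.0, 2.0], [3.0, 4.0])
        w, p = ranksum_by_gender(ds, "g0", "T")
        assert w == 3.0  # male samples hold ranks 1 and 2
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        ds = _gender_dataset([1.0, 2.0, 2.0], [2.0, 1.0, 2.0])
        _, p = ranksum_by_gender(ds, "g0", "T")
        assert p == 1.0

    def test_absent_gender_named(self):
        ds = _gender_dataset([1.0, 2.0], [])
        ds.gender = ["male", "male"]
        with pytest.raises(ValueError, match="female"):
            ranksum_by_gender(ds, "g0", "T")

    def test_unknown_gene_rejected(self):
        ds = _gender_dataset([1.0], [2.0])
        with pytest.raises(ValueError, match="nope"):
            ranksum_by_gender(ds, "nope", "T")

    def test_exact_branch_matches_full_enumeration(self, rng):
        """Group sizes up to 6, tie-heavy values, exact rational oracle."""
        for _ in range(40):
            nx = int(rng.integers(1, 7))
            ny = int(rng.integers(1, 7))
            x = rng.integers(0, 4, nx).astype(float)
            y = rng.integers(0, 4, ny).astype(float)
            expected = enumeration_ranksum_p(x.tolist(), y.tolist())
            got = _exact_ranksum_p(x, y)
            assert got == pytest.approx(float(expected), abs=1e-9)

    def test_exact_and_approx_branches_agree(self, rng):
        """At 10 vs 10 the normal approximation tracks the exact enumeration
        within 0.01 on continuous data; heavy ties (values rounded to one
        decimal) cost the approximation a little more."""
        worst = 0.0
        for _ in range(100):
            x, y = rng.normal(size=10), rng.normal(size=10)
            worst = max(worst, abs(_exact_ranksum_p(x, y) - _approx_ranksum_p(x, y)))
        assert worst < 0.01
        worst_tied = 0.0
        for _ in range(100):
            x = np.round(rng.normal(size=10), 1)
            y = np.round(rng.normal(size=10), 1)
            worst_tied = max(
                worst_tied, abs(_exact_ranksum_p(x, y) - _approx_ranksum_p(x, y))
            )
        assert worst_tied < 0.02

    def test_large_groups_use_approximation(self, rng):
        male = rng.normal(size=25).tolist()
        female = (rng.normal(size=30) + 2.0).tolist()
        ds = _gender_dataset(male, female)
        _, p = ranksum_by_gender(ds, "g0", "T")
        assert p < 1e-4  # clear shift is detected


def _cluster_table(dataset):
    return _table(list(dataset.gene_ids))


class TestSubtypeDiscovery:
    def test_planted_two_clusters_recovered(self):
        ds, labels = generate_survival_free_clusters(2, 25, 40, 10.0, seed=1)
        ds = ds.apply_floor_log2()
        res = subtype_discovery(ds, "C0", _cluster_table(ds), n_top=40,
                                candidate_k=(2, 3), seed=0)
        assert res.chosen_k == 2
        assert adjusted_rand_score(labels, res.assignments) == 1.0
        assert res.silhouette_by_k[2] > res.silhouette_by_k[3]

    def test_zero_iqr_gene_excluded(self):
        ds, _ = generate_survival_free_clusters(2, 20, 20, 8.0, seed=2)
        ds = ds.apply_floor_log2()
        ds.values[3, :] = 5.0  # constant within the class: zero IQR
        res = subtype_discovery(ds, "C0", _cluster_table(ds), n_top=20, seed=0)
        assert ds.gene_ids[3] not in res.genes_used
        assert len(res.genes_used) == 19

    def test_no_separation_scores_near_zero(self):
        ds, _ = generate_survival_free_clusters(2, 25, 40, 0.0, seed=3)
        ds = ds.apply_floor_log2()
        res = subtype_discovery(ds, "C0", _cluster_table(ds), n_top=40, seed=0)
        assert all(s < 0.2 for s in res.silhouette_by_k.values())

    def test_all_genes_constant_rejected(self):
        ds, _ = generate_survival_free_clusters(2, 10, 5, 5.0, seed=4)
        ds = ds.apply_floor_log2()
        ds.values[:, :] = 1.0
        with pytest.raises(ValueError, match="IQR"):
            subtype_discovery(ds, "C0", _cluster_table(ds), n_top=5, seed=0)


class TestMatchedSubsample:
    def _dataset(self, counts_male, counts_female):
        labels, gender = [], []
        for cls in sorted(set(counts_male) | set(counts_female)):
            labels += [cls] * counts_male.get(cls, 0)
            gender += ["male"] * counts_male.get(cls, 0)
            labels += [cls] * counts_female.get(cls, 0)
            gender += ["female"] * counts_female.get(cls, 0)
        n = len(labels)
        return ExpressionDataset(
            values=np.zeros((1, n)), gene_ids=["g0"],
            sample_ids=[f"s{i}" for i in range(n)],
            class_labels=labels, gender=gender, is_log2=True,
        )

    def test_full_pool_target_forces_whole_cohort(self):
        ds = self._dataset({"A": 3, "B": 2}, {"A": 1})
        reps = matched_subsample(ds, "male", {"A": 3, "B": 2}, 4, seed=0)
        male_pool = np.flatnonzero(np.asarray(ds.gender) == "male")
        for rep in reps:
            assert np.array_equal(rep, male_pool)

    def test_both_candidates_appear_across_replicates(self):
        ds = self._dataset({"A": 2}, {"A": 1})
        reps = matched_subsample(ds, "male", {"A": 1}, 50, seed=1)
        chosen = {int(rep[0]) for rep in reps}
        assert len(chosen) == 2

    def test_contract_counts_and_no_duplicates(self, rng):
        ds = self._dataset({"A": 9, "B": 6, "C": 4}, {"A": 5, "B": 2})
        labels = np.asarray(ds.class_labels)
        gender = np.asarray(ds.gender)
        for trial in range(20):
            target = {
                "A": int(rng.integers(1, 10)),
                "B": int(rng.integers(1, 7)),
                "C": int(rng.integers(1, 5)),
            }
            reps = matched_subsample(ds, "male", target, 3, seed=trial)
            for rep in reps:
                assert len(set(rep.tolist())) == rep.size  # no duplicates
                assert np.all(gender[rep] == "male")
                for cls, want in target.items():
                    assert int(np.sum(labels[rep] == cls)) == want

    def test_shortfall_names_class(self):
        ds = self._dataset({"A": 2}, {"A": 5})
        with pytest.raises(ValueError, match="A.*short by 3"):
            matched_subsample(ds, "male", {"A": 5}, 1, seed=0)

    def test_deterministic_given_seed(self):
        ds = self._dataset({"A": 8, "B": 5}, {})
        r1 = matched_subsample(ds, "male", {"A": 4, "B": 2}, 3, seed=9)
        r2 = matched_subsample(ds, "male", {"A": 4, "B": 2}, 3, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(r1, r2))
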