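# gaknn

Ensemble GA/KNN classification of multi-class gene-expression data, with
per-sample prediction profiles, frequency-based gene importance ranking,
and downstream analyses for subtype discovery, gene-class enrichment, and
cohort comparison.

## The problem

Given a genes × samples matrix of normalized RNA-seq expression values and
a class label per sample (e.g. tumor type), find small gene sets whose
expression distinguishes the classes — in a regime where genes vastly
outnumber samples, so many different gene sets classify about equally
well. The package is aimed at computational biologists who want both a
classifier with a principled reject option and a stable, interpretable
ranking of which genes matter.

## The method

A genetic algorithm searches over fixed-size gene subsets ("chromosomes",
default 20 genes). A subset's fitness is the leave-one-out training
accuracy of a k-nearest-neighbor classifier (k = 5, Euclidean distance on
per-gene z-scores) with a strict-majority vote: a class needs > k/2 of the
k nearest neighbors, otherwise the sample is *unclassifiable* (UC). Each
run stops once the best subset classifies ≥ 90% of training samples
correctly (or after 300 generations) and its best subset predicts the
held-out test samples.

Repeating the run R times over one fixed 75/25 stratified partition gives,
for each test sample, the proportion of runs assigning it to each of the
C + 1 categories (C classes plus UC). These proportions sum to 1; the
true-class entry is **π_cc**, the proportion of runs that classified the
sample correctly. The **modal prediction** is the category assigned most
often, and the **gene importance rank** orders genes by how many of the R
near-optimal subsets contained them. See `docs/methods.md` for the full
model description and design choices.

## Worked example

Simulate a dataset with planted structure (5 classes × 30 samples, 1000
genes, 5 discriminative genes per class at a 4-fold shift, 10% of genes
flagged as a pseudogene stand-in), then run a 50-run ensemble:

```python
import numpy as np
from gaknn import (SyntheticSpec, generate_dataset, stratified_split, GAConfig,
                   run_ensemble, compute_profiles, modal_accuracy,
                   gene_frequencies, hypergeom_enrichment)

spec = SyntheticSpec(n_classes=5, samples_per_class=(30,) * 5, n_genes=1000,
                     informative_per_class=5, effect_size=2.0, noise_sd=1.0,
                     flagged_fraction=0.10, flagged_informative_bias=0.8, seed=1)
dataset, truth = generate_dataset(spec)
dataset = dataset.apply_floor_log2()

partition = stratified_split(dataset.class_labels, 0.75, seed=2)
config = GAConfig(chromosome_length=10, population_size=50, max_generations=50)
result = run_ensemble(dataset, partition, config, n_runs=50, base_seed=1000)

per_class, overall = modal_accuracy(result)
profiles = compute_profiles(result)
table = gene_frequencies([result])
top25 = table.top(25)
planted = {dataset.gene_ids[g] for g in truth.all_informative()}
p = hypergeom_enrichment(sum(g in dataset.gene_flags for g in top25), 25,
                         len(dataset.gene_flags), dataset.n_genes)

print(f"modal prediction accuracy: {overall:.3f}")
print(f"mean pi_cc: {np.mean([pr.pi_cc for pr in profiles]):.3f}")
print(f"top-25 genes that were planted: {sum(g in planted for g in top25)}/25")
print(f"flagged-gene enrichment P = {p:.2e}")
```

Output:

```
modal prediction accuracy: 0.943
mean pi_cc: 0.682
top-25 genes that were planted: 25/25
flagged-gene enrichment P = 5.59e-17
```

Reading: 94% of test samples have their true class as the most frequent
prediction across the 50 runs; the average test sample was assigned its
true class in 68% of runs (the gap comes from runs whose neighbor vote was
split, producing UC assignments); the frequency ranking put all 25 planted
genes in the top 25; and the flagged genes, into which the planted genes
were biased, are strongly enriched at the top of the ranking.

The same pipeline is available from the shell via `gaknn simulate`,
`gaknn run`, `gaknn summarize`, `gaknn rank`, plus the downstream commands
`gaknn subtypes`, `gaknn enrich`, `gaknn compare-ranks`, `gaknn ranksum`,
and `gaknn match-subsample`; all read and write plain TSV.

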