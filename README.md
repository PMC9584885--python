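# proteostrat

Proteome-based patient stratification for CLL-like study designs, as a
tested, reusable Python library.

Chronic lymphocytic leukemia (CLL) patients are conventionally
stratified by genetics (IGHV mutation status, trisomy 12, *TP53*
aberrations).  Deep proteomic profiling reveals an additional
subgroup — about 20% of patients, invisible to genetics and
transcriptomics — characterized by high spliceosomal protein
abundance, low B-cell receptor (BcR) signaling protein abundance,
aberrant exon usage, and poor outcome ("ASB": **A**ltered
**S**pliceosome, low **B**cR).  `proteostrat` implements the full
statistical workflow used to find and validate such a subgroup, plus a
synthetic multi-omics cohort generator that plants the structure the
workflow must recover, so every stage is testable without access to
restricted patient data.

The package is aimed at computational biologists who want either the
individual statistical components or an end-to-end, seeded,
reproducible benchmark of the stratification workflow.

## Components

| Module | Contents |
| --- | --- |
| `proteostrat.simulate` | synthetic cohorts: six planted subgroups, chr12 dosage effects, class-dependent mRNA~protein coupling, splice-event counts, survival, drug screen |
| `proteostrat.io` | log2 abundance matrix / GMT / annotation TSV readers and writers, sample alignment |
| `proteostrat.differential` | empirical-Bayes moderated t (limma-style), BH, LOWESS dosage profiles, per-gene Spearman mRNA~protein correlation, KS comparison, Fisher over-representation, chr12-based trisomy inference |
| `proteostrat.consensus` | Monti-style resampling consensus clustering, delta-area k selection, genotype enrichment, PCA |
| `proteostrat.splicing` | PSI quantification, variable-event summaries, differential exon skipping (rank test + filters), permutation null for N_e, exon-level relative usage |
| `proteostrat.classifiers` | k-top-scoring-pairs classifier with Monte-Carlo CV and the missing-pair voting rule; NIPALS PLS-DA with leave-one-out AUROC |
| `proteostrat.survival` | endpoint construction (TTNT/TTFT/OS), Kaplan–Meier, log-rank, Newton–Raphson Cox (Efron/Breslow ties), lymphocyte growth rates, drug-plate viability normalization |
| `proteostrat.network` | protein correlation network, k-core, Louvain modules, module expansion and summaries |
| `proteostrat.pipeline` / CLI | seeded discovery + validation runs with JSON reports |

The statistic at the core of the subgroup discovery is the consensus
matrix M[i,j] = (# resampled clusterings putting samples i, j in the
same cluster) / (# resamplings containing both), partitioned at k = 6;
the subgroup's splicing phenotype is quantified by the percent
spliced-in value PSI = (I/l_I) / (I/l_I + S/l_S) of exon-skipping
events, with group differences tested by rank-sum + BH at FDR 1%,
|ΔPSI| > 0.1, mean inclusion coverage > 20, and the count N_e of
passing events tested against a label-permutation null,
p = (1 + #{N_e^null ≥ N_e}) / (n_perm + 1).

## Worked example

```python
from proteostrat.simulate import CohortConfig, simulate_cohort
from proteostrat.consensus import consensus_cluster, choose_k
from proteostrat.splicing import differential_psi, permutation_null
from sklearn.metrics import adjusted_rand_score

bundle = simulate_cohort(CohortConfig(seed=1))
print("samples:", len(bundle.sample_ids), "| proteins:", bundle.protein.n_features)

res = consensus_cluster(bundle.protein, [6], n_iter=200, seed=1)
k = choose_k(res, override=6)
labels = res.labels[k]
print("k =", k, "| ARI vs truth =", round(adjusted_rand_score(bundle.truth, labels), 3))

diff = differential_psi(bundle.events, bundle.truth, "ASB")
print("significant exon-skipping events (N_e):", int(diff["significant"].sum()))

perm = permutation_null(bundle.events, bundle.truth, "ASB", n_perm=57, seed=1)
print("permutation p =", round(perm.p, 4))
```

prints

```
samples: 68 | proteins: 1500
k = 6 | ARI vs truth = 0.853
significant exon-skipping events (N_e): 130
permutation p = 0.0172
```

Reading: consensus clustering of the simulated 68-patient proteome
recovers the six planted subgroups almost exactly (adjusted Rand index
0.85 against the generating labels); 130 exon-skipping events separate
the ASB-like group from the rest after all three filters; and none of
57 label permutations produces as many significant events, so the
permutation p-value is at its add-one floor 1/58 ≈ 0.0172 — the
splicing phenotype is not a relabeling artifact.

The same workflow is available from the shell:

```bash
proteostrat simulate --out cohort/ --seed 1
proteostrat cluster --bundle cohort/ --override-k 6 --iters 200 --seed 1
proteostrat splice diff --bundle cohort/ --group ASB
proteostrat run-all --out run/ --seed 1
```

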