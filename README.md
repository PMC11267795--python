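# gallimeta

Analysis toolkit for gene-catalogue metagenomics of poultry caecal
microbiomes — built for studies of scavenging indigenous chickens, where
communities are profiled from deep shotgun data via a non-redundant gene
catalogue and metagenome-assembled genomes (MAGs) rather than amplicons.
It is aimed at microbiome bioinformaticians who want the pipeline's
statistical machinery as a tested, scriptable library, with a synthetic
data generator so every stage can be verified against known ground truth
without touching the (very large) real inputs.

## What it implements

- **Gene catalogue** (`gallimeta.catalogue`): six-frame maximal-ORF
  prediction (length > 200 nt), greedy non-redundant clustering at 95%
  identity over 90% of the shorter sequence, and core-gene prevalence
  (core = present in ≥ 80% of samples).
- **Two-pass LCA taxonomy** (`gallimeta.taxonomy_lca`): significant hits
  (E < 10⁻⁵) define a per-query best E-value; second-pass hits at E-values
  ≤ that best form the homolog neighbourhood; the query is assigned the
  lowest common ancestor of the neighbourhood lineages, and abundances are
  length-normalised with unassigned mass conserved.
- **Diversity & differential abundance** (`gallimeta.profiles`): CPM
  filtering, Shannon / inverse Simpson / richness, Bray–Curtis, seeded
  PERMANOVA, Kruskal–Wallis + Benjamini–Hochberg, tenfold-enrichment
  classes, and site/sample core-species flags (100% of sites, ≥ 90% of
  samples).
- **Enterotypes** (`gallimeta.enterotype`): distances d = √JSD (base-2),
  deterministic PAM k-medoids, Calinski–Harabasz model selection,
  LEfSe-style discriminant ranking, and Spearman co-occurrence networks
  (|ρ| > 0.5, p < 0.01, abundance > 0.01%).
- **Ecology** (`gallimeta.ecology`): K-means climate zones (k = 5) on
  three standardised climate variables, VIF pruning (< 20), RDA on
  Hellinger-transformed abundances, Mantel tests, Spearman
  covariate associations with BH correction, AICc polynomial selection for
  the altitude–diversity trend, and stepwise-AIC linear models.
- **Genome comparison** (`gallimeta.genome_compare`): quality filtering
  (completeness ≥ 80%, contamination ≤ 5%), fragment-mapping ANI and
  reciprocal-best-hit AAI, greedy dereplication at 99% (strain) and 95%
  (species) ANI, single-linkage genus clusters at > 60% AAI, and the
  strain/species/genus uniqueness decision rules.
- **Functional summaries** (`gallimeta.function_summary`): CAZyme richness
  per genome, pathway completeness (8-step methanogenesis with the *mcr*
  key gene), UpSet-style SCFA intersection counts (≥ 10-genome filter),
  and the 5 h copiotroph/oligotroph boundary.
- **Synthetic data** (`gallimeta.synthetic`): genomes with exact pairwise
  substitution divergence, Dirichlet-multinomial communities with planted
  enterotypes linked to an altitude gradient, two-pass hit tables with
  optional decoys, and annotation/quality tables — all seeded and
  deterministic.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Simulate a 90-sample community with three planted enterotypes, recover
them, and rank the discriminating genera:

```python
from gallimeta import synthetic as syn, enterotype as ent

counts, env, truth = syn.gen_community(n_samples=90, seed=7)
rel = counts / counts.sum(axis=0)
dist = ent.jsd_distance(rel)
k, fit, scores = ent.select_k(dist, k_max=6)
print(f"selected k = {k}")
print("CH scores:", {kk: round(v, 1) for kk, v in scores.items()})

top = ent.top_features(ent.lda_effect_size(rel, fit.labels), n=3)
for cluster, genera in top.items():
    print(f"cluster {cluster}: {', '.join(genera)}")
```

Output:

```
selected k = 3
CH scores: {2: 24.7, 3: 48.4, 4: 33.3, 5: 25.7, 6: 21.2}
cluster 1: Alistipes, Brachyspira, Mucispirillum
cluster 2: Prevotella, Faecalibacterium, Megamonas
cluster 3: Bacteroides, Blautia, Clostridium
```

The Calinski–Harabasz score peaks at k = 3 (48.4 against 24.7 for k = 2):
the three planted enterotypes are recovered, and each cluster's top
discriminators are exactly its planted signature genera — a
Prevotella-driven cluster, an Alistipes-driven one and a
Bacteroides-driven one, mirroring the structure reported for real caecal
enterotypes.  On this seed the recovered labels match the ground truth
perfectly (adjusted Rand index 1.00).

The same operations are available from the shell:

```bash
gallimeta synth --n-samples 90 --seed 7
gallimeta enterotype fit synthetic.counts.tsv
gallimeta profiles diff synthetic.counts.tsv enterotypes.tsv
```

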