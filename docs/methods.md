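# Methods

`gallimeta` reimplements, as a tested library, the computational analysis
pipeline used for gene-catalogue metagenomics of scavenging-chicken caecal
communities: non-redundant gene-catalogue construction, two-pass
lowest-common-ancestor (LCA) taxonomy, enterotype detection, ecological
association, genome dereplication and novelty classification, and
functional summarisation.  Because the real inputs are hundreds of deep
shotgun metagenomes, every stage is exercised instead on synthetic data
with known ground truth; this note records the models, the defaults, and
the numerical choices, and what the synthetic results do and do not show.

## Synthetic data model

**Taxonomy.** `gen_taxonomy` builds a balanced 7-rank tree
(domain…species) with pseudo-Latin names; determinism is per-seed.

**Genomes.** Every species receives an ancestor sequence; strains are
substitution-mutated copies.  Divergence parameters are *pairwise*: each of
the k siblings mutates its own disjoint set of `d/2 · L` sites, so any two
siblings differ at a fraction `d` of sites exactly (up to rounding), rather
than in expectation.  Mutations are substitutions only — no indels — which
keeps the alignment problem for the ANI/AAI estimators honest but
trivially solvable; this is a deliberate fixture simplification, and
estimator accuracy on indel-rich real genomes is *not* demonstrated by the
tests.  Defaults place strain pairs at 2% divergence (ANI 98, inside the
conventional 95–99% strain band) and congeneric species pairs at 8%
(ANI 92, below the 95% species boundary), so that strain-level (99% ANI)
dereplication resolves strains and species-level (95%) dereplication
collapses them — the behaviour the real pipeline's strain/species MAG
counts rely on.  Each genus ancestor carries 30 planted protein-coding
genes (300 nt, stop-free interiors) whose translations provide proteomes
for AAI.

**Communities.** Counts are Dirichlet-multinomial: sample composition ~
Dirichlet(α₀·p(e)) around the sample's enterotype profile p(e), counts
multinomial at a fixed depth (exact depth, not Poisson, so
counts-per-million arithmetic is exact in tests).  Three default profiles
over 40 genera mirror the structure of real caecal enterotypes: each
enterotype has one discriminating genus (Alistipes, Bacteroides,
Prevotella) boosted 2.5-fold and four supporting signature genera boosted
1.8-fold, while carrying the other enterotypes' signature genera at 0.45×
baseline — enterotypes of real communities differ across many genera, not
one.  The profile structure is symmetric, so after renormalisation each
discriminating genus is *exactly* ≥ 2.5× more abundant in its own
enterotype's mean profile than in any other.  Defaults α₀ = 100 and depth
= 20 000 give realistic overdispersion for deeply sequenced gut
communities.  Sites map to five climate zones; zone 1 sits at ~3 100 m and
draws enterotype 3 with probability 0.62, the other zones favour
enterotypes 1–2; altitude, temperature and precipitation covary with zone,
all other covariates are uncorrelated noise by default.

**Hit tables.** For each query gene the first pass holds the true-species
hit at the lowest E-value plus weaker same-genus neighbours; the second
pass holds the homolog neighbourhood (same-genus hits at E-values at or
below the first-pass best), weaker homologs above it, and optional
off-lineage decoys at E ≥ 1e-5 — i.e. above the significance cutoff, so a
correct filter must discard them.  Decoys are drawn from a separate random
stream, so tables with and without decoys differ only by the decoy rows.
The E-values themselves are not calibrated to any alignment statistics;
only their order matters to the rules under test.

## Gene catalogue

ORF calling is a naive six-frame maximal-ORF finder (first ATG after each
stop, to the stop; codons containing N match nothing), not an HMM gene
predictor — adequate for planted-ORF fixtures, not for real contigs.  The
default length floor is 200 nt.  Redundancy removal follows the CD-HIT
contract: greedy longest-first clustering (ties by gene id), joining the
first representative matched at ≥ 95% identity over ≥ 90% of the shorter
sequence.  Identity is computed gaplessly at the best k-mer-anchored
offset (k = 8); the tests assert the *contract* — via an exhaustive
all-offsets oracle — rather than the specific anchoring heuristic.  Word
size and tie-breaking are not dictated by the original tooling's
documentation; the defaults here are stated choices.

## Two-pass LCA taxonomy

Hits are significant when E < 1e-5 (strict).  Per query, the first-pass
best E-value is the minimum over its significant hits; the homolog
neighbourhood is the set of significant second-pass hits with E-values at
or below that best value ("at or below" uses the per-query best, not
per-subject values — the finer-grained alternative is unspecified in the
original description).  The assignment is the deepest rank prefix shared
by all neighbourhood lineages, with an empty rank slot counting as
disagreement.  Rank profiles weight each gene by count/length, normalise
per sample, and keep unassigned mass in an explicit `unclassified` row so
per-sample totals are conserved to 1e-9.

## Enterotypes

Sample distances are the square root of the Jensen–Shannon divergence
(base-2 logs, range [0, 1]) after adding a 1e-6 pseudocount per entry and
renormalising — KL terms need full support; pseudocount 0 reproduces the
disjoint-support maximum of exactly 1.  Clustering is PAM k-medoids with a
deterministic greedy BUILD and best-improvement SWAP; there is no random
restart, so reruns are bit-identical and the objective is non-increasing
by construction.

The number of clusters is chosen by the Calinski–Harabasz index, computed
from the distance matrix via sum-of-squares identities: within-cluster SS
is Σ_{i<j∈c} d²ij / n_c, between SS is total minus within (the PERMANOVA
decomposition).  An alternative CH variant that measures between-cluster
spread as squared distances from cluster medoids to the overall medoid was
evaluated and rejected: the overall medoid is a data point inside one of
the clusters, that cluster's between-term vanishes, and with three planted
enterotypes the criterion preferred k = 2 even when PAM at k = 3 matched
the truth perfectly.  With the SS-identity form, k = 3 is recovered on
20/20 default-parameter simulations.  Silhouette width is reported
alongside as a diagnostic only.

Discriminant ranking is LEfSe-flavoured: a Kruskal–Wallis screen at raw
p < 0.05, abundances scaled to a per-sample total of 1e6, then a one-vs-rest
score log10(1 + |0.5·(w·s + Δ)|) per feature, where Δ is the between-class
mean difference and w·s the linear-discriminant coefficient rescaled by the
pooled within-class SD.  The original tool's subclass (Wilcoxon) stage and
LDA bootstrap are deliberately omitted — there are no subclasses here, and
a single deterministic least-squares fit replaces the bootstrap.  Absolute
scores are therefore not comparable with the original tool's 10⁰–10⁵ scale;
only within-class rankings are meaningful, and only rankings are tested.

Co-occurrence networks keep genus pairs with |Spearman ρ| > 0.5, p < 0.01
and both mean abundances above 0.01%; constant genera are skipped.

## Diversity and differential abundance

Shannon entropy uses natural logs (uniform over n gives ln n); inverse
Simpson is 1/Σp².  Bray–Curtis, PERMANOVA (pseudo-F with
p = (1 + #{F* ≥ F})/(1 + n_perm)) and Mantel (Spearman) come from
scipy/scikit-bio with explicit seeds, so identical seeds reproduce
identical p-values.  Kruskal–Wallis uses the chi-squared approximation
with tie correction; constant features are flagged with p = 1 rather than
dropped.  Benjamini–Hochberg is the classic step-up over all features of a
matrix.  Fold-enrichment compares *means*: a significant feature is
enriched in a group when its mean abundance there is at least 10× its mean
in every other group (medians would be a defensible alternative; means are
implemented and documented).  Core species carry two flags — present in at
least one sample of every site, and present in ≥ 90% of samples.

## Ecology

Climate zones are K-means (k = 5, Lloyd, seeded multi-start) on z-scored
annual temperature, annual precipitation and driest-quarter precipitation;
standardisation matters because the raw variable ranges differ by orders
of magnitude.  Collinearity pruning iteratively drops the highest-VIF
column until all VIF < 20, with infinite VIF (exact duplicates) handled
like any maximum.  RDA standardises constraints, regresses the
(Hellinger-transformed, a standard choice for abundance responses) matrix
on them by least squares, and reports trace(fitted²)/trace(centred²); the
implementation agrees with R vegan's `rda()` to 1e-7 on a frozen fixture.
The altitude–diversity trend uses AICc (small-sample corrected AIC) over
polynomial orders with an overall-F significance test; stepwise covariate
selection is forward–backward on AIC, deterministic given column order.
AIC stepwise is known to be liberal: under a pure null with five candidate
predictors it admits about one spurious variable on average — the tests
assert that calibrated behaviour rather than an empty selection.

## Genome comparison

ANI is fragment-mapping: the query is cut into non-overlapping 1 020-bp
fragments, each placed at its best k-mer-anchored offset (k = 16) and
scored gaplessly over the whole fragment; fragments under 80% identity do
not count as aligned, and ANI is undefined when fewer than half the
fragments align — undefined never merges anything.  Directional ANI is
symmetrised by the maximum.  On the substitution-only fixtures the
estimator is within 0.05 ANI points of truth across 0–5% divergence; on
real, rearranged, indel-bearing genomes it would not be — that is what the
fragment/identity floors are for, and why the tests only claim calibration
on the fixtures.  AAI is the mean identity of reciprocal best protein
hits, undefined below 5 RBH pairs.  Dereplication is greedy centroid
clustering in descending quality order, quality = completeness − 5 ×
contamination (the dominant terms of the usual dRep score; the N50 term is
omitted since synthetic genomes are single contigs).  Genus clusters are
single-linkage connected components over AAI > 60% edges (a componentwise
reading of "clustered at > 60% AAI"; average linkage would be stricter and
is noted as an alternative).  Novelty calls use strict inequalities — a
strain is known only above 99% ANI to a reference genome, a species above
95% — so a genome at exactly the threshold counts as unique; missing
comparisons yield an explicit indeterminate, never a silent "unique".

## Functional summaries

CAZy labels must match `^(GH|GT|PL|CE|CBM|AA)[0-9]+$`; richness reports
total genes, unique families and their GH-only restrictions, with genomes
above 250 CAZy genes flagged.  Pathway definitions ship as an editable
YAML file; methanogenesis is modelled as eight steps plus the key gene
*mcr*, which is tracked separately from the steps (whether the key gene
counts as a step is left open by the source material; here it does not).
`complete` requires all eight steps, `partial` at least four, and both
require the key gene when declared.  SCFA production potentials are
consumed as given labels and summarised as exclusive (UpSet-style)
intersections that partition the genome set; patterns under 10 genomes are
kept in totals but marked unreported.  Growth classification is by
doubling time with the open boundary at exactly 5 h resolved to
oligotroph.

## Problem sizes and verification

The shipped test-suite and acceptance-script problem sizes are: 2 000
genes for LCA recovery; 20 seeds × 90 samples for enterotype recovery;
10 seeds × 4 divergence levels (20-kb genomes) for ANI calibration and a
15-genome set for dereplication counts; 200 replicates × 199 permutations
for PERMANOVA/Mantel null calibration and 1 000 features for the
KW+BH null; 50 genes / 15 genomes for the greedy-vs-oracle contracts.
These sizes give tight Monte-Carlo error for every asserted property while
keeping a full run in tens of seconds.  What the passing suite shows:
the *rules* (filters, thresholds, LCA, model selection, estimators) are
implemented correctly and are well-calibrated on data satisfying their
assumptions.  What it does not show: performance on real metagenomes —
indel divergence, chimeric bins, uncalibrated E-values, compositional
artifacts and uneven depth are all outside the synthetic model.
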