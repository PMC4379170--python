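# Methods

This note documents the models and procedures implemented in
`targetprops`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Problem framing: positive–unlabelled classification

A protein is *positive* in a category dataset when it is the target of an
approved drug (for the cancer dataset, of an antineoplastic drug), and
*unlabelled* otherwise. The unlabelled class is not a negative class: it
contains both never-druggable proteins and future targets. Two
consequences drive the design:

* the classifier's per-protein score (positive similarity) matters more
  than its class calls — highly scored unlabelled proteins are the
  candidate future targets, not errors;
* evaluation must be unbiased for the very proteins the model was trained
  on, because the dataset *is* the population of interest. This is what
  the out-of-bag (OOB) scheme provides.

## Feature table

The canonical table has **104 numeric columns**, ordered alphabetically
within groups: 20 amino-acid frequencies; 8 amino-acid category fractions
(tiny, small, aliphatic, aromatic, non-polar, charged, positively and
negatively charged); 6 simple sequence properties (hydrophobicity,
isoelectric point, low-complexity regions, PEST motifs, sequence length,
signal peptide); 6 post-translational modification counts (N/O-linked
glycosylation, phospho-S/T/Y and their total); 4 secondary-structure
features (β-strand, buried and exposed α-helix fractions, transmembrane
helices); 4 germline variant counts (3'/5' UTR, nonsynonymous,
synonymous); 3 inter-protein relationship counts (alternative
transcripts, binary PPIs, paralogues); and 53 expression features (7
developmental stages, 45 body sites, plus the derived number of body
sites with non-zero expression).

Sequence-derived features are computed in-package; tool-derived features
(PEST motifs from epestfind-style analysis, low-complexity regions from
SEG-style masking, secondary-structure fractions from NetSurfP-style
prediction) and database-derived features (variants, transcripts,
paralogues, expression) are consumed as annotation TSV inputs. Missing
annotation bundles are zero-imputed with a logged count.

Numerical conventions:

* **Ambiguity codes** B/J/Z add 0.5 to each of their two IUPAC residues
  (B→D/N, J→I/L, Z→E/Q); X counts toward sequence length only. This
  keeps frequencies well-defined (they sum to ≤ 1, with equality when no
  X is present).
* **Hydrophobicity** is the mean Kyte–Doolittle index; ambiguous codes
  contribute the mean of their two residues, X contributes 0.
* **Isoelectric point** solves the Henderson–Hasselbalch net charge for
  zero by bisection on pH ∈ [0, 14] to 1e-4. The pKa table is the EMBOSS
  pepstats set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
  K 10.8, R 12.5, Y 10.1), pinned in `constants.py`. Net charge is
  strictly decreasing in pH, so the root is unique and always bracketed;
  a sequence with no ionizable side chains reduces to the closed-form
  terminal midpoint (8.6 + 3.6)/2 = 6.1, which the tests use as an
  oracle.

## Weighted PU random forest (`purf`)

Trees are axis-aligned binary CARTs grown on uniform bootstrap samples of
size n (with replacement). At each node a fresh uniform subset of `mtry`
features is evaluated; the split minimises weighted Gini impurity, with
every positive observation carrying weight `positive_weight` and every
unlabelled observation weight 1. Split thresholds are midpoints between
consecutive distinct sorted values; ties in impurity break toward the
lowest feature index, then the smallest split value. Growth stops at
pure nodes or nodes of at most `min_node_size` observations (default 1,
i.e. fully grown — standard random-forest practice). Leaves store the
summed class weights of their training observations.

**Class weighting enters three places**: the split criterion, the leaf
vote (a tree votes for the class with the larger weighted leaf mass,
ties voting unlabelled), and the forest-level aggregation, where a
positive tree vote carries weight `positive_weight` and an unlabelled
vote weight 1. The *positive similarity* of an observation is the
positive fraction of the total weighted vote. Weighting the aggregation
is essential: fully grown trees have pure leaves, so without it the
positive weight could not move the decision boundary at all, and the
observed behaviour that larger weights raise sensitivity (and that grid
search selects weights > 1 on imbalanced data) would be impossible.
Bootstrap sampling stays uniform, so OOB coverage is independent of the
weight.

**OOB prediction.** An observation is predicted only by trees whose
bootstrap sample excluded it (expected fraction (1 − 1/n)ⁿ ≈ e⁻¹ of the
forest). This gives unbiased predictions for the training set itself,
which is why the same dataset can serve for parameter optimisation,
feature selection and final scoring. Observations OOB for zero trees
get an undefined similarity and are excluded from confusion counts
(negligible beyond a few hundred trees). Proteins *outside* the
training set (e.g. those removed by redundancy culling) are scored by
the full forest.

**Metrics.** Class calls use a 0.5 similarity cutoff, positive iff
strictly above. Performance is the G mean,
`sqrt(sensitivity × specificity)` — the geometric mean weights both
classes equally regardless of imbalance.

**Grid search.** For every (mtry, positive weight) combination the same
seed list grows `n_forests` forests; OOB confusion counts are summed over
forests and the pooled G mean computed. Sharing seeds across
combinations makes performance differences attributable to the
parameters alone and makes the whole grid bitwise reproducible. Ties
break toward the smaller weight, then the smaller mtry. Desk-scale
defaults (10 forests of 200 trees) keep a full grid in seconds–minutes
on one core; production-scale values (100 forests of 1000 trees) are
plain configuration.

## CHC-GA feature selection (`chcga`)

Feature subsets are bitstrings evolved by Eshelman's CHC algorithm:
random pairing; mating only when half the parents' Hamming distance
exceeds the incest threshold d (initialised to L/4); HUX crossover
exchanging exactly half the differing bits; cross-generational elitism
(best `population_size` of parents + children survive); d decremented
whenever no child survives; and on d < 0 a cataclysmic restart that
keeps the best individual and re-seeds the rest by flipping a
`divergence_rate` (default 0.35) fraction of its bits. Fitness is the
pooled OOB G mean of forests on the selected columns, using the
dataset's optimal weight and mtry (capped at the subset size); subsets
are memoised by (bitstring, RF seed). Each repetition (one per value in
the `numberTrees` sweep) draws its own RF seed from the master seed, and
the winner is reported as a (feature subset, seed, forest size) triple —
the exact context needed to retrain the final model. Fitness pooling
uses fewer forests than the grid search (default 1–10); this is a
deliberate speed/fidelity trade-off, acceptable because the GA only
ranks subsets.

## Sequence redundancy (`redundancy`)

Pairwise identity defaults to a deterministic global alignment
(match +1, mismatch 0, gap open −10, extend −0.5, via Biopython's
`PairwiseAligner`), with identity = 100 × matched columns / alignment
columns; ambiguity codes match only when equal. Any identity function or
a precomputed matrix can be supplied instead — local-alignment tools
give systematically different values for partially overlapping proteins,
which is the main divergence to be aware of when comparing against
BLAST-derived numbers.

The similarity graph at threshold t connects pairs with identity ≥ t;
edge sets are nested across thresholds. Culling removes the
highest-degree vertex (ties: lexicographically smallest accession) until
the graph is edgeless, then re-adds removed vertices without kept
neighbours in lexicographic order. The result is always a *maximal
independent set* — no kept pair is similar, every removed protein has a
kept representative — and on small graphs it is within two vertices of
the brute-force maximum independent set (both properties are tested by
enumeration). The re-add pass exists because pure max-degree removal can
orphan a vertex whose neighbours are all removed later.

The threshold sweep retrains a forest on each non-redundant subset and
reports its OOB G mean there plus the confusion counts over the entire
dataset (kept proteins by OOB votes, removed proteins by the full
forest) and the fraction of proteins remaining.

## Feature statistics (`stats`)

Each feature is compared between classes with a two-tailed Mann–Whitney
U test; U counts pairs where the positive value exceeds the unlabelled
one, ties scoring 0.5 (computed via midranks). For pooled sample sizes
≤ 20 the p-value is exact, by full enumeration of the label assignments
(valid under ties); above that, a normal approximation with tie and
continuity corrections is used — agreement with reference
implementations is within 1% relative in the tests. Significance is
Bonferroni-corrected at family level 0.05, with the family being the
features actually tested in that run: the raw expression levels (mostly
zeros) and the tiny/small fractions (near-identical distributions) are
reported but never tested; the derived expression-breadth count is
tested. Constant features report PS 0.5 and p 1.

The probability of superiority PS = U/(m·n) is the chance a random
positive protein exceeds a random unlabelled one; PS(pos, unl) +
PS(unl, pos) = 1 always. A length-normalised PS (feature divided by
sequence length) separates size effects from per-residue effects.

Dataset homogeneity is the percentage of protein pairs at ≥ 20%
identity, overall and split into positive–positive (denominator
m(m−1)/2), unlabelled–unlabelled (n(n−1)/2) and cross-class (m·n)
pairs, with an optional cross-tabulation by a partition column (e.g.
metallo vs non-metallo proteases).

## Synthetic data (`synthetic_data`)

The generators produce the structure the analysis assumes, nothing more:

* **Feature tables**: an informative feature is Normal(δ, 1) for true
  positives and Normal(0, 1) for unlabelled, with δ = √2·Φ⁻¹(PS) so that
  the population PS is exactly the target (PS = Φ(δ/√2) for
  unit-variance normals). Noise features are Normal(0, 1) in both
  classes. A `mislabel_fraction` of true positives is relabelled
  unlabelled, emulating hidden future targets; the generating truth is
  retained so tests can verify that forests trained on contaminated
  labels still score hidden positives above true negatives. Integer
  count features can be drawn as Poisson with the positive-class rate
  solved numerically to hit the target PS.
* **Sequence families**: a random root per family, members mutated
  i.i.d. per site (substitution uniform over the 20 standard residues),
  giving controlled within-family identity and near-baseline cross-family
  identity.
* **XML fixtures**: emit the supported dialect such that parsing
  round-trips every record field exactly.

What these do *not* emulate: correlated features, heavy-tailed count
distributions, phylogenetic structure within families, or the
keyword/annotation biases of real curated databases. Passing tests
therefore demonstrate the correctness and calibration of the machinery,
not classifier performance on a real proteome.

## Problem sizes and defaults

Test and example configurations are sized for a single core: forests of
tens to hundreds of trees on tables of a few hundred proteins, grid
searches pooling 2–10 forests, GA populations of 6–10 over ≤ 10
generations, and culling validation on graphs of ≤ 12 vertices (where
brute-force enumeration is exact). All randomness flows through
per-stage seeded generators, so every number in the artifacts is
reproducible from the recorded master seed. Production-scale settings
(1000-tree forests, 100-forest pools, forest-size sweeps to 5000) are
reachable purely through configuration.

## Known limitations

* Global-alignment identity is not interchangeable with BLAST local
  identity; homogeneity percentages computed from it will differ for
  multi-domain proteins.
* The culling heuristic guarantees maximal independence, not maximum
  independent sets; at extreme thresholds the kept set size may differ
  slightly from an exact solver's.
* Odorant/olfactory GPCR status has no algorithmic rule here; it is an
  input accession list (default empty).
* Observations never OOB are dropped from pooled confusion counts rather
  than imputed.
* The exact-p enumeration is O(C(m+n, m)) and intentionally capped at
  pooled size 20; beyond that the corrected normal approximation is
  used.
* Annotation-tool internals (PEST scoring, low-complexity masking,
  secondary-structure prediction) are out of scope; their outputs are
  trusted inputs.
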