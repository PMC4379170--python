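# targetprops

Analysis toolkit for characterising **protein drug-target classes**: which
properties separate the targets of approved drugs from the rest of a
proteome, and which currently untargeted proteins look most like targets.

Only a small fraction of human proteins are targets of approved drugs, and
the non-target class is really *unlabelled* — it mixes proteins that will
never be druggable with future targets that simply have not been exploited
yet. `targetprops` treats the problem as positive–unlabelled (PU)
classification over per-protein feature tables (amino-acid composition,
hydrophobicity, isoelectric point, post-translational modifications,
secondary structure, germline variants, interactions, expression breadth)
and provides:

* **ingest** — parsing of a documented UniProt-XML subset into protein
  records; protein-family assignment from keywords and supplemental
  accession lists; construction of labelled category datasets
  (whole proteome, cancer, GPCR, ion channel, kinase, protease, and
  derived subsets such as non-odorant GPCRs or tyrosine-kinase positives).
* **features** — sequence-derived features and assembly of the canonical
  104-column feature table.
* **redundancy** — pairwise global-alignment sequence identity, similarity
  graphs, deterministic culling to maximal independent (non-redundant)
  sets, and the identity-threshold sweep experiment.
* **purf** — the core classifier: a weighted positive–unlabelled random
  forest with out-of-bag (OOB) prediction. Trees grow on uniform
  bootstrap samples; positives carry a configurable weight in the split
  criterion and in the vote aggregation. Each protein's **positive
  similarity** — the positive fraction of the forest's weighted vote —
  is its drug-target-likeness score, thresholded at 0.5 for a class
  call. Performance is the **G mean**, `sqrt(sensitivity × specificity)`,
  and a seed-shared grid search optimises `mtry` × positive weight.
* **chcga** — CHC genetic-algorithm feature selection (HUX crossover,
  incest prevention, cataclysmic restarts) maximising pooled OOB G mean.
* **stats** — per-feature two-tailed Mann–Whitney U tests with Bonferroni
  correction and the probability of superiority `PS = U/(m·n)` (the
  chance a random positive exceeds a random unlabelled protein), plus
  dataset-homogeneity reports from pairwise identity.
* **synthetic_data** — seeded generators for feature tables with
  PS-calibrated effect sizes, PU label contamination, sequence families
  with controlled identity, and XML fixtures that round-trip through the
  parser.

## Worked example

Simulate a contaminated PU dataset (100 positives, 400 unlabelled, three
informative features with PS 0.8/0.75/0.7, 10% of positives hidden in the
unlabelled class), optimise the forest, predict, and analyse features:

```bash
targetprops simulate --seed 5 --n-pos 100 --n-unl 400 \
    --ps 0.8 --ps 0.75 --ps 0.7 --n-noise 10 --mislabel 0.1 --out sim
targetprops optimize --table sim/table.tsv --mtry-grid 3,6 \
    --weight-grid 1,2,5 --n-forests 3 --trees 100 --seed 5 --out opt
targetprops predict --table sim/table.tsv --trees 200 --mtry 6 \
    --weight 5 --seed 5 --out pred
targetprops analyze --table sim/table.tsv --out stats
```

prints

```
wrote sim/table.tsv (100 positive / 400 unlabelled)
best: mtry=6 weight=5.0 G mean=0.719
G mean 0.738 (TP=70 FN=20 TN=287 FP=123)
wrote stats/feature_stats.tsv
```

The grid search picks a positive weight of 5 — with 1:4 imbalance and
label contamination, upweighting positives trades specificity for
sensitivity and maximises the pooled OOB G mean. The final forest calls
70 of the 90 nominal positives correctly (OOB, so the predictions are
unbiased for the training proteins); many of the 123 "false" positives
are by construction hidden true positives, which is exactly how candidate
future targets are ranked. The feature report recovers the planted
effects:

```
Feature         P-value     PS     Significant  Tested
informative_0   4.4e-12     0.73   True         True
informative_1   2.7e-08     0.69   True         True
informative_2   4.2e-12     0.73   True         True
noise_0         3.0e-01     0.47   False        True
```

The same subcommands run on real data: `ingest` + `features` build the
table from a UniProt-style XML export and annotation TSVs, `cull` /
`sweep` handle sequence redundancy from FASTA, and `select-features`
runs the CHC-GA.

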