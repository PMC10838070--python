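# barcodecv

Cross-validation of DNA-barcode reference databases for BLAST-style
taxonomic assignment.

## The problem

Metabarcoding studies (e.g. identifying pollen collected by bees from
ITS2 or *rbcL* amplicons) assign taxa to reads by searching a reference
database of identified barcode sequences and interpreting the top
alignment hits. Every pipeline hides consequential choices: best-hit vs
majority-vote assignment, full-length vs primer-restricted references,
a database limited to the local flora vs all available sequences, and
the identity/consensus thresholds below which an assignment should not
be trusted. `barcodecv` turns the reference database itself into the
test bench: it blasts a sample of the database's own sequences against
the remainder (*10-fold CV*) or against the full database (*leaked
CV*), compares predicted with known taxonomies, and calibrates discard
rules from the results. It is aimed at bioinformaticians who curate
reference databases and want accuracy estimates and threshold rules
*before* touching real samples.

## The method

From each query's top 10 hits (ranked by bit score), two statistics are
computed at each rank (family, genus, species):

- **identity score** — the percent identity (`pident`) of the
  maximum-bit-score hit matching the assigned taxon. This is not
  necessarily the maximum identity: 98% identity over a 400 bp
  alignment outranks 100% over 50 bp, because the bit score rewards
  alignment length.
- **consensus score** — the percentage of the considered hits matching
  the taxon. Ten hits mapping to 2× *Brassica napus*, 6× *Brassica
  nigra*, 2× *Sinapis alba* give a species consensus of 60% for
  *B. nigra*, 80% for the genus *Brassica*, 100% for the family
  Brassicaceae.

Four assignment methods are implemented: **TopHit** (best bit score),
**TopHitPlus** (best bit score, ties broken by consensus), **TopN**
(highest consensus per rank, independently), and **TopNPlus** (TopN
after discarding hits that fail per-rank thresholds on alignment
length, E-value, identity floor and identity distance to the best hit).

Predictions are scored by accuracy (unassigned counts as incorrect),
per-class precision P = TP/(TP+FP), recall R = TP/(TP+FN) and
F = 2PR/(P+R), plus their micro averages. Correctness is then modelled
against the two scores with a binomial GLM (logit link, interaction
term) and a Gini classification tree pruned by the one-standard-error
rule, from which declarative discard-rule cascades (Local DB first,
World DB as fallback) are built and applied.

A self-contained Smith–Waterman search backend and a synthetic database
generator (families → genera → species with controlled divergences)
make every experiment runnable at desk scale; hit tables from real
`blastn -outfmt "6 qseqid sseqid pident length evalue bitscore"` runs
can be imported instead.

## Worked example

```sh
barcodecv simulate --preset well-separated --outdir db
barcodecv cv db/reference.fasta db/taxonomy.tsv \
    --local-species db/local_species.txt --cv-mode kfold --seed 1 -o cv.tsv
barcodecv evaluate cv.tsv --rank species --method TopHitPlus
barcodecv evaluate cv.tsv --rank species --method TopN
```

prints

```
wrote 54 records (11 local species) to db
wrote 140 result rows to cv.tsv
TopHitPlus @ species: n=35 correct=35 wrong=0 no-ID=0 accuracy=100.0% microP=100.0% microR=100.0%
TopN @ species: n=35 correct=0 wrong=35 no-ID=0 accuracy=0.0% microP=0.0% microR=0.0%
```

The preset database has 18 species × 3 near-identical records, so
removing a fold still leaves each query a same-species twin:
best-bit-score assignment (TopHitPlus) is perfect. Majority vote
(TopN) fails completely on the same data — with the query's own record
removed, only 2 of the top 10 hits are conspecific while 3 hits each
come from the two congeneric species, so the wrong species wins the
vote. The same contrast (best-hit methods beating consensus methods at
species rank) is the central qualitative finding this framework is
designed to expose.

The same library surface is available from Python (`simulate_database`,
`run_cv`, `evaluate`, `fit_threshold_tree`, `apply_rules`, ...); see
`docs/methods.md` for the model details and parameter choices.

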