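# Methods

This note documents the models, conventions and numerical choices
behind `barcodecv`, in the spirit of a package vignette. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Scores and assignment methods

All methods consume, per query, the top `max_hits` (default 10) hits
ordered by (bit score descending, backend output order ascending).
Backend output order (`input_rank`) is the documented tie-break for
exactly equal bit scores; BLAST does not specify one, and a total
order is required for reproducibility.

The **consensus score** of a taxon at a rank is
`100 × (hits matching the taxon) / (hits considered)`. The denominator
is the number of hits actually considered — all retained hits for
TopHit/TopHitPlus/TopN, the post-filter survivors for TopNPlus — not a
fixed 10. With fewer than 10 hits a fixed denominator would cap the
consensus of a unanimous hit list below 100%, which is not meaningful.
Hits whose lineage is `unknown` at the rank stay in the denominator but
form no candidate taxon: an `unknown` label is not a taxon and can
never win a rank.

The **identity score** attributed to an assigned taxon is the `pident`
of the maximum-bit-score hit matching that taxon (ties by
`input_rank`). Every attributed identity is therefore the `pident` of
a real hit, never an aggregate.

Method-specific conventions, all deterministic:

- **TopHit** — single max-bit-score hit; its lineage is used at every
  rank. Empty hit lists leave every rank unassigned.
- **TopHitPlus** — among the hits tied at the maximum bit score, the
  taxon with the highest consensus (computed over all considered hits)
  wins; residual ties go to the alphabetically smallest taxon. When the
  best bit score is unique this reduces exactly to TopHit
  (property-tested).
- **TopN** — per rank independently, the consensus argmax; ties broken
  by higher attributed identity, then alphabetically. Cross-rank
  consistency is deliberately not enforced; the winning species can
  belong to a different genus than the winning genus.
- **TopNPlus** — per rank, hits are filtered by: alignment length
  ≥ 100 bp; E-value ≤ 1e-10; identity ≥ {97, 90, 80}% at
  species/genus/family; and identity strictly within {1, 10, 20}
  points of the best hit's identity. The "best hit" anchoring the
  window is the max-bit-score hit of the *original* top-10 list, before
  any filtering — the conventional reading of "the best hit"; an
  alternative (per-rank post-filter best) can be obtained by adjusting
  `TopNPlusParams`. Floors use ≥ and windows use strict <, matching
  the stated thresholds exactly. No survivors at a rank means no
  assignment at that rank. With fully permissive thresholds TopNPlus
  reduces exactly to TopN (property-tested).

## Search backend

The built-in backend aligns every query against every reference
sequence with Biopython's `PairwiseAligner` in local mode: match +2,
mismatch −3, gap open −5 (charged on the first gap position), gap
extension −2. Raw scores convert to bits via `(λS − ln K)/ln 2` with
fixed λ = 0.625, K = 0.41, and `E = m·n·2^(−bits)` with m the query
length and n the total reference length. These constants are
documented, not calibrated against NCBI blastn: the downstream logic
depends only on hit ranking, tie structure and `pident`, all of which
behave blast-like. Hits with E > 10 are dropped. Real blastn tabular
output (`-outfmt "6 qseqid sseqid pident length evalue bitscore"
-max_target_seqs 10`) can be imported instead; any producer of the six
canonical columns is an acceptable backend.

## Cross-validation designs

- **leaked** — queries are searched against the full database,
  measuring exact-match retrieval among near neighbours.
- **kfold** (default k = 10) — targets are permuted (seeded) and split
  into k folds differing in size by at most one; each fold's records
  are removed from the reference before searching.
- **restricted-general** — primer-restricted queries against the
  full-length database; every full-length record sharing a
  `source_accession` with a fold member is removed first.

Target selection keeps all local-species records plus a seeded uniform
sample of `round(f × n_foreign)` foreign records (default f = 0.10),
then drops hybrid and imprecise species names. The foreign sample is
drawn over records, not species, and is counted before the name
exclusions. Folds are drawn over the filtered target set, without
taxon stratification (a stratified option would change the estimand;
the plain split is the baseline design). A Local-DB scope drops
foreign records from the reference before fold construction; leaked CV
against a Local DB with foreign queries degenerates to k-fold-like
behaviour for those queries and triggers a warning rather than an
error.

Correctness is exact, case-sensitive string equality between predicted
and true taxon after whitespace normalisation; synonym resolution is
out of scope. Unassigned predictions count as incorrect in accuracy.

## Amplicon restriction

Primer sites are located by exhaustive sliding-window search with
IUPAC degeneracy honoured on the primer side only; the best site has
the fewest mismatches, with ties broken leftmost for the forward
primer and rightmost for the reverse (given 5'→3' on the reverse
strand and reverse-complemented before matching). Sites must have at
most `max_mismatch` mismatches (default 0). The extracted product
excludes the primers by default — restricted reference databases
typically store inserts — with an `include_primers` flag for the
inclusive dialect. A sequence lacking either site yields no restricted
record, mirroring the sequence loss real restriction pipelines see.

## Correctness models and discard rules

The **GLM** is a binomial logit fit of correct/incorrect on identity,
consensus and their interaction, by IRLS (tolerance 1e-8 on deviance,
100 iterations max). Constant predictors raise; an all-one-class
response or non-convergence sets a separation flag while still
returning the fitter's coefficients. Monotonicity of the fitted
probability in each score (other score at its median) is checked and
reported, not enforced. Unassigned rows carry no scores and are
excluded from training.

The **classification tree** is grown by scikit-learn's Gini CART
(defaults: max depth 6, min split 40, min leaf 20), then pruned by the
one-standard-error rule: the cost-complexity path supplies candidate
α values, a seeded stratified k-fold (default 10) yields per-α
per-observation 0/1 losses, the SE of an α's error is the standard
error of those losses, and the chosen subtree is the smallest (largest
α) with CV error ≤ min error + 1 SE — ties therefore resolve toward
fewer leaves. The hyperparameters are package defaults, configurable
through `TreeParams`.

**Discard rules** are boolean expressions over `identity` and
`consensus` (comparators, `and`/`or`/`not`, parentheses), organised as
ordered cascades of (db scope, rule) stages: a query keeps the first
stage's assignment its rule does not discard; a discarded query falls
through to the next stage; failing all stages leaves it unassigned. A
query that is *already unassigned* at a stage passes through as
unassigned rather than falling to the next stage — it has no
assignment to discard, and letting it pick up a later-stage assignment
would let a "filter" create identifications. The shipped rule sets
encode calibrated ITS2/rbcL thresholds at genus (World DB only) and
species (Local-then-World) level. The rbcL species local rule is
encoded verbatim with its vacuous `identity <= 100` clause, making it
equivalent to `identity < 99.7 or consensus < 50`; the
strict-inequality reading ships as `rbcl-species-strict`. The genus
rules read the conjunction literally (`consensus < 40 AND identity <
threshold`); `*-genus-or` variants provide the disjunctive reading.

Single-stage rule sets can only discard, so they never increase wrong
counts nor decrease unassigned counts — a theorem, property-tested.
For two-stage cascades this is not a theorem (a discarded-but-correct
local assignment could in principle be replaced by a kept-but-wrong
world one); it is verified empirically on the synthetic fixtures.

## Synthetic databases

`simulate_database` evolves a random root sequence down a star tree:
family, genus, species consensus sequences and per-record copies are
each derived by i.i.d. per-site substitution at configurable rates
(`d_family=0.20, d_genus=0.10, d_species=0.05, d_within=0.005` by
default), each substituted site moving to one of the three other bases
uniformly (Jukes–Cantor-like, no indels by default). Two sequences
whose connecting path carries divergences d₁, d₂ then differ per site
with probability d₁ + d₂ − (4/3)d₁d₂, which the tests check against a
binomial oracle. Default shape: 3 families × 2 genera × 3 species ×
3 records of 300 bp (54 records) — large enough to give every genus
congeners and every species twins, small enough that a full four-method
leaked-plus-10-fold comparison runs in seconds. Species are flagged
local by a seeded draw (default 50–60% depending on preset);
configurable fractions of species receive hybrid ("×") or open
nomenclature ("sp.") name forms to exercise target filtering.

What the generator does *not* emulate: rate heterogeneity, indel-rich
regions, primer-site polymorphism, database mislabelling, and the
skewed taxon abundances of real NCBI-derived databases. Passing tests
therefore demonstrate the correctness of the machinery and the
direction of the design contrasts (leaked ≥ k-fold, singleton species
unassignable at species rank, Local DB useless for foreign species,
best-hit beating consensus voting when conspecific records are
scarce), not the absolute error rates of any real barcode database.

## Known limitations

- Bit scores from the built-in backend are not calibrated to NCBI
  blastn; imported real hit tables should be used for absolute E-value
  semantics.
- Name comparison is string equality; synonyms and orthographic
  variants count as errors.
- The "doubtful name" filters are token heuristics
  (`sp./spp./cf./aff.`, "×"/" x "/"hybrid"), exposed as configurable
  token sets.
- Restriction is applied to the cleaned input database; pipelines that
  clip before cleaning can produce restricted databases that are not a
  subset of the general one.
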