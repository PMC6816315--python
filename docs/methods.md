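# Methods

This note documents the models, null hypotheses, parameter choices and
known limitations behind `phenopleio`. It is the package's own account
of its science; every number quoted here is computed by the test suite
or by `scripts/acceptance.py`.

## Ontology model

A phenotype ontology is a rooted DAG over `is_a` edges. Only `is_a` is
traversed: the HPO phenotype subontology is structured by `is_a`, and
top-level categories are conventionally defined as the direct children
of the phenotypic-abnormality root. Other relationship types
(`part_of`, …) are ignored. A term reachable through several categories
counts once in *each* of them (multi-assignment); nothing in standard
category-level aggregation demands exclusivity, and forcing a single
category would require an arbitrary tie-break.

Obsolete terms with a `replaced_by` target are silently remapped (the
alias map also resolves annotation files that still use superseded
accessions); obsolete terms without a replacement are dropped with a
logged warning. Terms that do not reach the designated root — other
subontologies in a full HPO-like file, such as inheritance or clinical
modifiers — are dropped with a warning rather than treated as errors,
matching how phenotype-only analyses consume HPO. Structural defects
that would corrupt the analysis (an `is_a` cycle, a dangling `is_a`
target, an ambiguous auto-detected root) are hard errors.

Real HPO exports carry ~29 top-level categories of very uneven size,
and analyses typically restrict to the 10–11 largest. The selection
rule here is explicit and configurable: categories are ranked by their
total annotation occurrences in the loaded corpus (each occurrence of a
term counts toward every category it maps to) and the top *k* are kept;
`k = None` (default) keeps every category that occurs.

## Similarity model

For annotation sets A, B the Jaccard/Tanimoto coefficient is
`T = |A∩B| / (|A| + |B| − |A∩B|)`. Similarity of two empty sets is
undefined and raised as an error; a disease pair with an empty side is
flagged *excluded* and reported rather than silently dropped, since
exclusion is an analysis decision, not a data fact.

**Exact significance.** The null model fixes both set sizes and the
universe: A and B are independent uniform random subsets of sizes
`na`, `nb` from `N` elements, making `K = |A∩B|` central
hypergeometric; the one-sided p-value is `P(K ≥ nc)` (similarity at
least as large as observed; `nc = 0` gives p = 1 exactly). This is the
simplest exact null in the family of published Jaccard tests; bootstrap
and asymptotic variants exist, but only the exact variant is
implemented, and the test suite verifies it against brute-force subset
enumeration to 12 significant digits for all feasible configurations
with N ≤ 10.

**The universe N** is the sampling frame actually observable from the
corpus: the number of distinct terms annotated to ≥ 1 disease for
term-level tests, the number of selected categories for category-level
tests, and the number of corpus genes for the category-vs-category
gene-set comparisons. Using the full ontology instead would anticonservatively
inflate significance, since unannotated terms are never sampled.

**FDR.** Benjamini–Hochberg step-up adjustment,
`q_(i) = min_{j≥i} m·p_(j)/j` clipped at 1, applied separately per
cohort × level family (mirroring separately reported panels). Ranking
ties are broken by stable input order, which provably does not change
the adjusted values; agreement with the statsmodels implementation is
asserted on 1,000 random p-vectors.

**Rank-sum contrasts.** Distribution contrasts between cohorts use
Mann–Whitney U (scipy backend): exact by enumeration when
`n1 + n2 ≤ 12` and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections. An independent
labeling-enumeration oracle checks the exact branch, and the
approximation is verified to sit within 0.02 of exact p for tie-free
6-vs-6 samples. Contrasts are emitted both per vocabulary (OMIM-based,
ORPHANET-based vs crosswalk) and pooled across the two gene-based
cohorts, since either convention is defensible.

## Disease pairs

Gene-based pairs: every gene with ≥ 2 diseases in a vocabulary
contributes all unordered pairs; pairs are *unique* — a pair shared by
several genes appears once, with the genes recorded in `shared_genes`.
Crosswalk pairs: one (OMIM, ORPHANET) pair per crosswalk row carrying
both identifiers; one-to-many granularity is allowed (each row is an
independent matched pair). Disease identity is always
vocabulary-qualified; cross-vocabulary identity exists only through the
crosswalk table (plus a manual-override file whose rows win over
automatic rows), never through name matching, which is irreproducible.

## Association metrics

Score strata: S1 ≥ 0.3, S2 ∈ [0.1, 0.3), S3 < 0.1. The conventional
two-decimal rendering of the middle band ("0.1–0.29") leaves
(0.29, 0.3) unassigned for continuous scores; the half-open closure
makes the partition exhaustive and is unobservable on two-decimal data.

DSI follows the published DisGeNET definition
`log(d_g/d_T) / log(1/d_T)` (1 = gene tied to a single disease, 0 =
tied to all); DPI is the fraction of disease classes spanned by the
gene's diseases. The class system is whatever classification column the
corpus supplies; the default denominator of 29 matches the MeSH
disease-class count DisGeNET uses. A gene whose diseases carry no class
labels gets a missing DPI, recorded as such.

The packaged table `data/multigene_disease_associations.tsv` is a
curated reference of inborn-error-of-immunity diseases with two or more
high-score gene associations, including PPI cluster memberships and
per-disease PPI enrichment p-values (values below the reporting floor
are stored as the printed `<1.0E-16` string and parsed at the floor).
Applying the score ≥ 0.3 / ≥ 2-gene filter to it yields 25 diseases,
with 15 genes on the Omenn-syndrome row — a fixed-point check that the
reporting logic reproduces the curation it came from.

## PPI and enrichment

Edges count when `combined_score > cutoff` (strictly; default 0.4, the
STRING convention). Clusters are connected components of the induced
subgraph, ordered by size then lexicographically; query genes absent
from the graph become singletons with a warning.

The PPI enrichment null is a **label permutation at fixed set size**:
the query is redrawn uniformly over graph nodes `n_perm` times and the
within-set above-cutoff edge count compared with the observed one;
`p = (1 + #{null ≥ obs}) / (1 + n_perm)`, so the smallest attainable
value is `1/(1+n_perm)` and p is bit-reproducible for a fixed seed.
This deliberately is *not* STRING's degree-corrected null: the
permutation null is self-contained and exactly testable, at the cost of
ignoring degree structure — a documented deviation, not an emulation.

Gene-set enrichment is the one-sided hypergeometric overrepresentation
test (the Fisher-style test behind Enrichr-like tools), BH-adjusted
across the library with a 5 % flagging threshold. The background
defaults to the union of library genes and the query (an explicit
background overrides it and is logged); odds-ratio or combined-score
rankings are out of scope. Phenotype–trait overlap is a pure join:
(gene, term, trait) rows where the gene carries both sides of a
term↔trait crosswalk row; the matching criteria live entirely in the
crosswalk file, so the operation is monotone in it.

## Synthetic generator

The generator emulates the *joint structure* of an
OMIM/ORPHANET/HPO/DisGeNET/STRING/GMT stack, not its content. Per gene,
a reference disease fixes a category set and term set; further diseases
of the same gene keep each category with probability `rho_cat`
(resampling otherwise) and reuse each reference term within kept
categories with probability `rho_term`. Fresh terms are always drawn
*outside* the reference set, so term reuse is governed by `rho_term`
alone and the expected term-level (category-level) T of same-gene pairs
is monotone in `rho_term` (`rho_cat`) — verified by simulation across
seeds. A fraction of diseases is duplicated into a second vocabulary
with small annotation jitter (the matched crosswalk pairs), and a
fraction of gene–disease links is left off the expert list entirely so
the expert/other partition of the descriptive summaries is non-trivial.

Default study conditions: 10 categories × 12 terms, 50 genes with 1–4
diseases each, 4–8 terms per disease over 3 categories,
`rho_cat = 0.9`, `rho_term = 0.1` — a strongly modular regime in which
the similarity study must find a category-vs-term median gap above 0.3
and a clear term-level contrast between gene-based and matched pairs.
Association scores come from a 20/30/50 mixture over the three strata
(chosen so every stratum is populated; not a claim about DisGeNET);
the PPI graph is Erdős–Rényi (100 nodes, edge probability 0.05) with a
planted 5-clique at score 0.95; the library holds 20 random 15-gene
sets plus one with 8 genes planted from a 10-gene query. A single seed
drives one named pseudorandom stream per artifact, so outputs are
byte-identical per seed and regenerating one artifact does not perturb
the others.

What the generator does **not** emulate: realistic disease nosology,
annotation-depth biases, term co-occurrence structure inside a
category, degree-correlated PPI topology, or database-version effects.
Passing tests therefore demonstrate that the machinery recovers planted
structure of the assumed form at these problem sizes — not that any
particular real-data estimate is correct.

## Numerical and degenerate-input choices

* Frequency bands are made total on [0, 100] by right-open closure
  (100 obligate; [80, 100) very frequent; [30, 80) frequent; [5, 30)
  occasional; (0, 5) very rare; 0 excluded); all integer edges map to
  the conventional ORPHANET classes, verified exhaustively.
* `p = 1` is returned exactly (not via the survival function) for a
  zero observed overlap.
* Empty p-vector → empty q-vector; p outside [0, 1] is an error.
* Pair families with < 2 pairs skip their contrast with a recorded
  warning; empty cohorts are reported, not errors.
* Duplicate annotation rows are deduplicated with a warning (loading is
  idempotent); unknown identifiers are collected and reported together
  as a hard error.
* The permutation p uses the add-one estimator, which can never return
  0.

## Problem sizes

The shipped tests and the acceptance script run the full study on the
default 50-gene corpus (~180 diseases, ~160 gene-based + ~50 crosswalk
pairs), 20 annotation permutations for null calibration, 999 PPI
permutations, and exhaustive enumeration oracles up to universes of
10–12 elements. These sizes give stable planted-structure recovery
(contrast p-values far below any threshold) while the whole pipeline
completes in seconds.

## Known limitations

* The exact similarity test conditions on both set sizes; if real
  annotation sizes are themselves informative, the null is conditional,
  not marginal.
* Term-level similarity ignores ontology depth: no information-content
  (Resnik/Lin) weighting, by design — the set-overlap coefficient is
  the object of study.
* The PPI permutation null ignores node degree; hub-heavy query sets
  will look more enriched than under a degree-corrected null.
* The crosswalk is taken as ground truth; curation errors propagate
  directly into the matched-pair cohort.
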