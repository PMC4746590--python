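# Methods

## The specificity score

The score condenses a gene's mutation-significance profile across a
pan-cancer cohort into a single scalar:

    S = log10((mostQ + ε) / (panQ + ε)) + k

with `mostQ` the smallest per-tumor-type q value, `panQ` the pooled
pan-cancer q value, and `k` the count of tumor types with q < τ.  The
log-ratio captures the intuition that a specific gene is strongly
significant in one type but unremarkable pan-cancer (ratio « 1, term
very negative), while a general gene is driven by the pooled cohort
(ratio » 1); adding `k` separates genes further by breadth.  S is
strictly increasing in `mostQ` and `k` and strictly decreasing in
`panQ` — the property-test suite enforces exactly this monotonicity
contract, which pins the score's qualitative behavior independent of its
precise functional form.

Parameters:

- **τ = 0.1** (significance threshold defining `k`, unitless q-value
  cutoff).  The threshold is a convention of mutation-significance
  analyses rather than a derived quantity, so it is surfaced as a flag
  everywhere (`--tau`).
- **ε = 1e-16** (pseudocount).  Published significance tables round the
  strongest hits to q = 0; ε keeps the ratio finite while leaving any
  q ≥ 1e-12 essentially untouched.  Genes with q = 0 in both columns get
  ratio term 0, which is the right degenerate answer.
- Tie-break for ranks: ascending S, then *descending* panQ (the more
  pan-significant gene is the more general one and ranks later), then
  gene id.  Purely for cross-platform determinism; scores are continuous
  and ties essentially only arise from saturated q = 0 entries.

The study-bias filter (drop genes with more than 500 publications,
`max_studies`) exists because annotation-dependent analyses (GO
enrichment, semantic similarity) otherwise partly measure research
attention; the threshold is the one used in the source analyses and is
configurable.

## Median-statistic permutation GSEA

A gene set's statistic is the median specificity score of its scored
members.  The null reassigns the full score vector to genes uniformly at
random, which for a set of m scored members is equivalent to drawing a
uniform m-subset of the scores.  Two one-sided p values are reported:
`p_specific` = P(permuted median ≤ observed), `p_general` =
P(permuted median ≥ observed).  Direction note: because small scores
mean specific, the "specific" tail is the lower one; descriptions of
this procedure that assign the "larger" fraction to the specific p value
presuppose the opposite score orientation, and this implementation
follows the score convention used throughout (small = specific).

Numerical choices:

- Monte-Carlo p values use the permutation-inclusive add-one form
  (count+1)/(N+1), the standard way to avoid reporting p = 0 and keep
  the null distribution of p stochastically ≥ uniform (conservative).
  Exhaustive mode (all C(n, m) subsets, used when C(n, m) ≤ 1e5)
  reports exact fractions without the correction.
- Ties between a permuted and the observed median count toward *both*
  tails — conservative for both p values.
- Default N = 1000 permutations; the acceptance benchmark verifies
  null uniformity (KS distance < 0.1, type-I error at 5% inside its
  binomial interval at 1000 null sets).
- Per-set generator streams are derived from (global seed,
  SHA-256(set name)), so results per set are independent of which other
  sets are in the collection.
- Set-size filter: strictly more than `min_size` = 8 scored members.
- BH correction runs separately within the specific and the general
  side, across the sets that survive the size filter.  Pooling both
  sides instead would roughly double each q; neither choice affects the
  ranking within a side.

## GO semantic similarity

Term information content uses annotation frequencies under the
true-path rule: p(t) = (genes annotated to t or a descendant) /
(annotated genes), IC = −log2 p.  The root has IC 0, and IC is
monotone non-decreasing from parent to child.  Term similarity is Lin's
normalization of the Resnik most-informative-common-ancestor score,
2·IC(MICA)/(IC(t1)+IC(t2)) ∈ [0, 1]; the log base cancels.  Terms from
different namespaces share no ancestor and contribute 0.

Gene-level similarity is the *all-pairs mean* over the two genes'
**direct** annotations.  Propagated annotations are used only for the
frequencies: averaging over propagated sets would let the shared
high-frequency ancestors dominate and push every pair toward the same
value.  All-pairs mean (rather than best-match average) is the literal
"mean similarity of all term pairs" aggregation; it is harsher on
multifunctional genes, which is acceptable because the analysis object
is a *contrast between groups*, not absolute similarities.  The extreme
contrast takes the `n_top` (default 30) most specific and most general
scored, annotated genes and compares the two within-group pairwise
similarity distributions with a two-sided rank-sum test.

## Rank-sum comparisons

All two-group score/breadth/similarity contrasts use the two-sided
Wilcoxon–Mann–Whitney test: the classical exact distribution when the
smaller group has ≤ 8 members and there are no ties, full enumeration
of group assignments when ties are present but C(n, n_a) ≤ 1e5 (exact
and tie-valid), and the normal approximation with tie correction
otherwise.  Two groups of identical constant values short-circuit to
p = 1.  Hallmark-class contrasts allow a gene annotated to two classes
(e.g. tumor suppressor + DNA repair) to appear in both samples, logged.

## DNA-repair pathways and tissues

Pathway classes come from propagated annotation to the three GO
classes (NER GO:0006289, MM GO:0006298, DSBR GO:0006302); only genes
hitting exactly one class enter the tissue counts ("multiple" genes are
excluded), and a gene contributes one count per associated tissue, with
no fractional weighting.  The per-cell association test is Fisher exact
(point-probability two-sided) on [pathway & tissue, pathway & other
tissues; other pathways & tissue, other pathways & other tissues].  The
2×2 construction — one pathway against the other two, one tissue against
the rest — is pinned here because "Fisher test" alone does not determine
it.  No multiple-testing correction is applied across the tissue ×
pathway grid by default (associations are reported at nominal p),
matching how such grids are usually read; a BH option exists.

The germline fold enrichment is a plain ratio of proportions,
(pathway∩germline / germline) / (pathway / total), with germline-only
counts in the numerator; genes mutated both ways sit only in the
totals.  The breadth comparison (germline vs somatic tissue counts)
excludes "both"-origin genes so differing curation strategies between
sources cannot masquerade as a breadth difference.  The tissue PCA is
column-centered SVD with component signs fixed so each loading vector's
largest-magnitude entry is positive.

## Chemical and virus enrichment

Chemical test, per (cancer type, chemical): 2×2 of interacting vs not
among the type's specific genes against the remaining specific genes,
Pearson χ² (df 1, no continuity correction), falling back to Fisher
exact — flagged in the output — whenever an expected count drops below
5 (routine at 8–20-gene sets).  The background universe is the union of
all investigated types' specific genes, matching the "chemicals that
interact with at least one specific-cancer gene of any investigated
type" framing; BH runs across all (type, chemical) pairs tested rather
than within type (the less favorable, hence conservative, choice).
"Reportable" = q < 0.01 *and* coverage ≥ 20% of the type's specific
genes; sub-threshold rows stay in the output file.

The air-pollutant contrast is Fisher exact of the reportable chemicals
against the rest of the background chemical universe on the pollutant
flag.  Virus analyses count distinct *strains* per gene for the tropism
breadth comparison (strains, not species, are the unit of host-range),
but group strains into *species* for tissue profiles; a profile entry is
the fraction of a species' cancer-gene interactors carrying that tissue
group, so rows need not sum to 1 (multi-tissue genes count everywhere
they belong).

Bias-control filters (drop single-evidence edges, drop approved cancer
drugs, keep only edges from studies reporting ≥ 30 chemical–gene or
≥ 500 virus–host interactions) are pure row filters and commute; the
package applies them before any test.

## The synthetic benchmark

The generators produce every input the pipeline reads, with planted
ground truth, from one seed (independent per-generator substreams, so
adding a generator never perturbs another's output).  Defaults encode
the study conditions: 224 genes × 21 tumor types; 58% of genes
significant in exactly one type (reproducing the ~130 single-solid-type
genes of the scored cohort), dealt across seven solid and four
hematological types; 20% general genes (k ≥ 8, pan-cancer
q ~ log-uniform 1e-12..1e-8); 37 genes studied > 500 times; 38 repair
genes of which 11 multi-annotated (27 uniquely assigned); planted
chemicals at coverage 0.5 of their target type against a 3% background
interaction rate with 3% background pollutant flags; planted virus
species drawing 85% of their host partners from a preferred tissue
group's gene pool (a strongly tropic virus — the regime in which a
tissue preference is the profile row maximum); expression over 60
tissues with exactly 1 direct and 3 adjacent planted
expression/pathology matches and all other specific genes' expression
argmax forced away from their cancer tissue.

What the generator does *not* emulate: correlated q values across
related tumor types, realistic GO DAG topology (it plants a tree plus
the three repair classes), literature-bias structure beyond a flat
high-study subset, dose/evidence semantics of curated chemical
interactions, or abundance distributions of real proteomics.  Passing
the planted-recovery benchmarks therefore demonstrates that the
*inference machinery* detects paper-scale signals under the stated
noise — not that real curated data would yield the same effect sizes.

## Pipeline and determinism

Stages communicate only via TSV files; a run writes a manifest with
input SHA-256 hashes, all parameters and the seed, sufficient to re-run
identically.  Identical seeds give bitwise-identical stage outputs
(floats are written at 10 significant digits through one writer).  The
acceptance script re-derives all headline quantities at run time:
worked examples at their printed precision, null calibration at 1000
sets × 1000 permutations, and 100-seed planted-recovery rates (the
100-seed loops and the 80-gene semantic-similarity cohorts keep the
whole script within a few tens of seconds on one CPU).

## Known limitations

- The score's functional form is a documented surrogate pinned by its
  monotonicity contract; any replacement respecting that contract slots
  in without interface changes but would shift absolute S values.
- Exhaustive GSEA mode is capped at C(n, m) ≤ 1e5 subsets; larger sets
  always use Monte-Carlo p values with resolution 1/(N+1).
- Gene identifiers are opaque case-sensitive strings; no symbol
  harmonization is attempted.
- The ontology reader implements the id/name/namespace/is_a subset of
  OBO 1.2 only; other relationship types are counted and ignored.
- Tissue vocabulary joining is input (the grouping map), not inference;
  the shipped defaults cover the 21-type cohort and one organ-system
  grouping and are user-overridable.
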