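# Methods

## The assay and what the pipeline models

NlaIII/MmeI tag profiling reduces each captured transcript to the 21-nt
sequence starting at the CATG site nearest its 3′ end (CATG + 17 nt).
Tag counts per library are therefore a censored, discretised readout of
transcript abundance: a gene with no CATG site — or none with a full
17-nt extension — produces no tag at all, and two genes sharing a
21-mer cannot be told apart.  The pipeline models exactly this
granularity: one tag site per captured molecule, integer counts, one
library per condition (no replicates), and ambiguity resolved by
discarding rather than by probabilistic assignment.

## Reference tags and mapping

All CATG occurrences with ≥ 17 nt downstream are indexed, not only the
3′-most one: partially digested molecules and internal priming make
upstream sites observable in practice, and the 3′-most flag is kept for
diagnostics and simulation.  Antisense tags (the same scan on the
reverse complement, recorded at the sense-strand coordinate) are
indexed too, but counts whose only hits are antisense are tabulated
separately and excluded from gene expression totals by default —
whether antisense hits should count toward a gene's expression is a
reporting choice, not something the assay decides, so a flag
(`include_antisense`) exposes the alternative.  Sites whose 21-mer
contains an N are skipped: under a 1-mismatch budget a wildcard
position inflates ambiguity without adding information.

Mapping uses best-tier precedence — exact first, then Hamming distance
one — because a tag that matches one gene exactly and another with a
mismatch is overwhelmingly more likely to originate from the former
(at a 1 % per-base error rate, an erroneous tag is ~20× rarer than a
correct one, and a *specific* single error rarer still).  Tags whose
best tier spans two or more genes are discarded from every gene; only
unambiguous tags contribute to counts.  Internally tags are packed two
bits per base into int64 codes, so the 1-mismatch tier is a 63-variant
XOR enumeration resolved by binary search; results are identical to the
all-pairs Hamming oracle the tests carry.

TPM uses the library's total clean tags as denominator — not the mapped
total — so a poorly mappable library correctly shows depressed TPMs
rather than silently renormalised ones.

## The Audic–Claverie test

For counts x (library size N₁) and y (N₂) the conditional law of y
given x is negative binomial with size x + 1 and success probability
N₂/(N₁+N₂).  Tails are summed directly in log space with log-gamma
factorials; the shorter tail (inclusive lower tail below the
conditional mean (x+1)·N₂/N₁, exclusive upper tail above it) is the one
summed, chunked until the remaining geometric mass is below ~1e-20 of
the running sum, and the other tail is its complement — so the reported
doubled-minimum never suffers catastrophic cancellation.  Agreement
with an exact rational-arithmetic oracle is ~5×10⁻¹³ relative over
counts up to 200 and library-size ratios up to 100.

The two-sided construction is `min(1, 2·min(P(Y ≤ y), P(Y > y)))`,
i.e. the point mass belongs to the lower tail only.  This is the unique
doubled-tail variant that is *exactly* symmetric under exchanging
(x, N₁) with (y, N₂), by the tail-exchange identity
P(Y ≤ y | x; N₁, N₂) = P(X > x | y; N₂, N₁); putting the point mass in
both tails (or half in each) breaks the symmetry.  Symmetry matters
because up- and down-regulation calls should not depend on which
library is labelled "control".

In a null simulation (2 000 equal-abundance genes, two 10⁵-tag
libraries, mean count 50) the empirical P(p ≤ 0.05) is ≈ 0.048 — the
test is close to nominal at these counts, mildly conservative at very
low ones, which is inherent to discrete tests.

## FDR and the two significance tiers

Benjamini–Hochberg step-up adjustment is applied within each
treatment-vs-control comparison separately, matching per-comparison DE
lists.  Calls use two tiers: *significant* requires FDR ≤ 0.001 and
|log₂ ratio| ≥ 1 (≥ 2-fold); *difference* covers fold ratios strictly
between 1 and 2 with p ≤ 0.01 and FDR ≤ 0.001.  Downstream set analysis
uses the significant tier; the difference tier is reported but not
pooled into it, since the two express different strengths of evidence.

Zero TPMs are floored at `floor_tpm` (default 0.001) *only* for the
ratio — the counts keep their true zeros for the test itself.  The
floor makes fold changes finite for genes absent from one library
(novel genes); its value only affects how such genes rank by |log₂
ratio|, never whether the test finds them.

## Time-course sets

The 7-region partition of three DE gene sets is asserted to be disjoint
and exhaustive on every run.  A gene called up at one time point and
down at another counts once in each direction total, so up + down
totals may exceed the number of distinct DE genes — this mirrors how
inconsistent regulation behaves in real time courses.  Shared
percentages are half-up rounded to one decimal, the convention of
printed summary tables.

**Novel gene** is operationalised as: zero unambiguous control count
and ≥ `min_count` (default 1) tags in a treatment library.  This is a
deliberate, and deliberately simple, definition — it conflates "newly
expressed" with "below detection in control", and at default settings a
single tag suffices.  Raising `min_count` trades sensitivity for
robustness to mapping noise.

## GO-slim enrichment

The ontology reader keeps id, name, namespace and is_a edges only
(part_of and other relations are ignored) and rejects cyclic inputs.
Slim mapping follows map2slim semantics: a term that is itself slim
maps to itself and shields everything above it; otherwise each parent
path is followed to its first slim term, keeping ties across distinct
paths.  Enrichment is the one-sided hypergeometric upper tail
P(X ≥ k); no multiple-testing correction is applied to enrichment
p-values by default (an optional BH pass reuses the DE module's
adjustment).  The default population is all genes with ≥ 1 slim
mapping; using all reference genes instead is supported, and the choice
materially shifts p-values — callers should state which they used.

## The simulator

What it emulates: geometric-length transcripts (heavy-tailed, mean
789 nt, minimum 60 nt, matching typical unigene length spectra);
i.i.d. uniform background sequence with spontaneous CATG occurrences
scrubbed and motifs re-injected at a target density (default 10/kb, so
site counts are controllable without a sequence-evolution model);
log-normal baseline abundances (σ = 1.2); designated up/down/novel gene
subsets at a configurable fold change (default 4), each perturbed in a
random non-empty subset of treatments (inclusion probability 0.6) so
the per-time-point DE sets overlap the way real time courses do;
multinomial sampling of exactly `depth` tags from the 3′-most usable
site per gene (a partial-digestion fall-through probability is exposed,
default 0); and uniform per-base substitution errors over all 21
positions (no indels — substitutions dominate Illumina error at this
read length).  Library depths default to 10⁵ and scale to the
multi-million-tag regime of real experiments when needed; simulation
studies here use 10⁵–10⁶ so the full suite runs in seconds to minutes.

An error that destroys the CATG anchor produces a tag a clean-tag
filter would discard as dirty, so the simulator drops such tags and
reports the clean total as the library size (the raw table is available
via `keep_dirty=True`).  This reproduces the raw-vs-clean tag attrition
of real libraries.

What it does *not* emulate: PCR duplication, adaptor artefacts, quality
scores, indels, positional error bias, partial digestion by default,
overdispersion beyond multinomial sampling, and correlated gene
expression.  Passing tests therefore demonstrate the *analytical*
chain — extraction, mapping, testing, set algebra — under the assay's
idealised noise model; they do not certify behaviour under biological
replicate variability, which the single-library design cannot estimate
in any case.

Genes without a usable CATG site are unobservable; in recovery metrics
the sensitivity of the *test* is measured over observable genes, and
the unobservable fraction is reported separately as capture dropout.

## Numerical and reproducibility choices

All randomness flows from one integer seed per call (numpy
`default_rng`); the pipeline derives per-library seeds from its master
seed, and a rerun of the same configuration is byte-identical output
for output.  JSON reports are key-sorted; tables are written in fixed
column orders so runs diff cleanly.  Degenerate inputs fail fast with
named errors: empty transcriptomes, duplicate gene ids, malformed tags
(wrong length or missing anchor, reported with the offending row),
zero library sizes, empty p-value vectors, cyclic ontologies and
study-outside-population enrichment calls.

## Known limitations

* One library per condition: no dispersion estimation, so p-values
  reflect sampling noise only and will be anti-conservative against
  true biological replicates.
* Tag-level resolution: genes sharing their 3′-most tag are partially
  or wholly invisible; the ambiguous fraction is reported, not rescued.
* The difference tier depends on the TPM floor for genes observed in
  only one library.
* The synthetic ontology used when no OBO/slim/annotation files are
  supplied is a stand-in with known structure, sufficient for exercising
  the enrichment stage, not a biological vocabulary.
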