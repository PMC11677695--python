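# Methods

`semark` implements a marker-gene discovery pipeline for somatic
embryogenesis (SE) in *Centaurium erythraea* in-vitro cultures. The
pipeline has five stages — rule-based transcript classification, subset
accounting, annotation joins, RT-qPCR relative quantification, and
hierarchical clustering — plus a synthetic-data generator that makes the
whole chain testable without the deposited expression table or wet-lab
measurements. This note records the models, the parameters that matter,
the numerical choices, and the limitations.

## Rule-based differential-expression calls

The input is a transcript × tissue FPKM matrix over six pooled tissue
libraries: rosette leaf (rl), rosette root (rr), adventitious bud (abl),
embryogenic callus (ec), globular somatic embryo (gse) and cotyledonary
somatic embryo (cse). Because each tissue is a single pooled library,
there is no replicate dimension and no dispersion to estimate; a
count-model DE test (DESeq2/edgeR-style) is not applicable. Differential
expression is instead defined by explicit FPKM rules with two parameters:

* `min_fpkm` (default **1** FPKM) — the floor below which a transcript
  does not count as expressed in a tissue;
* `fold_threshold` (default **8**) — the fold difference required by
  every "at least N times higher" comparison.

Seven subsets are defined: three tissue-specific subsets (target tissue
expressed and ≥ 8× every other tissue), ec-induction (ec expressed,
strictly above gse, ≥ 8× rl/rr/abl/cse), early SE, late SE (mirror of
ec-induction with cse vs gse/rl/rr/abl/ec) and an all-SE subset (every
embryogenic tissue expressed and ≥ 8× every organogenic tissue).

Numerical choices:

* "at least eight times higher" is evaluated multiplicatively,
  `target >= fold * comparator`, never as a ratio — zero-FPKM comparators
  need no special case and exact 8× equality passes ("at least");
* "higher expression in X than Y" is a strict `>`;
* rules are declarative disjunctions of conjunctions of three atom
  kinds (`MinFpkm`, `FoldAtLeast`, `StrictlyGreater`), evaluated
  vectorised; a naive per-transcript loop (`classify_bruteforce`) is kept
  as an independent oracle and the two are asserted equal in the tests.

The early-SE prose rule ("FPKM ≥ 1 in ec or gse or at least eight times
higher expression in one of them compared to abl") is ambiguous. The
default `conjunctive` reading requires a *single* early tissue
t ∈ {ec, gse} to pass both the floor and the fold test against abl; the
literal reading would admit any transcript merely expressed in ec, which
is incompatible with the early-SE subset being ~1.2% of a 160k-transcript
catalogue. The literal disjunction stays available as
`early_rule_mode="literal_or"` for auditability. This is a
reconstruction, not a claim about the original analysis code.

Three structural theorems follow from the rule algebra and are enforced
as property tests: (i) the tissue-specific subsets are pairwise disjoint
(a ≥ 8b and b ≥ 8a with a ≥ 1 is impossible); (ii) ec-induction and
late SE are disjoint (mutual 8× dominance of ec and cse is impossible);
(iii) every all-SE member satisfies the conjunctive early-SE clause, so
the all-SE subset can never contribute a unique gene.

## Subset accounting

Share percentages use the **total number of hits with multiplicity** as
the denominator (a transcript in two subsets contributes two hits); this
is the only reading that reproduces the published shares
(8687/16748 = 51.87%, etc.). Rounding is half-up at 2 decimals and only
at report time. Recomputation flags one discrepancy in the published
table: the adventitious-bud share prints as 4.56% while
727/16748 = 4.34% (4.56% equals the ec share 764/16748, consistent with
a typographic duplication). The package reports the recomputed value and
the test suite asserts the discrepancy rather than reproducing the
printed one. Overlap accounting over the four SE subsets enumerates the
15 Venn regions ("belongs to exactly this combination"); region counts
partition the SE union.

## Annotation joins and candidate selection

Coverage is the fraction of subset members with ≥ 1 hit in the given
database; annotated and NA percentages are computed as complements, so
they sum to 100 within rounding. (The published NCBI-nt NA percentages
52.26%/59.94% are not the complements of their own annotated
percentages; the computed complements 56.26%/56.94% are reported
instead.) Species tallies use one best hit per transcript — lowest
E-value, ties by lexicographic accession — so tally counts sum to the
number of annotated transcripts. GO rankings count distinct member
transcripts per term within one ontology category, exclude the three
ontology roots (GO:0008150, GO:0003674, GO:0005575; configurable
blocklist), and break count ties by GO id, making the ranking a pure
function of its inputs. "Unique" members for GO ranking are transcripts
in exactly one SE subset.

Candidate selection applies the E-value priority rule: a Swiss-Prot hit
with E < 1 × 10⁻¹⁵ (strict) wins; otherwise an NCBI-nt hit under the
same cutoff; otherwise the transcript is emitted as an unannotated
candidate only on request (the route that surfaces novel, unannotatable
transcripts). A transcript belonging to several SE subsets keeps its
most specific label (all-SE, then ec-induction, then late, then early).

## RT-qPCR quantification

Relative expression uses the Livak 2^−ΔΔCt model on the nine-tissue
panel (the six sequenced tissues plus nature-collected leaf/root nl/nr
and organogenic callus oc):

* the per-replicate reference Ct is the **arithmetic mean** of the two
  reference-gene Cts (RPL2, TBP1) — equivalently the geometric mean of
  their quantities; the combination rule is this package's choice, as
  only the use of both normalizers is given;
* ΔCt = Ct(target) − Ct(reference), paired by biological-replicate index
  (three replicates by default); ΔΔCt subtracts the **mean** calibrator
  ΔCt (rosette leaf), so the calibrator's mean log2 fold change is 0 by
  construction; log2 FC = −ΔΔCt;
* amplification efficiency is assumed 100% in the fold-change math (pure
  Livak). Standard curves — OLS of Ct on log10 template copies over a
  10⁹–10² copy dilution series, ≥ 3 levels required — serve two separate
  purposes: QC (efficiency 100·(10^(−1/slope) − 1), accepted in the
  90–110% band) and imputation (an undetected Ct is replaced by the
  curve's y-intercept, every substitution audited). ΔCt is invariant to
  adding a constant to all four measurements of a replicate, which the
  tests assert.

Per gene, replicate-level log2 fold changes are compared across tissues
by one-way ANOVA followed by all-pairs Tukey HSD at α = 0.05
(statsmodels `pairwise_tukeyhsd`), summarised as a compact letter
display via the insert-and-absorb algorithm over tissues ordered by
descending mean: tissues sharing a letter are not significantly
different, a property the tests verify pair by pair. Each tissue is also
flagged for its individual comparison against the calibrator, matching
how the study's figures annotate differences vs the control. All-zero
within-group variance is rejected with guidance rather than producing
degenerate statistics.

## Clustering

Tissues are clustered on Euclidean distances between their gene-profile
vectors with Ward agglomeration (Lance–Williams recurrence on squared
distances, merge heights reported on the distance scale — scipy's
convention, asserted against `scipy.cluster.hierarchy.linkage` on
tie-free data). Genes are clustered on correlation distance
(1 − Pearson r ∈ [0, 2]) with complete linkage ("furthest neighbour" and
"complete linkage" are the same criterion; the two names are treated as
one method). The agglomeration engine is implemented in the package so
that distance ties resolve deterministically — by the lexicographically
smallest leaf labels of the candidate pair — which makes trees invariant
to input ordering; a brute-force agglomerator that recomputes max
leaf-pair distances from scratch serves as the oracle for ≤ 6 leaves.
Zero-variance gene profiles and missing (gene, tissue) entries are
errors, not imputed: the design is complete by construction.

The heatmap orders rows and columns by dendrogram leaf order and uses a
diverging palette anchored at 0 with **red = decreased, blue =
increased** (deliberately inverting the more common heatmap convention,
to match the study's figure legend). Alongside the image the plotted
matrix (TSV) and both dendrograms (Newick) are written.

## Synthetic data

`gen_fpkm` emulates the pooled six-tissue FPKM table: background
transcripts are i.i.d. log-normal per tissue (median 2, σ = 1 by
default — a right-skewed bulk-expression shape) and rejection sampled
until they satisfy **no** rule, so negatives are guaranteed rather than
probabilistic. Planted transcripts are constructed to satisfy their
target rule with multiplicative slack ≥ `margin` (> 1) on every
inequality, with non-target tissues drawn U(0.2, 0.75) — below the
expression floor and spaced so no accidental 8× ratio can arise. The
recorded truth includes the implied memberships (an ec-induction plant
necessarily passes early SE; the all-SE plant is built with equal
embryogenic values so it passes early SE but fails the strict
comparisons of ec-induction and late SE). Classification therefore
recovers the planted truth exactly, which the acceptance test checks
over 20 seeds at 10 plants per subset over 5000 background transcripts.

`gen_ct` emulates the qPCR panel: target Ct = base Ct (25 cycles) −
planted log2 FC + N(0, σ_ct) per replicate; reference genes fluctuate
around their own bases (20 and 22 cycles) with the same noise and zero
planted change; any Ct above the detection ceiling (default 40 cycles,
the panel's cycle count) is emitted as undetected. With zero noise the
pipeline recovers planted log2 fold changes exactly; with σ_ct = 0.2
cycles and 3 replicates over 100 genes the mean absolute recovery error
is ≈ 0.13–0.18 log2 units (bound asserted at < 0.5).

What the generator does **not** emulate: library-size and length biases
behind FPKM, correlated expression across tissues, heteroscedastic qPCR
noise at high Ct, inter-plate effects, or primer-efficiency differences
between genes. Passing tests therefore demonstrate the correctness of
the pipeline's arithmetic and logic under the stated model, not
robustness to those real-data effects.

## Problem sizes and determinism

The validation suite uses 1200–2000-row random matrices for the oracle
equivalence and theorem checks, 20 × 5070 transcripts for planted
recovery, 100 genes × 9 tissues × 3 replicates for qPCR recovery, and
≤ 6-leaf instances for the clustering oracle — sizes at which the brute
force oracles remain exact and the whole suite runs in seconds. Every
stochastic component draws from `numpy.random.default_rng` seeded
through `RunConfig.seed` or an explicit seed argument; identical seeds
reproduce outputs bit-exactly.

## Known limitations

* The study-scale subset counts (e.g. 8687 rl-specific transcripts of
  160,839) require the deposited FPKM table and are covered only via the
  report-arithmetic identities and the property suite.
* The conjunctive early-SE rule is a documented reconstruction of an
  ambiguous prose rule.
* Only the pure Livak model is implemented; an efficiency-corrected
  (Pfaffl) model is out of scope.
* Tukey letters assume the usual ANOVA normality/homoscedasticity
  conditions; no non-parametric fallback is provided.
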