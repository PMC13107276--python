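# Methods

This note documents the models, defaults and numerical choices behind
each module, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates and plastome structure

All intervals are 0-based half-open; GenBank's 1-based inclusive
convention is converted at the I/O boundary. Plastomes are stored
linearized with the conventional start inside the LSC; a feature
wrapping the origin is split into two intervals and flagged.

The inverted repeat is located by exact 21-mer seeding of the sequence
against its own reverse complement, followed by ungapped X-drop
extension; the longest disjoint pair with identity at or above the
threshold wins (ties: higher identity, then leftmost). Defaults
`min_len = 1000`, `min_identity = 0.99` are deliberate choices — IR
boundaries in curated records are usually verified manually, and no
universal cutoff exists; both knobs are exposed. The SSC is defined as
the shorter single-copy segment between the two IR copies. Non-redundant
length = total − one IR copy. Sequences shorter than `2·min_len`
warn and return `has_ir = False` rather than raising.

GC is computed excluding N from numerator and denominator. Optional
95% CIs per region use a nonparametric bootstrap over 1 kb
non-overlapping windows, 1000 resamples, percentile intervals — a
pragmatic choice where no CI method is canonical.

## Gene-status classification

Scoring follows the annotation convention match +1 / mismatch −1 / gap
open −5 / extend −1 in global mode, delegated to
`Bio.Align.PairwiseAligner` (deterministic traceback). Coverage is the
fraction of reference CDS bases aligned to query bases; the decision
rule is inclusive: coverage ≥ 0.70 ⇒ intact.

Per gene, the homologous locus is the strongest cluster of exact
11-mer seed hits (clusters split at gaps > 1 kb); a gene whose best
locus covers < 50 bp is *lost*. Candidate ORFs (ATG → in-frame stop,
both strands, ≥ 10 codons) are ranked by overlap with the locus
footprint, ties broken by alignment score, and the winner is clipped
to the locus span before the coverage alignment. The last two rules
matter: a long chance ORF overlapping the locus, or a reading frame
running past a truncation point, otherwise accrues "aligned" reference
bases through mismatches (a mismatch costs −1 against −1 per gap
extension, so mismatch-aligning junk is score-optimal) and can push a
heavily truncated pseudogene over the 70% line. With no qualifying ORF
at all, the raw homologous segment is aligned as a fallback and the
call annotated accordingly.

A configurable override list (shipped: `psbI`) may stay intact below
threshold, for genes whose length variation is normal among
autotrophs. The ndh cascade runs last: if any of the eleven *ndh*
genes is pseudogene/lost, intact *ndh* genes are downgraded to
pseudogene (coverage evidence preserved, `cascade_applied` set); the
operation is idempotent.

## Repeats, homology and indels

One seed-and-extend engine serves self-comparison (short repeats) and
cross-genome homology: exact shared words (default size 7), ungapped
extension scored +2/−3 with X-drop 20, both orientations,
self-diagonal excluded and mirrored duplicates deduplicated. Gapped
extension is omitted on purpose: at word size 7 the short matches of
interest are dominated by ungapped alignments, and the exhaustive
repeat oracle used in testing stays exact. E-values use the
Karlin–Altschul form E = K·m·n·e^(−λS) with λ = 1.33, K = 0.62;
these constants make E-values comparable across genomes analysed with
this engine, not identical to any external tool, and every comparison
built on them is threshold-relative. Hits ≥ 500 bp are excluded from
the "short repeat" class. Repeat content = merged hit footprint /
non-redundant length, computed on the IR-reduced sequence; it is
monotone in the E threshold by construction, and the summary statistic
is the OLS slope of content on log10(E) with a t-based 95% CI.

Homology maps keep cross-genome anchors ≥ 30 bp (`min_anchor`) and
merge them per genome. Insertions are the complement of the query
footprint (denominator: query length), deletions the complement of the
reference footprint (denominator: reference length); fragments < 30 bp
are dropped as seed-level noise. Species-specific fragments are the
complement of the union of homology footprints against all
comparators, annotated with overlapping genes and IR membership. The
stringency of "no homology" is governed by `min_anchor` and the word
size, both exposed.

## Expression and RNA editing

FPKM uses fragments (a properly paired read pair = 1 fragment):
count·10⁶/(total·len_kb), with the per-sample total counting both
strands. Heatmap dendrograms use average-linkage (UPGMA) clustering on
Euclidean distances via scipy; merge order is deterministic.

The editing caller models the variant p-value as a one-sided binomial
tail against a uniform per-base error rate ε (default 0.001). The
strand-bias rule applies only when one strand carries > 65% of variant
reads; such a site is rejected when the two-sided Fisher exact test on
(variant, reference) × (plus, minus) gives p < 1e−5. Only C→T
(sense-strand C→U) and G→A (antisense) changes are editing candidates;
other variants passing the same filters are reported separately.
Silent/non-silent status comes from codon translation at the site's
codon position (the plastid protein code agrees with the universal
table over sense codons). Efficiency is the variant read fraction.
Shared-site matrices key sites by (gene, genome position) and feed the
ANOVA + LSD machinery.

## Codon models

The rate matrix is MG94-style over the 61 sense codons:
q_ij = r(a,b)·π_j·(ω if nonsynonymous), zero for multi-nucleotide
changes, π from F3×4 (empirical, never optimized), r from HKY κ
(default path) or a supplied symmetric GTR matrix. Every Q is
normalized to one expected substitution per codon, including each
site class of the branch-site models, so branch lengths are expected
substitutions per codon under that branch's own ω; the simulator uses
the identical convention, making recovery experiments and LRT
calibration internally consistent (this differs from PAML's scaling,
where branch lengths are defined under the full mixture).

Likelihoods use Felsenstein pruning over unique column patterns with
per-pattern rescaling. Reference evaluations (`mg94_loglik`) build
P(t) with scipy's Padé `expm`; the optimizers use a spectral
(π-symmetrized eigendecomposition) fast path that agrees to ~1e−6 in
log-likelihood — immaterial against LRT thresholds, and pinned by a
test.

Fitting: box-constrained L-BFGS-B in log-ω space, bounds [1e−4, 20].
Five canonical starts (ω ∈ {0.1, 0.3, 0.5, 1, 2}; b_free additionally
starts at foreground-neutral points); all starts are evaluated and
local search launched from the two most promising. κ is estimated
jointly under M0 and then fixed for b_neut, b_free and the branch-site
models, so LRT degrees of freedom count ω parameters only. Branch
lengths are taken from the input tree by default — the package's
choice for simulation studies and for trees whose lengths were
estimated upstream — rather than re-optimized per model. Nesting is
enforced structurally: if the b_free optimum ever falls below a null's
(both nulls are points of its space), the fit is re-anchored at that
null. Branch-site bsA/bsA1 use the standard four site classes with
shared proportions; positive-selection sites are identified by
empirical Bayes at the MLEs (NEB) with posterior ≥ 0.95 — a deliberate
simplification of full Bayes Empirical Bayes, which integrates over
parameter uncertainty; the BEB site ratio is selected sites / protein
length, binned as < 0.25%, 0.25–0.50%, above, or none.

NG86 counting: per-position site weights of 1/3 per alternative
nucleotide, with mutations to stop codons excluded from both tallies;
differences averaged over all minimal pathways that avoid stop
intermediates (all pathways if none avoids them); Jukes–Cantor
correction d = −3/4·ln(1 − 4p/3), with p ≥ 3/4 flagged as saturated.
Pairwise ML rates fit (t, ω) for two taxa and split t into dN and dS
by synonymous/nonsynonymous flow normalized by the ω = 1 opportunity
fractions, so dN/dS = ω̂ exactly. The branch dN–dS relation is
reported in both regression directions (which direction a published
slope uses is often ambiguous), with excluded branches summarized by
their own dS/dN ratio.

## Statistics

Two-group comparisons: Mann–Whitney, exact p from the standard
count-recursion for the null distribution of U (equivalent to full
labeling enumeration) when |x|·|y| ≤ 400 and no ties, else normal
approximation with tie correction and continuity correction. The
effect size is the Hodges–Lehmann median of pairwise differences with
its distribution-free CI from ordered pairwise differences; ratio-style
questions are answered on log-transformed data and exponentiated.
Multi-group: one-way ANOVA with protected LSD (pairwise t on pooled
MSE only when the omnibus F is significant at 0.05) and a greedy
insert-absorb compact letter display ordered by group means.
Correlation: Shapiro–Wilk at α = 0.05 on both variables selects
Pearson vs Spearman; the downstream significance threshold is 0.01.
BH adjustment delegates to statsmodels.

## Synthetic data

`make_plastome` assembles LSC + IRb + SSC + IRa (= reverse-complement
IRb) with defaults 84/25/18 kb and a 58-gene roster spanning PS, HK
and ndh categories, including the canonical ndhJ–ndhK–ndhC and
ndhH–ndhA–ndhI–ndhG–ndhE–psaC–ndhD clusters. Genes are random ORFs
(ATG + sense codons + stop) placed with 40–120 bp spacers; each region
and the structural edits draw from independently spawned child RNG
streams, so two genomes generated from one seed under different
degradation plans or region budgets remain base-for-base homologous
outside the planted edits — the property the indel and
species-specific-fragment analyses rely on. Degradations: truncation
to a target coverage fraction (truth records the exact planted
fraction), premature stop, or whole-gene deletion. Foreign insertions
are constructed to share no exact 12-mer with the host (iterative
repair), which guarantees no alignable anchor at the engine's word
size; planted duplications and SSC block inversions exercise the
repeat and structure code. Counts are negative-binomial around the
FPKM-inverted mean (dispersion 0 → Poisson); pileups draw Poisson
coverage split binomially across strands, uniform errors at ε, and
planted sites with binomial variant counts and a controllable
plus-strand fraction for the bias filter. Everything is byte-for-byte
reproducible under a fixed seed.

What the generator does **not** emulate: sequence-context-dependent
editing, non-uniform error profiles, tRNA/rRNA genes, introns, codon
usage bias beyond F3×4, indel evolution within alignments, alignment
and cleaning artifacts, or real divergence between homologs (planted
homologs are exact copies outside the edits). Passing recovery tests
therefore demonstrates the correctness of the decision rules and
estimators under their stated models, not robustness to the full
messiness of real plastome data — in particular, gene-status coverage
on real diverged pseudogenes and the absolute scale of E-values both
depend on settings a user should revisit for their data.

## Problem sizes in the validation suite

The test and acceptance runs are sized for a single CPU: branch-model
power uses 50 genes of 8 taxa × 500 codons, the null calibration 500
replicates of 100 codons, gene-status recovery 20 compact (~25 kb,
20-gene) genomes, the repeat oracle ten 2 kb sequences, the editing
screens a 150 kb pileup, and the acceptance script a cohort of eight
~150 kb plastomes with one classification pass and a 12-gene selection
study at 300 codons. These sizes are the package's chosen defaults for
its reproducibility study; all are parameters of the public API.

## Known limitations

- No gapped extension in the repeat/homology engine; diverged or
  indel-rich homology is fragmented into anchors.
- NEB instead of full BEB for branch-site site identification.
- No branch-length re-optimization per model; supply trees with
  meaningful lengths.
- The ORF scanner ignores ORFs spanning the circular origin
  (linearization is assumed to start in intergenic LSC).
- Editing annotation assumes single-copy CDS features; a site inside
  two overlapping features is attributed to the first.
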