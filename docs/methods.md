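# Methods

## Problem and model

`magtx` analyses genome-resolved metatranscriptomes: RNA-seq reads from a
mixed microbial community mapped onto a catalog of metagenome-assembled
genomes (MAGs). The raw count of gene *g* in sample *s* confounds four
quantities — sequencing depth, the abundance of the gene's MAG in the
community, the gene's length, and the quantity of interest, the per-cell
transcription rate. The package's generative model makes this explicit:

    count(g, s) ~ NB( mu(g, s), phi_g ),
    mu(g, s) = depth_s * abundance(mag(g), s) * lambda(g, cond, phase)
               * length_kb(g) / Z_s,

with NB variance = mu + phi*mu^2 and Z_s normalizing the expected total to
depth_s. `lambda` is the relative number of transcript copies per cell.

## Marker-gene normalization

Ten single-copy universal marker genes (a fetchMGs-style COG set, default
COG0012/0016/0018/0172/0215/0495/0525/0533/0541/0552) are constitutively
transcribed housekeeping genes, so their per-cell copy number is ~1
regardless of condition. Dividing each gene's length-normalized count (RPK)
by the per-sample *median* marker RPK of the same MAG cancels `depth_s`,
`abundance`, and `Z_s` simultaneously, leaving an estimate of `lambda` on a
per-cell scale. The full chain is:

1. **filter** — keep genes with raw count >= `min_count` (default 15) in at
   least *k* samples, *k* = size of the smallest (condition, phase) group.
   Marker genes are exempt: the divisor must exist in every sample.
2. **impute** — zeros become 0.5 so later ratios stay finite.
3. **length-normalize** — count / (length/1000).
4. **marker-normalize** — divide by the per-sample median marker RPK of the
   MAG. Computed on RPK, not raw counts: dividing raw by raw would leave a
   length bias in place. A MAG with fewer than `min_markers` (default 6)
   markers present is unquantifiable and dropped with a warning.
5. **rescale** — divide by the MAG's global maximum (over its surviving
   genes and all samples) and multiply by 1e9, producing integer-sized
   pseudo-counts for count-based testing. Within-MAG ratios are unchanged.

Guaranteed properties (all tested): marker medians are exactly 1 per MAG
and sample; scaling a zero-free sample's raw counts by any c > 0 leaves
marker-normalized values unchanged to float precision; one MAG's values
are unaffected by any other MAG's counts (MAG blocks are independent).

Two points were genuinely open and are fixed as package policy: the marker
median is taken on length-normalized values, and the rescaling maximum is
global per MAG (not per sample). Both are configurable indirectly through
the stage functions if a user needs the alternative reading.

## Differential transcription

One MAG, two conditions, each reactor phase tested separately. Three
native count tests run on the rescaled pseudo-counts rounded half-up, with
no additional library-size factors (marker normalization already equalizes
effective depths; offsets are fixed at 1):

* **Exact conditional NB test.** Group sums S_a ~ NB(n_a mu, phi/n_a),
  S_b likewise; conditioning on T = S_a + S_b gives a one-dimensional
  distribution enumerated exactly for T <= 10,000. Above that the
  conditional pmf — log-concave as a product of NB pmfs — is approximated
  by a Gaussian centered on the conditional mean with curvature-matched
  variance, using the analytic second derivative
  psi1(k + 1/phi) − psi1(k + 1) to avoid cancellation; a 0.5 continuity
  correction is applied. Near the switch point the two branches agree to a
  few percent (tested); at the rescaled 1e9 scale only the approximation is
  reachable, and only the enumerated branch is claimed exact.
* **NB-GLM Wald test.** Group means are the MLEs with known dispersion;
  SE(ln FC) = sqrt((1/mu_a + phi)/n_a + (1/mu_b + phi)/n_b) by the delta
  method; two-sided normal p. A pseudo-mean of 0.125 replaces zero group
  means.
* **Moderated t.** y = log2(value + 0.5); pooled per-gene variances are
  squeezed toward a scaled-inverse-chi-square prior fitted by moments on
  log s^2 (trigamma inversion by Newton iteration, as in standard
  empirical-Bayes variance moderation); the t statistic gains d0 prior
  degrees of freedom. d0 = 0 reduces exactly to the ordinary t-test.

Dispersions are method-of-moments estimates pooled across the two groups,
phi_g = max(0, (v − m)/m^2), shrunk toward the across-gene median with
prior weight d0 = 10. This is deliberately simpler than APL/trended or
quasi-likelihood machinery: the consensus rule, not any single test's
internals, is the procedure of interest.

**Consensus rule:** a gene is differentially transcribed when at least 2
of the 3 tests give a Benjamini–Hochberg adjusted p < 0.01, with no fold-
change restriction. BH adjustment delegates to
`statsmodels.stats.multitest.multipletests`; tests verify it against the
direct step-up formula. On simulations the consensus is conservative: null
consensus fraction << alpha, empirical FDR <= 0.05 with ~100% sensitivity
at 4-fold changes (n = 3, phi = 0.05, mean 200).

The constants 0.125 (pseudo-mean) and 0.5 (log offset) are conventional
smallest-count choices; they only matter for genes with empty groups.

## Dereplication and MAG selection

Genomes are clustered by single linkage at an ANI threshold (default 97%):
an edge exists when max(ANI(a,b), ANI(b,a)) >= threshold (the permissive
reading of asymmetric FastANI output), clusters are connected components,
and the representative maximizes completeness − 5·contamination, with ties
broken by fewer contigs, more markers, then id. Activity profiling sums
raw counts per MAG and sample into read proportions and breadth (fraction
of genes with >= 1 read); "active" MAGs must pass both thresholds
(defaults: proportion 0.05, breadth 0.5) in every sample (or a majority,
by configuration). The thresholds are configuration, not fixed constants —
the underlying selection criterion in this kind of study is qualitative.

## Cross-genome KO comparison

Counts are summed per (MAG, KO, sample); genes without a KO are dropped
from aggregation (but participate fully in gene-level testing). Only KOs
present in both genomes are tested — a KO private to one genome reflects
gene content, not transcription, and is reported separately. The
comparison runs the exact NB test on the per-cell (rescaled) values so
that differing MAG abundances cannot masquerade as transcription
differences; because both MAGs are measured in the same physical samples,
outputs carry an explicit paired-sample caveat. Venn-style overlap reports
compute all 2^k − 1 exclusive regions exactly for up to 6 sets. Pathway
panels (KO lists of interest, e.g. polyphosphate, EMC/MMC, PHA, glycogen,
TCA panels for EBPR communities) are user configuration; the summary
reports per-KO group means, consensus calls, and missing-in-genome flags.

## Synthetic data: what it does and does not emulate

The generator reproduces the downstream structure of a two-experiment
EBPR metatranscriptomics design: 12 samples (2 phosphate conditions x 2
phases x 3 cycles), several MAGs with ~80% shared KO content (a common
core KO set plus genome-private KOs; ~5% of genes unannotated), lognormal
gene lengths (median ~900 bp, clipped to 150–30,000), lognormal per-cell
rates with markers pinned at exactly 1, Dirichlet MAG abundances whose
concentrations shift between conditions by ratios up to 10x (floored at 5%
of the total so every MAG stays quantifiable, mirroring studies where the
profiled MAGs remain abundant), ~10% library-size spread, and a fixed
count of true DE genes at a signed log2FC of 2 shared by both phases.

It does **not** emulate: read-level artifacts (mapping ambiguity, rRNA
carryover, positional bias), trended mean–dispersion relationships,
paralogs (each KO appears once per genome), phase-dependent DE,
correlation between replicates beyond the shared abundance draw, or
marker genes that deviate from constitutive single-copy behavior. Passing
tests therefore demonstrate correctness of the computational chain under
the stated model, not robustness to every violation real data can show —
in particular, real marker transcription varies somewhat across growth
states, which would propagate directly into the per-cell scale.

## Problem sizes and numerical choices

Verification runs use deliberately compact configurations — e.g. 3 MAGs x
500 genes at depth 1e6 for parameter recovery, 2000 genes for error
control, totals <= 50 for enumeration oracles — chosen so the full suite
and the acceptance script each complete in seconds while estimates remain
stable across seeds. Seeds flow from a single integer through named
`numpy.random.SeedSequence` substreams, so catalogs, truths and counts are
independently reproducible. Ties in the exact test are absorbed with a
1e-12 relative tolerance at the observed probability level. Degenerate
inputs (all-zero genes, empty groups, T = 0) uniformly return p = 1 and
log2FC = 0 rather than NaN.

## Known limitations

* The three tests are native analogues, not numerical clones, of the
  DESeq2/edgeR/limma family; per-gene p-values will differ from those
  packages even where the consensus calls agree.
* The exact test's large-count branch is an approximation (accurate to a
  few percent of the p-value near the branch point, tested); p-values deep
  in the tails at the 1e9 pseudo-count scale are approximation-limited.
* Phase-vs-phase contrasts are intentionally unsupported; the design
  treats phases as separate strata.
* Dereplication consumes a precomputed ANI matrix and quality table;
  computing ANI or quality from sequences is out of scope.
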