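# Methods

## Model and assumptions

The analysis treats each transcript position with a fixed inter-genomic
difference (a *diagnostic SNP*: one base fixed in all P-genome parental
libraries, a different base fixed in all A-genome libraries) as a sampling
point for the relative transcriptional output of the two homoeologs.  Read
counts at a site are modelled implicitly as a binomial draw: if a fraction
θ of a transcript's molecules carry the A variant, a read carries the A
base with probability θ, distorted by mapping bias (below).  The estimate
of θ per transcript and library is f_A = mean_A / (mean_A + mean_P), where
mean_P and mean_A are arithmetic means of the corrected per-site counts.

Assumptions worth stating explicitly:

* one global bias factor — mapping efficiency advantage of
  reference-matching reads is shared across loci and libraries;
* sites within a transcript are exchangeable draws from the same θ
  (isoform effects and position-specific coverage are ignored);
* in a PAA triploid the two A homoeolog copies are indistinguishable, so
  "A" is their pooled output and the balanced dosage expectation is
  f_A = 2/3 rather than 1/2.

## Filtering parameters

| parameter | default | meaning |
|---|---|---|
| min consensus quality | 20 | phred-like site quality floor |
| min depth | 3 | per covering library, reads at the site |
| min spacing | 5 bp | to the previously *kept* candidate, greedy left-to-right |
| min border distance | 5 bp | strict: min(pos−1, len−pos) must exceed it |
| min supporting reads | 20 | raw P+A reads at a site, else dropped from quantification |

The depth rule applies to the site itself in every library that covers it;
an uncovered library leaves a site uninformative rather than disqualified.
The spacing tie-break keeps the left site and drops the follower, which
mirrors sequential calling; both neighbours surviving when ≥ 5 bp apart.

The read-support filter is applied to raw counts — it describes sequencing
evidence, not the corrected quantities; `filter_after_correction=True`
provides the other reading.

## Heterozygosity calling and bias estimation

A parental library is heterozygous at a site when its second-most-common
base has ≥ 2 reads *and* ≥ 10% of the site depth; singletons are treated as
sequencing errors so that fixed calls are not destroyed by noise.  At a
heterozygous site the true allele ratio is 1:1, so the observed ratio
(reference-matching / other reads) measures the mapping bias.  Per usable
parental library j the arithmetic mean of site ratios gives D_j, and the
correction factor C is the unweighted mean of the D_j; the
reference-matching count at every diagnostic site is divided by C.
Libraries can be excluded from estimation (`use_for_bias=false`), the
analogue of dropping pooled samples of mixed ploidy.

Two documented caveats: the arithmetic mean of raw ratios is upward-biased
at finite depth (E[X/(d−X)] > odds), so C estimated from data sits above
the underlying odds factor b even with infinite sites — `use_log_mean=True`
averages log-ratios instead; and dividing the reference count by C is
algebraically equivalent, for fractions, to multiplying the other count.

## Classification geometry

Balanced expression is the *open* window (0.3, 0.7) on f_A for diploids and
(0.5, 0.9) for triploids; boundary values count as biased ("less than 70%
preference" makes balanced the open set).  Silencing is strict: f_A < 0.1
is monogenomic-P, f_A > 0.9 monogenomic-A, at both ploidies.  A geometric
consequence of the defaults: in triploids the biased-toward-A region minus
the silenced region is the single point f_A = 0.9, so in practice triploid
HEB(A) counts equal MGE(A) counts.  Percentages round to the nearest
integer, ties away from zero.

## Chi-squared tests

Both tests are Pearson χ² with df = 1 and no continuity correction, α =
0.05.  The direction test is a goodness-of-fit of (HEB-P, HEB-A) counts
against an equal split; the ploidy test is independence on
[[HEB, BHE] at 2n, [HEB, BHE] at 3n].  The qualitative conclusions on the
published liver and juvenile tables are robust to Yates' correction either
way (verified in the test suite).  The orchestrator skips a ploidy test
whose table has an empty margin (e.g. a run with no biased transcripts);
calling the test directly with such a table is an error.

## Enrichment

DAVID-style term enrichment is replaced by the exact hypergeometric upper
tail P(X ≥ k) with Benjamini–Hochberg adjustment within each (group,
namespace); an optional EASE-like conservative variant subtracts one from k.
The background is the set of transcripts quantified in the group's
contributing libraries.  Published enrichment p-values depend on an
external annotation service and background and are not reproduction
targets; the implementation is validated against exhaustive enumeration on
small instances instead.

## Synthetic data generator

`simulate_complex` emulates the study design: 5 PP and 4 AA parental
libraries (two AA pools excluded from bias estimation), four hybrid
libraries crossing tissue (liver/juvenile) with ploidy (PA/PAA).  Per
transcript it draws a class from a mixture (default 68% balanced, 11%/6%
biased, 12%/3% silenced — the diploid liver row of the study's summary
table), then a true θ per ploidy from a Beta(3,3) *rescaled onto the
class's window at that ploidy*, so truth labels and classifier geometry
agree by construction.  Rescaling (rather than truncating a global Beta)
puts the class mass mid-window; truncation piles mass on the window edges
and makes classes inseparable at any finite depth.  For the degenerate
triploid biased-toward-A window, θ is the boundary point 0.9 itself.

Defaults and their provenance: ~2.5 diagnostic sites per transcript
(matching 2807 SNPs over 1121 transcripts in the study's diploid liver
library); negative-binomial site depth, mean 100 and dispersion 5 (typical
bulk RNA-seq overdispersion; the study states no depth model); transcript
length ~N(800, 200²) bp, floored at 60; bias factor b = 1.2 (the study
never quantifies its bias; this is a plausible magnitude, not a published
value); the reference base matches the A variant with probability 0.5
(which genome "wins" the assembly consensus is data-dependent); intragenomic
heterozygosity rate 0.1 per site.  Heterozygous sites are emitted as
separate positions where exactly one parental library is heterozygous for
(reference base, other base) with a true 1:1 ratio distorted only by b —
which also removes them from the diagnostic set, as in real data.  Decoy
sites each violating exactly one filter criterion can be appended to
exercise the filters.

What the generator does not emulate: read-level error and alignment,
isoform structure, locus-specific bias, library-size differences, and
correlation of θ across tissues beyond sharing θ per ploidy.  Passing
recovery tests therefore demonstrates correctness of the counting,
correction and classification logic under the stated model, not robustness
to alignment artefacts or annotation error in real libraries.

## Numerical choices and problem sizes

* Recovery checks run at 2000 transcripts and site depth means of 100–200;
  bias calibration uses ~5000 heterozygous sites, recovering C within a
  fraction of a percent of its analytic mean-of-ratios expectation
  (computed by marginalising E[ref/alt | het detected] over the
  negative-binomial depth law).
* Classifier truth-label recovery exceeds 95% under the default mixture at
  depth mean 200; residual error is concentrated at window boundaries and
  in the degenerate triploid HEB(A) point class.
* The f_A → θ convergence check uses depth mean 1000: a single 200-read
  site at θ = 0.5 has binomial sd ≈ 0.035, so a ±0.05 band can only hold at
  the 99% level under genuinely deep coverage.
* The direction test's type-I error is calibrated on 10,000 null
  replicates of 200 biased transcripts (empirically ≈ 5.3%, the slight
  excess being χ² discreteness at finite counts).
* All simulations are seeded; identical seeds give byte-identical outputs,
  and pipeline outputs contain no timestamps, so reruns are bit-stable.

## Known limitations

* No per-transcript uncertainty on f_A (no binomial confidence intervals
  or per-gene imbalance tests); classification is a point-estimate rule.
* The global C cannot capture locus-specific mapping bias; strongly
  paralogous loci may remain distorted after correction.
* The greedy spacing rule and the all-libraries-fixed requirement are
  deliberate, stricter readings of under-specified published criteria;
  both are configurable (`min_spacing`, `n_*_required`).
* GO term relationships are ignored (no graph propagation); enrichment
  treats terms independently.
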