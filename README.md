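# homeobias

Homoeolog expression bias and allelic silencing in hybrid / allopolyploid
transcriptomes, from per-site allele read counts.

## The problem

In an allopolyploid, each gene exists as homoeologs — copies inherited from
the different parental species.  The motivating system is the Iberian fish
complex built from a *Squalius pyrenaicus*-derived genome (P) and an
*Anaecypris*-like genome (A), whose hybrids occur as PA diploids and PAA
triploids.  Given RNA-seq read counts at transcriptome positions, the
package answers, per transcript and per hybrid library: how much of the
expression comes from each parental genome, is the split balanced for the
ploidy's dosage, and is one genome silenced outright?

## Method

1. **SNV filtering.** Sites must have consensus quality ≥ 20, per-library
   depth ≥ 3, distance > 5 bp from transcript ends, and ≥ 5 bp from the
   previously kept candidate (greedy, left-to-right).
2. **Diagnostic SNPs.** A site is diagnostic when every AA parental library
   is fixed for one base, every PP library for a different base.  Hybrid
   reads at such sites are assignable to P or A.
3. **Reference-bias correction.** Reads carrying the assembly reference
   base map more efficiently.  At intragenomic heterozygous sites of
   parental libraries the truth is 1:1, so the mean reference/other ratio
   D_j per library, averaged over libraries, gives a global correction
   factor C; the reference-matching count at every site is divided by C.
4. **Quantification.** Sites with < 20 supporting reads are dropped; per
   transcript, corrected P and A counts are averaged over sites and the
   A-genome fraction is f_A = mean_A / (mean_A + mean_P).
5. **Classification.** Balanced homoeolog expression (BHE) is f_A inside
   the open window (0.3, 0.7) for diploids or (0.5, 0.9) for triploids
   (dosage expectation 1 P : 2 A); otherwise the transcript shows homoeolog
   expression bias toward P (f_A ≤ L) or A (f_A ≥ U).  Monogenomic
   expression (allelic silencing) is f_A < 0.1 (MGE-P) or f_A > 0.9 (MGE-A).
6. **Tests.** Pearson χ² (df = 1, no continuity correction): bias direction
   among HEB transcripts against an equal split, and HEB prevalence against
   ploidy on a 2×2 table.
7. **Grouping and enrichment.** Silenced transcripts are pooled by tissue
   and by genomotype into eight MGE groups; terms are tested with the exact
   hypergeometric upper tail and Benjamini–Hochberg correction within each
   namespace.

A synthetic-data generator (`homeobias.simulate`) emulates the whole design
— parental panels, diagnostic and heterozygous sites, negative-binomial
depth, a multiplicative reference bias, and class-structured true fractions
— so every stage is testable against known ground truth.

## Worked example

```sh
homeobias simulate --seed 3 --out sim/
homeobias run --counts sim/counts.tsv --meta sim/meta.tsv --out out/
```

prints

```
wrote 2482 sites for 13 libraries to sim/
done: 2240 diagnostic SNPs, C = 1.2317, 4 hybrid libraries -> out/
```

2482 simulated sites yield 2240 diagnostic SNPs (most of the rest are
parental heterozygous sites used for bias calibration), and the estimated
correction factor C ≈ 1.23 recovers the generator's configured bias of 1.2
(the raw mean-of-ratios estimator sits slightly above the odds factor at
finite depth).  `out/summary.tsv` then holds the per-library BHE/HEB/MGE
table, `out/tests.tsv` the χ² results, and `out/report.md` a readable
digest:

```
| library | BHE | HEB | HEB(P) | HEB(A) | MGE(P) | MGE(A) | total |
| liv-PA  | 654 (68%) | 311 (32%) | 221 (23%) | 90 (9%) | 106 (11%) | 27 (3%) | 965 |
| liv-PAA | 692 (71%) | 278 (29%) | 221 (23%) | 57 (6%) | 108 (11%) | 57 (6%) | 970 |
```

i.e. about two thirds of transcripts show balanced homoeolog expression and
~14–17% show monogenomic expression, matching the generator's configured
class mixture.  The same objects are available from Python:

```python
from homeobias import SimulationConfig, simulate_complex, PipelineConfig, run_from_records
records, meta, truth = simulate_complex(SimulationConfig(seed=3))
bundle = run_from_records(records, meta, PipelineConfig())
bundle.summaries["liv-PA"].percentages   # {'BHE': 68, 'HEB': 32, ...}
```

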