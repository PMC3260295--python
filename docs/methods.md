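# Methods

This note documents the models, statistics and numerical choices behind
`isodiv`, and what the synthetic-data generator does and does not
emulate.

## Expression reliability and the abundance floor

An isoform's FPKM estimate is labelled *reliable* iff the lower bound of
its 95% confidence interval strictly exceeds 0; a bound of exactly 0 is
the unreliable signal and is a retained observation, never an input
error. Reliability is modelled by maximum-likelihood logistic regression
on **log₁₀ FPKM** (`statsmodels` behind the module surface). Base 10 is
a declared convention: the model's predictions are invariant to the log
base, but fixing it makes coefficients comparable across runs.
Zero-FPKM records are excluded from the fit (log undefined) and counted
in the report. Complete or quasi-complete separation is reported as
`converged=False` with a separation flag instead of silently returning
divergent coefficients.

The expression floor is selected on a user grid (default: integers
1..200 FPKM) by minimizing |fp − fn|, where fp is the fraction of
unreliable records at or above the candidate floor and fn the fraction
of reliable records below it; ties go to the smaller threshold. This
formalizes choosing a floor with "nearly balanced" misclassification
rates; the selected value depends on the dataset's abundance
distribution and is not a constant of the method.

The abundance distribution is summarized by regressing log₁₀ binned
density on log₁₀ bin center over logarithmically spaced bins (default
30; bins normalized by width; empty bins dropped; ≥3 nonzero bins
required). The reported exponent is the slope magnitude r of
P(k) ∝ k^(−r). Log-binned density regression was chosen because it is
the standard estimator behind log-log abundance plots; it is not a
tail-index MLE (Hill/Pareto estimators are out of scope).

## Isoform features

Three positional features distinguish isoforms: the TSS (first
transcribed base: smallest exon start on +, largest exon end − 1 on −),
the internal exon chain (exons 2 .. second-to-last in transcription
order), and the last exon. The internal chain is a purely structural
proxy for a CDS change — no ORF prediction is attempted — with the
documented consequence that one- and two-exon transcripts (empty chain)
can never differ "in CDS". Distinct-CDS counts are taken within each
gene so that empty chains do not collapse across unrelated loci.

Reference comparison codes: `=` requires an identical intron chain on
the same contig and strand (identical exon for single-exon queries,
zero tolerance); `j` requires at least one shared splice junction or a
same-strand exon overlap; everything else, including antisense overlap,
is `u`. Requiring same-strand evidence for `j` keeps the class an
"isoform of a known locus" call rather than an antisense conflation.

The expression floor used for expressed sets is inclusive (FPKM ≥ 50 by
default) with a `strict_gt` switch, reflecting the ambiguity between
"≥" and ">" conventions in common usage; the inclusive reading is the
default because it is the one attached to whole-transcriptome counts in
the motivating analysis.

## Differential expression

All fold-change arithmetic is in natural-log units and the
Jensen–Shannon divergence uses natural-log entropy, so the statistic
√JSD lives in [0, √ln 2] and the fold-change criterion is e-fold. √JSD
is a metric on the simplex (verified by property test against direct
evaluation and `scipy.spatial.distance.jensenshannon`).

Per isoform, the test statistic is √JSD between the two-condition
composition (m_A, m_B)/(m_A + m_B) of replicate-mean abundances and the
balanced (½, ½). This is a bounded, monotone transform of
|ln(m_B/m_A)| that is defined for every isoform. A gene-level
composition-switching statistic over isoform-share vectors
(`gene_js_switch`) is provided separately; it is identically zero for
single-isoform genes, which is why it cannot serve as the per-isoform
expression test.

Significance is by replicate-label permutation. For one isoform with
R_a + R_b replicates, all distinct label assignments are enumerated when
there are at most 500 (otherwise 1000 seeded random draws); the original
assignment and, in balanced designs, its complement are trivial (they
reproduce the observed statistic by construction) and are excluded from
the null. An isoform is testable only with ≥2 replicates per condition
and a non-degenerate permutation set (≥10 distinct statistic values).
Because a single 3-vs-3 isoform admits only 18 non-trivial relabellings
(p-value floor 1/19), the pipeline (`de_analyze`) pools the permutation
statistics of all testable isoforms into one empirical null and ranks
each observed statistic against the pool — the SAM-style device that
makes small p-values attainable at realistic replicate counts. Under
the global null the pooled statistics are exchangeable, and the type-I
property test confirms the BH-adjusted call rate stays within its
binomial envelope.

Upper-quartile normalization divides each sample by the 75th percentile
of its nonzero values and restores the grand scale with the geometric
mean of those percentiles. The final filter requires a testable
statistic, BH-adjusted p < 0.05, |ln fold| strictly > 1 (a `fc_ge`
switch gives ≥, covering the "e-fold or greater" reading), and an FPKM
floor applied to the **larger** of the two condition means — requiring
both means to pass would contradict calling condition-specific isoforms
differential.

## Motif enrichment

Promoters are the 1300-bp window −1000..+300 around the TSS on the
transcription strand (minus-strand windows are reverse-complemented so
the TSS sits at offset 1000); windows running off a contig are clipped
with a warning and their effective length used, never padded. 3′UTRs
are last-exon sequences.

PWM scanning scores each window by summed log-odds of
pseudocount-adjusted column frequencies (+0.01) against a uniform 0.25
background; a hit requires a score of at least
min + 0.80·(max − min) of the attainable range. Both strands are
scanned, overlapping hits count separately, and windows containing N
are skipped. All four choices (pseudocount, threshold, background,
strandedness) are exposed as arguments. Per-bp denominators are the
scanned window counts after N exclusion, summed over both strands, not
nominal sequence lengths.

miRNA seed sites follow the TargetScan classes: with S7 the reverse
complement of miRNA positions 2–8 and S6 that of positions 2–7, an S7
occurrence followed by A is an 8mer, otherwise a 7mer-m8; an S6
occurrence followed by A whose preceding base does not pair miRNA
position 8 is a 7mer-1A. Each occurrence belongs to exactly one class
with 8mer dominating. The classifier is property-tested against a
brute-force all-substrings oracle.

Enrichment uses the binomial frequency model: the background rate
f_bg = bg_hits/bg_bp estimated from a random background set (sampled
uniformly without replacement; an undersized pool is an error), the
expectation E = f_bg·group_bp, and z = (obs − E)/√(E(1 − f_bg)), which
is exactly 0 at obs = E and antisymmetric about it. A zero-hit
background yields a flagged degenerate result. Two caveats are worth
knowing: palindromic consensus sites are counted on both strands, which
doubles their effective site weight and inflates |z| for palindromic
motifs; and a finite background pool adds estimation variance to z
beyond the binomial unit scale (visible when the background is small
relative to the group).

Motif selection keeps rows at least one column SD (population SD) from
the column mean in at least one group; zero-SD columns are flagged and
skipped. Note the rule is *relative*: in an all-null matrix it still
flags ~1-SD outliers, so its specificity comes from genuinely
differential motifs inflating the column SD — the calibration test
embeds the null motif in a matrix with planted signal rows for exactly
this reason.

Row clustering is average-linkage on correlation distance (1 − Pearson
across groups), with constant rows handled deterministically (two equal
constant rows at distance 0, constant vs. non-constant at distance 1)
and rows pre-sorted by motif id so equal-distance merges are
reproducible. The dendrogram is exportable as Newick, and a k-cut gives
cluster labels. The network step is a pure one-step filter: edges of a
user-supplied signed interaction table whose endpoints both lie in the
union of the TF and miRNA candidate sets.

## Validation statistics

Kendall's tau-b (tie-corrected; `scipy.stats.kendalltau`) with the
packaged 18-pair RNA-Seq/qPCR fold-change table as the canonical
fixture; tau-b is the variant used because the table contains a tied
fold-change value, and the tie-corrected statistic reproduces the
reference value 0.525 at 3 d.p. The probability of concordance is the
affine map (1 + τ)/2 (0.50 at τ = 0). qPCR quantification is Livak's
2^(−ΔΔCt); reciprocity under test/calibrator swap is a property test.

## The synthetic generator

The generator's defaults are the study conditions: ~18% of loci
multi-isoform (categorical 1–4 isoforms per gene), 52% of genes shared
between conditions (the remainder split evenly between the two),
power-law abundance exponent r = 1.5 (a typical transcriptome
heavy-tail value; truncated discrete Zipf, max FPKM 10⁶), reliability
logistic (β₀, β₁) = (−3, 2) on log₁₀ FPKM, 3 replicates per condition,
log-normal replicate jitter σ = 0.2 (ln scale; replicate dispersion is
a free parameter of the generator, not an inference), planted ln effect
2.0 in 10% of shared isoforms (split symmetrically across conditions so
the marginal abundance law is preserved), 1300-bp promoters, and
non-overlapping motif sites planted at per-bp Poisson rates (5×10⁻³
group / 10⁻³ background). Genes with at least 4 exons guarantee all
three variation modes are expressible; variants cycle deterministically
through alternative-first-exon, internal-exon-drop and
alternative-last-exon edits, and the mode of every variant is recorded
in the truth ledger. All randomness flows from the single config seed;
same seed, byte-identical outputs.

What the generator does **not** emulate: read-level noise and coverage
bias (no FASTQ), splice-graph complexity beyond the three variation
modes, correlated replicate structure, genome sequence composition
(uniform random DNA), motif co-occurrence and positional bias, and
annotation-scale reference catalogs. Tests passing on generated data
therefore demonstrate the correctness and calibration of the
*algorithms* under the stated statistical assumptions, not robustness
to every artifact of real RNA-Seq data.

## Problem sizes in the test and acceptance runs

Parameter-recovery gates run at the sizes where their tolerances were
derived: logistic recovery at n = 5000, power-law recovery at
n = 20000, DE recovery on a 1500-gene transcriptome (≈1000 shared
isoforms, 30% planted effects), motif detection with a 1000-promoter
enriched group against a 2000-sequence background, and the 100-seed
null-motif calibrations at 140 group/350–800 background sequences of
200 bp. DE-recovery sensitivity is computed over planted isoforms whose
true pooled abundance passes the FPKM ≥ 50 floor, because the filter
itself discards the sub-floor stratum by design.

## Known limitations

* The permutation-pooling device assumes approximately exchangeable
  statistic scales across isoforms; strongly heteroscedastic data would
  warrant a studentized statistic.
* The binomial z model ignores background-estimation variance and
  double-counts palindromic sites (above).
* The balanced-threshold criterion has no uncertainty estimate; it is a
  grid argmin, not an inferential procedure.
* Kendall tau p-values and amplification-efficiency-corrected qPCR
  models are out of scope.
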