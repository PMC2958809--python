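# Methods

`mirscape` implements a genome-wide miRNA target-identification
analysis that combines two independent lines of evidence about a single
transfected miRNA: transcriptome profiling (which genes go down when
the miRNA is introduced) and Argonaute RIP-seq (which transcripts are
physically pulled down with the silencing complex). Every stage is
exercised end-to-end on synthetic data with planted ground truth.

## Seed matching

A mature miRNA recognises targets primarily through its seed,
nucleotides 2–8. Sites in a 3′UTR are DNA matches to the reverse
complement of the seed, counted in three nested classes: 6-mer
(seed 2–7), 7-mer (seed 2–8, the 7mer-m8 class) and 8-mer (7-mer site
followed by an A opposite miRNA position 1, the 8mer-A1 class), so
`n8 ≤ n7 ≤ n6` always. Occurrences are counted with overlaps allowed by
an exhaustive sliding window; UTRs are normalised U→T before matching.
The 7-mer is deliberately the m8 class (not 7mer-A1) so the three
classes nest; no conservation or context scoring is attempted.

## Differential expression and the B-statistic

Expression input is a genes × samples matrix of normalised log2
intensities with ≥ 2 replicates per group. Per gene, `logFC =
mean(control) − mean(treatment)`, so positive logFC means the gene is
*down* upon miRNA transfection; the pooled within-group variance `s²`
has `df = n1 + n2 − 2`.

Moderation follows the hierarchical normal–inverse-χ² model: the prior
`σ² ~ s₀²·d₀/χ²(d₀)` is fitted by matching the first two moments of
`log s²` (digamma/trigamma inversion, Newton), variances are shrunk to
`s²_post = (d₀s₀² + df·s²)/(d₀ + df)`, and the moderated t has
`d₀ + df` degrees of freedom (capped at the pooled ensemble df). When
the ensemble shows no excess dispersion, d₀ = ∞ and `s²_post` collapses
to the mean variance. Zero-variance genes are retained, offset to
1e-5 × median before the log-moment fit. The B-statistic is the log
posterior odds of differential expression under a two-component
mixture with prior probability 0.01 (configurable); the effect-variance
inflation v₀ is estimated from the top tail of the moderated t so that
roughly the prior fraction of genes can reach B > 0. One test
cross-checks the whole stage against Bioconductor `limma::eBayes`
through `Rscript` (agreement ~1e-8 on t and B); limma is an oracle
there, never the implementation. Selection uses B > 5 by default, split
by the sign of logFC; p-values get a Benjamini–Hochberg column.

## Word-enrichment landscape

Genes are ranked most-downregulated first and scanned with growing
leading edges (default: ~100 evenly spaced cutoffs). For every DNA
word of length k (default 6), the occurrences in the leading edge are
compared with a hypergeometric draw of the leading edge's *word slots*
(`length − k + 1` per UTR) from the pooled corpus slots — long UTRs
thus carry proportionally more of the null. Scores are signed
−log10 tail probabilities (positive = overrepresented). Tails are
computed by a vectorised outward summation of the hypergeometric pmf
recurrence (validated to 7e-15 against exact rational enumeration);
entries whose pmf underflows double precision are recomputed in log
space, so strongly enriched words remain strictly ordered instead of
saturating at a probability floor. A Bonferroni reference line
(words × cutoffs) is reported alongside, never applied silently.

The candidate cut-off is the maximum of the first contiguous run of
positive mean scores of the miRNA's three site hexamers (the 6-mers
contained in the 8-mer site); genes ranked above it with at least one
6-mer seed match are the candidate targets.

**Calibration caveat.** The slot-level hypergeometric null is exact
when word occurrences are exchangeable across the ranking. Two real
features break that at gene granularity: words recurring within one
gene enter the leading edge together, and between-gene GC heterogeneity
makes extreme-composition words cluster by gene. No Markov/composition
correction is implemented (a deliberate non-goal), so on heterogeneous
corpora the extreme-word null is anticonservative — which is precisely
the background effect the bias module measures. The null-calibration
test therefore runs on a compositionally homogeneous short-UTR corpus,
where the stated null holds.

## RIP-seq binomial enrichment

Per gene, the IP fraction is `f = k_ip/(k_ip + k_in)`; with balanced
libraries f ≈ 0.5 means no enrichment. Differential representation is
the binomial upper tail `P(X ≥ k_ip | n = k_ip + k_in, p₀)`. The null
proportion p₀ defaults to the global library proportion
`K_ip/(K_ip + K_in)` over genes passing the read filter (min 10 reads,
configurable), which absorbs library imbalance; a fixed p₀ = 0.5 is
available since the choice is not uniquely determined by the fraction
statistic alone. Calls use raw p < 0.003 with no multiplicity
correction, mirroring the raw-threshold procedure; a BH column is
emitted for users. Low-coverage genes are flagged, never deleted.
The empirical CDF of f serves to compare conditions: extra pull-down
shifts mass above 0.5.

## Hexamer GC-bias diagnostic

The pooled overlapping-hexamer composition of the top-enriched UTRs
(≈500, or 5% of smaller corpora) is compared against mid-ranking
"non-enriched" UTRs (≈2000 / 20%; the background definition is a
package decision — the middle of the p-value ranking). Per hexamer, a
0.5-occurrence pseudocount keeps log2 ratios finite; the Spearman
correlation of log-ratio against hexamer GC (7 tie-heavy levels,
handled exactly) summarises GC-driven background binding, flagged at
rho > 0, p < 0.01.

**Limitation.** The Spearman p-value treats the 4,096 hexamers as
sampling units. When between-gene GC variance is large, a *random*
500-gene set shifts the whole hexamer spectrum coherently (set-level
mean-GC noise ~ sd/√500), and the nominal p becomes anticonservative in
both directions. The detection-contrast test therefore uses a corpus
with per-gene GC sd ≈ 0.01, where set-sampling noise sits below the
hexamer counting noise and the trend genuinely reflects GC-dependent
selection. On real, heterogeneous UTRs the rho is a descriptive
effect size; its p-value should not be read literally.

## Integration

The analysis universe is the intersection of genes with expression
data, RIP counts passing the read filter, and an annotated UTR. Genes
are ranked by increasing enrichment p-value and, for any prediction
set, the cumulative fraction of prefix genes in the set is plotted
against an independence baseline `|set|/|universe|` (the curve's
terminal point equals the baseline exactly). A curve "beats" the
baseline over the first decile when its mean there exceeds
baseline + 2·SE(baseline at the decile size) — a pure-chance curve
passes a raw `> baseline` comparison half the time, so the margin is
part of the definition. Set overlaps (e.g. array candidates × IP
enriched) use the one-sided hypergeometric (Fisher-exact equivalent)
with full four-cell Venn bookkeeping summing to the universe.

## Synthetic data

The generator emulates the study design the analysis assumes, at desk
scale, and shares no statistical code with the stages it tests.
Defaults (the study conditions; all configurable):

| parameter | default | rationale |
|---|---|---|
| genes | 10,000 | order of an expression array's annotated genes |
| UTR length | log-normal, median 800 nt, σ 0.7, min 30 | mammalian 3′UTR-like |
| UTR GC | Beta, mean 0.44, concentration 20 | mammalian 3′UTR-like (sd ≈ 0.10) |
| target fraction | 5% | a few hundred true targets per miRNA |
| sites per target | 1 + Poisson(0.5) | mostly single-site targets |
| replicates | 3 per group | triplicate transfections |
| expression noise | σ = 0.3 log2 | replicate scatter of arrays |
| repression | 0.8 log2 per site | strong-transfection knockdown |
| RIP depth | mean 100 reads/gene/library, NB dispersion 0.3 | overdispersed libraries |
| IP enrichment | 4× for targets (treatment run) | clear but not trivial pull-down |
| GC binding β | 2.0 treatment / 1.0 control | background binding in both, stronger with the targeting miRNA |
| library ratio | 1:1 | balanced IP/INPUT |

UTRs: per-base composition at the gene's GC value; targets receive
non-overlapping planted 8-mer sites; non-targets are rejection-sampled
until they carry zero 6-mer seed matches (≤1000 attempts), so planted
truth is unambiguous. Rejection slightly disfavours mid-GC sequences
(the seed word is half-GC); the realized non-target GC sits within
~0.005 of the configured mean and the effect is asserted in the tests.

Expression: baseline 8.0 log2 plus Gaussian noise; in the treatment
run each target's treatment-group mean drops by repression × sites;
the control-miRNA run is a global null.

RIP: per gene a Poisson–Gamma read pool (marginally negative binomial
with the configured dispersion) is split between IP and INPUT by
binomial thinning with odds ∝ enrichment × exp(β·gc), rescaled by an
exact root-solve so the expected library split equals the configured
ratio. Under the null this makes the per-gene IP count exactly
binomial given the gene total, so the caller's null calibration is a
property of the model, not a coincidence of parameters.

## Problem sizes and numerical choices

Tests and the acceptance script run the calibration/recovery studies
at 10,000 genes (10 seeds where a property is frequency-based) and
unit tests at 600–1,000 genes; a full pipeline run takes ~10 s on one
core. Ties in every ranking break lexicographically by gene id, so
runs are byte-reproducible given the seed. Probabilities are floored
at 1e-300 only as a last-resort guard; landscape scores use exact
log-space tails instead of the floor. The trigamma inversion falls
back to d₀ = ∞ (posterior variance = mean variance) when the variance
ensemble shows no excess dispersion.

## Known limitations

- No Sylamer-style Markov composition correction in the landscape;
  extreme-composition words are anticonservative on heterogeneous
  corpora (see above).
- The hexamer GC diagnostic's p-value assumes hexamer independence;
  treat it as descriptive on real data.
- The binomial RIP model conditions on per-gene totals; it does not
  model between-replicate biological variance of the IP efficiency.
- Synthetic UTRs are i.i.d.-composition sequences: no repeats, no
  conservation structure, no isoform-level UTR variation. Passing
  tests demonstrate correct recovery of the planted statistical
  structure, not performance on real annotation.
- Probe-level microarray collapsing (max |logFC| probe per gene) is
  implemented for array inputs but exercised only on synthetic
  probe tables, not on any real platform's annotation.
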