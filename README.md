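# mirscape

Genome-wide identification of the targets of a single microRNA from two
independent kinds of evidence: **transcriptome profiling** (which genes
go down when the miRNA is transfected into cells lacking endogenous
miRNAs) and **Argonaute RIP-seq** (which transcripts co-purify with the
silencing complex, measured as IP vs INPUT read counts). The package is
aimed at computational biologists who want a self-contained, tested
implementation of this analysis with a planted-truth simulator to
validate every stage.

## The analysis

A metazoan miRNA represses targets through its *seed* (nucleotides
2–8); target sites are 3′UTR matches to the reverse complement of the
seed, in nested 6-mer / 7-mer (7mer-m8) / 8-mer (8mer-A1) classes.

1. **Differential expression** (`mirscape.diffexp`). For replicated
   two-group log2 expression, empirical-Bayes moderated statistics:
   per-gene variances `s²_g` are shrunk via the hierarchical model
   `s²_post = (d₀s₀² + df·s²)/(d₀+df)` with `(d₀, s₀²)` fitted by
   moment-matching on `log s²`; genes are selected by the B-statistic
   (log posterior odds of differential expression) at B > 5, and ranked
   by logFC, most-downregulated first (`logFC = control − treatment`, so
   positive = down upon transfection). Cross-checked against
   `limma::eBayes` in the test suite.
2. **Word-enrichment landscape** (`mirscape.wordscape`). For every DNA
   word of length k over growing leading edges of the ranked list, a
   signed −log10 hypergeometric tail probability, with UTR *word slots*
   as the sampling unit. A ranking driven by the miRNA produces a sharp
   peak for its seed-match words; the maximum of the first enrichment
   peak is the candidate cut-off, and genes above it with ≥1 6-mer seed
   match are candidate targets.
3. **RIP enrichment** (`mirscape.ripscore`). Per gene, the IP fraction
   `f = k_ip/(k_ip+k_in)` and the binomial upper tail
   `P(X ≥ k_ip | n, p₀)` with `p₀` the global library proportion
   (0.5 optional); genes called enriched at raw p < 0.003.
4. **GC-bias diagnostic** (`mirscape.biascheck`). Hexamer composition of
   top-enriched vs mid-ranking UTRs; the Spearman trend of log2
   frequency ratio against hexamer GC quantifies GC-dependent
   background binding, which must be separated from seed-driven
   enrichment.
5. **Integration** (`mirscape.integrate`). Cumulative
   prediction-fraction curves against an independence baseline,
   hypergeometric set-overlap (Venn) tests, and a one-command pipeline.
6. **Synthetic data** (`mirscape.synthetic`). A generator with planted
   targets (seed sites, expression repression, IP enrichment,
   GC-dependent background) and scrubbed non-targets, so that every
   stage's recovery and calibration can be tested against known truth.

See `docs/methods.md` for the model details, parameter defaults and
known limitations.

## Worked example

Run the full pipeline on a simulated study (4,000 genes, triplicate
transfections, treatment and control miRNA):

```python
from mirscape.integrate import PipelineConfig, run_pipeline
from mirscape.synthetic import SimConfig

res = run_pipeline(PipelineConfig(sim=SimConfig(n_genes=4000, seed=7)),
                   outdir="demo")
```

or, from the shell, `mirscape all --seed 7 --outdir demo` (subcommands
`simulate`, `diffexp`, `wordscape`, `ripscore`, `biascheck` run single
stages on files). `demo/summary.txt` then reads:

```
mirscape 0.1.0 pipeline summary
seed: 7  genes: 4000
miRNA: syn-miR-1  seed7: CAGUACG
B > 5.0: 85 downregulated, 0 upregulated
word-landscape peak threshold: 160 genes
candidate targets (>=1 6-mer above threshold): 155
IP-enriched at p < 0.003: 337 (treatment), 56 (control)
hexamer GC-bias rho: 0.417 (treatment), 0.960 (control)
analysis universe: 4000 genes
array-candidates vs IP-enriched overlap: 154 (fold 11.79, p 6.05e-181)
Venn neither-set remainder: 3662
```

Reading these numbers: of the 200 planted targets, 85 clear the
conservative B > 5 cut-off (only downregulated genes, as planted); the
seed-word landscape peaks at gene 160 of the ranked list, yielding 155
candidate targets (all of which are true targets here — non-targets are
scrubbed of seed matches). The RIP stage calls 337 genes enriched in
the treatment transfection but only 56 in the control (GC-driven
background), and the array candidates overlap the IP-enriched set 154
times — 11.8-fold above independence. The positive GC-bias rho in both
runs reproduces the background-binding signature; per-stage tables
(`diffexp.tsv`, `landscape.tsv`, `ripscore_*.tsv`,
`hexamer_bias_*.tsv`, `cumulative_fraction_*.tsv`) and a JSON manifest
land next to the summary.

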