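# methylome-tdmr

Tissue-specific differentially methylated region (tDMR) analysis for
450K-style methylation beta-value matrices.

The pipeline: probe filtering (SNP-flagged and selected chromosomes) →
grouping of position-sorted probes into runs with all inter-probe gaps
< 3 kb → minimum-description-length segmentation of each run (dynamic
programming over a two-part Gaussian code, segments of 1–50 probes) →
one-vs-rest ANOVA on per-sample segment means with per-group Bonferroni
correction (calls need ≥ 3 probes and adjusted p < 0.05) → annotation
and Table-style summaries. Companion modules compute genome-wide
summaries (invariant hyper/hypo classification at β > 0.9 / β < 0.1,
region and CGI distributions, tissue correlation and complete-linkage
clustering, per-CpG tissue/individual variance decomposition,
gap-stratified adjacent-probe correlation) and methylation–expression
Pearson-correlation classification tables. A seeded simulator generates
450K-like datasets with planted tDMRs and a truth table for recovery
testing.

## CLI

`methylome-tdmr` exposes the stages as subcommands:

```sh
# simulate a dataset with ground truth
methylome-tdmr simulate --seed 1 --out-dir sim/

# run individual stages
methylome-tdmr filter --betas sim/betas.tsv --annotation sim/annotation.csv \
    --drop-snp --drop-chrom chrX,chrY -o filtered.tsv
methylome-tdmr segment --betas filtered.tsv --annotation sim/annotation.csv \
    --design sim/design.csv -o segments.tsv
methylome-tdmr call --betas filtered.tsv --annotation sim/annotation.csv \
    --design sim/design.csv --segments segments.tsv \
    -o tdmrs.tsv --bed tdmrs.bed
methylome-tdmr global-stats --betas sim/betas.tsv \
    --annotation sim/annotation.csv --design sim/design.csv -o report/
methylome-tdmr expr-corr --betas sim/betas.tsv \
    --annotation sim/annotation.csv --design sim/design.csv \
    --expression expr.tsv -o corr_tables.tsv

# everything end to end on a fresh simulation
methylome-tdmr demo --seed 1 --out-dir demo_out/
```

Exit codes: 0 success, 1 validation error, 2 I/O error.

Input formats: beta matrix as TSV (first column `probe_id`, one column
per sample, values in [0, 1], blanks allowed); annotation as CSV
(`probe_id, chromosome, position, gene, gene_region, cgi_relation,
snp_flag`, with semicolon-joined parallel gene/region lists); sample
sheet as CSV (`sample_id, tissue, tissue_group, individual_id,
replicate_of`); expression as gene × tissue TSV. Annotation positions
are 1-based; exported BED is 0-based half-open.

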