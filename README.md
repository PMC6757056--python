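# switchseq

Analytics for massively parallel ribozyme-switch (aptazyme) screens in
mammalian cells. The package takes architecture-matched sequencing reads of
a hammerhead-ribozyme library with a degenerate stem loop and produces:

- **RNA-seq activity**: per-variant RNA/DNA read-count ratios normalized to
  a non-cleaving spiked-in control (scaled so the control sits at 100),
  ligand activation ratios, and switching significance with
  Benjamini–Hochberg FDR control (`rnaseq_quant`);
- **FACS-seq (sort-seq) fluorescence**: reconstruction of per-variant
  log10 fluorescence-ratio distributions from sorted-bin read counts via an
  interval-censored normal maximum-likelihood fit, calibrated to relative
  fluorescence units with spiked-in controls (`facsseq`);
- **Sequence–function analysis** of the randomized loop: 14-bin activity
  partitioning, Shannon-entropy logo matrices, pairwise mutual information,
  percentile contribution tensors, one-hot encoding, and IUPAC motif
  subsetting (`seqfun`);
- **Closed-form assay utilities**: gel densitometry fractions, qPCR
  normalization, gated flow-cytometry relative fluorescence, and one-site
  equilibrium binding fits (`assay_utils`);
- **A seeded simulator** (`synthetic_data`) generating ground-truth
  libraries, multinomial DNA/RNA read counts with copy-number dispersion,
  architecture-bearing FASTQ reads, and sorted-bin FACS counts, so the full
  pipeline is testable without external data.

## CLI

The `switchseq` entry point exposes the pipeline stages:

```sh
# end-to-end simulated run (simulate -> count -> quantify -> facsfit -> seqfun)
switchseq run --seed 1 --outdir out/

# individual stages
switchseq simulate --seed 1 --n-variants 200 --outdir sim/
switchseq count --reads sim/reads.fastq --controls controls.fasta \
    --barcodes sim/barcodes.tsv --aptamer ATACCAGC... --lengths 4,5 \
    --min-dna 100 --out counts.tsv
switchseq quantify --counts counts.tsv --control sTRSVctl --sided two \
    --out activity.tsv
switchseq facsfit --bins facs_minus.tsv --sidecar facs_minus.json \
    --controls controls.fasta --out fits.tsv
switchseq seqfun --activity activity.tsv --q 5 --motif NRRAR --outdir fun/

# small assay helpers
switchseq gel --bands bands.tsv
switchseq qpcr --samples qpcr.tsv
switchseq flow --events cells.tsv --control-events ctl_cells.tsv
switchseq binding --curve spr.tsv
```

`switchseq run` accepts a YAML config (`--config`) with `seed` plus optional
`simulate`, `count`, `quantify`, `facs`, and `seqfun` override sections; it
writes result tables and a `report.json` with stage timings, filter
statistics, output checksums, and the control-normalization check.

## Conventions

- Sequences are held internally as DNA (U mapped to T on ingest); one-hot
  and frequency tables use base ordering A, C, U/T, G.
- Architecture matching is exact (zero mismatches) by default; spiked-in
  controls are matched before the library architecture.
- The DNA-coverage filter keeps variants with at least 100 DNA reads in
  every condition and replicate; controls are exempt.
- t-tests operate on log10 activity with pooled variance, two-tailed by
  default; activity values of 0 are excluded from log-scale analyses (no
  pseudocount).
- Percentiles use linear interpolation between order statistics.
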