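# hrepipe

An integrative ChIP-seq / transcriptome analysis pipeline that classifies
promoter-bound genes into stimulus-responsive vs unresponsive sets. The
toolkit covers:

- **Motif scanning** (`hrepipe.motif_scan`) — IUPAC consensus search
  (the RCGTG hypoxia-response-element core) on both strands, plus
  GC/length-matched background sampling for enrichment.
- **Peak operations** (`hrepipe.peak_ops`) — definitive-peak score
  filtering (strictly >20 by default), transitive overlap merging with
  provenance, Venn-style set overlap counts, midpoint-based genomic
  category annotation (promoter > exon > intron/intergenic), strand-aware
  promoter windows (−1500/+500 bp around the TSS), nearest-TSS assignment,
  and promoter-HRE gene selection (peak ∩ motif hit ∩ window).
- **Expression** (`hrepipe.expression`) — counts → log2-TPM transform,
  NA / zero-SD row filters, >1.2-fold induction filter (24 h vs 4 h),
  >2-fold WT-vs-KO dependence classification, and stimulus-specific gene
  sets. All fold thresholds use strict inequalities.
- **Clustering & statistics** (`hrepipe.cluster_stats`) — Euclidean
  hierarchical clustering with R-convention `ward.D` (Lance–Williams on
  unsquared distances) or `ward.D2`, height/k dendrogram cuts, the
  between-minus-within mean-distance separation statistic, and its
  Monte-Carlo (999 label permutations, p = count/n) and exhaustive
  permutation tests.
- **Enrichment** (`hrepipe.enrichment`) — cumulative-binomial motif
  enrichment against matched backgrounds with Benjamini–Hochberg
  adjustment.
- **Synthetic data** (`hrepipe.synthetic_data`) — seeded generator for toy
  gene models, promoter sequences with planted motifs, WT/KO peak sets
  with sub-threshold decoys, and {WT,KO} × {LPS,hypoxia} × {0,4,24 h}
  expression matrices with planted responsive / unresponsive groups and
  full ground-truth labels, so every stage is testable without any
  sequencing downloads.
- **Pipeline + CLI** (`hrepipe.pipeline_cli`) — one `hrepipe` command
  orchestrating everything with YAML config, per-stage derived seeds, and
  a machine-readable run manifest.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (permutation-test
exactness and null calibration, scanner/Ward/binomial oracle equivalence,
end-to-end ground-truth recovery, TPM and strict-boundary contracts, and
enrichment ranking); the other modules carry the unit and property tests
with their independent brute-force oracles in `tests/_oracles.py`.

## CLI

```sh
# generate a synthetic benchmark
hrepipe simulate --out data/ --seed 1 --n-genes 100

# run the whole pipeline on synthetic data
hrepipe run-all --out run/ --seed 1

# or from a YAML config / individual stages
hrepipe run-all --config config.yaml --out run/
hrepipe scan --fasta data/promoters.fa --out hits.tsv
hrepipe peaks --bed data/peaks.bed --min-score 20 --out merged.bed
hrepipe expr --matrix data/expression.tsv --samples data/samples.tsv --out induced.txt
hrepipe cluster --matrix m.tsv --samples s.tsv --height 50 --out clusters.tsv
hrepipe permtest --matrix m.tsv --labels labels.tsv --n-permutations 999 --seed 7 --out p.json
hrepipe enrich --targets t.fa --background b.fa --out enrichment.tsv
```

A run directory contains `data/` (the inputs), per-stage outputs
(`motif_hits.tsv`, `merged_peaks.bed`, `selected_genes.txt`,
`clusters.tsv`, `permutation_test.json`, `classification.tsv`,
`enrichment.tsv`) and `manifest.json` with the config snapshot, per-stage
record counts, and result summaries.

## File formats

BED3/BED6 for peaks, GFF3 for gene models (converted to internal 0-based
half-open coordinates at the I/O boundary), FASTA for promoter sequences,
TSV for matrices (first column `gene_id`, header of sample ids) with a
sidecar sample-metadata TSV (`sample_id`, `genotype`, `condition`,
`timepoint_h`, `replicate`), and a ground-truth TSV from the simulator.
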