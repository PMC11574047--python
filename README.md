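# damidpipe

Tissue-specific DamID chromatin-association and RNA-polymerase-DamID
(RAPID) expression analysis, reimplemented as a tested, reusable Python
pipeline, together with a synthetic-study generator so every stage can be
exercised without any external data.

## What it does

- **genome_model** — GATC-site discovery, GATC-fragment maps, fixed-size
  bin grids (2/10/100 kb), gene intervals with ±500 bp extensions, and the
  autosomal arm/center partition (built-in ce11 border coordinates; chrX is
  excluded because no usable border is available).
- **damid_quant** — adapter filtering (`CGCGGCCGAG`) with GATC anchoring,
  fragment counting, midpoint binning, and the normalization chain:
  pseudocount → relative reads per replicate → replicate averaging →
  log2(fusion/control) → genome-wide mean centering. Gene-level variants
  included.
- **enrichment_stats** — a self-contained negative-binomial Wald test
  (median-of-ratios size factors, trend-shrunk method-of-moments
  dispersions) standing in for DESeq2, Benjamini–Hochberg correction,
  differential accessibility, genotype-differential association
  (|Δlog2| > 0.58, FDR 0.05), and arm/center Wilcoxon comparisons.
- **rapid_expression** — per-gene Pol II occupancy, expressed-gene calling
  at FDR 0.05 against a seeded permutation null, replicate-consistent
  deregulation calls (|Δlog2| > 1 in every replicate pair), and paired
  t-test crosslinks back to binding tracks.
- **set_analysis** — associated-gene calling, Venn overlaps, multi-dataset
  membership and expression-category summaries with integer percentages.
- **synthetic_data** — deterministic simulator: toy genome with discovered
  GATC sites, non-overlapping genes, arm-biased binding, planted
  genotype-differential bins, planted expressed/deregulated genes,
  NB-distributed counts and adapter-prefixed FASTQ emission with exact
  round-trip guarantees.
- **pipeline / cli** — end-to-end binding and expression analyses with
  JSON reports.

## CLI

```bash
damid simulate --config sim.yaml --out data/         # synthetic study
damid quantify --counts rep1.tsv --counts rep2.tsv \
    --control-counts c1.tsv --genome genome.fa \
    --bin-size 10000 --out track.bedgraph            # normalized track
damid enrich --fusion-counts ... --control-counts ... --out enrich.tsv
damid diffassoc --enrich-a a.tsv --enrich-b b.tsv \
    --track-a a.bedgraph --track-b b.bedgraph --min-delta 0.58 --out d.tsv
damid armcenter --track track.bedgraph --out summary.json
damid rapid --rpb6 r1.tsv --rpb6 r2.tsv --control c1.tsv --control c2.tsv \
    --genome genome.fa --annotation genes.gff3 --out rapid.tsv
damid dereg --wt wt.tsv --mut mut.tsv --threshold 1.0 --out dereg.tsv
damid overlap setA.txt setB.txt                      # Venn / membership
damid report --config sim.yaml --out reports/        # both end-to-end runs
```

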