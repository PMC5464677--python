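# galmap

Quantitative pipeline for yeast GAL-pathway nutrient-decision genetics:

- **flow phenotyping** — induced fractions from single-cell glucose
  titrations, Hill/interpolation fits of the decision threshold (F50, the
  glucose concentration at which 50% of cells induce the reporter at fixed
  galactose), reference-strain and replicate-outlier QC, fold-range and
  distinguishable-phenotype summaries
- **bulk-segregant mapping** — depth filtering, 100-bp binning, a binomial
  likelihood-ratio LOD contrast between ON/OFF pool allele counts with
  pool-size-limited effective counts and linkage-scale Gaussian smoothing,
  locus calling with 2-LOD support intervals, 20-kb cross-clustering and
  gene overlap from GFF3
- **variance partitioning** — V_P = ε² + V_GAL3 + V_BG decomposition of
  segregant decision thresholds across three hybrid designs, with upper and
  lower bounds on the focal-allele contribution
- **growth analysis** — exponential rates in the OD600 ∈ [2⁻⁶, 2⁻⁴] window,
  diauxic lag lengths from rate-threshold crossings, threshold–lag
  correlation
- **sequence popgen** — haplotype counting over promoter/coding SNP
  matrices, synonymous/nonsynonymous classification by codon translation,
  McDonald–Kreitman test with Fisher exact p, and a cross-repetition
  permutation test
- **synthetic data** — generators for every input (titration cells tables,
  meiotic segregants with Haldane crossovers and intercrossing, sorted-pool
  allele counts with Poisson depth, hybrid phenotype tables, two-phase
  growth curves, strain × SNP matrices with an outgroup), each with a
  ground-truth sidecar so every stage is testable offline.

## CLI

```sh
galmap simulate  --seed 1 --out-dir out/            # all synthetic inputs + truth JSON
galmap phenotype --cells out/cells.tsv.gz --out out/thresholds.tsv
galmap bsa       --counts out/allele_counts.tsv --gff genes.gff3 --out-prefix out/cross1
galmap varpart   --phenotypes out/phenotypes.tsv --out out/varpart.json
galmap growth    --curves out/growth.csv --out out/growth_summary.tsv
galmap popgen    --variants out/variants.tsv --cds out/cds.fa --outgroup out/outgroup.fa --out out/popgen.json
galmap all       --seed 1 --out-dir out/            # simulate + every stage
```

Tables are TSV/CSV (gzip-aware by extension); sequences FASTA; annotations
GFF3. Coordinates are 0-based half-open internally and 1-based only at file
boundaries.

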