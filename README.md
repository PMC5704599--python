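# rumivir

Analysis toolkit for rumen virome studies built around a 5-steer ×
4-diet crossover feeding trial. It covers the full post-assembly
pipeline:

- **`rumivir.synthetic_data`** — generates every input the pipeline
  consumes with known ground truth: the crossover design and diet
  composition table, contig catalogs with candidate binnings and
  terL/bacterial-SCG marker annotations, per-contig count and
  covered-base matrices with planted diet (TDN) effects and planted core
  populations, OTU tables with random phylogenies, and ORF→KO tables for
  AMG analysis.
- **`rumivir.curation`** — delineates viral populations from binned
  contigs: viral/length filtering, binning selection by duplicate-terL
  count, multi-terL removal with long-contig rescue, bacterial-SCG
  decontamination, and taxonomy assignment via the longest classified
  contig.
- **`rumivir.abundance`** — aggregation to populations/families, breadth
  of coverage, log2 CPM/CPKM and relative-abundance normalizations,
  protein-cluster retention filtering, reads-recruited summaries.
- **`rumivir.core_virome`** — near-ubiquitous population detection
  (breadth ≥ 15% in ≥ 80% of samples, both boundaries inclusive).
- **`rumivir.ecology`** — Chao1, Shannon, rarefaction, Bray-Curtis,
  weighted UniFrac, multi-factor PERMANOVA with sequential sums of
  squares and permutation (or exhaustive) P-values, betadisper-style
  dispersion homogeneity tests, intra-group distance contrasts, and
  alpha-diversity ANOVA with pairwise tests.
- **`rumivir.drivers`** — Pearson collinearity prefilter, CAP/db-RDA
  with overall and marginal permutation tests, backward stepwise
  selection, variance inflation factors, PLSR responder screening and
  univariate regression support.
- **`rumivir.amg`** — Class-I auxiliary metabolic gene classification
  from KO pathway memberships (exclusion list with carbon/nitrogen/PPP
  rescue), median-of-ratios size factors computed from all ORFs, and a
  negative-binomial Wald test for differential abundance.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance battery: printed-value
checks, brute-force/enumeration oracle equivalences, null calibration of
every inferential test, and planted-truth recovery on synthetic data.

## CLI

```sh
rumivir simulate --preset paper --seed 1 --outdir data/      # synthetic dataset
rumivir curate --contigs data/contigs.tsv --markers data/markers.tsv \
    --bins data/binning_candidate_0.tsv --hits data/hits.tsv --out pops.tsv
rumivir core --breadth breadth.tsv --counts counts.tsv --out core.tsv
rumivir ecology --table data/otus.tsv --design data/design.tsv \
    --metric braycurtis --perm 999 --seed 1 --outdir eco/
rumivir drivers --distance eco/distance.tsv --explanatory X.tsv --outdir drv/
rumivir amg --annotations data/orf_ko.tsv --pathways data/ko_pathways.tsv \
    --orf-counts data/orf_counts.tsv --outdir amg/
```

All interchange formats are single-header TSV files; trees are Newick.

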