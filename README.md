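# cellvar

Cell-to-cell variability analysis toolkit for clonal cancer-cell
subpopulations. Implements, as a tested reusable pipeline:

- **core** — coefficient of variation (sample s.d./mean), sample-size
  equalization by repeated subsampling, matched paired CV comparisons
  (fraction of features with higher CV + paired t-test), Levene's
  variance-equality test.
- **morphology** — debris filtering, per-clone equalized CVs of six size
  parameters, a PCA (PC1) variability score with high-variability
  flagging, mitotic index.
- **scvar** — single-cell expression variability between two populations:
  cell QC, spike-in technical check, cell-number equalization, transcript
  filtering (detection + Gaussian-mixture mean threshold), per-transcript
  CV comparison, subsample stability across set sizes, and exhaustive
  leave-one-out robustness analysis.
- **splicing** — intron-retention ratios (intron reads over the two
  flanking exons), retention and exon-exon-junction CV comparisons, and a
  knockdown retention-shift test.
- **enrichment** — four-bin CV-log-ratio categorization across two
  comparisons and per-bin hypergeometric gene-set enrichment with a
  "highest in bin 4, lowest in bin 1" relevance rule.
- **overlap** — hypergeometric overlap of knockdown-dependent and highly
  variable transcript sets, plus a deregulation-vs-variability trend.
- **phylo** — Nei's standard genetic distance from variant allele
  frequencies and neighbor-joining with newick output.
- **simulate** — synthetic generators for every input above with known
  ground truth (gamma-Poisson counts with controllable dispersion
  inflation, spike-ins, intron/junction layers, correlated log-normal
  morphology, allele-frequency drift along a clone tree, knockdown
  fold-changes and gene sets with planted signal).

## CLI

`cellvar` exposes subcommands `run`, `synthesize`, `morphology`, `scvar`,
`splicing`, `enrich`, `overlap`, `phylo`, and `report`:

```sh
# full synthetic end-to-end run, then a markdown report
cellvar run --seed 1 --outdir runs/demo
cellvar report runs/demo

# individual stages on files
cellvar synthesize --seed 1 --outdir data
cellvar scvar data/expression_matrix.tsv data/expression_cells.tsv \
    --features-path data/expression_features.tsv --set-sizes 5,7
cellvar phylo vaf.tsv --out tree.nwk
```

`cellvar run` accepts a YAML config (`--config`) with per-stage sections
(`sim`, `qc`, `scvar`, `morphology`, `splicing`, `enrich`, `overlap`,
`phylo`, plus `stages`); unknown keys are rejected and all effective
values, seeds and filter counts are logged. Identical config + seed gives
byte-identical outputs.

## File formats

Expression matrices are read/written as dense TSV or MatrixMarket
(`.mtx`) with `features.tsv`/`cells.tsv` sidecars; cell metadata needs
columns `population`, `total_reads`, `mapped_reads`, `spikein_reads`.
Intron and junction tables are long-format TSV; gene sets are GMT; allele
frequencies are TSV with a `variant_id` column plus one column per
population; distance matrices are written as TSV or PHYLIP square format;
trees are newick.

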