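# degnet

Reconstruction of weighted substrate→product biodegradation meta-networks
from per-sample catabolic gene annotations, with metabolomics-calibrated
confidence that each chemical is degraded, and the comparative ecology layer
around them (diversity, ordination and cluster testing, temperature
regressions, fold-change contrasts, LC-MS feature filtering). A synthetic
study generator plants known structure — a linear temperature→catabolic
fraction, a richness–temperature anticorrelation, two community clusters and
a gene-count→degradation probability curve — so that every stage of the
pipeline can be tested for recovery of its ground truth.

## Layout

- `src/degnet/io_catalog.py` — domain types and TSV readers/writers for every
  artifact (hit tables, reaction catalogs, OTU tables, genome annotations,
  OTU→genome maps, metadata, metabolite evidence, feature matrices), plus
  GraphML/DOT/edge-TSV network export.
- `src/degnet/abundance.py` — hit screening (bit score > 45, e-value < 1e-3,
  both strict), family relative-abundance profiles (percent of total genes),
  taxonomy-based imputation and pooled-count merging of DNA with imputed
  evidence.
- `src/degnet/metaweb.py` — network construction (one edge per detected
  reaction, per-sample weights = family percentages), the monotone
  gene-count→confidence model (Laplace-smoothed tail frequencies +
  pool-adjacent-violators), degradable-chemical enumeration at a confidence
  threshold (default 0.90, inclusive), reachability and network comparison.
- `src/degnet/ecostats.py` — Shannon diversity (nats), Bray–Curtis /
  Hellinger-Euclidean distances, classical-scaling PCoA, best contiguous
  split along an ordination axis (Welch t), OLS regression, fold tests,
  two-step mass-feature filtering and validation accounting.
- `src/degnet/synthetic_data.py` — study generator with planted truth,
  focused generators for confidence-evidence and LC-MS feature matrices, and
  a compact default reaction catalog.
- `src/degnet/cli.py` — `degnet` command with `simulate`, `screen`,
  `impute`, `merge`, `network`, `confidence`, `stats`, `report`.

## CLI walkthrough

```sh
degnet --seed 7 simulate --outdir study/
degnet screen --hits study/hits_dna.tsv --totals study/totals_dna.tsv \
    --out-hits screened.tsv --out-totals screened_totals.tsv \
    --profile-out profiles_dna.tsv
degnet impute --otu-table study/otu_table.tsv --otu-map study/otu_map.tsv \
    --genomes study/genomes.tsv --out-hits imputed.tsv --out-totals imputed_totals.tsv
degnet screen --hits imputed.tsv --totals imputed_totals.tsv --source imputed \
    --out-hits imp_screened.tsv --out-totals imp_tot.tsv --profile-out profiles_imp.tsv
degnet merge --dna profiles_dna.tsv --imputed profiles_imp.tsv --out profiles.tsv
degnet network --profiles profiles.tsv --catalog study/catalog.tsv \
    --out network.tsv --format edge_tsv
degnet confidence --evidence study/evidence.tsv --gene-counts study/gene_counts.tsv \
    --out model.json --network network.tsv --degradable-out degradable.tsv
degnet stats --otu-table study/otu_table.tsv --profiles profiles.tsv \
    --metadata study/metadata.tsv --outdir stats/
degnet report --profiles profiles.tsv --degradable degradable.tsv --out summary.json
```

All tables are TSV with a mandatory header; `NA` marks missing values;
identifiers are preserved verbatim, and every writer round-trips through its
reader.

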