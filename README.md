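# mirmaster

miRNA master-regulator discovery on count matrices: from raw miRNA/mRNA
counts to consistently upregulated miRNAs, a mutual-information miRNA–mRNA
network, enrichment-based master-regulator (MMR) calls, per-regulator
Oncogenic Activity scores, and median-split survival stratification.
A first-class synthetic-cohort generator with serialized ground truth makes
every stage testable without external downloads.

## Pipeline stages

1. **synthetic** (`mirmaster.synthetic`) — negative-binomial cohorts
   (mean/size parameterization: `Var = mu + dispersion * mu^2`) with planted
   stage-correlated miRNAs, planted signed miRNA→gene edges, driver-role
   labels, mock target databases at configurable recall/precision, and
   exponential proportional-hazards survival coupled to regulator
   expression.
2. **normalization / DE** (`mirmaster.de`) — median-of-ratios size factors,
   a deterministic `log2(count/factor + 1)` variance-stabilizing stand-in,
   a per-feature NB Wald test (pooled method-of-moments dispersion), and
   Benjamini–Hochberg adjustment.
3. **stage filter** (`mirmaster.stage`) — miRNAs with FDR ≤ 0.05 and
   log2FC ≥ +0.5 in *every* stage-vs-normal contrast, plus a positive
   Spearman correlation (p ≤ 0.05) with clinical stage over tumors.
4. **network** (`mirmaster.network`) — rank-based adaptive-partitioning
   mutual information, a seeded permutation-null MI threshold, data
   processing inequality pruning (triangles closed through regulator-side
   MI), and bootstrap consensus with a Poisson support test.
5. **database filter** (`mirmaster.dbfilter`) — keep edges present in the
   union of the supplied target databases, with per-edge evidence.
6. **master regulators** (`mirmaster.mmr`) — regulons from the network,
   a probit gene signature from tumor-vs-normal DE, normalized enrichment
   scores against a size-matched gene-sampling null, BH-thresholded calls.
   A negative NES means the regulon's targets are downregulated in tumors.
7. **oncogenic activity** (`mirmaster.oncogenic`) —
   `Oe = (UONC + DTSG) − ONCTSG`, `Ae = (DONC + UTSG) − ONCTSG`,
   `OA = (Oe − Ae)/T`; regulators classify as oncogenic (OA > 0), neutral
   (OA = 0 or no driver targets) or suppressor (OA < 0).
8. **survival** (`mirmaster.survival`) — median dichotomization,
   Kaplan–Meier, two-group log-rank, and Cox regression (lifelines, Efron
   ties) with age/stage/ER/PR adjustment.

## CLI

```sh
mirmaster simulate --config cohort.yaml --outdir data/
mirmaster de --counts data/mrna_counts.tsv --meta data/metadata.tsv \
    --contrast tumor_vs_normal --out de_mrna.tsv
mirmaster stage-filter --de-dir out/ --expr data/mirna_counts.tsv \
    --meta data/metadata.tsv --out stage_filter.tsv
mirmaster network --mirna mirna_vst.tsv --mrna mrna_vst.tsv --boot 100 \
    --seed 7 --out network.tsv
mirmaster dbfilter --network network.tsv --db data/db_mockdb1.tsv --out filtered.tsv
mirmaster mmr --network filtered.tsv --de de_mrna.tsv --nnull 1000 --seed 7 \
    --out mmr_calls.tsv
mirmaster oa --regulons filtered.tsv --drivers data/driver_annotation.tsv \
    --de de_mrna.tsv --out oa.tsv
mirmaster survival --expr data/mirna_counts.tsv --meta data/metadata.tsv \
    --mirnas mir-001,mir-002 --out survival.tsv
mirmaster run --config pipeline.yaml --outdir out/
```

`mirmaster run` executes every stage from one YAML config with a single
seed fanned out into per-stage substreams; all intermediates are TSV and a
`manifest.json` records seed, thresholds and versions.  Two runs with the
same config and seed produce byte-identical outputs.

Minimal pipeline config:

```yaml
seed: 7
simulate:
  n_tumor: 300
  n_normal: 100
  n_mirna: 10
  n_mrna: 200
  planted_mmr_ids: [mir-001]
  planted_edges: [[mir-001, gene-0001, -1, 1.5]]
  stage_trend: 0.25
  tumor_lfc: 2.0
  databases: {n_dbs: 3, recall: 0.8, precision: 0.5}
thresholds: {de_fdr: 0.05, de_lfc: 0.5, corr_p: 0.05, mmr_fdr: 0.05}
network: {n_boot: 100, mi_p: 1.0e-4, dpi_tolerance: 0.0}
```

Existing data can be supplied instead of `simulate` via an `inputs` block
(`mirna_counts`, `mrna_counts`, `metadata`, optional `databases` and
`driver_annotation` paths, same TSV dialect as the generator writes).

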