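# nmfselect

Two-stage filter feature selection for ordinal clinical symptom matrices.

Given a samples x symptoms matrix of nonnegative integer severity codes with
a clinical stage label per sample, the pipeline:

1. **Screens irrelevant symptoms** — symptoms whose positive frequency
   (value > 0) is below a threshold (default 10%) in *every* clinical
   stratum are removed.
2. **Builds a representative sample** — within each stage class, the samples
   closest to the class centroid are taken, with per-level quotas on a
   binary covariate (default 40 per class, 20 male : 20 female).
3. **Factorizes** the representative matrix (features x samples) with
   KL-divergence NMF by multiplicative updates, selecting the rank by
   consensus clustering over restarts (cophenetic coefficient, with the RSS
   curve reported alongside) unless a fixed rank is configured.
4. **Groups redundant symptoms** — features are compared through their basis
   rows with a combined distance/correlation similarity; pairs with both
   similarities above a threshold (default 0.95) and the same dominant basis
   are linked, and connected components of size >= 2 form redundant groups.
5. **Compresses** each group into one mixed feature (member mean by default)
   and validates the selected subset with a grid-searched least-squares SVM
   (RBF kernel, stratified k-fold cross-validation).

A synthetic-data module generates cohort-shaped datasets (407 samples split
82/195/130 across three stages, 57 symptoms) with planted irrelevant
symptoms and planted redundant groups, so every stage of the pipeline is
testable with known ground truth.

## CLI

Each pipeline stage is a subcommand; `run-all` chains them:

```bash
nmfselect simulate --seed 1 --out data.tsv --truth truth.json
nmfselect screen data.tsv --out screened.tsv --threshold 0.10
nmfselect sample screened.tsv --per-class 40 --ratio 20:20 --out rep.tsv
nmfselect rank rep.tsv --min-rank 2 --max-rank 7 --out survey.tsv
nmfselect factorize rep.tsv --rank 3 --out-w W.tsv --out-h H.tsv
nmfselect similarity W.tsv --out-dir sims/
nmfselect transform screened.tsv W.tsv --theta 0.95 \
    --out-subset subset.tsv --out-groups groups.json
nmfselect validate rep.tsv test.tsv --groups groups.json --out acc.json
nmfselect run-all --input data.tsv --outdir out/ --seed 1
```

`run-all` accepts a YAML config (`--config cfg.yaml`) with any
`PipelineConfig` field; command-line flags override it.  All tabular
artifacts are TSV tagged with the configuration hash; group and accuracy
reports are JSON.

Datasets are delimited text with a header row, one sample per row, symptom
columns, and label columns `substage` / `stage` / `sex` (a transposed layout
is accepted via `orientation="symptoms"` in the API).

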