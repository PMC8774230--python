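# dbupipe

A tested pipeline for distinguishing two histologically similar tumor
classes from multi-study bulk expression data:

- **synthetic_data** — multi-batch surrogate generator with planted class
  effects, batch location/scale shifts, redundant probes of varying quality,
  and an RNA-seq-like (log-CPM) platform; every planted quantity is exposed
  as ground truth for recovery tests.
- **preprocess** — best-probe-per-gene collapse (specificity × coverage ×
  robustness), log-scale detection, merging on common genes, parametric
  empirical-Bayes location/scale batch adjustment, and a PCA batch audit
  (R² of batch vs histology groupings on PC1–2).
- **ensemble** — the consensus classifier: repeated random-gene-subset UMAP
  embedding + DBSCAN (eps from a k-distance elbow or fixed), assignment-
  problem label alignment across iterations, plurality voting with an
  inclusive 70% support threshold and an "ambiguous" call below it, plus a
  hyperparameter grid search and correlation-distance hierarchical
  clustering for validation.
- **signature** — moderated-t differential expression (variance shrinkage by
  digamma/trigamma moment matching), BH adjustment, rank-based AUROC,
  percentile-cutpoint sensitivity/specificity/accuracy profiling, and the
  staged selection cascade that emits a fixed-size marker panel.
- **enrichment** — preranked permutation GSEA: weighted running-sum
  enrichment score, per-size permutation null, sign-stratified NES, BH
  adjustment.
- **iohub / cli** — TSV/CSV/GMT/JSON readers and writers and the
  command-line entry points.

## CLI

All stages are exposed through one executable; stochastic stages take
`--seed` and every stage writes into the directory given by `-o`:

```sh
dbupipe simulate --seed 1 -o runs/sim                 # surrogate data + truth
dbupipe preprocess --expr runs/sim/expression.tsv \
    --pheno runs/sim/phenotype.csv \
    --annotation runs/sim/annotation.tsv -o runs/pre  # collapse/merge/adjust
dbupipe dbu --expr runs/pre/adjusted.tsv --pheno runs/sim/phenotype.csv \
    --iterations 1000 --seed 7 -o runs/dbu            # consensus classifier
dbupipe dge --expr runs/pre/adjusted.tsv --pheno runs/sim/phenotype.csv \
    -o runs/dge                                       # moderated t-tests
dbupipe signature --expr runs/pre/adjusted.tsv \
    --pheno runs/sim/phenotype.csv -o runs/sig        # 30-gene panel
dbupipe gsea --ranks runs/ranks.tsv --gmt sets.gmt --seed 3 -o runs/gsea
dbupipe validate --expr other/adjusted.tsv --pheno other/phenotype.csv \
    --signature runs/sig/signature.tsv -o runs/val
```

A YAML file can pre-set options per subcommand
(`dbupipe --config cfg.yaml dbu ...`); explicit flags win.

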