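# ptrkit

Analysis pipeline for paired microbial transcriptome/proteome studies:
protein-to-mRNA ratio (ptr) structure, essential-gene contrasts,
standardized-residual ptr-outlier detection, and gene-specific
RNA-to-protein (RTP) conversion factors with leave-one-out cross-condition
validation and a randomized (k = h) null — plus a synthetic-data module
that generates studies with the same statistical shape so the whole
pipeline is testable offline.

## Layout

| module | what it does |
| --- | --- |
| `ptrkit.synthetic` | multi-condition paired study generator with ground truth (`SyntheticConfig`, `generate_study`, `truth_rtp`) |
| `ptrkit.io_tables` | abundance TSVs, OrthoFinder-style `Orthogroups.tsv`, gene lists |
| `ptrkit.preprocess` | RPM normalization, PCR-hotspot filter, cross-condition protein scaling, detection rules, log2 profiles |
| `ptrkit.correlation` | Spearman/R², binned scatter, pairwise ortholog correlation matrices, protein-vs-mRNA conservation test |
| `ptrkit.essential` | essential vs non-essential contrasts, histogram summaries, expression-matched control |
| `ptrkit.outliers` | log2 protein~mRNA OLS, standardized residuals, high/low ptr classes, conserved outlier ranking |
| `ptrkit.rtp` | RTP factors, protein prediction, leave-one-out validation, randomized null |
| `ptrkit.stats` | exact Wilcoxon signed-rank (DP over sign assignments, ties handled), rank-sum policy |
| `ptrkit.pipeline` / `ptrkit.cli` | end-to-end orchestration, manifests, `ptrkit` CLI |

## CLI

```sh
# write a synthetic study (TSVs, Orthogroups.tsv, essential lists, truth)
ptrkit simulate --outdir out/sim --seed 1

# run the full pipeline from a config
ptrkit run --config pipeline.yaml --outdir out/run --seed 1
ptrkit report --outdir out/run
```

A config selects either a synthetic study or real files:

```yaml
# synthetic mode
synthetic:
  n_conditions: 9
  genes_per_condition: 2500

# ... or data mode
data:
  conditions:
    - {id: Pa, mrna: Pa_mrna.tsv, protein: Pa_protein.tsv, essential: Pa_ess.txt}
    - {id: Sa, mrna: Sa_mrna.tsv, protein: Sa_protein.tsv}
  orthogroups: Orthogroups.tsv
options:
  hotspot_threshold: 100000
  null_draws: 200
```

Outputs per run: `detection.tsv`, `correlations.tsv`, pairwise
`pair_counts.tsv` / `pair_rho_{mrna,protein}.tsv`, `outlier_counts.tsv`,
conserved ranking matrices, `loo.tsv` with the aggregate signed-rank test,
`null_deltas.tsv`, a `summary.json` assembled from the stage TSVs, and a
`manifest.json` with config hash, derived per-stage seeds, and input
checksums.

## Abundance table format

TSV with a gene-ID column followed by one column per replicate; mRNA tables
hold raw counts (RPM is applied by the pipeline), protein tables hold
reporter-ion-style linear abundances with 0 meaning not observed in that
replicate.
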