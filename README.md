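# m6apattern

Analysis of N6-methyladenosine (m6A) modification patterns in rheumatoid
arthritis (RA) transcriptomes. RA is clinically heterogeneous and
response to biologics such as infliximab is hard to predict; the
expression of the 20 canonical m6A regulators (8 writers, 2 erasers, 10
readers) provides a molecular axis for stratifying patients. This
package implements that analysis as a tested, configurable pipeline for
bulk expression data, together with a synthetic-cohort generator that
plants every structure the pipeline is meant to recover:

1. **Diagnosis** — stratified 70/30 split, SMOTE balancing of the
   healthy-control minority, a random-forest RA-vs-HC classifier on the
   regulator panel, and a tie-corrected Mann–Whitney ROC/AUC.
2. **Modification patterns** — Monti-style consensus clustering of RA
   samples over the regulators, with CDF/delta-area and silhouette
   diagnostics selecting the number of clusters k.
3. **Immune profiling** — single-sample GSEA (ssGSEA) enrichment of
   immune-cell and pathway gene sets, compared across clusters by
   Wilcoxon/Kruskal–Wallis with BH correction; the same comparison shows
   the clusters are blind to DAS28 disease activity.
4. **Shared DEGs** — empirical-Bayes moderated t-tests between the three
   clusters (p < 0.05), three-way intersection, and hypergeometric
   over-representation against user-supplied gene sets (GMT).
5. **m6Ascore** — shared DEGs split into positively/negatively
   correlated sign groups, Boruta shadow-feature pruning, and the
   PCA-subtraction score

   `score = Σ PC1_i − Σ PC1_j`

   (first principal component of the positive block minus that of the
   negative block, each oriented to track its block's mean expression).
   Samples split at the median score; a lower score predicts infliximab
   response.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic cohort (300 RA / 100 HC, three planted regulator subgroups,
four immune signature blocks, a 154-sample infliximab arm with 77
responders carrying a one-sd lower latent signature activity). They are
thin drivers over the library and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_diagnosis_model.py
python analysis/03_consensus_clusters.py
python analysis/04_immune_profiling.py
python analysis/05_shared_degs.py
python analysis/06_m6a_score_response.py
```

Output of a full run (seed 1):

```
cohort: 620 genes x 400 samples (300 RA, 100 HC)
held-out ROC AUC = 1.000 -> the regulator panel separates RA from healthy controls
 k  cdf_area  delta_area  silhouette
 2     0.501       0.501       1.000
 3     0.631       0.258       1.000
 4     0.640       0.014       0.969
chosen k = 3; cluster sizes {'C1': 147, 'C2': 83, 'C3': 70}
adjusted Rand index vs planted subgroups = 1.000
DAS28 omnibus p-values by cluster (expect > 0.05): {'das28_esr': 0.265, 'das28_crp': 0.925}
shared DEGs across all three contrasts: 100
immune sets over-represented in the shared DEGs: ['IMM1', 'IMM2', 'IMM3', 'IMM4']
sign groups after Boruta: 75 positive, 22 negative genes
median m6Ascore by cluster: {'C1': 1.84, 'C2': 8.63, 'C3': -12.45}
infliximab arm: responders median -7.51 vs non-responders 3.10;
Wilcoxon p = 5.05e-12; response ROC AUC = 0.808
-> responders carry a lower m6Ascore in this cohort
```

Reading the numbers: the delta-area curve collapses after k = 3 (0.258
to 0.014), so three modification patterns are selected and they match
the planted subgroups exactly; the 100 shared DEGs are precisely the
planted signature genes; and in the treated arm the fitted score is
systematically lower in responders, so ranking patients by −score
predicts response (AUC 0.81).

The same experiment is available as one command through the CLI:

```sh
m6apattern run --outdir my_run            # full synthetic experiment
m6apattern simulate --outdir data --seed 1  # just write a cohort
m6apattern --help                           # per-stage subcommands
```

Real data enter through plain formats: expression as a genes-by-samples
TSV, metadata as CSV (disease status, cohort, DAS28, treatment,
response), gene sets as GMT.

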