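# codep

Drug–gene co-dependency discovery and translational validation pipeline for
matched pharmacogenomic screens.

The package implements an end-to-end, fully seedable analysis chain:

1. **discovery** — for each drug with an annotated on-target gene, fit
   `AUC ~ on-target dependency` (OLS), correlate the residuals with every
   other gene's dependency profile, fit a combined two-covariate model for
   the leading candidates, and prioritize pairs by the gain in explained
   variance (ΔR²) with Benjamini–Hochberg FDR control on the partial
   correlation p-values.
2. **robustness** — permutation testing (AUC label shuffles),
   leave-one-line-out refitting, and random-drug specificity testing per
   retained interaction.
3. **cohort_validation** — test whether co-target *expression* predicts
   ex vivo drug response (AUC) in a primary-specimen cohort, with and
   without the on-target gene as covariate; quartile contrasts,
   negative-control drug panels, and resistance correlations.
4. **survival** — composite two-gene linear predictor (sum of z-scores),
   median-split Kaplan–Meier + log-rank, Cox proportional hazards (Efron
   ties, Newton iteration) across a ladder of progressively adjusted
   models, IPCW time-dependent AUC at yearly horizons, and
   mutation-subgroup contrasts.
5. **signature** — projection of the signature onto a cell-type-labelled
   expression atlas (per-type means, fold enrichment) and a genome-wide
   Spearman correlation landscape ranked against the linear predictor.
6. **enrichment** — preranked GSEA (weighted KS running sum, gene-label
   permutation null, sign-matched NES, sign-pooled FDR) and simplified
   regulon activity (signed mean of z-scored target expression) correlated
   with the linear predictor.
7. **synthetic_data** — generators for every input the pipeline consumes
   (panel, cohort, atlas, gene sets/regulons) with planted effects of known
   size and a ground-truth manifest, so every stage is testable offline.
8. **stats_core** — shared oracle-tested primitives (Pearson/Spearman and
   partial correlations, BH adjustment, rank-sum test, z-scores).

Conventions: lower AUC = greater drug sensitivity; more negative dependency
score = more essential gene; survival times in days, AUC horizons in years
(365.25 d/y); pairwise-complete missing-data handling with the used `n`
reported everywhere; midranks for ties; two-sided p-values.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence, type-I/power calibration of the screen, permutation
calibration, Cox recovery and CI coverage, time-dependent AUC sanity,
projection recovery, GSEA oracle, end-to-end byte determinism), one test
class per criterion.

## CLI

Every command reads/writes plain text (TSV/GMT/JSON) and takes `--seed`
wherever randomness is involved.

```bash
# generate synthetic inputs (spec files are YAML/JSON parameter overrides)
codep simulate panel  --spec panel.yaml  --seed 7 --out-dir data/panel
codep simulate cohort --spec cohort.yaml --seed 7 --out-dir data/cohort
codep simulate atlas  --spec atlas.yaml  --seed 7 --out-dir data/atlas
codep simulate sets   --universe data/cohort/expression.tsv --seed 7 \
      --out-dir data/sets

# discovery screen + robustness metrics
codep discover --auc data/panel/auc.tsv --dependency data/panel/dependency.tsv \
      --annotations data/panel/annotations.tsv --delta-r2-min 0.02 \
      --fdr 0.01 --top-k 50 --screen-method spearman --out interactions.tsv
codep robustness --interactions interactions.tsv --auc data/panel/auc.tsv \
      --dependency data/panel/dependency.tsv \
      --annotations data/panel/annotations.tsv \
      --n-perm 200 --n-random 100 --seed 7 --out interactions_robust.tsv

# cohort validation, survival, signature, enrichment
codep validate --cohort-dir data/cohort --interactions interactions.tsv \
      --mapping mapping.tsv --fdr 0.05 --out validation.tsv
codep survival --cohort-dir data/cohort --genes SRC,ACSL4 \
      --horizons 1,2,3 --out survival_out/
codep project  --atlas data/atlas/atlas_expression.tsv \
      --labels data/atlas/atlas_labels.tsv --genes SRC,ACSL4 --out proj.tsv
codep landscape --expression data/cohort/expression.tsv \
      --genes SRC,ACSL4 --out landscape.tsv
codep gsea --expression data/cohort/expression.tsv --sets sets.gmt \
      --n-perm 1000 --seed 7 --out gsea.tsv
codep regulons --expression data/cohort/expression.tsv \
      --regulons regulons.tsv --min-size 10 --out regulons_out.tsv
```

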