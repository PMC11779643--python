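# regionsig

Toolkit for evaluating prognostic gene-expression signatures on multiregion
tumor RNA-seq cohorts: linear signature scoring with affine batch correction
and risk dichotomization, four tumor-sampling-bias metrics with signature
ranking, a survival-validation layer (Cox, Kaplan-Meier/log-rank, a
pseudo-single-biopsy bootstrap, Harrell's C, variance explained over
follow-up time, fixed-effect meta-analysis, linear mixed-effects trends),
association analyses (driver-mutation enrichment, drug-sensitivity
screening, determinants regression) and a synthetic multiregion cohort
generator that provides ground truth for every pipeline stage.

## Library overview

| module                   | contents |
|--------------------------|----------|
| `regionsig.signature`    | `SignatureModel`, YAML/TSV signature configs |
| `regionsig.cohort`       | `ExpressionCohort` (genes x samples + sample sheet, optional TPM layer) |
| `regionsig.scoring`      | low-TPM gene filter, region scoring, batch correction, risk classes & patient aggregation |
| `regionsig.bias`         | discordance rate, clustering-concordance AUC, per-gene variability, within/between-tumor variance decomposition, biopsies-to-stability, signature ranking |
| `regionsig.survival`     | `fit_cox`, `km_logrank`, `pseudo_single_biopsy_bootstrap`, `concordance_index`, `pve_over_time`, `meta_fixed_effect`, `mixed_effects_trend` |
| `regionsig.associations` | Fisher-exact driver enrichment, IC50 drug screen with missing-data filters, determinants OLS |
| `regionsig.simulate`     | `SyntheticCohortSpec` and generators for expression, survival, screens and mutation tables |

A minimal end-to-end run:

```python
from regionsig import (SyntheticCohortSpec, simulate_multiregion_expression,
                       simulate_survival, score_cohort, compute_bias_report,
                       pseudo_single_biopsy_bootstrap)

spec = SyntheticCohortSpec(n_patients=200, tau2=2.0, sigma2=1.0, seed=0)
cohort, truth = simulate_multiregion_expression(spec)
sig = truth["signature"]                      # or regionsig.load_signature("sig.yaml")
profile = score_cohort(cohort, sig)
report = compute_bias_report(cohort, sig, profile, theta=0.2)
clinical = simulate_survival(truth["z"], spec)
boot = pseudo_single_biopsy_bootstrap(profile, clinical, "os", seed=7)
```

## Command line

```bash
regionsig simulate --spec spec.yaml --out cohort/      # expr/tpm/samples/clinical/truth
regionsig score --expr X.tsv --samples S.tsv --signature oracle.yaml \
    [--tpm T.tsv] --out scores.tsv --patient-out patients.tsv
regionsig bias --expr X.tsv --samples S.tsv --signatures configs/ \
    --theta 0.2 --out bias_report.tsv
regionsig survival --scores patients.tsv --clinical clin.tsv --endpoint os \
    --adjust age,sex,pack_years,adjuvant,stage,grade --out cox.tsv
regionsig pseudobiopsy --scores scores.tsv --clinical clin.tsv \
    --n-iter 1000 --seed 7 --out boot.json
regionsig enrich --scores scores.tsv --mutations muts.tsv --out enrich.tsv
regionsig screen --scores lines.tsv --ic50 ic50.tsv --pathways p.tsv --out screen.tsv
```

Signature configs are YAML (see `src/regionsig/configs/example_signature.yaml`)
or two-column gene/weight TSVs; weights and thresholds come from the
signature's source publication. The batch-correction fields map scores from
an updated preprocessing pipeline back onto the scale the threshold was
defined on (identity by default).

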