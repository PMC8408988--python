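# hrdimmune

Combined homologous-recombination-deficiency (HRD) and immune-activation
analysis for predicting response to anthracycline + cyclophosphamide +
taxane (ACT) chemotherapy in triple-negative breast cancer (TNBC).

TNBC tumours frequently carry defects in homologous-recombination repair
(HRR) of DNA double-strand breaks — through BRCA1/2 mutation, BRCA1
promoter hypermethylation, or other lesions — and such tumours are
unusually sensitive to DNA-damaging chemotherapy. But HRD alone does not
identify all responders: tumours with an activated immune
microenvironment also do well. This package implements, as a tested
pipeline, the combined classifier **responder-positive ⇔ HRD ∨
immune-score-positive**, together with every ingredient it needs, for
bioinformaticians analysing allele-specific copy-number, mutation,
expression, methylation and clinical outcome data.

## What it computes

* **Genomic scars** — LOH, telomeric allelic imbalance (ntAI) and
  large-scale state transitions (LST) from allele-specific segments;
  HRD score = LOH + ntAI + LST; HR-deficient ⇔ deleterious tumour
  BRCA1/2 mutation or score ≥ 42. Plus BRCA1 promoter-methylation calls
  (cg13782816 β > 0.9) and tumour mutation burden.
* **Mutational signatures** — 96-channel trinucleotide spectra;
  per-sample exposures by forward selection with non-negative
  least-squares refitting (6% drop floor); SBS3 dominance (≥ 0.3); an
  HRDetect-style lasso-logistic deficiency classifier over
  {HRD score, SBS1/3/6/20 exposures, insertion/deletion ratio}.
* **Immune scores** — rank-based single-sample gene-set activity
  (ssGSEA statistic, exponent 0.25); IS = Σ pathway activities or mean
  marker expression; IS⁺ = top quartile.
* **Transcriptional HRD signature** — negative-binomial differential
  expression (FDR ≤ 0.05, |FC| ≥ 2) → univariate Cox on the failure-free
  interval (FFI) → lasso-logistic reduction; prognostic scores

      PS_i = Σ_j Exp_ij / HR_j        (up and down factors separately)
      HRDPS_i = PS_i,up − PS_i,down

  where Exp is log expression and HR_j the factor's univariate hazard
  ratio (up factors protective, HR < 1; down factors risk, HR > 1).
* **Cohort statistics** — Kaplan-Meier/log-rank, Cox PH (Efron ties)
  with Wald CIs, nested-model likelihood-ratio tests, time-fixed ROC/AUC
  at 60 months, Fisher's exact test (both sidedness variants),
  Wilcoxon/Kruskal-Wallis with BH correction and permutation p-values.
* **Synthetic cohorts** — a generator that plants the structure above
  (57.8% HRD prevalence, BRCA1/2 at 7.2%/6.0%, FFI hazard ratio 0.16 for
  HRD, immune activation in 25%, a 4-up/11-down expression signature,
  bimodal methylation) and returns the ground truth, so every stage is
  testable without access to patient data.

## Worked example

```python
import pandas as pd
import hrdimmune as h

# simulate an 83-patient discovery cohort with planted effects
bundle, truth = h.generate_cohort(h.CohortConfig(seed=7, n_genes=400))

report = h.run_discovery(bundle)
s = report["survival"]
print(f"HR deficiency: {report['hr_status']['n_deficient']}/{report['n_samples']}")
print(f"FFI hazard ratio (HRD, adjusted): {s['ffi_hr_hrd']:.3f}"
      f"  CI [{s['ffi_hr_hrd_ci'][0]:.3f}, {s['ffi_hr_hrd_ci'][1]:.3f}]")
print(f"5-year AUC combined={s['auc_combined']:.2f}  HRD alone={s['auc_hrd_alone']:.2f}")
```

prints

```
HR deficiency: 48/83
FFI hazard ratio (HRD, adjusted): 0.145  CI [0.077, 0.275]
5-year AUC combined=0.75  HRD alone=0.74
```

i.e. in this 83-sample draw HR deficiency is strongly protective for the
failure-free interval (hazard ratio 0.145 with CI excluding 1), and the
combined HRD-or-immune classifier edges out HRD status alone on the
5-year time-fixed AUC; the advantage becomes statistically reliable at a
few hundred samples (see the acceptance checks). The same run is
available from the shell:

```bash
hrdimmune simulate --n-samples 83 --seed 7 --out cohort/
hrdimmune discover --cohort cohort/ --out report.json
```

`hrdimmune --help` lists the remaining commands (`scars`, `brca1meth`,
`signatures`, `immune`, `hrdps derive/score`, `survival km`, `validate`).

## Layout

```
src/hrdimmune/
  genome.py      chromosome/centromere annotations (toy + simulation genomes)
  scars.py       LOH/ntAI/LST, HRD score, HR status, methylation, TMB
  signatures.py  96-channel spectra, exposure fitting, HRDetect-style model
  immune.py      ssGSEA-style activity, immune scores, quartile positivity
  expression.py  DE, Cox screen, lasso reduction, PS/HRDPS
  stats.py       KM/log-rank, Cox, LR test, time-fixed ROC, Fisher, rank tests
  synthetic.py   cohort generator with ground truth
  pipeline.py    FFI derivation, ACT labels, combined status, end-to-end runs
  cli.py         click command-line interface
```

See `docs/methods.md` for the models, defaults and their rationale, the
generator's assumptions, and known limitations.
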