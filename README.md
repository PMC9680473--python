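# ivimdce

Quantitative MRI modelling for discriminating benign from malignant
**BI-RADS 4 breast lesions** — a tested, fully synthetic, desk-scale
re-implementation of the analysis chain used in clinical IVIM + DCE-MRI
studies. It is written for radiology researchers and methodologists who
want to exercise, validate, or extend this kind of pipeline without access
to patient images.

The chain:

1. **Synthetic cohort** — 20 benign / 80 malignant lesions with ground-truth
   diffusion and pharmacokinetic parameters drawn from literature-derived
   per-group distributions; voxelwise maps with calibrated intra-lesion
   heterogeneity; multi-b DWI signals with Rician noise and DCE
   concentration curves with additive noise; two simulated readers with
   agreement calibrated to published inter-reader ICCs.
2. **Diffusion fitting** — two-point ADC, `ADC = ln(S₀/S₈₀₀)/800`, and the
   segmented IVIM fit of
   `S(b)/S₀ = (1−f)·e^(−bD) + f·e^(−b(D+D*))`
   (D from b > 200 s/mm², then f and D* with D fixed).
3. **Pharmacokinetic fitting** — the extended Tofts model
   `Ct(t) = v_p·Cp(t) + K^trans·∫₀ᵗ Cp(τ)·e^(−k_ep(t−τ)) dτ`
   by the Murase linear least-squares formulation, on a 7.84 s/frame,
   42-frame grid with a Parker-type population AIF.
4. **ROI summaries** — mean/min/max (diffusion) and min/max/median/mean
   (pharmacokinetic) per lesion, honouring exclusion masks.
5. **Agreement screening** — ICC(2,1) per parameter; parameters below 0.75
   are removed before analysis.
6. **Group statistics** — Shapiro–Wilk-gated t-test / Mann–Whitney U with
   Levene-selected t variant, mean±SD or median(IQR) presentation.
7. **Diagnostic models** — five logistic models (ADC, IVIM, DCE, DCE+ADC,
   DCE+IVIM) built by forward likelihood-ratio selection (entry p < 0.05),
   compared by ROC/AUC with DeLong standard errors, Youden operating
   points, pairwise DeLong tests, and leave-one-out cross-validation.

See `docs/methods.md` for the full model descriptions, calibration
rationale, and limitations.

## Worked example

```python
from ivimdce.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(outdir="run"))   # default 100-lesion cohort
print(report.warnings)
cols = ["model", "variables", "auc", "ci_low", "ci_high",
        "loocv_accuracy", "sensitivity_pct", "specificity_pct"]
print(report.tables["model_performance"][cols].round(3).to_string(index=False))
```

prints (default seed 20221031):

```
['parameter Dstar_min removed (ICC=0.534 < 0.75)']
         model                                                            variables   auc  ci_low  ci_high  loocv_accuracy  sensitivity_pct  specificity_pct
     model_ADC                                                             ADC_mean 0.772   0.649    0.894            0.81             70.0             80.0
    model_IVIM                                                    D_max, Dstar_mean 0.796   0.691    0.900            0.80             70.0             80.0
     model_DCE                                         Kep_min, Ktrans_mean, Ve_min 0.915   0.855    0.975            0.84             92.5             80.0
 model_DCE+ADC          ADC_mean, Kep_max, Ktrans_mean, Ve_min, Kep_median, Kep_min 0.976   0.952    1.000            0.92             90.0            100.0
model_DCE+IVIM Kep_max, D_max, Kep_min, Ktrans_mean, Dstar_mean, Ve_min, Kep_median 0.981   0.958    1.000            0.91             95.0            100.0
```

Reading this: the pseudo-diffusion minimum is screened out for poor
inter-reader agreement before any modelling; the ADC-only model is the
weakest discriminator (AUC 0.77) and the combined DCE+IVIM model the
strongest (AUC 0.98 on this single synthetic cohort, with high sensitivity
at the Youden point). Variable lists from a single 100-lesion cohort are
unstable — with ~19 candidates, forward selection routinely admits extra
correlated variables — so conclusions about *which* parameters matter
should come from repeated cohorts: across 200 simulated cohorts the modal
leading pair of the combined model is {Kep_max, D_mean} and mean AUC orders
as DCE+IVIM ≥ IVIM ≥ ADC (this is part of the acceptance test suite).

The benign-vs-malignant comparison table (`report.tables["comparison"]`)
shows the expected physiology: diffusion metrics lower in malignant lesions
(cellularity restricts water), perfusion fraction and k_ep higher
(angiogenesis and permeability), v_e uninformative.

A command-line interface mirrors the library stages:

```sh
ivimdce run-all --seed 7 --outdir run7
ivimdce simulate --outdir cohort && ivimdce fit-dwi --outdir cohort
ivimdce screen --readers run7/reader_table.csv --out icc.csv
```

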