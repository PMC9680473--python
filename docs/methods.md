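# Methods

This note records the models, the synthetic-cohort design, the numerical
choices, and the known limitations of `ivimdce`. It is the authoritative
description of *why* the package behaves as it does; the README shows *how*
to run it.

## Scientific setting

BI-RADS 4 breast lesions carry a malignancy probability anywhere between 2%
and 95%, so biopsy is routinely recommended — including for the substantial
fraction of lesions that turn out benign. Quantitative MRI offers
non-invasive discriminators: diffusion-weighted imaging (ADC and the IVIM
decomposition into pure diffusion D, pseudo-diffusion D\*, and perfusion
fraction f) and dynamic contrast-enhanced imaging (extended-Tofts
pharmacokinetics: K^trans, k_ep, v_e). The package implements the complete
desk-scale analysis chain for such a study: forward simulation of a lesion
cohort, voxelwise model fitting, ROI summarisation, inter-reader agreement
screening, group statistics, and diagnostic-model construction and
comparison.

## Signal models

**ADC (mono-exponential), two-point form.**
`ADC = ln(S(0)/S(800)) / 800` in mm²/s, from the b = 0 and b = 800 s/mm²
samples only.

**IVIM (bi-exponential).**
`S(b)/S0 = (1−f)·exp(−bD) + f·exp(−b(D+D*))`.
The production estimator is the classical segmented fit:

1. ordinary least squares of ln S(b) on b restricted to b **strictly**
   greater than 200 s/mm² (i.e. b ∈ {400, 600, 800}), giving D — the
   pseudo-diffusion term is negligible there;
2. with D fixed, bounded nonlinear least squares over (S0, f, D\*) on all
   nine b values, with f ∈ [0, 1] and D\* ∈ [D, 0.5 mm²/s], initialised at
   f₀ = 1 − exp(intercept)/S(0) and D\*₀ = 10·D.

S0 is refit jointly in step 2 (only D is frozen). Non-positive signal
samples are rejected rather than clipped; at the simulated noise levels they
essentially never occur (magnitude noise is strictly positive). A perfectly
flat signal takes the degenerate branch D = 0, f = 0, converged.

A free four-parameter fit (`fit_ivim_full`) exists as a cross-check oracle
only; it is initialised at the segmented solution, so its residual is never
worse — tests use this as a nesting invariant.

For whole-cohort maps a batched variable-projection version is used: with D
fixed, the model is linear in the two compartment amplitudes, so D\* is
profiled on a log-spaced coarse grid (48 points) refined once (24 points)
around the per-voxel optimum. Agreement with the scalar optimizer is tested
at the 2% level on noisy voxels and much tighter on noiseless ones.

**Extended Tofts.**
`Ct(t) = vp·Cp(t) + Ktrans·∫₀ᵗ Cp(τ)·exp(−kep(t−τ)) dτ`.
The production estimator is the Murase linearisation: cumulative-trapezoid
integrals of Cp and Ct on the grid (in minutes) enter the regression
`Ct = α∫Cp + β∫Ct + γCp`, solved by least squares, with
kep = −β, vp = γ, Ktrans = α − kep·vp, and ve = Ktrans/kep clamped to
[0, 1]. `converged` is false when kep ≤ 0, the design is rank-deficient, or
the curve is identically zero; negative Ktrans/vp are clamped to zero with a
quality flag (mirroring how clinical mapping software floors negative rate
estimates — visible as the 0.000 minima such software reports).

The DCE grid defaults to 7.84 s/frame, 42 frames, bolus at the start of
frame 4 (frames 1–3 are zero-concentration baseline; injection delay within
frame 4 is taken as 0 s). The pipeline operates in concentration space; the
signal-to-concentration conversion (T1 mapping, relaxivity) is explicitly
out of scope, so absolute K^trans values are comparable only within the
package, not against any particular vendor implementation.

**AIF.** A Parker-type population input (two Gaussian boluses plus a
sigmoid-gated exponential washout, mM, time in minutes), shifted to the
injection frame and zero before it. Weinmann-style bi-exponential and
tabulated forms are available behind the same interface.

**Forward DCE simulation** uses the closed-form exponential-kernel
convolution for a piecewise-linear Cp (an exact recursion, not a rectangle
rule); tests verify it against adaptive quadrature to better than 0.1%.

## Synthetic cohort design

The generator emulates a 20-benign / 80-malignant cohort whose ROI-summary
distributions match a reference population table of per-group statistics
(means ± SD for normally-reported parameters, medians with interquartile
ranges for skewed ones, and per-parameter inter-reader ICCs).

**Lesion-level truth.**

| parameter | distribution | source row |
|---|---|---|
| D | truncated normal (mean ± SD) | D_mean |
| D\* | log-normal (median/IQR matched), capped at 0.15 mm²/s | D\*_mean |
| f | log-normal (median/IQR matched) | f_mean |
| k_ep | log-normal (median/IQR matched) | Kep_mean |
| v_e | log-normal (median/IQR matched), clamped ≤ 1 | Ve_mean |
| K^trans | **derived**: kep·ve | — |
| v_p | Uniform(0.005, 0.05) | not reported; exercises the extended model |

Log-normal matching is closed-form: μ = ln(median),
σ = ln(Q3/Q1)/(2·z₀.₇₅) — the median and the quartile *ratio* are matched
exactly (a two-parameter family cannot also centre the quartiles
asymmetrically). Invariants (D\* ≥ D, 0 ≤ f ≤ 1, kep > 0) are enforced by
rejection. With all width parameters scaled to zero every draw equals the
group central value exactly, which downstream fits then recover to numerical
precision — the core identifiability check.

Deriving K^trans as kep·ve rather than sampling it independently encodes the
model constraint kep = K^trans/v_e. It also reproduces the reference table's
internal structure remarkably well (malignant median 0.61 × 0.68 = 0.41
vs the printed 0.39; log-spread √(0.55² + 0.61²) = 0.82 vs 0.83) and keeps
v_e group-uninformative, as the reference comparisons show (no significant
v_e row; Ve_max pinned at 1.00 in both groups). The D\* truth cap at
0.15 mm²/s removes the non-physiological upper tail that median/IQR-matched
log-normals otherwise extrapolate.

**Intra-lesion heterogeneity.** Each voxel parameter is the lesion value
times a *split* log-normal multiplier `exp(σ_low·Z)` for Z < 0 and
`exp(σ_high·Z)` for Z ≥ 0. The two sides are calibrated separately so the
expected single-voxel extreme of an n-voxel ROI reproduces the reference
min-row and max-row to mean-row ratios: σ = |ln r|/z_n, with z_n the
expected extreme of n standard normals (computed by quadrature). The
asymmetry is required by the data: D_min sits proportionally far below
D_mean (low-diffusivity voxel tails) while D_max sits only ~7% above it.
Rows that are floor-clamped artefacts (Kep_min = 0.000) and the one
internally-inconsistent printed IQR (benign D\*_max) are excluded from the
relevant calibrations; derived v_e needs no heterogeneity of its own
(voxel ve = voxel Ktrans / voxel kep, clamped — which pins the measured
Ve_max at 1.00, exactly as the reference table shows).

**Noise.** DWI magnitude noise is Rician: each sample becomes
√((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, σ²). The default σ = 5 at S0 = 1000
(map-effective SNR 200) represents vendor parameter maps after spatial
filtering rather than raw acquisitions: with raw-acquisition noise the
simulated ROI extremes would far exceed the reference extreme-to-mean ratios
(e.g. D_max/D_mean ≈ 1.4 instead of the printed 1.07). Concentration curves
receive additive Gaussian noise (default SD 0.02 mM against peak tissue
concentrations of roughly 0.3–1 mM).

**Readers.** Two readers are simulated per parameter by adding independent
Gaussian noise with SD σ_b·√((1−ICC)/ICC) to the true ROI summary, where
σ_b is the between-lesion SD and ICC is the per-parameter reference
agreement. Expected ICC(2,1) then equals the target by construction; the
poorly reproducible parameters (D\*_min at 0.419, Kep_min at 0.701) fall
below the 0.75 retention cutoff in most realisations. Post-screening
analysis uses the mean of the two readers (a declared convention; which
reader fed the reference analysis is unknowable).

**What the generator does not emulate:** spatial voxel correlation and
anatomy (voxels are exchangeable draws), k-space/partial-Fourier artefacts,
B1/motion effects, lesion-to-lesion variation of heterogeneity within a
group (σ's are fixed per group/parameter — real extreme summaries are
noisier across lesions than simulated ones), or any correlation between
diffusion and pharmacokinetic truth beyond the kep–K^trans link. Passing
tests therefore demonstrate correctness of the estimators and the
statistical machinery under the stated population model — not performance
on real images.

## Statistical pipeline

**ICC.** ICC(2,1) — two-way random effects, absolute agreement, single
measurement — from the ANOVA mean squares. A zero-variance table is
degenerate and reported as 1.0 with a flag. The retention cutoff 0.75
("good" agreement) reproduces the reference screening exactly: it separates
0.419/0.701 from the ≥ 0.82 block.

**Group comparison.** Shapiro–Wilk per group at α = 0.05; both groups
normal → independent-samples t-test (pooled vs Welch chosen by Levene with
mean centring at α = 0.05) and mean ± SD presentation; otherwise
Mann–Whitney U (exact when both groups ≤ 20 without ties, otherwise the
tie-corrected normal approximation without continuity correction) and
median (Q1, Q3) presentation with linear-interpolation quantiles. Constant
samples are treated as non-normal. No multiple-testing correction is
applied, matching standard practice in this literature for single-cohort
descriptive tables.

**Diagnostic models.** Five candidate families: ADC summaries; IVIM
summaries (D, D\*, f); DCE summaries (K^trans, k_ep, v_e); and the DCE+ADC
and DCE+IVIM unions — always restricted to screened parameters. Variables
enter by forward likelihood-ratio selection: at each step the candidate with
the smallest LR chi-square p-value (df = 1) enters if p < 0.05, then
included variables are retested and removed at p ≥ 0.10 (the conventional
Forward:LR removal default; the entry threshold is the stated criterion).
The inner maximum-likelihood fits use Newton/IRLS; complete separation is
detected (the Newton path fails) and the refit coefficients are capped at
±30 on the log-odds scale with a flag.

**ROC.** AUC by the rank (Mann–Whitney) estimator; SE and 95% CI by the
DeLong structural-components method (normal approximation, CI clipped to
[0, 1]). Operating point by the Youden index over all achievable cuts,
scanning thresholds from high to low so ties break toward higher
specificity — the biopsy-sparing direction. Correlated AUCs are compared
with the DeLong test on placement values; a model against itself (zero
variance of the difference) is degenerate with p = 1.

**LOOCV.** Variable selection is frozen at the full-data selection; each
fold refits coefficients on n−1 lesions and classifies the held-out lesion
at probability 0.5. A failed fold fit counts as misclassified. Both LOOCV
and apparent accuracy are reported, because with a 20/80 class split the
0.5-cutoff accuracy is dominated by the base rate (a null model already
achieves ≈ 0.8) and neither is individually interpretable.

With ~19 screened candidates and n = 100, forward selection is an unstable
statistic: after two genuinely informative variables enter, each remaining
candidate still has roughly a 5% chance of entering, so three-or-more
variable selections are common and the exact selected set varies across
seeds. Repeated-cohort summaries therefore track the *leading pair* (first
two variables entered), which is stable: across 200 cohorts the modal
leading pair of the combined DCE+IVIM model is {Kep_max, D_mean}, and mean
AUC orders as DCE+IVIM ≥ IVIM ≥ ADC.

## Numerical choices and problem sizes

- Optimiser tolerances 1e-14 (scalar trust-region fits); batched D\*
  profiling uses a 48-point coarse / 24-point refined log grid.
- The linear extended-Tofts estimator carries a documented discretization
  bias at 7.84 s sampling: kep within 1% up to ≈ 1.8 min⁻¹, ≈ 1.3% at
  3 min⁻¹; vp absorbs the bolus-peak residual (absolute error up to
  ≈ 0.003) and is bounded absolutely, not relatively, in tests.
- All randomness flows from one seeded NumPy generator; a fixed seed makes
  cohorts, fits and output files byte-reproducible. Default seed 20221031.
- Internal units are mm²/s, fractions, and min⁻¹; reported tables use
  10⁻³ mm²/s, percent, and min⁻¹.
- Test problem sizes: 10⁴ draws for sampling statistics, 200 Rician
  replicates for the D\* instability check, 2000 null simulations per
  type-I calibration, 200 cohorts for the repeated-cohort model study,
  exhaustive 252-permutation enumeration for the small-sample Mann–Whitney
  oracle, and a 10⁵-replicate paired bootstrap for the DeLong cross-check.

## Known limitations

- The measurement chain is calibrated to reproduce *summary-level*
  population structure; it is not an image simulator, and absolute
  pharmacokinetic scales depend on the chosen population AIF.
- Forward selection instability (above) means single-cohort variable lists
  should not be over-read; only repeated-cohort statements are robust.
- Fixed per-group heterogeneity makes extreme-value summaries (minima,
  maxima) somewhat cleaner discriminators than in real data, where
  heterogeneity itself varies between lesions; occasional entry of
  suppressor variables (e.g. Ktrans_min alongside Kep_max) is a visible
  consequence.
- The exact Mann–Whitney branch is limited to ≤ 20 per group without ties;
  larger or tied samples use the asymptotic form.
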