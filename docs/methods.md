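# Methods

## Problem setting

Single-kernel NIR spectra are collected on-line as kernels fall through a
glass tube: each kernel yields one raw intensity vector `S_raw` over 512
channels spanning 899–1715 nm, and the empty light path yields a white
reference `S_white`. All modelling operates on the corrected ratio
`S_c = S_raw / S_white`, a dimensionless quantity in (0, 1]. The task is
binary: aged kernels (class −1) versus newly harvested kernels (class +1).
A study consists of 400 kernels (200 per class) split 80/20 into training
and prediction sets, stratified by class (160/40 per class).

## Synthetic data generator

Because raw kernel spectra from such devices are rarely shareable, the
package ships a generator that emulates the statistical structure the
analysis relies on. Per kernel `i` with label `y_i`:

```
c_i(λ)   = baseline(λ) − Σ_b A_b g(λ; c_b, w_b) − (y_i/2) Σ_e δ_e g(λ; c_e, w_e)
s_i(λ)   = (1 + γ_i) · clip(c_i(λ), (0,1]) + o_i          γ_i ~ N(0, scatter_sd), o_i ~ N(0, offset_sd)
raw_i(λ) = white(λ) · (s_i(λ) + ε_iλ)                      ε ~ N(0, noise_sd)
```

with `g` a unit-height Gaussian. All bands are Gaussian in wavelength — the
standard first-order approximation for NIR absorption features, and
analytically convenient for testing (peak position, width and height are
closed-form).

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| grid | 512 channels, 899–1715 nm, linear | study-scale device range; channel spacing unspecified by hardware, so the simplest reproducible convention |
| shared bands | 1110/1200/1300 nm, σ 25–40 nm, depth 0.08–0.12 | the common absorption features of maize kernels (C–H second overtone, amide combinations) |
| effect bands | 1010/1280/1450/1510 nm, σ 5/10/15/5 nm, δ = 0.1 | centered in the four discriminative regions; σ chosen so that ±2σ spans exactly 1000–1020, 1260–1300, 1420–1480, 1500–1520 nm, making "inside the planted band" well defined |
| scatter_sd | 0.05 | ±5% per-kernel gain, typical particle-size/orientation scatter; motivates SNV/MSC |
| offset_sd | 0.02 | small additive baseline drift |
| noise_sd | 0.02 | ≈3% relative channel noise, plausible for a 100 ms single-kernel integration; makes smoothing and wavelength selection consequential rather than cosmetic |
| seed | config field | one `numpy` Generator per bundle; identical configs are bit-identical |

`truth_transmittance` stores the noise-free corrected signal *including*
the per-kernel gain and offset, so the white-reference correction recovers
it exactly when `noise_sd = 0` — the generator's built-in oracle. Channel
noise is applied inside the white multiplication (`white · (s + ε)`), i.e.
`noise_sd` is expressed on the corrected-ratio scale.

`recovery_config()` is the benchmark variant used for selector-recovery
studies: the same grid with four *narrow* effect bands (σ = 3 nm, ~30
informative channels in total) against a pure-channel-noise background
(scatter and offset zero). With scatter present, out-of-band channels carry
genuine common-mode information that a PLS model legitimately uses to
cancel gain variation, so band membership ceases to measure selector
quality; the recovery benchmark removes that confound, while scatter
handling is validated separately through the SNV/MSC tests.

What the generator does **not** emulate: within-class compositional
variability (the dominant error source in real seed spectra),
wavelength-correlated detector noise, nonlinear detector response, and
kernel-orientation effects. Consequently the synthetic study is *cleaner*
than the real one — full-spectrum classifiers reach 100% prediction
accuracy at the default effect size, where the physical study sat near 90%.
Passing tests therefore demonstrate correctness of the algorithms (signal
found when planted, chance when absent, selectors concentrating on planted
bands), not field-level error rates.

## Algorithmic conventions

**PLS-DA.** SIMPLS on column-centered spectra against the centered ±1
label; the continuous score is thresholded at 0, with a score of exactly 0
mapped to +1. Latent variables are chosen as the smallest count attaining
the maximum stratified 10-fold CV accuracy (ties → fewer LVs). Requesting
more components than the deflation supports is a hard error in
`plsda_fit`; selector sub-models cap gracefully instead, since they
routinely fit tiny channel subsets. At full rank the coefficients coincide
with ordinary least squares (tested at 1e−8), and for a univariate response
SIMPLS coincides with NIPALS PLS1 (cross-checked against scikit-learn).

**LS-SVM.** Dual system `[[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y]` solved
exactly; RBF kernel `exp(−d²/σ²)` (the σ²-naming convention, not
`2σ²`). The tuning grid is log-spaced 10⁻²…10⁶ (13 points) for both γ and
σ²; the squared-distance matrix is computed once and reused across the
whole grid. CV ties prefer smaller γ, then smaller σ².

**KNN.** Euclidean, cityblock and cosine metrics, K = 1…15. Distance ties
resolve to the smaller training index (stable sort), vote ties to +1.

**ELM.** Input weights and biases ~ Uniform(−1, 1) from a seeded
generator, sigmoid hidden layer, output weights by pseudo-inverse; hidden
sizes 10…150 in steps of 10 by CV (ties → fewer neurons).

**RMSECV/RMSEP.** For this discriminant response, model errors are RMS
errors of the *continuous* PLS score against the ±1 label; on pure noise
the floor is 1.0 (the trivial constant predictor). All sub-models of one
selector run share one fold assignment, so sub-model errors are comparable.

**MC-UVE.** Stability_j = mean/sd (n−1) of coefficient j over `n_mc`
Monte-Carlo fits on 80% sample subsets. Channels are ranked by |stability|
and the retained count N swept over 20…500 (step 20, capped at p) by RMSEP.
By default the sweep is scored on an inner stratified hold-out (25%) carved
from the input — scoring on the external prediction set, as sometimes done,
leaks information; an explicit `eval_set` argument reproduces that
protocol when comparison to it is wanted.

**CARS.** `n_runs = 100` iterations; at iteration i the retained budget is
`⌈r_i·p⌉` with `r_i = (p/2)^((1−i)/(n_runs−1))`, so every channel is
eligible at iteration 1 and exactly 2 channels remain at the end. Each
iteration fits PLS on a random 80% sample of kernels, keeps the top-budget
channels by |coefficient| and resamples the budget with replacement
proportionally to weight (adaptive reweighted sampling, unique draws kept).
The iteration subset with minimum 10-fold RMSECV wins.

**BOSS.** Equal initial weights; each iteration draws `n_bootstrap`
variable subsets by weighted bootstrap sampling (pool-size draws with
replacement, subset = unique draws), ranks sub-models by RMSECV, keeps the
best 10%, and sums their normalized |coefficients| into the next weights.
Variables with zero weight leave the pool; iteration continues to a single
variable; the sub-model with the global minimum RMSECV is returned. If an
iteration leaves the pool unchanged (possible when every variable appears
in some kept sub-model), the single minimum-weight variable is dropped so
the advertised strictly-terminating, non-increasing `nVAR` trace always
holds.

**SPA.** From every start channel a chain grows by repeatedly projecting
the remaining columns onto the orthogonal complement of the selected ones
and taking the maximum-norm residual; exactly collinear columns (zero
residual) end the chain. Every (start, length) prefix within
[min_vars, max_vars] is scored by 10-fold RMSECV of an intercept MLR model
(rank-deficient fits fall back to least-squares pseudo-inverse and are
flagged in the trace). Global ties prefer fewer variables, then the
smaller start index.

**Sub-model components.** Where a selector's `n_lv` is not given it is
chosen once per run by CV on the full input pool, capped at 10.

**Chains.** Stage k+1 operates on the channel subset of stage k; indices
are mapped back to the original grid, provenance strings concatenate
(`"MC-UVE>BOSS"`), and traces are merged.

**Seeds.** Every stochastic routine takes an explicit seed; the pipeline
derives stage seeds from a master seed through a fixed offset table
(simulate +0, partition +1, CV +2, MC-UVE +3, CARS +4, BOSS +5, SPA +6,
ELM +7), so a whole experiment is a pure function of (dataset, config).

## Study sizes used in validation

The library defaults (MC-UVE `n_mc = 500`, BOSS `n_bootstrap = 500`) suit
one-off analyses; the validation suite and the acceptance script run the
same algorithms at `n_mc = 100` and `n_bootstrap = 100`, 20 replicates for
the recovery and null studies and 5 for the acceptance summaries — sizes at
which every reported statistic is stable across reseeding while the whole
suite completes in a few minutes on one core.

## Known limitations

- The synthetic study overstates separability (see above); reported
  accuracies characterize the pipeline, not maize seeds.
- MSC's reference is frozen from the training set; spectra with chemistry
  far outside the training envelope would need a re-fit reference.
- Closure-type pretreatments (SNV, Norm) redistribute a band-localized
  class difference into every channel via the row statistic; selector
  subsets computed after them are correct but not band-interpretable.
- CARS cannot resurrect a channel once sampled away; on flat RMSECV
  surfaces (very clean data) its returned subset size is driven by where
  the shallow minimum happens to fall.
- The row-permutation invariance of CV results holds in distribution, not
  bitwise: fold assignments are index-based seeded shuffles.
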