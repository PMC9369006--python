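# Methods

This note documents the models, estimators and numerical conventions behind
`nethomog`, the choices made where the design was genuinely open, and what
the simulation-based tests do and do not establish.

## Synthetic cohorts

**Signal model.** Every in-network voxel of region *r* carries a shared
factor: `y_i(t) = λ_g · s_r(t) + sqrt(1 − λ_g²) · ε_i(t)`, with `s_r` a
unit-variance latent region series, `ε_i` independent white Gaussian noise,
and `λ_g ∈ [0, 1)` the loading of the subject's group *g*. The population
correlation between two voxels of one region is therefore exactly `λ²`,
which gives every downstream stage a closed-form target; group NH
differences are planted by giving the groups different loadings.
Out-of-network voxels are independent noise.

**Network coherence.** Region latents share a subject-level network factor:
`s_r = ρ·s_net + sqrt(1 − ρ²)·u_r` with ρ = 0.9 by default. This leaves the
within-region correlation exactly λ² but makes the regions cohere as one
network (node-mean time-course correlations ≈ 0.75, typical of default-mode
nodes), which is what lets group ICA find the whole network as a single
component. With independent region latents, spatial ICA correctly returns
one component per region and no single component matches the full network
mask.

**Why white noise.** Latents and noise are temporally white; the band-limited
structure of real BOLD data is imposed by the band-pass stage when the
preprocessing path is exercised. Keeping the generator white keeps the λ²
analytics exact on raw generator output. Filtering both sides of the factor
model leaves correlations unchanged in expectation.

**Defaults.** 20×20×20 grid, 3-mm voxels, 240 timepoints at TR = 2 s (the
sampling regime of a standard ~8-minute resting-state acquisition), 20+20
subjects, four 81-voxel spherical regions separated by several kernel
widths, loadings 0.65 vs 0.50 (two regions patients-higher, two
patients-lower). The cohort is smaller than a typical clinical study
(~50–60 per group) but large enough for recovery tests. Demographics
(age, sex, education, illness duration, PANSS subscales) are drawn from
distributions matching a first-episode, drug-naïve cohort versus matched
controls, so the confounder code paths run on realistic inputs. Cognition
scores are linear in group, per-subject regional NH and demographics with
known coefficients (stored as ground truth) plus Gaussian residuals.

**What the generator does not emulate.** Hemodynamics, physiological noise,
spatial inhomogeneity of noise, motion artefacts in the data themselves
(motion parameter tables are simulated only for the screening gate), and
between-subject variation in coupling strength. The last point matters for
interpretation: with λ fixed per group, between-subject NH variance is pure
sampling noise, so planted group differences are "clean" and desk-scale
classification saturates near 100% accuracy / AUC ≈ 1. Passing classifier
tests therefore demonstrates correctness of the machinery, not the
real-data separability of patients and controls (where AUCs near 0.7 are
typical).

## Preprocessing

Order is fixed: linear detrend → band-pass → nuisance regression, following
the conventional narrative order of resting-state pipelines. The band-pass
(0.01–0.08 Hz) is an ideal frequency-domain filter — FFT bins outside the
band, including DC, are zeroed — the convention of the DPARSF/REST lineage;
it has no order or ripple parameters to choose. Nuisance regression
projects each voxel series onto the orthogonal complement of
[intercept | confounds] (Friston-24 motion expansion, with lagged terms
zero-padded at t = 0, plus any ROI mean signals supplied); the whole-brain
global mean is deliberately **not** removed. The motion gate excludes a
subject when any |translation| exceeds 3 mm or |rotation| exceeds 3° —
strictly greater, so values exactly at the threshold pass.

## Network mask by group ICA

Temporal-concatenation group ICA: per-subject PCA to k dimensions,
concatenation, second PCA to k, FastICA on the reduced data, spatial maps
z-scored. k = 20 is a fixed decomposition size, not estimated from the data
(model-order estimation is a separate problem and is not implemented).
Back-reconstruction projects each subject's centered data on the
pseudo-inverse of the group maps. The network component is the argmax of
|Pearson correlation| between component map and template indicator (ties →
lowest index); its sign is oriented toward the template before binarizing
at z > 1.0 (the threshold is a parameter — published NH studies typically do
not state theirs). A user-supplied mask bypasses this stage entirely; the
NH analysis is mask-agnostic.

## The NH statistic

`NH_i = mean_{j≠i} r(x_i, x_j)` over mask voxels, computed by standardizing
each series once and accumulating `Σ_j r_ij` as an inner product with the
summed standardized series — algebraically identical to the O(N²) double
loop, which the tests keep as an oracle. The mean correlation is computed
first and then Fisher-transformed (average-then-transform); the alternative
(transform each r, then average) exists as an option but is off by default.
|r| is clamped to 1 − 1e−7 before atanh so identical series stay finite
while no empirical correlation is affected.

Smoothing (8-mm FWHM, σ = FWHM / (2√(2 ln 2)) per axis in mm) is applied to
the z maps and renormalized within the mask: both the value map and the
mask indicator are smoothed and their ratio taken, so out-of-mask voxels
neither leak signal in nor dilute edge voxels, and a constant map is
preserved exactly. How out-of-mask neighbourhoods are handled during
smoothing is rarely stated in the literature; mask renormalization is the
choice here and is what the conservation tests pin down.

## Group statistics and GRF cluster inference

Per mask voxel, OLS on [intercept, group, age, sex, education] (sex coded
0/1, covariates untransformed); the group t statistic is two-sided with
df = n − p. Residual smoothness comes from the standard random-field
estimator: residuals are standardized to unit sum-of-squares per voxel, and
the variance λ of their spatial first differences along each axis gives
FWHM = sqrt(4 ln 2 / λ) voxels; resels = mask volume / Π FWHM. The t map is
converted to z equivalents (exact tail-probability matching) before
applying Gaussian-field formulas — standard practice at moderate df.

Clusters form per sign at |z| > Φ⁻¹(1 − p_vox/2) with 26-neighbour
connectivity (a parameter; 6 and 18 available). Cluster-level corrected p
uses the expected-Euler-characteristic and expected-extent formulas

```
E[m] = R · (4 ln 2)^{3/2} (2π)^{-2} (u² − 1) e^{−u²/2}
P(n ≥ k) = exp(−β k^{2/3}),  β = (Γ(5/2) · E[m] / E[N])^{2/3}
p_corr = 1 − exp(−E[m] · P(n ≥ k))
```

with E[N] the expected suprathreshold voxel count. Each sign is corrected
against its own one-sided search at the stated cluster threshold — the
convention of the REST/DPABI family of tools. The alternative (doubling
E[m] across signs) was measured to push the realized family-wise error of
the whole NH pipeline to ~0.013 under the null, well below the nominal
0.05, while the per-sign convention calibrates at ~0.03–0.05; the
calibration suite enforces a [0.02, 0.09] band at nominal 0.05 over 500
null cohorts (15³ grid, 10+10 subjects, λ = 0.5 regions). The calibration
uses a full-grid analysis mask (~150 resels at 8-mm smoothness): with a
mask of only a few hundred strongly-coupled voxels the search volume is
below one resel, every suprathreshold cluster trivially survives, and the
voxel threshold alone controls error — a regime that exercises nothing.
Note that the cluster table of a small, highly coherent network mask (the
default demo) is in exactly that sub-resel regime, which is fine when
planted effects are large but means corrected p values there lean liberal.

## Clinical associations

Two-sample t-tests take an explicit pooled/Welch variant and accept either
raw samples or (n, mean, SD) summaries, reducing to identical formulas.
The cohort-comparison table gates the variant per row with a two-sided
variance-ratio F test at α = 0.05 (Welch when rejected), logging the
choice — published tables mix both variants and rarely state the rule. The
2×2 χ² is Pearson's without continuity correction. Stepwise regression is
classic forward entry (smallest partial p ≤ 0.05) with backward removal
(largest p ≥ 0.10), iterated to stability with a cycle guard; it reports
standardized β = b·sd(x)/sd(y), adjusted R², model F and p, and an empty
model is a legitimate outcome. A perfect-fit guard stops entry once the
residual sum of squares is numerically zero. One property worth knowing:
with c independent null decoys, each forward sweep admits a decoy with
probability ≈ 1 − 0.95^c, so even a strong true predictor is selected
*alone* only ~80–85% of the time at these thresholds; that is a property
of stepwise selection itself, not of the implementation.

## Classification

ROC: trapezoidal AUC over all distinct thresholds (equal to the
Mann–Whitney concordance probability with ties counted half, which the
tests verify by exhaustive pair counting); the Youden cut-off maximizes
sensitivity + specificity − 1 with ties resolved toward higher sensitivity.
Patients are the positive class; if the raw AUC is below 0.5 the score is
negated and the flip recorded, since NH may run in either direction.
Accuracy is reported at the Youden cut-off and labelled as such.

SVM: RBF kernel, leave-one-out accuracy per (C, γ) on the canonical grids
C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, …, 2³}, feature standardization refit
inside every fold. The reported accuracy is the grid maximum (ties →
smallest C, then γ) — the convention of small-sample neuroimaging studies,
which is optimistically biased because the same LOO estimate selects and
evaluates; a fully nested mode (grid search re-run inside each outer fold)
is provided for unbiased estimates. Constant features are dropped with a
warning; with no informative feature left the classifier predicts the
majority class. Subset search evaluates all 2^k − 1 nonempty feature
subsets independently, keyed by concatenated indices ("1", "12", "134", …).

## Problem sizes

Simulation suites run at deliberately modest sizes chosen to make the
statistics informative while keeping a full test run in minutes: 500 null
cohorts for calibration, 10 seeds for planted-effect recovery (λ 0.7 vs 0.4,
30-voxel region, 20+20 subjects), 20 seeds for the shared-factor closed
form, 100–150 seeds for stepwise selection rates, 200 random instances for
the NH oracle. The reproduction script (`scripts/acceptance.py`) re-runs
the same computations from scratch under a user seed.

## Known limitations

- RFT cluster inference assumes a stationary, reasonably smooth Gaussian
  field; on masks of a few hundred voxels it degenerates (sub-resel search
  volumes) and on coherent-network masks smoothness is non-stationary.
  Permutation inference would be the robust alternative and is out of scope.
- The stepwise procedure inherits all classical criticisms of stepwise
  selection (selection noise, biased R²); it is provided because it is what
  the emulated analysis tradition uses.
- Group ICA here is the plain concatenation algorithm; no ICASSO-style
  stability resampling, no model-order estimation.
- The generator's clinical scores are linear with Gaussian residuals;
  floor/ceiling effects and item-level structure of real instruments are
  not modelled.
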