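# Methods

This note records the models, parameter choices and numerical decisions behind
`ctqpr`, and what the synthetic-data experiments do and do not demonstrate.

## Perfusion model and deconvolution

The tissue enhancement of a voxel is modeled by indicator-dilution theory:

    C(t) = (C_a ⊛ k)(t),      k(t) = ρ · (MBF/60) · R(t)

with C_a the arterial input function (AIF), ρ = 1.05 g/mL the myocardial
tissue density (the standard convention for per-gram flow units), and R(t) the
impulse residue function. We use a **plug-flow (box) residue**, R(t) = 1 for
t < MTT and 0 after: it is the simplest residue for which the maximum of the
flow-scaled residue equals ρ·MBF/60 exactly, so recovery accuracy is directly
checkable. Contrast recirculation, dual-input supply and partial-volume
effects in the AIF are not modeled.

On a uniform time grid the convolution is a lower-triangular Toeplitz system
A k = c with A[i,j] = Δt·C_a[i−j]. Non-uniform (per-heartbeat) acquisitions
are first resampled to the median frame interval by linear interpolation, and
each voxel curve is baseline-corrected by subtracting the mean of its first
`baseline_frames` (default 3) pre-contrast samples.

**Regularization.** The system is inverted by SVD with Tikhonov filter
factors s/(s² + λ²), λ = `regularization_fraction` × s_max with default 0.15,
a value in the conventional range for first-pass bolus deconvolution. A hard
truncated SVD was evaluated and rejected: the box residue's sharp trailing
edge produces Gibbs ringing under hard truncation that biases the residue
maximum by 8–14% even on noiseless data, for every truncation fraction tried
(0.01–0.3). The smooth filter keeps the noiseless maximum-of-residue error
below ~3% across MBF ∈ [0.5, 2.5] mL/g/min and MTT ∈ [4, 12] s at a 0.75 s
frame interval, with a median bias under 10% at 5%-of-peak Gaussian noise.
Negative flow estimates are clamped to zero. The estimator retains a small
positive bias (~3% at the defaults); because it is a global, roughly
multiplicative bias, it cancels in the QPR (see below).

MBF is read out as max_t k(t)·60/ρ, not from a maximum-slope approximation;
the read-out is therefore delay-insensitive as long as tissue and artery share
the bolus arrival.

The optional `temporal_smooth` step is a per-voxel moving median over time
(odd window, default off) that removes single-frame noise spikes; it stands in
for heavier proprietary spatio-temporal diffusion filtering, which is out of
scope, as is elastic motion compensation — all grids are assumed co-registered.

## Voronoi territories and the stenosis-related region

Each LV-mask voxel is assigned to the coronary branch minimizing the Euclidean
distance (world mm, voxel-center convention, 0-based indices) from the voxel
center to the branch centerline. Polylines are resampled at arc-length steps
≤ 0.5 × the smallest voxel spacing so the point-sampled distance approximates
the continuous curve distance; exactly tied distances resolve to the lowest
branch id. Vessel radius, septal sharing and transmural layers are
deliberately not special-cased — the partition is the pure nearest-centerline
rule, verified exactly against an independent brute-force oracle in the tests.

The myocardium related to a stenosis is the Voronoi territory of the coronary
subtree distal to the seed: the seed's branch from the seed vertex to its tip
plus every descendant attached at or beyond it. Within a labeled territory a
voxel counts as distal when its nearest point on its own branch lies at or
beyond the seed, which makes the region monotonically shrink as the seed moves
distally. When a vessel carries several seeds, the most proximal one (smallest
arc length from the vessel root; ties to the lowest branch id) is the culprit.

## Reference MBF and QPR

The reference MBF is the mode of the whole-LV MBF histogram: Freedman–Diaconis
binning, highest-count bin (ties to the lowest bin), refined as the mean of
values within one bin width of that bin's center. The mode is used because
normal myocardium dominates the LV volume, making the estimate robust to a
hypoperfused minority; whether stenotic territories should be excluded
outright is unknowable from the method's public description, so the whole-LV
mode is the declared choice. The rule is exactly scale-equivariant, so
QPR = MBF/reference is invariant to any global rescaling of the MBF map —
the mechanism behind QPR's lower between-patient coefficient of variation
compared with absolute MBF, and the reason the deconvolution's global bias
does not propagate into QPR.

Stenosis-related MBF and QPR are arithmetic means (not medians) over the
distal territory; the mean is fixed for reproducibility where the choice was
open. Effective dose converts dose-length product with the standard chest
coefficient 0.014 mSv·mGy⁻¹·cm⁻¹.

## Statistics

* Disease labels: FFR ≤ 0.80; FFR is interrogated for stenoses in the
  30–69% QCA band; CTA significance is ≥ 50% luminal reduction or an
  un-assessable (calcified) segment.
* ROC analysis treats **lower** index values as indicating disease. The AUC is
  the Mann–Whitney pair-counting statistic (ties ½), which equals the
  trapezoidal area under the empirical ROC; the Youden cutoff maximizes
  sensitivity + specificity − 1, ties resolving to higher sensitivity then
  the less extreme threshold, and the returned cutoff is the midpoint of the
  indifference gap.
* Proportion CIs are Wald intervals truncated to [0, 100]%. Truncated Wald
  reproduces printed intervals of the form 95 (85–100) and 90 (76–100) from
  the underlying counts; note that published PPV/NPV intervals of that study
  design are often computed by other (unstated) methods and will not
  generally match Wald on raw counts.
* Correlated AUCs are compared with the DeLong placement-value covariance
  estimator and a two-sided normal p-value (identical score vectors return
  p = 1). The single-AUC CI uses the same variance estimator.
* Interobserver agreement is ICC(2,1) — two-way random effects, absolute
  agreement, single measures — cross-checked against an independent
  implementation in the tests. The CV's CI uses the normal-approximation
  standard error CV·√(1/(2(n−1)))·√(1+2CV²).
* `binormal_auc` gives the closed-form AUC Φ(|μ₁−μ₀|/√(σ₁²+σ₀²)) implied by
  two normal group summaries; it is the analytic bridge between group
  (mean, SD) statistics and diagnostic performance.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| frame interval | 0.73 s | one frame per heartbeat at ~82 bpm stress HR |
| n_frames | 30 | ~22 s acquisition covering the first pass |
| AIF | gamma-variate, peak 400 HU at 10.5 s | first-pass arterial bolus |
| MTT | 8 s | tissue transit time (box residue width) |
| normal MBF | 1.95 mL/g/min | stress normal-myocardium level, back-computed from the group pairs 1.38/0.71 and 1.74/0.86 |
| MBF groups | 1.38 ± 0.27 / 1.74 ± 0.35 | stenosis-related MBF by FFR group |
| QPR groups | 0.71 ± 0.08 / 0.86 ± 0.07 | stenosis-related QPR by FFR group |
| prevalence | 20/39 | fraction of FFR ≤ 0.8 vessels |
| copula correlation | 0.7 | latent link between FFR and the indices |

The phantom is an ellipsoidal myocardial shell with branch polylines on the
epicardial surface. Normal myocardium sits at the reference level; for every
FFR ≤ 0.8 vessel the region **distal to its stenosis seed** is reduced by a
factor drawn from the significant-group QPR component, so hypoperfusion is
strictly distal to the lesion as in a flow-limiting stenosis, and the phantom
reproduces the printed group QPR structure by construction. FFR > 0.8 vessels
remain at the normal level. Vessel-level tables are generated independently of
the imaging phantom, with a shared-latent Gaussian copula (correlation 0.7,
within-group Spearman ≈ 0.68) linking FFR to both indices; vessels are treated
as independent because within-patient correlation is not quantifiable from the
available summaries.

Passing tests on these phantoms demonstrate the *numerical* correctness of
deconvolution, territory assignment and the statistics under the model's own
assumptions. They do not demonstrate robustness to beam hardening, scatter,
cardiac motion, registration error, recirculation, AIF partial-volume effects
or anatomical variability — none of which the generator emulates.

## Problem sizes and determinism

Default experiment sizes were chosen so every property is tested at
comfortable statistical resolution on a single CPU: 24³–32³ phantom grids
(~3,000 myocardial voxels), 30-frame series, 1,000-instance ROC equivalence
sweeps, 10,000-draw bootstrap and two-group simulations. Every stochastic
operation takes an explicit integer seed and equal seeds give bit-identical
output; reruns of the CLI with the same config and seed reproduce identical
reports.

## Known limitations

* The deconvolution carries a small (~3%) positive MBF bias at the default
  regularization; absolute-MBF results inherit it, QPR does not.
* The reference-MBF mode assumes normal myocardium is the histogram's
  dominant component; a patient (or phantom) with balanced multivessel
  hypoperfusion violates this and biases the reference downward.
* The box residue is a deliberate simplification; dispersed residues
  (e.g. Fermi or gamma families) would lower the recoverable maximum and are
  not modeled.
* Wald proportion CIs are anti-conservative at small n; they are kept because
  interval *shape* compatibility with the published table format was the
  design goal, and the counts are tiny either way.
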