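# ctqpr — stenosis-related quantitative perfusion ratio from dynamic cardiac CT

`ctqpr` implements a complete analysis pipeline for judging whether a coronary
artery stenosis is hemodynamically significant from non-invasive CT imaging,
using the **quantitative perfusion ratio (QPR)** — myocardial blood flow
relative to the patient's own normal-myocardium level — instead of absolute
flow. It is aimed at researchers in quantitative cardiac imaging who want an
open, testable reference implementation of the full chain from dynamic
contrast-enhanced CT volumes to vessel-level diagnostic statistics.

## The method

1. **Voxel-wise myocardial blood flow (MBF).** Each voxel's time–attenuation
   curve C(t) in a stress dynamic CT perfusion series is related to the
   arterial input function (AIF) C_a(t) by the indicator-dilution model
   C(t) = (AIF ⊛ k)(t), where k(t) = ρ·MBF/60 · R(t) is the flow-scaled
   impulse residue. The discrete convolution is inverted by SVD with Tikhonov
   filter factors s/(s² + λ²), λ = 0.15·s_max, and
   MBF = max_t k(t) · 60/ρ (mL/g/min, ρ = 1.05 g/mL).
2. **Voronoi perfusion territories.** Every voxel of the LV myocardium is
   allocated to the spatially nearest coronary branch centerline (Euclidean
   distance in world mm, deterministic tie-break), partitioning the myocardium
   into per-branch territories from the CTA-derived coronary tree.
3. **Reference MBF and QPR.** The reference (normal-tissue) MBF is the mode of
   the whole-LV MBF histogram (Freedman–Diaconis binning with a refinement
   step); QPR(voxel) = MBF(voxel)/reference. The **stenosis-related** MBF and
   QPR of a lesion are the means over the myocardium perfused by the coronary
   subtree distal to the stenosis seed point (the most proximal seed is the
   culprit when a vessel has several).
4. **Diagnostic statistics.** Against invasive fractional flow reserve
   (FFR ≤ 0.80 = disease), the package computes Spearman correlations,
   pooled-variance t tests, empirical ROC curves with Mann–Whitney AUCs and
   Youden-index cutoffs, sensitivity/specificity/PPV/NPV with truncated Wald
   95% CIs, the DeLong test for correlated AUCs, ICC(2,1) interobserver
   agreement, and coefficients of variation.

Because no public dynamic-CTP dataset exists for this problem, the package
ships a first-class synthetic-data generator (`ctqpr.synthetic`): gamma-variate
AIF, indicator-dilution tissue curves sampled once per heartbeat, an
ellipsoidal-shell LV phantom with coronary polylines and brute-force
ground-truth territories, and vessel tables whose group distributions default
to stenosis-related MBF 1.38 ± 0.27 vs 1.74 ± 0.35 mL/g/min and QPR
0.71 ± 0.08 vs 0.86 ± 0.07 (disease prevalence 20/39).

## Worked example

Run the whole pipeline — phantom, dynamic series, deconvolution, territories,
QPR, evaluation — with one command:

```sh
ctqpr full-run --seed 0 --out demo_out
```

or in Python:

```python
from ctqpr import RunConfig
from ctqpr.cli import cmd_full_run

summary = cmd_full_run(RunConfig(seed=0), "demo_out")
```

With seed 0 the phantom draws FFR 0.85 (LAD), 0.50 (LCX), 0.98 (RCA), so the
LCX territory is hypoperfused. The summary prints:

```
reference_mbf 2.011
LAD MBF 2.01  QPR 1.00  territory 22.1 mL
LCX MBF 1.64  QPR 0.81  territory 15.3 mL
RCA MBF 2.01  QPR 1.00  territory 19.5 mL
```

The recovered reference MBF (2.01 mL/g/min) sits ~3% above the phantom's true
normal level of 1.95 — the residual deconvolution bias — but the QPR values
are unaffected by that global scale: the diseased LCX is flagged by its low
QPR (0.81) while both normal vessels sit at 1.00. The accompanying
vessel-table evaluation (n = 39 vessels, prevalence 51.3%) reports:

```
Spearman vs FFR:  MBF r = 0.64,  QPR r = 0.83
AUC:              MBF 0.83,      QPR 0.92   (DeLong p = 0.269)
MBF cutoff 1.53 mL/g/min: sensitivity 80% (62–98), specificity 79% (61–97)
QPR cutoff 0.79:          sensitivity 80% (62–98), specificity 100% (100–100)
```

i.e. the relative index (QPR) discriminates FFR-positive vessels better than
absolute MBF, which is the scientific point of the method.

## Layout

| module | contents |
| --- | --- |
| `ctqpr.core` | shared containers (maps, series, trees, vessel records) |
| `ctqpr.synthetic` | phantoms, AIF/tissue curves, vessel tables |
| `ctqpr.perfusion` | baseline correction, temporal smoothing, deconvolution |
| `ctqpr.territory` | Voronoi territories, distal subtrees, culprit selection |
| `ctqpr.qpr` | reference MBF, QPR maps, stenosis-related values, dose |
| `ctqpr.stats` | ROC/Youden/DeLong, CIs, ICC, CV, binormal AUC |
| `ctqpr.io`, `ctqpr.cli` | NIfTI/CSV/JSON/YAML I/O and the `ctqpr` CLI |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
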