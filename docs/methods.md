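# Methods

This note documents the models implemented by `hepaquant`, the
parameter choices that matter, what the synthetic phantom does and does
not emulate, and the numerical decisions behind the code.

## Processing chain

A subject's imaging scores come from one axial T1-weighted slice
(typically at the level of the hepatic hilum, a user decision). The
stages are: (1) joint bias-field estimation and liver segmentation by a
level-set model inside a rough user region; (2) bias correction by
division; (3) sub-pixel contour extraction of the segmented liver as
the surface reference line; (4) L_Het from circular parenchymal ROIs
on the bias-corrected image; (5) L_Nod from polynomial reference fits
to user-selected surface segments; (6) the combined product score;
(7) optional FIB-4 staging from a serologic table and ROC/ICC
reporting across subjects.

## Segmentation model

Two-phase local-intensity-clustering (LIC) level set. The image is
modelled as `I(x) = b(x)·c_i + n(x)` in phase `i ∈ {liver, background}`
with `b` a smooth multiplicative bias field. The energy is the
kernel-weighted within-phase squared deviation

```
E(φ, c, b) = Σ_i ∫∫ K_σ(y−x) |I(x) − b(y) c_i|² M_i(φ(x)) dy dx
           + ν ∫ |∇H(φ)| + μ ∫ ½(|∇φ| − 1)²
```

minimised by alternating closed-form updates of `c_i` and `b` with an
explicit gradient-descent step on `φ` (smoothed Heaviside/delta with
width `ε`). The third term keeps `φ` near a signed-distance function
without reinitialisation; the segmented region is `φ < 0`.

Parameters (all exposed in `LevelSetParams`, units in pixels of the
input slice):

| parameter | default | meaning |
|---|---|---|
| `kernel_sigma_px` | 8 | locality scale of `K_σ`; also the resolution of the recovered bias field |
| `length_weight_rel` | 0.003 | `ν = 0.003 · 255²` after internal normalisation; contour smoothness |
| `distance_reg_weight` | 1.0 | signed-distance regularisation `μ` |
| `timestep` | 0.1 | explicit step; `Δt·μ < 0.25` enforced for stability |
| `heaviside_eps` | 1.0 | smoothing width of the Heaviside/delta pair |
| `max_iters` / `convergence_tol` | 300 / 1e-3 | stop when the segmented area changes < 0.1 % over a 10-iteration window |

Choices worth recording:

- **Intensity normalisation.** The working window is mapped to
  [0, 255] before evolution. This makes the segmentation exactly
  invariant to global intensity scaling (MR intensities are
  arbitrary-unit) and lets `ν` be quoted relative to a fixed range.
  Cluster means are reported back on the original scale.
- **Kernel scale.** σ = 8 px rather than the smaller values sometimes
  quoted for LIC. Coil-induced bias in abdominal MR varies over tens of
  millimetres (~50 px at 0.74 mm spacing); with σ = 4 the bias estimate
  is too local — it absorbs parenchymal noise and misses the
  large-scale trend (on the default phantom: bias-truth correlation
  0.88 and Dice 0.95 at σ = 4 versus 0.999 and 1.00 at σ = 8). Values
  of 8–12 behave equivalently.
- **Initialisation** is a binary step (−2 inside the user ROI, +2
  outside). The smoothed delta is then non-zero everywhere, so the data
  term acts globally and convergence takes tens, not hundreds, of
  iterations; the result is insensitive to the rough ROI.
- **Restriction to the dilated ROI bounding box** (padding
  `6σ + 10` px) matches the semiautomated workflow and bounds runtime;
  a 256×256 slice segments in well under a second.
- **Energy descent.** The energy is recorded per iteration and is
  non-increasing to within 1e-6 of its magnitude under the default
  conditions used in the tests. Because the `φ` step is explicit,
  terminal oscillations of order 1e-5 relative can occur on some noise
  draws; the acceptance script reports the largest observed rise so
  this is visible rather than hidden.

Bias correction is plain division by the estimated field; on the
default phantom (true CV 0.05, 20 % bias) it lowers the interior CV
from ~0.075 to ~0.051.

## L_Het

Per ROI: sample SD over mean × 100 of the pixel intensities. The
subject score is the arithmetic mean over the ROIs (≥ 3 required,
5 default). "40 pixels" is read as the ROI *area* (radius
≈ √(40/π) ≈ 3.57 px); a 40-px-radius disk would not fit a liver at
0.74 mm spacing. The sample SD (divisor n−1) is the default because at
n ≈ 40 the population-SD bias is ~0.6 %; `ddof=0` is available. ROIs
must lie wholly inside the liver mask and ≥ 2 px from the boundary —
pixels excluded from the mask stand in for vessels and lesions that an
operator would avoid.

The **L_Het map** generalises the same statistic to a centred odd
square window (default 7×7 ≈ 49 px, comparable to the ROI area),
restricted to in-mask pixels and NaN elsewhere. The printed form of a
CV map ("CV / pixel value") is under-specified; the sliding-window CV
is the reading consistent with the CV-map literature the approach
builds on. Intensities are centred on the in-mask mean before the
windowed moments to avoid catastrophic cancellation (a constant image
maps to exactly zero).

## L_Nod

Each surface segment (an open run of the closed liver contour, ≥ 20 mm
of arc) is fitted by ordinary least squares with both coordinates
regressed independently on *normalised arc length* — liver segments
are not single-valued functions of an image axis, and arc-length
parameterisation makes the score rigid-motion invariant. Orders 2–4
are supported; 3 is the default and is recorded in the output. The
per-segment score is the RMS of the index-aligned point-to-point
Euclidean distances in mm between surface and fitted line: RMS has
distance units, scales linearly with amplitude, and for a sinusoidal
perturbation the ideal value is `amplitude/√2`. The subject score is
the mean over ≥ 3 segments.

Contour extraction uses sub-pixel marching squares on the largest
connected component (holes filled), followed by a periodic Gaussian
smoothing of the vertex coordinates (σ = 2 vertices, a parameter).
Rationale: raw marching squares on a binary mask carries a half-pixel
staircase ripple (~0.2 mm RMS at 0.74 mm spacing) that would swamp the
smooth-boundary nodularity floor; σ = 2 removes it while attenuating
features at the phantom's lobe wavelength (~30–45 px) by under 5 %.
Orientation is normalised counter-clockwise (positive shoelace area in
row/col axes); a component touching the image border is rejected.

Because a finite segment's polynomial reference absorbs part of a
boundary undulation, measured L_Nod is attenuated relative to
`amplitude/√2` by a factor depending on periods-per-segment; scores
rise strictly with true amplitude, which is the property the staging
contrasts rely on. Absolute calibration against any particular
clinical score scale is not claimed.

## Scoring, FIB-4, reporting

Combined score = `L_Het × L_Nod`. Repeated measurements of a subject
are averaged field-wise and the combined score recomputed from the
averaged factors. FIB-4 = `(age·AST)/(platelets·√ALT)`; bands
F1 < 1.45, F2 1.45–3.25 (both endpoints included), F3 > 3.25, read
literally from the staging convention; F0 is only assignable as an
external biopsy-proven label. The recorded upper limit of normal for
AST (35 U/L) plays no role in the formula and is deliberately not
guessed into it.

AUROC is the Mann–Whitney probability (ties half-weighted), CI by
DeLong's structural components. The operating point maximises the
Youden index over midpoints of adjacent sorted unique scores with ties
resolved to the lower threshold, classifying `score ≥ cutoff` as
positive — the imaging scores rise with fibrosis stage. Observer
agreement is ICC(2,1) (two-way random, absolute agreement, single
measure) from ANOVA mean squares with the McGraw–Wong F-based CI,
banded poor/moderate/good/excellent at 0.4/0.6/0.8; repeatability is
the mean per-subject CV (%). All of these are cross-checked in the
tests against independent oracles (brute-force pair counting,
exhaustive threshold scans, a second mean-squares implementation and
`pingouin`).

## Phantom

The phantom emulates a T1-weighted axial liver slice at 0.74 mm
in-plane spacing: an ellipse (default semi-axes 70 × 52 mm in a
256×256 slice) whose boundary radius is perturbed by `A·sin(kθ)`
(default k = 12 lobes), filled with `μ·b(x)·(1 + cv·g)` Gaussian noise
(μ = 100, background 20), under a Gaussian-bump-mixture bias field
rescaled to mean exactly 1 over the liver and peak deviation
`bias_amplitude`. Everything derives from a single integer seed.
Closed-form truth: interior CV = `parenchyma_cv`; boundary RMS
deviation = `A/√2`; bias range `[1−a, 1+a]`.

Gaussian rather than Rician noise keeps the true CV analytic, which is
what parameter-recovery testing needs; at parenchymal SNR ~20 the
difference is negligible anyway. The phantom has no vessels, bile
ducts, lesions, partial-volume blur or k-space artefacts, and the
background is uniform. Passing the recovery tests therefore shows the
*estimators* are correct and stable — not that the scores are robust
to anatomical confounders, operator ROI choices on real livers, or
scanner/protocol variation.

## Validation conditions and problem sizes

The recovery studies use: L_Het — true CV ∈ {0.02, 0.05, 0.10}, five
40-px ROIs, 20 replicate phantoms per level, at zero bias amplitude
(bias handling is validated separately, since correction precedes
L_Het in the chain); L_Nod — amplitudes {0, 0.5, 1.0} mm through the
full segmentation pipeline with three segments of one eighth of the
contour each, plus the analytic 200 mm line with a 1 mm, 10-period
sinusoid; segmentation — the default 256×256 phantom with 20 % bias
and 5 % noise. The simulated observer study reads 8 phantom subjects
(true CV 0.03–0.12) with independent ROI placements per observer.

## Known limitations

- Single-slice, two-phase segmentation only; no 3-D surface
  nodularity, no multi-organ handling, no automatic liver localisation
  or hilum-slice selection.
- The level-set parameter values of the original interactive tools in
  this field are not published; the defaults here are conventional and
  validated only against the phantom.
- Eq-level ambiguities (CV-map denominator and window, SD flavour,
  L_Nod units/normalisation) are resolved as documented above and kept
  configurable where meaningful; absolute score scales may therefore
  differ from other implementations while orderings are preserved.
- ROI and segment placement on clinical images remains an operator
  responsibility; only the phantom path places them automatically.
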