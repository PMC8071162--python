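# hepaquant

Semiautomated quantification of liver fibrosis surrogates from single
2-D abdominal MR slices. Chronic liver disease progressively disrupts
the liver: the parenchyma becomes texturally heterogeneous and the
organ surface becomes nodular. `hepaquant` measures both from a routine
T1-weighted axial slice:

- **L_Het** — parenchymal heterogeneity: the coefficient of variation
  of signal intensity, `SD / mean × 100`, averaged over (by default
  five) circular ~40-pixel regions of interest placed in the liver
  parenchyma, plus a sliding-window per-pixel CV map.
- **L_Nod** — surface nodularity: the liver boundary ("reference
  line") is extracted from a segmentation mask at sub-pixel resolution;
  each user-selected surface segment is compared against a low-order
  (2nd–4th) polynomial reference curve fitted over arc length, and the
  RMS point-wise deviation in millimetres is averaged over segments.
- **Combined score** — the product `L_Het × L_Nod`.
- **FIB-4 staging** — the serologic index
  `FIB-4 = (age × AST) / (platelets × √ALT)` with stage bands
  F1 (< 1.45), F2 (1.45–3.25), F3 (> 3.25); F0 is a biopsy-proven
  external label.

Before scoring, the liver is segmented by a two-phase
local-intensity-clustering level-set model that jointly estimates the
smooth multiplicative bias field of the scanner coil, so the CV-based
texture scores are not inflated by intensity inhomogeneity.
Diagnostic-performance reporting (Mann–Whitney AUROC with DeLong CI,
Youden-optimal cutoff with sensitivity/specificity/PPV/NPV/accuracy,
ICC(2,1) observer agreement, repeatability CV) rounds out the pipeline.

A synthetic liver-phantom generator with analytic ground truth
(known parenchymal CV, boundary nodularity amplitude, bias field)
makes every stage testable without clinical data.

## Worked example

```python
from hepaquant import PhantomSpec, generate_phantom
from hepaquant.pipeline import run_phantom_pipeline, dice

spec = PhantomSpec(parenchyma_cv=0.05, bias_amplitude=0.2,
                   nodularity_amplitude_mm=1.0, noise_seed=42)
res = run_phantom_pipeline(spec, roi_seed=42)
_, truth = generate_phantom(spec)
print(f"Dice vs truth : {dice(res.segmentation.mask, truth.mask):.3f}")
print(f"L_Het  = {res.het.lhet_score:.2f}")
print(f"L_Nod  = {res.nod.lnod_score:.3f} mm")
print(f"L_Het x L_Nod = {res.scores.combined:.3f}")
```

prints

```
Dice vs truth : 1.000
L_Het  = 5.20
L_Nod  = 0.385 mm
L_Het x L_Nod = 1.998
```

The phantom's true CV of 0.05 appears as an L_Het near 5 (the score is
CV in percent); the 1 mm sinusoidal boundary perturbation appears as a
sub-millimetre L_Nod (the polynomial reference absorbs part of a lobe
within each finite segment, so the score is attenuated relative to the
ideal `amplitude/√2` but rises strictly with amplitude).

The same stages are available from the shell:

```bash
hepaquant phantom --cv 0.05 --bias-amplitude 0.2 --seed 42 \
    --out-image slice.png --out-mask mask.png --out-truth truth.json
hepaquant segment --image slice.png --init-mask init.png \
    --out-mask seg.png --out-contour contour.csv
hepaquant het --image slice.png --mask seg.png --out het.json
hepaquant nod --contour contour.csv --ranges ranges.csv --order 3 --out nod.json
hepaquant fib4 --clinical clinical.csv --out staged.csv
hepaquant roc --scores scores.csv --positive F2 --out roc.csv
```

## Documentation

See `docs/methods.md` for the models, parameter choices, numerical
details and known limitations.
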