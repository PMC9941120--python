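# habitatdyn

Image-informed **tumor habitat** identification and **coupled-ODE modelling of
habitat dynamics**, aimed at preclinical quantitative-MRI studies of glioma
(and similar solid tumors) where DCE- and DW-MRI are acquired serially over
days.

Solid tumors are not well-mixed: a well-perfused rim, a hypoxic band and a
necrotic core coexist and evolve differently under treatment.  `habitatdyn`
implements a pipeline that

1. extracts four quantitative MRI parameters per voxel — the Kety–Tofts
   perfusion parameters K^trans (min⁻¹), v_e, k_ep = K^trans/v_e (min⁻¹)
   from DCE-MRI, and the apparent diffusion coefficient ADC (mm²/s) from
   DW-MRI;
2. pools all voxels (subjects × visits), z-scores each parameter, and
   clusters with k-means (k = 3) into physiological **habitats**:
   high-vascularity high-cellularity (HV-HC), low-vascularity
   high-cellularity (LV-HC), and low-vascularity low-cellularity (LV-LC),
   verifying spatial contiguity with a multiregional spatial-interaction
   (MSI) permutation test;
3. models the habitat volumes C₁, C₂, C₃ (mm³) with a nested family of
   coupled ODEs sharing a logistic carrying capacity θ:

       V = (C₁ + C₂ + C₃)/θ
       dC₁/dt = k₁C₁(1 − V) − d₁₂C₁ + d₂₁C₂ − d₁₃C₁
       dC₂/dt = k₂C₂(1 − V) + d₁₂C₁ − d₂₁C₂ − d₂₃C₂
       dC₃/dt = d₁₃C₁ + d₂₃C₂

   with variants A (all 7 parameters), B (d₂₁ = 0), C (d₁₃ = 0) and
   D (d₂₁ = d₁₃ = 0, 5 parameters);
4. calibrates each variant per subject by 50-start Latin-hypercube bounded
   least squares on residuals normalized to each habitat's maximum observed
   volume, and selects the most parsimonious variant by the
   small-sample-corrected AIC,
   AICc = T ln(RSS/T) + 2k + 2k(k+1)/(T−k−1);
5. forecasts held-out subjects by similarity-weighted leave-one-out
   parameter averaging (three weighting schemes) or by truncated-normal
   bootstrapping (N_b = 200 draws from the cohort parameter spread,
   restricted to the 25th–75th percentile band) with optional **data
   updating**: blending the bootstrap mean with an individual calibration
   to early visits, weight w = (v − 1)/(V_total − 1).

Because no public dataset accompanies this problem, the package ships a
first-class synthetic-data module (`habitatdyn.synthdata`) that emulates the
study design: shell-structured feature phantoms with the published habitat
distribution moments, raw DCE/DW signals, and cohorts of 8 control + 8
treated subjects with 5–7 visits spaced 1–2 days.

## Worked example

```bash
python examples/03_calibrate_and_select.py
```

prints (abridged):

```
subject control_01: 7 visits over 9.0 days, final habitat volumes [ 18.3  87.6 322. ] mm^3 (HV-HC, LV-HC, LV-LC)
variant  k        rss      AICc    CCC
      A  7    0.01226   -133.75  0.998
      B  6    0.01237   -138.17  0.998
      C  6    0.01226   -138.36  0.998
      D  5    0.01237   -142.17  0.998
selected: variant D (5 free parameters) — lowest AICc wins; extra transition rates do not buy enough fit
     k1: fitted    1.980   true    1.987
```

All four variants fit this series essentially equally well (similar RSS and
CCC ≈ 1), so the AICc parameter penalty decides: variant D — the generating
model — has the fewest free parameters and wins.  The fitted growth rate k₁
recovers the ground truth within a few percent despite 5% observation noise.

Other examples: `01_phantom_habitats.py` (clustering + contiguity),
`02_qmri_fitting.py` (Kety–Tofts and ADC fits), `04_forecasting.py`
(LOO vs bootstrap vs data updating), `05_full_pipeline.py` (end-to-end run
directory).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch at the given seed — cohort
synthesis, phantom clustering and contiguity testing, four-variant
calibration with AICc selection, and all forecasting methods — leaving its
artifacts (series CSV, NIfTI label map, calibration and summary JSON) under
`scratch/`, and writes the result file to `--out`.

## Layout

```
src/habitatdyn/
  synthdata.py   # phantoms, DCE/DW signals, ODE-simulated cohorts
  qmri.py        # Kety–Tofts forward/inverse, ADC fit, reference correction
  habitats.py    # z-scoring, clustering, labelling, series, MSI contiguity
  models.py      # the ODE family and its integrator
  calibrate.py   # multistart bounded least squares, CCC, AICc, selection
  predict.py     # LOO weighting, truncated bootstrap, data updating
  pipeline.py    # CSV/NIfTI/YAML formats and the end-to-end workflow
```

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
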