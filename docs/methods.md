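# Methods

## The habitat model family

Tumor habitats are compartments: C₁ (HV-HC vascular rim), C₂ (LV-HC hypoxic
band) and C₃ (LV-LC necrotic-like core), all in mm³.  C₁ and C₂ proliferate
logistically against a shared carrying capacity θ (mm³) — the fraction
V = (C₁+C₂+C₃)/θ is re-evaluated from the instantaneous state at every
right-hand-side call, never frozen per step.  Volume moves irreversibly
down the physiological cascade rim → band → core through first-order
transition rates, with two optional routes: the back-transition d₂₁
(re-vascularization of hypoxic tissue) and direct necrosis d₁₃.  Zeroing
those routes gives the nested variants B, C and D; D (5 free parameters) is
the most parsimonious.  C₃ has no outflow, so along any trajectory with
non-negative states the necrotic volume is monotone non-decreasing, and
with k₁ = k₂ = 0 total volume is conserved — both properties are enforced
by tests.

Units: all rates are day⁻¹.  (Some sources print the transition rates as
mm³/day; that is dimensionally inconsistent with rate-times-volume terms
and contradicts growth rates quoted in day⁻¹, so day⁻¹ is used throughout.)
Fitting bounds: every rate in [0, 5] day⁻¹, θ in (0, 2000] mm³ (upper
bound of order a rat brain's volume).

### Integration

`scipy.integrate.odeint` (LSODA, stiff-capable, adaptive) with
rtol = 1e-10, atol = 1e-12.  These tolerances are tighter than typical
defaults because calibration demands residuals far below the observation
scale; they were set so a pure-logistic trajectory matches its closed form
to < 1e-6 mm³ (at rtol 1e-8 the error is ~2e-6).  Undershoots below
−1e-9 mm³ raise; values in [−1e-9, 0) are clamped to zero.

## Calibration

Per subject and variant, bounded nonlinear least squares on residuals
r_{h,t} = (model_{h,t} − data_{h,t}) / max_t(data_{h,·}); the per-habitat
maximum-volume normalization makes habitats of very different size count
equally.  A habitat observed as all-zero is normalized by the global
maximum and flagged.  Initial compartment volumes are the first-visit
observations (day 0 is defined as the first imaging visit) and are not
fitted.

Multistart: Latin-hypercube initial guesses (blocks of 10 from one seeded
stream, so a larger multistart extends a smaller one and the best RSS is
monotone in the number of starts).  Rates start uniformly over their box;
θ starts log-uniformly between the maximum observed total volume and the
upper bound.  The solver is `scipy.optimize.least_squares` (trust-region
reflective) — the bounded analogue of Levenberg–Marquardt, which cannot
itself honor box constraints — with xtol = ftol = gtol = 1e-12.  Default
50 starts; on noiseless synthetic data all five variant-D parameters are
recovered to ~1e-14 relative error.

### Goodness of fit and model selection

* Normalized SSE per habitat: Σ_t r²_{h,t} (dimensionless).
* Lin's concordance correlation coefficient with population (1/n) moments;
  degenerate conventions: both sequences constant and equal → 1, otherwise
  a constant sequence → 0.
* AICc = T ln(RSS/T) + 2k + 2k(k+1)/(T−k−1), where RSS is the summed
  squared normalized residual and k the variant's free-parameter count.
  **T is the residual-point count, visits × 3 habitats** (21 for 7 visits).
  Counting visits alone would make the correction term's denominator
  negative for the 7-parameter variant at the 5-visit study minimum
  (5 − 7 − 1 < 0), leaving the criterion undefined; counting all residuals
  keeps every variant comparable and cannot change the AICc ordering logic.
  The smallest AICc wins; ties within 1e-9 break toward fewer parameters;
  non-finite values exclude a variant with a warning.

## Forecasting

* **LOO weighted averaging.** The held-out subject's parameter vector is a
  weighted mean of cohort fitted parameters, w_i ∝ 1/(d_i + ε) with
  ε = 1e-6 and Euclidean distance d_i between first-visit summaries under
  one of three schemes (initial total volume, initial habitat-volume
  fractions, initial HV-HC volume).  The inverse-distance kernel is the
  simplest choice matching "weight by similarity"; an exact match dominates
  without a division by zero.
* **Truncated bootstrap.** Each parameter gets a normal with the cohort's
  leave-one-out mean and SD, sampled N_b = 200 times restricted to the
  25th–75th percentile interval by inverse-CDF mapping of
  u ~ Uniform(0.25, 0.75) — deterministic per seed, no rejection.  Zero-SD
  parameters stay at their mean.  The forecast is the pointwise mean curve;
  the band is the pointwise 2.5th/97.5th percentile of the draws (a
  nominal 95% interval; no level was prescribed).  The Monte-Carlo SE of
  the mean curve shrinks as 1/√N_b and is ~1% of the curve scale by
  N_b = 200.
* **Data updating.** With v of V_total visits available, the variant is
  recalibrated to those v visits and blended with the bootstrap mean as
  (1 − w)·bootstrap + w·individual, w = (v − 1)/(V_total − 1): linear in
  the available information and exact at both boundaries (v = 1 → pure
  bootstrap, v = V_total → pure retrospective fit, flagged since no
  forecast remains).  Forecast error is the normalized SSE over the
  withheld visits.

Methods are compared per habitat with two-sided Wilcoxon rank-sum tests on
the subject-level SSE distributions at the 5% level.

## Quantitative MRI layer

* Kety–Tofts forward model: C_t(t) = K^trans ∫₀ᵗ C_p(u) e^{−k_ep(t−u)} du.
  The convolution is advanced on a 10× refined grid with an exponential
  integrator (semigroup recursion plus the exact integral of a linearly
  interpolated AIF), so a piecewise-constant AIF is integrated exactly and
  a smooth AIF to O(dt²).  The default synthetic AIF is a biexponential
  population curve (amplitudes 5 and 1 mM, decays 3 and 0.016 min⁻¹).
* Inversion by single-start bounded least squares (K^trans ∈ [0, 5] min⁻¹,
  v_e ∈ (0, 1], start (0.1, 0.2)); the problem is well-conditioned, so the
  multistart machinery is reserved for the ODE layer.  k_ep is always
  reported as K^trans/v_e exactly.  An all-zero curve returns the flagged
  degenerate solution (0, v_e lower bound, 0).
* ADC by log-linear least squares on S(b) = S₀e^{−b·ADC}; non-positive
  signals exclude the voxel with a flag.  With exactly two b-values the fit
  equals the analytic two-point slope.
* Reference-tissue correction: tumor value × (reference muscle value /
  this visit's muscle value), reference defaulting to the median muscle
  value across visits — the simplest ratio scheme that cancels
  slow scanner/physiology drift; non-positive muscle values skip the
  correction with a warning.

## Synthetic data: what it emulates, what it does not

The generators state a world mirroring the study design: cohorts of 8
subjects per arm, 7 visits (study range 5–7) spaced 1.5 days (range 1–2),
5% multiplicative observation noise on habitat volumes, floored at zero.
Per-subject parameters are drawn from normals with the control-arm centers
k₁ = 1.99 day⁻¹ (the reported in-vivo average for the selected model),
k₂ = 0.6, d₁₂ = 0.35, d₂₃ = 0.25, d₂₁ = 0.03, d₁₃ = 0.02 day⁻¹ (the
excluded routes sit one-to-two orders below the forward rates, which is
what motivates the reduced variants), θ = 300 mm³; 25% between-subject CV,
bounded rejection inside the fitting box.  Initial volumes are lognormal
around (30, 15, 5) mm³ (rim-dominated early tumor) with 30% CV.  Treatment
enters only through parameter differences — the treated arm halves the
growth-rate centers; the ODEs carry no explicit dose term.

Phantom voxel features are independent normals per parameter per habitat
with the published cohort means/SDs, clipped at 1e-6 in native units; the
geometry is three concentric shells with equal volumes (radii
∝ 1 : 2^{1/3} : 3^{1/3}), so each habitat's distribution is equally
sampled.  Known departures from real data: features are independent within
a habitat (no K^trans–k_ep correlation, even though k_ep = K^trans/v_e
voxelwise in fitted data); the shells are perfect spheres; there is no
partial-volume mixing, registration error, or visit-to-visit drift unless
explicitly simulated.  A green clustering test therefore establishes that
the pipeline recovers habitats *under the published moments*, not that it
would segment arbitrary real tumors; with the published SDs the class
overlap caps the achievable adjusted Rand index near 0.9
(Bayes-optimal), and k-means reaches ~0.77.

## Known limitations

* The exact reference-tissue scheme, AIF handling, LOO weight formulas and
  per-point confidence intervals of the original study are not public;
  the versions here are declared stand-ins chosen for simplicity and
  testability.
* The MSI contiguity statistic (symmetrized 6-connectivity pair counts,
  row-normalized, mean diagonal mass, 200-permutation null) is one
  reasonable operationalization of "spatially contiguous"; other
  normalizations exist.
* AICc selection compares variants on the same residual definition; it
  says nothing about absolute adequacy of the parent model.
* No Bayesian parameter uncertainty: cohort spread plus bootstrap bands
  are the only uncertainty statements.
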