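# nirsasym

Interhemispheric hemodynamic-asymmetry analysis for motor-imagery fNIRS
(functional near-infrared spectroscopy), aimed at NIRS-BCI studies of
post-stroke motor rehabilitation.

After a unilateral stroke, the normal contralateral dominance of the motor
cortex's hemodynamic response is disrupted, and the balance of activation
between the lesioned and intact hemispheres is a candidate biomarker of
neuroplastic reorganization.  Quantifying that balance from fNIRS is
awkward because GLM response amplitudes can be *negative*, which breaks
laterality formulas designed for positive-valued measures (spectral power,
cluster sizes).  This package implements two bounded, polarity-preserving
asymmetry indices built on the normalization

```
f(a, b) = (a − b) / √(2 (a² + b²)) ∈ [−1, 1],     f(0, 0) := 0
```

* **LC** (laterality coefficient): `a = R_h,contra`, `b = R_h,ipsi` — one
  motor-imagery task's response amplitudes on a homotopic channel pair,
  contralateral vs ipsilateral to the imagined hand `h`.
* **TRAC** (task response asymmetry coefficient): `a = R_contra,k`,
  `b = R_ipsi,k` — one channel `k`'s response amplitudes to
  contralateral-hand vs ipsilateral-hand motor imagery.

`|f| ≤ 1` follows from Cauchy–Schwarz, with equality exactly at `b = −a`.
For comparison, three reconstructed laterality normalizations from the
earlier fNIRS literature are provided, each exhibiting its documented
pathology on signed data: `(|a|−|b|)/(|a|+|b|)` is blind to response
polarity, `(a−b)/(|a|+|b|)` saturates at ±1 whenever the signs differ, and
`(a−b)/(a+b)` diverges as `b → −a` (a "zeroing negative coefficients"
variant is also included).

## What the package does

* **Montage & events** — 28-channel clinical and 33-channel healthy motor
  montages with homotopic channel pairs (YAML configs); block/trial
  schedules for the BCI protocol (17 s rest + 17 s motor imagery per
  clinical trial, 2 s preparation + 15 s execution per phase; 3 s + 20 s
  for the healthy protocol); lesion-side channel mirroring so the left
  labels always denote the lesioned hemisphere.
* **Optics** — modified Beer–Lambert law conversion of dual-wavelength
  (760/850 nm) intensities to ΔHbO/ΔHbR.
* **Preprocessing** — 4th-order zero-phase Chebyshev type-I band-pass,
  0.005–0.09 Hz.
* **Response GLM** — canonical double-gamma HRF, boxcar + cue-delta design
  (rest unmodeled as baseline, preparation regressors excluded), OLS per
  channel/chromophore; the task coefficients are the response amplitudes.
* **Statistics** — aligned-rank-transform (ART) repeated-measures factorial
  ANOVA, per-pair Wilcoxon signed-rank tests with Benjamini–Yekutieli FDR
  adjustment, per-channel daily-slope regressions, Pearson correlation with
  clinical ARAT scores.
* **Synthetic cohorts** — a forward model that plants known response
  amplitudes, lesion-dependent asymmetry, day-by-day drift and
  physiological noise, and writes SNIRF v1.1 files; every pipeline stage is
  validated against this ground truth.

The signal-chain stages are also exposed as scikit-learn compatible
estimators (`BeerLambert`, `ChebyshevBandpass`, `HemodynamicGLM`) that
compose with sklearn pipelines.

## Worked example

```python
>>> from nirsasym import lc, alt_laterality
>>> round(lc(0.8, 0.2), 4)        # contralateral dominance, bounded
0.5145
>>> lc(0.5, -0.5)                  # opposite-sign responses: saturates at 1
1.0
>>> alt_laterality(0.5, -0.5, "eq3")   # the unbounded ratio form diverges
inf
```

End-to-end on a synthetic four-patient cohort (three days, one session per
day, planted lesioned-hemisphere HbO TRAC ≈ +0.2 vs intact ≈ −0.05):

```python
from nirsasym.pipeline import RunConfig, run_pipeline
out = run_pipeline(RunConfig(out_dir="demo_out", n_patients=4, n_blocks=4,
                             n_days=3, sessions_per_day=1, seed=1))
```

prints into `demo_out/anova.csv`:

```
analysis             effect          F  df  df_res            p
HbO TRAC         hemisphere 240.329388   1      81 5.886168e-26
HbO TRAC            channel   0.438757  13      81 9.504560e-01
HbO TRAC hemisphere:channel   0.602148  13      81 8.456436e-01
```

and the recovered group means are `HbO TRAC = 0.179` (lesioned) vs
`−0.042` (intact): the hemisphere main effect is detected, channel and
interaction effects are absent, matching what was planted.  The same run
writes `coefficients.csv` (GLM amplitudes), `asymmetry.csv` (LC/TRAC per
subject/session/channel/chromophore), Wilcoxon/slope/correlation tables and
a provenance-stamped config.

A thin CLI wraps the library: `nirsasym simulate` writes synthetic SNIRF
sessions with planted-truth sidecars, `nirsasym run` executes the full
pipeline (`--index`, `--low/--high/--order/--ripple`, `--no-subject-term`,
`--seed`, ...).

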