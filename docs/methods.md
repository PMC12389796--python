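# Methods

This note documents the models, defaults and numerical choices behind
`nirsasym`, and what the synthetic validation does and does not establish.

## Signal model and estimation chain

A recording is a set of channels (emitter–detector label pairs) sampled at
`Fs` (15.6 Hz for the clinical protocol, 3.9 Hz for the healthy one).  The
chain is:

1. **Optical density.** `ΔOD_λ(t) = −log10(I_λ(t)/I0_λ)` per channel and
   wavelength.  `I0` defaults to the whole-recording mean intensity; the
   subsequent 0.005 Hz high-pass removes the arbitrary offset this choice
   leaves, so the baseline statistic is not critical.  A `first_n_seconds`
   baseline and an explicit `given` baseline are available (the latter is
   what the exact round-trip tests use).
2. **Modified Beer–Lambert law.** `(ΔHbO, ΔHbR)` solve the 2×2 system
   `ΔOD_λ = (ε_HbO(λ) ΔHbO + ε_HbR(λ) ΔHbR)·d·DPF_λ`.  Defaults: the
   Gratzer/Cope extinction compilation at 760/850 nm
   (0.5864/1.5485 and 1.0580/0.6913 mM⁻¹cm⁻¹ for HbO/HbR), `DPF = 6.0`
   at both wavelengths, `d = 3 cm`, concentrations carried in µM.  These
   constants rescale the response amplitudes jointly; LC and TRAC are
   scale-free ratios, so absolute calibration does not affect any
   downstream statistic (asserted numerically in the tests).  All constants
   are overridable.
3. **Band-pass.** Chebyshev type-I, order 4, 0.1 dB passband ripple,
   0.005–0.09 Hz, applied forward–backward (`sosfiltfilt`), i.e. zero
   phase and squared magnitude response.  "Chebyshev" unqualified is taken
   as type I, and the stated order is the order *before* the
   forward–backward doubling; both are configurable.  Edge handling:
   odd-reflection padding targeting 3× the filter's settling length
   (samples until the slowest pole decays to 1e-3), capped at the series
   length − 1.  Second-order sections are used throughout — at
   0.005 Hz/15.6 Hz a transfer-function realization would be numerically
   fragile.
4. **Design matrix and GLM.** The canonical HRF is the double-gamma
   difference `γ(t; 6, 1) − γ(t; 16, 1)/6`, sampled at `1/Fs` over 32 s and
   normalized to unit sum, so a long boxcar convolves to a plateau of
   height 1 and coefficients read as response amplitudes in concentration
   units.  Regressors: one boxcar per motor-imagery task covering its
   execution windows, one shared delta-train over non-preparatory visual
   cues, and an intercept.  Rest is left unmodeled (baseline).
   Preparation-interval regressors are constructed, their correlation with
   the cue regressor recorded (≈ 0.9 on the clinical schedule — the reason
   they are excluded), and dropped from the fitted model.  The design
   columns (except the intercept) are passed through the same band-pass as
   the data; filtering only one side of the regression would bias the
   coefficients, whereas matched filtering leaves noise-free recovery exact
   (a property test).  Estimation is plain OLS with no prewhitening, fitted
   per session; coefficients are later averaged across sessions.

## Asymmetry indices

Both indices use `f(a, b) = (a − b)/√(2(a² + b²))`, defined as 0 at
`a = b = 0`.  Cauchy–Schwarz gives `|f| ≤ 1` with equality iff `b = −a ≠ 0`;
`f` is antisymmetric and equivariant under scaling (`f(ca, cb) =
sign(c)·f(a, b)`).  Outputs are clipped to `[−1, 1]` to absorb one-ulp
floating-point overshoot.  LC contrasts one task between the two channels
of a homotopic pair; TRAC contrasts the two tasks on one channel.  For
patients, homotopic channels of right-lesioned subjects are mirrored first
so that left labels always denote the lesioned hemisphere, and tasks are
relabeled affected/intact from the lesion side; healthy subjects are
untouched.

The three reconstructed earlier normalizations — `(|a|−|b|)/(|a|+|b|)`,
`(a−b)/(|a|+|b|)`, `(a−b)/(a+b)`, plus the negative-zeroing variant of the
last — are *reconstructions*: the source formulas are not reprinted in the
literature we follow, so the simplest standard forms reproducing each
described failure mode (polarity blindness, opposite-sign saturation,
denominator singularity) are used and labeled `alt_*` in all outputs.
Vanishing denominators yield signed-infinity sentinels (NaN at 0/0) with
`overflow` flags, never exceptions.  `stability_report` summarizes
saturation (`|v| = 1` at tolerance 1e-12, `|v| > 0.99`) and tail behavior
(95th percentile, max; a nearest-order-statistic percentile is used when
infinities are present).

## Statistics

* **ART ANOVA.** For each effect of the subject × 2-level × k-level
  within-subject design, the balanced table is decomposed orthogonally into
  grand mean, subject, two main effects, interaction and residual; the
  effect's component plus residuals is ranked (average ranks) and pushed
  through a balanced factorial ANOVA on ranks, reporting only that effect's
  F/df/p — three alignments per analysis.  The subject blocking term is
  included by default (residual df 378 for a 15 × 2 × 14 table, 104 for
  9 × 2 × 7); `include_subject_term=False` reproduces the plain two-way
  residual df (392).  Both are exposed because the repeated-measures
  convention and the plain layout disagree on this design.  Null
  simulations at the 15 × 2 × 14 size put the type-I error of all three
  effects in [0.03, 0.07] at α = 0.05.  F statistics are invariant under
  affine transforms of the data (alignment is affine-equivariant and ranks
  are unchanged); general monotone transforms are *not* exactly invariant
  because alignment precedes ranking.
* **Wilcoxon + BY.** Per homotopic pair, two-sided signed-rank on the
  per-subject left-minus-right differences; zeros dropped and counted,
  exact null for n ≤ 25 without ties, tie-corrected normal approximation
  otherwise; pairs with < 5 nonzero differences flagged underpowered.
  Benjamini–Yekutieli adjustment (`p·m·c(m)/rank` with step-up
  monotonicity, `c(m) = Σ 1/i`) is applied within each
  (index kind, chromophore) family, via statsmodels and cross-checked
  against a brute-force oracle.
* **Daily slopes.** Values are averaged across sessions within day, then
  each (subject, channel, index, chromophore) series is regressed on day
  number (≥ 3 distinct days required); BY families span channels within
  (subject, index kind, chromophore); `*` marks raw p < α, `**` marks
  BY-adjusted p < α.
* **Clinical correlations.** Pearson r between subject-level asymmetry
  metrics and baseline ARAT / relative ARAT improvement; zero-variance or
  < 3-subject cases are flagged missing rather than computed.

## Synthetic cohort generator

The generator is the validation bed: a session's concentration series is
`HRF-convolved design × (amplitude + day·daily_slope) + noise`, per channel
and chromophore, with HbR amplitudes defaulting to −1/3 of HbO.  Noise is
white Gaussian + random-walk drift + three fixed-frequency sinusoids
(Mayer ~0.1 Hz, respiration ~0.25 Hz, cardiac ~1.1 Hz) with per-channel
random phases, generated in continuous time and sampled at `Fs` (so cardiac
aliases freely at 3.9 Hz, as in real acquisition).  Defaults
(`white_sd 0.5, drift_sd 0.015/sample, Mayer 0.4, resp 0.3, cardiac 0.3`,
concentration units) put the per-session GLM coefficient standard error at
≈ 0.1 of a unit planted amplitude on the standard 4-block clinical session
— the realistic signal-to-noise regime the validation targets; the drift
and Mayer terms dominate because they leak into the 0.005–0.09 Hz band,
which is exactly what the band-pass is there to limit.

Patient scenarios plant contralateral/ipsilateral task amplitudes of
1.0/0.66 on lesioned-hemisphere channels and 0.9/1.0 on intact-side
channels (analytic HbO TRAC ≈ +0.20 and ≈ −0.05), with 0.08 SD per-channel
jitter; healthy scenarios are symmetric 1.0/0.8.  Cohort layouts follow
the clinical protocol ranges (7–15 days, 1–2 sessions/day, capped at 24
sessions; lesion sides alternating so 15 patients split 8 left / 7 right);
an optional `lesioned_daily_slope` plants the substantial-recovery drift
pattern (negative on the lesioned hemisphere, opposite at half magnitude on
the intact side).

What the generator does *not* emulate: motion artifacts, superficial-layer
(scalp) hemodynamics, photon-transport realism, heteroscedastic or
autocorrelated-beyond-drift noise, HRF shape variability across subjects.
Passing tests therefore demonstrate correctness of the estimation and
inference chain under the stated forward model, not robustness of the
indices on arbitrary real recordings.

## Problem sizes used in validation

Simulation-based checks run at reduced but structurally faithful sizes,
chosen as a deliberate compute/fidelity trade-off: GLM bias uses 200
replicate 4-block sessions on a one-pair montage; ART calibration uses
1000 null tables at the full 15 × 2 × 14 design; the end-to-end
sign-pattern check uses 100 replicate 15-patient cohorts with one 2-block
session each; the slope-recovery check uses 3 patients × 8 days.  The
full-protocol sizes remain the generator defaults.

## Known limitations

* The emitter–detector adjacency of both montages is a plausible
  reconstruction from the published optode positions (the channel pairings
  themselves are not printed); it only affects labeling, not any
  computation.  The healthy montage's 7 analyzed homotopic pairs are the
  ones formed by the 14 channels shared with the clinical montage.
* The `alt_*` formulas are behavioral reconstructions (see above), not
  verbatim reproductions of their source.
* Group-level numbers from the original clinical cohort are not
  reproducible here (data not public); the package reproduces the
  qualitative structure — boundedness, saturation/singularity pathologies
  of the alternatives, hemisphere sign pattern, slope-sign recovery — on
  synthetic cohorts with known truth.
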