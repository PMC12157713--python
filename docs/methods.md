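# Methods

## The measurement and its confounder

An e-Nose measurement is a three-phase recording of 8 MOS channel
resistances (two units each of TGS2603 and TGS2600, one each of TGS2610,
TGS2620, TGS2611, TGS2602): 1 min of clean humidified reference air
("before"), 5 min of exhaled breath drawn from the sampling bag
("during"), 10 min of clean-air recovery ("after"); default phase bounds
(60, 360, 960) s.  The acquisition rate is not fixed by the protocol; it is
stored in every file header and defaults to 1 Hz.  Tests and the demo
pipeline use coarser grids (0.125–0.25 Hz) purely for speed — every
contract is rate-agnostic.

For n-type MOS sensors, reducing volatiles lower the resistance and oxygen
raises it.  Since FiO₂ is escalated in deteriorating (LPS) animals but not
in controls, the oxygen response is a *group-correlated confounder*: an
uncorrected classifier can separate the groups on oxygen alone.  The
correction surfaces exist to remove exactly this channel.

## Correction surfaces

Per channel, the mean clean-air curve R̄(t, f) over 3 replicates at each
calibration level f ∈ {0.21, 0.25, 0.30, 0.35, 0.40, 0.50} defines

* k_diff(t, f) = R̄(t, f) − R̄(t, 0.21), applied as R_corr = R_bas − k_diff
  to subtract-baselined samples (R_bas = R_S − R_S(0));
* k_ratio(t, f) = R̄(t, f) / R̄(t, 0.21), applied as R_corr = R_bas / k_ratio
  to divide-baselined samples (R_bas = R_S / R_S(0)).

Both are evaluated by bilinear interpolation on the (time × level) grid.
Numerical choices:

* **Calibration baseline.** The mean calibration curves are baseline-removed
  with the strategy's own mode *before* differencing/ratioing, so k carries
  the same units as the curve it corrects and k_diff(0, ·) = 0,
  k_ratio(0, ·) = 1.  `raw_calibration=True` reproduces the literal
  raw-curve construction (for this generator the two coincide, because
  replicates share their baseline exactly).
* **Reference identity.** The 21 % column is forced to exactly 0 / 1, and
  correction at FiO₂ = 0.21 short-circuits to the identity map, so the
  reference-level invariant holds to the bit.
* **Extrapolation.** Levels outside [0.21, 0.50] clamp to the nearest
  characterized level with an `ExtrapolationWarning`; MOS–O₂ linearity
  beyond the characterized range is unsupported, so we refuse to invent it.
  Times outside the calibration grid are an error.
* **Grid mismatch.** The surface is resampled (linearly in t) onto the
  sample's grid, never the sample onto the surface's.
* The ratio strategy divides the baselined curve by k_ratio (not k_diff);
  ratio surfaces must be strictly positive, which is validated.

## Synthetic generator: what it emulates, and what not

No real cohort is available, so the generator is the package's test bed.
One channel's forward model is a first-order on/off envelope g(t)
(rise constant τ_on in "during", decay τ_off in "after") with separable
volatile-compound (VC) and O₂ terms:

* additive: R(t) = r₀·(1 − α·v·g) + r₀·β·(FiO₂ − 0.21)·g
* multiplicative: R(t) = r₀·(1 − α·v·g)·(1 + β·(FiO₂ − 0.21)·g)

with v the VC load, α (`alpha_vc`) the maximal fractional drop, β
(`beta_o2`) the fractional rise per unit FiO₂ above room air, and
multiplicative lognormal noise of CV `noise_cv`.  This is the minimal model
that reproduces the observed directionality (resistance down on breath, up
with oxygen) *and* makes each correction strategy exact for its matching
coupling: additive ↔ k_diff, multiplicative ↔ k_ratio.  That collapse
identity — corrected noise-free curves at every level coincide with the
reference-level VC-only curve at machine precision — is the pipeline's core
cross-module oracle.  With noise, the residual relative RMS deviation is
measured against the channel's natural scale (r₀ for ohm-scale diff
curves, the unit baseline for dimensionless ratio curves); normalizing by
the VC deviation instead would make the number depend on the arbitrary
effect size of the test sample.

Defaults (assumptions, not estimates of any device or of the study):
per-channel r₀ 8–55 kΩ, β 0.5–1.2, α 0.22–0.50, τ_on ≈ 20 s, τ_off ≈ 60 s,
noise CV 0.01, multiplicative O₂ coupling.

Cohorts follow the study design: 9 control + 10 LPS animals, 8 timepoints
(t0, t5 … t180 min).  The LPS VC load rises monotonically with the stepped
dose escalation (0.05 → 0.90 arbitrary units); per-animal loads are drawn
with SD 0.05.  FiO₂ policy: control flat 0.30; LPS 0.30 until t30, then
0.35/0.40/0.45/0.50 — group-correlated escalation within the calibration
hull.  Physiology (MAP/DBP/SBP, HR, T) reproduces the managed targets —
control MAP held above 80 mmHg, LPS MAP drifting into 40–60 mmHg with
rising heart rate and temperature — with DBP ≤ MAP ≤ SBP enforced
per record.  Named scenarios: `null_cohort_spec` (no VC effect, shared
FiO₂, identical physiology — labels carry no information),
`strong_effect_spec` (fast-onset large VC divergence, flat shared FiO₂ —
the signal is strong over the *whole* cumulative window, because
per-timepoint models pool all rows since t5 and a ramp that only becomes
separable late cannot exceed ~90 % pooled accuracy even for an optimal
classifier), `confounded_spec` (no VC effect, group-coupled FiO₂ — the
only group signal is oxygen).

Not emulated: chemically realistic VC mixtures, Nalophan humidity
equilibration kinetics (the protocol equalizes humidity; an explicit
nuisance term is out of the default path), bag storage deterioration,
animal-level random sensor effects.  A green synthetic test therefore
establishes the *algorithms*' correctness and calibration, not field
performance of any instrument.

## Classification

Per timepoint t ∈ {t5 … t180}, the sample set is cumulative (all rows from
t5 through t; the t0 baseline is excluded, switchable).  Four variants:

| variant | features | transform | classifier |
|---|---|---|---|
| physio | MAP, DBP, SBP, HR, T | z-score → PCA(5) | logistic regression |
| enose_raw | curve features, subtract baseline | IQR screen → z-score → PCA(2) | decision tree (depth 3) |
| enose_kdiff | as raw + k_diff correction | same | same |
| enose_kratio | divide baseline + k_ratio | same | same |

Evaluation is leave-one-out with every transformation — outlier screen,
scaler, PCA, classifier — refit inside each training fold (no leakage; a
fold's fit is bit-identical whether or not the held-out rows exist in the
input table).  Design choices:

* **LOO unit.** Default `animal`: with cumulative assembly an animal
  contributes several rows, and row-level folds would leak its identity.
  `sample` is available for literal replication and for calibration checks
  whose reference distribution assumes independent predictions.
* **Class-prior balancing.** Both classifiers use balanced class weights.
  Leave-one-unit-out makes the majority class of every training fold the
  opposite of the held-out unit's; an unbalanced noise-fit classifier votes
  with that majority and drives null-data accuracy systematically below
  chance (measured ≈ 41 % pooled).  Balancing removes the artifact without
  touching informative fits.
* **PCA determinism.** Loadings are sign-fixed (largest-magnitude element
  positive); components are capped at the usable rank of the training fold.
* **z-score** uses population SD (ddof 0); zero-SD columns map to 0 with a
  warning.
* **Outlier screen.** Tukey fences at `fence_mult`·IQR per (timepoint,
  feature) within the training fold (default 1.5; 0 gives the literal
  outside-the-IQR rule, which would discard ~half the data).  Flagged cells
  are masked and median-imputed rather than deleting samples, keeping the
  LOO design balanced; groups under 4 values or with zero IQR are left
  alone.  The screen is idempotent.
* **Metrics.** Accuracy, sensitivity (LPS = positive), specificity in
  percent, each with a Wald 95 % CI (p̂ ± 1.96·√(p̂(1−p̂)/n), clipped to
  [0, 100], n the metric's own denominator); Wilson intervals by flag.
  Zero-denominator metrics are reported missing, not zero.  Training folds
  missing a class are excluded from pooling and counted.

The physiological trajectory summary fits z-score + PCA on the t0 records
only, projects every later timepoint into that frozen space, and reports
per-animal displacement vectors (modulus × direction) and their group
means — a descriptive view of how the LPS group leaves its baseline state.

## Breath sampling simulation

Pressure-control ventilation is modeled as a PIP/PEEP square wave with
additive Gaussian noise.  Exhalation detection follows the hardware's
comparator semantics: open strictly below the threshold, close at/above it,
with an N-sample debounce (default 2; the hardware's hysteresis behavior is
unspecified) and explicit flagging of a segment truncated by trace end.
Bag filling is ceiling arithmetic over detected exhalations.  Edge
boundaries on a sampled grid are exact up to one sample (float-modulo
jitter at the wave edges).

## Known limitations

* The six-feature set is a pragmatic superset of the three documented
  example features; no frequency-domain or model-fit features.
* Wald intervals are poor near 0/1 with small n (they clip); Wilson is
  available but not the default.
* The generator's separable VC/O₂ coupling makes the matched correction
  exact by construction; real sensors may mix couplings, in which case both
  strategies are approximations — the package measures, but cannot close,
  that gap.
* Leave-one-out estimates on ≤ 19 animals have large variance; per-seed
  accuracies of ± 10 points around the mean are normal and the CIs reflect
  only the binomial part of it.
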