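# enosepy

Exhaled-breath analysis for mechanically ventilated subjects with a
metal-oxide-semiconductor (MOS) electronic nose, built as a reusable,
fully synthetic-testable pipeline:

* **ventilator-synchronized sampling** — simulation of the expiratory-line
  pressure signal and the threshold detector that fills a Nalophan bag only
  during exhalations;
* **FiO₂ confounder correction** — n-type MOS sensors raise their
  resistance with the oxygen fraction of the sample, and the inspired
  oxygen fraction (FiO₂) of a sick, ventilated subject is escalated
  clinically, so oxygen is a *group-correlated confounder* of any breath
  classifier.  Clean-air measurements at FiO₂ ∈ {21, 25, 30, 35, 40, 50} %
  (3 replicates each) define, per channel, a bivariate correction surface

  &nbsp;&nbsp; k_diff(t, FiO₂) = R̄(t, FiO₂) − R̄(t, 21 %)  or
  k_ratio(t, FiO₂) = R̄(t, FiO₂) / R̄(t, 21 %),

  linearly interpolated in time and level; sample curves are
  baseline-removed (R_bas = R_S − R_S(0) or R_S / R_S(0)) and corrected by
  R_corr = R_bas − k_diff or R_bas / k_ratio at the sample's FiO₂;
* **curve features** — amplitude, area under the deviation curve, on/off
  slopes, time-to-extremum, recovery fraction, per channel, with Tukey-fence
  IQR outlier screening per (timepoint, feature);
* **per-timepoint classification** — control vs LPS (endotoxemia) animals,
  z-score → PCA → classifier (5 components + logistic regression for the
  physiological model; 2 components + decision tree for the e-Nose models),
  evaluated by leave-one-out with cumulative data assembly (the model at
  t60 trains on t5 ∪ t30 ∪ t60) and Wald 95 % confidence intervals.

Because no real cohort is distributable, the package ships a first-class
synthetic generator (`enose.simulate`) whose forward model reproduces the
relevant physics: resistance drops with breath volatile load, rises with
oxygen, and the additive/multiplicative O₂ coupling is corrected *exactly*
by k_diff/k_ratio respectively — an algebraic identity the test suite
exploits throughout.

## Worked example

```python
from enose import BreathStudy, CohortSpec

spec = CohortSpec(n_control=9, n_lps=10, rate_hz=0.25, seed=7)
study = BreathStudy.from_spec(spec, timepoints=["t5", "t60", "t120", "t180"])
results = study.fit()
print(results.summary())
```

```
Per-timepoint LOO classification (accuracy %, [95 % CI])
================================================================
       physio    t5:  73.7 [ 53.9,  93.5]  (n=19)
       physio   t60:  87.7 [ 79.2,  96.2]  (n=57)
       physio  t120:  93.7 [ 88.8,  98.6]  (n=95)
       physio  t180:  94.0 [ 89.9,  98.0]  (n=133)
    enose_raw    t5:  63.2 [ 41.5,  84.8]  (n=19)
    enose_raw   t60:  73.7 [ 62.3,  85.1]  (n=57)
    enose_raw  t120:  75.8 [ 67.2,  84.4]  (n=95)
    enose_raw  t180:  75.2 [ 67.8,  82.5]  (n=133)
  enose_kdiff    t5:  73.7 [ 53.9,  93.5]  (n=19)
  enose_kdiff   t60:  86.0 [ 76.9,  95.0]  (n=57)
  enose_kdiff  t120:  85.3 [ 78.1,  92.4]  (n=95)
  enose_kdiff  t180:  90.2 [ 85.2,  95.3]  (n=133)
 enose_kratio    t5:  63.2 [ 41.5,  84.8]  (n=19)
 enose_kratio   t60:  84.2 [ 74.7,  93.7]  (n=57)
 enose_kratio  t120:  89.5 [ 83.3,  95.6]  (n=95)
 enose_kratio  t180:  88.7 [ 83.3,  94.1]  (n=133)
```

Each row is one model variant evaluated at one timepoint on all samples
collected since LPS/placebo administration (`n` counts pooled predictions;
every animal is held out once with all its rows).  In this default world
the LPS group's volatile signature grows with the dose schedule and its
FiO₂ escalates after t30, so accuracies rise with time; `enose_raw` (no
FiO₂ correction) classifies partly on oxygen, which the corrected variants
remove.  `results.frame` gives the same numbers tidy (with sensitivity and
specificity), `results.plot_accuracy()` plots them.

The command-line interface mirrors the stages
(`enose simulate | sample-sim | calibrate | correct | featurize |
train-eval | report | run-all`); `enose run-all` writes every intermediate
(measurement CSVs, correction surfaces, feature tables, results CSV) into
one reproducible, config-stamped output directory.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the full demonstration pipeline end to end (simulate → calibrate →
correct → featurize → per-timepoint LOO evaluation) and writes the
acceptance JSON.  The package's quantitative guarantees are property-based
and live in `tests/test_acceptance.py`: exact reference-level identities of
the correction surfaces, exact collapse of matched-mode synthetic curves,
closed-form surface plateaus, brute-force LOO oracle equivalence,
chance-level behavior under a null generator, label recovery under a strong
effect, raw-vs-corrected asymmetry under a pure FiO₂ confound, exhalation
detection on constructed waves, Wald CI arithmetic, and byte-identical
re-runs.

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
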