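# tapage — behavioral age from smartphone touchscreen dynamics

Smartphones log the onset of every touchscreen interaction, producing a
dense behavioral time series ("tappigraphy").  How those interactions are
timed changes with age: the probability of fast (~100 ms) consecutive
inter-touch intervals falls across adulthood while multi-second intervals
become more common.  `tapage` turns that observation into a normative
aging pipeline for digital-phenotyping research:

1. **Joint interval distribution (JID).**  Consecutive inter-touch
   intervals (ITI at k vs ITI at k+1) are log10-transformed and smoothed
   with a Gaussian kernel (bandwidth 0.1) onto a 50×50 grid spanning
   10^0.5–10^5 ms, giving each subject a 2,500-bin behavioral fingerprint
   that sums to one.
2. **Normative age model.**  An XGBoost regression (depth 9, 567 trees,
   learning rate 1e-2, minimum child weight 8, L1 alpha 1e-3) predicts
   chronological age from the JID plus gender, JID entropy, log10 median
   daily interaction count and screen size, under 10-fold cross-validation.
   Performance is summarized by ME = mean(predicted − real) in years
   (positive ⇒ "older" behavior), MAE, and R² (squared Pearson correlation
   of predicted vs real age).
3. **Attribution.**  Exact tree Shapley values (computed in double
   precision) decompose each prediction into per-feature years; population
   maps show where on the interval plane behavior pushes age estimates up
   or down.
4. **Deviation analysis.**  The healthy-trained model is deployed on a
   disease cohort; the ten per-fold-model median errors are contrasted with
   a bootstrap null built from age-matched healthy subjects' out-of-fold
   errors (10,000 iterations, ±2-year matching without replacement),
   compared by a two-sample t-test, and complemented by a per-patient
   Huber robust regression of predicted on real age.

Because no public tap-stream corpus ships with the package, a first-class
synthetic generator (`tapage.synthetic`) produces multi-day tap streams
from an age-dependent Markov mixture of log-normal ITI regimes, with an
optional "disease" mode that advances a subject's *effective* age.  All
statistical structure the pipeline assumes is therefore testable end to
end; see `docs/methods.md` for what the generator does and does not
emulate.

## Worked example

`examples/` contains one narrative script per capability.  Training a
small normative model and deploying it on an accelerated-aging cohort
(`python examples/05_disease_deviation.py`) prints:

```
patients: 20 (injected acceleration: +8 years)
median error per fold model (first 3): [7.41 8.03 6.48]
age-matched healthy null mean: -0.05 years
behavioral age gap: +6.57 years (injected: +8)
two-sample t = 14.40, p = 1.35e-07
robust fit predicted~real: slope 0.80, R2 0.88, t(18) = 16.32
```

The *behavioral age gap* is the mean patient median error minus the mean
of the age-matched healthy null — the years by which the model considers
patient behavior "older" than matched healthy behavior.  The injected +8
years is recovered attenuated by the model's calibration slope (tree
regressions shrink toward the training mean), which is the expected
behavior of normative age models.

The full-scale pipeline is a one-liner:

```bash
tapage run --config config.yaml --seed 7 --out runs/demo
```

producing cohort CSVs, feature matrices, the serialized 10-fold bundle,
attribution maps, a deviation report and a human-readable summary in the
run directory.  Individual stages (`simulate`, `featurize`, `train`,
`attribute`, `deviate`, `report`) are also exposed as subcommands.

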