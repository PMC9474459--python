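# tetramap

Branched-GDGT paleoclimate reconstruction: fractional abundances, classic
proxy indices, susceptibility-weighted age models, precipitation
calibrations (multiple linear regression and a from-scratch deep
feed-forward network with recurrent baselines), cross-wavelet phase
analysis, and a synthetic-data generator for end-to-end validation.

## Science background

Branched glycerol dialkyl glycerol tetraethers (brGDGTs) are bacterial
membrane lipids preserved in soils and sediments.  Fifteen structural
variants (Ia … IIIc′) differ in methylation number, cyclopentane rings, and
methyl position (5- vs 6-methyl).  Their relative abundances respond to
temperature, soil pH and moisture, which makes downcore brGDGT
distributions a quantitative paleoclimate archive — for example in
loess–paleosol sequences, where magnetic susceptibility additionally
tracks pedogenic intensity and supports orbital-scale age models.

`tetramap` implements this workflow end to end:

- **`tetramap.registry` / `abundance`** — the 15-compound registry
  (masses, methylation classes, SIM ions) and peak-area → fractional
  abundance / absolute quantification against a C46 internal standard.
- **`tetramap.proxies`** — MBT′, MBT′6ME, IR6ME, CBT′, CBT, soil-pH,
  four MAT calibrations, and leaf-wax n-alkane CPI/ACL.
- **`tetramap.agemodel`** — susceptibility-weighted accumulation between
  age-control points (constant susceptibility reduces exactly to linear
  depth–age interpolation), plus uniform age-grid resampling.
- **`tetramap.calibration`** — MAP (mean annual precipitation)
  calibration models: `MlrModel` with full diagnostics (t, F, VIF,
  collinearity detection), a deep feed-forward network (`train_dlnn`)
  trained with from-scratch Adam on MAE loss, RNN/LSTM/GRU baselines
  (`train_baseline`) with exact backpropagation through time, and a
  grid-search / feature-ablation protocol.
- **`tetramap.spectral`** — continuous and cross wavelet transforms
  (Morlet, ω₀ = 6), band-phase summaries with anti-phase verdicts, cone
  of influence, and PCA summaries.
- **`tetramap.synthetic`** — a Dirichlet compositional generator with
  linear / saturating / mixed climate links, downcore profiles with
  orbital periodicities, and phase-shifted paired series.
- **`tetramap.cli`** — a `tetramap` command covering
  simulate / proxies / agemodel / calibrate / predict / gridsearch /
  ablate / mlr / baselines / xwt / pca, with byte-reproducible outputs
  for fixed seeds.

## Worked example

The calibration core follows the statsmodels idiom: construct a model from
data, call `fit()` / `train_*()`, inspect a results object.

```python
import tetramap as tm

# 1. simulate a surface-soil calibration compilation
config = tm.GeneratorConfig(n=400, seed=42)
dataset, truth = tm.generate_calibration_dataset(config)

# 2. classic proxy indices
suite = tm.compute_proxy_suite(dataset.abundances)
print(suite[["MBT_prime", "CBT_prime", "pH", "IR_6ME"]].describe()
      .loc[["mean", "std"]].round(3))

# 3. multiple linear regression, statsmodels style
model = tm.MlrModel(dataset.map_mm.to_numpy(),
                    dataset.features(tm.DEFAULT_FEATURES))
results = model.fit()
print(results.summary())

# 4. deep feed-forward network with a held-out validation split
training, validation = dataset.split(0.25, seed=0)
spec = tm.NetworkSpec(hidden_layers=4, neurons=64, epochs=600, seed=0)
net = tm.train_dlnn(training, spec, validation=validation)
print(f"DLNN validation R2 = {net.validation_metrics.r2:.3f}, "
      f"RMSE = {net.validation_metrics.rmse:.0f} mm/yr")
```

Output:

```text
      MBT_prime  CBT_prime     pH  IR_6ME
mean      0.755      0.535  8.000   0.179
std       0.165      0.331  0.526   0.115
Multiple linear regression
================================================================
                    coef     std err         t     P>|t|     VIF
intercept     -1161.2302
Ia             2908.2683    408.8338     7.114    0.0000  10.764
Ic             -904.7497   1951.5821    -0.464    0.6432   1.994
IIa′           2771.6780   1634.5968     1.696    0.0908  17.473
IIb′         -17050.9535   3289.5175    -5.183    0.0000   4.880
IIc′          12936.4829   3010.3257     4.297    0.0000   3.313
IIIa′          -385.5683   1934.1022    -0.199    0.8421  13.276
IIIb′         16789.4516   3042.0433     5.519    0.0000   2.706
IIIc′         28132.3643   3524.6008     7.982    0.0000   2.642
----------------------------------------------------------------
n=400  R=0.8573  R2=0.7349  s=455.0074  F=135.518
DLNN validation R2 = 0.886, RMSE = 281 mm/yr
```

On the same validation rows the linear model reaches R² = 0.731 — the
network's advantage grows on saturating precipitation links, where a
linear model systematically under-predicts wet sites.

From the command line, an end-to-end anti-phase detection:

```console
$ tetramap simulate --kind series --seed 0 --out pair
$ tetramap xwt pair_s1.csv pair_s2.csv --out xwt.csv --band-period-ka 23
band 23.0 ka: mean phase -3.1245 rad, antiphase=True
```

Run headers (package/library versions, input digests, resolved
parameters) go to stderr, so numeric outputs are byte-identical across
reruns with the same seed.

## Testing

```bash
python -m pytest -q
```

The suite contains unit tests, seeded property tests (hypothesis), and
`tests/test_acceptance.py` with one test per release criterion.  One
acceptance test is a **known partial failure**:
`test_criterion_5_recurrent_overfitting_gap` requires each of the
RNN/LSTM/GRU baselines to overfit more than the validation-tuned DLNN in a
majority of ten seeds; the RNN (6/10) and LSTM (8/10) satisfy it, the GRU
reaches only 5/10 — its update gate acts as an implicit regularizer.  The
protocol was frozen before its first full evaluation and is shipped
unchanged; see `docs/methods.md`.

## Reproducing results

```bash
python scripts/acceptance.py --seed 0 --out targets.json
```

recomputes the six headline targets from scratch through the public API
(calibration intercepts 7.17 °C, 5.58 °C, 20.9 °C, 0.81 °C, pH 7.15, and
the first-Adam-step magnitude 0.001).  The `--seed` only randomizes
abundance mass on compounds each equation ignores; the values are
seed-invariant by construction.  All generator defaults
(`GeneratorConfig`: n = 712, mixed link, Dirichlet concentration 500,
50 mm MAP noise) are the study conditions used throughout the tests.

Methods, model equations and parameter rationale: `docs/methods.md`.
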