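# floralecho

Echo-acoustics of flowers, end to end: ultrasonic impulse-response
measurement by maximum-length-sequence (MLS) deconvolution, calibrated
spectral target strength, bell-flower morphometrics, the associated
statistics, and echo-spectrogram species classification with a multi-input
convolutional network.

## The scientific problem

Nectar-feeding bats find flowers in the dark largely by echolocation, and
some bat-pollinated ("chiropterophilous") plants have evolved acoustically
conspicuous floral structures. Two questions drive this package:

1. **Do bat-pollinated flowers sound different?** Comparing flowers across
   pollination syndromes requires echo measurements that are calibrated
   (independent of the loudspeaker/microphone) and morphology-aware, since
   echo strength grows with flower size.
2. **Are flower echoes species-specific enough to classify?** If a machine
   classifier can name the species from one or a few echo spectrograms, an
   echolocating bat plausibly could too.

The package provides the full computational chain for such a study, plus a
calibrated synthetic-data generator so every stage is testable without any
recordings. For users with real data, the same chain consumes WAV
recordings and a CSV morphology table.

## Models and statistics at the core

* **IR recovery.** A target is ensonified with a periodic MLS (order 14:
  L = 16 383 samples, 33 ms at 500 kHz). Since the circular autocorrelation
  of an MLS is L·δ − 1, cross-correlating the period-averaged steady-state
  recording (50 of the 60 usable periods in a 2 s recording) with the
  sequence yields the impulse response.
* **Target strength.** TS(f) = 10·log₁₀ P_flower(f) − 10·log₁₀ P_plate(f),
  the windowed-echo PSD referenced to a flat plate at 10 cm measured through
  the identical chain. Band values (broad 40–160 kHz; 45/68/102/153 kHz
  ±20 %) and angle/plane averages are computed on linear power ("after
  delog").
* **Morphometrics.** Bell surface area
  `F_sur = π·r_p/(6h²)·[(r_p² + 4h²)^{3/2} − r_p³] + π·r_c²`
  (paraboloid chalice of radius r_p = inner diameter/2 and height
  h = corolla length, plus the opening disc of radius r_c = outer
  diameter/2); relative variability via the coefficient of variation
  c_V = σ/μ (sample SD).
* **Statistics.** OLS of band TS on ln(area); Welch's t on the residuals by
  syndrome; per-species/per-syndrome c_V summaries; likelihood-ratio tests
  of nested linear mixed models (random family intercept, ML refits).
* **Classifier.** Echoes = high-passed bat call ∗ IR; spectrograms
  (Hann 256, 90 % overlap); chunks of k ∈ {1,3,5,7,10} echoes per flower,
  sampled randomly or at angular intervals; flower-stratified
  train/val/test splits (8/2/2 of 14); a shared-branch CNN (conv 16 →
  pool per echo, concatenate, conv 32 → pool, dense 256/128/12, softmax)
  trained with Adam and early stopping; evaluation with confusion matrices
  and exact Clopper–Pearson intervals.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a study and run the acoustic/statistical analysis:

```bash
python analysis/01_simulate_study.py          # 168 flowers, 2-plane scans
python analysis/02_target_strength.py         # band TS + statistics
python analysis/03_morphometrics.py           # cV tables and summaries
python analysis/04_train_classifier.py        # quick CNN demo (k=3)
```

Output of the analysis on the default seed:

```
TS ~ ln(area): slope 3.451 dB/ln(mm^2), intercept -32.173 dB, R^2 0.843 (n=168)
residual syndrome contrast: bat - other = 2.92 dB (Welch t=32.65, df=165.7, p=4.34e-74)
LMM LR test (syndrome + interaction): chi2(2) = 336.78, p = 7.38e-74
morphological cV: bat 0.085 vs other 0.156
```

The slope/intercept recover the generator's calibrated log-linear TS model
(3.488, −32.422) within sampling error; the ~3 dB residual contrast is the
configured bat-syndrome offset; the c_V group means recover the calibrated
morphological variability (0.08 vs 0.16). The classifier demo trains a
k = 3 multi-input CNN on reduced scans; on a 3-species well-separated
benchmark (as run in the test suite) it reaches:

```
test accuracy: 0.967   (30 epochs, 3 classes, k=3 random chunks)
```

On the full 12-species catalog at quick-demo settings (15 epochs, 21-angle
scans) it reaches ~32 % versus the 8.3 % chance level; species in the
default generator differ mainly by size, so long training mostly sharpens
size discrimination.

A library-level sketch of the same pipeline:

```python
from floralecho import synthdata, sonar, pipeline, stats

table = pipeline.simulated_band_ts_table(seed=1)   # 168 flowers -> band TS
fit = stats.fit_ts_regression(table)               # TS = a ln(area) + b
welch = stats.residual_syndrome_test(fit, table["syndrome"])
print(fit.slope, fit.intercept, welch.difference)
```

There is also a CLI: `floralecho simulate|process|train|evaluate --help`.

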