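# throwspeed

Estimating how fast a handball player throws usually requires a multi-camera
motion-capture laboratory, which rules out routine monitoring in training
halls. A cheap alternative is a wrist-worn triaxial accelerometer: the peak
total acceleration of the wrist during a throw carries most of the
information about ball release speed. `throwspeed` implements that
estimation method end to end, for sports scientists and injury researchers
who want to develop, validate or reuse accelerometer-based throwing-speed
models:

* a **synthetic study generator** that emulates a laboratory validation
  cohort — 19 players (8 female, 11 male), 25 throws each over five throw
  types, with 240 Hz ball/hand marker trajectories and a continuous 500 Hz
  wrist-acceleration stream per session;
* the **kinematic ground truth**: ball release speed measured from marker
  data (two-way 2nd-order Butterworth low-pass at 20 Hz, forward-difference
  speed, release = first frame where the ball–hand distance grows by >1 cm);
* the **accelerometer feature**: per-throw peak total acceleration
  `a = max ‖(ax, ay, az)‖` in g, extracted by segmenting the session stream
  at norm peaks;
* the **four prediction models**, ordinary least-squares regressions of
  release speed `v` (m/s) on the log peak acceleration and optional
  covariates (treatment coding, references female / jump throw):

  ```
  Base:  v = β₀ + β₁ ln a
  Sex:   v = β₀ + β₁ ln a + β₂ 1[male]
  Type:  v = β₀ + β₁ ln a + β_type
  Full:  v = β₀ + β₁ ln a + β₂ 1[male] + β_type
  ```

  including `published_model(...)`, each model pre-loaded with the published
  coefficient estimates and 95% CIs (e.g. Full: β₀ = 9.0, β₁ = 2.7,
  β₂ = 2.4);
* **validation**: 10-fold cross-validation with per-fold R² and mean
  absolute error, and three-level calibration assessment on the pooled
  out-of-fold predictions — mean calibration (mean predicted − mean
  observed), calibration slope (OLS slope of observed on predicted) and a
  binned moderate-calibration curve with plots.

## Worked example

```python
import numpy as np
from throwspeed import GeneratorConfig, generate_study, fit_model, cross_validate, published_model
from throwspeed.synthdata import features_from_truth
from throwspeed.models import predict

# a full synthetic study: 19 participants x 25 throws
study = generate_study(GeneratorConfig(seed=0))
features = features_from_truth(study.truth)

full = fit_model(features, "Full")
print(full.params.round(2))
report = cross_validate(features, "Full", k=10, seed=0)
print(f"MAE {report.mae_mean:.2f} m/s, R2 {report.r2_mean:.2f}, "
      f"slope {report.calibration_slope:.2f}, "
      f"mean calibration {report.mean_calibration:+.3f} m/s")

# published Full model: a 80 g jump throw by a female player
rows = features.iloc[:1].assign(log_peak_accel=np.log(80.0), sex="female", throw_type="jump")
print(f"predicted speed {predict(published_model('Full'), rows)[0]:.2f} m/s")
```

prints

```
intercept         8.81
log_peak_accel    2.75
sex_male          2.37
type_low_norun   -4.91
type_med_norun   -3.64
type_max_norun   -0.36
type_max_run      0.59
dtype: float64
MAE 1.24 m/s, R2 0.84, slope 1.00, mean calibration +0.001 m/s
predicted speed 20.83 m/s
```

The fitted coefficients recover the generating (published) values within
their sampling error; the cross-validated Full model is well calibrated
(slope 1.00, mean calibration ≈ 0) with MAE ≈ 1.3 m/s, the precision implied
by the generator's 1.63 m/s residual SD (`E|N(0,σ)| = σ√(2/π)`), and the
published Full model maps an 80 g peak to 9.0 + 2.7·ln 80 = 20.83 m/s.

## The analysis, step by step

The numbered scripts under `analysis/` run the study as a narrative, each a
thin driver over the library that prints what it found and writes its tables
under `results/`:

```bash
python analysis/01_simulate.py --seed 0    # truth table + raw signals
python analysis/02_release_speeds.py       # marker kinematics -> speeds
python analysis/03_extract_features.py     # stream segmentation -> peaks
python analysis/04_fit_models.py           # OLS coefficients + 95% CIs
python analysis/05_validate.py             # 10-fold CV + calibration plots
```

The same chain is available as a single command (`throwspeed run --out
results/run --seed 0`), and each stage individually as `throwspeed
simulate|speeds|features|fit|predict|validate`.

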