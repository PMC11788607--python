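# reachbias

Simulation and analysis pipeline for **embodied perceptual decision
making**: does the reaching distance to a response button bias a
two-alternative forced choice (2AFC)?

The package is aimed at psychophysicists who run (or re-analyze)
touchscreen 2AFC experiments in which the left/right response buttons sit at
different reaching distances — a near button at 15.4 cm and a far button at
38.5 cm from the start position, with the near side varying randomly across
trials.  It provides:

* a **synthetic observer** with a known, condition-dependent decision bias,
  run through the experiment's adaptive design (four interleaved 1-up/1-down
  staircases of 75 trials per 300-trial block, for a motion-coherence task
  and a Gabor-orientation task, each with a main and a control block),
  including 60-Hz stylus trajectories with rare changes of mind;
* **psychometric fitting**: maximum-likelihood equal-asymptote cumulative
  Gaussians, ψ(x) = λ + (1 − 2λ)Φ((x − m)/σ), parameterized by threshold m,
  width w = 3.2897 σ and guess/lapse rate λ, with parametric-bootstrap 95%
  CIs and a lapse-based screening rule (λ > 0.05);
* the **decision-bias statistic** — bias = m(right closer) − m(left closer),
  negative = attraction to the nearer button — with root-sum-of-squares CI
  propagation, Wilcoxon signed-rank tests (exact p for n ≤ 25, W as the
  smaller rank sum, rank-biserial effect size r_rb = (W⁺ − W⁻)/(W⁺ + W⁻)),
  main-vs-control comparison and cross-task Spearman correlation;
* **trajectory kinematics**: reaction time, movement time, initial velocity
  and first-exit-side change-of-mind classification, with
  median-of-medians group summaries;
* a coordinate-level **random-dot kinematogram** generator (alternating dot
  sets, limited lifetime, mirrored noise directions) and the Gabor angle
  mapping (angles symmetric about 45°).

Externally recorded trial logs in the documented CSV schema can be run
through the same fit/analyze/report stages.

## Worked example

```bash
reachbias all --seed 1 --n-participants 24 --out-dir runs/demo
```

simulates a 24-participant cohort (28,800 trials), fits 192 psychometric
curves, and writes `trials.csv`, `fits.csv`, `bias.csv`, `stats.json` and
`report.md`.  The same analysis from Python:

```python
from reachbias import observer, pipeline

trials, _ = observer.simulate_experiment(n_participants=24, master_seed=1,
                                         collect_trajectories=False)
fits = pipeline.fit_cohort(trials)
biases = pipeline.compute_biases(fits)
stats = pipeline.analyze_biases(biases)
print(biases.groupby(["task", "block"]).bias.mean().round(1))
print(stats["per_block"]["motion/main"])
```

prints (seed 1):

```
task         block
motion       control    -2.5
             main       -6.8
orientation  control    -1.1
             main       -5.9
Name: bias, dtype: float64
{'n': 24, 'median': -8.65..., 'W': 37.0, 'w_plus': 37.0, 'w_minus': 263.0,
 'r_rb': -0.753..., 'p': 0.00065, 'method': 'exact'}
```

The generator's task presets carry a true main-block bias of −9.9%
(motion) and −7.0° (orientation) plus between-participant spread, so the
estimated mean biases above recover the generating values within cohort
noise, the main-block signed-rank tests are strongly significant, and the
control-block biases are small — the structure the analysis is designed to
detect.  `report.md` lays the same numbers out as a parameter table
(threshold/width/lapse per task × block × condition), a bias table and test
lines of the form `Mdn, W, r_rb, p`.

See `docs/methods.md` for the model, the estimator's numerical choices, the
synthetic observer's assumptions, and known limitations; run
`reachbias config-template` for the full configuration surface.

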