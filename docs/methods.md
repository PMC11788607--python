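# Methods

`reachbias` implements, end to end, the analysis of a two-alternative
forced-choice (2AFC) touchscreen experiment in which the two response
buttons sit at different reaching distances, together with a synthetic-data
generator that emulates the experiment closely enough for every stage of the
analysis to be validated by parameter recovery.

## The experimental design being modelled

Participants slide a stylus from a start button (radius 2.5 cm, centred at
(0, 7.5) cm in a frame with x from the body midline and y from the screen
bottom) to one of two response buttons (radius 1.7 cm).  The buttons are
placed asymmetrically: the near button is 15.4 cm from the start, the far
button 38.5 cm.  Two conditions swap which side is near
(`left_closer`: left at (−12.5, 16.5), right at (31.25, 30);
`right_closer`: mirrored).  Two tasks supply the perceptual evidence:

* **motion** — a random-dot kinematogram; the signed stimulus level is the
  coherence in % (negative = leftward);
* **orientation** — two Gabor patches with angles symmetric about 45° from
  vertical; the level is the angle difference left − right in degrees
  (positive = right Gabor more vertical).

Each block runs four interleaved fixed-length staircases (condition ×
starting sign; 75 trials each, 300 per block), 1-up/1-down on the *response*:
a "left" answer moves that staircase's next level one step towards rightward
evidence.  Motion staircases start at ±50% with 5% steps and ±100% limits;
orientation at ±40° with 2° steps and ±80° limits.  In the *main* block the
buttons are visible before the stimulus; in the *control* block they appear
only once the stylus leaves the start button.

## Statistical model

Choices are modelled by an equal-asymptote cumulative Gaussian

ψ(x) = λ + (1 − 2λ) Φ((x − m)/σ),

with threshold m (level of 50% rightward choice), width
w = 2 Φ⁻¹(0.95) σ ≈ 3.2897 σ (distance between the 5% and 95% points of the
unscaled sigmoid), and a single guess/lapse rate λ ∈ [0, 0.49].  One curve is
fitted per participant × task × block × condition (pooling that condition's
two staircases), by constrained maximum likelihood with every trial weighted
equally.

The **decision bias** is m(right closer) − m(left closer); negative values
mean attraction towards the nearer button.  Its 95% CI combines the two
threshold CIs by root-sum-of-squares of the per-side half-widths.  Group
inference uses the Wilcoxon signed-rank test: zeros dropped, average ranks
for ties, W reported as the smaller rank sum, exact two-tailed p from the
rank-sum distribution recursion for tie-free samples with n ≤ 25, otherwise
a tie-corrected normal approximation without continuity correction.  The
effect size is the signed rank-biserial correlation
r_rb = (W⁺ − W⁻)/(W⁺ + W⁻); this (W = min-sum, r_rb signed) convention is
self-consistent across all the group statistics the package reports.
Cross-task association of biases uses Spearman's ρ with a permutation
p-value (10⁴ shuffles by default).

### Numerical choices

* Optimization: L-BFGS-B with analytic gradients; deterministic multi-start
  over threshold ∈ observed-level quantiles {0.25, 0.5, 0.75} ×
  width ∈ {span/4, span/2, span} × lapse ∈ {0.01, 0.05}; local searches run
  from the six grid points with the best likelihood.  Bounds: threshold
  within the observed range padded by one span, width in [span/20, 5·span],
  lapse in [0, 0.49] (the upper bound must admit severely lapsing curves,
  e.g. 0.24).
* ψ is clamped to [1e−10, 1 − 1e−10] before logs.
* Degenerate data (all responses to one side) return an unconverged fit with
  the threshold pinned just outside the observed range instead of raising.
* CIs: parametric bootstrap (999 draws by default) — binomial resampling
  from the fitted curve at the observed levels, refits seeded at the
  original estimates, percentile intervals; refit failures are dropped and
  more than 10% failures flags the CI unreliable.
* Lapse screening: participants with any fitted λ > 0.05 (strictly) are
  flagged; exclusion itself is left to the analyst.
* Medians of even-count sets are the mean of the two central order
  statistics.

## Kinematic measures

From each 60-Hz stylus trace: reaction time = timestamp of the first sample
outside the start disk (inside means distance ≤ radius); movement time =
from that exit to the first sample strictly inside a response button;
initial velocity = displacement across the boundary-crossing sample pair
divided by the sample interval; change of mind = first-exit side (sign of x
relative to the start centre) differs from the registered response side,
with exits exactly on the midline deferring to the next off-midline sample
(no change of mind if none).  Reaction times and movement times are
summarized as means across participants of per-participant medians (per
stimulus level and overall), excluding misses.

## The synthetic observer

The generator's purpose is to produce data whose *statistical structure*
matches what the analysis assumes, with a known ground truth:

* **Choices**: ψ as above, with condition-dependent threshold
  m_c = m0 ± delta/2 (+ for `left_closer`), so the implied decision bias is
  exactly −delta.  Control blocks use `control_delta` instead.  A
  `miss_rate` (default 0.01) produces no-response trials, which consume a
  staircase trial without moving the level and are excluded from fitting.
* **Reaction times**: lognormal around
  base + gain · exp(−|x − peak|/τ), slowest near a slightly off-zero level,
  emulating the uncertainty peak of the empirical RT curves.
* **Trajectories**: constant-speed polyline reaches sampled on the 60-Hz
  grid — dwell at the start centre until the drawn RT, then straight to the
  chosen button at the near/far speed (77 / 87 cm/s, ~10% lognormal jitter),
  scaled by 0.8 in control blocks (a more cautious start).  With probability
  `com_prob` (default 0.01) the first 2.8–4 cm of the path head towards the
  *other* button before redirecting; the excursion is drawn beyond the
  2.5-cm start radius so the first-exit classifier can see it — shorter
  excursions would redirect inside the start disk and be undetectable by
  construction.

Task presets place the generator at the study's scale: motion m0 = −3.8,
delta = 9.9, σ = 29.5 (width ≈ 97%), control_delta = 3.1; orientation
m0 = 7.3, delta = 7.0, σ = 14.9 (width ≈ 49°), control_delta = 1.0.  Cohort
simulations draw per-participant parameters around the presets
(m0 SD 8%/4°, delta SD 8%/5°, lognormal σ spread 0.4/0.5), chosen to match
the between-participant SDs of the fitted parameters; an optional
`cross_task_r` correlates a participant's biases across tasks (default 0).
Seeds flow master → participant → (task × block) → {schedule, response
stream, motor stream}, so a cohort is byte-reproducible from one integer and
the response sequences do not depend on whether trajectories are collected.

What the generator does **not** emulate: sequential dependencies and
learning, RT–choice coupling beyond the shared stimulus level, curved or
accelerating reach kinematics, and any coupling between initial velocity and
movement time — a single constant sliding speed cannot reproduce both the
empirical initial-velocity (~130–160 cm/s) and movement-time (~200/440 ms)
medians simultaneously, and the movement-time scale was prioritized.
Passing recovery tests therefore validate the estimators and test machinery
under the model's assumptions, not the analysis' robustness to real motor
behaviour.

## Random-dot kinematogram generator

Coordinates only (no rendering): 102 dots in 3 sets of 34 displayed on
alternating frames, so each set updates every third frame and a surviving
dot moves dot_speed · 3/frame_rate = 0.825 cm per update (16.5 cm/s on
screen).  Per update a dot is redrawn uniformly in the aperture with
probability 1/6 (expected lifetime 6 updates = 100 ms at 60 Hz) or when it
leaves the aperture.  round(|c|/100 · 34) dots per set (round half away from
zero) move coherently at 0° or 180°; the noise dots are assigned directions
in right–left mirrored pairs (θ, 180° − θ) so their summed horizontal unit
components cancel exactly, with an odd leftover dot sent straight up or
down.  The aperture radius defaults to the displayed 8.5-cm cloud; the
24.6-cm generator-unit figure is carried as metadata since its relation to
the displayed size is not fully determined.  Each simulated trial draws a
fresh kinematogram rather than reusing a bank of pre-generated movies.

## Validation scale and known limitations

The test suite validates, at the study's own design size (4 × 75 trials per
block): threshold recovery within width/5 for ≥90% of 400 fits over 200
simulated participants; cohort-level bias recovery (24 participants,
delta = 10 → mean estimated bias within [−13, −7] and a significant
signed-rank test) with a ~5% false-positive rate over 200 null cohorts;
exact signed-rank p-values against exhaustive sign enumeration for n ≤ 10;
parametric-bootstrap threshold-CI coverage of 95% ± 3% over 500 replicates
of a 300-trial constant-stimuli design; and recovery of a 1% change-of-mind
rate from 10⁴ classified reaches.  In the recovery experiments the
generating bias is held fixed across participants so the target is known
exactly; the heterogeneous cohort presets are used for realistic end-to-end
simulations.

Known limitations:

* With *staircase-only* data the lapse rate is poorly identified (nearly all
  trials sit near threshold), and the plain MLE trades lapse against width;
  threshold estimates remain accurate, but parametric-bootstrap threshold
  CIs become mildly anticonservative (~88% empirical coverage in a 200-check
  experiment).  A lapse prior would mitigate this but would depart from
  plain maximum likelihood; the CI coverage guarantee above is stated for
  designs that constrain the asymptotes.
* The exact Wilcoxon path requires tie-free |differences|; fitted biases are
  continuous so ties essentially never occur there, but externally supplied
  rounded data will silently use the normal approximation (reported in the
  `method` field).
* Counterbalancing of task/block order is not simulated: the observer has
  no session-order effects, so order bookkeeping would be inert.
* Practice blocks, the screen tilt (43°) and viewing distance (70 cm) are
  metadata only; no 3-D reach modelling.
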