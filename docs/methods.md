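# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Decoder

The group-weight decoder maps per-channel spike counts on a 100 ms grid
to 2-D cursor velocity. Per bin: (1) a trailing 5-bin moving average of
counts, zero-padded at session start (equivalent to assuming silence
before t = 0 — simple and causal), converted to rates in Hz; (2) group
sums over the four channel groups, ordered (right, left, up, down) =
(+x, −x, +y, −y); (3) z-normalization against pre-experiment (μ_k,
δ_k), offset by c and rectified at zero; (4) velocity
v_x = w(a_1 − a_2), v_y = w(a_3 − a_4), clamped per axis after the gain
(no magnitude clamp — the two axes are treated independently
throughout, so a diagonal command may exceed v_max in Euclidean norm by
√2).

Defaults: bin width 0.1 s, 5 smoothing bins, c = 1 (an action value of
1 means "group at its resting mean"), w = 0.375 cm/s per action-value
unit, v_max = 15 cm/s. All are configurable in `DecoderConfig`.

**Normalization.** μ_k is the mean of the group-summed rate over the
pre-experiment's 100 ms bins; δ_k is the *population* SD of the same
series, floored at `delta_floor` (0.1 Hz) so a near-constant
pre-experiment cannot blow up the division. By default δ_k is computed
on the **raw binned** sums rather than the smoothed series. This is a
deliberate calibration choice: the run-time signal is smoothed over 5
bins, so its SD is roughly δ_raw/√5 for weakly correlated input, and
z-scores computed against δ_raw rarely fall below −c. The rectification
then almost never bites, giving the decoder its designed stationarity
property — on input statistically identical to the pre-experiment, mean
action value ≈ c and mean velocity ≈ (0, 0). Had δ been computed on the
smoothed series, the run-time z-score would have unit SD and
rectification at c = 1 would inflate the mean action value by
φ(1) − Φ(−1) ≈ 0.08, a systematic directional bias whenever opposing
groups differ in variability. `normalize_on_smoothed=True` restores the
other reading (the pre-experiment statistics then use only
fully-populated smoothing windows to avoid the startup ramp).

**Chaining.** Each session's (μ, δ) come from its own pre-experiment
segment; that segment itself runs closed-loop under the previous
session's constants. The first session's constants come from an idle
recording (no task-directed intent).

## Task

Center-out task in two variants. Variant T: peripheral targets only, at
the four cardinal directions (uniform draw), random freeze period
(default 2.5–5 s) before each movement during which decoded velocity is
ignored, cursor reset to center after every trial. Variant K: center
and uniform-random-angle peripheral targets alternate without delay, no
freeze, no reset; a trial's direction is the angle from its start
position to the target center. Timing: hold 200 ms, movement timeout
15 s by default (10 s is the other published setting), both excluding
freeze. A trial fails on the first bin whose cumulative movement time
exceeds the timeout; its recorded duration is clamped to the timeout.

Numerical decisions: the target ring is treated as a capture disk
(distance to center ≤ radius); the hold clock accumulates in whole
100 ms bins and resets on target exit (the conservative convention for
center-out tasks); integration is forward Euler at dt = 0.1 s with the
position clipped to the workspace rectangle. Geometry is not part of
the published parameter set, so the package defaults are target
distance 7 cm, target radius 1.5 cm, workspace 30 × 25 cm, all
configurable.

## Synthetic population

The stand-in for recorded motor-cortical multi-units. Each unit fires
as an inhomogeneous Poisson process in 10 ms bins with rate

    max(0, baseline + depth·cos(θ_intent − PD) + ε),  ε ~ N(0, σ²)

with ε drawn once per 100 ms bin (a shared slow noise component;
the Poisson draw adds fast variability), falling back to baseline + ε
when there is no intent. The simulated user's intent is a straight
line to the current target, absent during freeze bins and, with
probability 1 − engagement, on disengaged bins. No refractoriness is
modeled; at 100 ms decoding resolution the Poisson aggregate is an
adequate multi-unit model.

Defaults (the package's study conditions): 16 direct units (4 per
group) + 16 indirect units; baseline 10 Hz; depth 8 Hz direct, 1.5 Hz
indirect; σ = 5 Hz direct, 2 Hz indirect; engagement 0.85. Direct
units start with PDs offset uniformly 45–135° from their assigned
direction: early-session tuning should *not* be aligned with the
decoder — initial control is poor, which is precisely the situation
bio-feedback learning starts from. With smaller initial offsets
(≤ 45°) the first session already succeeds almost always and there is
no learning curve to detect.

**Learning is imposed, not emergent.** Between sessions each direct
unit's PD rotates along the shorter arc toward its AD by up to 11°
(never overshooting) and σ is multiplied by 0.82; indirect units are
untouched. This is a generator of data with the statistical signatures
a learning analysis must detect (rising success, rising output-potent
values, rising tuning R², shrinking |PD − AD|), not a model of how
cortex learns. The null schedule (rotation 0, decay 1) is the
no-learning control. Consequences for interpretation: passing tests
show the *analyses detect imposed learning of this shape and size*;
they say nothing about whether real cortex learns this way, and the
simulator does not reproduce absolute published success-rate numbers,
which depend on animal behavior.

What the generator does not emulate: electrode drift and unit dropout,
inter-unit noise correlations, non-cosine tuning, reaction times and
re-aiming dynamics, reward-modulated engagement, slow non-stationarity
within a session.

## Chance baseline

Movement-epoch bins (inside trials, freeze excluded) are extracted at
10 ms resolution, permuted jointly across channels — the stricter null,
preserving each bin's population vector and hence instantaneous
correlations — re-summed into 100 ms bins, and replayed through a fresh
decoder with the session's own (μ, δ). The offline task uses the
session's parameters except that every trial is clocked at exactly
10 s; failures consume the full 10 s of data, successes end at hold
completion. Between replay trials the cursor is reset to center
(variant T) or relocated to the last target's center (variant K). An
incomplete final trial is discarded.

## Analyses

* **Trajectory score**: path length of a successful trial divided by
  the start-to-target-center distance; 1 is perfectly straight.
* **Output-potent / output-null**: using the target sector's group pair,
  potent = a_toward − a_away, null = a_toward + a_away, averaged per
  trial. The optional medium-speed filter keeps bins with Euclidean
  cursor speed in [0.25, 0.75]·v_max; v_max (the clamp, 15 cm/s) is
  used as the "maximum speed" reference — the session's empirical
  maximum is the other defensible reading. Trials with no surviving
  bins are flagged and excluded from averages.
* **Direction tuning**: OLS of rate on (1, cos θ, sin θ) over movement
  bins, θ the current target direction (callers supply cursor-relative
  angles for variant-K style analyses). PD = atan2(b2, b1); tuning
  depth = 2‖(b1, b2)‖, the peak-to-trough range of the fitted cosine;
  R² is the coefficient of determination.
* **Normalized |PD − AD|**: |wrap(PD − AD)|/π ∈ [0, 1]; 0 = aligned,
  1 = opposite, 0.25 at the 45° sector edge.
* **Success trend**: logistic regression of trial outcome on session
  index (aggregated to per-session binomial counts — identical
  likelihood, faster). Significance is the Wald test on the slope;
  the fit quality measure is McFadden's pseudo-R² computed on the
  Bernoulli log-likelihood scale. Complete separation (including
  constant outcomes) is detected and flagged; a ridge-penalized fit is
  then reported with a NaN p-value rather than a spurious one.
* **Occupancy maps**: per-cell visit counts of logged positions on a
  user-supplied grid, poolable by direction and session stage.

Early/late comparisons throughout use the first and last quarter of
sessions.

## Problem sizes and determinism

The packaged study conditions for multi-session runs are 12 sessions of
180 s with 60 s pre-experiments — long enough for ~10–15 trials per
session and stable normalization, small enough that a five-seed
replication suite runs in well under a minute. Statistical calibration
checks use 10⁴ decoder bins (stationarity), 50 units × 2000 bins
(tuning recovery), and 500 replicates of 12 × 100 trials (trend-test
type-I error and power). All randomness flows from explicit
`numpy.random.Generator` seeds; identical seeds give byte-identical
session logs.

## Known limitations

* The decoder's clamp is per axis; diagonal speeds can reach √2·v_max.
* The baseline's radius-monotonicity property is only measurable where
  the shuffled replay can actually reach targets; under the default
  7 cm geometry the light-tailed synthetic noise diffuses ~1 cm in
  10 s and chance success is 0 at any radius, so that check uses a
  2.5 cm target distance.
* `select_groups` borrows out-of-sector units by angular distance to
  the sector center with deterministic channel-id tie-breaks; other
  "nearby" rules are admissible and may pick different borderline
  units.
* Variant K's relative-direction tuning regressor is left to the
  caller; `unit_tuning_table` uses absolute target direction.
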