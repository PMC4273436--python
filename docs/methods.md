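# Methods

## Arena model and conventions

The arena is a disk of radius 50 mm centered on the origin, with the two
illumination borders fixed along the coordinate axes. Quadrants are labeled
by the sign pattern of (x, y) — Q1 = (+,+), Q2 = (−,+), Q3 = (+,−),
Q4 = (−,−) — so the diagonal pairs {Q2, Q3} and {Q1, Q4} are the units of
illumination. Points exactly on an axis are assigned deterministically by
treating the zero coordinate as positive (x first, then y); border-distance
ties choose the vertical border. Positions up to 1 mm outside the radius
are tolerated as tracker jitter; anything farther raises an error, so a
cm-vs-mm unit mistake fails loudly instead of silently rescaling.

The default schedule is the standard 120 s protocol (dark / Q2&3 lit /
dark / Q1&4 lit, 30 s each). On the lit side the irradiance ramps linearly
from 3 µW/mm² at the border to 34 µW/mm² at 10 mm, constant beyond; the
dark side is modeled as 0 µW/mm² — spill below the ramp minimum exists in
real arenas but is not quantified, and no analysis here consumes absolute
intensity on the dark side.

## Choice-zone segmentation and classification

The choice zone is the ±5 mm band around either border, excluding a
central disk (default radius 10 mm). The exclusion exists because the two
borders intersect at the center (which also houses an air hole): inside
that disk "distance to *the* border" and "side of *the* border" are not
well defined. An event opens at the first sample inside the band after a
sample outside it and closes at the first subsequent sample outside the
band. Entry side is the illumination state of the pre-entry sample; exit
side is the illumination state of the first out-of-band sample.

Events are censored rather than classified when the label would be
ill-defined: tracking gaps within the event, track loss inside the band,
dark epochs (no lit side exists), events straddling an epoch boundary,
entries within 1 s of a light-on transition (the light state must be
stable), and events that enter from or exit into the central exclusion
disk. The last rule is a deliberate design choice: classifying center
exits by quadrant sign assigns a near-coin-flip side to visits that never
resolved into a border crossing, which adds an occupancy-dependent bias to
exit fractions. All censoring reasons are counted and reported, so the
exclusions are auditable.

Entry angle is measured from the displacement vector spanning the 3 frames
(0.1 s) before entry to the entry frame, against the border line, folded to
[0°, 180°) with 90° = perpendicular; the window is configurable and the
3-frame default suppresses single-frame jitter while staying local. Prior
displacement is net displacement over the 1 s before entry (path length is
available as an option); the filter keeps events with angle in [45°, 135°]
and displacement strictly greater than 5 mm. Confidence intervals on exit
fractions are Wilson 95% intervals. Re-entries by the same fly count as
independent events — the trajectory, not the fly, is the unit, matching how
group assays with unidentified individuals are scored.

## Kinematics

Speed is ‖p_t − p_{t−1}‖ · f at frame rate f; angular speed is the absolute
change of the velocity heading between successive displacement steps,
wrapped to [0°, 180°] per frame, times f. Headings are undefined below
0.5 mm/s (configurable), where displacement direction is jitter-dominated;
frames following tracking gaps are undefined. Velocity heading is used
rather than body orientation because centroid trackers provide no reliable
orientation; for walking flies the two agree except near standstill, which
the speed threshold removes.

State-conditioned means (lit vs unlit quadrants during light-on epochs)
pool frames across flies within one video; the video is the replicate unit.
A frame's speed is attributed to a state only when both flanking samples
share that state: the boundary-crossing step is size-biased (fast steps are
more likely to cross), and including it inflates the mean of whichever
state is occupied mainly in transit. Angular speed analogously requires
three consecutive same-state samples.

## Memory indices

All reciprocal designs use the same convention: the per-group index is the
normalized count difference between CS− and CS+ options, signed so that
positive always means behavior consistent with training (avoid a punished
CS+, approach a rewarded CS+), and the performance index is the mean of the
two reciprocal group indices. With this sign convention an innate bias
identical in both groups cancels exactly — algebraically, not just in
expectation. The visual assay also exposes a "difference" convention (the
between-group difference of raw preferences, i.e. twice the mean) because
both conventions circulate for that assay; the mean-of-reciprocals is the
default for cross-assay comparability. Time-series inputs are averaged over
the final 10 s of a 2-min T-maze choice period, or the whole 90 s visual
test at 1 frame/s. Flies that fail to choose are excluded from totals by
construction (only arm counts enter).

## Sleep scoring

Sleep is a maximal run of ≥ 5 consecutive minutes with zero beam-crossing
counts (the standard single-beam DAM criterion); runs of 4 minutes or less
contribute nothing. Daily totals intersect bouts with calendar days and the
12:12 light/dark split, apportioning boundary-spanning bouts by minutes.
Percent sleep change is 100 · (mean daily sleep on days 4–5 − day-3 sleep)
/ day-3 sleep, per fly; the cohort summary reports both the mean of per-fly
changes and the change computed on cohort-mean sleep. The per-fly mean
inherits a small positive Jensen bias from the noisy single-day
denominator, so the cohort-mean aggregation is the better-behaved summary
and both are always reported. A trailing all-zero run of ≥ 12 h to the end
of the record flags the channel as a dead fly for exclusion. Missing
minutes are an error — no imputation.

## The synthetic generators

The generators exist to exercise the analysis code with data whose
ground-truth structure is known; they make no claim of mechanistic fidelity
to the underlying neural circuits.

**Arena cohorts** are correlated random walks: 20 flies, 120 s at 30 fps by
default. Per frame, speed is drawn from a normal (mean 10 mm/s, sd 3,
truncated at 0) and heading diffuses with variance 3000 deg²/s — together
these give a mean angular speed of roughly 240 deg/s, in the range of
walking flies, and a nonzero spontaneous turnaround rate inside the choice
zone (~15% of committed approaches at valence 0), which is the baseline the
valence mechanism modulates. Near the wall (within 8 mm) flies steer
smoothly toward the center; a step that would exit the arena instead slides
along the wall by rotation about the center, preserving step length so wall
contact cannot distort measured speed.

Valence acts only at choice-zone entries, not on steady-state kinematics.
On entering the band during a light-on epoch a fly makes one decision:
heading toward the lit side it reverses (a smooth ~180° turn over ~0.3 s,
jittered) with probability max(0, −v), or commits to the crossing with
probability max(0, +v); heading toward the dark side the probabilities
swap. A committed fly aims across the nearest border and suspends heading
diffusion until it leaves the band — without the commitment branch the
expected exit fraction would be flat for all favorable valences, because
the forced-reversal probability is zero there; with it the expected
dark-entry exit-to-lit fraction is strictly increasing in v on both sides
of zero. Separate lit-quadrant multipliers scale speed and heading
diffusion to emulate kinematic (sensory-driven) phenotypes; they default
to 1, so valence and kinematics are independent axes. Co-activation adds
valences and clips to [−1, 1]. One caveat documented here: forced
reversals are themselves turning maneuvers executed on a specific side of
the border, so strong valences leave a signature in state-conditioned
*angular* speed even with multipliers at 1; the speed null is clean.

**DAM activity** is a per-minute two-state Markov chain (wake/sleep) with
light-dependent transition probabilities: wake→sleep 0.03 (day) / 0.09
(night), sleep→wake 0.08 (day) / 0.05 (night). This gives ~650 min of
daily sleep, night-dominant, with mean bouts of ~12 min by day and ~20 min
by night — within the realistic range for female flies, and short enough
that single-day sleep totals have moderate sampling variance, so a
32-channel design resolves cohort effects of tens of percent. Counts are
Poisson (mean 2/min) while awake and 0 while asleep; awake zero-count
minutes are allowed and occur (~14%), mildly extending scored bouts exactly
as in real DAM data. The activation phase rescales the stationary sleep
probability by a factor f (f = 0.6 imposes −40%) by adjusting only the
wake→sleep rate, which leaves the bout-length distribution unchanged so
the ≥ 5-min scoring criterion affects all phases equally and the imposed
percent change survives scoring.

**T-maze outcomes** are binomial: each fly picks the bias-favored odor with
probability 0.5 + b/2 ∓ δ/2, the δ sign set by the group's CS+; the
expected PI is exactly δ and the bias b cancels in the reciprocal mean.

What the generators do *not* emulate: inter-fly interactions and collisions,
identity-swap tracking errors, body orientation (headings are velocity
headings by construction), arousal/latency structure in sleep, circadian
drift within a phase, and non-stationary walking statistics. Passing tests
therefore validate the *analysis* under the stated statistical structure,
not robustness to these real-data complications; the strict readers and
censoring rules are the first line of defense for real inputs.

## Numerical and design choices

* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical outputs.
* Preference frames with zero tracked flies are undefined (NaN), never 0;
  untracked flies reduce the per-frame denominator.
* The PI window average is an unweighted mean over frames (frames are
  equally spaced).
* Equal-proportions tests apply the Yates continuity correction only for
  2×2 tables by default (switchable); a margin of zeros (all successes or
  all failures) returns statistic 0, p = 1 rather than an error.
* Dunn's post-test uses pooled mid-ranks with tie correction and a Šidák
  family adjustment over the control comparisons by default (Bonferroni and
  unadjusted available). An all-identical sample set takes the documented
  degenerate path (H = 0, p = 1).
* Correlation always reports Spearman's rho *and* Pearson's r (with R²),
  because index-vs-index relationships in this field are routinely
  summarized with either and the two are conflated often enough that
  reporting both is the only safe interface. Zero-variance input is flagged
  undefined.
* Problem sizes in the test suite and acceptance script — 10 replicate
  cohorts per valence level, 20 flies per cohort, 32 DAM channels, 10⁴
  flies per T-maze group, 1000 oracle vectors, 2000 null simulations — are
  the package's chosen study sizes: large enough that every stochastic
  check sits several standard errors from its threshold, small enough to
  run comfortably on one CPU.

## Known limitations

* Entry angle uses a fixed 3-frame heading window; very slow approaches can
  fold jitter into the angle (mitigated, not eliminated, by the prior-
  movement filter).
* The censoring taxonomy treats any event spanning a light transition as
  unusable; analyses of the transition itself need different tooling.
* Sleep scoring is the binary ≥ 5-min criterion only; arousal thresholds,
  sleep latency and circadian phase metrics are out of scope.
* The visual-assay factor-of-two convention difference is exposed as an
  option but defaults to mean-of-reciprocals; users comparing against
  difference-convention numbers must select it explicitly.
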