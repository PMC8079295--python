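# Methods

This note documents the models, numerical choices, and limitations behind
the `shuttlebox` package: what the synthetic trials contain, how each
analysis stage is computed, and which design decisions were genuinely open.

## Trial protocol and arena

A trial is a stepped-hypoxia schedule for the compartment the fish prefers
("hypoxic side"): a normoxic baseline (default 40 min at 97 %sat in both
compartments), then for each target in 70/50/30/25/20/15/10 %sat a linear
ramp (10 min) followed by a hold (10 min), then reoxygenation (20 min ramp
back).  The first ramp (normoxia → 70 %) counts as a ramp segment, so the
default trial is exactly 40 + 7·(10+10) + 20 = 200 min.  Analysis bins are
the baseline block plus one bin per ramp/hold and 10-min slices of the
reoxygenation; hold bins carry the step target as nominal DO, ramp bins the
bin-mean of the linear target, and the baseline is coded at 100 %sat.  The
refuge side is held at 90 %sat after baseline (always above the 80 %sat
floor).

The arena is two 50-cm circles joined by an 8.5 × 14 cm passage, origin at
the arena centroid, x along the compartment–passage–compartment axis.  Zone
assignment tests the passage rectangle first, then the circles; boundary
points therefore resolve to the passage, which makes side changes well
defined.  Coordinates are always arena-centered by construction, so the
occupancy metrics cannot depend on an arbitrary origin.  "Time in shelter"
needs a geometric region the experiment itself never defines, so the shelter
zone is the 15 × 2.6 cm tube footprint dilated by 1 cm on every side; a
0.05 cm boundary tolerance absorbs coordinates rounded onto the wrong side
of a wall by the 0.01 cm log format.

## Synthetic trials

The generator's defaults are the study conditions the analysis assumes:
16 fish, body lengths 7.6–10.4 cm, base EOD frequencies 807–1151 Hz at
~25.7 °C, preferred sides balanced to within one fish, exactly one
non-responder per 16-fish cohort, population avoidance threshold
θ* = 22 %sat with 2 %sat between-fish SD, linear water-temperature drift of
−0.15 °C per trial, Q10 = 1.55, and 0.5 %sat DO measurement noise.  One RNG
stream is derived per (seed, fish index, purpose), so cohorts are extensible
without reshuffling earlier fish.

Behavior is a per-second Markov chain over four states (shelter, roam,
cross-compartment transit, homing to the shelter).  Avoidance intensity is
graded, `a = clip((θ − DO_target)/20, 0, 1)`: it is zero at and above the
fish's threshold and saturates 20 %sat below it.  With rising `a` the fish
leaves its shelter more readily (0.004 → 0.25 s⁻¹), leaves the hypoxic side
while roaming at rate `a / 20 s`, and returns only at the excursion rate
(0.01 s⁻¹) plus a term 0.05·(1 − a) that vanishes at full avoidance.  The
symmetric two-state side-switching makes hypoxic-side occupancy decline
approximately linearly from ~1 toward the excursion floor as `a` grows —
the flat-then-linear dose-response shape the broken-stick estimator is built
for — while re-entries in deep hypoxia are brief excursions (geometric
dwell, mean 20 s).  Roaming is a heading-persistent walk (speed ~1.3 cm/s,
heading diffusion 0.7 rad/s) confined to the current compartment; side
changes and homing follow way-points through the passage at 12 cm/s, so
every per-second step is bounded by the transit speed and paths are
continuous.  These rates were fixed once against the qualitative structure
of real trials (near-exclusive baseline side preference, shelter-resting at
normoxia, upregulated swimming with ~10 side changes, ~12 m distance and
~0.1 BL/s median velocity in the lowest-DO bin) and against the package's
own cohort-level recovery requirement (below).

What the generator does *not* emulate: water currents (metrics are
deliberately uncorrected), surface respiration, wall-following and other
thigmotaxis, multi-fish interaction, tracking dropouts, and any direct
effect of hypoxia on the EOD.  Passing tests therefore show that the
*analysis* behaves correctly on data with the assumed structure, not that
real fish obey the movement model.

EOD synthesis integrates the phase sample-by-sample with instantaneous
frequency `f(t) = f0 · Q10^((T(t) − T0)/10)`, adds a configurable harmonic
series (default relative amplitudes 1/0.25/0.08) and white noise, at
20 kHz.  Full-length synthesis of a 200-min trial is contiguous and
phase-continuous; a decimated mode (one 1-s snippet every k seconds, with
window times recorded) keeps long-trial fixtures small, at the cost of phase
resets between snippets.

## EOD frequency tracking

Non-overlapping 1-s windows aligned to the trial clock are Hann-tapered and
zero-padded to 2^18 points; the per-second frequency is the PSD argmax
within the 300–5000 Hz analysis band, giving a bin width of
20000/2^18 ≈ 0.076 Hz.  Among spectral peaks within 6 dB of the maximum the
lowest frequency wins, which keeps a strong second harmonic from capturing
the estimate.  All-zero windows yield NaN and a log message.  Interval
medians are normalized as percent change from the baseline median, so the
baseline's change is 0 by construction.  The band-pass filter used for raw
voltage traces is a 5th-order Butterworth (300 Hz–5 kHz) applied
forward-backward for zero phase.  The taper, transform length and overlap
are not uniquely determined by the stated 0.076 Hz resolution; the choices
here (Hann, 2^18, no overlap) are the simplest consistent set and are
configurable.

## Broken-stick threshold estimation

Estimation is by **maximum likelihood**, not REML: the split search compares
models across subsets, and ML keeps the residual criterion commensurable.
The RSS minimized is that of the *conditional* residuals (observed − fixed
effects − predicted random intercept).  Candidate splits are midpoints
between consecutive distinct DO levels; rows at or below the split form the
post (low-DO) segment.  Ties in total RSS resolve toward the higher-DO
split.  A segment whose random-intercept variance collapses numerically
(τ² < 10⁻⁷·σ²) is refitted as OLS with a flag; a pure-OLS mode (the
classical two-segment procedure) and a per-fish random-slope mode are
exposed as options, random-intercept being the default.

**Minimum levels per segment.**  Each segment must keep at least two
distinct DO levels.  Two levels × 16 fish give 32 observations — a fully
identified line, not a degenerate one — and the looser bound matters: with
the 8-level grid and a three-level minimum, a true threshold at the
second-lowest level (15 %sat) is structurally unrecoverable, because the
post segment is forced to contain the at-plateau level 20 and the fitted
line then cannot intersect the plateau below ~18 %sat.  With the two-level
minimum the package recovers population thresholds of 15/22/30 %sat with
median errors of 0.5/2.1/1.3 %sat over ten seeded cohorts (the package's
cohort-level calibration requirement, tested in the acceptance suite).  A
`min_levels` argument restores the stricter rule.

Satterthwaite degrees of freedom are computed from the profile-ML
likelihood: for each fixed effect, `df = 2·f²/(gᵀ A g)` with
`f = Var(β̂_j)` as a function of the variance components, `g` its central
finite-difference gradient, and `A` the inverse observed information of the
variance components (finite-difference Hessian of the profile
log-likelihood).  On a 16-fish fixture the estimates, SEs, DFs and t values
agree with lme4/lmerTest to within fractions of a percent (tested by
driving Rscript).  Nakagawa R² takes the fixed-effect variance as the
variance of the fixed-effect linear predictor over the data; marginal R² is
reported as-is, with no extra adjustment.

Degenerate inputs: fewer than four distinct levels, residence outside
[0, 100], or parallel segment lines (no intersection) raise typed errors;
thresholds are otherwise finite whenever the slopes differ.

## Hypothesis tests

The paired per-fish comparisons are **signed-rank** tests (a paired design
admits no two-sample rank-sum): exact null for n ≤ 25 without ties, normal
approximation with continuity correction otherwise; intervals with fewer
than five informative (non-zero) pairs report NaN with a warning and are
excluded from the Holm family.  The Holm family is the full set of
post-baseline bins for one metric.  Friedman's test uses average ranks with
the general tie-corrected statistic; a fully tied matrix returns (0, 1)
rather than 0/0.  The EOD mixed model regresses per-interval percent change
on experimental time and the interaction of inverted DO with the fraction of
time in hypoxia — inverted DO defaults to (100 − DO)/100 so the interaction
grows as oxygen falls (1/DO is available) — with a per-fish random slope on
time and no intercept (the response is anchored at zero at baseline); an AIC
table compares the candidate fixed-effect sets {time}, {time + interaction},
{interaction}.  The repeatability ANOVA treats DO as a between-subject
factor with subject = (fish, DO-level) cell and day as the within-subject
factor, as the design is conventionally described, although every fish
experiences all levels; when day 2 duplicates day 1 exactly the day effect
is reported as F = 0, p = 1 instead of the undefined 0/0 ratio.

## Known limitations

- The movement model is phenomenological; its rates reproduce the assumed
  dose-response structure, not fish biomechanics.
- The intersection threshold inherits the coarseness of the DO grid: even
  noiseless cohorts localize a threshold only to within a few %sat of the
  inter-level spacing, which is why the recovery requirement is ±3 %sat.
- Decimated EOD synthesis breaks phase continuity at snippet boundaries;
  use full-length synthesis when phase matters.
- The between-day repeatability simulation shares all fish parameters and
  differs only in the stochastic behavior stream; systematic day effects
  (habituation, mass change) are not modeled.
- No confidence interval is provided for the threshold itself; a cohort
  bootstrap would be the natural extension.
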