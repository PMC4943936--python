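# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data tests do and do not
establish about real sessions.

## Task and data model

A session is a stream of millisecond-stamped events — cue onsets/offsets for
two auditory cues (large- and small-reward predictive), photobeam receptacle
entries/exits, reward deliveries — plus an optional 30 frames/s trace of two
head-mounted LEDs. A trial is one cue presentation; it is R+ if a receptacle
entry occurred during the cue window (at most 5 s; an in-window entry
terminates the cue and triggers reward), else R−. Two conventions the raw
data do not dictate:

- An animal already inside the receptacle at cue onset counts as R− unless
  it re-enters during the cue. The task requires *entering* during the cue;
  occupancy alone is not an approach.
- The first trial's preceding inter-trial interval (ITI) is measured from
  session start, since no prior cue exists.

## Two-state Markov description

Responding is summarised by the right-stochastic 2×2 matrix of consecutive
R+/R− couplets, P(ab) = N(ab)/N(a), where N(a) counts occurrences of `a` as
the *first* member of a couplet (a final-position trial has no successor and
does not enter its row's denominator). The stationary vector uses the 2×2
closed form π₊ = P(R−R+)/(P(R+R−)+P(R−R+)) rather than a generic
eigensolver: it is exact, cannot return a spurious complex pair, and the
eigenvector and matrix-power routes are retained as independent oracles in
the test suite (agreement to 1e−10; the power-iteration depth is scaled by
the spectral gap, since a fixed depth has not converged for near-absorbing
chains).

Degenerate cases are reported, never imputed: a row whose antecedent never
occurs is *undefined* (not 0/0 → 0) and blocks the stationary computation
with advice to pool a longer window; a block that is entirely R+ (or R−)
gets the conventional π = (1, 0) (or (0, 1)) with a degenerate flag, so
floor/ceiling sessions remain visible; a chain with both off-diagonals zero
has no unique stationary law and is flagged; a period-2 chain (both
off-diagonals one) returns (0.5, 0.5), the time-average occupancy. Couplets
straddling an hour boundary are assigned to the hour of their first trial,
matching the couplet's conditioning on the antecedent.

## Pauses

A pause is a maximal run of ≥ 2 consecutive R− trials. Its duration spans
the cue *onsets* of the flanking responded cues — onsets exist for every
trial, entry times only for R+ trials. Runs touching the session boundaries
substitute the session start/end and carry left/right censoring flags;
censored pauses are included in cumulative curves (no exclusion rule is
imposed), and the flags allow sensitivity analyses. Empty response-ratio
bins report an undefined (NaN) ratio, never 0%.

## Tracking pipeline

Centroid = LED midpoint where both LEDs are tracked; gaps of ≤ 10 frames are
linearly interpolated between the flanking valid centroids, longer gaps (and
gaps at the trace ends) are invalid. Interpolated points lie on the segment
between their anchors by construction. "Discarding" long gaps means: frames
invalid, plus exclusion (with reason) of any trial or ITI window the invalid
frames touch.

Movement detection works on the log of (SD + ε), ε = 1e−6 cm, of centroid
dispersion in a centered 7-frame window (≈ 233 ms at 30 fps — the smallest
odd frame count covering 200 ms; centering avoids a systematic latency
bias). The dispersion statistic is, by default, the SD of each windowed
centroid's distance from the window's mean centroid; because the statistic
inside the window is genuinely ambiguous in this family of pipelines, SD of
successive displacements (`"step"`) and SD of pairwise distances
(`"pairwise"`) are selectable alternatives rather than silent guesses.

The still/moving threshold comes from a two-component Gaussian mixture
fitted by EM to the raw log-SD values (not to a histogram), initialised
deterministically at the 25th/75th percentiles with equal weights and pooled
variance — reproducible without a random seed. "Least overlap" is
operationalised as the abscissa between the component means where the two
*weighted* component densities intersect (closed-form quadratic). Two guards
reject unimodal data: a collapsed fit (component weight < 0.01 or SD <
1e−6), and a missing density valley — the mixture density at the crossing
must lie below the density at both component means, otherwise the crossing
is not a separating point. A movement bout is ≥ 8 consecutive valid
supra-threshold frames; invalid frames break runs.

All time windows are half-open [start, end): an entry exactly at cue onset
is post-cue, not pre-cue. Pixel→cm scaling is a single scalar per session;
no lens-distortion model. Movement-onset latency is 0, with a
`moving_at_cue` flag, when a bout already spans cue onset — the flag
preserves the distinction instead of deciding it. Path efficiency is clipped
to ≤ 1 (frame discretisation can make the measured path a hair shorter than
the straight line).

## Statistics

Sidak: p_adj = 1 − (1 − p)^m, capped at 1; the family size m is a parameter,
not hard-coded. Welch's t delegates to scipy with Satterthwaite degrees of
freedom (verified against the textbook formula to 1e−10 in tests). The
paired signed-rank test drops zero differences, midranks ties, and computes
the two-sided p exactly for ≤ 12 nonzero differences by enumerating all 2^n
sign patterns (p = P(|W − μ| ≥ |w − μ|) under the symmetric null); larger n
uses the normal approximation. scipy's exact mode is the independent
cross-check on tie-free inputs, not the implementation.

## Synthetic-session generator

The generator defines the study conditions; its defaults are not tuning
knobs.

**Trial timing.** ITIs are truncated-exponential with bounds (10 s, 90 s) —
unstated in the source protocol; these keep trials/hour near the implied
~100 and avoid degenerate near-zero ITIs — and the parent rate is solved
numerically (Brent) so the *realized* truncated mean is 30 s, the only
stated moment. Achievable means lie strictly between the lower bound and
the bounds' midpoint; anything else is an invalid-config error. A session
lasts 7200 s and yields ~200–220 trials.

**Latent state and emissions.** A responsive/non-responsive Markov chain
evolves over trials; the matrix in force for the step k→k+1 is the one
covering trial k's onset, and matrices switch instantaneously at t = 3600 s
(the analyses treat hours as blocks). The initial state is drawn from the
first hour's stationary law, making first-hour cohort expectations equal the
stationary-occupancy × emission product. Observed responses are
state-conditional Bernoulli, keyed by cue type:
P(respond | responsive, large) = 0.95, (non-responsive, large) = 0.13,
(responsive, small) = 0.60, (non-responsive, small) = 0.06. The analysis
stages operate on observed R+/R− exactly as the couplet estimator defines
them; the emission layer exists so transition-matrix recovery can be tested
in the observable limit p = (1, 0), where the response sequence *is* the
state sequence.

**Shipped conditions.** Control (saline): hour 1 [[0.88, 0.12],
[0.12, 0.88]] (π₊ = 0.5), hour 2 [[0.75, 0.25], [0.07, 0.93]] (π₊ ≈ 0.22).
With the emissions above, first-hour expected ratios are
0.5·0.95 + 0.5·0.13 = 54% (large) and 0.5·0.60 + 0.5·0.06 = 33% (small).
High-dose agonists stabilise the responsive state in both hours
([[0.95, 0.05], [0.35, 0.65]], π₊ = 0.875); low doses are intermediate
([[0.90, 0.10], [0.18, 0.82]]); antagonists impose the control's hour-2
matrix from the first hour. These reproduce the qualitative contrasts the
pipeline is tested against: control-only hour effect, no hour effect under
agonists, antagonist hour 1 ≈ control hour 2, and agonist < control <
antagonist ordering of cumulative pause time.

**Events.** Responded trials place ENTRY at onset + latency
(truncated-normal, mean 1.5 s, SD 0.6 s, support [0.3, 4.5] s — strictly
inside the 5-s window so generated flags are recoverable exactly), with cue
off and reward at the entry instant and exit after a truncated-normal
consumption period. Spontaneous ITI entries form a 0.02 Hz Poisson process
(magnitude unstated in the source; needed to exercise the pre-cue entry
rate) and never intrude into cue windows. Timestamps round to 1 ms; entries
and exits strictly alternate by construction.

**Tracking.** The centroid follows a piecewise-linear path: jitter-only
stillness, spontaneous bouts (15 cm/s, exponential durations clipped to
[0.3, 2] s) at a Poisson rate that depends on the upcoming trial's latent
state (0.08 Hz responsive vs 0.03 Hz non-responsive — this coupling is what
produces the "more ITI locomotion before responded trials" contrast), a
straight approach from the movement-onset position to the receptacle
arriving at the logged entry time, and a post-reward departure step. Bout
directions are re-drawn (up to 8 times) to keep the straight bout path
inside the chamber so realized bout length equals speed × duration; wall
folding is the fallback. LEDs sit 2 cm apart about the centroid with 0.03 cm
per-frame jitter; missing-frame gaps start at 0.002/frame and are long
(> 10 frames) with probability 0.15, so both interpolatable and discardable
gaps occur. The trace does not route to the receptacle for spontaneous
(uncued) entries in the event log; no analysis stage cross-references those
positions.

**Determinism.** One `numpy.random.Generator` drives a session; cohorts
spawn per-session seeds from a root `SeedSequence`. Identical (config, seed)
reproduces event logs and traces bit for bit.

## What the synthetic tests do and do not show

Passing tests establish that the estimators recover known generating
parameters (transition matrices to ±0.02 at 20k trials, mixture thresholds
to ±0.05 at ≥ 2 pooled-SD separation), that the descriptive statistics match
brute-force enumeration on all short sequences, and that the shipped
condition library reproduces the qualitative pharmacology as sign/order
constraints at n = 7 sessions per condition. They do not validate the
generator against real kinematics: trajectories are piecewise-linear with
isotropic jitter (no velocity profiles, head direction, licking or
consumption structure), response emissions are conditionally independent
given the state, and ITIs do not modulate response probability (by design,
matching the observed flatness of response ratio across ITI bins).

## Problem sizes and tolerances in the checked runs

Cohort-level checks use 7-session cohorts (the study's own per-condition
scale); the acceptance script averages ten such cohorts so the reported
cohort statistic has a standard error near 1.5 percentage points, small
against its ±5-point band. Chain-recovery checks use 20,000 trials
(binomial SE ≈ 0.004 per entry against a ±0.02 band); the ITI calibration
uses 10,000 draws (SE ≈ 0.17 s against a ±0.6 s band). Oracle equivalences
are asserted at 1e−10, well above float64 round-off for 2×2 algebra.
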