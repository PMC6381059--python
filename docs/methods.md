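# Methods

## Overview

`scfield` simulates saccadic action selection in the gap pro-/anti-saccade
task as competitive integration in a one-dimensional dynamic neural field
representing the intermediate superior colliculus (SCi).  Eight inputs —
fashioned after components of sensory, automated, voluntary and inhibitory
neural signals — are summed into the field at every millisecond; the first
threshold crossing of the field's output activity at a non-central location
is the saccade.  The model has no stochastic component.  All behavioral
variability is produced by a factorial grid over ten input attributes.

## Field dynamics

The field is a ring of N = 100 nodes covering 10 mm of SCi (node spacing
Δx = 0.1 mm); node i sits at x_i = i·Δx − 5, so node 50 is the fixation
point and nodes 25/75 are the ±2.5 mm stimulus/goal sites.  Distances (for
both the input profiles and the lateral kernel) are measured on the torus,
min(|x_i − μ|, 10 − |x_i − μ|), avoiding boundary effects.

State update (explicit Euler, Δt = 1 ms, τ = 4 ms):

    u(t+Δt) = (1 − Δt/τ) u(t) + (Δt/τ) (c_ext(t) + W a(t))
    a = 1 / (1 + exp(−β u)),  β = 0.09

The lateral kernel is a shifted Gaussian, W = (G − 0.8·max G)·Δx with
G_ij = 74.7·exp(−d_ij²/(2·0.85²)): excitatory within roughly ±1 mm,
uniformly inhibitory beyond.  The internal contribution for a step is
computed from the activity *before* the update.  At trial start u = −30
everywhere (a ≈ 0.063), representing a hyperpolarized resting state; the
paper-described reset of the internal contribution to −30 is realized by
this initialization alone, since the lateral term is recomputed from a at
every step and any separately stored value would be overwritten
immediately.

A saccade is triggered when a ≥ 0.7 at any node with |x| > 1.0 mm.  The
1.0 mm fixation exclusion radius quantifies "non-central": it covers the
fixation input profile (γ = 0.6 mm) while leaving the ±2.5 mm sites
eligible; it is configurable.  If several nodes cross simultaneously the
winner is the node with maximal activity, ties broken by smallest |x|, then
leftmost.  The baseline experiment never needs the tie-break (one stimulus,
one goal), but the contract is total.

## Trial timeline

Fixation is acquired at −1000 ms, the fixation point disappears at −200 ms
(200 ms gap), the stimulus appears at 0 ms, and a trial is abandoned as
`no_response` at +600 ms (the baseline grid produces none).  The 800 ms of
stable fixation before the gap is an assumption — the task constrains only
the gap duration — and matters solely through the voluntary-preparation
ramp slope (below).

## The eight inputs

Each input is a Gaussian profile k (γ = 0.6 mm, amplitude 1.05) times a
piecewise-linear amplitude: after an onset delay keyed to a trial event the
value changes by k·RoR·Δt per step (RoR in fraction per ms), capped so the
peak never exceeds MaxVal.  Caps are profile-wise (node i's ceiling is
MaxVal·k_i/amp), preserving the Gaussian shape at saturation.  Attributes
per input (Onset delay ms / RoR % / MaxVal; {a, b, c} = the small/medium/
large levels of the factorial design):

| # | input                 | delay         | RoR          | MaxVal    | centre               |
|---|-----------------------|---------------|--------------|-----------|----------------------|
| 1 | visual transient      | 50            | 15           | 8         | stimulus             |
| 2 | automated motor       | 60            | {4, 6, 8}    | {4, 6, 8} | stimulus             |
| 3 | automated fixation    | 60            | 10           | 6         | fovea                |
| 4 | voluntary motor       | {140,155,170} | {5, 10, 15}  | uncapped  | goal                 |
| 5 | voluntary fixation    | shared        | 10           | {4, 6, 8} | fovea                |
| 6 | voluntary preparation | shared        | dependent    | {4, 6, 8} | both ±2.5 mm sites   |
| 7 | inhibitory gate       | shared        | {5, 10, 15}  | {4, 6, 8} | goal (opening)       |
| 8 | peripheral inhibition | shared        | {5, 10, 15}  | {4, 6, 8} | fovea (spared)       |

Inputs 4–8 share one onset delay per trial (a common internal "go" for the
voluntary system), counted from stimulus onset — except the preparation
input, whose delay runs from fixation acquisition.  The goal is the
stimulus site in the pro task and its mirror in the anti task, so for
identical settings the anti-trial input bank equals the pro bank with
inputs 4 and 7 mirrored about fixation.

Input-specific rules:

* **Visual transient** rises from 50 ms after stimulus onset until it
  reaches its cap, then fades at half its RoR to zero.  The fade is tied to
  reaching the cap (≈51 ms of rise at the baseline RoR), no earlier than
  50 ms after response onset.  The rise-to-cap reading was chosen over a
  strict fade-at-50-ms reading (the two are a documented ambiguity of the
  input's verbal definition); it is also the reading under which the model's
  express-saccade rate and error timing match the reference behavior.
* **Automated motor** rises from 60 ms post-stimulus and holds at MaxVal
  until the saccade.
* **Automated fixation** starts at MaxVal and fades at its RoR from 60 ms
  after fixation offset (first decrement at −139 ms); with the gap timing
  it is gone ~57 ms later, before the stimulus appears.
* **Voluntary motor** rises without bound from its onset until the saccade
  (a cap would only encode unwillingness to do the task).
* **Voluntary fixation** starts at MaxVal and decays from the shared
  voluntary onset.
* **Voluntary preparation** is the element-wise maximum of Gaussians at
  ±2.5 mm (the two possible stimulus sites), rising from fixation
  acquisition + delay with a dependent RoR = MaxVal/(amp·ramp) so both
  peaks reach MaxVal exactly at the expected stimulus onset, then holding.
* **Inhibitory gate** is a uniform wall at −MaxVal across the entire field
  (fixation node included); from the voluntary onset a Gaussian opening
  grows at the goal, clamped so no node goes above zero.
* **Peripheral inhibition** has the fovea-sparing shape −MaxVal·(1 −
  k⁰/amp) — a smooth complement-of-Gaussian notch rather than a hard
  cutoff, avoiding edge artifacts — and is released uniformly at
  amp·RoR·Δt per step, each node clamped at zero.

Post-saccade input restoration is not modeled: a trial ends at its saccade.

Amplitudes are evaluated in closed form (each is piecewise linear in t),
which is exactly the per-step update integrated; the test suite checks the
engine against an independent per-step accumulation simulator, which agrees
on every SRT and winning node and on u to ~1e−10.

## The factorial experiment

Ten attributes (table above) take three monotonically increasing values
each; every combination runs in both tasks: 3¹⁰ × 2 = 118,098 trials, with
no a-priori pro/anti differences and every level appearing in exactly one
third of the trials per task.  The stimulus is placed on the right for the
canonical grid; mirror symmetry of the field makes the left-side grid
redundant (this is asserted in tests, and both sides can be run
explicitly).  Trials are ordered lexicographically over the documented
attribute order so trial ids are stable identifiers.

Two exact optimizations keep the experiment at desk scale (~1.5–2 min per
full grid on one CPU): the pre-stimulus epoch depends only on five of the
ten attributes, so at most 3⁵ = 243 unique prefixes are simulated once and
shared; and trials leave the batch at their saccade.  Both are pure
restructurings of identical arithmetic — batched, chunked and single-trial
runs produce identical records, which is tested.

## Classification and statistics

SRT < 90 ms → anticipatory (excluded from the five types; the baseline grid
produces none).  Express window: the closed interval [90, 138] ms (138 is a
multiple of the 6-ms histogram bin); 139 ms is regular.  Pro saccades
toward the stimulus split into Express-/Regular-Pro; anti saccades toward
the stimulus into Express-/Regular-Error; anti saccades away are
Correct-Anti, never split by latency.  Pro saccades away from the stimulus
would be labelled `pro_error`; the baseline model produces none (asserted).

Summary statistics: percentages use per-task denominators; STD uses the
sample (n−1) denominator; the median of an even-sized group is the mean of
the central order statistics; skewness is the adjusted Fisher–Pearson
estimator.  Histograms use 6-ms bins aligned at zero.  Attribute effects
are quantified as the median SRT shift (large − small level) with Cohen's
d = shift / (that behavior's full-SRT STD), plus a tie-corrected
Kruskal-Wallis test; selection effects as a chi-square goodness-of-fit of
the level distribution within a saccade type against uniform thirds
(df = 2).  The selection test is reported both on raw counts and on the
level percentages (distribution rescaled to base 100); significance
classification uses the percentage form.  The distinction matters: the
majority behaviors comprise tens of thousands of trials, where a
count-based test flags proportion deviations of a percentage point or two
as overwhelmingly significant even though no setting meaningfully selects
for the behavior — the same large-n inflation that motivates using the
median shift rather than the Kruskal-Wallis p-value as the measure of
temporal effect.  On the percentage scale, regular-latency pro-saccades
and correct anti-saccades show no significant level preference for any
attribute, while express saccades (identically in both tasks) require
large automated-motor RoR and preparation MaxVal together with small
fixation/inhibition MaxVals, and regular errors follow large
automated-motor and preparation MaxVals against a small gate MaxVal.

The anti-saccade difference curve is cumulative %Correct-Anti minus
cumulative %direction-error per 6-ms bin (percent of anti trials); the
Voluntary Override Time is the time of the first bin after the curve's
global minimum that rises by ≥ 1 percentage point over its predecessor.
The binned resolution of this rule is configurable to per-ms; the bin-edge
convention reports the right edge of the qualifying bin.

## Post-hoc manipulations

* **Ablation** forces an input's RoR to zero: rising-from-zero inputs stay
  identically zero; inputs with non-zero initial values (fixation,
  inhibition) are frozen there.  Ablating the automated motor input alone
  abolishes direction errors; ablating the visual transient as well leaves
  the two tasks' SRT distributions identical trial-for-trial, because the
  remaining drive is purely voluntary and the model is noise-free.
* **Intentional-state filtering** removes pro trials with large MaxVal and
  anti trials with small MaxVal for the voluntary-fixation,
  inhibitory-gate and peripheral-inhibition inputs — per input, or
  combined.  The combined filter uses ANY semantics (drop if any of the
  three levels matches); ALL semantics is available behind a flag.  The ANY
  reading is the one consistent with the reference percentages (≈21 %
  Express-Pro, 0 % Express-Error among survivors).  Filtering is pure
  post-selection: no simulated outcome changes.
* **Crosstalk** subtracts 25 % of the horizontally flipped voluntary-motor
  vector from the automated-motor vector at every step before summation,
  clamping at zero.  It is a no-op before the voluntary onset (≥ 140 ms),
  so express saccades are untouched; it specifically removes late
  (> 200 ms) regular errors, raising the early (140–199 ms) to late
  (200–259 ms) regular-error count ratio from ≈1.8 to ≈3.1.

## Numerical choices and degenerate inputs

Double precision throughout.  Threshold and cap comparisons are inclusive
(reaching 0.7 triggers; a value exactly at MaxVal holds).  Input onset
semantics: an input's first non-zero value occurs one step after its onset
time (value = RoR·(t − onset)).  Non-finite field states abort the trial
with a diagnostic naming the trial id.  An empty grid, empty record sets,
empty statistic subgroups, zero expected chi-square counts and zero
standard deviations raise errors rather than propagating NaNs.  A
preparation ramp of non-positive duration (onset delay ≥ fixation period)
is a configuration error.

## Known limitations

The synthetic experiment *is* the study object — there is no external data
ingestion.  The packaged human reference table is a published population
summary used only for side-by-side comparison; no inferential statistics
are computed against it.  The model does not emulate corrective saccades
after errors, post-saccade input restoration, step (no-gap) protocols,
2-D field geometry, spiking dynamics, or neural firing rates; express/
regular boundaries are conventions, not mechanism labels.  Because the
model is deterministic with three levels per attribute, its SRT histograms
are lumpy at the millisecond scale where human histograms are smooth;
comparisons are therefore made at the 6-ms bin scale and on summary
statistics.
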