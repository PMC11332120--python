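# Methods

This note documents the model, the analysis conventions, and the design choices
made where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Representational space and encoding

A single 2-D space is shared by all participants: the x-axis carries auditory
features, the y-axis visual features.  For a McGurk pairing the three relevant
tokens (auditory, fusion, visual — e.g. *baba*, *dada*, *gaga*) are placed
collinearly and equidistantly on the diagonal at (0,0), (1,1), (2,2).  Only the
ordinal structure (the fusion token strictly between the other two) is
theoretically constrained; collinear equidistant means are chosen because
nearest-mean classification then depends only on the projection onto the token
line, giving every fusion probability an exact univariate Gaussian closed form
(`token_probability`).  Non-collinear spaces are supported through a
deterministic Gauss–Hermite fallback (101×101 tensor nodes, accurate to ~1e-3).

Encoding distributions are axis-aligned Gaussians, fixed across participants and
never fit to data.  The anisotropy direction is structural: A is reliable along
x (σ²ₓ < σ²ᵧ), V the reverse.  The magnitudes are a calibration choice of this
package: **A = diag(0.005, 0.025), V = diag(0.025, 0.005)**.  These place the
unshifted auditory representation 5.77 projected standard deviations from the
fusion-region boundary, so its fusion mass is 3.9e-9 — pre-test fusion reports
are essentially impossible, matching the behaviour the model must reproduce
(veridical pre-test perception, and exactly zero recalibration for
non-fusers).  Larger encoding variances (e.g. σ²ᵧ on the order of the token
spacing) would leak double-digit fusion percentages into the pre-test and are
therefore not usable as defaults.

## Integration and individual differences

The pooled representation is the per-axis inverse-variance combination of A and
V; an infinitely unreliable cue contributes zero precision and drops out.  The
integrated AV representation mixes the pooled (common cause, C=1) and auditory
(separate causes, C=2) hypotheses linearly in the observer's common-cause
probability `p_common`, for both centers and covariances (model averaging).
Model selection (take the higher-weighted hypothesis whole) is available via
`ModelConfig(integration="select")`; averaging is the default because it is
smooth in `p_common`, which makes the exposure-rate inversion well posed.

Individual differences enter exactly twice:

* `p_common` is obtained by inverting the closed-form fusion probability of AV
  to the participant's observed exposure fusion fraction (bisection to 1e-12;
  clamped to 0/1 outside the attainable range; a non-monotone
  probability-vs-`p_common` map raises, since it indicates degenerate
  geometry).  With the default geometry the attainable exposure fusion rate
  rises from ~0 at `p_common ≈ 0.4` to ~1 at `p_common ≈ 0.7`; observed rates of
  95% and 6% therefore correspond to `p_common ≈ 0.62` and `≈ 0.38`.  Only the
  ordering of `p_common` across participants is interpretable; its absolute
  scale is an artifact of the geometry.
* The day-1 fusion fraction *f* (fusion percepts / trials of the target McGurk
  stimulus on the first exposure day) sets the recalibration shift
  A′ = A + f·(AV − A), with proportionality constant 1 (f = 1 moves A fully
  onto AV).  The shift moves the center only; encoding uncertainty is conserved.
  Recalibration is applied once, keyed to Day 1, not incrementally over the 14
  days — the fitting procedure defines the shift in terms of Day-1 percepts.

Exposure trials are simulated with common random numbers: the encoded A and AV
locations share a standardized noise draw, so at `p_common = 0` they coincide
and the error signal is exactly zero (the percept marginal is unaffected by
this choice).  The per-trial error signal is the Euclidean distance between the
two encoded locations.

## Synthetic cohort generator

The generator is the study design's generative twin and its defaults are the
study conditions: 28 participants; Day-1 pre-test with 5 repetitions of the
primary auditory token, 10 of the secondary, and 25 control syllables; 14
exposure days with 5 + 10 repetitions (9 of the secondary stimulus on Days
8–13); a Day-16 post-test; and 6 monthly long-term tests.  Half the cohort is
assigned to the fusion-perceiver class (exact split), and each participant draws
`p_common` from a class Beta distribution — mean 0.62 (sd 0.025) for the high
class, 0.38 (sd 0.025) for the low class.  The class means are placed where the
model's implied exposure fusion rates match the bimodal rates the design is
meant to emulate (~95% vs ~6%); under the near-deterministic baseline geometry
those rates correspond to moderate, not extreme, `p_common` values.  The
secondary, weaker McGurk stimulus draws its class independently
(P(fusion class) = 4/28), so susceptibility can dissociate across stimuli.

Responses are emitted as raw text (the percept token) plus the coded category,
so the coding stage can be exercised end to end.  A 1% lapse rate replaces a
report with a uniform draw over the other categories definable for that
stimulus; control syllables are answered correctly with probability 0.96
(so measured control accuracy is 0.96 × 0.99 ≈ 0.95).

Long-term trajectories apply to fusion perceivers: persistent participants
(default 30%) keep their shift; decaying participants (70%) relax it so their
fusion probability follows FIR(t) = FIR(0)·e^{bt} with b = −0.545/month
(≈ 42% lost per month) — relaxation is computed on the probability scale and
inverted to an effective shift fraction, so generated series lie exactly in the
NLS family the decay fitter assumes (`decay_scale="shift"` gives the literal
shift-fraction relaxation instead).  An "absent" class (default proportion 0)
attenuates the shift from the 24-h post-test on; it emulates fusion perceivers
in whom recalibration never consolidates, a pattern real cohorts show but one
that lies outside the error-driven generative family — enabling it therefore
degrades the model's predicted-vs-realized correlation by construction.
Auditory perceivers produce absent trajectories on their own.  Exposure-phase
percept statistics are kept stationary across the 14 days (audiovisual trials
are always simulated from the unshifted-A-based AV distribution): feeding A′
back into exposure would inflate the exposure fusion fraction used to invert
`p_common` relative to its own definition.  Everything is reproducible from a
single seed.

What the generator does not emulate: open-text typing variability beyond the
token string (spelling variants appear only in coding tests), reaction times,
day-to-day drift in susceptibility, dropout, and the fusion-perceiver/no-FIR
dissociation unless the absent class is enabled.  Passing recovery tests on
generated cohorts therefore demonstrates internal consistency of the pipeline
under the model's own assumptions, not correctness on real data.

## Behavioural statistics

* **Descriptives** are raw-count percentages per cell; empty cells are missing,
  not zero, and results are invariant to trial order.
* **Perceiver classes**: fusion perceiver iff exposure fusion fraction ≥ 0.5.
  The bimodality of susceptibility makes the result insensitive to the
  threshold; the fraction is reported alongside.
* **Mixed models**: fusion vs non-fusion counts, binomial GLMM with
  time × class fixed effects and a participant random intercept (plus a
  stimulus intercept when several stimuli are modelled; a singular fit falls
  back to the participant-only structure).  Implemented through the standard R
  toolchain (lme4, car::Anova type II Wald chi-squares, emmeans post-hoc
  contrasts back-transformed from log-odds) called via `Rscript`; replicate
  batches are fit in a single R session.  When the GLMM is unfittable
  (degenerate random-effect structure, e.g. one participant per class), the
  backend drops to the fixed-effects binomial GLM — the zero-variance limit —
  with LR chi-squares, flagged as singular; failure after fallback raises.
  Pre-test cells with zero fusion counts produce the usual
  complete-separation pathology (huge odds ratios with unbounded CIs); the
  affected contrasts are reported as fitted, with non-finite bounds preserved.
* **Exclusions**: participants whose pre-test control accuracy falls below 0.80
  are excluded (the criterion is configurable; control syllables are the only
  performance gauge without correct/incorrect ambiguity).
* **Decay fits**: nonlinear least squares of *fusion* = a·e^{bt} (t in months
  since the final exposure; the 24-h post-test is t = 0), initialized from a
  log-linear fit; significance by residual F comparison against the
  intercept-only model.  Both b and the derived monthly loss 100·(1−e^b) are
  reported.  Group fits operate on group-mean series; per-participant fits feed
  trajectory grouping.  All-zero series are flagged (a = 0, b undefined); a
  `b ≤ 0` bound is applied only when requested.
* **Trajectory grouping** (the numeric stand-in for by-eye grouping): absent if
  the 24-h %FIR is below 10%; else decaying if the per-participant fit has
  b significantly < 0 (α = 0.05) or the final value falls below 10%; else
  persistent.  Thresholds are configurable and reported with the output.
* **Model evaluation**: Pearson r between predicted and observed %FIR with a
  Fisher r-to-z 95% CI.  For visualization-style error bars, the model SEM at
  each day-1 fusion-count level is the SD of simulated binomial data at the
  level's mean fitted rate over the post-test trial count (the closed-form fit
  itself is effectively an infinite-trial quantity), and the participant SEM is
  the pooled across-level SD divided by √(participants at the level).  Zero
  variance in either vector flags r as undefined instead of raising.

## Numerical choices and problem sizes

Bisection tolerances are 1e-12 (both inversions); classification ties break by
configured token order; closed-form masses use scipy's normal CDF.  The
replicate studies run at 100 cohorts (recovery) and 200 replicates (mixed-model
null calibration, 28 participants × 10 trials per phase, participant logit sd
0.5), sizes at which the Monte-Carlo error of the reported rates is ~1.5–5
percentage points and a full run stays within a few minutes on one CPU.  Wald
intervals for the GLMM interaction show the mild undercoverage typical at this
design size (~91–93% observed against the nominal 95%).

## Known limitations

The model fixes encoding covariances and token geometry a priori; no
quantities are in physical units, so only probabilities and their orderings are
comparable to data.  The single-shot (Day-1) recalibration rule cannot express
slow accumulation over exposure days (an incremental variant would need a
learning rate the data here cannot identify).  The GLMM stage requires an R
installation with lme4/car/emmeans/jsonlite; all other stages are pure Python.
Forced-choice coding assumes the replication's closed response list; open-text
coding is deliberately shallow (initial-consonant matching with a configurable
equivalence table) and makes no attempt at phonetic transcription.
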