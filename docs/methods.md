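# Methods

This note documents the models and conventions behind `motioncues`: what each
quantity is, the choices made where the underlying method description left
room, and what the synthetic generator does and does not emulate.

## Coordinate model and preprocessing

Trajectories are sequences of 2-D image coordinates (origin upper-left,
y increasing downward, pixels), one sample per `sampling_step` source frames
(default 3 frames at 25 fps → 0.12 s per step, 133 samples ≈ 16 s). The
source frame rate of broadcast parliamentary footage is not recorded with
the data; 25 fps is the European broadcast default and is configurable in
the metadata sidecar.

Missingness is explicit: a boolean mask per sample, encoded on disk as an
absent CSV row. Tracker losses that a manual workflow would fix by hand are
handled by per-coordinate linear interpolation with a hard cap
(`interpolate_gaps(max_gap)`); runs longer than the cap raise rather than
silently inventing motion. Endpoints must be observed.

`lectern_y` — the vertical position of the lectern edge — is required
metadata and must lie below the forehead track; there is no automatic
lectern detection. The body-height proxy is `max_t(lectern_y − y_forehead(t))`.

## Cue definitions and conventions

All cues operate on shoulder-referenced coordinates (shoulder against the
image origin, other landmarks against the same-step shoulder) and on the
cross-landmark aggregate amplitude series `AH_t`, `AV_t`. Aggregation across
landmarks (rather than per-landmark cues) matches the "global descriptor"
aim; per-landmark series remain accessible on `AmplitudeSeries`.

* **Amplitude sums** divide by the body-height proxy, making them
  dimensionless and camera-scale free. Cues are per-clip totals, not
  per-second rates: all clips share one length by design.
* **Turbulence** uses the sample standard deviation (ddof = 1) by default;
  `CueConfig.sd_ddof` switches to the population convention. A zero-mean
  series (motionless clip) yields NaN, logged and pairwise-excluded
  downstream — never imputed.
* **Expressiveness** is operationalized as the mean absolute second
  difference of the signed per-step displacement, averaged over landmarks
  and steps — a discrete jerk magnitude. The original description labels
  this family "relative overall velocity" while characterizing it by
  "smooth" versus "twitchy"; at a fixed sampling interval mean per-step
  amplitude *is* velocity and already appears as the amplitude sum, so the
  velocity-change signal is the operationalization that separates jerky
  from smooth motion at equal activity. Two activity corrections are
  provided: `ratio` (default; divide by the clip's mean aggregate amplitude
  on the same axis — sample-independent) and `residual` (OLS residual of
  the raw index on activity across the speaker sample; exactly uncorrelated
  with activity by construction).
* **Direction switches** compare the aggregate horizontal and vertical
  amplitudes per step. Whether the original count compares axes within one
  landmark or across the aggregate is not specified; the aggregate is used,
  consistent with the other cues. Ties carry the previous dominant axis
  (first-step ties default to horizontal); the rule is arbitrary but fixed,
  configurable (`tie_rule`), and exhaustively tested against a brute-force
  oracle.

## Ratings and careers

Aggregation is median-then-sum: reversed items are reflected (100 − v),
each item reduced to its median across raters (midpoint convention for even
counts), each dimension to the sum of its four item medians (0–400).
Cronbach's α is computed over speaker-level item medians — the level at
which scores enter the analysis — not over raw rater responses, since each
rater judged only a small subset of speakers. The instrument's adjective
pairs and polarities are not public, so the default item key marks no
reversals and the generator emits already-oriented items; real data needs a
user-supplied key. Career metrics are `entry_years = parliament_year −
party_year` and memberships / leadership counts divided by age.

## Statistical layer

Bivariate relations are Spearman correlations (mid-ranks on ties, two-sided
p via the t approximation), pairwise-deleting undefined cells. Each
criterion is regressed on the z-scored seven cues by OLS (listwise
deletion); `R_mult` is the positive root of R², the model test is the
F test, and VIF_j = 1/(1 − R_j²) from per-column regressions. Structure
coefficients divide the *Spearman* bivariate correlation by the OLS
`R_mult` — the convention the published tables follow, verified against
five printed cells — with a Pearson option for conventional use. All stored
values keep full precision; rendering rounds to two decimals. A few
published structure cells (e.g. .64/.74 printed as .87 rather than .86) are
consistent with computation from unrounded inputs, which is exactly what the
implementation does. No multiple-testing correction is applied, matching the
original analysis. Confidence intervals and model selection are out of
scope.

## Synthetic generator

The generator replaces three unavailable inputs — videos, raters,
biographies — with a latent-style model chosen for *identifiability*: each
style parameter should map monotonically onto one cue family so parameter
recovery is a meaningful end-to-end test.

Per speaker, both hands share one scalar motion signal apiece: a smooth
sinusoid (0.45 Hz, random phase) plus sign-randomized jerk noise, gated by a
periodic on/off gate and leakily integrated into positions (decay 0.95 per
step, which keeps tracks inside the 640×480 frame). The signal is projected
onto the axes through weights that favor the currently dominant axis (4:1
contrast, split by `vertical_bias`); the dominant axis flips at Poisson
event times with expectation `switch_rate` per clip, and weight flips are
absorbed into a position-continuity offset so the horizontal:vertical
displacement ratio follows the planted dominance exactly at every step —
the measured switch count reproduces the planted process rather than
envelope noise. The gate has period 33 steps (~4 s activity cycle) with
duty cycle `1 − burstiness` and a low-level floor (0.15) instead of full
stops; its on-level is rescaled so expected total amplitude is independent
of burstiness — burstiness moves dispersion (turbulence), not totals
(amplitude sums). Jerk magnitude scales with `jerkiness × activity`, so the
activity-corrected expressiveness tracks jerkiness alone. The shoulder adds
a slow, small, mostly horizontal sway scaled by activity (a fully still
style therefore yields a perfectly constant recording), and the forehead
rides on the shoulder. Style priors default to uniform ranges spanning
clearly distinct speakers; `vertical_bias` is confined to [0.3, 0.7] because
extreme axis preference would override planted dominance switching.

Raters are linear: item value = 50 + loadings · z(true cues) + Gaussian
noise (sd 12 rating points), clipped to [0, 100]; rater counts per speaker
are uniform on [14, 19]. The default loading matrix plants the qualitative
impression pattern under study: amplitude → extraversion (+), jerk →
emotional stability (−), direction variation → openness (+), vertical
amplitude → agreeableness (−), horizontal turbulence → conscientiousness
(+). Biographies draw around the published career-measure moments
(16.9 ± 9.2 entry years, 0.36 ± 0.14 memberships/yr, 0.09 ± 0.05 leadership
positions/yr, ages 35–65) with optional style links; the default links are
zero — the original cue–career associations were weak, so the default
scenario treats careers as independent of motion style, and tests plant
links explicitly when recovery is asserted.

What the generator does *not* emulate: biomechanics (arms are signals, not
limbs), speech-coupled gesture structure, tracker noise and drift, rater
idiosyncrasies beyond iid noise (no rater main effects; each synthetic rater
judges one speaker rather than a subset of eight), and item-level
personality structure (items within a dimension are parallel, which is why
synthetic Cronbach's α ≈ .9+, higher than real instruments). Passing
recovery tests therefore demonstrates that the pipeline measures what the
cue definitions claim, not that real speakers are this well separated.

## Determinism and numerics

Every generator output is a pure function of (parameters, seed) through
named per-speaker, per-stage substreams (`SeedSequence(seed, spawn_key)`),
so enlarging a sample never perturbs existing speakers. Undefined values
(zero-mean CV, zero-activity ratio, zero rank variance, zero R) are NaN
with a logged warning, excluded pairwise in correlation matrices and
listwise in regressions; they are never imputed. Rank-deficient predictor
sets raise with the offending columns named; perfect collinearity in VIF
yields +inf with a warning. Test and default problem sizes (40 speakers,
133 samples, 10–20 seeds) mirror the study scale, which a laptop handles in
seconds.
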