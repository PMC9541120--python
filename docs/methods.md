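# Methods

This note documents the models, preprocessing choices and synthetic-data
assumptions behind `gazepref`, in the spirit of a package vignette: what is
computed, why the defaults are what they are, and what the tests do and do
not establish.

## Data model and conventions

A recording is a participant's time-ordered sample stream at a nominal
30 Hz: time (s), gaze position (screen pixels), pupil diameter (mm) and a
validity flag, partitioned into trial phases (`baseline` — the 4 s
phase-scrambled screen, `stimulus` — the web-shop image, `question`).
A sample is invalid when the tracker flags it or when any gaze/pupil field
fails to parse; both collapse to the same missing representation, and the
invalid fraction is the recording's *data loss*.

Screen coordinates originate at the top-left with y growing downward.
Product areas are half-open rectangles $[x_0, x_1) \times [y_0, y_1)$:
stimuli tile products edge to edge with no gap, and the half-open
convention guarantees a pixel on a shared border belongs to exactly one
product.  Five validated, mutually disjoint areas are required per trial.

## Stimulus preparation

**Luminance equalization.** Pupil size responds strongly to luminance, so
stimulus images must carry equal overall brightness: each image has its
per-image median grey level subtracted and the corpus mean of those medians
added back, clipping to [0, 255].  Absent clipping the operation is
idempotent and puts every image's median at the common value.

**Phase scrambling.** The pre-trial baseline screen is a phase-scrambled
version of the upcoming stimulus: same 2-D Fourier amplitude spectrum
(hence the same luminance/contrast statistics driving the pupil), no
recognisable content.  Implementation: a random phase offset is drawn per
frequency and antisymmetrised over conjugate pairs
($\delta(-\mathbf{f}) = -\delta(\mathbf{f})$), so the spectrum keeps
conjugate symmetry and the inverse transform is exactly real.
Self-conjugate bins (DC and Nyquist) get a zero offset by construction,
which preserves the image mean exactly — required, since the scramble's
purpose is luminance control.  Scrambling is deterministic given a seed.

## Pupil preprocessing

**Gap interpolation.** Blinks and dropouts appear as missing runs.  Runs of
at most `max_gap` = 1.0 s (covering ordinary blinks of ~100–400 ms with
margin) with observations on both sides are filled by shape-preserving
piecewise-cubic Hermite interpolation (pchip), which cannot overshoot the
flanking values; longer runs and runs at the recording edges stay missing
and count as data loss.  Gap duration is counted in samples at the nominal
rate.  No velocity-based blink detector is attempted — at 30 Hz a blink is
simply a short missing run.

**Detrending.** Pupil size drifts slowly (over minutes) during an
experiment.  The drift is estimated as the output of a first-order low-pass
Butterworth filter, cutoff 0.1 Hz, applied zero-phase, and subtracted.  Two
numerical choices:

- *Zero phase, symmetrised.* A causal pass would delay the trend relative
  to dwell timing, so the filter is applied forward–backward.  The trend is
  additionally averaged with its time-reversed application, making
  detrending exactly equivariant under time reversal (plain
  forward–backward filtering is only approximately so at a cutoff this far
  below the sampling rate).
- *Mean restoration.* The session mean (mean of the estimated trend over
  observed samples) is added back after subtraction, so detrended pupil
  size stays on the mm scale of the raw signal and the session mean is
  preserved to machine precision.  Detrending is per session, not per
  trial, since the phenomenon it removes is the multi-minute drift.

**Baseline.** A trial's baseline is the mean (observed + interpolated)
pupil diameter over its full 4 s phase-scrambled period.  If fewer than
half of the window's samples are usable the baseline is missing and the
trial's baseline-referenced variable is flagged.  Whether the original
study used the full scramble or only its tail is not derivable from the
feature definitions; the full window is the default and the window is a
config key.

## Dwell extraction

Per-sample labels (product 1–5, `outside`, `missing`) are segmented into
dwells — maximal runs on one product — with one bridging rule: a missing
run of at most `bridge_gap` = 1.0 s flanked on *both* sides by the same
product is absorbed into a single dwell (a blink while looking at a product
counts as looking at it), and its samples count toward the dwell's
duration.  A single sample on another product or outside ends the dwell;
`outside` runs are never bridged, because gaze demonstrably left the area.
Missing runs at trial edges or between different products are discarded.
There is no minimum dwell duration — a single 33 ms sample is a dwell; both
the bridging threshold and the absence of a minimum are config-exposed.

## Features, ranks and discrimination statistics

Six variables per trial × product (see README for definitions).  A product
never dwelled on gets 0 for the gaze variables and missing for the pupil
variables — no viewing, no pupil sample — and missing pupil values are
excluded from pupil AUC pools.  "Median dwell duration" is the median of
the product's *individual* dwell durations within the trial (a per-dwell
statistic on the ~0.5 s scale); an across-participants median of total
dwell time is a summary-level quantity, not a per-product feature, and is
not used in ranks or models.

Ranks order the five products per trial and variable from 1 (highest) to 5
(lowest), ties broken by ascending product id, missing values below all
observed ones.  The rank-choice distribution reports, per variable, the
percentage of trials in which the chosen product held each rank.

Preferred/nonpreferred comparisons use participant-level means (chosen
product's value averaged over trials vs the four non-chosen products
averaged within, then over, trials) in a paired t-test with df = n − 1.
The AUC is the Mann–Whitney probability, computed via midranks and
verified in tests against brute-force all-pairs counting.  By default one
AUC is computed per participant from their pooled trial × product values
and then averaged ("per_participant" pooling); a fully pooled variant is a
config switch.  Event-locked pupil traces average fixed-length
pupil segments aligned at dwell onsets, dropping segments truncated by the
end of the recording, separately for preferred and nonpreferred onsets.

## Preference models

Per participant, a cumulative-link (ordered-logit) model is fitted by
maximum likelihood over trial × product rows, outcome coded as two ordered
categories 1 = chosen < 2 = not chosen.  With two categories this is
equivalent to binary logistic regression up to sign; the coding is chosen
so that a variable promoting choice receives a *negative* coefficient.
Predictors are z-scored within participant so coefficient magnitudes are
comparable; raw values are the default, within-trial ranks a config
option.  Rows with missing predictors are dropped, and at least 10 trials
with complete predictors are required.  Perfect separation is detected
(non-convergence or any |β| above a 25 cap), flagged, and the reported
coefficients clipped at the cap.

Model accuracy is the AUC of the model's continuous preference score (the
negated linear predictor) against the chosen indicator.  The default is
in-sample, matching the simplest reading of a per-participant descriptive
fit; a k-fold cross-validated AUC over trials (5 folds, deterministic
split) is available via `AnalysisConfig(cross_validate=True)`.  The
distinction matters: an in-sample ML fit sits above 0.5 even under a null
generator (≈0.57–0.59 with 3–6 noise predictors on 60 trials), so *null
calibration* of model accuracy is only meaningful out-of-sample, and the
calibration tests use the cross-validated variant.  Feature-level AUCs
involve no fitting and need no such distinction.  Nested predictor sets
(dwell only ⊂ all gaze ⊂ gaze + pupil) are compared by paired t-tests on
per-participant AUCs; in-sample log-likelihood is monotone in the predictor
set by construction and is asserted in tests.

## Synthetic data generator

The generator emulates the study conditions end to end: 61 participants ×
60 trials at 30 Hz, each trial a 4 s baseline followed by a 15 s stimulus
(15 s accommodates the ~12.7 s of combined in-area viewing implied by the
per-product dwell totals).  Five equal product rectangles tile the screen's
central band; the designated preferred product (uniform per trial) is
always the recorded choice — the generator encodes the premise that choice
and gaze bias are linked, and the pipeline must recover the link from gaze
alone.

**Gaze** is a semi-Markov renewal process over visit targets (five
products + outside).  Each visit draws a target — never the immediately
preceding one, since consecutive same-target visits would merge into one
dwell — with the preferred product's weight scaled by `gaze_bias` = 1.5,
and a log-normal duration (CV 0.5) with mean 0.45 s for the preferred vs
0.35 s for other products.  These values put the expected per-trial
structure near ~9–10 preferred vs ~6–7 nonpreferred dwells and ~4 s vs
~2 s total dwell time.  Preference strength varies across trials: both the
weight and the duration advantage are raised to a per-trial exponent
~ N(1, 0.75), so most trials show the configured bias, some almost none,
and a minority are reversed — gaze bias is a tendency, not a law.  Within a
visit, gaze coordinates are uniform over the target rectangle; spatial
realism beyond area membership is irrelevant to a dwell-level pipeline.

**Pupil** = participant base diameter (3.3 ± 0.35 mm) + a slow sinusoidal
session drift (0.15 mm amplitude, 900 s period) + two Ornstein–Uhlenbeck
components for spontaneous fluctuations — a slow arousal wandering (SD
0.15 mm, τ = 20 s, mostly below the 0.1 Hz detrend cutoff) and an in-band
hippus-like component (SD 0.2 mm, τ = 1.5 s, surviving detrending) — + a
constant 0.02 mm dilation while gaze is inside the preferred area + white
measurement noise (SD 0.05 mm).  Without the OU components a 0.02 mm
offset over iid noise would be recovered almost perfectly after averaging
~100 samples, giving pupil AUCs near 1.0; with them, pupil AUCs land in
the weakly-discriminating regime (~0.53–0.63) that real pupillometry
shows, while the mean effect remains 0.02 mm.

**Loss** combines blinks (Poisson at 12/min, log-normal ~0.25 s, inserted
as missing runs) with random sample invalidation topped up so the total
expected loss equals `data_loss_rate` = 7.6%.

What the generator does *not* emulate: saliency-driven first fixations and
spatial scanpath structure, luminance-evoked pupil responses, event-locked
pupil-response kinetics (the preference dilation switches on and off
instantaneously), foreshortening error, tracker timestamp jitter, and any
trial in which the recorded choice differs from the gaze-biased product.
Passing tests therefore establish that the pipeline correctly recovers
dwell/pupil structure of this form at realistic noise levels — not that
real recordings meet the generator's assumptions.

## Problem sizes and determinism

The calibration and reproduction checks run on full-size synthetic
experiments (61 × 60 trials, ~2.1 M samples) with fixed seeds; oracle
checks use exhaustive enumeration (all label sequences up to length 8) or
1,000 random small instances.  All randomness flows from explicit seeds
through `numpy.random.Generator`; generating the same configuration twice
yields byte-identical files.

## Known limitations

- The cumulative-link fit uses BFGS; under perfect separation coefficients
  are capped rather than profiled out.
- Baseline windows shorter than 50% usable samples drop the trial's
  baseline-referenced variable rather than imputing.
- The TSV dialect is this package's canonical form; mapping real tracker
  exports (e.g. vendor column names, milliseconds) onto it is left to a
  thin conversion step by the user.
- `effect_size_report` treats the configured visit-weight ratio as the
  expected dwell-count ratio; renewal-process edge effects (trial
  truncation, no-immediate-repeat sampling) bias it slightly.
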