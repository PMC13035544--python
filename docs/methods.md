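# Methods

## The problem

Video-based eye trackers image the pupil from a fixed camera. When the
eye rotates away from the camera, the projected pupil foreshortens into
an ellipse and the reported pupil size shrinks — by up to ~1 mm depending
on gaze angle and setup — without any physiological change. This pupil
foreshortening error (PFE) confounds any pupillometry experiment in which
gaze position differs across conditions. Geometric PFE maps require full
knowledge of the setup geometry and break down behind refractive or
reflective surfaces (glasses, tower-mount mirrors, fMRI periscopes);
data-driven calibrations risk "correcting" genuine saccade-related pupil
dynamics away.

`pupilstitch` implements the saccade-locked alternative: gaze is mostly
displaced by saccades, which are fast (tens of ms), while true pupil
dynamics are sluggish (hundreds of ms). The pupil-size difference
measured immediately across a saccade can therefore be attributed to the
PFE and removed, with no knowledge of the setup at all.

## The correction

For each detector-supplied saccade `[onset, offset]` (closed sample
interval, 0-based):

1. **Effective bounds.** Both boundaries are extended outward by
   `extension` samples (default 1) to absorb saccades that start
   mid-sample. If the extended interval plus its median windows does not
   fit inside the trace, the saccade is *skipped*, not fatal.
2. **Step estimate.** `pre` = median of the `window` samples (default 4)
   immediately before the effective onset; `post` = median of the
   `window` samples immediately after the effective offset. The raw step
   is `post − pre`. Medians over four samples absorb sample-to-sample
   noise while staying robust to a stray contaminated sample.
3. **Stitch.** The applied correction is subtracted from every sample
   after the effective offset, cumulatively across saccades. Windows for
   later saccades are evaluated on the already-corrected trace; this is
   numerically identical to raw-trace evaluation because earlier
   corrections shift a saccade's pre and post windows equally (unit
   tested).
4. **Interpolation.** In-flight samples `[eff_onset, eff_offset]` are
   replaced by linear interpolation between the last sample before and
   the first sample after the snip, as is standard for blinks.

### Slope variant

The simple variant assumes the pupil does not truly change in flight.
It does: saccade preparation and the anticipatory light response move
pupil size on exactly this timescale. The `slope` method fits an OLS line
to the valid samples in the `slope_window_ms` (default 100 ms) before the
effective onset and subtracts the extrapolated intra-saccadic change,
`slope × span`, from the step estimate.

**Span definition.** A window median on a locally linear trace sits at
the *center* of its window, so the interval the measured step actually
covers runs from the center of the pre window to the center of the post
window. That is the default (`span_mode="centers"`) and the only choice
under which the slope variant recovers an injected step exactly on a
noiseless linear ramp (a unit-tested invariant). Two alternative readings
of "saccade duration" are exposed: `"edges"` (inner window edges) and
`"detector"` (detector onset→offset).

### Close and merged saccades

If the post window of one saccade would collide with the pre window of
the next (after extension), both adjacent windows shrink symmetrically,
never below 2 samples. If even the extended intervals nearly touch
(fewer than 4 clear samples between), the saccades are merged into a
single snip interval. This preserves correction coverage in bursts of
corrective saccades.

### Window tuning

`optimize_windows` tunes `(window, extension)` by minimizing the mean
absolute leftover error over two-saccade trials. The objective treats the
parameters as continuous, rounding each evaluation to integers clamped to
a bounded box (default window 1–8, extension 0–4). Because the rounded
objective is piecewise constant, a lone Nelder–Mead simplex stalls on its
plateaus; the implementation therefore brackets on the integer grid and
lets Nelder–Mead polish from the bracket's best point. Ties break toward
smaller extension, then smaller window (least data discarded).

## Quantifying the PFE and the leftover error

In the double-step reference design (center → target → center), the two
saccades carry equal and opposite PFE. Per trial:

- **PFE estimate** = mean of the slope-variant correction values, the
  return saccade's value inverted, signed so forward shrinkage is
  positive.
- **Leftover error** = (corrected_end − raw_end)/2, where each end value
  is the median of the final `window` valid samples. At trial end gaze is
  back at the reference point, so raw and perfectly-corrected traces must
  agree; halving expresses the residual per saccade.
- **Percent reduction** = 100 × (1 − median|leftover| / median|PFE|),
  medians by default (a mean option exists).

A do-nothing correction trivially scores zero leftover, so two
independent measures are provided: the across-trial SD locked to saccade
onset (optionally after subtracting a presaccadic per-trial baseline, so
slow pupil-state variance does not mask the artifact variance) and the
across-trial mean absolute sample-to-sample velocity. For an identity
correction both are exactly unchanged — reduction identically zero — so a
null method cannot masquerade as a perfect one.

Group comparisons use one-sided Wilcoxon signed-rank tests (paired
|PFE| vs. |leftover|) and Mann–Whitney U (between conditions), via
`scipy.stats`.

## Build-up over saccade sequences

Each corrected saccade leaves a small residual, largely genuine in-flight
pupil change masked by the snip; unlike the PFE it does not cancel
between forward and return saccades, so it accumulates linearly over
sequences. To measure it, consecutive trials are chained into
pseudotrials (every contiguous run of 1..15 trials; chains break at
session gaps). Chaining aligns each trial's correction offset to continue
from the previous chain state — raw traces are never concatenated across
recording gaps — so the chain-end leftover (not halved) is the sum of the
constituent trials' corrected-minus-raw end differences.

The through-origin model `y = βx` (leftover vs. cumulative saccade count)
is fitted per group by the closed form `β = Σxy / Σx²`; its standard
error is `sqrt(Σr² / ((n−1) Σx²))`. `apply_buildup` subtracts the
staircase `β × k` after the k-th corrected saccade (interpolated spans
are re-anchored). Refitting after applying the factor to its own fitting
set returns β = 0 by construction — the meaningful check, unit tested, is
parameter recovery: a hidden per-saccade true-pupil change of b mm yields
β ≈ −b.

`saccade_budget` reports the largest n with n × (mean post-correction
residual per saccade) ≤ median PFE: how long a sequence can be corrected
before the accumulated residual exceeds the error being removed.

## The simulator

`simulate_trial` emulates the double-step design: 800-ms center hold,
ballistic saccade to a 10° target (sigmoidal position profile; duration
from the main-sequence rule 2.2 ms/deg × amplitude + 21 ms), 800-ms
target hold, return saccade, 400-ms end hold, at 500 Hz by default. True
pupil = 3.0 mm baseline + optional linear drift + optional hippus-like
sinusoid (fixed or per-trial random phase) + optional saccade-evoked
kernel + optional hidden per-saccade in-flight change (`saccade_bias_mm`,
the mechanism behind the build-up). Three PFE surfaces:

- `step` — an additive offset of exactly −k mm while gaze is at the
  periphery, ramped in flight. Additive rather than multiplicative so the
  injected steps are exact in mm even when the true pupil drifts, which
  is what makes the noiseless exactness tests sharp.
- `cosine` — multiplicative `cos(θ)^α` with θ the gaze-to-camera angle
  (camera 10° below the line of sight by default, α = 0.5, the classic
  foreshortening of a tilted disc), normalized to 1 at the center.
- `linear` — multiplicative `1 − c × eccentricity`.

Measurement noise is white Gaussian (default SD 0.01 mm, typical of
video trackers after mm conversion). Ground-truth events are emitted
directly — saccade detection is out of scope — with an optional ±j-sample
jitter to stress window placement. Sessions derive per-trial generators
from one seed sequence, so everything is reproducible from one integer.

What the simulator does **not** emulate: smooth pursuit (the method
cannot correct gradual gaze shifts by design), glissades and other
detector imperfections beyond uniform jitter, blinks, pupillary light
responses to actual luminance, or refraction-dependent PFE surfaces.
Passing tests therefore demonstrate the algebra and the estimators, not
performance on any particular tracker.

## Numerical choices and degenerate inputs

- Sampling must be uniform (relative tolerance 1e-6); event times map to
  sample indices by round-half-up.
- Median windows require at least ⌈window/2⌉ valid samples; the slope fit
  requires max(3, half the nominal window) valid samples, else it falls
  back to slope 0 with a warning.
- The slope fit uses times relative to the window start to keep the
  normal equations well-conditioned.
- Trials longer than 3000 ms, or with any invalid sample inside an
  extended saccade interval, are filtered out with per-trial reasons; a
  user-supplied exclusion list covers manual rejections.
- Zero-saccade trials pass through corrections unchanged; all-zero paired
  differences report p = 1.

## Benchmark conditions

`scripts/acceptance.py` simulates one 400-trial session at 10° with a
0.05 ± 0.05 mm foreshortening step (trial scatter comparable to the
median, as observed in real double-step data), 0.05-mm random-phase
hippus, a hidden 2-µm in-flight change per saccade, and 0.01-mm noise,
then reports retained trials, median PFE, per-method leftover and percent
reduction, the Wilcoxon p, pseudotrial count, fitted β, the saccade
budget, and the median locked-SD reduction over the peripheral fixation.
These sizes keep the full run under a few seconds on one core.
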