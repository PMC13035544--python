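# pupilstitch

Saccade-locked correction of the **pupil foreshortening error (PFE)** in
pupillometry.

A video-based eye tracker reports apparent pupil size. When gaze shifts,
the eye rotates relative to the camera, the projected pupil foreshortens,
and the reported size drops — a purely geometric artifact that can exceed
the cognitive effects pupillometrists care about. `pupilstitch` removes
it without any knowledge of the setup geometry, exploiting the fact that
gaze is displaced by fast, ballistic saccades while true pupil dynamics
are slow: the pupil-size difference measured immediately across a saccade
*is* the PFE.

For each detected saccade the trace is **snipped** (in-flight samples
discarded), the apparent step is estimated as

```
ΔPFE = median(post-saccadic window) − median(presaccadic window)
```

(4-sample windows just outside the saccade, boundaries extended by one
sample), and the post-saccadic trace is **stitched** by subtracting ΔPFE
from every later sample; the gap is linearly interpolated. The `slope`
variant additionally fits a line to the 100 ms before onset and subtracts
the extrapolated intra-saccadic change, `slope × span`, so genuine pupil
change in flight is preserved. Over long saccade sequences the small
per-saccade residual accumulates linearly; a through-origin fit
`y = βx` of chain-end leftover error against saccade count yields a
per-saccade correction factor that removes the systematic build-up.

The package ships a synthetic gaze/pupil simulator with exact ground
truth (injected steps, cosine/linear foreshortening surfaces, hippus,
drift, noise), so every stage is testable without downloading anything.

Intended users: researchers in pupillometry and eye-tracking methods who
need a post-hoc, calibration-free PFE correction — including for setups
with mirrors or glasses where geometric corrections do not apply.

## Worked example

```python
import numpy as np
from pupilstitch import (CorrectionConfig, SimScene, simulate_session,
                         stitch_trial, trial_pfe, leftover_error,
                         percent_reduction)

scene = SimScene(step_mm=0.05, noise_sd_mm=0.01)   # 0.05-mm PFE at 10 deg
session = simulate_session(scene, n_trials=40, seed=7)
trials = [trial for trial, _ in session]

cfg = CorrectionConfig(method="slope")
pfes, leftovers = [], []
for trial in trials:
    pfes.append(trial_pfe(trial, cfg))
    result = stitch_trial(trial, cfg)
    leftovers.append(leftover_error(trial, result, cfg))

print(f"median PFE:       {np.median([p.pfe_mm for p in pfes]):.4f} mm")
print(f"median |leftover|: {np.median([abs(l.leftover_mm) for l in leftovers]):.4f} mm")
print(f"PFE reduction:    {percent_reduction(pfes, leftovers):.1f} %")
```

prints

```
median PFE:       0.0513 mm
median |leftover|: 0.0041 mm
PFE reduction:    92.0 %
```

Each trial is a double-step (center → 10° target → center). The per-trial
PFE estimate recovers the simulated 0.05-mm apparent step; after
correction, the corrected and raw traces disagree by only ~4 µm per
saccade once gaze is back at the center, i.e. 92% of the artifact is
removed. On noiseless input the removal is exact to 1e-9 mm.

The same pipeline is available from the shell:

```
pupilstitch simulate --n-trials 40 --seed 7 --out-samples s.csv --out-events e.csv
pupilstitch correct  --samples s.csv --events e.csv --fs 500 --method slope \
                     --out corrected.csv --report report.json
pupilstitch evaluate --samples s.csv --events e.csv --fs 500 --out eval.json
pupilstitch buildup  --samples s.csv --events e.csv --fs 500 --out buildup.json
```

Input files are plain CSV/TSV: samples with columns
`trial_id, t_ms, pupil[, gaze_x, gaze_y, valid]`, events with
`trial_id, onset_ms, offset_ms[, is_return]` from any saccade detector.
`convert_units` applies an artificial-eye conversion factor (mm per
arbitrary tracker unit) before correction.

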