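"""Saccade-locked snip-and-stitch correction of the pupil foreshortening error.

When the eye rotates away from the camera during a saccade, the projected
pupil image foreshortens and the tracker reports an apparent size change
that has no physiological origin. Because saccades are fast and pupil
dynamics are sluggish, the size difference measured immediately across a
saccade can be attributed to this foreshortening error (PFE). The
correction therefore:

1. estimates the step as the difference between the median pupil size in a
   short window after saccade offset and one before saccade onset
   ("snip"), with the detector's boundaries extended outward by a sample
   to absorb saccades starting mid-sample;
2. subtracts that step from every sample after the saccade ("stitch"),
   cumulatively across saccades;
3. linearly interpolates the in-flight samples, as is standard for blinks.

The ``slope`` variant additionally fits a line to the pupil trace in the
100 ms before onset and subtracts the extrapolated intra-saccadic change
(slope x measured span) from the step estimate, so that genuine pupil
change in flight is not mistaken for PFE.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .types import (
    CorrectionConfig,
    InsufficientContextError,
    PupilTrace,
    SaccadeEvent,
    Trial,
)

__all__ = [
    "SaccadeCorrection",
    "CorrectionResult",
    "effective_bounds",
    "window_median",
    "estimate_step",
    "presaccadic_slope",
    "correct_saccade",
    "stitch_trial",
    "optimize_windows",
    "end_value",
]


@dataclass(frozen=True)
class SaccadeCorrection:
    """The correction computed for one saccade (or merged saccade burst)."""

    saccade: SaccadeEvent
    eff_onset: int
    eff_offset: int
    pre_median: float
    post_median: float
    raw_step: float
    slope: float                 # mm/ms; 0 for method="simple"
    span_ms: float
    intrasaccadic_change: float  # slope * span_ms
    applied_correction: float    # raw_step - intrasaccadic_change
    merged_from: tuple = ()      # original events if this is a merged burst


@dataclass
class CorrectionResult:
    """A corrected trace plus per-saccade bookkeeping."""

    corrected: PupilTrace
    raw: PupilTrace
    per_saccade: list[SaccadeCorrection] = field(default_factory=list)
    interpolated: np.ndarray = None  # bool mask of interpolated samples
    skipped: list[tuple[SaccadeEvent, str]] = field(default_factory=list)

    @property
    def total_correction(self) -> float:
        return float(sum(c.applied_correction for c in self.per_saccade))


def effective_bounds(
    s: SaccadeEvent, cfg: CorrectionConfig, trace_len: int,
    pre_n: int | None = None, post_n: int | None = None,
) -> tuple[int, int]:
    """Extend a saccade's boundaries outward by ``cfg.extension`` samples.

    Raises :class:`InsufficientContextError` when the extended interval
    plus its median windows would not fit inside the trace; such a saccade
    is skippable, not fatal.
    """
    pre_n = cfg.window if pre_n is None else pre_n
    post_n = cfg.window if post_n is None else post_n
    eff_onset = s.onset - cfg.extension
    eff_offset = s.offset + cfg.extension
    if eff_onset < pre_n:
        raise InsufficientContextError(
            f"saccade [{s.onset},{s.offset}]: no room for a {pre_n}-sample "
            f"pre window before effective onset {eff_onset}"
        )
    if eff_offset > trace_len - 1 - post_n:
        raise InsufficientContextError(
            f"saccade [{s.onset},{s.offset}]: no room for a {post_n}-sample "
            f"post window after effective offset {eff_offset}"
        )
    return eff_onset, eff_offset


def window_median(trace: PupilTrace, start: int, n: int,
                  pupil: np.ndarray | None = None) -> float:
    """Median pupil size over valid samples in the index range [start, start+n).

    Requires at least ``ceil(n/2)`` valid samples; even counts average the
    two central values (ordinary median).
    """
    if start < 0 or start + n > len(trace):
        raise InsufficientContextError(
            f"window [{start}, {start + n}) outside trace of length {len(trace)}"
        )
    pupil = trace.pupil if pupil is None else pupil
    sl = slice(start, start + n)
    vals = pupil[sl][trace.valid[sl]]
    if vals.size < math.ceil(n / 2):
        raise InsufficientContextError(
            f"window [{start}, {start + n}): only {vals.size} of {n} samples valid"
        )
    return float(np.median(vals))


def _window_centers_ms(trace, eff_onset, eff_offset, pre_n, post_n):
    pre_t = trace.t[eff_onset - pre_n:eff_onset]
    post_t = trace.t[eff_offset + 1:eff_offset + 1 + post_n]
    return float(np.mean(pre_t)), float(np.mean(post_t))


def estimate_step(
    trace: PupilTrace, s: SaccadeEvent, cfg: CorrectionConfig,
    pupil: np.ndarray | None = None,
    pre_n: int | None = None, post_n: int | None = None,
) -> tuple[float, float, float]:
    """Measure the apparent pupil-size step across one saccade.

    Returns ``(raw_step, pre_median, post_median)`` where the pre window
    covers the ``pre_n`` samples immediately before the effective onset and
    the post window the ``post_n`` samples immediately after the effective
    offset; ``raw_step = post_median - pre_median``.
    """
    pre_n = cfg.window if pre_n is None else pre_n
    post_n = cfg.window if post_n is None else post_n
    eff_onset, eff_offset = effective_bounds(s, cfg, len(trace), pre_n, post_n)
    pre_median = window_median(trace, eff_onset - pre_n, pre_n, pupil)
    post_median = window_median(trace, eff_offset + 1, post_n, pupil)
    return post_median - pre_median, pre_median, post_median


def presaccadic_slope(
    trace: PupilTrace, s: SaccadeEvent, cfg: CorrectionConfig,
    pupil: np.ndarray | None = None,
) -> float:
    """OLS slope (mm/ms) of pupil vs. time in the window before saccade onset.

    The window covers ``cfg.slope_window_ms`` ending at the effective onset.
    With fewer than ``max(3, half the nominal window)`` valid samples the
    slope falls back to 0 with a warning (the correction degrades to the
    simple variant for that saccade).
    """
    pupil = trace.pupil if pupil is None else pupil
    eff_onset = s.onset - cfg.extension
    n_slope = int(round(trace.fs * cfg.slope_window_ms / 1000.0))
    start = max(0, eff_onset - n_slope)
    sl = slice(start, eff_onset)
    mask = trace.valid[sl]
    need = max(3, int(trace.fs * cfg.slope_window_ms / 1000.0 * 0.5))
    if int(mask.sum()) < need:
        warnings.warn(
            f"saccade [{s.onset},{s.offset}]: only {int(mask.sum())} valid "
            f"samples in the {cfg.slope_window_ms:g}-ms presaccadic window "
            f"(need {need}); slope set to 0",
            stacklevel=2,
        )
        return 0.0
    # times relative to window start keep the normal equations well-conditioned
    tt = trace.t[sl][mask] - trace.t[start]
    yy = pupil[sl][mask]
    slope, _ = np.polyfit(tt, yy, 1)
    return float(slope)


def _span_ms(trace, s, cfg, eff_onset, eff_offset, pre_n, post_n) -> float:
    if cfg.span_mode == "centers":
        pre_c, post_c = _window_centers_ms(trace, eff_onset, eff_offset, pre_n, post_n)
        return post_c - pre_c
    if cfg.span_mode == "edges":
        return float(trace.t[eff_offset + 1] - trace.t[eff_onset - 1])
    return s.duration_ms(trace.fs)  # "detector"


def correct_saccade(
    trace: PupilTrace, s: SaccadeEvent, cfg: CorrectionConfig,
    pupil: np.ndarray | None = None,
    pre_n: int | None = None, post_n: int | None = None,
    merged_from: tuple = (),
) -> SaccadeCorrection:
    """Compute the correction value for one saccade.

    For ``method="simple"`` the applied correction is the raw measured step.
    For ``method="slope"`` the extrapolated intra-saccadic pupil change
    (presaccadic slope x the span the measured step covers) is subtracted
    from the step first, so genuine in-flight pupil change is preserved.
    """
    pre_n = cfg.window if pre_n is None else pre_n
    post_n = cfg.window if post_n is None else post_n
    eff_onset, eff_offset = effective_bounds(s, cfg, len(trace), pre_n, post_n)
    raw_step, pre_median, post_median = estimate_step(
        trace, s, cfg, pupil, pre_n, post_n)
    span = _span_ms(trace, s, cfg, eff_onset, eff_offset, pre_n, post_n)
    if cfg.method == "slope":
        slope = presaccadic_slope(trace, s, cfg, pupil)
    else:
        slope = 0.0
    intra = slope * span
    return SaccadeCorrection(
        saccade=s,
        eff_onset=eff_onset,
        eff_offset=eff_offset,
        pre_median=pre_median,
        post_median=post_median,
        raw_step=raw_step,
        slope=slope,
        span_ms=span,
        intrasaccadic_change=intra,
        applied_correction=raw_step - intra,
        merged_from=merged_from,
    )


MIN_WINDOW = 2  # windows between close saccades shrink down to this


def _plan_snips(saccades, cfg: CorrectionConfig):
    """Merge saccades whose extended intervals (or median windows) collide.

    Returns a list of ``(event, pre_n, post_n, merged_from)``: consecutive
    saccades leaving fewer than 2x``MIN_WINDOW`` clear samples between their
    extended bounds are merged into one snip interval; otherwise the
    adjacent windows are shrunk symmetrically to fit the gap, never below
    ``MIN_WINDOW`` and never above ``cfg.window``.
    """
    ext = cfg.extension
    groups: list[list[SaccadeEvent]] = []
    for s in saccades:
        if groups and (s.onset - ext) - (groups[-1][-1].offset + ext) - 1 < 2 * MIN_WINDOW:
            groups[-1].append(s)
        else:
            groups.append([s])
    merged = []
    for g in groups:
        ev = g[0] if len(g) == 1 else SaccadeEvent(
            onset=g[0].onset, offset=g[-1].offset, is_return=g[-1].is_return)
        merged.append([ev, cfg.window, cfg.window, tuple(g) if len(g) > 1 else ()])
    for a, b in itertools.pairwise(merged):
        gap = (b[0].onset - ext) - (a[0].offset + ext) - 1
        if gap < 2 * cfg.window:
            fit = max(MIN_WINDOW, gap // 2)
            a[2] = min(a[2], fit)   # post window of the earlier snip
            b[1] = min(b[1], fit)   # pre window of the later snip
    return [tuple(m) for m in merged]


def stitch_trial(trial: Trial, cfg: CorrectionConfig | None = None) -> CorrectionResult:
    """Apply the full snip-and-stitch correction to one trial.

    Saccades are processed in temporal order; each correction value is
    subtracted from every sample after the saccade's effective offset
    (cumulatively), and the in-flight samples are replaced by linear
    interpolation between the last sample before and first sample after
    the snip. Saccades without enough surrounding context are skipped and
    leave the trace untouched over their span.
    """
    cfg = cfg or CorrectionConfig()
    trace = trial.trace
    corrected = trace.copy()
    interpolated = np.zeros(len(trace), dtype=bool)
    per_saccade: list[SaccadeCorrection] = []
    skipped: list[tuple[SaccadeEvent, str]] = []

    for ev, pre_n, post_n, merged_from in _plan_snips(trial.saccades, cfg):
        try:
            # windows are evaluated on the already-corrected trace; earlier
            # corrections shift pre and post windows equally, so this equals
            # raw-trace evaluation
            corr = correct_saccade(
                trace, ev, cfg, pupil=corrected.pupil,
                pre_n=pre_n, post_n=post_n, merged_from=merged_from)
        except InsufficientContextError as exc:
            for orig in (merged_from or (ev,)):
                skipped.append((orig, str(exc)))
            continue
        corrected.pupil[corr.eff_offset + 1:] -= corr.applied_correction
        lo, hi = corr.eff_onset, corr.eff_offset
        t0, t1 = trace.t[lo - 1], trace.t[hi + 1]
        y0, y1 = corrected.pupil[lo - 1], corrected.pupil[hi + 1]
        corrected.pupil[lo:hi + 1] = y0 + (trace.t[lo:hi + 1] - t0) * (y1 - y0) / (t1 - t0)
        corrected.valid[lo:hi + 1] = True
        interpolated[lo:hi + 1] = True
        per_saccade.append(corr)

    return CorrectionResult(
        corrected=corrected,
        raw=trace,
        per_saccade=per_saccade,
        interpolated=interpolated,
        skipped=skipped,
    )


def end_value(trace: PupilTrace, n: int, pupil: np.ndarray | None = None) -> float:
    """Median of the final ``n`` valid samples of a trace."""
    pupil = trace.pupil if pupil is None else pupil
    vals = pupil[trace.valid]
    if vals.size < n:
        raise ValueError(
            f"trial {trace.trial_id!r}: need {n} valid terminal samples, "
            f"have {vals.size}")
    return float(np.median(vals[-n:]))


def optimize_windows(trials: list[Trial], cfg0: CorrectionConfig | None = None,
                     max_window: int = 8, max_extension: int = 4,
                     ) -> CorrectionConfig:
    """Tune (window, extension) by Nelder-Mead on the mean absolute leftover.

    The objective is the mean |leftover error| over trials with exactly two
    saccades (forward + return to the reference point), where the leftover
    is half the corrected-minus-raw difference at trial end. The simplex
    treats the two parameters as continuous and rounds each evaluation to
    integers >= (1, 0); because the rounded objective is piecewise constant
    a lone simplex stalls on its plateaus, so the search is bracketed on
    the integer grid ``window x extension`` given by ``max_window`` /
    ``max_extension`` and Nelder-Mead then polishes from the bracket's best
    point. The best evaluated integer point wins, ties broken toward
    smaller extension then smaller window.
    """
    cfg0 = cfg0 or CorrectionConfig()
    usable = [t for t in trials if t.n_saccades == 2]
    if len(usable) < 10:
        raise ValueError(
            f"window optimization needs >= 10 two-saccade trials, got {len(usable)}")

    cache: dict[tuple[int, int], float] = {}

    def objective(x) -> float:
        w = min(max_window, max(1, int(round(x[0]))))
        e = min(max_extension, max(0, int(round(x[1]))))
        key = (w, e)
        if key not in cache:
            cfg = replace(cfg0, window=w, extension=e)
            losses = []
            for trial in usable:
                res = stitch_trial(trial, cfg)
                if res.skipped:
                    continue
                try:
                    leftover = (end_value(res.corrected, w)
                                - end_value(res.raw, w)) / 2.0
                except ValueError:
                    continue
                losses.append(abs(leftover))
            cache[key] = float(np.mean(losses)) if losses else float("inf")
        return cache[key]

    for w in range(1, max_window + 1):
        for e in range(0, max_extension + 1):
            objective((w, e))
    (w0, e0), _ = min(cache.items(), key=lambda kv: (kv[1], kv[0][1], kv[0][0]))
    minimize(objective, (float(w0), float(e0)), method="Nelder-Mead",
             options={"xatol": 0.5, "fatol": 1e-12, "maxiter": 200,
                      "initial_simplex": [(w0, e0), (w0 + 2.0, e0), (w0, e0 + 2.0)]})
    (w, e), _ = min(cache.items(), key=lambda kv: (kv[1], kv[0][1], kv[0][0]))
    return replace(cfg0, window=w, extension=e)
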