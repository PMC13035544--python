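"""Unit conversion and trial-level quality filters.

Eye trackers report pupil size in arbitrary device units; a conversion
factor obtained with an artificial eye of known diameter maps those units
to millimeters so effect sizes are comparable across studies. Trials are
then screened for excessive duration and for blinks that collide with a
saccade's correction windows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import CorrectionConfig, PupilTrace, Trial


def convert_units(trace: PupilTrace, factor: float) -> PupilTrace:
    """Scale pupil size by ``factor`` (mm per arbitrary unit).

    All other fields are unchanged. ``factor`` must be > 0.
    """
    if not factor > 0:
        raise ValueError(f"conversion factor must be > 0, got {factor}")
    out = trace.copy()
    out.pupil = out.pupil * factor
    return out


@dataclass(frozen=True)
class Rejection:
    trial_id: object
    reason: str       # "duration" | "blink-in-saccade" | "excluded"
    detail: str = ""


def filter_trials(
    trials: list[Trial],
    max_duration_ms: float = 3000.0,
    extension: int = CorrectionConfig().extension,
    exclude_ids: set | None = None,
) -> tuple[list[Trial], list[Rejection]]:
    """Partition trials into kept and rejected, with per-trial reasons.

    A trial is rejected when its trace spans more than ``max_duration_ms``,
    or when any invalid sample (blink/dropout) falls inside a saccade
    interval extended outward by ``extension`` samples — those samples feed
    the correction's median windows. ``exclude_ids`` supports a user-supplied
    manual exclusion list (e.g. trials flagged on visual inspection).
    """
    exclude_ids = exclude_ids or set()
    kept: list[Trial] = []
    rejected: list[Rejection] = []
    for trial in trials:
        trace = trial.trace
        if trial.trial_id in exclude_ids:
            rejected.append(Rejection(trial.trial_id, "excluded",
                                      "user-supplied exclusion list"))
            continue
        if trace.duration_ms > max_duration_ms:
            rejected.append(Rejection(
                trial.trial_id, "duration",
                f"{trace.duration_ms:g} ms > {max_duration_ms:g} ms"))
            continue
        blink = None
        for s in trial.saccades:
            lo = max(0, s.onset - extension)
            hi = min(len(trace) - 1, s.offset + extension)
            if not trace.valid[lo:hi + 1].all():
                blink = s
                break
        if blink is not None:
            rejected.append(Rejection(
                trial.trial_id, "blink-in-saccade",
                f"invalid sample within saccade [{blink.onset}, {blink.offset}] "
                f"extended by {extension}"))
            continue
        kept.append(trial)
    return kept, rejected
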