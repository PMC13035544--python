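"""Quantifying the foreshortening error and the quality of its correction.

The reference design is a trial with exactly two saccades: forward from a
central reference point to a peripheral target, then back. At the central
point there is no foreshortening relative to itself, so (a) the two
apparent steps are equal and opposite, giving a per-trial PFE estimate,
and (b) any corrected-minus-raw difference once gaze has returned is
leftover error introduced by the correction, halved to express it per
saccade. Because a do-nothing correction would score a perfect leftover,
two independent measures are also provided: the across-trial standard
deviation locked to saccade onset, and the mean absolute sample-to-sample
pupil velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .correction import CorrectionResult, correct_saccade, end_value, stitch_trial
from .types import CorrectionConfig, Trial

__all__ = [
    "TrialPfe",
    "LeftoverError",
    "trial_pfe",
    "leftover_error",
    "percent_reduction",
    "locked_sd",
    "velocity_profile",
    "paired_test",
]


@dataclass(frozen=True)
class TrialPfe:
    trial_id: object
    pfe_mm: float
    n_saccades: int
    condition: dict


@dataclass(frozen=True)
class LeftoverError:
    trial_id: object
    leftover_mm: float
    method: str


def trial_pfe(trial: Trial, cfg: CorrectionConfig | None = None) -> TrialPfe:
    """Per-trial PFE estimate from a forward + return saccade pair.

    Runs the slope variant on both saccades and averages the correction
    values, with the return saccade's value inverted so that forward
    apparent shrinkage is reported as positive. By default the second
    saccade of the pair is taken to be the return unless ``is_return``
    flags say otherwise.
    """
    if trial.n_saccades != 2:
        raise ValueError(
            f"trial {trial.trial_id!r}: PFE quantification needs exactly two "
            f"saccades, got {trial.n_saccades}")
    cfg = replace(cfg or CorrectionConfig(), method="slope")
    flags = [s.is_return for s in trial.saccades]
    if any(f is None for f in flags):
        flags = [False, True]
    signed = []
    for s, is_ret in zip(trial.saccades, flags):
        corr = correct_saccade(trial.trace, s, cfg)  # raises if skippable
        signed.append(corr.applied_correction if is_ret else -corr.applied_correction)
    return TrialPfe(
        trial_id=trial.trial_id,
        pfe_mm=float(np.mean(signed)),
        n_saccades=2,
        condition=dict(trial.meta),
    )


def leftover_error(trial: Trial, result: CorrectionResult,
                   cfg: CorrectionConfig | None = None) -> LeftoverError:
    """Per-saccade leftover error of a corrected two-saccade trial.

    End-of-trial values are the medians of the final ``cfg.window`` valid
    samples of the corrected and the raw trace; the difference is halved
    because the trial contains two saccades whose PFE cancels.
    """
    cfg = cfg or CorrectionConfig()
    if trial.n_saccades != 2:
        raise ValueError(
            f"trial {trial.trial_id!r}: the halving convention needs exactly "
            f"two saccades, got {trial.n_saccades}")
    corr_end = end_value(result.corrected, cfg.window)
    raw_end = end_value(result.raw, cfg.window)
    return LeftoverError(
        trial_id=trial.trial_id,
        leftover_mm=(corr_end - raw_end) / 2.0,
        method=cfg.method,
    )


def percent_reduction(pfes: list[TrialPfe], leftovers: list[LeftoverError],
                      center: str = "median") -> float:
    """Percent reduction of the PFE: 100 x (1 - m|leftover| / m|PFE|).

    ``center`` selects the across-trial summary (median by default, mean
    optionally); inputs are matched by trial id.
    """
    by_id = {l.trial_id: l for l in leftovers}
    pairs = [(p.pfe_mm, by_id[p.trial_id].leftover_mm)
             for p in pfes if p.trial_id in by_id]
    if not pairs:
        raise ValueError("no matched trial ids between PFE and leftover lists")
    agg = np.median if center == "median" else np.mean
    pfe_c = float(agg([abs(a) for a, _ in pairs]))
    left_c = float(agg([abs(b) for _, b in pairs]))
    if pfe_c == 0:
        warnings.warn("central |PFE| is 0; percent reduction undefined",
                      stacklevel=2)
        return float("nan")
    return 100.0 * (1.0 - left_c / pfe_c)


def _aligned(trials, results, which, baseline_ms=None):
    """Stack traces aligned at the first saccade onset, truncated to the
    common number of samples before and after the lock; optionally express
    each trial as change from its mean over the ``baseline_ms`` preceding
    the lock (removes slow between-trial state variance)."""
    if len(trials) < 2:
        raise ValueError("alignment needs >= 2 trials")
    locks = [t.saccades[0].onset if t.saccades else 0 for t in trials]
    pre = min(locks)
    post = min(len(t.trace) - lk for t, lk in zip(trials, locks))
    rows = []
    for trial, res, lk in zip(trials, results, locks):
        trace = res.corrected if which == "corrected" else res.raw
        row = trace.pupil[lk - pre:lk + post]
        if baseline_ms is not None:
            nb = max(1, min(pre, int(round(baseline_ms / trace.dt_ms))))
            row = row - np.mean(trace.pupil[lk - nb:lk])
        rows.append(row)
    return np.vstack(rows), pre


def locked_sd(trials: list[Trial], results: list[CorrectionResult],
              baseline_ms: float | None = None,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-trial SD over time, locked to the first saccade onset.

    Returns ``(sd_raw, sd_corr, reduction_pct)`` where the reduction is
    ``100 x (1 - sd_corr / sd_raw)`` per timepoint; timepoints with zero
    raw SD report a reduction of 0 with a warning. With ``baseline_ms``
    each trial is expressed as change from its presaccadic baseline, so
    slow between-trial pupil-state variance does not mask the
    saccade-locked artifact variance.
    """
    raw, _ = _aligned(trials, results, "raw", baseline_ms)
    corr, _ = _aligned(trials, results, "corrected", baseline_ms)
    sd_raw = raw.std(axis=0, ddof=1)
    sd_corr = corr.std(axis=0, ddof=1)
    reduction = np.zeros_like(sd_raw)
    # guard against numerically-zero SD from identical trials
    nz = sd_raw > 1e-12 * np.maximum(1.0, np.abs(raw).max())
    if not nz.all():
        warnings.warn("zero raw SD at some timepoints; reduction reported as 0",
                      stacklevel=2)
    reduction[nz] = 100.0 * (1.0 - sd_corr[nz] / sd_raw[nz])
    return sd_raw, sd_corr, reduction


def velocity_profile(trials: list[Trial], results: list[CorrectionResult],
                     signed: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial mean pupil velocity (first difference per sample) over
    time, locked to the first saccade onset; absolute by default."""
    raw, _ = _aligned(trials, results, "raw")
    corr, _ = _aligned(trials, results, "corrected")
    op = (lambda x: x) if signed else np.abs
    return (op(np.diff(raw, axis=1)).mean(axis=0),
            op(np.diff(corr, axis=1)).mean(axis=0))


def paired_test(a, b, alternative: str = "greater", paired: bool = True
                ) -> tuple[float, float]:
    """Nonparametric comparison of two samples of error magnitudes.

    Paired: one-sided Wilcoxon signed-rank (default ``alternative=
    "greater"`` tests a > b, e.g. |PFE| exceeds |leftover|). Unpaired:
    Mann-Whitney U for between-condition contrasts. All-zero paired
    differences are degenerate and report p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length samples")
        if len(a) < 6:
            raise ValueError("paired test needs n >= 6")
        if np.all(a == b):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative=alternative)
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def evaluate_trials(trials: list[Trial], cfg: CorrectionConfig | None = None
                    ) -> dict:
    """Convenience pipeline: correct, quantify PFE and leftover, summarise.

    Operates on two-saccade trials only; returns per-trial values plus the
    grouped medians and the percent PFE reduction.
    """
    cfg = cfg or CorrectionConfig()
    pfes, leftovers = [], []
    for trial in trials:
        if trial.n_saccades != 2:
            continue
        try:
            pfes.append(trial_pfe(trial, cfg))
        except Exception:
            continue
        res = stitch_trial(trial, cfg)
        leftovers.append(leftover_error(trial, res, cfg))
    out = {
        "n_trials": len(pfes),
        "median_pfe_mm": float(np.median([p.pfe_mm for p in pfes])) if pfes else float("nan"),
        "median_abs_leftover_mm": float(np.median([abs(l.leftover_mm) for l in leftovers])) if leftovers else float("nan"),
        "pfes": pfes,
        "leftovers": leftovers,
    }
    out["percent_reduction"] = (percent_reduction(pfes, leftovers)
                                if pfes and leftovers else float("nan"))
    return out
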