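"""Systematic leftover-error build-up across saccade sequences.

Each corrected saccade leaves a small residual (largely genuine in-flight
pupil change masked by the snip), and these residuals do not cancel across
a sequence the way the foreshortening steps do. To measure the build-up,
consecutive trials — each starting and ending at the reference point — are
chained into pseudotrials of up to ``max_chain`` trials; the corrected
minus raw difference at the chain end (not halved) is the accumulated
leftover y after x = total saccades. A through-origin least-squares fit
``y = beta * x`` gives a per-saccade correction factor beta per
participant/experiment, which is then subtracted as a staircase: beta x k
after the k-th corrected saccade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .correction import CorrectionResult, end_value, stitch_trial
from .types import CorrectionConfig, Trial

__all__ = [
    "Pseudotrial",
    "BuildupModel",
    "make_pseudotrials",
    "fit_buildup",
    "apply_buildup",
    "saccade_budget",
    "UNBOUNDED",
]

#: Sentinel returned by :func:`saccade_budget` when the residual is zero.
UNBOUNDED = math.inf


@dataclass(frozen=True)
class Pseudotrial:
    trial_ids: tuple
    n_saccades: int
    leftover_mm: float
    group: object = None


@dataclass(frozen=True)
class BuildupModel:
    """Through-origin slope of accumulated leftover vs. saccade count."""

    beta: float                  # mm per saccade
    group: object
    n_pseudotrials: int
    se: float                    # standard error of beta
    residual_per_saccade: float  # mean |y - beta*x| / x after correction


def _consecutive(id_a, id_b) -> bool:
    """Trials chain only when session-consecutive; integer-like trial ids
    must differ by exactly 1, otherwise adjacency in the list is trusted."""
    try:
        return int(id_b) - int(id_a) == 1
    except (TypeError, ValueError):
        return True


def make_pseudotrials(
    trials: list[Trial],
    cfg: CorrectionConfig | None = None,
    max_chain: int = 15,
    group_key=None,
    results: list[CorrectionResult] | None = None,
) -> list[Pseudotrial]:
    """Chain every contiguous run of 1..max_chain successive trials.

    Each trial is corrected once with :func:`stitch_trial`; chaining aligns
    each trial's correction offset to continue from the previous chain
    state (raw traces are never concatenated numerically), so the chain-end
    leftover is the sum of the constituent trials' corrected-minus-raw end
    differences. Chains break at session gaps (non-consecutive trial ids)
    and at group boundaries when ``group_key`` is given.
    """
    cfg = cfg or CorrectionConfig()
    if results is None:
        results = [stitch_trial(t, cfg) for t in trials]

    # contiguous blocks of session-consecutive, same-group trials
    blocks: list[list[int]] = []
    for i, trial in enumerate(trials):
        new_block = not blocks
        if blocks:
            prev = trials[blocks[-1][-1]]
            if not _consecutive(prev.trial_id, trial.trial_id):
                new_block = True
            elif group_key is not None and group_key(prev) != group_key(trial):
                new_block = True
        if new_block:
            blocks.append([i])
        else:
            blocks[-1].append(i)

    out: list[Pseudotrial] = []
    for block in blocks:
        contrib = []
        for i in block:
            res = results[i]
            contrib.append(end_value(res.corrected, cfg.window)
                           - end_value(res.raw, cfg.window))
        nsac = [trials[i].n_saccades for i in block]
        m = len(block)
        for start in range(m):
            acc_left = 0.0
            acc_sac = 0
            for length in range(1, min(max_chain, m - start) + 1):
                i = block[start + length - 1]
                acc_left += contrib[start + length - 1]
                acc_sac += nsac[start + length - 1]
                out.append(Pseudotrial(
                    trial_ids=tuple(trials[block[start + j]].trial_id
                                    for j in range(length)),
                    n_saccades=acc_sac,
                    leftover_mm=acc_left,
                    group=(group_key(trials[i]) if group_key else None),
                ))
    return out


def fit_buildup(pseudotrials: list[Pseudotrial]) -> dict[object, BuildupModel]:
    """Fit ``y = beta * x`` (leftover vs. saccade count) per group.

    Through-origin OLS closed form: ``beta = sum(x*y) / sum(x^2)``.
    """
    groups: dict[object, list[Pseudotrial]] = {}
    for p in pseudotrials:
        groups.setdefault(p.group, []).append(p)
    models: dict[object, BuildupModel] = {}
    for g, ps in groups.items():
        ps = [p for p in ps if p.n_saccades > 0]
        if len(ps) < 2:
            raise ValueError(f"group {g!r}: need >= 2 pseudotrials with saccades")
        x = np.array([p.n_saccades for p in ps], dtype=float)
        y = np.array([p.leftover_mm for p in ps])
        sxx = float(np.sum(x * x))
        if sxx == 0:
            raise ValueError(f"group {g!r}: sum(x^2) is zero")
        beta = float(np.sum(x * y) / sxx)
        resid = y - beta * x
        n = len(ps)
        se = math.sqrt(float(np.sum(resid**2)) / ((n - 1) * sxx)) if n > 1 else float("nan")
        models[g] = BuildupModel(
            beta=beta,
            group=g,
            n_pseudotrials=n,
            se=se,
            residual_per_saccade=float(np.mean(np.abs(resid) / x)),
        )
    return models


def apply_buildup(result: CorrectionResult, model: BuildupModel) -> CorrectionResult:
    """Subtract the build-up staircase beta x k after the k-th corrected
    saccade's effective offset; interpolated spans are re-anchored."""
    corrected = result.corrected.copy()
    for corr in result.per_saccade:
        corrected.pupil[corr.eff_offset + 1:] -= model.beta
    for corr in result.per_saccade:
        lo, hi = corr.eff_onset, corr.eff_offset
        t = corrected.t
        y0, y1 = corrected.pupil[lo - 1], corrected.pupil[hi + 1]
        corrected.pupil[lo:hi + 1] = (
            y0 + (t[lo:hi + 1] - t[lo - 1]) * (y1 - y0) / (t[hi + 1] - t[lo - 1]))
    return replace(result, corrected=corrected)


def saccade_budget(model: BuildupModel, median_pfe: float) -> float:
    """Largest saccade count n with n x residual-per-saccade <= median PFE.

    Answers: how long a saccade sequence can be corrected before the
    accumulated residual exceeds the error the correction removes. A zero
    residual returns the :data:`UNBOUNDED` sentinel.
    """
    if not median_pfe > 0:
        raise ValueError("median_pfe must be > 0")
    r = model.residual_per_saccade
    if r == 0:
        return UNBOUNDED
    return float(math.floor(median_pfe / r))
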