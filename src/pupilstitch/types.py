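"""Core domain types for saccade-locked pupil-size correction.

The central object is a :class:`PupilTrace`: one trial's uniformly sampled
pupil-size time series (mm after unit conversion), optionally with gaze
position, and a per-sample validity mask (``False`` marks blinks/dropouts).
Saccades are half-open nowhere: a :class:`SaccadeEvent` spans the closed
sample-index interval ``[onset, offset]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class DataError(ValueError):
    """Input data violates a structural contract (non-uniform sampling,
    overlapping events, out-of-range events, ...)."""


class FormatError(ValueError):
    """A file is missing a required column or is otherwise malformed."""


class InsufficientContextError(ValueError):
    """A saccade sits too close to a trace edge (or a blink) for its
    median windows to be formed; the saccade is skippable, not fatal."""


#: Relative tolerance on the sample-period uniformity check.
UNIFORMITY_RTOL = 1e-6


@dataclass
class PupilTrace:
    """One trial's uniformly sampled pupil trace.

    Parameters
    ----------
    trial_id : label for the trial (opaque; often an integer-like string).
    t : timestamps in ms, strictly increasing with constant step ``1000/fs``.
    fs : sampling frequency in Hz.
    pupil : pupil size per sample; mm after conversion, arbitrary units before.
    gaze_x, gaze_y : optional gaze position in degrees of visual angle.
    valid : per-sample validity mask; ``False`` = blink/dropout.
    """

    trial_id: object
    t: np.ndarray
    fs: float
    pupil: np.ndarray
    gaze_x: Optional[np.ndarray] = None
    gaze_y: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.pupil) & (self.pupil > 0)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.gaze_x is not None:
            self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        if self.gaze_y is not None:
            self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        n = len(self.t)
        if n < 1:
            raise DataError(f"trial {self.trial_id!r}: empty trace")
        for name in ("pupil", "valid", "gaze_x", "gaze_y"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise DataError(
                    f"trial {self.trial_id!r}: {name} has length "
                    f"{len(arr)} but t has length {n}"
                )
        if self.fs <= 0:
            raise DataError(f"trial {self.trial_id!r}: fs must be > 0")
        if n > 1:
            dt = 1000.0 / self.fs
            gaps = np.diff(self.t)
            bad = np.nonzero(np.abs(gaps - dt) > UNIFORMITY_RTOL * dt)[0]
            if bad.size:
                i = int(bad[0])
                raise DataError(
                    f"trial {self.trial_id!r}: non-uniform sampling at sample "
                    f"{i} -> {i + 1} (gap {gaps[i]:g} ms, expected {dt:g} ms)"
                )
        p = self.pupil[self.valid]
        if p.size and not (np.all(np.isfinite(p)) and np.all(p > 0)):
            raise DataError(
                f"trial {self.trial_id!r}: valid samples must have finite, "
                "positive pupil size"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def duration_ms(self) -> float:
        """Trace span from first to last sample, in ms."""
        return float(self.t[-1] - self.t[0])

    def copy(self) -> "PupilTrace":
        return replace(
            self,
            t=self.t.copy(),
            pupil=self.pupil.copy(),
            valid=self.valid.copy(),
            gaze_x=None if self.gaze_x is None else self.gaze_x.copy(),
            gaze_y=None if self.gaze_y is None else self.gaze_y.copy(),
        )


@dataclass(frozen=True)
class SaccadeEvent:
    """A detector-supplied saccade, as a closed sample-index interval."""

    onset: int
    offset: int
    is_return: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise DataError(
                f"saccade [{self.onset}, {self.offset}] must satisfy "
                "0 <= onset < offset"
            )

    def duration_ms(self, fs: float) -> float:
        return (self.offset - self.onset) / fs * 1000.0

    def validate_for(self, trace: PupilTrace) -> None:
        if self.offset >= len(trace):
            raise DataError(
                f"trial {trace.trial_id!r}: saccade offset {self.offset} "
                f"outside trace of length {len(trace)}"
            )


def check_saccades(saccades: list[SaccadeEvent], trace: PupilTrace) -> None:
    """Enforce per-trial saccade contracts: in range, sorted, non-overlapping."""
    prev: Optional[SaccadeEvent] = None
    for s in saccades:
        s.validate_for(trace)
        if prev is not None:
            if s.onset < prev.onset:
                raise DataError(
                    f"trial {trace.trial_id!r}: saccades not sorted by onset"
                )
            if s.onset <= prev.offset:
                raise DataError(
                    f"trial {trace.trial_id!r}: saccades "
                    f"[{prev.onset},{prev.offset}] and [{s.onset},{s.offset}] "
                    "overlap"
                )
        prev = s


# Allowed readings of "saccade duration" in the slope x duration product.
SPAN_MODES = ("centers", "edges", "detector")


@dataclass(frozen=True)
class CorrectionConfig:
    """Tunable parameters of the snip-and-stitch correction.

    window : samples per pre/post median window (default 4).
    extension : samples each saccade boundary is extended outward (default 1),
        guarding against saccades that start mid-sample.
    slope_window_ms : presaccadic linear-fit window in ms (default 100).
    method : ``"simple"`` subtracts the raw measured step; ``"slope"``
        additionally removes the extrapolated intra-saccadic pupil change.
    span_mode : which interval the fitted slope is multiplied by.
        ``"centers"`` (default) uses the time between the centers of the two
        median windows — the interval the measured step actually covers;
        ``"edges"`` uses the inner edges of the windows; ``"detector"`` uses
        the detector's onset-to-offset duration.
    """

    window: int = 4
    extension: int = 1
    slope_window_ms: float = 100.0
    method: str = "simple"
    span_mode: str = "centers"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        if not self.slope_window_ms > 0:
            raise ValueError("slope_window_ms must be > 0")
        if self.method not in ("simple", "slope"):
            raise ValueError("method must be 'simple' or 'slope'")
        if self.span_mode not in SPAN_MODES:
            raise ValueError(f"span_mode must be one of {SPAN_MODES}")


@dataclass
class Trial:
    """A trace, its detected saccades, and condition labels."""

    trace: PupilTrace
    saccades: list[SaccadeEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_saccades(self.saccades, self.trace)

    @property
    def trial_id(self) -> object:
        return self.trace.trial_id

    @property
    def n_saccades(self) -> int:
        return len(self.saccades)
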