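import numpy as np
import pytest

from pupilstitch.types import PupilTrace, SaccadeEvent, Trial


FS = 500.0
DT = 1000.0 / FS


def make_trace(pupil, fs=FS, trial_id="t0", valid=None, **kw):
    pupil = np.asarray(pupil, dtype=float)
    t = np.arange(len(pupil)) * (1000.0 / fs)
    return PupilTrace(trial_id=trial_id, t=t, fs=fs, pupil=pupil,
                      valid=valid, **kw)


def step_trial(n=400, onsets=((100, 110), (250, 260)), steps=(-0.05, 0.05),
               baseline=3.0, ramp=0.0, fs=FS, trial_id="t0"):
    """Trial with pure apparent steps on a constant (or ramping) true pupil.

    Each step is applied from the sample after the saccade onset; the
    in-flight samples ramp linearly so endpoints stay clean.
    """
    t = np.arange(n) * (1000.0 / fs)
    pupil = baseline + ramp * t
    offset = np.zeros(n)
    for (on, off), k in zip(onsets, steps):
        offset[on:off + 1] += k * np.linspace(0.0, 1.0, off - on + 1)
        offset[off + 1:] += k
    trace = PupilTrace(trial_id=trial_id, t=t, fs=fs, pupil=pupil + offset)
    sacs = [SaccadeEvent(on, off, is_return=(i == len(onsets) - 1))
            for i, (on, off) in enumerate(onsets)]
    return Trial(trace=trace, saccades=sacs,
                 meta={"participant": "p0", "experiment": "e0"})


@pytest.fixture
def flat_trace():
    return make_trace(np.full(300, 3.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
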