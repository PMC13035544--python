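"""Synthetic gaze/pupil trials with known ground truth.

The generator emulates the double-step saccade design used to quantify
the pupil foreshortening error: gaze holds a central reference point,
makes a ballistic saccade to a peripheral target, holds it, and saccades
back. Saccade duration follows a main-sequence rule (2.2 ms/deg x
amplitude + 21 ms by default). On top of a slow true-pupil process
(baseline, optional linear drift, optional hippus-like sinusoid, optional
saccade-evoked response), gaze-angle-dependent apparent shrinkage is
applied, plus white measurement noise:

- ``step``  — an additive apparent offset of exactly -k mm while gaze is
  at the periphery (ramped in flight), so the injected per-saccade steps
  are +-k mm exactly regardless of true-pupil dynamics;
- ``cosine`` — multiplicative attenuation cos(theta)^alpha with theta the
  gaze-to-camera angle (camera slightly below the line of sight),
  normalized to 1 at the central reference point;
- ``linear`` — multiplicative attenuation 1 - c x eccentricity_deg.

Ground-truth saccade on/offsets are emitted directly (saccade detection
is out of scope); an optional jitter stresses window placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import CorrectionConfig, PupilTrace, SaccadeEvent, Trial

__all__ = ["SimScene", "SimTruth", "simulate_trial", "simulate_session",
           "attenuation"]


@dataclass(frozen=True)
class SimScene:
    """Simulator configuration; defaults mirror the double-step design
    (800-ms holds, 10 deg targets, tower-mount-like 500 Hz sampling)."""

    fs: float = 500.0
    center_hold_ms: float = 800.0
    target_hold_ms: float = 800.0
    end_hold_ms: float = 400.0
    eccentricity_deg: float = 10.0
    direction_deg: float = 0.0

    # main-sequence rule: duration_ms = slope * amplitude_deg + intercept
    main_sequence_slope: float = 2.2
    main_sequence_intercept_ms: float = 21.0

    return_saccade: bool = True        # False: single outward saccade only

    pfe_model: str = "step"            # step | cosine | linear
    step_mm: float = 0.05              # apparent shrinkage at the target
    step_sd_mm: float = 0.0            # across-trial SD of the step
    cosine_alpha: float = 0.5
    camera_elevation_deg: float = -10.0
    linear_atten_per_deg: float = 0.002

    baseline_mm: float = 3.0
    drift_mm_per_ms: float = 0.0
    sine_amp_mm: float = 0.0
    sine_period_ms: float = 2500.0
    sine_phase_rad: float | None = 0.0  # None: drawn per trial (hippus)
    evoked_amp_mm: float = 0.0         # saccade-evoked response amplitude
    evoked_tau_ms: float = 500.0
    saccade_bias_mm: float = 0.0       # true-pupil change hidden in flight

    noise_sd_mm: float = 0.01
    jitter_samples: int = 0            # event on/offset jitter (+- samples)
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity_deg must be >= 0")
        if self.pfe_model not in ("step", "cosine", "linear"):
            raise ValueError("pfe_model must be step, cosine or linear")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated trial."""

    true_pupil: np.ndarray       # physiological pupil size, mm
    apparent: np.ndarray         # observed minus noise (true + PFE)
    true_steps: list[float]      # per-saccade injected apparent change, mm
    true_saccades: list[SaccadeEvent]


def attenuation(ecc_deg: np.ndarray, direction_deg: float, scene: SimScene
                ) -> np.ndarray:
    """Multiplicative foreshortening factor at the given gaze eccentricity.

    For the cosine model, theta is the angle between the gaze direction
    and a camera axis at ``camera_elevation_deg`` below straight ahead;
    the factor is cos(theta)^alpha normalized to 1 at eccentricity 0.
    """
    ecc = np.asarray(ecc_deg, dtype=float)
    if scene.pfe_model == "linear":
        return np.clip(1.0 - scene.linear_atten_per_deg * ecc, 0.0, None)
    if scene.pfe_model == "cosine":
        el = math.radians(scene.camera_elevation_deg)
        cam = np.array([0.0, math.sin(el), math.cos(el)])
        th = np.radians(ecc)
        d = math.radians(direction_deg)
        gaze = np.stack([np.sin(th) * math.cos(d),
                         np.sin(th) * math.sin(d),
                         np.cos(th)], axis=-1)
        cos_theta = np.clip(gaze @ cam, 1e-9, 1.0)
        center = np.clip(cam[2], 1e-9, 1.0)  # gaze [0,0,1] at ecc 0
        return (cos_theta / center) ** scene.cosine_alpha
    raise ValueError("attenuation is defined for cosine/linear models only")


def _sigmoid_profile(n: int) -> np.ndarray:
    """S-shaped 0->1 position profile over n samples, exact at endpoints."""
    u = np.linspace(0.0, 1.0, n)
    s = 1.0 / (1.0 + np.exp(-10.0 * (u - 0.5)))
    return (s - s[0]) / (s[-1] - s[0])


def simulate_trial(scene: SimScene, rng: np.random.Generator | None = None,
                   trial_id=0) -> tuple[Trial, SimTruth]:
    """Generate one double-step trial with ground truth.

    The trial layout is center hold -> forward saccade -> target hold ->
    return saccade -> end hold; gaze follows a sigmoidal position profile
    in flight. Observed pupil = foreshortened true pupil + Gaussian noise.
    """
    rng = rng or np.random.default_rng(scene.seed)
    dt = 1000.0 / scene.fs
    cfg = CorrectionConfig()
    n_center = int(round(scene.center_hold_ms / dt))
    n_target = int(round(scene.target_hold_ms / dt))
    n_end = int(round(scene.end_hold_ms / dt))
    if n_target < 2 * (cfg.window + cfg.extension):
        raise ValueError(
            f"target_hold_ms={scene.target_hold_ms:g} is shorter than the "
            f"post-saccade correction context "
            f"({2 * (cfg.window + cfg.extension)} samples at fs={scene.fs:g})")
    dur_ms = (scene.main_sequence_slope * scene.eccentricity_deg
              + scene.main_sequence_intercept_ms)
    n_flight = max(2, int(round(dur_ms / dt)))

    on1 = n_center
    off1 = on1 + n_flight - 1
    if scene.return_saccade:
        on2 = off1 + 1 + n_target
        off2 = on2 + n_flight - 1
        n = off2 + 1 + n_end
    else:
        n = off1 + 1 + n_target + n_end
    t = np.arange(n) * dt

    ecc = np.zeros(n)
    prof = _sigmoid_profile(n_flight) * scene.eccentricity_deg
    ecc[on1:off1 + 1] = prof
    if scene.return_saccade:
        ecc[off1 + 1:on2] = scene.eccentricity_deg
        ecc[on2:off2 + 1] = prof[::-1]
    else:
        ecc[off1 + 1:] = scene.eccentricity_deg

    true_pupil = np.full(n, scene.baseline_mm)
    true_pupil += scene.drift_mm_per_ms * t
    if scene.sine_amp_mm:
        phase = scene.sine_phase_rad
        if phase is None:
            phase = rng.uniform(0.0, 2 * np.pi)
        true_pupil += scene.sine_amp_mm * np.sin(
            2 * np.pi * t / scene.sine_period_ms + phase)
    saccades = [SaccadeEvent(on1, off1, is_return=False)]
    if scene.return_saccade:
        saccades.append(SaccadeEvent(on2, off2, is_return=True))
    if scene.evoked_amp_mm:
        for s in saccades:
            lag = t[s.onset:] - t[s.onset]
            true_pupil[s.onset:] += scene.evoked_amp_mm * (
                lag / scene.evoked_tau_ms) * np.exp(1 - lag / scene.evoked_tau_ms)
    if scene.saccade_bias_mm:
        # genuine pupil change hidden in flight: ramps over each saccade
        for s in saccades:
            ramp = _sigmoid_profile(s.offset - s.onset + 1) * scene.saccade_bias_mm
            true_pupil[s.onset:s.offset + 1] += ramp
            true_pupil[s.offset + 1:] += scene.saccade_bias_mm

    k = scene.step_mm
    if scene.step_sd_mm:
        k = rng.normal(scene.step_mm, scene.step_sd_mm)
    if scene.pfe_model == "step":
        apparent = true_pupil - k * (
            ecc / scene.eccentricity_deg if scene.eccentricity_deg else 0.0)
    else:
        apparent = true_pupil * attenuation(ecc, scene.direction_deg, scene)

    observed = apparent.copy()
    if scene.noise_sd_mm:
        observed = observed + rng.normal(0.0, scene.noise_sd_mm, size=n)

    d = scene.direction_deg
    trace = PupilTrace(
        trial_id=trial_id, t=t, fs=scene.fs, pupil=observed,
        gaze_x=ecc * math.cos(math.radians(d)),
        gaze_y=ecc * math.sin(math.radians(d)),
        valid=np.ones(n, dtype=bool),
    )
    true_steps = [float((apparent[s.offset + 1] - true_pupil[s.offset + 1])
                        - (apparent[s.onset - 1] - true_pupil[s.onset - 1]))
                  for s in saccades]

    events = saccades
    if scene.jitter_samples:
        j = scene.jitter_samples
        events = []
        for s in saccades:
            events.append(SaccadeEvent(
                onset=max(1, s.onset + int(rng.integers(-j, j + 1))),
                offset=min(n - 2, s.offset + int(rng.integers(-j, j + 1))),
                is_return=s.is_return,
            ))

    meta = {"participant": "sim", "experiment": "sim",
            "eccentricity_deg": scene.eccentricity_deg,
            "direction_deg": scene.direction_deg}
    trial = Trial(trace=trace, saccades=events, meta=meta)
    truth = SimTruth(true_pupil=true_pupil, apparent=apparent,
                     true_steps=true_steps, true_saccades=saccades)
    return trial, truth


def simulate_session(scene: SimScene, n_trials: int, seed: int | None = None
                     ) -> list[tuple[Trial, SimTruth]]:
    """Generate ``n_trials`` independent trials with consecutive ids.

    Per-trial generators are spawned from one seed sequence, so the whole
    session is reproducible from a single integer and any subset of trials
    is independent of the others.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(scene.seed if seed is None else seed)
    out = []
    for i, child in enumerate(ss.spawn(n_trials)):
        rng = np.random.default_rng(child)
        out.append(simulate_trial(scene, rng=rng, trial_id=i))
    return out
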