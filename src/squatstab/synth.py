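"""Synthetic squat-exergame session generator with known instability ground truth.

Emulates a cohort of subjects performing repeated squats in front of a depth
camera (~60 Hz joint positions) while standing on a force plate (50 Hz
center-of-pressure, millimeters). Each squat is a smooth raised-cosine torso
descent-hold-ascent; a configurable fraction of squats ("knee instability")
additionally carries a mediolateral sinusoidal knee oscillation, antiphase
between the knees by default (valgus-like wobble), whose amplitude/frequency
are drawn so that the resulting peak knee-shakiness velocity straddles the
0.03 m/s labeling threshold from opposite sides for stable vs unstable squats.
The oscillation is coupled into the mediolateral CoP channel with a unitless
gain. Device start times differ by a uniform offset of a few seconds, as in
real dual-device recordings.

The generator is deterministic: every subject draws from an independent
substream derived from (seed, subject_id), so cohorts are reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError
from .preprocess import (CAMERA_CHANNELS, DEFAULT_CUTOFF_HZ, PLATE_CHANNELS,
                         SensorStream)

GROUND_TRUTH_COLUMNS = ("subject", "squat", "true_unstable", "osc_amp_m",
                        "osc_freq_hz", "depth_m", "t_on", "t_off")

#: minimum squat depth accepted by the segmenter's spurious-detection filter
SPURIOUS_MIN_DEPTH_M = 0.15


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study: 28 subjects x 130 squats (3640 total)
    at ~6.5% instability prevalence, camera at 60 Hz / plate at 50 Hz, start
    offsets up to a few seconds. Oscillation frequencies stay in 1-4 Hz so the
    injected instability survives the 5 Hz low-pass; unstable amplitudes
    (4-10 mm) put peak knee shakiness well above 0.03 m/s after filtering,
    stable residual wobble (<= 0.3 mm) stays well below it.
    """

    n_subjects: int = 28
    squats_per_subject: int = 130
    camera_rate: float = 60.0       # Hz
    plate_rate: float = 50.0        # Hz
    start_offset_max: float = 3.0   # s
    standing_height: float = 1.0    # m, torso tracker height when standing
    depth_range: tuple[float, float] = (0.25, 0.45)          # m
    stance_width_range: tuple[float, float] = (0.30, 0.45)   # m
    cycle_duration_range: tuple[float, float] = (3.0, 5.0)   # s
    hold_fraction: float = 0.3      # fraction of the cycle spent near peak depth
    rest_duration: float = 1.5      # s standing between squats
    instability_prevalence: float = 0.065
    osc_amp_stable: float = 0.0003                    # m, max residual wobble
    osc_amp_unstable: tuple[float, float] = (0.004, 0.010)  # m
    osc_freq_range: tuple[float, float] = (1.0, 4.0)  # Hz
    cop_coupling_gain: float = 0.5  # unitless knee-osc -> CoPx coupling
    cop_sway_sd: float = 3.0        # mm, baseline postural sway amplitude
    cop_sway_tau: float = 1.0       # s, sway correlation time
    noise_sd_camera: float = 0.0003  # m, white marker jitter
    noise_sd_cop: float = 1.0        # mm, white CoP measurement noise
    antiphase: bool = True           # valgus-like knee coupling
    seed: int = 0

    def validate(self) -> None:
        if not self.camera_rate > 2 * DEFAULT_CUTOFF_HZ:
            raise ConfigurationError(
                f"camera_rate {self.camera_rate} Hz must exceed twice the "
                f"{DEFAULT_CUTOFF_HZ} Hz filter cutoff")
        if not self.plate_rate > 2 * DEFAULT_CUTOFF_HZ:
            raise ConfigurationError(
                f"plate_rate {self.plate_rate} Hz must exceed twice the "
                f"{DEFAULT_CUTOFF_HZ} Hz filter cutoff")
        if not 0.0 <= self.instability_prevalence <= 1.0:
            raise ConfigurationError(
                f"instability_prevalence {self.instability_prevalence} outside [0, 1]")
        if not self.depth_range[0] > SPURIOUS_MIN_DEPTH_M:
            raise ConfigurationError(
                f"depth_range minimum {self.depth_range[0]} m must exceed the "
                f"segmenter's spurious-rejection depth {SPURIOUS_MIN_DEPTH_M} m")
        if not self.osc_freq_range[1] < DEFAULT_CUTOFF_HZ:
            raise ConfigurationError(
                f"osc_freq_range upper bound {self.osc_freq_range[1]} Hz must stay "
                f"below the {DEFAULT_CUTOFF_HZ} Hz low-pass cutoff")
        for name in ("depth_range", "stance_width_range", "cycle_duration_range",
                     "osc_amp_unstable", "osc_freq_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigurationError(f"{name} min {lo} exceeds max {hi}")
        if not 0.0 < self.hold_fraction < 1.0:
            raise ConfigurationError(f"hold_fraction {self.hold_fraction} outside (0, 1)")


class Session(NamedTuple):
    subject: int
    camera: SensorStream
    plate: SensorStream
    ground_truth: pd.DataFrame


@dataclass
class _SquatPlan:
    t_on: float
    duration: float
    depth: float
    unstable: bool
    osc_amp: float
    osc_freq: float
    osc_phase: float

    @property
    def t_off(self) -> float:
        return self.t_on + self.duration


def _depth_profile(t: np.ndarray, plan: _SquatPlan, hold_fraction: float) -> np.ndarray:
    """Raised-cosine descent / flat hold / raised-cosine ascent, depth >= 0."""
    td = plan.duration * (1.0 - hold_fraction) / 2.0  # descent = ascent time
    th = plan.duration * hold_fraction
    s = t - plan.t_on
    out = np.zeros_like(t)
    m = (s >= 0) & (s < td)
    out[m] = plan.depth * 0.5 * (1.0 - np.cos(np.pi * s[m] / td))
    m = (s >= td) & (s < td + th)
    out[m] = plan.depth
    m = (s >= td + th) & (s <= plan.duration)
    out[m] = plan.depth * 0.5 * (1.0 - np.cos(np.pi * (plan.duration - s[m]) / td))
    return out


def _osc_signal(t: np.ndarray, plan: _SquatPlan) -> np.ndarray:
    """Sinusoidal knee oscillation with a sin^2 envelope over the cycle
    (smooth onset/offset; envelope ~1 through the hold phase)."""
    s = t - plan.t_on
    out = np.zeros_like(t)
    m = (s >= 0) & (s <= plan.duration)
    env = np.sin(np.pi * s[m] / plan.duration) ** 2
    out[m] = plan.osc_amp * env * np.sin(2 * np.pi * plan.osc_freq * s[m] + plan.osc_phase)
    return out


def _plan_session(config: SynthConfig, rng: np.random.Generator) -> list[_SquatPlan]:
    plans = []
    # lead-in standing: exercise begins only after the slowest device can
    # have started, so no squat is ever truncated by the recording overlap
    t = config.start_offset_max + 2.0
    for _ in range(config.squats_per_subject):
        duration = rng.uniform(*config.cycle_duration_range)
        depth = rng.uniform(*config.depth_range)
        unstable = bool(rng.random() < config.instability_prevalence)
        if unstable:
            amp = rng.uniform(*config.osc_amp_unstable)
        else:
            amp = rng.uniform(0.0, config.osc_amp_stable)
        freq = rng.uniform(*config.osc_freq_range)
        phase = rng.uniform(0.0, 2 * np.pi)
        plans.append(_SquatPlan(t, duration, depth, unstable, amp, freq, phase))
        t += duration + config.rest_duration
    return plans


def _ar1_sway(n: int, dt: float, sd: float, tau: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) approximation of slow postural sway."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)  # stationary start
    e[1:] = rng.normal(0.0, innov_sd, size=n - 1)
    return lfilter([1.0], [1.0, -phi], e)


def _subject_rng(config: SynthConfig, subject_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(subject_id)]))


def generate_session(config: SynthConfig, subject_id: int) -> Session:
    """Generate one subject's camera stream, plate stream and ground truth.

    Camera channels (meters): x_left_knee, x_right_knee, y_torso at
    ``camera_rate``. Plate channels (millimeters, force-plate convention):
    cop_x (ML), cop_y (AP) at ``plate_rate``, starting a uniform offset
    after the camera.
    """
    config.validate()
    rng = _subject_rng(config, subject_id)

    plans = _plan_session(config, rng)
    session_end = plans[-1].t_off + 2.0 if plans else 4.0
    stance = rng.uniform(*config.stance_width_range)
    plate_start = rng.uniform(0.0, config.start_offset_max)

    t_cam = np.arange(0.0, session_end, 1.0 / config.camera_rate)
    t_plate = plate_start + np.arange(
        0.0, session_end - plate_start, 1.0 / config.plate_rate)

    depth_cam = np.zeros_like(t_cam)
    osc_cam = np.zeros_like(t_cam)
    depth_plate = np.zeros_like(t_plate)
    osc_plate = np.zeros_like(t_plate)
    for plan in plans:
        depth_cam += _depth_profile(t_cam, plan, config.hold_fraction)
        depth_plate += _depth_profile(t_plate, plan, config.hold_fraction)
        if plan.osc_amp > 0.0:
            osc_cam += _osc_signal(t_cam, plan)
            osc_plate += _osc_signal(t_plate, plan)

    y_torso = config.standing_height - depth_cam
    sign_r = -1.0 if config.antiphase else 1.0
    x_lk = stance / 2.0 + osc_cam
    x_rk = -stance / 2.0 + sign_r * osc_cam
    if config.noise_sd_camera > 0.0:
        x_lk = x_lk + rng.normal(0.0, config.noise_sd_camera, t_cam.size)
        x_rk = x_rk + rng.normal(0.0, config.noise_sd_camera, t_cam.size)
        y_torso = y_torso + rng.normal(0.0, config.noise_sd_camera, t_cam.size)

    # CoP in millimeters: correlated baseline sway + squat-locked AP shift +
    # coupled knee oscillation in ML + white measurement noise.
    dt_p = 1.0 / config.plate_rate
    shared = _ar1_sway(t_plate.size, dt_p, config.cop_sway_sd, config.cop_sway_tau, rng)
    own_x = _ar1_sway(t_plate.size, dt_p, config.cop_sway_sd, config.cop_sway_tau, rng)
    own_y = _ar1_sway(t_plate.size, dt_p, config.cop_sway_sd, config.cop_sway_tau, rng)
    cop_x = 0.5 * shared + np.sqrt(0.75) * own_x
    cop_y = 0.5 * shared + np.sqrt(0.75) * own_y
    cop_x = cop_x + config.cop_coupling_gain * osc_plate * 1e3
    cop_y = cop_y - 30.0 * depth_plate  # mild posterior shift while squatting (mm)
    if config.noise_sd_cop > 0.0:
        cop_x = cop_x + rng.normal(0.0, config.noise_sd_cop, t_plate.size)
        cop_y = cop_y + rng.normal(0.0, config.noise_sd_cop, t_plate.size)

    camera = SensorStream(
        modality="camera", timestamps=t_cam, nominal_rate=config.camera_rate,
        channels={"x_left_knee": x_lk, "x_right_knee": x_rk, "y_torso": y_torso},
        units={c: "m" for c in CAMERA_CHANNELS})
    plate = SensorStream(
        modality="plate", timestamps=t_plate, nominal_rate=config.plate_rate,
        channels={"cop_x": cop_x, "cop_y": cop_y},
        units={c: "mm" for c in PLATE_CHANNELS})

    gt = pd.DataFrame({
        "subject": subject_id,
        "squat": np.arange(len(plans)),
        "true_unstable": [p.unstable for p in plans],
        "osc_amp_m": [p.osc_amp for p in plans],
        "osc_freq_hz": [p.osc_freq for p in plans],
        "depth_m": [p.depth for p in plans],
        "t_on": [p.t_on for p in plans],
        "t_off": [p.t_off for p in plans],
    })
    return Session(subject=subject_id, camera=camera, plate=plate, ground_truth=gt)


def generate_cohort(config: SynthConfig) -> tuple[list[Session], pd.DataFrame]:
    """Generate all subjects' sessions plus the concatenated ground-truth table.

    Bit-for-bit reproducible for a fixed seed; subjects use independent
    substreams keyed by (seed, subject_id).
    """
    config.validate()
    sessions = [generate_session(config, sid) for sid in range(config.n_subjects)]
    truth = pd.concat([s.ground_truth for s in sessions], ignore_index=True)
    return sessions, truth


def write_session(session: Session, out_dir) -> dict[str, str]:
    """Write one session's streams as CSV (t_sec + channel columns)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, stream in (("camera", session.camera), ("plate", session.plate)):
        p = os.path.join(out_dir, f"subject_{session.subject:03d}_{name}.csv")
        stream.write_csv(p)
        paths[name] = p
    return paths
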