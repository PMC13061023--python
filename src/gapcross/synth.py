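"""Synthetic gap-crossing jump trials with known ground truth.

The generator emulates the structure of mouse gap-crossing jumps:

* four behavioral phases (preparation, propulsion, flight, landing) with a
  preparatory counter-movement crouch, a rapid multi-joint extension whose
  peak falls just after takeoff, in-flight hindlimb flexion, and partial
  re-extension for landing;
* a 2-D kinematic chain over a canonical 10-landmark skeleton, rooted at
  the hindpaw.  The paw is planted through stance, accelerates under a
  ramp-and-hold push that ends abruptly at takeoff, is ballistic (constant
  vertical acceleration) through flight, and decelerates sharply at
  landing.  This gives the hindpaw-acceleration trace the canonical jump
  signature used for phase segmentation and makes the flight trajectory an
  exact parabola;
* phase-locked EMG as amplitude-modulated unit-variance Gaussian noise
  ``s(t) = env(t) * n(t)``, with a pre-takeoff extensor burst whose peak
  scales linearly with gap distance across animals via random intercepts,
  a flexor (IP/TA) co-activation burst preceding flight, and an extensor
  landing burst;
* closed-loop stimulation effects: envelope suppression within an epoch,
  or a blended drive of the joint angles toward flexion targets with a
  configurable latency and rise time.

All randomness is drawn from a single seed; identical (config, seed) give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .records import (
    CANONICAL_LANDMARKS,
    PHASES,
    CohortDataset,
    EMGRecording,
    GroundTruth,
    StimEpoch,
    TrialRecording,
)

GRAVITY_MM_S2 = 9810.0

# segment lengths of the chain, mm
_SEG_LEN = {"foot": 18.0, "shank": 24.0, "thigh": 22.0}
_HEAD_LEN, _EAR_LEN, _ARM_LEN, _TAIL_LEN = 22.0, 10.0, 16.0, 14.0

# per-phase posture parameters: hindlimb joint angles (deg), absolute foot
# orientation (deg, hindpaw->ankle), trunk length (mm) and absolute forelimb
# segment orientations (deg).  "countermove" is the brief extra flexion dip
# at the start of propulsion that precedes the extension; "peak" is the
# peri-takeoff extension maximum reached just after the paw leaves the
# platform.
_DEFAULT_TEMPLATES: dict[str, dict[str, float]] = {
    "preparation": {"hip": 75, "knee": 65, "ankle": 75, "foot": 100,
                    "trunk": 52, "fore1": -100, "fore2": -20},
    "countermove": {"hip": 70, "knee": 53, "ankle": 65, "foot": 100,
                    "trunk": 50, "fore1": -100, "fore2": -20},
    "propulsion":  {"hip": 140, "knee": 150, "ankle": 140, "foot": 70,
                    "trunk": 75, "fore1": -135, "fore2": -120},
    "peak":        {"hip": 165, "knee": 170, "ankle": 160, "foot": 55,
                    "trunk": 78, "fore1": -135, "fore2": -120},
    "flight":      {"hip": 60, "knee": 50, "ankle": 60, "foot": 140,
                    "trunk": 60, "fore1": -20, "fore2": -10},
    "landing":     {"hip": 110, "knee": 120, "ankle": 110, "foot": 95,
                    "trunk": 66, "fore1": -80, "fore2": -60},
}

_PARAMS = ("hip", "knee", "ankle", "foot", "trunk", "fore1", "fore2")
_ANGLE_PARAMS = ("hip", "knee", "ankle", "foot", "fore1", "fore2")

#: hindlimb joint-angle triplets (proximal, vertex, distal)
JOINT_TRIPLETS: dict[str, tuple[str, str, str]] = {
    "hip": ("shoulder", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "hindpaw"),
}

#: recorded muscle roster and functional roles
MUSCLE_ROLES: dict[str, str] = {
    "Glut": "extensor", "BF": "bi-articular", "RF": "bi-articular",
    "Sol": "extensor", "GS": "bi-articular", "IP": "flexor", "TA": "flexor",
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic jump generator.

    Durations are ms, positions mm, angles degrees, EMG in mV-like units.
    ``extensor_gain_beta`` is the slope of the pre-takeoff extensor-burst
    peak per cm of gap distance (reference distance 10 cm), the quantity
    the mixed-effects tuning analysis recovers.
    """

    frame_rate: float = 500.0
    landmarks: tuple[str, ...] = CANONICAL_LANDMARKS
    phase_durations: dict = field(default_factory=lambda: {
        "preparation": 100.0, "propulsion": 60.0,
        "flight": 80.0, "landing": 100.0,
    })
    joint_angle_templates: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_TEMPLATES.items()}
    )
    landmark_noise_sd: float = 0.15
    gap_distances: tuple[float, ...] = (10.0, 15.0, 20.0)
    extensor_gain_beta: float = 0.269
    extensor_base_amp: float = 1.0
    animal_intercept_sd: float = 0.3
    emg_sampling_rate: float = 2000.0
    seed: int = 0

    # trial-to-trial variability: per-phase jitter on posture templates,
    # scaled by the phase noise schedule below
    trial_jitter_deg: float = 1.0
    trial_jitter_trunk_mm: float = 1.0
    peak_jitter_sd: float = 0.08
    # within-trial postural wander (Ornstein-Uhlenbeck on the chain
    # parameters): continuous postural sway that dominates across-trial
    # posture variability without contaminating the hindpaw acceleration
    # signal (the wander rides on the body, not on the paw root)
    angle_wander_deg: float = 3.0
    trunk_wander_mm: float = 1.5
    wander_tau_ms: float = 12.0
    # per-phase multiplier on landmark noise, template jitter and wander;
    # propulsion is the most stereotyped phase, landing the most variable
    phase_noise_schedule: dict = field(default_factory=lambda: {
        "preparation": 1.0, "propulsion": 0.5, "flight": 0.8, "landing": 1.1,
    })

    # transition timing (ms)
    ramp_ms: float = 15.0            # generic boundary ramp
    countermove_ms: float = 8.0      # counter-movement dip at propulsion onset
    ext_pre_ms: float = 15.0         # extension ramp begins before takeoff
    ext_post_ms: float = 6.0         # extension peak reached after takeoff
    flex_ramp_ms: float = 24.0       # peak -> flight flexion ramp
    push_ramp_ms: float = 10.0       # rise of the propulsive push
    landing_stop_ms: float = 30.0    # deceleration time after touch-down
    flight_slope_ms_per_cm: float = 2.5   # flight lengthens with distance
    flight_ref_distance_cm: float = 15.0

    # EMG envelope shape (ms relative to takeoff unless noted)
    ext_burst_center_ms: float = -25.0
    ext_burst_sigma_ms: float = 18.0
    flex_burst_center_ms: float = -8.0
    flex_burst_sigma_ms: float = 10.0
    flex_burst_amp: float = 1.5
    landing_burst_amp: float = 1.2
    landing_burst_sigma_ms: float = 12.0
    prep_tonic_amp: float = 0.25
    envelope_floor: float = 0.02
    emg_ref_distance_cm: float = 10.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.landmark_noise_sd < 0:
            raise ConfigurationError("landmark_noise_sd must be >= 0")
        if set(self.phase_durations) != set(PHASES):
            raise ConfigurationError(
                f"phase_durations must have exactly the keys {PHASES}"
            )
        if any(v <= 0 for v in self.phase_durations.values()):
            raise ConfigurationError("phase durations must be positive")
        unknown = set(self.joint_angle_templates) - set(_DEFAULT_TEMPLATES)
        if unknown:
            raise ConfigurationError(f"unknown phase key(s) in templates: {unknown}")
        if any(
            v < 0
            for v in (self.flex_burst_amp, self.landing_burst_amp,
                      self.prep_tonic_amp, self.extensor_base_amp,
                      self.envelope_floor)
        ):
            raise ConfigurationError("envelope parameters must be non-negative")
        for name in self.landmarks:
            if name not in CANONICAL_LANDMARKS:
                raise ConfigurationError(f"unknown landmark {name!r}")

    def noiseless(self) -> "SynthConfig":
        """Copy of the config with all kinematic randomness switched off."""
        cfg = SynthConfig(**{**asdict(self)})
        cfg.landmark_noise_sd = 0.0
        cfg.trial_jitter_deg = 0.0
        cfg.trial_jitter_trunk_mm = 0.0
        cfg.peak_jitter_sd = 0.0
        cfg.angle_wander_deg = 0.0
        cfg.trunk_wander_mm = 0.0
        return cfg

    # -- timing helpers -------------------------------------------------
    def flight_ms(self, gap_distance: float) -> float:
        return self.phase_durations["flight"] + self.flight_slope_ms_per_cm * (
            gap_distance - self.flight_ref_distance_cm
        )

    def frames_per_ms(self) -> float:
        return self.frame_rate / 1000.0

    def boundaries(self, gap_distance: float) -> tuple[int, int, int, int]:
        """(b1, b2, b3, T) frame indices of the phase boundaries."""
        fpm = self.frames_per_ms()
        n_prep = round(self.phase_durations["preparation"] * fpm)
        n_prop = round(self.phase_durations["propulsion"] * fpm)
        n_fly = round(self.flight_ms(gap_distance) * fpm)
        n_land = round(self.phase_durations["landing"] * fpm)
        b1 = n_prep
        b2 = b1 + n_prop
        b3 = b2 + n_fly
        return b1, b2, b3, b3 + n_land


# ---------------------------------------------------------------------------
# control-point interpolation


def _cosine_knots(frames: np.ndarray, knots: Sequence[tuple[float, float]]) -> np.ndarray:
    """Evaluate a cosine-ramp piecewise curve through (frame, value) knots.

    Constant before the first and after the last knot; between consecutive
    knots the value follows a half-cosine, so each knot value is attained
    exactly and velocity is zero there.
    """
    t = np.asarray(frames, dtype=float)
    kt = np.array([k[0] for k in knots], dtype=float)
    kv = np.array([k[1] for k in knots], dtype=float)
    if np.any(np.diff(kt) < 0):
        raise ConfigurationError("transition knots overlap; ramps too long for phases")
    out = np.empty_like(t)
    out[t < kt[0]] = kv[0]
    out[t >= kt[-1]] = kv[-1]
    for (t0, v0), (t1, v1) in zip(knots[:-1], knots[1:]):
        m = (t >= t0) & (t < t1)
        if t1 == t0 or not np.any(m):
            continue
        s = (t[m] - t0) / (t1 - t0)
        out[m] = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))
    return out


def _param_series(
    cfg: SynthConfig,
    values: Mapping[str, Mapping[str, float]],
    b1: int, b2: int, b3: int, n_frames: int,
) -> dict[str, np.ndarray]:
    """Per-frame series for every chain parameter from per-phase values."""
    fpm = cfg.frames_per_ms()
    r1 = cfg.ramp_ms * fpm
    re_pre = cfg.ext_pre_ms * fpm
    re_post = cfg.ext_post_ms * fpm
    r_flex = cfg.flex_ramp_ms * fpm
    r_cm = cfg.countermove_ms * fpm
    frames = np.arange(n_frames)
    series = {}
    for p in _PARAMS:
        v = {phase: values[phase][p] for phase in values}
        knots = [
            (float(b1), v["preparation"]),
            (b1 + r_cm, v["countermove"]),
            (b1 + r_cm + r1, v["propulsion"]),
            (b2 - re_pre, v["propulsion"]),
            (b2 + re_post, v["peak"]),
            (b2 + re_post + r_flex, v["flight"]),
            (float(b3), v["flight"]),
            (b3 + r1, v["landing"]),
        ]
        series[p] = _cosine_knots(frames, knots)
    return series


# ---------------------------------------------------------------------------
# hindpaw root trajectory


def _push_integrals(tau: float, r: float) -> tuple[float, float]:
    """(velocity, position) integrals of the ramp-and-hold push profile."""
    if tau <= r:
        i1 = tau / 2.0 - (r / (2.0 * math.pi)) * math.sin(math.pi * tau / r)
        i2 = tau ** 2 / 4.0 + (r ** 2 / (2.0 * math.pi ** 2)) * (
            math.cos(math.pi * tau / r) - 1.0
        )
        return i1, i2
    i1r = r / 2.0
    i2r = r ** 2 / 4.0 - r ** 2 / math.pi ** 2
    dt = tau - r
    return i1r + dt, i2r + i1r * dt + dt ** 2 / 2.0


def _root_path(cfg: SynthConfig, gap_distance: float,
               b1: int, b2: int, b3: int, n_frames: int) -> np.ndarray:
    """Hindpaw trajectory (T, 2): planted, push, ballistic flight, braking."""
    fps = cfg.frame_rate
    t_frames = np.arange(n_frames) / fps  # s
    t1, t2, t3 = b1 / fps, b2 / fps, b3 / fps
    push = t2 - t1
    ramp = min(cfg.push_ramp_ms / 1000.0, push)
    t_fly = t3 - t2
    gap_mm = 10.0 * gap_distance

    i1p, i2p = _push_integrals(push, ramp)
    ax = gap_mm / (t_fly * i1p + i2p)
    vy_to = GRAVITY_MM_S2 * t_fly / 2.0
    ay = vy_to / i1p

    pos = np.zeros((n_frames, 2))
    # propulsion push
    for k in range(b1, b2):
        i1, i2 = _push_integrals(t_frames[k] - t1, ramp)
        pos[k] = (ax * i2, ay * i2)
    # takeoff state
    _, i2p_ = _push_integrals(push, ramp)
    x_to, y_to = ax * i2p_, ay * i2p_
    vx = ax * i1p
    # ballistic flight
    tau = t_frames[b2:b3] - t2
    pos[b2:b3, 0] = x_to + vx * tau
    pos[b2:b3, 1] = y_to + vy_to * tau - 0.5 * GRAVITY_MM_S2 * tau ** 2
    # landing: constant deceleration to rest over landing_stop_ms
    x_land = x_to + vx * t_fly
    y_land = y_to + vy_to * t_fly - 0.5 * GRAVITY_MM_S2 * t_fly ** 2
    v_land = np.array([vx, vy_to - GRAVITY_MM_S2 * t_fly])
    stop = cfg.landing_stop_ms / 1000.0
    tau3 = t_frames[b3:] - t3
    inside = np.minimum(tau3, stop)
    disp = v_land[None, :] * inside[:, None] - (
        v_land[None, :] / (2.0 * stop)
    ) * inside[:, None] ** 2
    pos[b3:] = np.array([x_land, y_land]) + disp
    return pos


# ---------------------------------------------------------------------------
# forward kinematics


def _unit(deg: np.ndarray) -> np.ndarray:
    rad = np.deg2rad(deg)
    return np.stack([np.cos(rad), np.sin(rad)], axis=-1)


def chain_landmarks(series: Mapping[str, np.ndarray], root: np.ndarray) -> dict[str, np.ndarray]:
    """Build all landmark trajectories from parameter series and root path.

    The chain runs hindpaw -> ankle -> knee -> hip -> shoulder; joint
    angles are interior angles of the stated triplets, so recomputing them
    from the landmark positions reproduces the input series exactly.
    """
    psi_f = series["foot"]
    psi_s = psi_f - 180.0 + series["ankle"]
    psi_t = psi_s + 180.0 - series["knee"]
    psi_tr = psi_t + 180.0 + series["hip"]

    pts: dict[str, np.ndarray] = {}
    pts["hindpaw"] = root
    pts["ankle"] = root + _SEG_LEN["foot"] * _unit(psi_f)
    pts["knee"] = pts["ankle"] + _SEG_LEN["shank"] * _unit(psi_s)
    pts["hip"] = pts["knee"] + _SEG_LEN["thigh"] * _unit(psi_t)
    pts["shoulder"] = pts["hip"] + series["trunk"][:, None] * _unit(psi_tr)
    pts["nose"] = pts["shoulder"] + _HEAD_LEN * _unit(psi_tr + 15.0)
    pts["ear"] = pts["shoulder"] + _EAR_LEN * _unit(psi_tr + 60.0)
    pts["elbow"] = pts["shoulder"] + _ARM_LEN * _unit(series["fore1"])
    pts["forepaw"] = pts["elbow"] + _ARM_LEN * _unit(series["fore2"])
    pts["tail_base"] = pts["hip"] + _TAIL_LEN * _unit(psi_tr + 190.0)
    return pts


# ---------------------------------------------------------------------------
# trial generation


def _jittered_values(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, dict[str, float]]:
    base = {k: dict(_DEFAULT_TEMPLATES[k]) for k in _DEFAULT_TEMPLATES}
    for k, overrides in cfg.joint_angle_templates.items():
        base[k].update(overrides)
    sched = cfg.phase_noise_schedule
    # one offset per (parameter, phase); peak/countermove share the
    # adjacent phase's offset so ramps stay consistent within a trial
    share = {"countermove": "preparation", "peak": "propulsion"}
    offsets = {
        phase: {
            p: rng.normal(
                0.0,
                (cfg.trial_jitter_trunk_mm if p == "trunk" else cfg.trial_jitter_deg)
                * sched[phase],
            )
            for p in _PARAMS
        }
        for phase in PHASES
    }
    out = {}
    for key, vals in base.items():
        src = offsets[share.get(key, key)] if (key in share or key in PHASES) else None
        out[key] = {
            p: vals[p] + (src[p] if src is not None else 0.0) for p in _PARAMS
        }
    return out


def _ou_series(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance Ornstein-Uhlenbeck samples."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * math.sqrt(1.0 - rho ** 2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def _add_wander(cfg: SynthConfig, series: dict[str, np.ndarray],
                b1: int, b2: int, b3: int, n_frames: int,
                rng: np.random.Generator) -> None:
    if cfg.angle_wander_deg == 0 and cfg.trunk_wander_mm == 0:
        return
    rho = math.exp(-1000.0 / (cfg.frame_rate * cfg.wander_tau_ms))
    sched = cfg.phase_noise_schedule
    scale = np.empty(n_frames)
    scale[:b1] = sched["preparation"]
    scale[b1:b2] = sched["propulsion"]
    scale[b2:b3] = sched["flight"]
    scale[b3:] = sched["landing"]
    for p in _PARAMS:
        sd = cfg.trunk_wander_mm if p == "trunk" else cfg.angle_wander_deg
        if sd > 0:
            series[p] = series[p] + sd * scale * _ou_series(n_frames, rho, rng)


def generate_trial(
    config: SynthConfig,
    animal_id: str = "A0",
    gap_distance: float = 15.0,
    seed: int = 0,
    trial_id: str | None = None,
    condition: str = "control",
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one synthetic jump trial and its ground truth."""
    if gap_distance not in config.gap_distances:
        raise ConfigurationError(
            f"gap_distance {gap_distance} not in config.gap_distances"
        )
    rng = np.random.default_rng(seed)
    b1, b2, b3, n_frames = config.boundaries(gap_distance)
    values = _jittered_values(config, rng)
    series = _param_series(config, values, b1, b2, b3, n_frames)
    _add_wander(config, series, b1, b2, b3, n_frames, rng)
    root = _root_path(config, gap_distance, b1, b2, b3, n_frames)
    pts = chain_landmarks(series, root)

    phase_per_frame = np.empty(n_frames, dtype=object)
    phase_per_frame[:b1] = "preparation"
    phase_per_frame[b1:b2] = "propulsion"
    phase_per_frame[b2:b3] = "flight"
    phase_per_frame[b3:] = "landing"

    sched = config.phase_noise_schedule
    frame_sd = config.landmark_noise_sd * np.array(
        [sched[p] for p in phase_per_frame]
    )
    noise = rng.normal(size=(n_frames, len(config.landmarks), 2)) * frame_sd[:, None, None]

    positions = np.stack([pts[name] for name in config.landmarks], axis=1) + noise

    tid = trial_id or f"{animal_id}_d{gap_distance:g}_s{seed}"
    truth = GroundTruth(
        phase_boundaries=(b1, b2, b3),
        phase_per_frame=phase_per_frame,
        joint_angles={j: series[j].copy() for j in ("hip", "knee", "ankle")},
        root_path=root,
        extras={"series": series, "noise": noise, "values": values},
    )
    trial = TrialRecording(
        trial_id=tid,
        animal_id=animal_id,
        frame_rate=config.frame_rate,
        landmarks=tuple(config.landmarks),
        positions=positions,
        takeoff_frame=b2,
        gap_distance=gap_distance,
        condition=condition,
        metadata={"seed": seed, "truth": truth},
    )
    return trial, truth


def template_check_frames(truth: GroundTruth) -> dict[str, int]:
    """A frame per phase at which the posture equals the phase template.

    Phase midpoints rounded up: transitions start at boundaries, so the
    rounded-up midpoint always lies in the template-constant stretch.
    """
    b1, b2, b3 = truth.phase_boundaries
    t = len(truth.phase_per_frame)
    return {
        "preparation": math.ceil(b1 / 2),
        "propulsion": math.ceil((b1 + b2) / 2),
        "flight": math.ceil((b2 + b3) / 2),
        "landing": math.ceil((b3 + t) / 2),
    }


# ---------------------------------------------------------------------------
# EMG generation


def analytic_envelopes(
    config: SynthConfig,
    truth: GroundTruth,
    gap_distance: float,
    animal_intercept: float = 0.0,
    peak_jitter: Mapping[str, float] | None = None,
    muscles: Iterable[str] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """(time_ms, envelope per muscle) at the EMG sampling grid."""
    b1, b2, b3 = truth.phase_boundaries
    fps_ms = config.frame_rate / 1000.0
    t0 = -b2 / fps_ms  # trial start, ms relative to takeoff
    t_end = (len(truth.phase_per_frame) - b2) / fps_ms
    dt = 1000.0 / config.emg_sampling_rate
    t = np.arange(t0, t_end, dt)

    prep_mid = t0 + (b1 / fps_ms) / 2.0  # midpoint of preparation
    prep_sigma = (b1 / fps_ms) / 3.0
    land_on = (b3 - b2) / fps_ms

    amp_main = (
        config.extensor_base_amp
        * (1.0 + config.extensor_gain_beta
           * (gap_distance - config.emg_ref_distance_cm))
        + animal_intercept
    )
    jit = peak_jitter or {}

    def gauss(center: float, sigma: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - center) / sigma) ** 2)

    envs: dict[str, np.ndarray] = {}
    roster = list(muscles) if muscles is not None else list(MUSCLE_ROLES)
    for m in roster:
        role = MUSCLE_ROLES[m]
        env = np.full_like(t, config.envelope_floor)
        if role in ("extensor", "bi-articular"):
            env = env + config.prep_tonic_amp * gauss(prep_mid, prep_sigma)
            env = env + max(amp_main + jit.get(m, 0.0), 0.0) * gauss(
                config.ext_burst_center_ms, config.ext_burst_sigma_ms
            )
            env = env + config.landing_burst_amp * gauss(
                land_on + 15.0, config.landing_burst_sigma_ms
            )
        else:  # flexor
            env = env + max(config.flex_burst_amp + jit.get(m, 0.0), 0.0) * gauss(
                config.flex_burst_center_ms, config.flex_burst_sigma_ms
            )
        envs[m] = env
    return t, envs


def generate_emg(
    config: SynthConfig,
    truth: GroundTruth,
    gap_distance: float,
    animal_intercept: float = 0.0,
    seed: int = 0,
    trial_id: str = "",
    muscles: Iterable[str] | None = None,
) -> list[EMGRecording]:
    """Amplitude-modulated Gaussian-noise EMG for one trial."""
    rng = np.random.default_rng(seed)
    roster = list(muscles) if muscles is not None else list(MUSCLE_ROLES)
    jitter = {
        m: rng.normal(0.0, config.peak_jitter_sd) if config.peak_jitter_sd > 0 else 0.0
        for m in roster
    }
    t, envs = analytic_envelopes(
        config, truth, gap_distance, animal_intercept, jitter, roster
    )
    truth.envelopes = envs
    b2 = truth.phase_boundaries[1]
    offset = t[0]
    recs = []
    for m in roster:
        carrier = rng.standard_normal(t.size)
        recs.append(
            EMGRecording(
                muscle=m,
                role=MUSCLE_ROLES[m],
                signal=envs[m] * carrier,
                sampling_rate=config.emg_sampling_rate,
                trial_id=trial_id,
                time_offset_ms=offset,
            )
        )
    return recs


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    config: SynthConfig,
    n_animals: int = 6,
    trials_per_condition: int = 4,
    seed: int = 0,
    include_emg: bool = True,
    include_landmarks: bool = True,
    emg_muscles: Iterable[str] | None = None,
) -> CohortDataset:
    """A multi-animal cohort across all configured gap distances.

    Per-animal extensor intercepts are drawn from
    ``N(0, animal_intercept_sd^2)``; the planted distance slope and the
    intercepts are stored for parameter-recovery tests.
    """
    if n_animals < 2:
        raise ConfigurationError("n_animals must be >= 2")
    if trials_per_condition < 1:
        raise ConfigurationError("trials_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    animals = [f"A{i}" for i in range(n_animals)]
    intercepts = {
        a: (rng.normal(0.0, config.animal_intercept_sd)
            if config.animal_intercept_sd > 0 else 0.0)
        for a in animals
    }
    trials, truths, emg = [], [], []
    for a in animals:
        for d in config.gap_distances:
            for r in range(trials_per_condition):
                s = int(rng.integers(0, 2 ** 31 - 1))
                tid = f"{a}_d{d:g}_r{r}"
                if include_landmarks:
                    trial, truth = generate_trial(
                        config, a, d, seed=s, trial_id=tid
                    )
                else:
                    b1, b2, b3, n = config.boundaries(d)
                    phase = np.empty(n, dtype=object)
                    phase[:b1], phase[b1:b2] = "preparation", "propulsion"
                    phase[b2:b3], phase[b3:] = "flight", "landing"
                    truth = GroundTruth(
                        phase_boundaries=(b1, b2, b3),
                        phase_per_frame=phase,
                        joint_angles={},
                        root_path=np.zeros((n, 2)),
                    )
                    trial = TrialRecording(
                        trial_id=tid, animal_id=a, frame_rate=config.frame_rate,
                        landmarks=("hindpaw",), positions=np.zeros((n, 1, 2)),
                        takeoff_frame=b2, gap_distance=d,
                    )
                chans = (
                    generate_emg(
                        config, truth, d, intercepts[a],
                        seed=s + 1, trial_id=tid, muscles=emg_muscles,
                    )
                    if include_emg else []
                )
                trials.append(trial)
                truths.append(truth)
                emg.append(chans)
    return CohortDataset(
        trials=trials, truths=truths, emg=emg,
        beta=config.extensor_gain_beta * config.extensor_base_amp,
        animal_intercepts=intercepts, config=config,
    )


# ---------------------------------------------------------------------------
# stimulation effects


def apply_stim_effect(
    trial: TrialRecording,
    emg: list[EMGRecording],
    epoch: StimEpoch,
    mode: str,
    suppress_factor: float = 0.0,
    latency_ms: float = 10.0,
    rise_ms: float = 10.0,
    hold_after_ms: float = 20.0,
    decay_ms: float = 30.0,
    blend: float = 1.0,
    flex_targets: Mapping[str, float] | None = None,
) -> tuple[TrialRecording, list[EMGRecording]]:
    """Inject a stimulation effect into a synthetic trial.

    ``suppress`` multiplies the EMG signal by ``suppress_factor`` inside
    the epoch.  ``flex_drive`` blends the hindlimb joint-angle series
    toward flexion targets starting ``latency_ms`` after epoch onset, with
    a cosine rise, a hold through the epoch plus ``hold_after_ms``, and a
    cosine decay; landmark trajectories are rebuilt from the blended
    angles with the trial's original noise realization.
    """
    if mode not in ("suppress", "flex_drive"):
        raise ConfigurationError(f"unknown stimulation mode {mode!r}")
    rel = trial.relative_time_ms
    if rel is None:
        raise ValueError("trial must be takeoff-aligned")
    if epoch.onset_ms < rel[0] or epoch.offset_ms > rel[-1]:
        raise ValueError("stimulation epoch lies outside the trial")

    stim_meta = {
        "mode": mode, "onset_ms": epoch.onset_ms,
        "duration_ms": epoch.duration_ms, "phase_label": epoch.phase_label,
    }

    if mode == "suppress":
        new_emg = []
        for rec in emg:
            sig = rec.signal.copy()
            tm = rec.time_ms
            m = (tm >= epoch.onset_ms) & (tm < epoch.offset_ms)
            sig[m] *= suppress_factor
            new_emg.append(
                EMGRecording(
                    muscle=rec.muscle, role=rec.role, signal=sig,
                    sampling_rate=rec.sampling_rate, trial_id=rec.trial_id,
                    time_offset_ms=rec.time_offset_ms,
                )
            )
        out = trial.copy(condition="stim_suppress")
        stim_meta["suppress_factor"] = suppress_factor
        out.metadata["stim"] = stim_meta
        return out, new_emg

    truth: GroundTruth | None = trial.metadata.get("truth")
    if truth is None or "series" not in truth.extras:
        raise ValueError("flex_drive requires a generator-produced trial")
    targets = dict(flex_targets or _DEFAULT_TEMPLATES["flight"])
    series = {k: v.copy() for k, v in truth.extras["series"].items()}

    w = np.zeros_like(rel)
    t_on = epoch.onset_ms + latency_ms
    t_hold_end = epoch.offset_ms + hold_after_ms
    rising = (rel >= t_on) & (rel < t_on + rise_ms)
    w[rising] = 0.5 * (1.0 - np.cos(np.pi * (rel[rising] - t_on) / rise_ms))
    w[(rel >= t_on + rise_ms) & (rel < t_hold_end)] = 1.0
    decaying = (rel >= t_hold_end) & (rel < t_hold_end + decay_ms)
    w[decaying] = 0.5 * (1.0 + np.cos(np.pi * (rel[decaying] - t_hold_end) / decay_ms))
    w *= blend

    for p in ("hip", "knee", "ankle", "foot"):
        if p in targets or p in ("hip", "knee", "ankle"):
            tgt = targets.get(p, _DEFAULT_TEMPLATES["flight"][p])
            series[p] = (1.0 - w) * series[p] + w * tgt

    pts = chain_landmarks(series, truth.root_path)
    noise = truth.extras.get("noise", 0.0)
    positions = np.stack([pts[name] for name in trial.landmarks], axis=1) + noise

    out = trial.copy(positions=positions, condition="stim_flex")
    stim_meta.update({
        "latency_ms": latency_ms, "rise_ms": rise_ms, "blend": blend,
    })
    out.metadata["stim"] = stim_meta
    new_truth = GroundTruth(
        phase_boundaries=truth.phase_boundaries,
        phase_per_frame=truth.phase_per_frame,
        joint_angles={j: series[j].copy() for j in ("hip", "knee", "ankle")},
        root_path=truth.root_path,
        extras={**truth.extras, "series": series},
    )
    out.metadata["truth"] = new_truth
    return out, emg
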