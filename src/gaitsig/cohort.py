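"""Synthetic multi-subject, multi-speed treadmill gait cohort.

The generator produces continuous multi-channel gait time series with known
ground truth for every structure the downstream analyses estimate: individual
identity (subject-specific harmonic waveform shape), linear speed modulation
of amplitude and cadence, stride-to-stride timing jitter, and a stance-only
vertical ground reaction force usable for gait event detection.

Waveform model
--------------
Cadence is linear in belt speed, ``cadence(s) = c0 + c1 * s`` (steps/min).
Stride phase ``phi(t)`` advances at ``cadence / 120`` strides per second with
per-stride multiplicative jitter.  Each channel is a truncated Fourier series
on stride phase::

    x_c(t) = sum_h A[c, h] * (1 + gamma * (s - s_mid) / s_mid)
             * cos(2 pi h phi(t) + psi[c, h]) + eps,   eps ~ N(0, noise_sd^2)

where ``s_mid`` is the cohort mid-speed, so the amplitude gain stays positive
across the speed grid.  The vertical GRF is a body-weight-scaled two-peak
stance template, exactly zero during swing; the stance fraction decreases
linearly with speed from 0.65 to 0.55.  Left-side events are offset from the
right by half a stride (symmetric able-bodied gait).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

G = 9.81  # m/s^2, gravitational acceleration for body-weight scaling

SIDES = ("r", "l")
JOINTS = ("hip", "knee", "ankle")
PLANES = ("sagittal", "frontal", "transverse")
GRF_AXES = ("vertical", "anterior_posterior", "medial_lateral")

#: Channel counts per data type (2D/3D kinematics, 3D kinetics, combination).
DATA_TYPE_CHANNELS = {"kin2d": 6, "kin3d": 18, "kinetics3d": 42, "combined": 60}

# Internal stance-template shape: two-peak (M-shaped) vertical GRF on the
# stance-normalized axis u in [0, 1); a 0.15 body-weight pedestal makes the
# loading onset steep so the 20 N event threshold is crossed at the first
# stance sample.
_VGRF_PEDESTAL = 0.15


def kinematic_channel_labels(planes: tuple[str, ...] = PLANES) -> list[str]:
    return [
        f"{joint}_{plane}_angle_{side}"
        for side in SIDES
        for joint in JOINTS
        for plane in planes
    ]


def kinetic_channel_labels() -> list[str]:
    labels = [f"grf_{axis}_{side}" for side in SIDES for axis in GRF_AXES]
    for quantity in ("moment", "power"):
        labels += [
            f"{joint}_{plane}_{quantity}_{side}"
            for side in SIDES
            for joint in JOINTS
            for plane in PLANES
        ]
    return labels


def channel_labels(data_type: str) -> list[str]:
    """Fixed, documented channel order for each data type."""
    if data_type == "kin2d":
        return kinematic_channel_labels(planes=("sagittal",))
    if data_type == "kin3d":
        return kinematic_channel_labels()
    if data_type == "kinetics3d":
        return kinetic_channel_labels()
    if data_type == "combined":
        return kinematic_channel_labels() + kinetic_channel_labels()
    raise ValueError(f"unknown data_type {data_type!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults emulate the study layout the pipeline targets: 60 s trials at
    100 Hz over a 9-point speed grid from a very slow 0.3 m/s up to a
    walk-to-run transition around 2 m/s, 17 subjects.
    """

    n_subjects: int = 17
    speeds_per_subject: int = 9
    speed_min: float = 0.3
    speed_max: float = 2.0
    duration_s: float = 60.0
    fs: float = 100.0
    data_type: str = "kin3d"
    n_harmonics: int = 4
    noise_sd: float = 0.5  # channel units
    jitter_sd: float = 0.02  # fraction of stride period
    dispersion: float = 1.0  # scale on all between-subject variation
    amplitude_gain: float = 0.3  # gamma: fractional amplitude change per
    # fractional speed deviation from mid-speed
    ss_balance_r: float = 0.5  # target corr(ss_speed, balance_score)
    speed_perturbation_sd: float = 0.0  # per-subject jitter of the speed grid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_min <= 0:
            raise ValueError("speed_min must be positive")
        if self.speed_max < self.speed_min:
            raise ValueError("speed_max must be >= speed_min")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_subjects < 1 or self.speeds_per_subject < 1:
            raise ValueError("n_subjects and speeds_per_subject must be >= 1")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer")
        if self.data_type not in DATA_TYPE_CHANNELS:
            raise ValueError(
                f"data_type must be one of {sorted(DATA_TYPE_CHANNELS)}, "
                f"got {self.data_type!r}"
            )
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.noise_sd < 0 or self.jitter_sd < 0 or self.dispersion < 0:
            raise ValueError("noise_sd, jitter_sd, dispersion must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def n_channels(self) -> int:
        return DATA_TYPE_CHANNELS[self.data_type]

    @property
    def mid_speed(self) -> float:
        return 0.5 * (self.speed_min + self.speed_max)


@dataclass
class SubjectParams:
    """Individual-specific generator parameters (one synthetic subject)."""

    subject_id: str
    body_mass: float  # kg
    cadence_intercept: float  # c0, steps/min
    cadence_slope: float  # c1, steps/min per m/s
    amplitudes: np.ndarray  # (C, n_harmonics), channel units
    phases: np.ndarray  # (C, n_harmonics), radians in [-pi, pi)
    amplitude_gain: float  # gamma, dimensionless
    ss_speed: float  # m/s
    balance_score: float  # feet, narrowing-beam distance
    step_width: float  # m

    def cadence(self, speed: float) -> float:
        return self.cadence_intercept + self.cadence_slope * speed


@dataclass
class TrialTimeSeries:
    """One trial's continuous multi-channel gait data plus metadata."""

    subject_id: str
    speed: float
    data_type: str
    samples: np.ndarray  # (T, C), channel units
    channel_labels: list[str]
    fs: float
    body_mass: float
    vgrf_right: np.ndarray  # (T,), N
    vgrf_left: np.ndarray  # (T,), N
    trial_id: str = ""


@dataclass
class GroundTruth:
    """Generator-side truth for events and spatiotemporal variables."""

    true_heel_strikes_right: np.ndarray  # sample indices
    true_heel_strikes_left: np.ndarray
    true_toe_offs_right: np.ndarray
    true_toe_offs_left: np.ndarray
    true_cadence: float  # steps/min
    true_step_length: float  # m
    true_stance_duration: float  # s
    true_swing_duration: float  # s
    true_step_width: float  # m


def _wrap_phase(psi: np.ndarray) -> np.ndarray:
    return np.mod(psi + np.pi, 2.0 * np.pi) - np.pi


def _population_params(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cohort-level mean harmonic structure shared by all subjects."""
    rng = np.random.default_rng([config.seed, 982_451_653])
    n_c, n_h = config.n_channels, config.n_harmonics
    base = rng.uniform(5.0, 15.0, size=n_c)
    decay = 0.45 ** np.arange(n_h)
    amplitudes = base[:, None] * decay[None, :]
    phases = rng.uniform(-np.pi, np.pi, size=(n_c, n_h))
    return amplitudes, phases


def draw_subject_params(config: CohortConfig, subject_index: int) -> SubjectParams:
    """Draw one subject's parameters, deterministic in (seed, subject_index).

    Between-subject dispersion of amplitudes/phases/cadence scales with
    ``config.dispersion`` (0 collapses the cohort onto identical waveforms).
    Self-selected speed and balance score are drawn jointly with Pearson
    correlation target ``config.ss_balance_r``.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} out of range for "
            f"{config.n_subjects} subjects"
        )
    amp_pop, psi_pop = _population_params(config)
    rng = np.random.default_rng([config.seed, subject_index])
    d = config.dispersion
    n_c, n_h = amp_pop.shape

    amplitudes = amp_pop * np.exp(0.20 * d * rng.standard_normal((n_c, n_h)))
    phases = _wrap_phase(psi_pop + 0.30 * d * rng.standard_normal((n_c, n_h)))
    c0 = 60.0 + 4.0 * d * rng.standard_normal()
    c1 = max(40.0 + 4.0 * d * rng.standard_normal(), 5.0)
    gamma = max(config.amplitude_gain + 0.05 * d * rng.standard_normal(), 0.0)
    body_mass = float(np.clip(77.0 + 15.0 * d * rng.standard_normal(), 45.0, 130.0))
    step_width = float(np.clip(0.10 + 0.02 * d * rng.standard_normal(), 0.03, 0.25))

    # Correlated (ss_speed, balance) via a Gaussian copula-free bivariate draw.
    r = float(np.clip(config.ss_balance_r, -1.0, 1.0))
    z1, z2 = rng.standard_normal(2)
    z_bal = r * z1 + math.sqrt(max(1.0 - r * r, 0.0)) * z2
    ss_speed = float(np.clip(1.25 + 0.15 * z1, config.speed_min, config.speed_max))
    balance = float(np.clip(15.0 + 4.0 * z_bal, 1.0, 30.0))

    return SubjectParams(
        subject_id=f"S{subject_index:02d}",
        body_mass=body_mass,
        cadence_intercept=c0,
        cadence_slope=c1,
        amplitudes=amplitudes,
        phases=phases,
        amplitude_gain=gamma,
        ss_speed=ss_speed,
        balance_score=balance,
        step_width=step_width,
    )


def _stance_fraction(speed: float, config: CohortConfig) -> float:
    """Stance fraction of the stride, 0.65 at speed_min -> 0.55 at speed_max."""
    if config.speed_max == config.speed_min:
        return 0.65
    frac = (speed - config.speed_min) / (config.speed_max - config.speed_min)
    return 0.65 - 0.10 * float(np.clip(frac, 0.0, 1.0))


def _vgrf_template(u: np.ndarray) -> np.ndarray:
    """Two-peak stance shape on u in [0, 1), in body-weight units."""
    return _VGRF_PEDESTAL + np.sin(np.pi * u) + 0.3 * np.sin(3.0 * np.pi * u)


def _stride_phase(
    speed: float, params: SubjectParams, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample stride phase and the realized per-stride durations (s)."""
    cadence = params.cadence(speed)
    if cadence <= 0:
        raise ValueError(
            f"non-positive cadence {cadence:.2f} steps/min for subject "
            f"{params.subject_id} at speed {speed:.3f} m/s"
        )
    stride_s = 120.0 / cadence  # one stride = two steps
    n_strides = int(math.ceil(config.duration_s / stride_s * 1.5)) + 4
    factors = 1.0 + config.jitter_sd * rng.standard_normal(n_strides)
    durations = stride_s * np.clip(factors, 0.3, 3.0)
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    t = np.arange(config.n_samples) / config.fs
    phi = np.interp(t, boundaries, np.arange(n_strides + 1, dtype=float))
    return phi, durations


def _crossing_indices(phi: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Sample indices where phi crosses an integer (plus offset), interior only."""
    k = np.floor(phi - offset).astype(int)
    return np.nonzero(np.diff(k) > 0)[0] + 1


def generate_trial(
    params: SubjectParams,
    speed: float,
    config: CohortConfig,
    seed: int | list[int] | None = None,
) -> tuple[TrialTimeSeries, GroundTruth]:
    """Generate one trial at a given belt speed, with its ground truth.

    ``seed`` controls jitter/noise; when omitted it is derived from the config
    seed and the requested speed so standalone calls stay deterministic.
    """
    if not (config.speed_min - 1e-9 <= speed <= config.speed_max + 1e-9):
        raise ValueError(
            f"speed {speed} outside [{config.speed_min}, {config.speed_max}]"
        )
    if seed is None:
        seed = [config.seed, int(round(speed * 1000)), 7919]
    rng = np.random.default_rng(seed)

    phi, durations = _stride_phase(speed, params, config, rng)
    labels = channel_labels(config.data_type)
    n_c = len(labels)
    gain = 1.0 + params.amplitude_gain * (speed - config.mid_speed) / config.mid_speed

    sf = _stance_fraction(speed, config)
    frac_r = phi - np.floor(phi)
    frac_l = np.mod(phi + 0.5, 1.0)
    stance_r = frac_r < sf
    stance_l = frac_l < sf
    body_weight = params.body_mass * G
    vgrf_right = np.where(stance_r, body_weight * _vgrf_template(frac_r / sf), 0.0)
    vgrf_left = np.where(stance_l, body_weight * _vgrf_template(frac_l / sf), 0.0)

    h = np.arange(1, config.n_harmonics + 1, dtype=float)
    # (T, n_h) harmonic carriers on stride phase
    carriers = 2.0 * np.pi * phi[:, None] * h[None, :]
    samples = np.empty((config.n_samples, n_c))
    for c, label in enumerate(labels):
        amp = params.amplitudes[c] * gain
        if label.startswith("grf_"):
            # Kinetic GRF channels share the harmonic model but are gated to
            # stance of their own side and scaled toward body weight.
            amp = amp * (body_weight * 0.04)
        wave = np.cos(carriers + params.phases[c][None, :]) @ amp
        if label.startswith("grf_"):
            gate = stance_r if label.endswith("_r") else stance_l
            wave = np.where(gate, np.abs(wave), 0.0)
        samples[:, c] = wave
    if config.noise_sd > 0:
        noise = rng.standard_normal(samples.shape) * config.noise_sd
        grf_cols = [c for c, lab in enumerate(labels) if lab.startswith("grf_")]
        samples = samples + noise
        if grf_cols:
            # keep GRF channels non-negative and swing-gated under noise
            for c in grf_cols:
                gate = stance_r if labels[c].endswith("_r") else stance_l
                samples[:, c] = np.where(gate, np.maximum(samples[:, c], 0.0), 0.0)

    hs_r = _crossing_indices(phi)
    hs_l = _crossing_indices(phi, offset=0.5)
    to_r = _crossing_indices(phi - sf)
    to_l = _crossing_indices(phi + 0.5 - sf)

    completed = np.nonzero(np.cumsum(durations) <= config.duration_s + 1e-12)[0]
    m = max(len(completed), 1)
    mean_stride = float(np.mean(durations[:m]))
    mean_step = mean_stride / 2.0
    truth = GroundTruth(
        true_heel_strikes_right=hs_r,
        true_heel_strikes_left=hs_l,
        true_toe_offs_right=to_r,
        true_toe_offs_left=to_l,
        true_cadence=60.0 / mean_step,
        true_step_length=speed * mean_step,
        true_stance_duration=sf * mean_stride,
        true_swing_duration=(1.0 - sf) * mean_stride,
        true_step_width=params.step_width,
    )
    trial = TrialTimeSeries(
        subject_id=params.subject_id,
        speed=float(speed),
        data_type=config.data_type,
        samples=samples,
        channel_labels=labels,
        fs=config.fs,
        body_mass=params.body_mass,
        vgrf_right=vgrf_right,
        vgrf_left=vgrf_left,
    )
    return trial, truth


def subject_speed_grid(config: CohortConfig, params: SubjectParams,
                       subject_index: int) -> np.ndarray:
    """Evenly spaced speed grid, optionally perturbed per subject."""
    grid = np.linspace(config.speed_min, config.speed_max, config.speeds_per_subject)
    if config.speed_perturbation_sd > 0:
        rng = np.random.default_rng([config.seed, subject_index, 104_729])
        grid = grid + config.speed_perturbation_sd * rng.standard_normal(grid.shape)
        grid = np.clip(grid, config.speed_min, config.speed_max)
    return grid


def generate_cohort(
    config: CohortConfig,
    exclude: list[tuple[str, int]] | None = None,
) -> tuple[list[tuple[TrialTimeSeries, GroundTruth]], pd.DataFrame]:
    """Generate the full cohort: one trial per (subject x speed condition).

    ``exclude`` lists (subject_id, speed_index) pairs to drop, mirroring
    trials lost to technical errors in real data collections.  Returns the
    trial list and a cohort metadata table (subject_id, trial_id, speed,
    speed_index, is_ss flag, ss_speed, balance_score, body_mass).
    """
    exclude = set(exclude or [])
    trials: list[tuple[TrialTimeSeries, GroundTruth]] = []
    rows = []
    for idx in range(config.n_subjects):
        params = draw_subject_params(config, idx)
        grid = subject_speed_grid(config, params, idx)
        ss_idx = int(np.argmin(np.abs(grid - params.ss_speed)))
        for j, speed in enumerate(grid):
            if (params.subject_id, j) in exclude:
                continue
            trial, truth = generate_trial(
                params, float(speed), config, seed=[config.seed, idx, j, 1]
            )
            trial.trial_id = f"{params.subject_id}_v{j}"
            trials.append((trial, truth))
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "subject_id": params.subject_id,
                    "speed": float(speed),
                    "speed_index": j,
                    "is_ss": j == ss_idx,
                    "ss_speed": params.ss_speed,
                    "balance_score": params.balance_score,
                    "body_mass": params.body_mass,
                }
            )
    metadata = pd.DataFrame(rows)
    return trials, metadata


def write_trial_csv(trial: TrialTimeSeries, path) -> None:
    """One trial per file: time + channels + vGRF columns, plain CSV."""
    t = np.arange(trial.samples.shape[0]) / trial.fs
    df = pd.DataFrame(trial.samples, columns=trial.channel_labels)
    df.insert(0, "time", t)
    df["vgrf_right"] = trial.vgrf_right
    df["vgrf_left"] = trial.vgrf_left
    df.to_csv(path, index=False)


def read_trial_csv(path, subject_id: str, speed: float, data_type: str,
                   fs: float, body_mass: float) -> TrialTimeSeries:
    df = pd.read_csv(path)
    labels = [c for c in df.columns if c not in ("time", "vgrf_right", "vgrf_left")]
    return TrialTimeSeries(
        subject_id=subject_id,
        speed=speed,
        data_type=data_type,
        samples=df[labels].to_numpy(),
        channel_labels=labels,
        fs=fs,
        body_mass=body_mass,
        vgrf_right=df["vgrf_right"].to_numpy(),
        vgrf_left=df["vgrf_left"].to_numpy(),
    )
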