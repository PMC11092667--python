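"""Signal conditioning, gait event detection, and discrete gait variables.

All operations are deterministic.  Filtering is zero-phase (forward-backward
Butterworth, order 4) so event timing is preserved; gait events are detected
from the vertical ground reaction force with a 20 N threshold; strides are
half-open intervals ``[HS_i, HS_{i+1})`` with 0-based sample indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import signal as sps

from gaitsig.cohort import DATA_TYPE_CHANNELS, G, TrialTimeSeries, channel_labels

DEFAULT_GRF_THRESHOLD_N = 20.0

#: Discrete-variable feature sets and their column counts.
FEATURE_SET_SIZES = {
    "biomech26": 26,
    "kinematic18": 18,
    "kinetic8": 8,
    "spatiotemporal10": 10,
}


@dataclass
class GaitEvents:
    """Heel-strike / toe-off sample indices per side (0-based)."""

    heel_strikes_right: np.ndarray
    heel_strikes_left: np.ndarray
    toe_offs_right: np.ndarray
    toe_offs_left: np.ndarray

    def n_strides(self, side: str = "r") -> int:
        hs = self.heel_strikes_right if side == "r" else self.heel_strikes_left
        return max(len(hs) - 1, 0)


@dataclass
class SpatiotemporalRecord:
    """Trial-averaged spatiotemporal variables, one value set per side."""

    cadence_r: float  # steps/min
    cadence_l: float
    step_length_r: float  # m
    step_length_l: float
    stance_duration_r: float  # s
    stance_duration_l: float
    swing_duration_r: float
    swing_duration_l: float
    step_width_r: float  # m
    step_width_l: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def lowpass_filter(series: np.ndarray, cutoff: float, fs: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter applied along axis 0.

    Output length equals input length; a constant signal passes through
    unchanged.
    """
    if cutoff >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2.0} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=0)


def downsample(series: np.ndarray, from_fs: float, to_fs: float) -> np.ndarray:
    """Anti-alias filter then decimate by the integer factor from_fs/to_fs."""
    ratio = from_fs / to_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"from_fs/to_fs must be an integer, got {ratio}")
    q = int(round(ratio))
    x = np.asarray(series, dtype=float)
    if q == 1:
        return x.copy()
    return sps.decimate(x, q, ftype="fir", zero_phase=True, axis=0)


def _threshold_crossings(above: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior rise/fall indices of a boolean stance indicator."""
    d = np.diff(above.astype(np.int8))
    rises = np.nonzero(d == 1)[0] + 1
    falls = np.nonzero(d == -1)[0] + 1
    return rises, falls


def _merge_refractory(indices: np.ndarray, window: int) -> np.ndarray:
    """Drop crossings closer than `window` samples to the previous kept one."""
    if len(indices) == 0 or window <= 0:
        return indices
    kept = [int(indices[0])]
    for i in indices[1:]:
        if int(i) - kept[-1] >= window:
            kept.append(int(i))
    return np.asarray(kept, dtype=int)


def _detect_side(vgrf: np.ndarray, fs: float, threshold: float,
                 refractory_frac: float) -> tuple[np.ndarray, np.ndarray]:
    above = np.asarray(vgrf) >= threshold
    rises, falls = _threshold_crossings(above)
    if len(rises) >= 2:
        window = int(round(refractory_frac * float(np.median(np.diff(rises)))))
        rises = _merge_refractory(rises, window)
        falls = _merge_refractory(falls, window)
    return rises, falls


def detect_gait_events(
    vgrf_right: np.ndarray,
    vgrf_left: np.ndarray,
    fs: float,
    threshold: float = DEFAULT_GRF_THRESHOLD_N,
    refractory_frac: float = 0.2,
) -> GaitEvents:
    """Detect bilateral heel strikes and toe-offs from vertical GRF.

    Heel strike = upward crossing of the force threshold after a below-
    threshold (swing) interval; toe-off = downward crossing.  Crossings
    within ``refractory_frac`` of the median stride are merged so noise
    around the threshold cannot split a stance.  Requires at least 3
    detected strides on the right side.
    """
    if np.any(np.asarray(vgrf_right) < 0) or np.any(np.asarray(vgrf_left) < 0):
        raise ValueError("vertical GRF must be non-negative")
    hs_r, to_r = _detect_side(vgrf_right, fs, threshold, refractory_frac)
    hs_l, to_l = _detect_side(vgrf_left, fs, threshold, refractory_frac)
    if len(hs_r) - 1 < 3:
        raise ValueError(
            f"insufficient strides: detected {max(len(hs_r) - 1, 0)} right "
            "strides, need >= 3"
        )
    return GaitEvents(
        heel_strikes_right=hs_r,
        heel_strikes_left=hs_l,
        toe_offs_right=to_r,
        toe_offs_left=to_l,
    )


def assemble_feature_set(trial: TrialTimeSeries, data_type: str) -> tuple[np.ndarray, list[str]]:
    """Select and order the channel set the dynamics model consumes.

    GRF channels are expressed in body-weight units (force / (mass * g)).
    Raises if the trial lacks any requested channel.
    """
    if data_type not in DATA_TYPE_CHANNELS:
        raise ValueError(f"unknown data_type {data_type!r}")
    wanted = channel_labels(data_type)
    index = {lab: i for i, lab in enumerate(trial.channel_labels)}
    missing = [lab for lab in wanted if lab not in index]
    if missing:
        raise ValueError(f"trial is missing channel(s): {', '.join(missing)}")
    cols = [index[lab] for lab in wanted]
    out = trial.samples[:, cols].astype(float).copy()
    bw = trial.body_mass * G
    for j, lab in enumerate(wanted):
        if lab.startswith("grf_"):
            out[:, j] /= bw
    return out, wanted


def _stride_intervals(hs: np.ndarray) -> list[tuple[int, int]]:
    return [(int(hs[i]), int(hs[i + 1])) for i in range(len(hs) - 1)]


def _stance_times(hs: np.ndarray, to: np.ndarray, fs: float) -> np.ndarray:
    """Per-stride stance durations: heel strike to the next toe-off."""
    out = []
    for a, b in _stride_intervals(hs):
        t = to[(to > a) & (to <= b)]
        if len(t):
            out.append((t[0] - a) / fs)
    return np.asarray(out)


def compute_spatiotemporal(
    trial: TrialTimeSeries,
    events: GaitEvents,
    step_width: float | None = None,
) -> SpatiotemporalRecord:
    """Trial-averaged cadence, step length, stance/swing duration, step width.

    Cadence is 60 / mean step time (step time = half the mean stride time of
    that side); step length uses the treadmill belt-frame definition
    speed x step time.  Step width comes from lateral foot position channels
    when present; the synthetic pipeline passes the ground-truth value.
    """
    fs = trial.fs
    rec = {}
    for side, hs, to in (
        ("r", events.heel_strikes_right, events.toe_offs_right),
        ("l", events.heel_strikes_left, events.toe_offs_left),
    ):
        if len(hs) - 1 < 3:
            raise ValueError(f"insufficient strides on side {side!r}: need >= 3")
        stride = float(np.mean(np.diff(hs))) / fs
        step = stride / 2.0
        stance = _stance_times(hs, to, fs)
        if len(stance) == 0:
            raise ValueError(f"no stance intervals on side {side!r}")
        stance_d = float(np.mean(stance))
        rec[f"cadence_{side}"] = 60.0 / step
        rec[f"step_length_{side}"] = trial.speed * step
        rec[f"stance_duration_{side}"] = stance_d
        rec[f"swing_duration_{side}"] = stride - stance_d
        rec[f"step_width_{side}"] = float(step_width) if step_width is not None else np.nan
    return SpatiotemporalRecord(**rec)


def _per_stride_stats(x: np.ndarray, hs: np.ndarray) -> tuple[float, float, float]:
    """Trial-averaged (peak, minimum, excursion) across strides of channel x."""
    peaks, mins = [], []
    for a, b in _stride_intervals(hs):
        seg = x[a:b]
        if len(seg):
            peaks.append(np.max(seg))
            mins.append(np.min(seg))
    p, m = float(np.mean(peaks)), float(np.mean(mins))
    return p, m, p - m


def compute_discrete_variables(
    trial: TrialTimeSeries,
    events: GaitEvents,
    set_name: str,
    step_width: float | None = None,
) -> dict[str, float]:
    """One trial's row of a discrete-variable table.

    kinematic18: per-side peak / minimum / excursion of hip, knee, ankle
    sagittal angles.  kinetic8: per-side peak vertical GRF, peak propulsive
    (anterior-posterior) GRF, peak ankle sagittal moment, peak ankle sagittal
    power.  biomech26 = kinematic18 + kinetic8.  spatiotemporal10 = bilateral
    spatiotemporal record.  All values are stride-averaged.
    """
    if set_name not in FEATURE_SET_SIZES:
        raise ValueError(f"unknown feature set {set_name!r}")
    index = {lab: i for i, lab in enumerate(trial.channel_labels)}

    def chan(lab: str) -> np.ndarray:
        if lab not in index:
            raise ValueError(f"trial is missing channel {lab!r}")
        return trial.samples[:, index[lab]]

    row: dict[str, float] = {}
    if set_name in ("kinematic18", "biomech26"):
        for side, hs in (("r", events.heel_strikes_right),
                         ("l", events.heel_strikes_left)):
            if len(hs) - 1 < 3:
                raise ValueError(f"insufficient strides on side {side!r}")
            for joint in ("hip", "knee", "ankle"):
                x = chan(f"{joint}_sagittal_angle_{side}")
                p, m, e = _per_stride_stats(x, hs)
                row[f"{joint}_peak_{side}"] = p
                row[f"{joint}_min_{side}"] = m
                row[f"{joint}_excursion_{side}"] = e
    if set_name in ("kinetic8", "biomech26"):
        bw = trial.body_mass * G
        for side, hs in (("r", events.heel_strikes_right),
                         ("l", events.heel_strikes_left)):
            if len(hs) - 1 < 3:
                raise ValueError(f"insufficient strides on side {side!r}")
            row[f"grf_vertical_peak_{side}"] = _per_stride_stats(
                chan(f"grf_vertical_{side}") / bw, hs)[0]
            row[f"grf_propulsive_peak_{side}"] = _per_stride_stats(
                chan(f"grf_anterior_posterior_{side}") / bw, hs)[0]
            row[f"ankle_moment_peak_{side}"] = _per_stride_stats(
                chan(f"ankle_sagittal_moment_{side}"), hs)[0]
            row[f"ankle_power_peak_{side}"] = _per_stride_stats(
                chan(f"ankle_sagittal_power_{side}"), hs)[0]
    if set_name == "spatiotemporal10":
        row = compute_spatiotemporal(trial, events, step_width=step_width).as_dict()
    if len(row) != FEATURE_SET_SIZES[set_name]:
        raise AssertionError(
            f"{set_name} row has {len(row)} columns, "
            f"expected {FEATURE_SET_SIZES[set_name]}"
        )
    return row
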