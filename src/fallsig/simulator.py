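"""Synthetic ADL + fall recordings with ground truth.

Generates uniform-frame inertial recordings of everyday activity (standing,
walking, sitting, lying) with embedded fall events, each following the
canonical phase sequence: pre-fall activity, falling (free-fall dip of the
total acceleration magnitude), impact (short high-g spike), resting in the
end orientation (gravity redirected to the medio-lateral or
anterior-posterior axis), and an optional recovery back to upright followed
by walking.  Kinematics are piecewise phase templates with raised-cosine
transitions — fully controllable and sufficient to exercise every
identification, verification and extraction rule, not a biomechanical body
model.

Gravity uses g = 9.81 m/s^2 throughout (display values of "10 m/s^2" in
plots are rounded).  The gyroscope is synthesized as the finite-difference
angular rate of the orientation trajectory; the magnetometer as a fixed
Earth-field vector rotated by the same trajectory.  A seeded generator fixes
all randomness, including the configurable fall-report corruption used to
exercise every verification-certainty category.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .events import time_of_day_category
from .signal_io import (
    GRAVITY,
    FallReport,
    SensorMeta,
    SensorRecording,
    write_recording,
)
from .timebase import CalendarDateTime

__all__ = [
    "FallSpec",
    "ReportErrorModel",
    "SimulationConfig",
    "FallTruth",
    "GroundTruth",
    "simulate_recording",
    "make_fall_report",
    "simulate_study",
    "description_matches",
    "ACTIVITIES",
]

ACTIVITIES = ("standing", "walking", "sitting", "lying")

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

#: gravity direction (body frame) per activity; sitting = mild trunk tilt
_ACTIVITY_DIR = {
    "standing": _X,
    "walking": _X,
    "sitting": np.array([np.cos(np.radians(15.0)), 0.0, np.sin(np.radians(15.0))]),
    "lying": _Z,
}

#: end orientation per fall direction: backward -> supine (AP reads +g)
_FALL_DIR = {"backward": _Z, "forward": -_Z, "lateral": _Y}

_EARTH_FIELD_UT = np.array([44.0, 0.0, 20.0])  # body-frame reading when upright

_ADL_TRANSITION_S = 1.5   # sit-to-stand etc.
_RECOVERY_RISE_S = 3.0    # lying -> upright during recovery
_POST_RECOVERY_WALK_S = 30.0
_SOFT_FALL_S = 3.0        # slow-collapse transition (no impact)


@dataclass
class FallSpec:
    """One scripted fall.  ``time_s`` is the impact time from recording start.

    ``peak_g`` is the impact-spike peak in g; ``freefall_depth`` the total
    magnitude (m/s^2) the free-fall dip descends to; ``recovery_s`` the time
    after impact at which the recovery movement starts (``None`` = long lie).
    ``soft=True`` scripts a slow collapse with neither dip nor impact spike —
    only the posture change remains detectable.
    """

    time_s: float
    direction: str = "backward"
    peak_g: float = 3.0
    freefall_depth: float = 2.0
    freefall_duration_s: float = 0.35
    rest_duration_s: float = 60.0
    recovery_s: float | None = 180.0
    soft: bool = False

    def __post_init__(self) -> None:
        if self.direction not in _FALL_DIR:
            raise ValueError(f"unknown fall direction {self.direction!r}")
        if self.recovery_s is not None and self.recovery_s <= self.rest_duration_s:
            self.rest_duration_s = max(1.0, self.recovery_s - 1.0)


@dataclass
class ReportErrorModel:
    """Seeded corruption applied when deriving a fall report from the truth."""

    lag_sd_min: float = 10.0
    date_error_p: float = 0.0
    misdescription_p: float = 0.0
    tod_only_p: float = 0.0
    date_only_p: float = 0.0

    def __post_init__(self) -> None:
        for name in ("date_error_p", "misdescription_p", "tod_only_p", "date_only_p"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")


@dataclass
class SimulationConfig:
    sample_rate: float = 100.0
    duration_s: float = 600.0
    seed: int = 0
    noise_sd: float = 0.2  # accelerometer noise, m/s^2 per axis
    start: CalendarDateTime = field(default_factory=lambda: CalendarDateTime(2014, 3, 9, 8, 0, 0))
    schedule: list[tuple[str, float]] | None = None
    falls: list[FallSpec] = field(default_factory=list)
    channels: tuple[str, ...] = ("gyro", "mag")
    report_errors: ReportErrorModel = field(default_factory=ReportErrorModel)
    placement: str = "L5"

    def __post_init__(self) -> None:
        for f in self.falls:
            lead = (0.5 if f.soft else f.freefall_duration_s) + 1.0
            if not (lead <= f.time_s <= self.duration_s - 2.0):
                raise ValueError(f"fall at {f.time_s} s outside the recording")
        times = [f.time_s for f in self.falls]
        if times != sorted(times):
            raise ValueError("falls must be listed in time order")


@dataclass
class FallTruth:
    """Ground truth for one simulated fall."""

    impact_time_s: float
    impact_index: int
    impact_datetime: CalendarDateTime
    direction: str
    pre_fall_activity: str
    phases: dict
    recovery_time_s: float | None  # absolute seconds from recording start
    end_orientation: tuple[float, float, float]
    mode: str  # "impact" | "posture-change"


@dataclass
class GroundTruth:
    falls: list[FallTruth]
    schedule: list[tuple[str, float]]


def _default_schedule(duration_s: float) -> list[tuple[str, float]]:
    cycle = [("walking", 120.0), ("standing", 60.0), ("sitting", 120.0), ("standing", 60.0)]
    out: list[tuple[str, float]] = []
    total = 0.0
    i = 0
    while total < duration_s:
        act, dur = cycle[i % len(cycle)]
        dur = min(dur, duration_s - total)
        out.append((act, dur))
        total += dur
        i += 1
    return out


def _slerp(a: np.ndarray, b: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors with fractions ``s``."""
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-8:
        return np.outer(np.ones_like(s), b)
    if omega > np.pi - 1e-6:  # antiparallel: route through the medio-lateral axis
        mid = np.cross(a, _Y)
        mid = mid / np.linalg.norm(mid) if np.linalg.norm(mid) > 1e-9 else _Z
        half = len(s) // 2 or 1
        top = _slerp(a, mid, np.clip(s[:half] * 2.0, 0.0, 1.0))
        bottom = _slerp(mid, b, np.clip(s[half:] * 2.0 - 1.0, 0.0, 1.0))
        return np.vstack([top, bottom])
    so = np.sin(omega)
    return (
        np.outer(np.sin((1.0 - s) * omega) / so, a)
        + np.outer(np.sin(s * omega) / so, b)
    )


def _raised_cosine(n: int) -> np.ndarray:
    u = (np.arange(1, n + 1)) / n
    return (1.0 - np.cos(np.pi * u)) / 2.0


def simulate_recording(config: SimulationConfig) -> tuple[SensorRecording, GroundTruth]:
    """Generate one uniform-frame recording and its ground truth."""
    fs = float(config.sample_rate)
    n = int(round(config.duration_s * fs))
    if n < 2:
        raise ValueError("duration too short")
    rng = np.random.default_rng(config.seed)
    schedule = config.schedule or _default_schedule(config.duration_s)
    if sum(d for _, d in schedule) < config.duration_s - 1e-9:
        raise ValueError("schedule does not cover the recording duration")
    for act, _ in schedule:
        if act not in _ACTIVITY_DIR:
            raise ValueError(f"unknown activity {act!r}")

    # -- activity labels from the schedule ----------------------------------
    labels = np.zeros(n, dtype=np.int8)
    act_codes = {a: i for i, a in enumerate(ACTIVITIES)}
    pos = 0
    for act, dur in schedule:
        m = min(n - pos, int(round(dur * fs)))
        labels[pos:pos + m] = act_codes[act]
        pos += m
        if pos >= n:
            break
    labels[pos:] = labels[pos - 1] if pos > 0 else act_codes["standing"]

    # -- orientation keyframes ----------------------------------------------
    # (index, target gravity direction, transition length in samples)
    adl_n = max(1, int(round(_ADL_TRANSITION_S * fs)))
    keyframes: list[tuple[int, np.ndarray, int]] = []
    pos = 0
    for act, dur in schedule:
        keyframes.append((pos, _ACTIVITY_DIR[act], adl_n if pos else 1))
        pos += int(round(dur * fs))
        if pos >= n:
            break

    env = np.ones(n)
    spike = np.zeros((n, 3))
    truths: list[FallTruth] = []
    walking_overrides: list[tuple[int, int]] = []
    lying_overrides: list[tuple[int, int]] = []

    falls = list(config.falls)
    for k, fall in enumerate(falls):
        i_imp = int(round(fall.time_s * fs))
        fall_dir = _FALL_DIR[fall.direction]
        scope_end = (
            int(round((falls[k + 1].time_s - falls[k + 1].freefall_duration_s - 1.0) * fs))
            if k + 1 < len(falls)
            else n
        )
        pre_activity = ACTIVITIES[labels[max(0, i_imp - int(2 * fs))]]
        if fall.soft:
            trans_n = max(2, int(round(_SOFT_FALL_S * fs)))
            i_start = i_imp
            i_settled = i_imp + trans_n
            mode = "posture-change"
            phases = {
                "falling": (i_start / fs, i_settled / fs),
                "impact": None,
            }
        else:
            ff_n = max(1, int(round(fall.freefall_duration_s * fs)))
            tip_n = max(1, int(round(0.5 * fs)))
            spike_n = max(3, int(round(0.12 * fs)))
            i_start = i_imp - ff_n
            i_settled = i_imp + tip_n
            mode = "impact"
            # free-fall dip: descend over the first 60 %, flat at the trough
            d_n = max(1, int(round(0.6 * ff_n)))
            depth_frac = fall.freefall_depth / GRAVITY
            env[i_start:i_start + d_n] = 1.0 + (depth_frac - 1.0) * _raised_cosine(d_n)
            env[i_start + d_n:i_imp + spike_n] = depth_frac
            r_n = max(1, int(round(0.3 * fs)))
            env[i_imp + spike_n:i_imp + spike_n + r_n] = (
                depth_frac + (1.0 - depth_frac) * _raised_cosine(r_n)
            )
            # impact spike: half-sine along a mostly-vertical shock axis
            u = 0.8 * _X + 0.6 * fall_dir
            u /= np.linalg.norm(u)
            amp = fall.peak_g * GRAVITY - fall.freefall_depth
            m = np.arange(spike_n + 1)
            prof = amp * np.sin(np.pi * m / spike_n)
            hi = min(n, i_imp + spike_n + 1)
            spike[i_imp:hi] += prof[: hi - i_imp, None] * u[None, :]
            phases = {
                "falling": (i_start / fs, i_imp / fs),
                "impact": (i_imp / fs, (i_imp + spike_n) / fs),
            }

        # orientation: fall controls [i_start, i_resume)
        i_rest_end = i_imp + int(round(fall.rest_duration_s * fs))
        if fall.recovery_s is not None:
            i_rec = i_imp + int(round(fall.recovery_s * fs))
            rise_n = max(2, int(round(_RECOVERY_RISE_S * fs)))
            i_resume = min(i_rec + rise_n, scope_end)
        else:
            i_rec = None
            i_resume = scope_end
        keyframes = [kf for kf in keyframes if not (i_start <= kf[0] < i_resume)]
        keyframes.append((i_start, fall_dir, i_settled - i_start))
        lying_overrides.append((i_start, i_resume))
        if i_rec is not None:
            keyframes.append((i_rec, _X, rise_n))
            walk_end = min(i_resume + int(round(_POST_RECOVERY_WALK_S * fs)), scope_end)
            walking_overrides.append((i_resume, walk_end))
        phases["resting"] = (
            (i_imp if fall.soft else i_imp + int(round(0.5 * fs))) / fs,
            min(i_rest_end, i_resume) / fs,
        )
        if i_rec is not None:
            phases["recovery"] = (i_rec / fs, i_resume / fs)
        truths.append(
            FallTruth(
                impact_time_s=i_imp / fs,
                impact_index=i_imp,
                impact_datetime=config.start.add_seconds(i_imp / fs),
                direction=fall.direction,
                pre_fall_activity=pre_activity,
                phases=phases,
                recovery_time_s=None if i_rec is None else i_rec / fs,
                end_orientation=tuple(float(v) for v in fall_dir),
                mode=mode,
            )
        )

    for s, e in lying_overrides:
        labels[s:e] = act_codes["lying"]
    for s, e in walking_overrides:
        labels[s:e] = act_codes["walking"]

    # -- build the gravity-direction trajectory ------------------------------
    keyframes.sort(key=lambda kf: kf[0])
    dir_arr = np.empty((n, 3))
    current = keyframes[0][1]
    cursor = 0
    for j, (i, target, tn) in enumerate(keyframes):
        nxt = keyframes[j + 1][0] if j + 1 < len(keyframes) else n
        i = max(i, cursor)
        dir_arr[cursor:i] = current
        stop = min(i + tn, nxt, n)
        if stop > i:
            s = _raised_cosine(stop - i)
            dir_arr[i:stop] = _slerp(current, target, s)
        current = target
        cursor = stop
    dir_arr[cursor:] = current

    # -- dynamics + noise -----------------------------------------------------
    t = np.arange(n) / fs
    dyn = np.zeros((n, 3))
    walking = labels == act_codes["walking"]
    if walking.any():
        f_step = rng.uniform(1.5, 2.5)
        phase = rng.uniform(0.0, 2 * np.pi, size=3)
        dyn[walking, 0] = 2.0 * np.sin(2 * np.pi * f_step * t[walking] + phase[0])
        dyn[walking, 1] = 0.5 * np.sin(2 * np.pi * f_step / 2 * t[walking] + phase[1])
        dyn[walking, 2] = 0.5 * np.sin(2 * np.pi * f_step * t[walking] + phase[2])

    acc = GRAVITY * env[:, None] * dir_arr + spike + dyn
    if config.noise_sd > 0:
        acc = acc + rng.normal(0.0, config.noise_sd, size=(n, 3))

    channels = [acc]
    sensor_types = ["accelerometer"]
    if "gyro" in config.channels or "mag" in config.channels:
        axis = np.cross(np.broadcast_to(_X, (n, 3)), dir_arr)
        norm = np.linalg.norm(axis, axis=1, keepdims=True)
        angle = np.arccos(np.clip(dir_arr[:, 0], -1.0, 1.0))
        safe = norm[:, 0] > 1e-12
        rotvec = np.zeros((n, 3))
        rotvec[safe] = axis[safe] / norm[safe] * angle[safe, None]
        rot = Rotation.from_rotvec(rotvec)
        if "gyro" in config.channels:
            rel = rot[:-1].inv() * rot[1:]
            omega = np.degrees(rel.as_rotvec()) * fs
            gyro = np.vstack([omega, omega[-1:]])
            gyro = gyro + rng.normal(0.0, 0.5, size=(n, 3))
            channels.append(gyro)
            sensor_types.append("gyroscope")
        else:
            channels.append(np.full((n, 3), np.nan))
        if "mag" in config.channels:
            mag = rot.apply(_EARTH_FIELD_UT) + rng.normal(0.0, 0.3, size=(n, 3))
            channels.append(mag)
            sensor_types.append("magnetometer")
    else:
        channels.append(np.full((n, 3), np.nan))

    meta = SensorMeta(
        device_type="synthetic-imu",
        sensor_types=tuple(sensor_types),
        sample_rate=fs,
        sensor_range={"accelerometer": 16.0 * GRAVITY, "gyroscope": 2000.0, "magnetometer": 100.0},
        placement=config.placement,
    )
    recording = SensorRecording(config.start, np.hstack(channels), meta, frame="uniform")
    return recording, GroundTruth(falls=truths, schedule=schedule)


# ---------------------------------------------------------------------------
# fall reports from truth (with seeded corruption)
# ---------------------------------------------------------------------------


def make_fall_report(
    truth: FallTruth,
    errors: ReportErrorModel,
    rng: np.random.Generator,
) -> tuple[FallReport, dict]:
    """Derive a (possibly corrupted) fall report from a truth record.

    Returns the report plus a truth-vs-reported summary for the manifest.
    """
    lag_min = float(rng.normal(0.0, errors.lag_sd_min))
    reported = truth.impact_datetime.add_seconds(lag_min * 60.0)
    date_error = bool(rng.random() < errors.date_error_p)
    if date_error:
        shift = int(rng.choice([-1, 1]))
        reported_date = reported.date + _dt.timedelta(days=shift)
    else:
        reported_date = reported.date

    u = float(rng.random())
    reported_time: _dt.time | None = _dt.time(reported.hour, reported.minute, reported.second)
    time_of_day: str | None = None
    if u < errors.date_only_p:
        form = "date-only"
        reported_time = None
    elif u < errors.date_only_p + errors.tod_only_p:
        form = "time-of-day"
        time_of_day = time_of_day_category(reported.seconds_of_day() / 3600.0)
        reported_time = None
    else:
        form = "exact"

    misdescribed = bool(rng.random() < errors.misdescription_p)
    activity = truth.pre_fall_activity
    direction = truth.direction
    if misdescribed:
        activity = str(rng.choice([a for a in ACTIVITIES if a != activity]))
        direction = str(rng.choice([d for d in _FALL_DIR if d != direction]))

    report = FallReport(
        fall_date=reported_date,
        reported_time=reported_time,
        time_of_day=time_of_day,
        pre_fall_activity=activity,
        fall_direction=direction,
        environment="indoors",
        report_latency_days=float(rng.uniform(0.0, 1.0)),
    )
    summary = {
        "true_impact": str(truth.impact_datetime),
        "reported_lag_min": lag_min,
        "date_error": date_error,
        "misdescribed": misdescribed,
        "form": form,
    }
    return report, summary


def description_matches(report: FallReport, truth: FallTruth) -> bool:
    """Oracle stand-in for the rater's correspondence judgment."""
    return (
        report.pre_fall_activity == truth.pre_fall_activity
        and report.fall_direction == truth.direction
    )


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------


def simulate_study(
    configs: list[SimulationConfig],
    out_dir: str | Path,
) -> dict:
    """Generate a directory of recordings, fall reports and a truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": []}
    for k, config in enumerate(configs):
        subject_id = f"sim{k:03d}"
        recording, truth = simulate_recording(config)
        rec_path = out / f"{subject_id}-recording.csv"
        write_recording(recording, rec_path)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA11]))
        entry = {
            "subject_id": subject_id,
            "recording": rec_path.name,
            "sample_rate": float(config.sample_rate),
            "falls": [],
        }
        for j, ft in enumerate(truth.falls):
            report, summary = make_fall_report(ft, config.report_errors, rng)
            rep_path = out / f"{subject_id}-fall{j + 1:02d}-report.yaml"
            rep_path.write_text(yaml.safe_dump(report.to_dict(), sort_keys=False))
            entry["falls"].append(
                {
                    "report": rep_path.name,
                    "impact_time_s": ft.impact_time_s,
                    "impact_datetime": str(ft.impact_datetime),
                    "direction": ft.direction,
                    "pre_fall_activity": ft.pre_fall_activity,
                    "mode": ft.mode,
                    "recovery_time_s": ft.recovery_time_s,
                    "report_truth": summary,
                }
            )
        manifest["subjects"].append(entry)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
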