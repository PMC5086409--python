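"""Locate candidate fall events in a uniform-frame recording.

The primary anchor is the start of the impact phase: a local minimum of the
vertical-axis acceleration (the free-fall dip) followed by a rapid rise as
the body strikes the ground.  "Rapid" is made operational as a configurable
policy: the vertical signal must climb by at least ``rise_threshold``
(default 1 g) within ``rise_window_s`` after the minimum, and the total
acceleration magnitude must exceed ``peak_threshold`` (default 2 g) within
``peak_window_s``.  When no impact is visible — low sample rate, soft fall —
the fall event is instead anchored at the first sustained change in posture.

Candidates closer together than the refractory period are merged (a single
fall produces several impacts: body, then head/arms); the candidate with the
larger peak magnitude represents the cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import medfilt

from . import timebase
from .orientation import posture_angle
from .signal_io import GRAVITY, FallReport, SensorRecording, TIME_OF_DAY_CATEGORIES

__all__ = [
    "IdentifiedEvent",
    "DetectionPolicy",
    "detect_impact_candidates",
    "detect_posture_changes",
    "identify_fall",
    "TIME_OF_DAY_HOURS",
]

#: clock intervals [start hour, end hour) for the reported time-of-day
#: categories; night wraps around midnight.
TIME_OF_DAY_HOURS: dict[str, tuple[float, float]] = {
    "morning": (6.0, 11.0),
    "noon": (11.0, 14.0),
    "afternoon": (14.0, 18.0),
    "evening": (18.0, 23.0),
    "night": (23.0, 30.0),  # 23:00 -> 06:00 next day
}


def time_of_day_category(hour_of_day: float) -> str:
    """Map a clock hour (0-24) to its reporting category."""
    h = hour_of_day % 24.0
    for name, (lo, hi) in TIME_OF_DAY_HOURS.items():
        if lo <= h < hi or lo <= h + 24.0 < hi:
            return name
    raise ValueError(f"hour {hour_of_day} not covered by any category")


def time_of_day_midpoint_s(category: str) -> float:
    """Seconds-of-day at the midpoint of a time-of-day category interval."""
    lo, hi = TIME_OF_DAY_HOURS[category]
    return ((lo + hi) / 2.0 % 24.0) * 3600.0


@dataclass(frozen=True)
class IdentifiedEvent:
    """A candidate fall event anchored at the impact-phase start."""

    index: int
    time_s: float
    abs_days: float
    mode: str  # "impact" | "posture-change"
    features: dict = field(default_factory=dict)
    rater: str | None = None

    def with_rater(self, rater: str) -> "IdentifiedEvent":
        return replace(self, rater=rater)


@dataclass
class DetectionPolicy:
    """Tunable thresholds for fall-candidate detection.

    Defaults: a 1 g vertical rise within 0.4 s of the local minimum (widened
    to 0.5 s at sample rates of 20 Hz and below, where the impact is spread
    over fewer samples), a 2 g total-magnitude peak within 1 s, and a 5 s
    refractory period between candidates.  Posture-change fallback requires
    a tilt transition from below ``posture_upright_max_deg`` to above
    ``posture_lying_min_deg`` sustained for ``posture_sustain_s``.
    """

    rise_threshold: float = GRAVITY          # m/s^2
    rise_window_s: float = 0.4               # s (rates > low_rate_max_hz)
    rise_window_low_rate_s: float = 0.5      # s (rates <= low_rate_max_hz)
    low_rate_max_hz: float = 20.0
    peak_threshold: float = 2.0 * GRAVITY    # m/s^2, total magnitude
    peak_window_s: float = 1.0
    refractory_s: float = 5.0
    median_kernel: int = 3
    posture_upright_max_deg: float = 30.0
    posture_lying_min_deg: float = 60.0
    posture_sustain_s: float = 5.0
    min_posture_change_deg: float = 45.0

    def rise_window_for(self, fs: float) -> float:
        return self.rise_window_low_rate_s if fs <= self.low_rate_max_hz else self.rise_window_s

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionPolicy":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _window_indices(recording: SensorRecording, window: tuple[float, float] | None) -> tuple[int, int]:
    n = recording.n_samples
    if window is None:
        return 0, n
    t0, t1 = window
    if t0 < 0 or t1 > recording.duration_s + 0.5 / recording.sample_rate or t0 >= t1:
        raise ValueError(
            f"search window ({t0}, {t1}) s outside recording of {recording.duration_s:.2f} s"
        )
    fs = recording.sample_rate
    return int(math.floor(t0 * fs)), min(n, int(math.ceil(t1 * fs)) + 1)


def _merge_refractory(
    events: list[IdentifiedEvent], refractory_s: float, strength: str
) -> list[IdentifiedEvent]:
    """Greedy time-cluster merge; the strongest candidate represents a cluster."""
    merged: list[IdentifiedEvent] = []
    cluster: list[IdentifiedEvent] = []

    def flush() -> None:
        if cluster:
            best = max(cluster, key=lambda e: (e.features.get(strength, 0.0), -e.index))
            merged.append(best)

    for ev in events:
        if cluster and ev.time_s - cluster[-1].time_s < refractory_s:
            cluster.append(ev)
        else:
            flush()
            cluster = [ev]
    flush()
    return merged


def detect_impact_candidates(
    recording: SensorRecording,
    window: tuple[float, float] | None = None,
    policy: DetectionPolicy | None = None,
) -> list[IdentifiedEvent]:
    """Scan for impact-phase starts in the vertical acceleration.

    A candidate sample ``i`` is a local minimum of the (3-sample median
    filtered) vertical acceleration with ``max(v[i+1 .. i+W]) - v[i] >=
    rise_threshold`` and ``max(|a|[i .. i+P]) >= peak_threshold``.  Candidates
    are returned in time order after refractory merging.
    """
    if recording.frame != "uniform":
        raise ValueError("impact detection requires a uniform-frame recording")
    policy = policy or DetectionPolicy()
    fs = recording.sample_rate
    i0, i1 = _window_indices(recording, window)
    n = recording.n_samples
    v = medfilt(recording.acc[:, 0], policy.median_kernel)
    mag = np.linalg.norm(recording.acc, axis=1)

    W = max(1, int(round(policy.rise_window_for(fs) * fs)))
    P = max(1, int(round(policy.peak_window_s * fs)))

    # forward-window maxima: fmax_v[i] = max(v[i .. i+W]); since v[i] <= v[i+1]
    # at a local minimum, this equals max(v[i+1 .. i+W]) there.
    pad_v = np.concatenate([v, np.full(W, -np.inf)])
    fmax_v = np.lib.stride_tricks.sliding_window_view(pad_v, W + 1).max(axis=1)
    pad_m = np.concatenate([mag, np.full(P, -np.inf)])
    fmax_m = np.lib.stride_tricks.sliding_window_view(pad_m, P + 1).max(axis=1)

    lo = max(i0, 1)
    hi = min(i1, n - 1)  # need v[i+1]
    idx = np.arange(lo, hi)
    if idx.size == 0:
        return []
    is_min = (v[idx] <= v[idx - 1]) & (v[idx] < v[idx + 1])
    hit = is_min & (fmax_v[idx] - v[idx] >= policy.rise_threshold) & (
        fmax_m[idx] >= policy.peak_threshold
    )
    start_days = recording.start_days()
    events: list[IdentifiedEvent] = []
    for i in idx[hit]:
        i = int(i)
        seg = v[i + 1: i + W + 1]
        rise_at = int(np.argmax(seg)) + 1
        events.append(
            IdentifiedEvent(
                index=i,
                time_s=i / fs,
                abs_days=start_days + (i / fs) / timebase.DAY_SECONDS,
                mode="impact",
                features={
                    "local_min": float(v[i]),
                    "rise_amplitude": float(fmax_v[i] - v[i]),
                    "rise_time_s": rise_at / fs,
                    "peak_magnitude": float(fmax_m[i]),
                },
            )
        )
    return _merge_refractory(events, policy.refractory_s, strength="peak_magnitude")


def detect_posture_changes(
    recording: SensorRecording,
    window: tuple[float, float] | None = None,
    policy: DetectionPolicy | None = None,
) -> list[IdentifiedEvent]:
    """Fallback anchor: the first sample of each sustained tilt transition.

    A transition qualifies when the low-pass tilt leaves the upright band
    (< ``posture_upright_max_deg``), reaches the lying band
    (> ``posture_lying_min_deg``) and stays there for ``posture_sustain_s``,
    with a total tilt change of at least ``min_posture_change_deg``.
    """
    if recording.frame != "uniform":
        raise ValueError("posture-change detection requires a uniform-frame recording")
    policy = policy or DetectionPolicy()
    fs = recording.sample_rate
    i0, i1 = _window_indices(recording, window)
    tilt = posture_angle(recording)
    lying = tilt > policy.posture_lying_min_deg
    upright = tilt < policy.posture_upright_max_deg
    sustain = max(1, int(round(policy.posture_sustain_s * fs)))

    # run-length encode the lying mask
    padded = np.concatenate([[False], lying, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    start_days = recording.start_days()
    events: list[IdentifiedEvent] = []
    for s, e in zip(starts, stops):
        if e - s < sustain or not (i0 <= s < i1):
            continue
        prior = np.flatnonzero(upright[:s])
        if prior.size == 0:
            continue  # never upright before: no transition to anchor
        p = int(prior[-1])
        onset = p + 1  # first sample out of the upright band
        change = float(np.median(tilt[s:min(e, s + sustain)]) - tilt[p])
        if change < policy.min_posture_change_deg:
            continue
        events.append(
            IdentifiedEvent(
                index=onset,
                time_s=onset / fs,
                abs_days=start_days + (onset / fs) / timebase.DAY_SECONDS,
                mode="posture-change",
                features={"posture_change_deg": change, "tilt_before": float(tilt[p])},
            )
        )
    return _merge_refractory(events, policy.refractory_s, strength="posture_change_deg")


def _reported_seconds_of_day(report: FallReport) -> float:
    if report.reported_time is not None:
        t = report.reported_time
        return t.hour * 3600.0 + t.minute * 60.0 + t.second + t.microsecond / 1e6
    if report.time_of_day is not None:
        return time_of_day_midpoint_s(report.time_of_day)
    return 12.0 * 3600.0  # date-only report: nearest-to-noon convention


def identify_fall(
    recording: SensorRecording,
    report: FallReport,
    policy: DetectionPolicy | None = None,
) -> tuple[IdentifiedEvent | None, int]:
    """Screen the recording for the fall described by a report.

    Impact candidates are searched on the reported calendar date first;
    posture-change candidates only when no impact is found.  Returns the
    candidate nearest the reported time (category reports use the interval
    midpoint, date-only reports noon) together with the number of plausible
    candidates on that date — more than one renders the fall not verifiable
    downstream.
    """
    policy = policy or DetectionPolicy()
    day = timebase.to_absolute_days(
        timebase.CalendarDateTime(report.fall_date.year, report.fall_date.month, report.fall_date.day)
    )
    absd = recording.absolute_days()
    mask = (absd >= day) & (absd < day + 1.0)
    if not mask.any():
        raise ValueError(
            f"report date {report.fall_date.isoformat()} not covered by the recording"
        )
    idx = np.flatnonzero(mask)
    fs = recording.sample_rate
    window = (idx[0] / fs, idx[-1] / fs)
    candidates = detect_impact_candidates(recording, window, policy)
    if not candidates:
        candidates = detect_posture_changes(recording, window, policy)
    if not candidates:
        return None, 0
    target = day + _reported_seconds_of_day(report) / timebase.DAY_SECONDS
    best = min(candidates, key=lambda e: abs(e.abs_days - target))
    return best, len(candidates)
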