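"""Cut the standardized fall window around a finally verified event.

The stored fall file spans 10 minutes before the impact-start sample and at
least 10 minutes after it; when a recovery movement (return to sustained
upright posture, or reappearance of walking-band dynamics) happens later
than 10 minutes post-impact, the window extends to cover it.  Windows are
truncated — with a logged warning — when the source recording is shorter.
Boundaries snap to whole samples toward the outside, so rounding never
shortens the nominal window.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .events import IdentifiedEvent
from .orientation import posture_angle
from .signal_io import FallSignalFile, FilenameFields, SensorRecording, build_fall_matrix
from .verification import Certainty

__all__ = [
    "PRE_FALL_S",
    "POST_FALL_MIN_S",
    "detect_recovery",
    "extract_fall_window",
]

logger = logging.getLogger(__name__)

PRE_FALL_S = 600.0       # 10 min of signal before the impact
POST_FALL_MIN_S = 600.0  # at least 10 min after it


def detect_recovery(
    recording: SensorRecording,
    from_s: float,
    upright_max_deg: float = 30.0,
    sustain_s: float = 10.0,
    walk_band_hz: tuple[float, float] = (0.5, 3.0),
    walk_var_threshold: float = 0.5,
    guard_s: float = 10.0,
) -> float | None:
    """Earliest recovery-movement time (s from recording start) after ``from_s``.

    Recovery is the posture returning upright (tilt < ``upright_max_deg``
    sustained for ``sustain_s``) or walking-band acceleration variance
    reappearing (rolling 2 s variance of the band-passed magnitude above
    ``walk_var_threshold`` (m/s^2)^2).  The first ``guard_s`` seconds after
    the impact are skipped so the impact transient itself cannot register.
    Returns ``None`` when no recovery occurs before the recording ends.
    """
    fs = recording.sample_rate
    n = recording.n_samples
    i_from = recording.index_at(from_s)
    i_start = min(n, i_from + int(round(guard_s * fs)))
    candidates: list[int] = []

    # sustained upright posture: first run of >= sustain_s below the tilt cap
    tilt = posture_angle(recording)
    win = max(1, int(round(sustain_s * fs)))
    upright = np.concatenate([[False], tilt < upright_max_deg, [False]])
    edges = np.flatnonzero(np.diff(upright.astype(np.int8)))
    for s, e in zip(edges[0::2], edges[1::2]):
        first = max(int(s), i_start)
        if int(e) - first >= win:
            candidates.append(first)
            break

    # walking-band dynamics: rolling variance of the band-passed magnitude
    mag = np.linalg.norm(recording.acc, axis=1)
    nyq = fs / 2.0
    hi = min(walk_band_hz[1], 0.95 * nyq)
    if hi > walk_band_hz[0] and n > 30:
        sos = butter(2, (walk_band_hz[0], hi), btype="band", fs=fs, output="sos")
        band = sosfiltfilt(sos, mag)
        w = max(2, int(round(2.0 * fs)))
        var = uniform_filter1d(band * band, size=w) - uniform_filter1d(band, size=w) ** 2
        ok = np.flatnonzero(var[i_start:] > walk_var_threshold)
        if ok.size:
            candidates.append(i_start + int(ok[0]))

    if not candidates:
        return None
    return min(candidates) / fs


def extract_fall_window(
    recording: SensorRecording,
    event: IdentifiedEvent,
    certainty: Certainty | int,
    random_id: str = "anon",
    fall_number: int = 1,
    recovery_s: float | None = "auto",  # type: ignore[assignment]
) -> FallSignalFile:
    """Cut the standard pre/post window around a finally verified impact.

    ``certainty`` (1-4) becomes the fall-indicator value at the impact-start
    sample.  ``recovery_s`` is the recovery time in seconds from the start of
    the recording; by default it is detected with :func:`detect_recovery`.
    """
    cert = int(certainty)
    if cert not in (1, 2, 3, 4):
        raise ValueError(f"certainty must be 1..4 to extract a fall file, got {certainty}")
    if recording.frame != "uniform":
        raise ValueError("extraction requires a uniform-frame recording")
    fs = recording.sample_rate
    n = recording.n_samples
    i_imp = event.index
    if not (0 <= i_imp < n):
        raise ValueError(f"impact sample {i_imp} outside recording")

    i0 = i_imp - int(math.ceil(PRE_FALL_S * fs))
    if i0 < 0:
        logger.warning(
            "pre-fall window truncated: recording starts %.1f s before the impact "
            "(nominal %.0f s)", i_imp / fs, PRE_FALL_S,
        )
        i0 = 0

    if recovery_s == "auto":
        recovery_s = detect_recovery(recording, event.time_s)
    post_s = POST_FALL_MIN_S
    if recovery_s is not None:
        post_s = max(POST_FALL_MIN_S, float(recovery_s) - event.time_s)
    i1 = i_imp + int(math.ceil(post_s * fs)) + 1
    if i1 > n:
        logger.warning(
            "post-fall window truncated: recording ends %.1f s after the impact "
            "(nominal %.0f s)", (n - 1 - i_imp) / fs, post_s,
        )
        i1 = n

    piece = recording.slice(i0, i1)
    matrix = build_fall_matrix(piece, (i_imp - i0, cert))
    timestamp = recording.start.add_seconds(i_imp / fs)
    fields = FilenameFields(random_id, fall_number, timestamp)
    return FallSignalFile(matrix, fields, recording.meta)
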